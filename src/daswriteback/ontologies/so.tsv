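# Sequence Ontology (SO) — bundled subset for feature TYPE suggestions
SO:0000001	region
SO:0000110	sequence_feature
SO:0000409	binding_site
SO:0000417	polypeptide_domain
SO:0000419	mature_protein_region
SO:0000691	cleavage_site
SO:0000839	polypeptide_region
SO:0001062	propeptide
SO:0001063	immature_peptide_region
SO:0001077	transmembrane_polypeptide_region
SO:0001079	polypeptide_structural_motif
SO:0001082	polypeptide_sequencing_information
SO:0001088	disulfide_bond
SO:0001089	post_translationally_modified_region
SO:0001093	polypeptide_binding_motif
SO:0001104	catalytic_residue
SO:0001114	peptide_helix
SO:0001117	alpha_helix
SO:0001121	pi_helix
SO:0001128	polypeptide_turn_motif
SO:0001129	asx_turn
SO:0001157	beta_turn
SO:0001159	beta_strand
SO:0100001	biochemical_region_of_peptide
SO:0100017	polypeptide_conserved_region
SO:0100019	polypeptide_variation_site
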