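# BioSapiens annotation vocabulary (BS) — bundled subset for feature TYPE suggestions
BS:00026	active_site
BS:00027	binding_site
BS:00028	metal_contact
BS:00031	disulfide_cross-link
BS:00034	glycosylation_site
BS:00035	lipidation_site
BS:00037	phosphorylation_site
BS:00042	sequence_conflict
BS:00043	sequence_variant
BS:00046	signal_peptide
BS:00048	transit_peptide
BS:00049	transmembrane_region
BS:00051	domain
BS:00052	repeat
BS:00054	coiled_coil
BS:00056	zinc_finger
BS:00073	secondary_structure
BS:00089	region
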