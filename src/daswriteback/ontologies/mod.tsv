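# Protein Modification ontology (PSI-MOD) — bundled subset for feature TYPE suggestions
MOD:00394	acetylated residue
MOD:00400	deamidated residue
MOD:00408	dihydroxylated residue
MOD:00412	hydroxylated residue
MOD:00427	methylated residue
MOD:00429	dimethylated residue
MOD:00430	trimethylated residue
MOD:00492	N6-acetyl-L-lysine
MOD:00675	oxidized residue
MOD:00693	glycosylated residue
MOD:00696	phosphorylated residue
MOD:00046	O-phospho-L-serine
MOD:00047	O-phospho-L-threonine
MOD:00048	O4'-phospho-L-tyrosine
MOD:00134	N-glycosylated residue
MOD:00167	O-glycosylated residue
MOD:00738	palmitoylated residue
MOD:00764	geranylgeranylated residue
MOD:01148	ubiquitinylation residue
MOD:01149	sumoylated lysine
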