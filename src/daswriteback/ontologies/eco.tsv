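# Evidence Code Ontology (ECO) — bundled subset for feature METHOD suggestions
ECO:0000001	inference from background scientific knowledge
ECO:0000002	direct assay evidence
ECO:0000006	experimental evidence
ECO:0000019	genomic context evidence
ECO:0000041	similarity evidence
ECO:0000044	sequence similarity evidence
ECO:0000053	computational combinatorial evidence
ECO:0000063	computational evidence used in automatic assertion
ECO:0000088	biological system reconstruction evidence
ECO:0000205	curator inference
ECO:0000218	manual assertion
ECO:0000248	sequence alignment evidence
ECO:0000250	sequence similarity evidence used in manual assertion
ECO:0000255	match to sequence model evidence used in manual assertion
ECO:0000269	experimental evidence used in manual assertion
ECO:0000303	non-traceable author statement used in manual assertion
ECO:0000305	curator inference used in manual assertion
ECO:0000313	imported information used in automatic assertion
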