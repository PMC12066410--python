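enzyme_name	amino_acid	direction	ammonia_product
urease	arginine	degradation	True
tryptophanase	tryptophan	degradation	True
glutamate decarboxylase	glutamate	degradation	False
alanine dehydrogenase	alanine	degradation	True
cysteine desulfurase	cysteine	degradation	True
branched-chain amino acid aminotransferase	leucine	degradation	False
ketoisovalerate oxidoreductase	valine	degradation	False
glutamine synthetase	glutamine	synthesis	False
aspartate aminotransferase	aspartate	interconversion	False
glutamate dehydrogenase	glutamate	reversible	True
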