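enzyme_name	broad_category	detailed_category	gh_family	pul_associated
ribosomal protein	gene expression	ribosome		False
RNA polymerase	gene expression	transcription		False
elongation factor Tu	gene expression	translation factors		False
chaperonin GroEL	stress and cell protection	protein folding		False
superoxide dismutase	stress and cell protection	oxidative stress		False
glyceraldehyde-3-phosphate dehydrogenase	monosaccharide metabolism	glycolysis		False
enolase	monosaccharide metabolism	glycolysis		False
glucokinase	monosaccharide metabolism	glycolysis		False
N-acetylneuraminate lyase	monosaccharide metabolism	amino sugar metabolism		False
glucosamine-6-phosphate deaminase	monosaccharide metabolism	amino sugar metabolism		False
pyruvate:ferredoxin oxidoreductase	fermentation	pyruvate metabolism		False
butyrate kinase	fermentation	short-chain fatty acid production		False
acetate kinase	fermentation	short-chain fatty acid production		False
urease	amino acid metabolism	urea hydrolysis		False
tryptophanase	amino acid metabolism	tryptophan degradation		False
glutamate decarboxylase	amino acid metabolism	glutamate degradation		False
alanine dehydrogenase	amino acid metabolism	alanine degradation		False
cysteine desulfurase	amino acid metabolism	cysteine degradation		False
branched-chain amino acid aminotransferase	amino acid metabolism	branched-chain amino acid degradation		False
ketoisovalerate oxidoreductase	amino acid metabolism	branched-chain amino acid degradation		False
glutamine synthetase	amino acid metabolism	glutamine synthesis		False
aspartate aminotransferase	amino acid metabolism	aspartate interconversion		False
glutamate dehydrogenase	amino acid metabolism	glutamate metabolism		False
endo-beta-N-acetylglucosaminidase	glycan degradation	protein deglycosylation	GH18	True
alpha-mannosidase	glycan degradation	mannan degradation	GH92	True
beta-galactosidase	glycan degradation	lactose and galactoside degradation	GH2	False
beta-hexosaminidase	glycan degradation	amino sugar release	GH20	True
alpha-fucosidase	glycan degradation	fucoside degradation	GH29	True
SusC outer membrane transporter	glycan degradation	polysaccharide utilization transport		True
SusD glycan-binding protein	glycan degradation	polysaccharide utilization transport		True
polyketide synthase	secondary metabolism	natural product biosynthesis		False
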