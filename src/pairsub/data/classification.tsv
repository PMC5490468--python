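# Amino-acid classification schemes (IMGT physicochemical classes,
# Pommie et al. 2004, J Mol Recognit 17:17-32).
# scheme	subgroup	residues
hydropathy	hydrophobic	ACFILMVW
hydropathy	neutral	GHPSTY
hydropathy	hydrophilic	DEKNQR
volume	very_small	AGS
volume	small	CDNPT
volume	medium	EHQV
volume	large	IKLMR
volume	very_large	FWY
chemical	aliphatic	AGILPV
chemical	aromatic	FWY
chemical	sulfur	CM
chemical	hydroxyl	ST
chemical	basic	HKR
chemical	acidic	DE
chemical	amide	NQ
charge	positive	HKR
charge	negative	DE
charge	uncharged	ACFGILMNPQSTVWY
hydrogen_don_acc	donor	KRW
hydrogen_don_acc	acceptor	DE
hydrogen_don_acc	both	HNQSTY
hydrogen_don_acc	none	ACFGILMPV
polarity	polar	DEHKNQRSTY
polarity	nonpolar	ACFGILMPVW
physicochemical	aliphatic	AILV
physicochemical	basic	HKR
physicochemical	sulfur	CM
physicochemical	hydroxyl	ST
physicochemical	acidic	DE
physicochemical	amide	NQ
physicochemical	G	G
physicochemical	F	F
physicochemical	P	P
physicochemical	W	W
physicochemical	Y	Y
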