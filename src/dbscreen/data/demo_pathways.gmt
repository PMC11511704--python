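HEMOSTASIS	platelet adhesion and granule release	ITGA2B	GP1BA	RAB27B	UNC13D	PROC	SERPINC1	SERPIND1
T_CELL_RECEPTOR	T-lymphocyte surface markers	CD2	CD3D	CD3E	CD5	CD247
NEUTROPHIL_DEGRANULATION	granulocyte granule proteins	ITGAM	ITGB2	CD33	CEACAM8	CTSG	MPO	ELANE	CYBA	CYBB
HEMOGLOBIN_COMPLEX	fetal and embryonic hemoglobin subunits	HBG1	HBG2	HBE1
COMPLEMENT_AND_COAGULATION	plasma protease cascades	SERPINC1	SERPIND1	PROC	HP
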