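adam_id	sh3_id	tier	previously_reported
ADAM8	SNX33	dominant	0
ADAM8	TOCA1	dominant	0
ADAM8	CIP4	strongly_selected	0
ADAM8	SNX9	strongly_selected	0
ADAM8	Tec	strongly_selected	0
ADAM8	Src	strongly_selected	0
ADAM8	NCF1(I)	significantly_enriched	0
ADAM8	OSTF1	significantly_enriched	0
ADAM9	SNX33	dominant	0
ADAM9	SNX9	dominant	1
ADAM9	Tec	strongly_selected	0
ADAM9	SNX18	strongly_selected	0
ADAM9	NCF1(I)	significantly_enriched	0
ADAM9	Lyn	significantly_enriched	0
ADAM9	ArgBP2(II)	significantly_enriched	0
ADAM12	Src	dominant	1
ADAM12	Nephrocystin	dominant	0
ADAM12	Lyn	strongly_selected	1
ADAM12	Tks5(V)	strongly_selected	1
ADAM12	Hck	strongly_selected	1
ADAM12	AHI1	strongly_selected	0
ADAM12	SNX33	significantly_enriched	0
ADAM12	SNX9	significantly_enriched	0
ADAM15	SNX33	dominant	1
ADAM15	Tks5(V)	strongly_selected	1
ADAM15	Src	strongly_selected	1
ADAM15	SNX9	strongly_selected	1
ADAM15	Nephrocystin	strongly_selected	1
ADAM15	Hck	strongly_selected	1
ADAM15	Tec	strongly_selected	0
ADAM15	Lyn	strongly_selected	1
ADAM15	Tks5(I)	strongly_selected	1
ADAM15	p85a	significantly_enriched	1
ADAM15	Btk	significantly_enriched	0
ADAM15	NCF1(I)	significantly_enriched	1
ADAM15	OSTF1	significantly_enriched	0
ADAM15	intersectin1(III)	significantly_enriched	0
ADAM19	Tks5(I)	dominant	0
ADAM19	Src	strongly_selected	0
ADAM19	RIMBP1(III)	strongly_selected	0
ADAM19	Eps8L1	strongly_selected	0
ADAM19	NCF1(I)	strongly_selected	0
ADAM19	Tec	significantly_enriched	0
ADAM19	Lyn	significantly_enriched	0
ADAM19	p85a	significantly_enriched	0
ADAM19	Nephrocystin	significantly_enriched	0
ADAM19	SNX33	significantly_enriched	0
ADAM19	TOCA1	significantly_enriched	0
ADAM19	SNX9	significantly_enriched	1
ADAM19	Tks5(V)	significantly_enriched	1
ADAM19	Hck	significantly_enriched	0
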