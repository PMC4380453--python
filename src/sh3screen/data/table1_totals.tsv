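adam_id	enrichment	reduction_libraries	total_clones	selected_domains
ADAM8	3000	5	332	8
ADAM9	>10,000	4	142	7
ADAM10	50	0	190	0
ADAM12	200	3	384	8
ADAM15	10,000	6	172	14
ADAM17	5	0	47	0
ADAM19	500	4	203	14
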