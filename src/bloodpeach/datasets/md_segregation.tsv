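cross	te_status	fdp_60_90	fdp_90_120	fdp_120_150	ratio	ratio_classes	chi2_printed	chi2_crit_printed
Yangzhou431(0/9) x Zhong07-4xi-28(0/9)	without_te	9	31	19	1:2:1	fdp_60_90,fdp_90_120,fdp_120_150	3.54	5.99
Yangzhou431(0/9) x Zhong07-4xi-28(0/9)	with_te	36	20	0	1:2:1	fdp_60_90,fdp_90_120,fdp_120_150	50.86	5.99
Zhaohui(0/0) x Zhong09-1xi-28(0/9)	without_te	6	50	75	1:1	fdp_90_120,fdp_120_150	4.39	3.84
Zhaohui(0/0) x Zhong09-1xi-28(0/9)	with_te	32	54	1	1:1	fdp_90_120,fdp_120_150	31.08	3.84
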