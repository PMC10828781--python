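blood_te	d_hap	t_hap	flesh
R1R2	D1D1	T1T1	dark
R1R2	D1D2	T1T1	blood
R1R2	D2D2	T1T1	light
R1R2	D2D2	T1T2	none
R2R2	D1D1	T1T1	none
R2R2	D1D2	T1T1	none
R2R2	D2D2	T1T1	none
R2R2	D2D2	T1T2	none
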