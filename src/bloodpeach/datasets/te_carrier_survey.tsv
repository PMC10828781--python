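group	category	n	carriers	percent_printed
Wild varieties	wild	13	0	0
Northwest China group	landrace	20	0	0
Yun-gui plateau group	landrace	18	0	0
Northeast China group	landrace	9	0	0
China North Plain group	landrace	20	7	35
Yangtze River middle and lower reaches group	landrace	22	10	45
South China subtropical area group	landrace	10	0	0
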