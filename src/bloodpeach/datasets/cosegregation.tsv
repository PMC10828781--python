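flesh	te_present	count
blood	true	143
none	false	190
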