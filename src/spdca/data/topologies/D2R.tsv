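label	category	start	end
N-Ter	N-terminal	1	37
ICL3	ICL	214	373
other	other	374	443
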