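label	category	start	end
ICL3	ICL	214	260
C-Ter	C-terminal	316	388
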