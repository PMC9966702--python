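label	category	start	end
N-Ter	N-terminal	1	8
ECL2	ECL	144	173
C-Ter	C-terminal	291	412
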