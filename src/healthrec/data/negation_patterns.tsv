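# trigger	direction	max_scope
no	FORWARD	6
no signs of	FORWARD	6
no sign of	FORWARD	6
no evidence of	FORWARD	6
without	FORWARD	6
absence of	FORWARD	6
in the absence of	FORWARD	6
did not provide evidence of	FORWARD	6
not	FORWARD	6
denies	FORWARD	6
denied	FORWARD	6
free of	FORWARD	6
negative for	FORWARD	6
ruled out	BACKWARD	6
rules out	FORWARD	6
excluded	BACKWARD	6
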