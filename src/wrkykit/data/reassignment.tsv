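name	label
RsWRKY3	IId
RsWRKY32	IIc
RsWRKY42	IIa
RsWRKY55	III
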