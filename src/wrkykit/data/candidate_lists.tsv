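stage	direction	gene
bud	up	RsWRKY21
bud	up	RsWRKY24
bud	up	RsWRKY33
bud	up	RsWRKY39
bud	down	RsWRKY2
bud	down	RsWRKY7
bud	down	RsWRKY17
bud	down	RsWRKY18
bud	down	RsWRKY26
bud	down	RsWRKY35
bud	down	RsWRKY36
bud	down	RsWRKY37
bud	down	RsWRKY38
bud	down	RsWRKY45
bud	down	RsWRKY47
bud	down	RsWRKY50
bud	down	RsWRKY52
full_bloom	up	RsWRKY10
full_bloom	up	RsWRKY27
full_bloom	up	RsWRKY41
full_bloom	up	RsWRKY51
full_bloom	down	RsWRKY13
full_bloom	down	RsWRKY25
full_bloom	down	RsWRKY26
full_bloom	down	RsWRKY29
full_bloom	down	RsWRKY49
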