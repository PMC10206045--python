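species	I	IIa	IIb	IIc	IId	IIe	III	total
Azalea	12	5	7	12	5	6	10	57
Rhododendron ovatum	15	5	8	15	7	9	9	68
Arabidopsis thaliana	13	4	7	18	7	9	14	72
Aquigelia coerulea	8	1	7	11	5	4	3	39
Amborella trichopoda	6	2	4	10	2	4	4	32
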