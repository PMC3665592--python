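# sigma54scan PWM v1
# n_sites: 186
# pseudocount: 0.5
# elements: -24=2,3; -12=14,15
pos	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16
A	0	0	0	0	186	0	0	46.5	46.5	46.5	46.5	0	0	0	0	93
C	0	0	0	186	0	186	0	46.5	46.5	46.5	46.5	0	0	0	186	0
G	0	186	186	0	0	0	186	46.5	46.5	46.5	46.5	0	0	186	0	0
T	186	0	0	0	0	0	0	46.5	46.5	46.5	46.5	186	186	0	0	93
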