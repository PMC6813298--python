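network	A	B	C	D	E	F	G	H	I	J	K	L	M	N	X
A	0.47	0.22	0.09	0.0	0.01	0.02	0.12	0.01	0.12	0.01	0.05	0.05	0.03	0.07	0.13
B	0.0	0.47	0.16	0.0	0.03	0.0	0.04	0.01	0.02	0.0	0.06	0.0	0.01	0.08	0.01
C	0.0	0.07	0.44	0.09	0.0	0.21	0.0	0.0	0.09	0.0	0.04	0.0	0.01	0.01	0.0
D	0.1	0.19	0.17	0.35	0.01	0.03	0.05	0.08	0.08	0.04	0.03	0.02	0.06	0.0	0.02
E	0.03	0.07	0.14	0.0	0.38	0.07	0.07	0.0	0.1	0.0	0.02	0.02	0.02	0.02	0.07
F	0.0	0.02	0.01	0.23	0.0	0.71	0.0	0.0	0.11	0.16	0.09	0.0	0.02	0.0	0.03
G	0.15	0.0	0.0	0.0	0.05	0.0	0.76	0.0	0.0	0.0	0.0	0.0	0.01	0.03	0.03
H	0.18	0.03	0.0	0.01	0.0	0.0	0.0	0.42	0.02	0.07	0.02	0.29	0.0	0.0	0.0
I	0.0	0.01	0.01	0.1	0.06	0.05	0.0	0.0	0.74	0.03	0.01	0.03	0.13	0.0	0.04
J	0.0	0.01	0.01	0.04	0.0	0.08	0.0	0.09	0.03	0.76	0.07	0.24	0.0	0.26	0.06
K	0.06	0.02	0.05	0.15	0.0	0.07	0.01	0.08	0.02	0.15	0.73	0.01	0.0	0.01	0.0
L	0.05	0.0	0.0	0.0	0.01	0.01	0.0	0.05	0.02	0.04	0.02	0.77	0.32	0.09	0.22
M	0.06	0.0	0.01	0.03	0.04	0.0	0.0	0.0	0.06	0.0	0.02	0.1	0.74	0.0	0.01
N	0.04	0.05	0.0	0.0	0.01	0.01	0.0	0.0	0.0	0.12	0.01	0.0	0.0	0.72	0.01
O	0.0	0.0	0.0	0.0	0.0	0.06	0.01	0.0	0.26	0.04	0.05	0.22	0.05	0.0	0.0
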