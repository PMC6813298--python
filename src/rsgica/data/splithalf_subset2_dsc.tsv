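network	A	B	C	D	F	G	H	I	J	K	L	N	Y	Z	V
A	0.41	0.09	0.1	0.05	0.01	0.05	0.0	0.16	0.0	0.03	0.04	0.09	0.27	0.18	0.11
B	0.0	0.34	0.31	0.01	0.06	0.03	0.02	0.11	0.0	0.04	0.0	0.03	0.0	0.23	0.16
C	0.0	0.03	0.52	0.22	0.0	0.0	0.0	0.12	0.0	0.02	0.0	0.0	0.06	0.0	0.04
D	0.08	0.05	0.01	0.5	0.07	0.05	0.09	0.05	0.03	0.04	0.04	0.01	0.08	0.13	0.02
E	0.05	0.0	0.04	0.06	0.06	0.06	0.01	0.02	0.0	0.02	0.02	0.02	0.1	0.14	0.11
F	0.0	0.0	0.06	0.02	0.32	0.0	0.12	0.0	0.09	0.12	0.0	0.0	0.19	0.0	0.01
G	0.14	0.0	0.0	0.01	0.0	0.77	0.0	0.03	0.0	0.0	0.0	0.02	0.09	0.01	0.02
H	0.35	0.0	0.0	0.05	0.0	0.0	0.56	0.0	0.14	0.02	0.13	0.0	0.02	0.0	0.16
I	0.0	0.0	0.01	0.04	0.25	0.0	0.07	0.37	0.04	0.1	0.03	0.0	0.09	0.01	0.08
J	0.02	0.0	0.01	0.03	0.11	0.0	0.13	0.0	0.73	0.04	0.15	0.27	0.06	0.0	0.06
K	0.12	0.0	0.18	0.12	0.06	0.01	0.05	0.0	0.08	0.55	0.0	0.01	0.01	0.0	0.08
L	0.06	0.0	0.0	0.01	0.08	0.0	0.11	0.0	0.21	0.0	0.81	0.12	0.0	0.03	0.14
M	0.04	0.0	0.0	0.03	0.15	0.0	0.0	0.0	0.0	0.0	0.22	0.0	0.0	0.0	0.05
N	0.04	0.03	0.02	0.01	0.0	0.0	0.0	0.03	0.0	0.0	0.03	0.85	0.0	0.03	0.02
O	0.01	0.0	0.0	0.0	0.01	0.01	0.01	0.07	0.08	0.18	0.18	0.0	0.11	0.0	0.17
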