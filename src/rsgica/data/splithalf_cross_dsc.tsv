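subset1	A	B	C	D	F	G	H	I	J	K	L	N	Y	Z	V
A	0.58	0.02	0.0	0.06	0.0	0.1	0.03	0.05	0.01	0.01	0.03	0.03	0.27	0.13	0.08
B	0.14	0.15	0.12	0.12	0.12	0.08	0.15	0.07	0.08	0.06	0.05	0.04	0.08	0.17	0.11
C	0.04	0.08	0.33	0.19	0.0	0.01	0.01	0.12	0.02	0.0	0.01	0.02	0.05	0.04	0.07
D	0.03	0.01	0.0	0.4	0.3	0.0	0.1	0.0	0.03	0.08	0.04	0.0	0.01	0.01	0.0
E	0.04	0.0	0.0	0.03	0.11	0.06	0.02	0.02	0.01	0.0	0.03	0.03	0.02	0.04	0.08
F	0.02	0.0	0.17	0.04	0.16	0.01	0.04	0.01	0.04	0.14	0.04	0.03	0.17	0.0	0.01
G	0.15	0.01	0.02	0.04	0.01	0.59	0.0	0.02	0.0	0.01	0.03	0.03	0.1	0.04	0.03
H	0.15	0.0	0.0	0.08	0.01	0.0	0.48	0.0	0.07	0.05	0.0	0.0	0.0	0.0	0.07
I	0.03	0.02	0.02	0.06	0.17	0.02	0.06	0.26	0.05	0.11	0.06	0.05	0.12	0.04	0.08
J	0.02	0.0	0.01	0.03	0.17	0.01	0.1	0.0	0.5	0.1	0.05	0.28	0.1	0.0	0.02
K	0.14	0.0	0.17	0.06	0.07	0.02	0.02	0.02	0.05	0.49	0.11	0.08	0.05	0.01	0.1
L	0.12	0.0	0.02	0.02	0.06	0.0	0.21	0.01	0.28	0.01	0.6	0.15	0.04	0.02	0.16
M	0.03	0.0	0.09	0.04	0.27	0.0	0.01	0.01	0.02	0.0	0.28	0.02	0.01	0.0	0.03
N	0.07	0.25	0.1	0.02	0.01	0.04	0.0	0.04	0.0	0.0	0.03	0.52	0.04	0.02	0.04
X	0.06	0.0	0.0	0.02	0.2	0.04	0.01	0.03	0.09	0.02	0.2	0.06	0.2	0.27	0.03
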