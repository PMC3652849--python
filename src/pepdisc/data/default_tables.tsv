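# Default discriminability tables and random-match probabilities.
# Intensity rows: 10 equal bins over normalized intensity [0,1) plus the
# base-peak category at exactly 1.0. m/z-error rows: 10 equal bins over
# [0,0.5] Da. Rows: b = plain b ions, y = plain y ions, s = all six ion
# types pooled (b, y and their H2O/NH3 losses).
[intensity]
row	0.0	0.1	0.2	0.3	0.4	0.5	0.6	0.7	0.8	0.9	1.0
b	1.14	2.61	4.03	5.29	5.95	6.21	6.98	6.63	5.24	4.69	3.67
y	4.03	13.39	23.69	30.40	29.95	26.05	26.32	31.62	37.41	48.42	35.63
s	1.48	1.96	2.05	2.21	2.34	2.39	2.26	2.31	2.43	2.57	3.09
[mz_error]
row	0.00	0.05	0.10	0.15	0.20	0.25	0.30	0.35	0.40	0.45
b	2.14	1.96	1.74	1.53	1.29	1.00	0.76	0.62	0.55	0.54
y	11.17	9.32	6.92	5.22	4.65	4.22	3.25	2.69	2.37	2.25
s	1.99	1.88	1.70	1.56	1.49	1.43	1.31	1.23	1.17	1.13
[constants]
p_frag	0.1406
p_consec	0.0279
p_by	0.0706
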