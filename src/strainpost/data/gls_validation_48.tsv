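# 48-subject paired GLS validation set (%), negative sign convention.
# a = EchoPAC (reference method), b = open post-processing tool (candidate).
# Transcribed as printed in the source table; the subject-19 candidate value
# is typographically suspect (see strainpost.io.load_gls_validation_pairs).
subject	gls_echopac	gls_postproc
1	-17.90	-17.88
2	-7.90	-9.50
3	-10.50	-11.10
4	-8.50	-8.19
5	-13.30	-13.55
6	-18.40	-18.26
7	-4.60	-4.21
8	-21.60	-21.48
9	-16.20	-16.36
10	-11.90	-11.41
11	-8.80	-7.33
12	-17.30	-17.23
13	-20.40	-20.32
14	-19.80	-19.40
15	-16.40	-15.27
16	-19.20	-19.38
17	-19.00	-19.03
18	-16.90	-16.82
19	-19.50	-16.68
20	-19.80	-19.83
21	-16.70	-17.04
22	-20.50	-20.93
23	-14.90	-14.71
24	-20.20	-19.76
25	-17.80	-18.19
26	-20.10	-20.47
27	-17.30	-17.60
28	-17.50	-16.96
29	-21.20	-20.28
30	-23.00	-23.06
31	-20.70	-19.91
32	-21.10	-21.22
33	-24.40	-24.62
34	-19.10	-19.57
35	-7.40	-6.46
36	-2.70	-3.37
37	-5.70	-5.22
38	-4.50	-4.32
39	-10.50	-9.83
40	-9.40	-10.95
41	-10.60	-10.47
42	-11.10	-11.15
43	-3.20	-3.69
44	-8.20	-8.64
45	-6.60	-6.01
46	-6.90	-6.85
47	-10.60	-10.11
48	-8.80	-9.28
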