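position	A	C	G	T
-3	0.33	0.37	0.18	0.12
-2	0.60	0.13	0.14	0.13
-1	0.08	0.04	0.81	0.07
+1	0.00	0.00	1.00	0.00
+2	0.00	0.00	0.00	1.00
+3	0.59	0.03	0.35	0.03
+4	0.71	0.08	0.12	0.09
+5	0.07	0.06	0.84	0.03
+6	0.16	0.17	0.19	0.48
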