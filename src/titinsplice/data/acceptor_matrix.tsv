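position	A	C	G	T
-14	0.11	0.30	0.10	0.49
-13	0.10	0.31	0.10	0.49
-12	0.10	0.30	0.11	0.49
-11	0.09	0.32	0.10	0.49
-10	0.10	0.31	0.09	0.50
-9	0.09	0.33	0.09	0.49
-8	0.09	0.34	0.08	0.49
-7	0.08	0.35	0.08	0.49
-6	0.08	0.36	0.07	0.49
-5	0.08	0.37	0.06	0.49
-4	0.24	0.31	0.21	0.24
-3	0.04	0.65	0.01	0.30
-2	1.00	0.00	0.00	0.00
-1	0.00	0.00	1.00	0.00
+1	0.25	0.15	0.50	0.10
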