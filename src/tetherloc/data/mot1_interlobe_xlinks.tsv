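# Inter-subdomain (RecA1-RecA2) lysine-lysine cross-links of the E. cuniculi
# Mot1 Swi2/Snf2 ATPase domain: Euclidean Ca-Ca distance of each linkage on
# the 'open', 'closed' and 'semi-closed' conformer models, with detection
# counts in the ADP-BeFx, ATPgS and ADP nucleotide datasets.
res_a	res_b	d_open	d_closed	d_semi-closed	n_ADP-BeFx	n_ATPgS	n_ADP
796	1013	16	22	20	1	1	1
796	1200	25	17	16	1	1	0
842	1055	58	52	52	0	1	0
864	1039	39	49	50	1	1	1
1003	1013	12	11	10	1	0	1
1003	1200	15	18	16	2	1	1
1008	1200	12	14	12	2	0	1
864	1200	34	24	24	1	1	1
919	1086	25	42	47	1	1	1
865	1200	31	20	21	1	1	0
919	1051	63	22	43	1	0	0
919	1055	57	19	36	2	2	0
919	1060	51	25	36	1	0	0
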