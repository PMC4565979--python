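# Published per-category cross-link counts for the Mot1:TBP:DNA:NC2 complex
# in three nucleotide states. 'total' includes redundant detections;
# 'nonredundant' counts unique lysine linkage pairs.
dataset	category	total	nonredundant
ADP-BeFx	crystal	46	42
ADP-BeFx	intralobe	21	17
ADP-BeFx	interlobe	15	12
ADP-BeFx	latch-crystal	8	8
ADP-BeFx	latch-ctd	5	5
ADP-BeFx	crystal-ctd	37	31
ADP-BeFx	ctd-linker	1	1
ATPgS	crystal	51	44
ATPgS	intralobe	17	14
ATPgS	interlobe	10	9
ATPgS	latch-crystal	11	11
ATPgS	latch-ctd	3	3
ATPgS	crystal-ctd	37	28
ADP	crystal	40	36
ADP	intralobe	14	11
ADP	interlobe	7	7
ADP	latch-crystal	11	10
ADP	latch-ctd	4	3
ADP	crystal-ctd	21	15
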