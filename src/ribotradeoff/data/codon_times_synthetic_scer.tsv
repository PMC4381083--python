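# Synthetic stand-in codon translation-time table (arbitrary units).
# Deterministic construction: a GC-content trend (GC-rich, G/C-balanced
# codons faster) plus a fixed codon-specific abundance component
# independent of composition; all 61 values distinct.
codon	time_au	source
AAA	100.68	synthetic_scer
AAC	100.91	synthetic_scer
AAG	86.44	synthetic_scer
AAT	119.47	synthetic_scer
ACA	104.2	synthetic_scer
ACC	98.61	synthetic_scer
ACG	75.13	synthetic_scer
ACT	107.75	synthetic_scer
AGA	109.94	synthetic_scer
AGC	65.42	synthetic_scer
AGG	65.63	synthetic_scer
AGT	96.64	synthetic_scer
ATA	139.43	synthetic_scer
ATC	79.86	synthetic_scer
ATG	124.71	synthetic_scer
ATT	127.42	synthetic_scer
CAA	118.47	synthetic_scer
CAC	74.65	synthetic_scer
CAG	90.1	synthetic_scer
CAT	113.4	synthetic_scer
CCA	109.74	synthetic_scer
CCC	50.17	synthetic_scer
CCG	49.17	synthetic_scer
CCT	107.92	synthetic_scer
CGA	100.67	synthetic_scer
CGC	61.77	synthetic_scer
CGG	51.12	synthetic_scer
CGT	88.78	synthetic_scer
CTA	124.08	synthetic_scer
CTC	71.94	synthetic_scer
CTG	92.9	synthetic_scer
CTT	83.94	synthetic_scer
GAA	119.92	synthetic_scer
GAC	69.98	synthetic_scer
GAG	114.95	synthetic_scer
GAT	82.79	synthetic_scer
GCA	80.7	synthetic_scer
GCC	76.41	synthetic_scer
GCG	75.54	synthetic_scer
GCT	67.0	synthetic_scer
GGA	72.67	synthetic_scer
GGC	60.56	synthetic_scer
GGG	60.65	synthetic_scer
GGT	98.55	synthetic_scer
GTA	97.62	synthetic_scer
GTC	92.16	synthetic_scer
GTG	110.15	synthetic_scer
GTT	109.75	synthetic_scer
TAC	98.6	synthetic_scer
TAT	128.03	synthetic_scer
TCA	124.52	synthetic_scer
TCC	86.51	synthetic_scer
TCG	87.62	synthetic_scer
TCT	90.76	synthetic_scer
TGC	92.31	synthetic_scer
TGG	74.09	synthetic_scer
TGT	112.2	synthetic_scer
TTA	140.86	synthetic_scer
TTC	112.81	synthetic_scer
TTG	85.48	synthetic_scer
TTT	98.19	synthetic_scer
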