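# Synthetic stand-in codon translation-time table (arbitrary units).
# Deterministic construction: a GC-content trend (GC-rich, G/C-balanced
# codons faster) plus a fixed codon-specific abundance component
# independent of composition; all 61 values distinct.
codon	time_au	source
AAA	111.92	synthetic_ecoli
AAC	117.81	synthetic_ecoli
AAG	108.21	synthetic_ecoli
AAT	118.86	synthetic_ecoli
ACA	102.06	synthetic_ecoli
ACC	106.52	synthetic_ecoli
ACG	109.01	synthetic_ecoli
ACT	88.32	synthetic_ecoli
AGA	119.02	synthetic_ecoli
AGC	75.23	synthetic_ecoli
AGG	116.75	synthetic_ecoli
AGT	130.18	synthetic_ecoli
ATA	134.35	synthetic_ecoli
ATC	120.96	synthetic_ecoli
ATG	107.73	synthetic_ecoli
ATT	141.2	synthetic_ecoli
CAA	108.13	synthetic_ecoli
CAC	82.06	synthetic_ecoli
CAG	74.72	synthetic_ecoli
CAT	91.9	synthetic_ecoli
CCA	92.75	synthetic_ecoli
CCC	67.5	synthetic_ecoli
CCG	76.58	synthetic_ecoli
CCT	60.23	synthetic_ecoli
CGA	84.65	synthetic_ecoli
CGC	60.1	synthetic_ecoli
CGG	50.66	synthetic_ecoli
CGT	89.1	synthetic_ecoli
CTA	104.24	synthetic_ecoli
CTC	76.73	synthetic_ecoli
CTG	67.73	synthetic_ecoli
CTT	125.05	synthetic_ecoli
GAA	128.8	synthetic_ecoli
GAC	94.19	synthetic_ecoli
GAG	83.61	synthetic_ecoli
GAT	133.37	synthetic_ecoli
GCA	91.97	synthetic_ecoli
GCC	64.72	synthetic_ecoli
GCG	90.99	synthetic_ecoli
GCT	74.51	synthetic_ecoli
GGA	103.68	synthetic_ecoli
GGC	58.34	synthetic_ecoli
GGG	59.49	synthetic_ecoli
GGT	100.16	synthetic_ecoli
GTA	93.74	synthetic_ecoli
GTC	84.66	synthetic_ecoli
GTG	93.6	synthetic_ecoli
GTT	87.77	synthetic_ecoli
TAC	122.21	synthetic_ecoli
TAT	128.05	synthetic_ecoli
TCA	116.2	synthetic_ecoli
TCC	82.31	synthetic_ecoli
TCG	81.07	synthetic_ecoli
TCT	105.32	synthetic_ecoli
TGC	84.0	synthetic_ecoli
TGG	99.59	synthetic_ecoli
TGT	110.14	synthetic_ecoli
TTA	121.2	synthetic_ecoli
TTC	78.06	synthetic_ecoli
TTG	122.5	synthetic_ecoli
TTT	123.19	synthetic_ecoli
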