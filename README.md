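# ribotradeoff

Genome-scale analysis of the trade-off between tRNA-abundance-based codon
translation times and mRNA secondary structure.

## The problem

Translation elongation speed along an mRNA is shaped by (at least) two
factors that are usually studied in isolation: how quickly the cognate
aminoacyl-tRNA of each codon can be delivered to the ribosome (fast for
codons read by abundant tRNAs, slow for rare ones), and how much local
secondary structure the ribosome has to unwind.  If genomes couple the two
— placing fast codons inside strongly structured regions and slow codons
in weakly structured ones — their opposing effects cancel and the overall
elongation rate is smoothed, which neither factor would reveal on its own.

`ribotradeoff` implements the full analysis pipeline for detecting and
quantifying this coupling, for computational biologists studying codon
usage, translation elongation, or synonymous gene design:

* **Sequence handling** — CDS loading from FASTA/GenBank, terminal
  trimming (first and last 51 nt = 17 codons removed before analysis),
  gene subsets (id lists, length bins).
* **Structure profiles** — experimental PARS-style per-nucleotide scores,
  or predicted minimum free energy (MFE) of a 101-nt centred sliding
  window; maximal high/low-structure regions by threshold (PARS > 0 vs
  ≤ 0; MFE < −35 vs > −20 kcal/mol) and minimum region length *R*<sub>l</sub>.
* **Elongation model** — codon translation-time tables (time ∝ 1/cognate
  aa-tRNA abundance, arbitrary units), per-gene speed profiles, 27-nt
  (9-codon, ≈ ribosome footprint) sliding-window smoothing.
* **The trade-off statistic** — codons assigned to regions by full
  containment; per-class time pools compared by medians:
  Δ*t* = median<sub>low</sub> − median<sub>high</sub> (positive when a
  trade-off exists), with IQRs and a two-sided Mann–Whitney test
  (tie-aware exact enumeration at small sample sizes).
* **Null models** — per-gene synonymous codon shuffling (protein and codon
  usage conserved) and whole-codon shuffling (codon usage conserved);
  structure recomputed per randomized genome; one-sample Wilcoxon
  comparison of the null score distribution against the observed score.
* **Expression analysis** — per-gene trade-off scores for synonymous
  variant libraries, Pearson correlation and least-squares fit against
  measured expression, and the codon adaptation index (CAI) as the
  whole-gene comparator.
* **Synthetic data** — a generator that plants the coupling at tunable
  strength β (high-structure blocks prefer each amino acid's fastest
  codon with probability β, low blocks the slowest), with an analytic
  expectation `expected_delta_t` for end-to-end validation.

Folding backends are pluggable: a fast, deterministic weighted
base-pair-maximisation engine (numba-compiled) is the default; ViennaRNA
is used via its Python bindings when available (`engine="vienna"`).

## Worked example

Generate a synthetic genome with a planted coupling (β = 0.6), then run
the high-vs-low comparison across minimum region lengths:

```python
from ribotradeoff import (
    SyntheticSpec, generate_genome, packaged_time_table, genome_tradeoff,
)
from ribotradeoff.sequence_io import trim_genome
from ribotradeoff.structure import ThresholdRule, load_structure_scores

table = packaged_time_table("synthetic_ecoli")
spec = SyntheticSpec(n_genes=100, gene_len_codons=200, beta=0.6,
                     time_table=table, seed=1)
genome = generate_genome(spec)
genome.write("demo_genome")

trimmed = trim_genome(genome.genes)
profiles = load_structure_scores("demo_genome/structure_scores.tsv", trimmed)
for rl in (10, 20, 30):
    res = genome_tradeoff(trimmed, profiles, table,
                          ThresholdRule.pars_default(rl), label=f"R_l={rl}")
    print(f"{res.label}: {res.n_regions_high} high / {res.n_regions_low} low regions, "
          f"median_high = {res.median_high:.1f} a.u., median_low = {res.median_low:.1f} a.u., "
          f"delta_t = {res.delta_t:.1f} a.u., p = {res.p_value:.3g}")
```

Output:

```
R_l=10: 857 high / 854 low regions, median_high = 88.3 a.u., median_low = 108.2 a.u., delta_t = 19.9 a.u., p = 0
R_l=20: 585 high / 621 low regions, median_high = 88.3 a.u., median_low = 109.0 a.u., delta_t = 20.7 a.u., p = 0
R_l=30: 409 high / 421 low regions, median_high = 88.3 a.u., median_low = 108.2 a.u., delta_t = 19.9 a.u., p = 0
```

Codons inside high-structure regions take a median 88.3 a.u. versus
108.2 a.u. in low-structure regions: the planted trade-off of roughly
20 a.u. is recovered at every region-length cut-off, with a
Mann–Whitney p below double-precision resolution given the ~10⁴ pooled
codons per class.

The same analyses run from the shell:

```sh
ribotradeoff synth --out demo_genome --seed 1 --n-genes 100 --beta 0.6
ribotradeoff table1 --config config.yaml --out results/
ribotradeoff randomize --config config.yaml --out results/ --seed 1
ribotradeoff expression --config config.yaml --out results/
```

See `ribotradeoff.cli`'s module docstring for the config-file keys, and
`docs/methods.md` for the model, parameter defaults, and design notes.

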