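# mitocup

Comparative mitogenomics and codon-usage-bias analysis for insect
mitochondrial genomes.

Insect mitogenomes are small circular chromosomes (~14–20 kb) carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one AT-rich control
region, split across the majority (J) and minority (N) strands.  Parasitoid
flies such as uziflies (Tachinidae) push this architecture to an extreme:
heavily AT-biased genomes, third codon positions that are >90% A/T, and
strongly biased synonymous codon choice.  `mitocup` is a toolkit for
quantifying that regime and asking what drives it — mutational pressure or
selection — for anyone comparing annotated mitogenomes across a species
panel.

## What it computes

Given annotated GenBank records (or genomes simulated by its own
generator), the pipeline derives:

- **Regions and boundaries** — intergenic spacers (IGS) and gene overlaps
  (OL) by circular interval arithmetic, gene orders normalized by rotation,
  and arrangement diffs against the ancestral dipteran order.
- **Composition and skews** — per region and strand,
  AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), and codon-position
  profiles (AT3, GC3, GC12 = (GC1+GC2)/2).
- **Codon usage under the invertebrate mitochondrial code** (translation
  table 5: Ser is one 8-fold family, Leu 6-fold; 62 sense codons, stops
  TAA/TAG) — RSCU (a codon's count over its family mean), GC3s, and the
  effective number of codons,
  ENc = Σ_k K_k / F̄_k over degeneracy classes k ∈ {2,4,6,8}
  with K = {12,6,1,1}, via either the plug-in homozygosity ("wright") or a
  pseudocount estimator ("sun2012").  Under table 5 the theoretical range
  is [20, 62].
- **Selection analyses** — the ENc-plot against the composition-only
  expectation ENc = 2 + s + 29/(s² + (1−s)²) at s = GC3s, and the
  neutrality plot (OLS of GC12 on GC3 across species per gene), whose slope
  m partitions codon-usage bias into mutational pressure M = 100·m % and
  selection/constraint N = 100 − M %.
- **Consensus motifs** — minimal IUPAC degenerate consensus of pre-aligned
  boundary regions (W = A/T, H = A/T/C, …).
- **Divergence** — pairwise synonymous/nonsynonymous rates (dS, dN,
  ω = dN/dS) by Nei–Gojobori counting: site fractions per codon position,
  equal-weight averaging over substitution pathways (stop-codon pathways
  excluded), Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p).
- **Regression suite** — linear, polynomial (AIC/BIC degree selection) and
  penalized-spline additive models of divergence rates on codon-usage
  indices, with 75/25 train/test splits, outlier filtering, test RMSE, and
  Breusch–Pagan / Shapiro–Wilk residual diagnostics.
- **Synthetic data** — a generator that realizes a 37-gene circular
  mitogenome in the ancestral dipteran arrangement with exact boundary
  plans, tunable AT3, incomplete stop codons and an AT-rich control region,
  plus genome pairs and panels diverged by known synonymous/nonsynonymous
  proportions.

## Worked example

Simulate a genome under the package's reference conditions (the published
uzifly annotation plan) and summarize it:

```sh
$ mitocup simulate --seed 42 -o uzifly.gb
wrote SYNBLEP01 (15080 bp) to uzifly.gb

$ mitocup summarize uzifly.gb | cut -f3-8,13,14
genome_bp  genome_at_pct  cr_bp  cr_at_pct  rrna_bp  rrna_at_pct  n_genes  total_codons
15080      78.57          168    95.24      2143     81.52        37       3722
```

A 15,080 bp circular genome, 78.6% A+T overall, with a 168 bp control
region and 3,722 PCG codons.  The boundary scan recovers the planned
spacers and overlaps — the 40 bp trnE–trnF spacer and the 8 bp trnW/trnC
overlap are the largest of each kind:

```sh
$ mitocup spacers uzifly.gb | awk -F'\t' '$5>=7' | cut -f2-5
upstream  downstream  kind  length
trnM      nad2        IGS   9
trnW      trnC        OL    8
atp8      atp6        OL    7
trnS1     trnE        IGS   19
trnE      trnF        IGS   40
nad5      trnH        IGS   15
nad4      nad4l       OL    7
trnS2     nad1        IGS   16
```

Per-gene codon-usage indices show the AT3-rich, low-ENc regime (an ENc
near 20 would mean one codon per family; near 62, no bias at all):

```sh
$ mitocup codon-usage uzifly.gb | head -4 | cut -f1-2,5-7,11,12
species    gene  at3    gc3    gc3s   enc_wright  enc_sun
SYNBLEP01  nad2  0.918  0.082  0.082  31.6        38.5
SYNBLEP01  cox1  0.898  0.102  0.102  32.2        37.6
SYNBLEP01  cox2  0.930  0.070  0.070  30.0        38.8
```

Other subcommands: `profile`, `encplot`, `neutrality`, `consensus`,
`divergence`, `regress` — each reads GenBank/FASTA/TSV and writes TSV plus
a JSON provenance record. The same operations are available as a library
(`import mitocup`).

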