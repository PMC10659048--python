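# vdjrep

Analysis pipeline for murine bone-marrow IgM heavy-chain repertoires, driven
by a mechanistic V(D)J recombination simulator.

The primary antibody repertoire is created during B lymphopoiesis when one
IGHV, one IGHD and one IGHJ gene segment are joined by V(D)J recombination.
The junction — spanning the conserved 2nd-CYS codon of V through the
conserved TRP codon of J — carries the imprints of the recombination
machinery: exonucleolytic trimming at the four coding ends (RAG1/2),
palindromic P nucleotides at untrimmed ends (Artemis), and nontemplated N
additions (TdT).  Stressors such as hindlimb unloading (HU, a ground model
of microgravity) and aging shift which IGHV segments are used — notably
along the distal/median/proximal zones of the murine *IGH* locus — and, with
age, the recombination imprints themselves.

`vdjrep` is for immunologists and simulation-minded analysts who want to

* simulate expressed IGH VDJ repertoires with ground truth, including
  condition knobs that emulate HU-like (distal-zone usage gradient) and
  aging-like effects (distal+median gradients, reduced IGHD trimming, longer
  N additions, more D–J palindromes);
* ingest annotated rearrangement tables (AIRR Rearrangement TSV, or
  IMGT/HighV-QUEST-style vocabularies via a column map), apply the
  expressed-repertoire retention rule (productive + CDR3 present, one
  representative per unique CDR3) and extract every categorical feature
  family the analysis compares;
* summarize each feature as a dispersion index and compare groups with the
  adaptive parametric/nonparametric decision tree used by common graphing
  software.

## The statistic

Each repertoire feature (segment usage, V×D×J associations, zone shares,
CDR3 length, CDR3 amino-acid composition, IGHD length, trims, palindromes, N
bins) is a frequency vector `p` over `K` categories.  Its **dispersion index**
is normalized Shannon evenness (Pielou):

    DI = H / ln K,   H = −Σᵢ pᵢ ln pᵢ

so DI = 0 when one category carries all mass (no diversity) and DI = 1 when
mass is uniform over the `K` categories (greatest diversity).  A normalized
Gini–Simpson evenness is available as an alternative metric.  Group
comparisons run per feature on per-library DIs: two groups use a Fisher
variance-ratio gate and a Lilliefors-corrected Kolmogorov–Smirnov normality
gate to choose Student *t* versus Mann–Whitney; three or more groups use
Bartlett and Shapiro–Wilk gates to choose one-way ANOVA + Tukey–Kramer
versus Kruskal–Wallis + Dunn (Bonferroni).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
cohorts (outputs land under `results/`):

```bash
python analysis/01_build_reference.py       # 130 functional IGHV, 15 D, 4 J
python analysis/02_simulate_cohorts.py      # 4 arms x 4 libraries x 10,000 seqs
python analysis/03_repertoire_features.py   # retention + 14 feature families
python analysis/04_dispersion_comparisons.py
```

`01` prints the reference composition:

```
functional segments: V=130 D=15 J=4
    distal:  81 IGHV (62.3%)
    median:  34 IGHV (26.2%)
  proximal:  15 IGHV (11.5%)
```

`04` prints, per comparison, the DI difference (condition mean − control
mean ± SD of per-library deviations), the gate-selected test and its p-value.
On the packaged effect sizes (seed 1):

```
HU vs control:
  v_usage            DI diff -0.010 +/- 0.001  [Mann-Whitney] p=0.0286 *
  v_usage_distal     DI diff -0.007 +/- 0.001  [           t] p=0.0000 ***
  v_usage_median     DI diff -0.001 +/- 0.000  [Mann-Whitney] p=0.2000 n.s.
  d_len              DI diff -0.000 +/- 0.001  [           t] p=0.9473 n.s.
  palindrome_dj      DI diff +0.006 +/- 0.010  [           t] p=0.2973 n.s.
  n_added_bins       DI diff +0.005 +/- 0.005  [           t] p=0.2423 n.s.

aged vs young:
  v_usage            DI diff -0.008 +/- 0.001  [           t] p=0.0000 ***
  v_usage_distal     DI diff -0.008 +/- 0.001  [           t] p=0.0000 ***
  v_usage_median     DI diff -0.009 +/- 0.001  [           t] p=0.0000 ***
  d_len              DI diff -0.132 +/- 0.001  [           t] p=0.0000 ***
  palindrome_dj      DI diff +0.264 +/- 0.003  [           t] p=0.0000 ***
  n_added_bins       DI diff -0.615 +/- 0.013  [           t] p=0.0000 ***
```

Reading: the HU-like knob moves overall IGHV usage through the distal zone
only, leaving recombination imprints (IGHD length, D–J palindromes, long N
additions) untouched, while the aging-like knobs move all of them — the
condition-specific signature the pipeline is designed to resolve.  IGHJ and
proximal-zone usage stay non-significant in both arms.

The same pipeline runs from a single config through the CLI:

```bash
vdjrep run --config analysis/demo_config.yaml --seed 1 --out results/demo
```

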