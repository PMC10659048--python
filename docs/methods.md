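# Methods

## Scope and design

`vdjrep` reconstructs, as a tested pipeline, a bone-marrow IgM heavy-chain
repertoire analysis: retention filtering and unique-CDR3 deduplication of
annotated VDJ rearrangements, extraction of the categorical feature families
the study compares, dispersion-index (DI) summaries, and an adaptive
parametric/nonparametric decision tree across experimental groups.  Because
the original sequencing libraries require external annotation services whose
databases drift, the pipeline is driven by a mechanistic V(D)J recombination
simulator with known ground truth; all validation is against that ground
truth plus closed-form oracles.

## Germline reference

A reference is a set of V/D/J segments with family, locus rank (1 = most 5',
i.e. distal), functionality, CDR3 anchor offsets (2nd-CYS for V, TRP for J)
and, for functional V segments, a locus zone (distal / median / proximal).
Zone assignment resolves gene-level entries first, then falls back to the
segment's family; an unresolvable gene is an error, never a silent default.
Allele suffixes (`*01`) are stripped on ingest — usage categories are genes.

The default synthetic reference carries 130 functional IGHV segments split
81/34/15 (62.3 / 26.2 / 11.5%) across the three zones, 15 IGHD and 4 IGHJ
segments — the zone composition of the functional murine IGHV set detected
in bone-marrow IgM libraries.  Sequences are random but seed-reproducible;
V segments are 48 nt with the CYS codon at offset 36 (a 9-nt trimmable 3'
tail), D segments 10–16 nt, J segments 21 nt with the TRP codon at offset 12
(a 12-nt trimmable 5' head).  These geometries put the simulated CDR3 mean
near 12 aa, the typical murine range.  The real murine zone boundaries are a
documented approximation configurable through the zone-map TSV.

## Generative model

One rearrangement is sampled as:

1. **Segment choice** — categorical draws of V, D, J with weights defaulting
   to uniform over functional segments.
2. **Trimming** — deletion lengths at the four coding ends (3'V, 5'D, 3'D,
   5'J) are truncated geometric, `P(T=t) ∝ p_trim^t` for `t = 0..max_trim`,
   further capped so anchors survive (`v3 ≤ tail−3`, `j5 ≤ head−3`,
   `d5+d3 ≤ len(D)`; invalid D pairs are resampled, and the exact-law oracle
   reproduces that conditioning by enumeration).  Defaults:
   `p_trim = 0.70/0.60/0.60/0.65` and `max_trim = 8/7/7/8` for v3/d5/d3/j5,
   giving mean deletions of roughly 1.5–2.3 nt per end.  A single-parameter
   memoryless law was chosen over empirical profiles because it scales
   cleanly under the aging knob.
3. **P nucleotides** — at each end with zero trimming, with probability
   `p_palindrome` (default 0.25 per end) the reverse complement of the
   terminal `max_p` nucleotides (default 2 — the short inverted repeats left
   by Artemis hairpin opening) is inserted.
4. **N additions** — Poisson lengths (default mean 4.0 per junction) of
   i.i.d. bases (uniform by default; GC bias configurable) at the V–D and
   D–J joins.
5. **Productivity** — a junction is productive iff its length is a multiple
   of 3, its translation is stop-free, and it is anchored C…W.  The three
   frame/stop outcomes carry an extra `anchor_mismatch` reason for in-frame
   stop-free junctions whose anchors are wrong (impossible for simulated
   records, possible for ingested data).  With `productive_only` (the
   default, emulating expressed IgM libraries) sampling rejects until the
   requested number of productive records is reached; a
   `nonfunctional_fraction` option retains a share of nonproductive records
   when mimicking raw libraries.

Every emitted record satisfies the decomposition identity
`len(junction) = (Vtail − v3) + p3v + n1 + p5d + (len(D) − d5 − d3) + p3d +
n2 + p5j + (Jhead − j5)` and P legality (P only at untrimmed ends).

**Condition knobs.**  `HU` scales distal-zone V weights; `aged` additionally
scales median-zone weights, multiplies `p_trim` at both D ends by
`d_trim_scale` (default 0.5: fewer IGHD nucleotides removed), both N means
by `n_mean_scale` (default 1.5; TdT acts at both junctions) and the D–J-side
palindrome probabilities by `p_dj_palindrome_scale` (default 1.5).  Zone
factors (default 2.5) act as a 5'→3' accessibility gradient within the
targeted zone — gene weight × `factor^w`, `w` linear from 1 at the zone's 5'
edge to 0 at its 3' edge — because a flat per-zone scalar renormalizes away
inside the zone and would leave the within-zone usage DI exactly unchanged;
a graded accessibility change along the locus is also the natural reading of
chromatin-mediated zone regulation.  These defaults are the packaged study
conditions; they were fixed by a design-stage power analysis so that, at 4
libraries per arm and n = 1500 unique sequences per library, the
condition-specific significance patterns are resolvable.

Two emergent couplings are worth knowing: reduced D trimming under `aged`
raises the share of untrimmed 5'D ends and therefore slightly raises V–D
palindrome rates too (the knob itself only touches the D–J side), and
trimming/selection makes IGHD *usage* weakly condition-sensitive even though
D weights are never scaled — both mirror qualitative observations in aged
repertoires.

## Ingest and retention

Tables are read from AIRR Rearrangement TSVs (or any TSV via a column map;
an IMGT/HighV-QUEST-style preset is included).  Retention keeps records that
are productive AND carry a CDR3, then deduplicates to one representative per
unique CDR3 (first occurrence; key = junction **nucleotide** sequence by
default, the stricter reading that preserves synonymous diversity;
amino-acid key available).  Junction decomposition columns (`x_`-prefixed)
absent from a source mark the table so that trim/P/N feature families are
skipped with a warning — never zero-filled.

## Features and category spaces

Fourteen families per library: V/D/J usage, V×J×(D∪{noD}) associations, zone
shares, per-zone V usage (renormalized within zone), CDR3 length (junction
aa minus the two anchors; support 1..30 with overflow), pooled amino-acid
composition for CDR3 lengths 11–14 (K = 20), retained-IGHD length, 3'V and
5'J trim distributions (capped support with overflow), V–D and D–J
palindrome presence (binary), and total N additions binned ≤6 / ≥7.
Frequency vectors always sum to 1 (±1e−9) or are marked empty.

Two K conventions: reference-defined spaces (usage per class, zone shares,
the 20 amino acids, binary bins) have fixed K so unused categories count;
observed spaces (associations, CDR3 lengths, D lengths, trims) take K as the
union of categories observed across the libraries being compared, resolved
at comparison time.  Composition is pooled across CDR3 positions rather than
per-position: it is the simplest statistic yielding one 20-category vector —
and hence one DI — per length class.

## Dispersion index and decision tree

DI = Pielou evenness `H / ln K` (natural logs; `0·ln 0 ≔ 0`; K = 1 → DI ≔ 0),
bounded [0, 1] with 0 = degenerate and 1 = uniform.  The metric sits behind
one function and a normalized Gini–Simpson evenness is provided as an
alternative.  Verified properties: endpoint closed forms, invariance under
category relabeling, and transfer monotonicity (moving mass from a more- to
a less-frequent category never decreases DI).

Two-group comparisons gate on a two-sided Fisher variance-ratio test and
Lilliefors-corrected KS normality per sample (Shapiro–Wilk below the
Lilliefors n = 4 minimum); both pass at α → Student *t*, else Mann–Whitney.
Zero-variance samples skip the gates and go nonparametric.  Multi-group
comparisons gate on Bartlett + per-group Shapiro–Wilk; pass → one-way ANOVA
with Tukey–Kramer pairwise post hocs, else Kruskal–Wallis with Dunn's rank
post hoc (tie-corrected, Bonferroni-adjusted).  α = 0.05 throughout.  Group
summaries report mean ± SD (SEM also emitted); the "DI difference" for a
(control, condition) pair is the mean of per-condition-library deviations
from the control mean, ± the SD of those deviations.

## Validation design

* **Simulator structure** — decomposition identity, P legality and
  non-negative retained D over 50,000 unselected records.
* **Parameter recovery** — 20 randomized configs (usage weights, per-end
  trim and palindrome parameters, N means), n = 20,000 records each,
  measured through the feature layer and compared to *exact* expectations
  derived from the ground-truth snapshot (truncated-geometric mixtures,
  the D-joint conditioning, Poisson tails), as z-scores.  Recovery runs with
  `productive_only=False` and without dedup: productivity selection tilts
  the generative law (each extra codon survives the stop filter with
  probability ~61/64, biasing N means low and favoring V genes with less
  stop-prone tails — a ~4.5 SE artifact at this n), so generative parameters
  are only identifiable from raw records.  With ~260 simultaneous 3σ checks,
  roughly one benign excursion beyond 3 SE is *expected* from sampling alone
  (P(all within 3σ) ≈ 0.5); the reproduction script therefore reports the
  fraction within 3 SE and the maximum |z|.
* **Null calibration** — 200 replicates of two identical-condition arms
  (4 libraries × 400 sequences) through the full simulate→ingest→features→
  compare path; the v_usage rejection rate at α = 0.05 lands in [0.025,
  0.075].
* **Effect patterns** — 50 replicates per condition at 4 libraries × 1500
  sequences: aged must shift v_usage, distal and median zone usage, IGHD
  length, D–J palindromes and the ≥7-N bin; HU only v_usage and distal
  usage, with the remaining families non-significant.  Each feature's
  expected status is required in ≥80% of replicates; per-feature null
  rejection rates were measured at 2–5%.

## What the synthetic data does and does not show

The simulator emulates segment choice, trimming, P/N addition and
productivity selection with condition-dependent parameter shifts.  It does
**not** model somatic hypermutation, clonal expansion (the pipeline analyzes
unique CDR3s precisely because clonal structure is unresolvable in such
libraries), sequencing error, chimeras, light chains or class switching, and
its trim law is a convenience rather than an empirical profile.  Passing
tests therefore demonstrate that the *pipeline* — filters, features, DI,
decision tree — is correct and well calibrated, and that effects injected at
the recombination level propagate to the statistics that detect them; they
do not certify biological parameter values.

## Numerical and reproducibility choices

Frequency sums are validated to 1e−9 (1e−6 at the DI boundary); DI is
clipped to [0, 1] against rounding.  All randomness flows from
`numpy.random.default_rng` seeds; multi-library runs derive child seeds via
`SeedSequence.spawn`, so every table is byte-stable for a fixed seed
(timestamps confined to the run log).  Rejection sampling aborts with a
diagnostic if productive acceptance falls below 1%.  Degenerate inputs:
empty repertoires produce empty-marked vectors that comparisons skip;
zero-variance DI lists route to the nonparametric branch; single-category
spaces have DI 0 by convention.
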