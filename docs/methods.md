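# Methods

## Problem and model

The package classifies protein sequences at two levels: a binary
decision (nuclear receptor vs not) gating an eight-way subfamily
assignment (NR1..NR8).  Both levels are soft-margin SVMs with the RBF
kernel `K(x, y) = exp(−γ‖x−y‖²)`; the multiclass level uses the
one-vs-one decomposition native to the LibSVM family.  Class weighting
is not applied.  Probability estimation is off throughout; ROC analysis
uses the real-valued decision function.

The underlying assumption is purely compositional: membership in the NR
family, and in a subfamily, is detectable from short-range residue
composition statistics — the frequencies of single residues (AAC), of
ordered residue-class triads (CTF), and of the coarse spatial
distribution of a chaos-game walk (CGR) — without alignment or domain
detection.

## Encoders

**AAC.**  `fᵢ = nᵢ/L` over the 20 residues in alphabetical one-letter
order.  Order must be fixed somewhere; alphabetical is self-documenting.

**CTF.**  The seven-class reduced alphabet is, in fixed group order,
{AGV}, {ILFP}, {YMTS}, {HNQW}, {RK}, {DE}, {C} (grouping by side-chain
dipole and volume).  Triad bins are ordered lexicographically with the
first window position most significant:
`index(c₁,c₂,c₃) = (c₁−1)·49 + (c₂−1)·7 + c₃`, which is bijective over
1..343 and makes the tab-delimited headers (`C-RK-AGV` etc.)
self-describing.  Any fixed bijection only permutes columns; published
orderings of the same 343 triads may differ by such a permutation.
Normalisation is by the window count `L−2`, so sequences shorter than
three residues are a domain error for CTF (and for every combined set
containing it); AAC and CGR accept `L ≥ 1`.

**CGR.**  Vertex k of the regular 12-gon sits at
`(cos((k−1)π/6), sin((k−1)π/6))`; the walk starts at the centre and each
residue moves the point halfway toward its class vertex, so every
trajectory point is a strict convex combination of an interior point
and a unit-circle vertex and stays strictly inside the disc.  Two
geometric conventions are not uniquely determined by the construction
and are fixed here as package defaults:

* *Segments.*  The 24 segments are equal angular sectors of width π/12,
  sector k covering `[(k−1)π/12, kπ/12)` counter-clockwise from the
  positive x-axis.  A point exactly on a boundary ray is assigned to the
  lower-index adjacent sector, with sector 1 owning angle 0 (the
  construction itself allows boundary points to be counted in either
  neighbour, so any total rule is admissible; this one is deterministic
  and total).  Boundary detection tolerates floating-point rounding to
  1e−9 of a sector width, because on-axis walks land an ulp on either
  side of the ray.
* *Vertex groups.*  The twelve residue groups are a required
  configuration parameter; the shipped default is the
  conservative-substitution partition {A}, {G}, {P}, {C}, {S,T}, {D,E},
  {N,Q}, {H}, {K,R}, {M}, {I,L,V}, {F,Y,W} assigned to vertices 1..12 in
  that order.  Any 12-group partition can be loaded from a small text
  config instead.  Different partitions (or segment numberings) permute
  or change the 24 features; models and encodings must therefore share
  one config, which the serialized model records.

Encoder outputs are frequencies in [0,1], each block summing to 1; no
further standardisation layer is applied.

## Cascade defaults and tuning

Tuned `(γ, C)` pairs per feature set ship as defaults for the subfamily
level (e.g. CTF: γ=0.0192, C=11.0849; AAC+CTF: γ=0.0159, C=10.3440).
The binary level has a published pair only for AAC+CTF (γ=0.1899,
C=10.1197) and falls back to the subfamily-level pair for the other
feature sets.  These constants were tuned on a curated real benchmark;
on other data (including the synthetic benchmark here) they can
underfit badly — frequency vectors concentrate near each other and a
small γ makes the kernel matrix nearly constant.  `grid_search` /
`tune_level` therefore provide the protocol's own parameter search: an
exhaustive sweep over log-spaced grids (default γ ∈ 2^{−9..5},
C ∈ 2^{−1..9}, odd exponents) scored by mean stratified k-fold CV
accuracy, ties broken toward smaller C then smaller γ.  Tuning is done
once on the level's full data and the chosen pair is then used inside
the reported 10-fold CV, mirroring how tuned "optimal parameters" are
conventionally reported alongside CV accuracy for this kind of
benchmark; the small optimistic bias this induces is irrelevant at the
separation levels involved, but worth remembering on marginal data.

## Evaluation protocol

Binary metrics from the confusion table: Sens = TP/(TP+FN),
Spec = TN/(TN+FP), Acc = (TP+TN)/total, and Matthews correlation with
the convention MCC = 0 whenever a factor under the square root
vanishes.  Multiclass metrics use one-vs-rest per-class counts
(TP(i) = N⁺(i) − misses-out, etc.); overall sensitivity is total
correct over total N, and overall Spec/Acc/MCC apply the binary
formulas to the micro-pooled one-vs-rest counts summed over classes —
one defensible convention among several, recorded here because
"overall MCC" is otherwise ambiguous.

K-fold CV is stratified by default (the smallest subfamily has 7
members; plain random 10-fold partitions would routinely lose it from
training folds) with a plain-random option.  A class smaller than k
triggers a warning, not an error, and may be absent from some folds —
the benchmark's own shape requires tolerating this.  Reported fold
averages are arithmetic means of per-fold metrics; pooled-confusion
metrics over the union of held-out predictions are emitted alongside,
since the two conventions differ slightly and either might be wanted.
The jackknife (leave-one-out) path is deterministic and order-invariant
and reports pooled counts only (per-fold metrics are degenerate at
fold size 1).  AUC is computed for the binary level only; no multiclass
AUC is defined.

Reports print at 4 decimal places; full precision is retained
internally.

## Feature ranking

Per-feature two-sided Wilcoxon rank-sum p-values between the two
groups, by the normal approximation with mid-ranks and tie-corrected
variance (triad frequency columns are zero-heavy, so ties are the rule,
and p-values as small as 1e−100 are only reachable asymptotically).
An exact-distribution option is selected automatically when both groups
have ≤ 10 samples.  Degenerate columns (identical in both groups) get
p = 1.  The census of features below a threshold (default p < 0.01) is
reported on raw p-values; a Bonferroni-adjusted census is available as
a clearly separate extension.  Ranking is by ascending p with ties
broken by ascending column index; top-k selection and its complement
(ablation) partition the feature set for every k — for the 343 triad
features and k = 50, ablation leaves 293 columns.

## Synthetic benchmark

`default_benchmark(seed)` emulates only the *shape* of a curated NR
benchmark: 474 positives over eight subfamilies with sizes
(162, 140, 82, 23, 29, 7, 21, 10) and 500 negatives, lengths uniform on
[100, 400] (typical single-domain-to-receptor lengths), residues i.i.d.
uniform over the 20 amino acids (a composition-matched background is
configurable).  Class identity is planted by overwriting random
positions with 3-mer motifs: every positive carries four shared
reduced-space motifs (`C-RK-AGV`, `AGV-C-RK`, `C-AGV-DE`, `DE-AGV-C`,
expected 6 copies each per sequence, Poisson-distributed) as the
NR-vs-non-NR signal, plus two subfamily-specific motifs (expected 8
copies each); negatives are pure background.  Motif weights are the
expected copy number per sequence, so the planted CTF component means
grow monotonically with weight and the planted triads dominate the
rank-sum ranking.

What passing on this benchmark shows: the encoders, cascade, CV
machinery, and ranking recover planted compositional structure at
realistic sample sizes, end to end.  What it does not show: performance
on real NR sequences — real subfamilies differ by domain architecture
and phylogeny, not by i.i.d. triad enrichment; real sequence identity
within subfamilies, shared motifs between subfamilies, and non-NR
proteins with NR-like composition all make the real task harder.
Headline accuracies from the curated benchmark (e.g. ~96 % level-1 CV
accuracy) are properties of that dataset and are not asserted anywhere
in this package's tests; `run_benchmark_protocol` will reproduce the
full report structure on the real data when a labeled FASTA of it is
supplied.

## Numerical and interface choices

* Residue policy for non-standard letters (B, J, O, U, X, Z, `*`,
  gaps): default `strip-residue` (drop the letter, keep the record,
  warn) — the encoders are frequency-based, so stripping preserves the
  most data; `strict` and `skip-record` are selectable.
* Sequence ids are the first whitespace-delimited header token; labels
  come canonically from a two-column TSV, optionally from headers via a
  delimiter.
* Feature matrices are tab-delimited with stable headers (residue
  letters, `S1..S24`, triad class labels); values are written with
  `repr` so a write/read round-trip is exact.
* Model archives store both SVMs, the encoder spec, alphabet configs,
  the seed and the package version; loading reproduces bit-identical
  predictions.
* All randomness (generation, fold shuffling, grid-search folds) flows
  from explicit integer seeds; identical seeds give identical outputs.

## Problem sizes in the shipped analyses

The test suite and the acceptance script run the full 474+500 benchmark
for the cascade CV and the feature census, a 20-seed (tests) or 10-seed
(script) sweep for planted-triad recovery, and smaller collections
(40–160 sequences) for the jackknife and CLI paths — sizes chosen so
the complete analysis re-runs comfortably on a single CPU while keeping
every class populated.

## Known limitations

* The 24-segment numbering and the 12 vertex groups of the chaos-game
  encoder are package conventions (see above); CGR features from other
  implementations are comparable only after aligning both conventions.
* The rank-sum normal approximation is anti-conservative for very small
  groups; the exact option covers n ≤ 10 but ignores ties.
* Grid search refits one SVM per grid point per fold; on large
  collections prefer the coarse default grid before refining.
* The cascade propagates level-1 errors: a false negative at level 1
  can never be recovered at level 2.  Level-2 metrics are therefore
  reported on the true-NR subset, matching the two-level reporting
  convention, and end-to-end cascade agreement is available separately.
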