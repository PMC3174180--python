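# Methods

## Coordinates and pairing rules

Sequences are handled 5'→3' in the RNA alphabet; UTR positions are
1-based with closed intervals. With miRNA position 1 aligned to UTR
position `p1`, the antiparallel duplex places miRNA position `k` opposite
UTR position `p1 − (k − 1)`. A base pair is Watson-Crick (A:U, U:A, G:C,
C:G) or a G:U/U:G wobble; anything else is unpaired.

A 6mer core is a UTR window pairing miRNA positions 2–7 or 3–8 with at
most one wobble. Upgrades apply to 2–7 cores only: the position-8 upgrade
demands a Watson-Crick pair (a wobble does not qualify), and the A1
anchor is an identity test for `A` on the target, not a pairing test —
3–8 cores are detected but never upgraded, since the 7/8mer classes are
defined on the 2–7 core. Overlapping windows each yield their own site;
one occurrence has exactly one category (upgrades replace, never
duplicate). The *effective* site of a pair is the strongest one
(8mer > 7mer-m8 > 7mer-A1 > 6mer, ties to fewer wobbles, then the
smallest start).

3'-supplementary pairing is a binary flag: all four UTR bases opposite
miRNA positions 13–16 Watson-Crick paired in the site's register; extra
pairing at positions 12/17 is retained as a count in the site context but
does not change the flag. The AU-rich flag pools up to 30 nt on each side
of the site (truncated at the UTR ends, site excluded) and fires at
≥60% A+U; an empty pool yields 0.

## Feature catalog

The 90 features are indexed 1–90 in seven categories of sizes
12/4/4/16/16/6/32. Nucleotides are ordered A, U, G, C; dinucleotides are
the 16 ordered pairs in that order; seed base pairs are ordered
A:U, U:A, U:G, G:C, G:U, C:G (miRNA:target); base-pair bigrams (read
5'→3' along the miRNA) use block order A:U, U:A, G:C, C:G, G:U, U:G for
each member with the four double-wobble combinations excluded — a site
carries at most one wobble, so they cannot occur, leaving exactly 32.
Category 1 is a 4+4+4 block over the site classes (6mer, 7mer-m8,
7mer-A1, 8mer): per-class site counts on the whole UTR, then the
supplementary-pairing flag and the AU-rich flag of each class's effective
site. Categories 2–7 are computed on the overall effective site and its
flanks; flank dinucleotides are counted per flank (never spanning the
site). Seed base-pair counts run over the *required* positions (2–7, or
2–8 when position 8 is part of the match; 3–8 for a 3–8 core), so their
sum is 6 or 7 and the bigram sum is one less — both are tested
invariants.

"Frequency" means a raw count within its region. Regions have
near-constant length (6–8 nt sites, ≤60 nt pooled flanks), counts keep
the features integer and exactly testable, and the classifier's min-max
scaler absorbs the scale. The composition of category 1 is the one block
whose exact published ordering is not fully pinned; the 4+4+4 layout
above is this package's declared convention and satisfies the published
size (12) and the published name of index 6.

## Classifier

`sklearn.svm.SVC` with the RBF kernel, fit tolerance 1e−3, shrinking on.
Features are min-max scaled to [0, 1] on training data only; the scaler
is stored in the model, and scoring applies mask → scaler → decision
function. The decision value is the prediction score; class = sign, with
an exact 0 assigned to the negative class (conservative on targets).
Defaults C = 1.0 and γ = 0.1 come from a distance-scale argument: for
min-max-scaled vectors of a few dozen features, typical squared distances
are of order 10, so γ ≈ 0.1 keeps the kernel responsive; both are
configurable and `grid_select` picks (C, γ) on a held-out validation set
from the classic exponential grid C ∈ {2⁻⁵ … 2¹⁵}, γ ∈ {2⁻¹⁵ … 2³}
(ties to the smallest C, then γ).

Cross-validated objectives use stratified k-fold (k = 5) with a seeded
shuffle and pool the confusion counts over folds before computing
(Sn, Sp, MCC) — micro aggregation is robust when folds contain few
negatives; per-fold averaging is the main alternative and differs only
at the third decimal on balanced data. MCC's zero-denominator convention
is 0. AUC is the rank-based (Mann-Whitney) statistic with half credit
for ties.

## AMOSA

Solutions are fixed-length bitstrings with ≥1 set bit; objectives are
maximized. The archive is mutually non-dominated at all times, with a
soft limit SL and hard limit HL ≤ SL; exceeding SL triggers
single-linkage clustering in objective space down to HL clusters, each
represented by its member of minimum average distance (ties to the
lexicographically smallest bitstring). Initialization draws `n_init`
random bitstrings, hill-climbs each for `hc_iters` single-bit-flip steps
(accepting only dominating neighbors), and keeps the non-dominated
survivors.

Annealing perturbs the current point by one uniformly chosen bit flip
(re-flipped if the result is all-zero) and applies three cases: a new
point that dominates the current one is accepted (and archived if no
member dominates it, displacing members it dominates); a dominated new
point is accepted with probability 1/(1 + exp(Δdom/T)), where Δdom
averages the amount of domination of the current point and any
dominating archive members over it; a mutually non-dominating new point
is accepted and archived when the archive does not dominate it, else
accepted with the same probabilistic form. The amount of domination is
the product of |aᵢ − bᵢ|/Rᵢ over differing objectives, with Rᵢ the
running min/max range of objective i (floored at 1e−6) — the objective
ranges are never known a priori for (Sn, Sp, MCC). Temperature cools
geometrically by α from Tmax to Tmin. All randomness flows from one
seeded generator, so runs are exactly reproducible.

## Feature selection and analytics

`select_features` runs AMOSA with the 5-fold-CV (Sn, Sp, MCC) evaluator
(cached by bitstring) and picks the archive member with the highest
pooled-CV accuracy on the balanced training data (ties: larger MCC,
fewer features, lexicographically smallest bits). `common_features`
returns the indices present in ≥ ceil(threshold·|archive|) members
(default 90%); the feature selection ratio (FSR) is
100·|mask ∩ category|/|category| per category, to 2 decimals.
Whether the original method's final pick used cross-validated or
resubstitution accuracy is not recoverable; pooled-CV accuracy reuses
the objective evaluations' folds and adds no extra data, so it is the
default here.

## Synthetic benchmark

`gen_dataset` emulates a curated balanced training collection (defaults:
289 positives + 289 negatives, 200-nt UTRs, 22-nt miRNAs drawn from a
pool of 50, GC 0.5 with A=U and G=C splits). Every positive receives a
planted strong site (7mer-m8 / 7mer-A1 / 8mer, uniformly), AU-rich
flanks with probability 0.9 and supplementary pairing with 0.7;
negatives receive only an unenriched weak 6mer with probability 0.2,
mimicking hard negatives rather than trivially site-free sequences.
Implanting writes the exact complement motif plus guard bases that
prevent accidental category upgrades, so a scan of the edited UTR is
guaranteed to report the requested category at the requested start.
What the generator does *not* emulate: real UTR length and composition
heterogeneity, site conservation, expression context, and the
correlation structure of real negatives — so passing tests demonstrate
algorithmic correctness and signal recovery, not field performance on
biological data.

`gen_feature_matrix` is the abstract counterpart for selection studies:
standard-normal noise in 90 columns with five informative columns (fixed
indices in category 4) whose positive-class mean is shifted by 1.0 SD —
a moderate, realistic per-feature effect giving a clearly learnable but
not trivial classification problem (full-90 CV MCC ≈ 0.7).

## Benchmark problem sizes and known limitations

The reduced annealing schedule used by the selection benchmark
(Tmax = 1.0, Tmin = 0.05, α = 0.4, 6 iterations per temperature,
n_init = 4, hc_iters = 6, HL = 10, SL = 20; ≈ 50–60 unique evaluations
per run) lets 100 seeded runs finish in minutes and reliably recovers
the planted features (≥3 of 5 recovered in every pre-registered check).

A measured limitation worth stating plainly: on the planted-matrix
benchmark the CV objectives are nearly flat in the number of *harmless*
noise features (planted-only mask accuracy 0.875 vs 0.875 with 40 extra
noise columns), so the wrapper criterion exerts almost no pressure to
*remove* noise features — wrapper selection finds sufficient subsets,
not minimal ones. Selected masks therefore stay roughly half-dense in
noise at any affordable schedule, and the per-run requirement that the
planted category's FSR strictly exceed every noise category's FSR fails
most of the time (small 4-feature categories quantize FSR in 25% steps).
The corresponding acceptance test is kept at its stated threshold and
documents this behavior rather than papering over it; the planted
category's *mean* FSR does exceed the global mean, and recovery of the
informative features themselves is essentially certain.

Other limitations: the scanner is exact but quadratic (every window ×
two registers) and intended for UTR-scale inputs, not genome scans; no
thermodynamic accessibility, conservation filtering or probability
calibration; the published model's (C, γ) and annealing constants are
not recoverable and are treated as configuration.
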