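# Methods

This note documents the models and procedures implemented in `mirvote`,
their assumptions, the parameters that matter, and the design decisions
taken where the published lineage of hairpin classifiers leaves choices
open.

## Secondary-structure engine

All structure-derived features are computed from a `FoldResult`: the MFE
structure, the minimum and ensemble free energies, the base-pair
probability matrix, and the Boltzmann frequency of the MFE structure.
Two backends satisfy this contract.

**ViennaRNA backend (production).** Turner-parameter MFE folding and the
McCaskill partition function, at a configurable temperature (default
37 °C). The MFE-structure frequency is derived from the energy gap,
`exp((efe − mfe)/kT)`. Energies from thermodynamic folders drift across
parameter sets and versions, so no test asserts specific Vienna energies —
only invariants (efe ≤ mfe, symmetry, per-row probability sums ≤ 1).

**Reference backend (exact, bundled).** Base-pair maximization over
canonical pairs (A-U, G-C, G-U) with an energy of −1 unit per pair,
minimum hairpin loop 3, kT = 1. MFE via Nussinov dynamic programming;
the partition function via an inside recursion over the same nested
ensemble; pair probabilities via an outside recursion that conditions on
the innermost enclosing pair (O(L⁴), intended for short sequences). Its
entire output is verified against brute-force enumeration of all nested
structures in the tests, which makes it the oracle for every downstream
module without tying the suite to external energy tables. Its energies
are temperature-independent by construction.

**Structure conventions.** Pair tables are 1-based. A *stem* is a maximal
run of stacked pairs ((i, j) stacking on (i+1, j−1)). A *loop* is a
maximal unpaired run flanked by paired positions on both sides — hairpin
loops, bulges, interior-loop sides, multiloop segments and inter-hairpin
exterior segments each count once; dangling ends never count. All
loop-normalized features (MFEI3, dH/loop, dS/loop, Tm/Loop, dQ/Loop,
Avg_BP_Loop) use this count.

**Melting estimates.** dS is a two-temperature finite difference,
`dS = −(mfe(T2) − mfe(T1))/(T2 − T1)` (defaults 37/67 °C), giving the
physically expected negative folding entropy; `dH = mfe(T1) + T1[K]·dS`
and `Tm = dH/dS` (0 when dS = 0). This replaces the external melting
programs used by earlier feature sets; it is cheap, deterministic, and
configurable through `FeatureConfig.melt_t2`.

## Dinucleotide shuffling and z-score features

Shuffles preserve the exact dinucleotide multiset via the
Altschul–Erickson Eulerian-walk construction (last-edge arborescence
rejection sampling, then a seeded walk), not approximate swap shuffling:
exact conservation is the defining property of the null model behind zG,
zP, zQ, zD, zF and Mean_dG. Default cohort size is 100 shuffles
(configurable); cohort standard deviations use ddof = 1, and a zero sd
yields a z-score of 0. Each shuffle is folded once; cohort statistics are
the shuffle's MFE, total base pairs, ensemble entropy, ensemble
diversity, and the Fiedler value of its bonding graph.

## Self-containment

SC embeds the candidate between two random flanks (default 100 nt each
side), refolds the concatenation, and records the fraction of the
standalone MFE pairs retained at the shifted coordinates; SC is the mean
over R = 20 seeded contexts. Flanks are sampled by default from a
first-order Markov chain fitted to the candidate with add-one smoothing
(dinucleotide-matched contexts avoid composition-driven artifacts); a
uniform i.i.d. model is selectable. A candidate whose standalone fold has
no pairs scores 0 by convention. Only MFE structures are needed, so SC
does not pay for partition functions. Exact numerical agreement with
other SC implementations is not a goal; the operative semantics — range
[0, 1], determinism given a seed, and strong right-skew for long clean
stems — are what the feature set and tests rely on.

## The 125-feature registry

The registry is the single source of truth for names, order, groups and
novelty flags (19 sequence, 30 structure, 32 base-pair, 32 triplet, 12
SC-derived; 22 flagged as robustness-oriented additions, 103 classic).
Points that are fixed here because the upstream feature lineage does not
pin them:

- `Prob` is the mean ensemble probability of the MFE structure's pairs;
  `Freq` is the Boltzmann frequency of the MFE structure. Both appear in
  the catalog and are deliberately distinct.
- `MFEI5 = dG/tot_bp` (length-normalized), distinct from
  `MFEI4 = MFE/tot_bp`.
- `dQ` is the pair-probability entropy `−Σ p·ln p / L` (natural log);
  `dD` the normalized ensemble diversity `Σ 2p(1−p)/L`; `div` its
  unnormalized form.
- `dF` is the Fiedler value (second-smallest Laplacian eigenvalue) of the
  graph with backbone plus MFE base-pair edges, divided by L.
- `Probpair1–10` histogram the MFE pairs' ensemble probabilities into
  bins ((b−1)/10, b/10], as fractions of tot_bp.
- Triplet elements map ')' onto '(' and normalize by L−2, so the 32
  values sum to 1 for any L ≥ 3.
- Every division is guarded: a zero denominator yields 0. This keeps all
  features finite for degenerate inputs (unpaired sequences, zero loops,
  zero unpaired residues of a given base).
- Name variants seen in prose (AU/L, ProbPair4, dH/Loop, Avg_BP_loop,
  SC/nonBP_A, unicode ×/−) resolve to canonical registry names through an
  alias table.

Features are computed at 37 °C by default. Per-sequence extraction seeds
are spawned from a master seed, so tables are reproducible and
independent of batch composition.

## Feature selection

Continuous features are discretized by Fayyad–Irani recursive MDL cuts
(base-2 entropies; constant or uninformative columns collapse to a single
bin). Symmetrical uncertainty `SU = 2·IG/(H_a + H_b)` feeds the CFS merit
`k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`. The subset search is a genetic
algorithm over bit masks — population 20, 50 generations, crossover 0.6,
per-bit mutation 0.033, elitism 1, fitness-proportional selection,
best-ever tracking — Weka-era conventions, seeded and configurable; on
tables of ≤ 12 features it recovers the exhaustive optimum in the tests.
ReliefF (k = 10 neighbors, range-normalized diffs, prior-weighted misses)
and MDL-based InfoGain are provided as the comparison rankers.
The 20-feature default selection is shipped as a named constant and is
the classification default; selection remains re-runnable on any labeled
table, by default on the full table before rebalancing.

## Rebalancing (modified-SMOTEbagging)

SMOTE runs once, globally, before subset formation: ⌊0.5·n⌋ seed
positives drawn without replacement, each interpolated toward one of its
k = 5 nearest minority neighbors with u ~ U(0, 1). Neighbor search is
Euclidean on z-standardized columns; interpolation is affine-invariant,
so synthetics live in the original feature space. Negatives are matched
to the post-SMOTE minority size (e.g. 1000 positives → 1500 per class);
the ncRNA pool is sampled with replacement when smaller than the target
(warned), and the three pseudo subsets are drawn independently — a strict
3-way partition is impossible at the reference scale (3×1500 > 4000).
With rate 0 the construction degenerates to plain balanced bagging.

## Ensemble

Base members are scikit-learn estimators behind a spec layer: RBF SVM
(C = 1, gamma = 1/d), kNN (k = 5), random forest (100 trees, seeded).
These defaults are ordinary library conventions; the original members'
hyperparameters are unpublished, so exact decision-boundary replication
is out of scope. A single `StandardScaler`, fitted on the full training
table restricted to the selected features, standardizes inputs for all
members and travels with the model archive. Votes are hard; the vote
fraction is the reported probability, and an exact 0.5 tie is called
negative (favoring specificity). Archives embed the catalog version and
refuse to load under a mismatched registry.

## Evaluation

Sn, Sp, ACC, PPV, FPR = 100 − Sp, and Gm = √(Sn·Sp) as percentages
(guarded 0/0 → 0, reported to two decimals); AUC is the rank-based
Mann–Whitney statistic with mid-ranks for ties, identical to the
trapezoidal ROC area. `repeated_cv` runs repeats × stratified-k-fold
(default 10 × 5) and hands the pipeline factory *only* the training fold,
so SMOTE, undersampling and selection can never see test rows; an
internal disjointness assertion enforces this. Resampling-before-split
(the optimistic ordering) is not the default and is not used anywhere in
the tests.

## Simulator

The simulator emulates the reference training composition: 1000
miRNA-like positives, 754 ncRNA-like and 4000 pseudo-hairpin negatives
(≈ 1:4.75), all counts scalable. Positives are near-palindromic stems of
25–40 bp (mismatch rate 0.05, bulge rate 0.02) closed by 4–8 nt loops;
ncRNA-like records are weaker hairpins (10–15 bp stems, mismatch 0.15)
padded to 70–150 nt; pseudo records are random sequences with
coding-like composition (GC 0.52) whose lengths track the positive
length distribution, rejection-sampled through the candidate filter
(≥ 18 bp stem, MFE ≤ −18 kcal/mol, length window) so every emitted
pseudo record is a hard negative. The ≥ 10 bp stem-length gap between
the positive and ncRNA generators is the class-separation dial.

What the simulator does *not* emulate: phylogenetic conservation,
miRNA/miRNA* duplex geometry, multi-loop plant precursors, transcript
context, or the sequence biases of real RefSeq coding regions. Passing
tests therefore demonstrate that the pipeline recovers a strong
structural signal when one exists and that its components are correct
and leak-free — not field performance on real genomes, for which real
miRBase/Rfam/RefSeq-derived sets should be supplied via `read_fasta`.

## Problem sizes used by the test suite

The suite runs the directional and end-to-end checks on one shared
simulated corpus of 90/60/300 records with a reduced extraction budget
(10 shuffles, 6 SC contexts, 40-nt flanks) — sizes chosen once as a
desk-scale rendering of the study conditions. Oracle checks use
enumeration up to L ≈ 18 (the reference model is exact at any length;
enumeration cost, not model validity, sets the bound), 20 random tables
for GA-vs-exhaustive, 100 instances for AUC-vs-all-pairs, and 1000
sequences for shuffle-conservation fuzzing.

## Known limitations

- The reference backend's O(L⁴) pair probabilities make it unsuitable for
  long sequences; use the Vienna backend outside tests.
- SC values depend on the context model and flank length; cross-tool SC
  comparisons are not meaningful without matching configurations.
- kNN members store their training subsets, so archives grow with
  training size.
- Exactly reproducing published real-data figures requires the original
  corpora and member hyperparameters, which are not redistributable or
  recoverable; the package exposes the method, not those artifacts.
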