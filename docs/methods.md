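# Methods

## Problem setting

Metabolic drug–drug interactions (DDIs) arise when two co-administered
drugs interact at the level of biotransformation, most often through one of
seven cytochrome P450 isoforms: CYP1A2, CYP2B6, CYP2C19, CYP2C8, CYP2C9,
CYP2D6 and CYP3A4. This package models the *pair* of structures as a single
object — without deciding which drug is the "object" and which the
"precipitant", and without requiring any experimental annotation — and
predicts, for each isoform, whether the pair is likely to interact at that
enzyme's level.

## Molecular substrate

Structures (SMILES or V2000 SDF) are parsed with RDKit and reduced to the
only information the descriptors consume: element symbol, ring membership,
and connectivity with explicit hydrogens. Design choices:

* **Ring membership is binary and cycle-based**: an atom is "in a ring" iff
  it lies on at least one cycle (equivalently, iff one of its bonds is not a
  bridge). This is independent of any smallest-set-of-smallest-rings choice.
  Implemented with a bridge-finding depth-first search; tested against a
  brute-force edge-removal oracle, networkx cycle bases and RDKit's ring
  perception.
* **Discarded information**: bond orders, formal charges, isotopes and all
  stereochemistry are parsed but excluded from the descriptor substrate.
  Atom identity is element + ring flag, nothing else — this matches the
  alphabet of the descriptor strings and keeps the model applicable when
  stereochemistry is unknown (e.g. virtual compounds).
* **Hydrogens** are completed from RDKit's valence model and become explicit
  degree-1 acyclic atoms; completion is idempotent.
* **Multi-component inputs** (salts, mixtures) are rejected by default;
  an opt-in `strip_salts` keeps the component with the most heavy atoms and
  errors on ties.

## MNA and PoSMNA descriptors

The Multilevel Neighborhoods of Atoms (MNA) descriptor of an atom at level
k is a canonical string defined recursively:

    D0(a) = label(a)
    Dk(a) = label(a) "(" sorted-concat of D(k-1) over all neighbors ")"

where `label` is the element symbol prefixed with `-` for acyclic atoms.
A molecule is represented by the **set** of unique level-2 descriptors of
its heavy-atom centers (hydrogens contribute to neighborhoods but are not
centers); multiplicities are deliberately discarded — descriptor semantics
are presence/absence.

A molecule *pair* is represented by the **PoSMNA set**: the direct product
of the two MNA/2 sets, each cross term written as the two component strings
joined by one space, components in canonical order so the representation is
invariant under swapping the molecules. Self-pairs `"x x"` are kept when
the same descriptor occurs in both molecules.

**Collation.** Neighbor sub-descriptors and pair components are sorted
character-wise under a fixed alphabet ranking: `(` < `)` < letters (ASCII
order) < `-`. Ranking the acyclic mark *after* all letters is the one
ordering that simultaneously reproduces both orderings visible in published
descriptor listings (`C(CCC)` before `C(CC-H)`; every ring-atom string
before every `-`-prefixed string). The pair separator (space) is ranked
lowest; since same-level descriptors are balanced-parenthesis strings, no
well-formed comparison is ever decided by it. A descriptor for an isolated
atom at level ≥ 1 follows the grammar literally (`-O()`); this cannot occur
for hydrogen-completed organic molecules.

## The classifier

One-vs-rest naive Bayes in the activity-spectrum style. For activity *a*
with N training pairs, N_a of them labeled *a*, and counts n_d (pairs
containing descriptor d) and n_ad (containing d and labeled a):

    P(a|d) = (n_ad + k·p_a) / (n_d + k),   p_a = N_a / N

with smoothing strength k (default 1.0; k=0 gives raw frequencies), falling
back to the prior p_a for descriptors unseen in training — so the effective
set size |D| is the same for every activity. The raw score of a pair with
descriptor set D is

    S_a(D) = (1/|D|) Σ_{d∈D} arcsin(2·P(a|d) − 1) ∈ [−π/2, π/2].

The combiner matters only up to strictly increasing transforms: all
calibrated outputs below are rank-based, so any monotone combiner yields
identical Pa/Pi and identical IAP. This rank invariance is asserted by a
test; the combiner is one swappable function.

**Calibration (Pa/Pi).** Leave-one-out scores of all training pairs are
computed analytically — for pair i every count it contributed to (N, N_a,
n_d, n_ad) is decremented before scoring — which is exactly equivalent to
refitting without the pair (asserted to 1e-12 against brute-force
retraining). For a new score s:

    Pa = [#{active LOO scores < s} + ½·#{= s}] / N_a
    Pi = [#{inactive LOO scores > s} + ½·#{= s}] / (N − N_a)

Pa estimates "probability to be active", Pi "to be inactive"; activities
are reported ranked by ΔP = Pa − Pi, and the qualitative YES call is
ΔP > 0 (threshold configurable). Note that a *typical* true interactor has
Pa near 0.5, not near 1 — Pa is a rank among known actives — which is why
the decision statistic is ΔP rather than Pa alone.

**Validation.** IAP — the probability that a random active outscores a
random inactive, ties counted ½ — is computed per activity over the LOO
scores; it is numerically the AUC ROC (Mann–Whitney form, midranks). With
the rank definitions above, IAP equals the mean of (1 − Pi) over active LOO
scores *exactly*; this identity is a test. The cross-validation unit is the
pair: molecules recurring in several pairs are never fully held out, a
leakage caveat inherited from pair-level LOO.

**Negatives.** The training schema carries only positive (pair, activity)
labels; negatives for activity a are all pairs not labeled a. This is a
modeling assumption, not data.

## Synthetic data generator

The reference corpora behind CYP-interaction models are not redistributable,
so the package ships a seeded generator with planted, recoverable structure:

* **Library**: ~40 curated drug-like scaffold templates (warfarin and
  naproxen pinned verbatim), each with two enumerated ring positions
  decorated from a set of 12 substituents (H, methyl, ethyl, hydroxyl,
  methoxy, F, Cl, Br, I, amino, nitrile, trifluoromethyl) — chemical
  validity by construction, 144 variants per scaffold. Generation is
  round-robin over scaffolds with a seeded non-repeating decoration order;
  the same seed yields byte-identical files.
* **Planted rules**: the first 14 scaffolds form seven disjoint family
  pairs, one per CYP class. Each rule's features are MNA/2 descriptor
  strings common to every member of a family and absent from every other
  library molecule (derived at run time, collation-minimal pick); a pair is
  labeled with the class whose two features its two molecules carry.
* **Imbalance**: pairs are allocated to classes by largest-remainder
  proportional allocation against a realistic interaction-corpus profile in
  which CYP3A4 dominates with ~69% of 2345 pairs; the default table size is
  that corpus size (2345), scaled down to 200 in the fast studies.
* **Noise**: with probability ε a pair's planted label is replaced by a
  different class drawn *proportionally to the class profile*. The
  composition-preserving destination keeps every class's noise fraction
  near ε; a uniform destination would make the rarest class (1.2% of
  pairs) majority-noise at any ε ≳ 0.05 and destroy recoverability by
  construction.

What the generator does *not* emulate: real pharmacology (labels are
substructure co-occurrence, not metabolism), inter-class chemical overlap
(class families are disjoint scaffold sets, so classes are more separable
than real data), and molecule-level diversity within a class (family
members differ only in two substituents). Green synthetic tests therefore
demonstrate correctness of the machinery, not real-world accuracy.

## Study sizes and observed behavior

All studies run in seconds on one CPU; sizes were chosen as the smallest
that exercise every class meaningfully.

* **Separability** (library 480, 200 pairs, ε=0): LOO IAP is exactly 1.0
  for all seven activities.
* **Corpus-scale noisy study** (library 4200, 2345 pairs, ε=0.1):
  per-activity LOO IAP ≈ 0.86–0.93, average ≈ 0.89.
* **Held-out top-rank recovery**: at ε=0 the planted class ranks first by
  ΔP for 100% of 200 held-out rule pairs. At ε=0.1 recovery is ≈ 0.86:
  flipped-away dominant-class labels sit atop that class's inactive
  calibration (a ~0.15 floor under its Pi), and flipped-in dominant-family
  pairs inside small classes' active calibrations create occasional ΔP
  spikes — both direct consequences of rank-based calibration under label
  noise, analyzed in the test suite's acceptance checks.
* **Permutation null**: label-permuted tables give IAP below chance for
  small classes (down to ~0.04 at N_a=2) rather than 0.5. This is a known
  pessimistic bias of leave-one-out scoring: the held-out active loses one
  count on every descriptor it shares with its co-actives, while
  near-duplicate inactives keep full counts. The bias shrinks as N_a grows
  (the dominant class sits at ~0.46).

## Numerical conventions

Ties get weight ½ everywhere (score ranks, AUC). Scores are IEEE doubles;
the analytic/brute-force LOO comparison is asserted at 1e-12 (identical up
to summation order). Floats are serialized with shortest-round-trip repr,
so save → load → predict is bit-identical. All randomness flows through a
single seeded NumPy generator per operation; every writer uses stable sort
orders, making end-to-end CLI runs byte-deterministic.

## Known limitations

* Pair-level LOO leaks molecule-level information; compound-level
  cross-validation would be stricter.
* The Pa/Pi estimator is empirical ranks; numeric agreement with other
  activity-spectrum implementations is not expected (rank semantics and the
  ΔP ordering are, and are what the tests pin down).
* Descriptor multiplicity and bond orders are discarded by design; pairs of
  constitutional near-isomers can collide.
* The level is fixed at 2 for modeling (configurable for research use);
  higher levels sharpen specificity at the cost of sparser counts.
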