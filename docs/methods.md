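# Methods

## Model

A linear motif class of length n over an alphabet 𝒜 of A symbols is a
sequence **A** = (A₁, …, Aₙ) of nonempty allowed-residue sets Aᵢ ⊆ 𝒜; an
instance is any sequence (a₁, …, aₙ) with aᵢ ∈ Aᵢ.  The structure
e = (e₁, …, eₙ) records the set sizes.  The model treats all symbols of the
alphabet as exchangeable: no residue-usage bias, no biophysics of the
binding interface — only set-combinatorial constraints on how many classes
can remain mutually distinguishable.

### Regex dialect and preprocessing

Classes are exchanged as a restricted regular-expression dialect: literal
residues, bracketed classes `[XY]`, negated classes `[^X]` (complement
set), `.` (full alphabet), transparent capture parentheses, and fixed
repetition `X{m}`.  Alternation, unbounded repetition and lookaround are
rejected with an error naming the construct and its offset.  Repetition
braces after a multi-position group are rejected; in curated motif tables
repetition attaches to single positions or single-position capture groups.

Raw ELM-style regexes are curated by `preprocess`, applying in order:

1. variable-length repetitions `{p,q}` → shortest version `{p}`
   (`{0,q}` deletes the position);
2. terminal anchors `^`/`$` stripped;
3. nonstandard residue letters rewritten through a symbol map
   (default `{U: C}`, selenocysteine to cysteine; the map is a config
   parameter because published class tables do not enumerate a complete
   modified-residue mapping);
4. flanking positions trimmed iteratively from both ends while the terminal
   position allows ≥ 11 residues.  A position allowing exactly 10 is kept.
   Fully wildcard motifs raise an error.

Preprocessing is idempotent and logs every applied rule.  Positions are
reported 1-based.

### Pairwise specificity (motif-discriminating positions)

A position is *fixed* if it allows at most 10 residues (configurable
threshold).  For equal-length classes,

mdp(A, B) = #{ i : Aᵢ ∩ Bᵢ = ∅, |Aᵢ| ≤ 10, |Bᵢ| ≤ 10 }.

For lengths n ≥ m, the shorter class is slid over the longer one through
the n − m + 1 no-overhang alignments.  An alignment with no fixed–fixed
position pair is uninformative and discarded; the pair's mdp is the minimum
over the informative alignments.  If no alignment is informative, mdp is
reported as 0 with `informative=False`, placing such pairs in the
"not separated" bin.  Identical classes are flagged `coincident` (defined
for equal lengths only); their single alignment is informative (fixed
positions align against themselves) with mdp 0.  Positions that share only
part of their allowed residues contribute 0, so the mdp is a lower bound on
the true separation in sequence space.

### Counting bounds

For a structure e and specificity level k, |M(k)| is the maximal number of
classes of structure e such that every pair has at least k discriminating
positions (plain set disjointness; the ≤ 10 threshold belongs to the
empirical specificity measure, not to the combinatorial model).

- **k = 0** (every pair intersects everywhere):
  |M(0)| ≤ ∏ᵢ C(A−1, eᵢ−1), per-position Erdős–Ko–Rado.  The formula is
  evaluated as printed at every position; where 2eᵢ > A the theorem does
  not apply (all eᵢ-sets pairwise intersect, the true per-position maximum
  is C(A, eᵢ)) and a warning is issued.  The reference value 361 for
  (2,20,1,20,2) requires this literal evaluation.
- **k = 1**: a blockwise construction — cut the alphabet at each position
  into ⌊A/eᵢ⌋ disjoint blocks of eᵢ consecutive symbols and take the
  Cartesian product of block choices — gives |M(1)| ≥ ∏ᵢ ⌊A/eᵢ⌋; the
  pigeonhole principle gives |M(1)| ≤ ∏ᵢ A/eᵢ.
- **1 ≤ k < n**: |M(k)| ≤ ∏ A/eᵢ over the n−(k−1) positions with the
  largest eᵢ (sorting descending before truncation sharpens the bound; the
  reference value 100 at k = 2 pins this convention down).
- **k = n**: |M(n)| = minᵢ ⌊A/eᵢ⌋, exact.

Flooring convention: upper bounds floor the **final** product once (so
(20/8)⁴ = 39.0625 reports 39); the constructive lower bound floors **per
factor** (so the 33-letter example gives 16·1·33·1·16 = 8448).  Products
are evaluated in exact rational arithmetic before flooring.  Two printed
reference values are knowingly inconsistent with the formulas and are not
asserted: the 29-letter per-factor arithmetic gives
⌊29/2⌋·1·29·1·⌊29/2⌋ = 5684, not the published 5864 (suspected digit
transposition), and the (7,6) upper bound is (20/7)(20/6) ≈ 9.52, not
"11.11".

### Exhaustive oracle

`exhaustive_max_discriminating` enumerates every candidate class of a
structure (deterministic lexicographic order over per-position subsets as
bit masks), links pairs satisfying the k-discrimination predicate, and
solves maximum clique exactly with a branch-and-bound using greedy-colouring
upper bounds over bitset vertex sets.  The enumeration is guarded by a cap
(default 10⁴ candidates).  Exact maximum clique on these graphs is
exponential in the worst case: dense instances such as A=5, e=(2,2,2), k=1
(1000 candidates) do not finish in practical time, while every structure
with n ≤ 2 over alphabets up to 6, every structure with n = 3 over
alphabets up to 4, all k = n instances and all single-position k = 0
instances solve in milliseconds.  The test suite sweeps exactly that
tractable frontier (238 oracle instances) and checks the k = 1 sandwich,
the k = n exact value and the Erdős–Ko–Rado bound.

### Sequence-space occupancy

One class of structure e covers ∏ eᵢ / Aⁿ of the Aⁿ length-n sequences.
If all potential classes at level k ≥ 1 existed (instances then belong to a
single class), the covered fraction is

PotentialOccupancy(e, k) = ∏ᵢ (eᵢ/A) · |M(k)|,

with |M(k)| kept **unfloored** for every k.  This choice makes two
identities exact at machine precision (the arithmetic is rational until the
final conversion): occupancy at k = 1 is 1 for every structure and alphabet
(telescoping product), and occupancy at k = 2 is minᵢ eᵢ / A.  Flooring the
k = n case would break both identities for motifs of length ≤ 2, so it is
not done.  k = 0 is rejected: with overlapping classes no product formula
holds.

### Effective alphabet under post-translational modification

Modified residues expand the alphabet, but modification types are used very
unevenly.  Their effective number is the Hill number of order one,
2^H with H = −Σ pᵢ log₂ pᵢ (base-2 entropy of the normalized mixture,
0·log 0 := 0, computed via `scipy.stats.entropy`), rounded to the nearest
integer for reporting.  The expanded alphabet size is
20 + 1 (selenocysteine, optional) + the rounded effective count — e.g. 12
effective modifications give A = 33.  A packaged 12-row frequency table
(`data/ptm_fixture_synthetic.tsv`) is synthetic scaffolding so the
computation runs without downloads; its counts are illustrative and never
asserted.

## Database-level pipeline

- **Redundancy removal**: within each group of classes sharing a functional
  name, pairs with mdp = 0 are linked; in each connected component only the
  class with the most known instances is kept (ties: earliest database
  order).  Idempotent; every removal is logged.
- **Distributions**: per-class |M(k)| (or occupancy) values, the survival
  curve P(value ≥ x), and its median — the largest value whose survival
  fraction is ≥ 0.5 — plus the standard interpolated median for comparison.
  Classes shorter than k are excluded from the k-distribution (k
  discriminating positions are undefined for n < k) and counted.
- **Alphabet sweep**: medians per (A, k) for A in a 20–40-style range, in
  both the per-factor-floored (lower-bound) and end-floored (upper-bound)
  variants, labelled, with fold changes against A = 20.  When the alphabet
  grows, structure entries equal to the full 20-letter alphabet (wildcards
  and `.`) scale to the new size; all other entries — including
  single-exclusion `[^X]` positions (e = 19) — stay as printed.
- **Robustness**: (i) subsampling 25% of classes ×10 replicates;
  (ii) splitting the database at the median number of potential instances
  (odd counts put the middle class in the more-specific half);
  (iii) mismatch tolerance — widening one random position to the full
  alphabet in a seeded share of classes.  Mismatch perturbations are
  *nested* across fractions for a fixed seed (one permutation and one
  widened position drawn per class; the fraction selects a prefix), so
  medians decrease monotonically with the tolerant fraction by
  construction.  All experiments are bit-reproducible from
  (seed, parameters) via `numpy.random.default_rng`; fold changes are
  reported but deliberately not hard-asserted, as they are
  sample-dependent.
- **Proteome arithmetic**: instances ≈ ⌊residues in motif regions /
  typical motif length⌋; classes ≈ round(instances / instances-per-class).

## Synthetic data

`sample_database` emulates the marginal statistics of a curated motif class
table: lengths on 3–10 with mode 5 (mass 0.22/0.28/0.18 on 4/5/6);
per-position allowed counts bimodal with mass 0.52 on 1–3 (fixed
positions) and 0.385 on 19–20 (wildcards and single exclusions);
heavy-tailed known-instance counts (log-normal, median ≈ 6); and a
configurable fraction of planted same-name near-duplicates (allowed sets
widened at one position, hence mdp 0 against their original, with strictly
fewer known instances) that the curation step must remove exactly.
Allowed sets are uniform random subsets of the configured size — the
model's exchangeability assumption, so the generator shares it.  What it
does **not** emulate: residue-usage bias, correlations between positions,
length–specificity correlations, and the literal class list of any curated
snapshot.  Passing pipeline tests therefore demonstrates correctness of
the computations and the qualitative behaviour of the summaries, not the
numerical medians of any real database (e.g. a real snapshot's published
medians require its exact class list).

Default problem sizes in the tests — 60–80-class databases, 5000 classes
for the marginal-convergence check (total-variation < 0.05), 1000 random
structures for the occupancy identity, 100 random structures for
constructive-family verification — were chosen so the whole suite runs in
well under a minute while keeping every check statistically meaningful.

## Known limitations

- The mdp measure depends on the fixed-position threshold (default 10,
  configurable); the counting theory uses plain disjointness.
- The k = 0 occupancy has no closed form and is not computed.
- The exhaustive oracle cannot certify the k = 1 bounds beyond the
  tractable frontier described above; for larger instances only the proven
  closed-form bounds are available.
- Curated-snapshot-specific results (pair counts, database medians) depend
  on the input class table; the package computes them for any table but
  ships none.
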