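# motifspace

Combinatorics of the protein linear-motif universe: how specific are known
short linear motif (SLiM) classes, how many motif classes *could* coexist at
a given specificity level, and what fraction of protein sequence space would
they cover?

Short linear motifs are protein subsequences of roughly 3–15 residues that
mediate protein–protein interactions, conventionally described by regular
expressions such as `[LI].C.[DE]` (the Rb pocket B binding ligand).  A motif
class is formalized as a sequence of allowed-amino-acid sets
(A₁, …, Aₙ), Aᵢ ⊆ 𝒜, and its **structure** as the size tuple
e = (|A₁|, …, |Aₙ|).  `motifspace` implements:

- **Parsing and curation** of ELM-style regular expressions into classes:
  shortest version of variable-length motifs, anchor stripping, rewriting of
  modified residues (U→C), and trimming of flanking positions that allow
  eleven or more amino acids (`motifspace.motif_model`).
- **Pairwise specificity** as motif-discriminating positions (mdp): aligned
  positions where both classes are fixed (≤ 10 allowed residues) and their
  allowed sets are disjoint.  Classes of unequal length are compared over
  all no-overhang alignments; alignments without a fixed–fixed position pair
  are discarded and the minimum over the rest is taken
  (`motifspace.specificity`).
- **Counting bounds** on the maximal number |M(k)| of classes of one
  structure that pairwise maintain k motif-discriminating positions, for any
  alphabet size A:

  | k | bound |
  |---|-------|
  | 0 | |M(0)| ≤ ∏ᵢ C(A−1, eᵢ−1) (per-position Erdős–Ko–Rado) |
  | 1 | ∏ᵢ ⌊A/eᵢ⌋ ≤ |M(1)| ≤ ∏ᵢ A/eᵢ (blockwise construction / pigeonhole) |
  | 1 ≤ k < n | |M(k)| ≤ ∏ A/eᵢ over the n−(k−1) largest-e positions |
  | n | |M(n)| = minᵢ ⌊A/eᵢ⌋ (exact) |

  plus an exhaustive maximum-clique oracle that verifies the bounds on tiny
  alphabets (`motifspace.combinatorics`).
- **Sequence-space occupancy**: one class covers ∏ eᵢ / Aⁿ of all length-n
  sequences; a full k-discriminating repertoire covers that times the
  unfloored |M(k)| — exactly 1 for k = 1 (`motifspace.occupancy`).
- **Alphabet expansion** by post-translational modification: the effective
  number of modifications is 2^H for the Shannon entropy H of their
  frequency mixture (`motifspace.alphabet_expansion`).
- **Database-level analysis**: redundancy removal, all-pairs mdp matrices,
  survival-curve medians of potential class counts and occupancies,
  alphabet sweeps, and seeded robustness experiments
  (`motifspace.pipeline`), all runnable on seeded synthetic ELM-like
  databases (`motifspace.synthetic_data`).

## Worked example

```python
>>> import motifspace as ms
>>> from motifspace import combinatorics as cb

>>> rb = ms.MotifClass.from_regex("RB_LIG", "[LI].C.[DE]")
>>> rb.structure
(2, 20, 1, 20, 2)

>>> fiw = ms.MotifClass.from_regex("FIW", "[FI].W")
>>> ms.mdp_general(rb, fiw)
PairSpecificity(mdp=1, informative=True, coincident=False,
                alignments_total=3, alignments_informative=2)
```

The two regular expressions admit three alignments; the middle one matches
no pair of fixed positions and is discarded, the outer two score 1 and 2
discriminating positions, and the minimum 1 is the pair's separation in
sequence space.

```python
>>> [cb.potential_classes((2, 20, 1, 20, 2), 20, k) for k in range(6)]
[361, 2000, 100, 10, 1, 1]
```

At most 2000 classes of this structure can pairwise keep one
motif-discriminating position over the 20-letter alphabet; requiring two
positions drops the ceiling to 100, and demanding disjointness at every
position leaves a single class.  Mild specificity maximizes how many motif
classes can coexist.

```python
>>> from motifspace import occupancy as oc
>>> oc.class_occupancy((2, 20, 1, 20, 2))   # 1600 instances / 20^5 sequences
0.0005
>>> oc.potential_occupancy((2, 20, 1, 20, 2), 20, 1)
1.0
>>> oc.potential_occupancy((2, 20, 1, 20, 2), 20, 2)
0.05
```

If all 2000 potential k=1 classes existed, their instances would tile the
entire length-5 sequence space (occupancy exactly 1, by the telescoping
identity ∏(eᵢ/A)·∏(A/eᵢ) = 1).

A command-line interface mirrors the library:

```sh
motifspace simulate --n-classes 172 --seed 7 --out classes.tsv
motifspace pairs --classes classes.tsv --out pairs.tsv
motifspace potential --structure 2,20,1,20,2 --k 1
motifspace run --classes classes.tsv --out results/
```

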