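# Methods

`nlrdiv` analyses intraspecies diversity of plant NLR immune receptors
from a pan-genome: it partitions an NB-ARC phylogeny into near-allelic
clades, measures per-column amino-acid diversity of each clade's protein
alignment by Shannon entropy, flags highly variable (hv) clades, maps
their diversity onto the 2D surface of the LRR domain, and — when a
receptor–ligand complex structure is available — scores the entropy-based
binding-site prediction by precision and recall.

## Diversity statistic

For one alignment column with amino-acid frequencies `p_i` over the 20
standard residues,

    H = -Σ_i p_i log2 p_i    (bits).

Gap characters (`-`, `.`) and ambiguity codes (`X`, `B`, `Z`, `*`) are
excluded from both the numerator and the denominator of `p_i`; a column
needs at least two distinct counted residues for non-zero entropy. `H`
ranges from 0 (invariant) to `log2 20 ≈ 4.32` (all twenty residues in
equal ratios); a balanced two-residue column scores exactly 1 bit. The
estimator is the plain plug-in form — no small-sample correction — and
the per-column observation count `n_obs` is reported so sparse columns
can be filtered downstream. An alignment is classified **hv** when it
has at least `min_positions = 10` columns at `entropy_cutoff = 1.5` bits
or more; both comparisons are inclusive (`≥`).

Hydrophobicity is reported per column as the percentage of observed
residues in a configurable hydrophobic set, default `{A,V,L,I,M,F,W,C}`
(the Kyte–Doolittle-positive residues; the set matters mostly for
flagging exposed aromatics such as W and F inside diverse surface
patches).

## Clade partitioning

The gene-family tree (built externally from the shared NB-ARC domain;
tree inference is out of scope) must be rooted; `root_between` places
the root on a named leaf bipartition, splitting that branch at its
midpoint, and `midpoint_root` is the default for per-clade trees.

**Initial assignment.** For every leaf, among all containing clades with
size in `[min_clade_size, max_clade_size]` (default 40–500) the one with
the strongest bootstrap support is selected; leaves with no
size-eligible clade fall back to clades below the minimum size. Missing
supports rank as 0. Ties are broken toward the larger clade, then the
clade closer to the root — deterministic and favouring inclusive
clades. The selected set is made non-nesting by discarding any selected
clade fully contained in another; its leaves inherit the enclosing
clade. Because clades of a rooted tree form a laminar family, the
result is provably disjoint, exhaustive and non-nesting, and these
invariants are asserted on every construction. Size bounds are applied
at selection time only, not re-checked after de-nesting.

**Refinement.** On a clade's full-length-alignment tree, every non-root
branch longer than `long_branch_cutoff = 0.3` substitutions/site is
cut, and every branch of `short_branch_cutoff = 0.1` or less is kept.
Branches in between have historically been decided by eye; here the
decision is automated: cut iff bootstrap support ≥ 70 **and** the
Jaccard index of the ecotype sets on the two sides is ≤ 0.25 (strong
support for a split that separates ecotype complements). The rule is a
declared, parameterised substitute for manual inspection, and every
branch decision (length, support, Jaccard, rule fired) is logged for
audit. Terminal branches follow the same rules; a long terminal branch
yields a singleton subclade. Gappy-column masking (columns with ≥ 90%
gaps) is available for first-round alignments; hv classification runs
on unmasked alignments by default.

**Allelic statistics.** A clade is an allelic series when no represented
ecotype contributes more than one gene. Reported: the fraction of such
clades, the fraction of sequences in clades of ≥ 20 members (large
enough to sample diversity), per-clade maxima, and the size histogram.

## LRR surface mapping

The LxxLxLxx core is detected by scanning for the pattern
`[aliphatic] x x [aliphatic] x [aliphatic] x x` with a configurable
aliphatic class (default `{L,I,V,F,M,C,A}`), greedy left-to-right with a
minimum spacing of 8 between core starts. The detector is deliberately
tolerant — curated annotations can be supplied instead and are passed
through verbatim. Repeats become matrix rows (rendered bottom-to-top);
columns are core positions 1–8 (conserved positions 1, 4, 6) plus up to
five flanking residues on each side, labelled −5…−1 and 9…13. Residues
between cores are attributed to the nearer core, ties to the preceding
repeat, which guarantees each residue occupies at most one cell.
Hiding columns 1, 4 and 6 leaves the solvent-exposed concave-face
array; the cross-receptor comparison view trims to positions
−2, −1, 2, 3, 5, 7, 8, 10, 11. Entropy/hydrophobicity overlays are
looked up through the alignment-column → reference-residue map, and a
cell is flagged as a candidate binding residue when `H ≥ 1.5` bits and
hydrophobic residues occur at that position.

## Structural evaluation

A receptor residue is a contact when any heavy atom lies within
`cutoff = 4.5 Å` of any ligand heavy atom (any-heavy-atom rule;
configurable — interface definitions based on buried surface area are
out of scope). Predictions at an entropy cutoff are the mapped residues
whose column reaches it; sweeping cutoffs 0.1–3.0 bits in 0.1-bit steps
yields the precision/recall curve. Precision with zero predictions is
recorded as missing rather than 0 or 1. Column→residue maps come from
ungapping the reference sequence; mismatches are reported, never
silently skipped. Entropy values can be exported unrescaled as
Chimera attribute files or iTOL gradient datasets for visualisation.

## Synthetic data generator

`simulate_nlrome` emulates the *structure* of a pan-NLRome, not its
evolutionary process: one subclade per gene family with an ecotype-
labelled leaf per ecotype (optional duplications), inter-family branch
lengths of 0.35–0.60 substitutions/site (above the long cutoff),
intra-family lengths 0.005–0.05 (below the short cutoff), family-root
bootstrap 100 against ≤ 99 within families and ≤ 69 on the backbone.
Alignments are sampled independently per column: background columns
hold a fixed residue mutated per sequence with probability 0.01; hv
families additionally carry 15 planted columns, each i.i.d. uniform
over k = 6 residues, placed on the solvent-exposed positions
(2, 3, 5, 7, 8) of a 24-residue LxxLxLxx template repeated 14 times.
Gaps enter as N-terminal truncations and short internal deletions
(never on the reference row). Defaults follow a 62-ecotype, 20-family
design with 5 hv families.

The point of i.i.d. per-column sampling is analytic control: a planted
column's expected plug-in entropy is ≈ log2 k (2.58 bits at k = 6, a
comfortable margin above the 1.5-bit cutoff with ~62 sequences), while
background columns stay far below 1 bit, so recovery tests have exact
ground truth. What the generator does **not** emulate: phylogenetic
correlation of substitutions, rate variation along branches,
recombination and gene conversion between paralogs, alignment error,
and annotation noise. Passing the recovery tests therefore shows the
machinery is correct under clean separation, not that real NLRomes are
this easy; on real data the intermediate-branch rule and the detector
tolerance are the places where judgement enters.

A toy receptor–ligand complex generator places designated contact
pairs at `cutoff − margin` and everything else beyond
`cutoff + margin`, giving exact contact ground truth for the
structural-evaluation path.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere (alignment columns,
  reference residues, PDB residue numbers).
* Gap-fraction masking uses `≥ cutoff`; hv thresholds use `≥` at both
  the bit and the position count.
* hv columns whose reference position is gapped are attributed to the
  domain of the nearest preceding reference residue (preNB when there
  is none) and flagged in the output, since per-domain counting
  requires a convention the data itself cannot supply.
* All randomness flows through one seeded generator per run; the same
  configuration reproduces outputs byte for byte.
* Tests and the bundled acceptance script use scaled-down simulations
  (12–62 ecotypes, 5–20 families, 8–14 repeats), chosen as the smallest
  sizes at which every recovery property is exercised.

## Known limitations

* The intermediate-branch automation (support ≥ 70, Jaccard ≤ 0.25) is
  a reproducible stand-in for expert tree inspection; on real data its
  thresholds deserve per-dataset review via the decision log.
* The LRR detector generalises the conserved positions to an aliphatic
  class and will both miss irregular repeats and fire on repeat-like
  patterns outside the LRR; curated annotations are first class for
  this reason.
* The plug-in entropy is biased downward for small clades; clades of
  fewer than ~20 sequences are reported but weakly powered, which is
  why the fraction of sequences in clades ≥ 20 is tracked.
* Published-scale datasets are download-gated and not bundled; see
  `scripts/real_data_check.py`.
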