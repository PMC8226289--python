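# nlrdiv

Toolkit for analysing intraspecies diversity of plant **NLR immune
receptors** from pan-genome data. Plant genomes encode hundreds of
Nucleotide-binding Leucine-Rich Repeat (NLR) receptors; a small subset
of them diversifies rapidly to track pathogen effectors by direct
binding. `nlrdiv` finds that subset and predicts where on the receptor
the binding happens, using nothing but sequences and a phylogeny:

1. **Clade partitioning** — assign every gene in an NB-ARC phylogeny to
   a *near-allelic clade*: per gene, the containing clade of bounded
   size (40–500 by default) with the strongest bootstrap support,
   de-nested so clades are disjoint and exhaustive. Clades are then
   refined on their own trees by branch-length rules (cut > 0.3
   substitutions/site, keep ≤ 0.1, decide 0.1–0.3 by support and
   ecotype overlap).
2. **Diversity profiling** — per alignment column, plug-in Shannon
   entropy over the 20 amino-acid frequencies (gaps and ambiguity codes
   not counted),

       H = −Σᵢ pᵢ log₂ pᵢ   (bits),

   from 0 (invariant) to log₂ 20 ≈ 4.32. A clade is a **highly
   variable NLR (hvNLR)** when ≥ 10 columns reach ≥ 1.5 bits.
3. **LRR surface mapping** — annotate LxxLxLxx repeats, lay the domain
   out as a repeats × positions matrix of the concave face (conserved
   leucines at core positions 1, 4, 6 hidden), and overlay entropy and
   hydrophobicity to localise the predicted binding site.
4. **Structural evaluation** — derive contact residues from a
   receptor–ligand complex (any heavy atom within 4.5 Å) and trace
   precision/recall of the entropy prediction across cutoffs; export
   entropy as Chimera attribute or iTOL annotation files.

A seeded synthetic-NLRome generator with full ground truth backs the
test suite end to end.

## Worked example

```python
from nlrdiv import (SimConfig, PartitionConfig, simulate_nlrome,
                    initial_assignment, allelic_series_stats,
                    profile_alignment, classify_hv)

cfg = SimConfig(seed=8, n_ecotypes=24, n_families=10,
                repeat_count=8, n_hv_columns=12)
tree, alignments, truth = simulate_nlrome(cfg)

part = initial_assignment(tree, PartitionConfig(min_clade_size=10,
                                                max_clade_size=100))
print(len(part.clades))                      # -> 10
stats = allelic_series_stats(part, truth.ecotype_of)
print(stats.allelic_fraction)                # -> 1.0

for fam, aln in alignments.items():
    is_hv, pos = classify_hv(profile_alignment(aln))
    if is_hv:
        print(fam, len(pos))                 # -> Fam03 12 / Fam06 12
```

The 240 simulated genes fall into 10 clades matching the generating
families exactly; every clade is a perfect allelic series (one gene per
ecotype), and the two families with planted high-diversity columns — 12
columns each drawn from 6 equiprobable residues, ≈ 2.4 bits realised —
are the only ones classified hv. The scripts in `examples/` walk
through each capability (entropy fingerprints, partitioning, hv
classification with per-domain counts, the LRR surface map, and
binding-site evaluation against a toy complex) and print the numbers
they compute; `examples/04_lrr_surface_map.py`, for instance, renders
the trimmed 9-position concave-face entropy matrix in which only the
planted surface positions exceed 1.5 bits.

A command-line layer mirrors the library
(`nlrdiv simulate | partition | refine | entropy | hv-classify |
domain-counts | lrr-annotate | lrr-map | contacts | pr-eval |
color-structure | run`); exit code 2 flags bad input, 3 a violated
invariant.

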