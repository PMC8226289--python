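"""End-to-end orchestration: partition -> refine -> entropy -> hv ->
surface -> allelic stats, with persisted per-stage outputs and a run
manifest that fully records the configuration and inputs."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .diversity import HvCriteria, classify_hv, profile_alignment
from .errors import InputError
from .io import Alignment, PhyloTree, write_tsv
from .partition import (
    AllelicStats,
    CladePartition,
    PartitionConfig,
    allelic_series_stats,
    initial_assignment,
    refine_clade,
    refine_partition_names,
)
from .surface import annotate_lrr, build_surface_matrix

STAGES = ("partition", "refinement", "entropy", "hv_classification",
          "surface", "allelic_stats")


@dataclass
class RunManifest:
    version: str
    config: dict
    inputs: dict                     # name -> sha256 (or inline description)
    started: float
    finished: float | None = None
    stage_outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    partition: CladePartition
    refined: CladePartition
    hv_table: pd.DataFrame
    allelic: AllelicStats
    manifest: RunManifest


def _match_alignment(clade_leaves, alignments: Mapping[str, Alignment]):
    for name, aln in alignments.items():
        if clade_leaves <= set(aln.ids):
            return name, aln
    return None, None


def run_pipeline(
    tree: PhyloTree,
    alignments: Mapping[str, Alignment],
    ecotypes: Mapping[str, str],
    outdir,
    partition_cfg: PartitionConfig | None = None,
    criteria: HvCriteria | None = None,
    refine: bool = True,
    input_paths: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run the full analysis on one tree plus per-clade alignments.

    ``alignments`` maps arbitrary keys to alignments whose ids must cover
    the leaves of the clades they serve.  Stage outputs are persisted as
    TSV under ``outdir`` and listed in the manifest.
    """
    partition_cfg = partition_cfg or PartitionConfig()
    criteria = criteria or HvCriteria()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # -- preconditions, checked before any work -------------------------
    leaves = set(tree.leaf_labels())
    covered = set()
    for aln in alignments.values():
        covered |= set(aln.ids)
    missing = sorted(leaves - covered)
    if missing:
        raise InputError(f"tree leaves absent from all alignments: {missing[:10]}")
    if refine:
        missing_eco = sorted(leaves - set(ecotypes))
        if missing_eco:
            raise InputError(
                f"refinement requested but ecotype labels missing for: {missing_eco[:10]}"
            )

    manifest = RunManifest(
        version=__version__,
        config={
            "partition": asdict(partition_cfg),
            "criteria": {
                "entropy_cutoff": criteria.entropy_cutoff,
                "min_positions": criteria.min_positions,
                "hydrophobic_set": "".join(sorted(criteria.hydrophobic_set)),
            },
            "refine": refine,
        },
        inputs={
            name: _sha256(p) for name, p in (input_paths or {}).items()
        },
        started=time.time(),
    )

    # -- stage 1: initial partition --------------------------------------
    part = initial_assignment(tree, partition_cfg)
    path = out / "partition.tsv"
    write_tsv(part.to_frame(), path)
    manifest.stage_outputs["partition"] = str(path)

    # -- stage 2: refinement ---------------------------------------------
    refined_clades: dict[str, frozenset] = {}
    logs = []
    if refine:
        for name, clade_leaves in part.clades.items():
            if len(clade_leaves) < 3:
                refined_clades[name] = clade_leaves
                continue
            sub = tree.tree.extract_tree_with_taxa_labels(sorted(clade_leaves))
            subtree = PhyloTree.from_dendropy(sub)
            subsets, log = refine_clade(subtree, partition_cfg, ecotypes)
            log.insert(0, "clade", name)
            logs.append(log)
            refined_clades.update(refine_partition_names(name, subsets))
    else:
        refined_clades = dict(part.clades)
    refined = CladePartition(clades=refined_clades)
    refined.validate(all_leaves=leaves)
    path = out / "refinement.tsv"
    write_tsv(refined.to_frame(), path)
    manifest.stage_outputs["refinement"] = str(path)
    if logs:
        write_tsv(pd.concat(logs, ignore_index=True), out / "refinement_log.tsv")

    # -- stages 3+4: entropy profiles and hv classification ---------------
    hv_rows = []
    profiles = {}
    ent_dir = out / "entropy"
    ent_dir.mkdir(exist_ok=True)
    for name, clade_leaves in refined.clades.items():
        _, aln = _match_alignment(clade_leaves, alignments)
        if aln is None:
            raise InputError(f"no alignment covers clade {name}")
        sub_aln = aln.subset(clade_leaves)
        profile = profile_alignment(sub_aln, criteria)
        profiles[name] = (sub_aln, profile)
        write_tsv(profile.to_frame(), ent_dir / f"{name}.tsv")
        is_hv, positions = classify_hv(profile, criteria)
        hv_rows.append(
            {"clade": name, "size": len(clade_leaves), "is_hv": is_hv,
             "n_hv_positions": len(positions)}
        )
    manifest.stage_outputs["entropy"] = str(ent_dir)
    hv_table = pd.DataFrame(hv_rows).sort_values("clade", ignore_index=True)
    path = out / "hv_classification.tsv"
    write_tsv(hv_table, path)
    manifest.stage_outputs["hv_classification"] = str(path)

    # -- stage 5: LRR surface maps for hv clades with a reference ---------
    surf_dir = out / "surface"
    surf_dir.mkdir(exist_ok=True)
    for row in hv_rows:
        if not row["is_hv"]:
            continue
        name = row["clade"]
        sub_aln, profile = profiles[name]
        if sub_aln.reference_id is None:
            continue
        ref_seq = sub_aln.ungapped_reference()
        ann = annotate_lrr(ref_seq)
        if not ann.repeats:
            continue
        matrix = build_surface_matrix(
            ann, ref_seq, profile=profile, column_map=sub_aln.reference_column_map()
        )
        write_tsv(matrix.rendered("entropy"), surf_dir / f"{name}_entropy.tsv", index=True)
        write_tsv(matrix.rendered("residue"), surf_dir / f"{name}_residues.tsv", index=True)
    manifest.stage_outputs["surface"] = str(surf_dir)

    # -- stage 6: allelic-series statistics --------------------------------
    stats = allelic_series_stats(refined, ecotypes)
    path = out / "allelic_stats.tsv"
    write_tsv(stats.to_frame(), path)
    manifest.stage_outputs["allelic_stats"] = str(path)

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return PipelineResult(
        partition=part,
        refined=refined,
        hv_table=hv_table,
        allelic=stats,
        manifest=manifest,
    )
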