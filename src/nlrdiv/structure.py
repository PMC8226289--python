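"""Receptor-ligand contacts and precision/recall of entropy-based
binding-site predictions.

Given a complex structure, a receptor residue counts as a contact when
any of its heavy atoms lies within a distance cutoff (4.5 Angstrom by
default) of any ligand heavy atom.  Predictions are the receptor residues
whose alignment column reaches a given entropy cutoff; sweeping the
cutoff traces a precision/recall curve against the structural contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .diversity import EntropyProfile
from .errors import InputError, InvariantError
from .io import StructureModel

#: Default sweep: 0.1-3.0 bits in 0.1-bit steps, bracketing the useful range.
DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.1, 3.01, 0.1), 10))


@dataclass
class ContactSet:
    receptor_chain: str
    ligand_chain: str
    contacts: frozenset
    cutoff: float

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise InputError("contact cutoff must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": sorted(self.contacts, key=str)},
        ).assign(
            receptor_chain=self.receptor_chain,
            ligand_chain=self.ligand_chain,
            cutoff=self.cutoff,
        )


def _heavy_coords(residues) -> tuple[list, np.ndarray]:
    """Per-chain heavy-atom coordinates with their residue keys."""
    keys, coords = [], []
    for res in residues:
        for atom in res.atoms:
            if atom.is_heavy:
                keys.append(res.key)
                coords.append((atom.x, atom.y, atom.z))
    return keys, np.asarray(coords, dtype=float)


def contacts_from_structure(
    model: StructureModel,
    receptor: str,
    ligand: str,
    cutoff: float = 4.5,
) -> ContactSet:
    """Receptor residues with any heavy atom within ``cutoff`` of any
    ligand heavy atom."""
    rec_res = model.chain(receptor)
    lig_res = model.chain(ligand)
    rec_keys, rec_xyz = _heavy_coords(rec_res)
    lig_keys, lig_xyz = _heavy_coords(lig_res)
    if len(rec_xyz) == 0:
        raise InputError(f"chain {receptor!r} has no heavy-atom coordinates")
    if len(lig_xyz) == 0:
        raise InputError(f"chain {ligand!r} has no heavy-atom coordinates")
    tree = cKDTree(lig_xyz)
    dists, _ = tree.query(rec_xyz, k=1)
    contacts = {key for key, d in zip(rec_keys, dists) if d <= cutoff}
    return ContactSet(
        receptor_chain=receptor,
        ligand_chain=ligand,
        contacts=frozenset(contacts),
        cutoff=cutoff,
    )


@dataclass
class PRPoint:
    entropy_cutoff: float
    precision: float | None  # None when nothing is predicted
    recall: float
    n_predicted: int
    n_true: int


@dataclass
class PRCurve:
    points: list[PRPoint]

    def __post_init__(self) -> None:
        prev_pred = None
        prev_rec = None
        for p in sorted(self.points, key=lambda q: q.entropy_cutoff):
            if prev_pred is not None and p.n_predicted > prev_pred:
                raise InvariantError("n_predicted increased with the cutoff")
            if prev_rec is not None and p.recall > prev_rec + 1e-12:
                raise InvariantError("recall increased with the cutoff")
            prev_pred, prev_rec = p.n_predicted, p.recall

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entropy_cutoff": [p.entropy_cutoff for p in self.points],
                "precision": [p.precision for p in self.points],
                "recall": [p.recall for p in self.points],
                "n_predicted": [p.n_predicted for p in self.points],
                "n_true": [p.n_true for p in self.points],
            }
        )

    def at(self, cutoff: float) -> PRPoint:
        for p in self.points:
            if abs(p.entropy_cutoff - cutoff) < 1e-9:
                return p
        raise KeyError(cutoff)


def precision_recall(
    profile: EntropyProfile,
    column_map: Mapping[int, int],
    truth: ContactSet,
    cutoffs: Sequence[float] = DEFAULT_CUTOFF_GRID,
) -> PRCurve:
    """Sweep entropy cutoffs; at each, predicted = mapped residues whose
    column entropy is >= the cutoff.

    precision = |predicted & true| / |predicted| (None when nothing is
    predicted); recall = |predicted & true| / |true|.
    """
    if not truth.contacts:
        raise InputError("empty truth contact set")
    residue_entropy: dict = {}
    for col, res in column_map.items():
        if not (1 <= col <= profile.n_columns):
            raise InputError(f"column {col} outside profile range")
        residue_entropy[res] = profile.entropy[col - 1]
    true_set = set(truth.contacts)
    points = []
    for c in sorted(cutoffs):
        predicted = {res for res, h in residue_entropy.items() if h >= c}
        tp = len(predicted & true_set)
        points.append(
            PRPoint(
                entropy_cutoff=float(c),
                precision=(tp / len(predicted)) if predicted else None,
                recall=tp / len(true_set),
                n_predicted=len(predicted),
                n_true=len(true_set),
            )
        )
    return PRCurve(points=points)


def entropy_to_structure(
    profile: EntropyProfile,
    column_map: Mapping[int, int],
    model: StructureModel,
    chain: str,
) -> tuple[dict, dict]:
    """Per-residue entropy scores for colouring a structure.

    Returns (residue -> entropy map restricted to residues present in the
    chain, report dict with mapped/unmapped tallies).  Scores are the
    profile's H values unrescaled; feed the map to
    :func:`nlrdiv.io.write_attribute_file`.
    """
    chain_res = {res.key for res in model.chain(chain)}
    scores: dict = {}
    for col, res in column_map.items():
        if res in chain_res:
            scores[res] = float(profile.entropy[col - 1])
    if not scores:
        raise InputError("no alignment columns map onto residues of the chain")
    unmapped = sorted(chain_res - set(scores), key=str)
    report = {
        "n_mapped": len(scores),
        "n_unmapped_chain_residues": len(unmapped),
        "unmapped": unmapped,
    }
    return scores, report
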