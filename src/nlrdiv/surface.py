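"""LRR repeat annotation and 2D concave-surface mapping.

Leucine-rich repeats fold so predictably that the beta-sheet on the
concave side of the domain can be reconstructed from sequence alone: one
row per repeat unit, one column per position of the canonical LxxLxLxx
core (positions 1-8, conserved leucine-class residues at 1, 4 and 6),
optionally extended by five flanking residues on either side (labels
-5..-1 before the core and 9..13 after it; there is no position 0).
Hiding the conserved-leucine columns leaves exactly the surface-exposed
array.  Overlaying per-column Shannon entropy and hydrophobicity on this
grid localises candidate binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import EntropyProfile, HvCriteria
from .errors import InputError, InvariantError

#: Residue classes accepted at the conserved core positions 1, 4, 6.
ALIPHATIC_DEFAULT = frozenset("LIVFMCA")

CORE_LENGTH = 8
CONSERVED_CORE_POSITIONS = (1, 4, 6)
#: Position labels for a full matrix with 5-residue flanks.
FULL_POSITIONS = tuple(range(-5, 0)) + tuple(range(1, 14))
#: The trimmed concave-face view used for cross-receptor comparison.
TRIM_DEFAULT = (-2, -1, 2, 3, 5, 7, 8, 10, 11)


@dataclass
class LRRRepeat:
    index: int        # 1-based repeat number, N- to C-terminal
    core_start: int   # 1-based residue of the first conserved position


@dataclass
class LRRAnnotation:
    repeats: list[LRRRepeat]
    source: str = "detector"  # or "user-supplied"

    def __post_init__(self) -> None:
        starts = [r.core_start for r in self.repeats]
        if starts != sorted(starts):
            raise InvariantError("repeats must be ordered by core start")
        for a, b in zip(starts, starts[1:]):
            if b - a < CORE_LENGTH:
                raise InvariantError("repeat cores overlap")

    def core_starts(self) -> list[int]:
        return [r.core_start for r in self.repeats]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": [r.index for r in self.repeats],
                "core_start": [r.core_start for r in self.repeats],
                "core_end": [r.core_start + CORE_LENGTH - 1 for r in self.repeats],
            }
        )


def annotate_lrr(
    sequence: str,
    aliphatic: frozenset[str] | str = ALIPHATIC_DEFAULT,
    min_spacing: int = CORE_LENGTH,
) -> LRRAnnotation:
    """Detect LxxLxLxx cores by scanning for the [aliphatic]xx[aliphatic]x
    [aliphatic]xx pattern, greedily left to right with ``min_spacing``
    between accepted core starts.

    The detector is a configurable stand-in for manual/structure-aware
    annotation; user-supplied annotations can be passed downstream
    unchanged.  Zero repeats is a valid result.
    """
    if len(sequence) < 3 * CORE_LENGTH:
        raise InputError("sequence shorter than 24 residues; not an LRR domain")
    cls = frozenset(c.upper() for c in aliphatic)
    seq = sequence.upper()
    repeats: list[LRRRepeat] = []
    last_start = -10**9
    for i in range(len(seq) - CORE_LENGTH + 1):
        if i - last_start < min_spacing:
            continue
        if seq[i] in cls and seq[i + 3] in cls and seq[i + 5] in cls:
            repeats.append(LRRRepeat(index=len(repeats) + 1, core_start=i + 1))
            last_start = i
    return LRRAnnotation(repeats=repeats, source="detector")


def user_annotation(core_starts: Sequence[int]) -> LRRAnnotation:
    """Wrap externally curated core starts (1-based) as an annotation."""
    return LRRAnnotation(
        repeats=[LRRRepeat(index=i + 1, core_start=s) for i, s in enumerate(core_starts)],
        source="user-supplied",
    )


@dataclass
class SurfaceMatrix:
    """repeats x repeat-positions grid over the LRR concave face.

    Rows are indexed by repeat number ascending (repeat 1 first); exports
    render them bottom-to-top so repeat 1 sits at the bottom, as the
    surface is conventionally drawn.  Cells hold the residue character,
    the 1-based reference residue number, and the entropy / hydrophobicity
    overlay (NaN when no profile was supplied).
    """

    residue: pd.DataFrame       # str or "" cells
    ref_residue: pd.DataFrame   # float (NaN = empty cell)
    entropy: pd.DataFrame
    hydrophobic: pd.DataFrame

    def __post_init__(self) -> None:
        shapes = {df.shape for df in (self.residue, self.ref_residue, self.entropy, self.hydrophobic)}
        if len(shapes) != 1:
            raise InvariantError("surface matrix layers differ in shape")
        filled = self.ref_residue.values
        vals = filled[~np.isnan(filled)]
        if len(vals) != len(set(vals)):
            raise InvariantError("a reference residue appears in more than one cell")

    @property
    def positions(self) -> list[int]:
        return list(self.residue.columns)

    @property
    def n_repeats(self) -> int:
        return len(self.residue.index)

    def rendered(self, layer: str = "residue") -> pd.DataFrame:
        """Bottom-to-top view (repeat 1 on the last row) of one layer."""
        return getattr(self, layer).iloc[::-1]


def build_surface_matrix(
    annotation: LRRAnnotation,
    sequence: str,
    profile: EntropyProfile | None = None,
    column_map: Mapping[int, int] | None = None,
    flank: int = 5,
) -> SurfaceMatrix:
    """Lay the annotated repeats out as a repeats x positions grid.

    ``column_map`` maps 1-based alignment columns to 1-based residues of
    ``sequence`` (the ungapped reference); it is inverted to look up each
    cell's entropy and hydrophobicity in ``profile``.  Inter-core residues
    go to the nearer core (ties to the preceding repeat); flanks that run
    off the sequence or into another repeat's claim stay empty.
    """
    if not annotation.repeats:
        raise InputError("annotation has no repeats")
    seq = sequence.upper()
    n = len(seq)
    for rep in annotation.repeats:
        if rep.core_start + CORE_LENGTH - 1 > n:
            raise InputError(f"repeat {rep.index} core extends past sequence end")

    positions = [p for p in range(-flank, flank + CORE_LENGTH + 1) if p != 0]
    res_to_col: dict[int, int] = {}
    if column_map is not None:
        for col, res in column_map.items():
            res_to_col[res] = col

    starts = annotation.core_starts()
    ends = [s + CORE_LENGTH - 1 for s in starts]

    # residue -> (repeat row, position label)
    claim: dict[int, tuple[int, int]] = {}
    for r, (s, e) in enumerate(zip(starts, ends)):
        for off in range(CORE_LENGTH):
            claim[s + off] = (r, off + 1)
    for res in range(1, n + 1):
        if res in claim:
            continue
        # candidate flank assignments relative to each neighbouring core
        prev_idx = next_idx = None
        for r, (s, e) in enumerate(zip(starts, ends)):
            if e < res:
                prev_idx = r
            if s > res and next_idx is None:
                next_idx = r
        choices = []  # (distance, tiebreak, repeat row, label)
        if prev_idx is not None:
            d = res - ends[prev_idx]
            if d <= flank:
                choices.append((d, 0, prev_idx, CORE_LENGTH + d))
        if next_idx is not None:
            d = starts[next_idx] - res
            if d <= flank:
                choices.append((d, 1, next_idx, -d))
        if choices:
            _, _, r, label = min(choices)
            claim[res] = (r, label)

    n_rep = len(starts)
    blank = lambda fill: pd.DataFrame(  # noqa: E731
        fill, index=pd.Index(range(1, n_rep + 1), name="repeat"),
        columns=pd.Index(positions, name="position"),
    )
    residue = blank("")
    ref_res = blank(np.nan)
    ent = blank(np.nan)
    hydro = blank(np.nan)

    missing: list[int] = []
    for res, (r, label) in claim.items():
        residue.iat[r, positions.index(label)] = seq[res - 1]
        ref_res.iat[r, positions.index(label)] = res
        if profile is not None:
            col = res_to_col.get(res)
            if col is None:
                missing.append(res)
                continue
            ent.iat[r, positions.index(label)] = profile.entropy[col - 1]
            hydro.iat[r, positions.index(label)] = profile.hydrophobic_fraction[col - 1]
    if profile is not None and missing:
        raise InputError(
            f"residues claimed by the annotation but absent from the "
            f"column map: {sorted(missing)}"
        )
    return SurfaceMatrix(residue=residue, ref_residue=ref_res, entropy=ent, hydrophobic=hydro)


def trim_matrix(matrix: SurfaceMatrix, keep_positions: Sequence[int] = TRIM_DEFAULT) -> SurfaceMatrix:
    """Column subset of the matrix (cell contents untouched, row order kept)."""
    unknown = [p for p in keep_positions if p not in matrix.positions]
    if unknown:
        raise InputError(f"unknown position labels: {unknown}")
    cols = [p for p in matrix.positions if p in set(keep_positions)]
    return SurfaceMatrix(
        residue=matrix.residue[cols],
        ref_residue=matrix.ref_residue[cols],
        entropy=matrix.entropy[cols],
        hydrophobic=matrix.hydrophobic[cols],
    )


def concave_face(matrix: SurfaceMatrix) -> SurfaceMatrix:
    """Hide the conserved-leucine columns (1, 4, 6): the exposed array."""
    keep = [p for p in matrix.positions if p not in CONSERVED_CORE_POSITIONS]
    return trim_matrix(matrix, keep)


@dataclass
class SurfaceReport:
    entropy: pd.DataFrame
    hydrophobic: pd.DataFrame
    flags: pd.DataFrame  # candidate binding residues

    def n_flagged(self) -> int:
        return int(self.flags.values.sum())


def surface_report(matrix: SurfaceMatrix, criteria: HvCriteria | None = None) -> SurfaceReport:
    """Aligned entropy and hydrophobicity tables plus candidate flags.

    A cell is flagged as a candidate binding residue when its entropy is
    at or above the hv cutoff AND hydrophobic residues occur there.
    """
    criteria = criteria or HvCriteria()
    if matrix.entropy.isna().values.all():
        raise InputError("matrix has no entropy overlay")
    flags = (matrix.entropy >= criteria.entropy_cutoff) & (matrix.hydrophobic > 0)
    return SurfaceReport(
        entropy=matrix.entropy.copy(),
        hydrophobic=matrix.hydrophobic.copy(),
        flags=flags.fillna(False),
    )
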