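"""Per-column Shannon entropy and hydrophobicity of clade alignments.

The diversity statistic is the plug-in Shannon entropy of the amino-acid
frequencies in one alignment column,

    H = -sum_i p_i log2 p_i      (i over the 20 standard amino acids),

in bits.  Gap characters and ambiguity codes (X, B, Z, *) are excluded
from both numerator and denominator, so an invariant column scores 0 and a
column with all 20 amino acids in equal ratios scores log2 20 ~ 4.32.  No
small-sample bias correction is applied; n_obs is reported per column so
users can filter sparse columns themselves.

A clade is called highly variable (hvNLR) when its alignment has 10 or
more positions with entropy of at least 1.5 bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .errors import InputError
from .io import AA20, Alignment, DOMAIN_NAMES, GAP_CHARS

#: Kyte-Doolittle-positive residues; the default "hydrophobic" set.
HYDROPHOBIC_DEFAULT = frozenset("AVLIMFWC")

MAX_ENTROPY_BITS = float(np.log2(len(AA20)))


@dataclass
class HvCriteria:
    """The hv-clade call: >= ``min_positions`` columns at >= ``entropy_cutoff`` bits."""

    entropy_cutoff: float = 1.5
    min_positions: int = 10
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_DEFAULT

    def __post_init__(self) -> None:
        if self.entropy_cutoff <= 0:
            raise InputError("entropy_cutoff must be > 0")
        if self.min_positions < 1:
            raise InputError("min_positions must be >= 1")
        self.hydrophobic_set = frozenset(c.upper() for c in self.hydrophobic_set)


@dataclass
class EntropyProfile:
    """Column-wise diversity profile of an alignment.

    ``frequencies`` is (n_columns, 20) over the amino acids in ``AA20``
    order; rows sum to 1 where ``n_obs >= 1`` and are all-zero for all-gap
    columns.  ``hydrophobic_fraction`` is a percentage.
    """

    frequencies: np.ndarray
    entropy: np.ndarray
    n_obs: np.ndarray
    hydrophobic_fraction: np.ndarray
    hv_flag: np.ndarray
    criteria: HvCriteria = field(default_factory=HvCriteria)

    @property
    def n_columns(self) -> int:
        return len(self.entropy)

    def hv_columns(self) -> list[int]:
        """1-based columns at or above the entropy cutoff."""
        return [int(i) + 1 for i in np.nonzero(self.hv_flag)[0]]

    def to_frame(self) -> pd.DataFrame:
        consensus = np.where(
            self.n_obs > 0,
            np.array(list(AA20))[np.argmax(self.frequencies, axis=1)],
            "-",
        )
        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_columns + 1),
                "consensus": consensus,
                "entropy_bits": self.entropy,
                "n_obs": self.n_obs,
                "hydrophobic_pct": self.hydrophobic_fraction,
                "hv": self.hv_flag,
            }
        )


def _counted(column: str) -> str:
    return "".join(c for c in column.upper() if c in AA20)


def column_entropy(column: str) -> float:
    """Shannon entropy (bits) of one alignment column.

    Frequencies are over non-gap, non-ambiguous residues only; a column
    with at most one distinct counted residue scores 0.
    """
    if not column:
        raise InputError("empty column")
    counted = _counted(column)
    if len(set(counted)) <= 1:
        return 0.0
    counts = np.array([counted.count(a) for a in sorted(set(counted))], dtype=float)
    return float(_scipy_entropy(counts, base=2))


def hydrophobic_fraction(column: str, hydrophobic_set=HYDROPHOBIC_DEFAULT) -> float:
    """Percent hydrophobic residues among observed (non-gap) residues.

    All-gap columns return 0 (there is nothing to score).
    """
    if not column:
        raise InputError("empty column")
    counted = _counted(column)
    if not counted:
        return 0.0
    hydro = sum(1 for c in counted if c in hydrophobic_set)
    return 100.0 * hydro / len(counted)


def profile_alignment(aln: Alignment, criteria: HvCriteria | None = None) -> EntropyProfile:
    """Column-wise entropy / n_obs / hydrophobicity / hv flags for an alignment."""
    criteria = criteria or HvCriteria()
    # (n_seq, n_col) byte matrix for vectorised counting.
    mat = np.frombuffer(
        "".join(rec.seq.upper() for rec in aln.records).encode("ascii"), dtype="S1"
    ).reshape(len(aln.records), aln.length)
    counts = np.zeros((aln.length, len(AA20)), dtype=float)
    for j, a in enumerate(AA20):
        counts[:, j] = (mat == a.encode()).sum(axis=0)
    n_obs = counts.sum(axis=1)
    freqs = np.where(n_obs[:, None] > 0, counts / np.maximum(n_obs, 1)[:, None], 0.0)
    logp = np.zeros_like(freqs)
    np.log2(freqs, out=logp, where=freqs > 0)
    H = -(freqs * logp).sum(axis=1) + 0.0  # "+ 0.0" clears IEEE -0.0
    H[n_obs == 0] = 0.0
    hydro_idx = [j for j, a in enumerate(AA20) if a in criteria.hydrophobic_set]
    hydro_counts = counts[:, hydro_idx].sum(axis=1)
    hydro_pct = np.where(n_obs > 0, 100.0 * hydro_counts / np.maximum(n_obs, 1), 0.0)
    return EntropyProfile(
        frequencies=freqs,
        entropy=H,
        n_obs=n_obs.astype(int),
        hydrophobic_fraction=hydro_pct,
        hv_flag=H >= criteria.entropy_cutoff,
        criteria=criteria,
    )


def mask_gappy_columns(
    aln: Alignment, fraction: float = 0.90
) -> tuple[Alignment, dict[int, int]]:
    """Drop columns whose gap fraction is >= ``fraction``.

    Returns the masked alignment and a map from new 1-based column index to
    the original 1-based column index.
    """
    n = len(aln.records)
    keep: list[int] = []
    for col in range(aln.length):
        gaps = sum(1 for rec in aln.records if rec.seq[col] in GAP_CHARS)
        if gaps / n < fraction:
            keep.append(col)
    if not keep:
        raise InputError("all columns are gappy at this cutoff; nothing left")
    from .io import AlignedSeq  # local import to avoid cycle at module load

    records = [
        AlignedSeq(id=rec.id, ecotype=rec.ecotype,
                   seq="".join(rec.seq[c] for c in keep))
        for rec in aln.records
    ]
    masked = Alignment(records=records, reference_id=aln.reference_id, domains=aln.domains)
    column_map = {new + 1: old + 1 for new, old in enumerate(keep)}
    return masked, column_map


def classify_hv(profile: EntropyProfile, criteria: HvCriteria | None = None) -> tuple[bool, list[int]]:
    """hv call: are there >= min_positions columns at >= entropy_cutoff bits?

    Returns the flag and the qualifying 1-based columns in ascending order.
    """
    criteria = criteria or profile.criteria
    positions = [
        int(i) + 1 for i in np.nonzero(profile.entropy >= criteria.entropy_cutoff)[0]
    ]
    return len(positions) >= criteria.min_positions, positions


def count_hv_by_domain(
    profile: EntropyProfile,
    aln: Alignment,
    column_to_reference: Mapping[int, int] | None = None,
    criteria: HvCriteria | None = None,
) -> pd.DataFrame:
    """Attribute high-entropy columns to reference domains.

    A qualifying column is assigned to the domain containing its reference
    residue.  Columns where the reference is gapped take the nearest
    preceding reference residue; residues upstream of every annotated
    domain fall to preNB.  ``pct_of_domain`` is 100 * count / domain length.
    """
    if aln.domains is None:
        raise InputError("alignment has no domain annotation")
    criteria = criteria or profile.criteria
    if column_to_reference is None:
        column_to_reference = aln.reference_column_map()
    _, hv_cols = classify_hv(profile, criteria)

    domains = list(aln.domains)
    dom_len = {name: end - start + 1 for name, start, end in domains}

    def domain_of_residue(res: int) -> tuple[str, bool]:
        for name, start, end in domains:
            if start <= res <= end:
                return name, False
        preceding = [name for name, _s, e in domains if e < res]
        if preceding:
            return preceding[-1], True
        return "preNB", True

    # Nearest preceding mapped column for gap-in-reference columns.
    mapped_cols = sorted(column_to_reference)
    counts: dict[str, int] = {name: 0 for name, _, _ in domains}
    flagged: dict[str, int] = {name: 0 for name, _, _ in domains}
    counts.setdefault("preNB", 0)
    flagged.setdefault("preNB", 0)
    for col in hv_cols:
        if col in column_to_reference:
            res = column_to_reference[col]
            approx = False
        else:
            prior = [c for c in mapped_cols if c < col]
            if not prior:
                counts["preNB"] += 1
                flagged["preNB"] += 1
                continue
            res = column_to_reference[prior[-1]]
            approx = True
        name, out_of_interval = domain_of_residue(res)
        counts[name] = counts.get(name, 0) + 1
        if approx or out_of_interval:
            flagged[name] = flagged.get(name, 0) + 1

    rows = []
    order = [n for n in DOMAIN_NAMES if n in counts] + [
        n for n in counts if n not in DOMAIN_NAMES
    ]
    for name in order:
        length = dom_len.get(name)
        count = counts.get(name, 0)
        rows.append(
            {
                "domain": name,
                "n_hv": count,
                "domain_length": length if length is not None else np.nan,
                "pct_of_domain": (100.0 * count / length) if length else np.nan,
                "n_gap_attributed": flagged.get(name, 0),
            }
        )
    return pd.DataFrame(
        rows, columns=["domain", "n_hv", "domain_length", "pct_of_domain", "n_gap_attributed"]
    )
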