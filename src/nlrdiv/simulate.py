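"""Synthetic pan-NLRome fixtures with machine-readable ground truth.

The generator emulates the structure of a multi-ecotype NLR dataset: a
bootstrapped gene tree with one well-supported subclade per gene family
(long inter-family branches, short intra-family branches), and one gapped
protein alignment per family in which a designated minority of families is
"highly variable": a set of planted columns inside the LRR repeat region
is drawn i.i.d. uniformly over k amino acids per sequence, against a
near-invariant background (fixed residue, small per-sequence substitution
probability).  This per-column sampling scheme is deliberately simple —
it gives analytically known expected entropies (log2 k for planted
columns) rather than realistic phylogenetically correlated evolution.

All sampling flows through one seeded generator, so a config reproduces
its outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .errors import InputError
from .io import AA20, AlignedSeq, Alignment, PhyloTree, StructureModel, ResidueRecord, AtomRecord
from .structure import ContactSet

#: 24-residue repeat template: LxxLxLxx core, then a linker free of
#: aliphatic-class residues so the core detector cannot fire spuriously.
REPEAT_CORE = "LRSLDLSN"
REPEAT_LINKER = "NKQGSEKQGDSTNRHE"
REPEAT_TEMPLATE = REPEAT_CORE + REPEAT_LINKER
#: Core offsets (1-8) that face the solvent; hv columns are planted here.
VARIABLE_CORE_OFFSETS = (2, 3, 5, 7, 8)

# Domain layout of the synthetic reference protein (lengths in residues).
PRE_NB_LEN = 60
NB_ARC_LEN = 300
LINKER_LEN = 40
POST_LRR_LEN = 60


@dataclass
class SimConfig:
    """Study-scale defaults: 62 ecotypes, 20 families of which a quarter
    are hv with 15 planted columns of 6 equiprobable residues each."""

    seed: int = 0
    n_ecotypes: int = 62
    n_families: int = 20
    hv_family_fraction: float = 0.25
    n_hv_columns: int = 15
    hv_column_k: int = 6
    background_substitution_rate: float = 0.01
    gap_rate: float = 0.05
    duplication_rate: float = 0.0
    repeat_count: int = 14
    intra_branch_range: tuple[float, float] = (0.005, 0.05)
    inter_branch_range: tuple[float, float] = (0.35, 0.60)

    def __post_init__(self) -> None:
        for name in ("hv_family_fraction", "background_substitution_rate",
                     "gap_rate", "duplication_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if not (2 <= self.hv_column_k <= 20):
            raise InputError("hv_column_k must be in [2, 20]")
        if self.n_ecotypes < 2 or self.n_families < 1:
            raise InputError("need >= 2 ecotypes and >= 1 family")
        avail = len(VARIABLE_CORE_OFFSETS) * self.repeat_count
        if self.n_hv_columns > avail:
            raise InputError(
                f"{self.n_hv_columns} hv columns requested but the LRR "
                f"template only has {avail} variable positions"
            )

    @property
    def lrr_len(self) -> int:
        return len(REPEAT_TEMPLATE) * self.repeat_count

    @property
    def seq_len(self) -> int:
        return PRE_NB_LEN + NB_ARC_LEN + LINKER_LEN + self.lrr_len + POST_LRR_LEN

    @property
    def lrr_start(self) -> int:
        """1-based first residue of the LRR region."""
        return PRE_NB_LEN + NB_ARC_LEN + LINKER_LEN + 1

    def domains(self) -> list[tuple[str, int, int]]:
        a = PRE_NB_LEN
        b = a + NB_ARC_LEN
        c = b + LINKER_LEN
        d = c + self.lrr_len
        e = d + POST_LRR_LEN
        return [
            ("preNB", 1, a),
            ("NB-ARC", a + 1, b),
            ("linker", b + 1, c),
            ("LRR", c + 1, d),
            ("postLRR", d + 1, e),
        ]


@dataclass
class FamilyTruth:
    name: str
    is_hv: bool
    hv_columns: list[int]          # 1-based alignment columns (== residues)
    lrr_core_starts: list[int]     # 1-based reference residues
    leaves: frozenset[str]


@dataclass
class GroundTruth:
    families: dict[str, FamilyTruth]
    ecotype_of: dict[str, str]
    seed: int

    def clade_of(self) -> dict[str, str]:
        return {
            leaf: fam.name
            for fam in self.families.values()
            for leaf in fam.leaves
        }


def _random_join_tree(labels, rng, blen_range, taxon_ns):
    """Random bifurcating topology by iteratively joining random pairs."""
    lo, hi = blen_range
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxon_ns.require_taxon(label=lab)
        node.edge.length = float(rng.uniform(lo, hi))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(lo, hi))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _simulate_tree(cfg: SimConfig, family_leaves: dict[str, list[str]], rng) -> PhyloTree:
    taxon_ns = dendropy.TaxonNamespace()
    family_roots = []
    for fam, leaves in family_leaves.items():
        sub = _random_join_tree(leaves, rng, cfg.intra_branch_range, taxon_ns)
        for node in sub.preorder_iter():
            if not node.is_leaf():
                node.support = float(rng.integers(50, 100))
        sub.support = 100.0  # the family clade is maximally supported
        sub.edge.length = float(rng.uniform(*cfg.inter_branch_range))
        family_roots.append(sub)
    if len(family_roots) == 1:
        root = family_roots[0]
    else:
        lo, hi = cfg.inter_branch_range
        nodes = family_roots[:]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[i], nodes[j]
            parent = dendropy.Node()
            parent.add_child(a)
            parent.add_child(b)
            parent.edge.length = float(rng.uniform(lo, hi))
            # deep backbone nodes are poorly supported, as in real NLR trees
            parent.support = float(rng.integers(10, 70))
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(parent)
        root = nodes[0]
    root.support = None
    root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    return PhyloTree.from_dendropy(tree)


def _reference_sequence(cfg: SimConfig, rng) -> np.ndarray:
    """Ungapped reference: random background outside the LRR, tiled
    repeat template inside it."""
    aa = np.array(list(AA20))
    seq = aa[rng.integers(0, 20, size=cfg.seq_len)]
    lrr0 = cfg.lrr_start - 1
    template = np.array(list(REPEAT_TEMPLATE * cfg.repeat_count))
    seq[lrr0:lrr0 + cfg.lrr_len] = template
    return seq


def _simulate_family_alignment(cfg: SimConfig, leaves, is_hv, rng):
    """Returns (Alignment, hv column list, core starts)."""
    n = len(leaves)
    ref = _reference_sequence(cfg, rng)
    L = cfg.seq_len
    aa = np.array(list(AA20))

    # matrix of residues: start everyone at the reference
    mat = np.tile(ref, (n, 1))

    # background substitutions (reference row 0 stays clean)
    sub_mask = rng.random((n, L)) < cfg.background_substitution_rate
    sub_mask[0, :] = False
    shift = rng.integers(1, 20, size=sub_mask.sum())
    idx = np.flatnonzero(sub_mask)
    ref_codes = np.searchsorted(aa, mat.ravel()[idx])
    mat.ravel()[idx] = aa[(ref_codes + shift) % 20]

    hv_columns: list[int] = []
    if is_hv:
        candidates = [
            cfg.lrr_start - 1 + r * len(REPEAT_TEMPLATE) + off - 1
            for r in range(cfg.repeat_count)
            for off in VARIABLE_CORE_OFFSETS
        ]
        chosen = rng.choice(len(candidates), size=cfg.n_hv_columns, replace=False)
        hv_cols0 = sorted(candidates[i] for i in chosen)
        for col in hv_cols0:
            alphabet = aa[rng.choice(20, size=cfg.hv_column_k, replace=False)]
            mat[:, col] = alphabet[rng.integers(0, cfg.hv_column_k, size=n)]
        hv_columns = [c + 1 for c in hv_cols0]

    # gaps: N-terminal truncations and short internal deletions
    # (never on the reference row)
    for i in range(1, n):
        if rng.random() < cfg.gap_rate:
            cut = int(rng.integers(5, 31))
            mat[i, :cut] = "-"
        if rng.random() < cfg.gap_rate:
            dlen = int(rng.integers(3, 11))
            start = int(rng.integers(0, L - dlen))
            mat[i, start:start + dlen] = "-"

    records = [
        AlignedSeq(id=leaf, ecotype=leaf.partition("|")[0], seq="".join(mat[i]))
        for i, leaf in enumerate(leaves)
    ]
    core_starts = [
        cfg.lrr_start + r * len(REPEAT_TEMPLATE) for r in range(cfg.repeat_count)
    ]
    aln = Alignment(records=records, reference_id=leaves[0], domains=cfg.domains())
    return aln, hv_columns, core_starts


def simulate_nlrome(cfg: SimConfig | None = None):
    """Generate (PhyloTree, {family: Alignment}, GroundTruth).

    Deterministic under ``cfg.seed``: the same config yields byte-identical
    FASTA/Newick output.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    n_hv = int(round(cfg.hv_family_fraction * cfg.n_families))
    hv_idx = set(rng.choice(cfg.n_families, size=n_hv, replace=False).tolist())

    family_leaves: dict[str, list[str]] = {}
    ecotype_of: dict[str, str] = {}
    for f in range(cfg.n_families):
        fam = f"Fam{f:02d}"
        leaves = []
        for e in range(cfg.n_ecotypes):
            eco = f"Eco{e:03d}"
            leaf = f"{eco}|{fam}"
            leaves.append(leaf)
            ecotype_of[leaf] = eco
        if cfg.duplication_rate > 0 and rng.random() < cfg.duplication_rate:
            e = int(rng.integers(0, cfg.n_ecotypes))
            eco = f"Eco{e:03d}"
            leaf = f"{eco}|{fam}_d2"
            leaves.append(leaf)
            ecotype_of[leaf] = eco
        family_leaves[fam] = leaves

    tree = _simulate_tree(cfg, family_leaves, rng)

    alignments: dict[str, Alignment] = {}
    families: dict[str, FamilyTruth] = {}
    for f, (fam, leaves) in enumerate(family_leaves.items()):
        is_hv = f in hv_idx
        aln, hv_columns, core_starts = _simulate_family_alignment(cfg, leaves, is_hv, rng)
        alignments[fam] = aln
        families[fam] = FamilyTruth(
            name=fam,
            is_hv=is_hv,
            hv_columns=hv_columns,
            lrr_core_starts=core_starts,
            leaves=frozenset(leaves),
        )
    truth = GroundTruth(families=families, ecotype_of=ecotype_of, seed=cfg.seed)
    return tree, alignments, truth


def write_fixture(outdir, tree: PhyloTree, alignments, truth: GroundTruth,
                  cfg: SimConfig) -> None:
    """Persist a simulated NLRome: Newick, per-family FASTA, ground truth."""
    from .io import write_alignment, write_tree

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tree(tree, out / "nlrome.nwk")
    for fam, aln in alignments.items():
        write_alignment(aln, out / f"{fam}.fasta")
    payload = {
        "seed": truth.seed,
        "config": asdict(cfg),
        "ecotype_of": truth.ecotype_of,
        "families": {
            name: {
                "is_hv": ft.is_hv,
                "hv_columns": ft.hv_columns,
                "lrr_core_starts": ft.lrr_core_starts,
                "leaves": sorted(ft.leaves),
            }
            for name, ft in truth.families.items()
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def make_toy_complex(
    n_receptor_res: int = 10,
    contact_positions=(3, 7),
    cutoff: float = 4.5,
    margin: float = 1.0,
) -> tuple[StructureModel, ContactSet]:
    """A two-chain point geometry with known contacts.

    Receptor residues sit on a line; for each designated contact the
    ligand chain carries an atom at distance ``cutoff - margin``, and every
    other receptor-ligand pair is farther than ``cutoff + margin``.
    """
    if margin >= cutoff:
        raise InputError("margin must be smaller than the contact cutoff")
    if margin <= 0:
        raise InputError("margin must be > 0")
    contact_positions = sorted(set(contact_positions))
    if contact_positions and not (
        1 <= contact_positions[0] and contact_positions[-1] <= n_receptor_res
    ):
        raise InputError("contact positions must lie within the receptor chain")
    spacing = max(10.0, 2 * (cutoff + margin) + 2.0)
    receptor = [
        ResidueRecord(
            number=i, icode="", name="ALA",
            atoms=[AtomRecord(name="CA", element="C", x=spacing * i, y=0.0, z=0.0)],
        )
        for i in range(1, n_receptor_res + 1)
    ]
    ligand = [
        ResidueRecord(
            number=1000 + i, icode="", name="GLY",
            atoms=[AtomRecord(name="CA", element="C",
                              x=spacing * i, y=cutoff - margin, z=0.0)],
        )
        for i in contact_positions
    ]
    # an always-present distant ligand residue keeps the chain non-empty
    ligand.append(
        ResidueRecord(
            number=1999, icode="", name="GLY",
            atoms=[AtomRecord(name="CA", element="C", x=0.0, y=1000.0, z=0.0)],
        )
    )
    model = StructureModel(chains={"A": receptor, "B": ligand})
    truth = ContactSet(
        receptor_chain="A",
        ligand_chain="B",
        contacts=frozenset(contact_positions),
        cutoff=cutoff,
    )
    return model, truth
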