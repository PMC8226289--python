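"""Readers and writers for the formats the pipeline touches.

Covers gapped protein FASTA alignments (with ecotype metadata parsed from
record ids), Newick trees with bootstrap supports, PDB structures, and the
two annotation sinks used for visualisation: UCSF-Chimera residue-attribute
files and iTOL gradient-dataset files.

Coordinates are 1-based inclusive throughout (alignment columns, reference
residues, structure residue numbers), matching structural-biology
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import gemmi
from Bio import SeqIO

from .errors import InputError, InvariantError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA20_SET = frozenset(AA20)
GAP_CHARS = frozenset("-.")
AMBIGUITY_CODES = frozenset("XBZ*")
DOMAIN_NAMES = ("preNB", "NB-ARC", "linker", "LRR", "postLRR")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignedSeq:
    """One row of a gapped alignment: sequence id, ecotype label, residues."""

    id: str
    ecotype: str
    seq: str


@dataclass
class Alignment:
    """A gapped protein multiple sequence alignment with optional reference
    domain annotation.

    ``domains`` are ``(name, start, end)`` intervals in 1-based inclusive
    *reference residue* coordinates (i.e. positions along the ungapped
    reference sequence), ordered and non-overlapping.
    """

    records: list[AlignedSeq]
    reference_id: str | None = None
    domains: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment has no sequences")
        length = len(self.records[0].seq)
        for rec in self.records:
            if not rec.seq:
                raise InputError(f"empty sequence for record {rec.id!r}")
            if len(rec.seq) != length:
                raise InputError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.seq)}, expected {length}"
                )
        ids = [rec.id for rec in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dup}")
        if self.reference_id is not None and self.reference_id not in set(ids):
            raise InputError(f"reference id {self.reference_id!r} not in alignment")
        if self.domains is not None:
            self._check_domains()

    def _check_domains(self) -> None:
        prev_end = 0
        for name, start, end in self.domains:  # type: ignore[union-attr]
            if name not in DOMAIN_NAMES:
                raise InputError(f"unknown domain name {name!r}")
            if not (1 <= start <= end):
                raise InputError(f"bad domain interval {name}: [{start}, {end}]")
            if start <= prev_end:
                raise InputError(f"domain {name} overlaps or is out of order")
            prev_end = end

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0].seq)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def get(self, seq_id: str) -> AlignedSeq:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        """Rows restricted to ``keep_ids`` (order preserved)."""
        keep = set(keep_ids)
        recs = [rec for rec in self.records if rec.id in keep]
        ref = self.reference_id if self.reference_id in {r.id for r in recs} else None
        return Alignment(records=recs, reference_id=ref, domains=self.domains)

    def reference_record(self) -> AlignedSeq:
        if self.reference_id is None:
            raise InputError("alignment has no designated reference sequence")
        return self.get(self.reference_id)

    def ungapped_reference(self) -> str:
        seq = self.reference_record().seq
        return "".join(c for c in seq if c not in GAP_CHARS)

    def reference_column_map(self) -> dict[int, int]:
        """Map 1-based alignment column -> 1-based reference residue number,
        for columns where the reference is not gapped."""
        mapping: dict[int, int] = {}
        res = 0
        for col, c in enumerate(self.reference_record().seq, start=1):
            if c not in GAP_CHARS:
                res += 1
                mapping[col] = res
        return mapping

    def flagged_ambiguities(self) -> list[tuple[str, int]]:
        """(record id, 1-based column) pairs holding ambiguity codes."""
        out = []
        for rec in self.records:
            for col, c in enumerate(rec.seq, start=1):
                if c.upper() in AMBIGUITY_CODES:
                    out.append((rec.id, col))
        return out


def default_ecotype_parser(separator: str = "|") -> Callable[[str], str]:
    """Ecotype = prefix of the record id before the first ``separator``.

    Deposited pan-genome datasets differ in id scheme, hence the rule is a
    configurable callable rather than a constant.
    """

    def parse(seq_id: str) -> str:
        head, sep, _ = seq_id.partition(separator)
        return head if sep else ""

    return parse


def read_alignment(
    path,
    ecotype_parser: Callable[[str], str] | str | None = "|",
    reference_id: str | None = None,
    domains: list[tuple[str, int, int]] | None = None,
) -> Alignment:
    """Read a gapped protein FASTA alignment.

    ``ecotype_parser`` is either a callable id -> ecotype, a separator
    string for the default prefix rule, or None (no ecotype extraction).
    """
    if ecotype_parser is None:
        parse = lambda _s: ""  # noqa: E731
    elif isinstance(ecotype_parser, str):
        parse = default_ecotype_parser(ecotype_parser)
    else:
        parse = ecotype_parser
    records = [
        AlignedSeq(id=rec.id, ecotype=parse(rec.id), seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return Alignment(records=records, reference_id=reference_id, domains=domains)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """A phylogeny with branch lengths (substitutions/site) and optional
    integer bootstrap supports (0-100) on internal nodes.

    Thin wrapper over :class:`dendropy.Tree`; every node carries two extra
    attributes after normalisation: ``index`` (stable preorder id) and
    ``support`` (float in [0, 100] or None when absent).
    """

    tree: dendropy.Tree

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, validate: bool = True) -> "PhyloTree":
        obj = cls(tree=tree)
        obj._normalize()
        if validate:
            obj.validate()
        return obj

    def _normalize(self) -> None:
        for i, node in enumerate(self.tree.preorder_node_iter()):
            node.index = i
            if not hasattr(node, "support"):
                node.support = None

    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise InvariantError("duplicate leaf labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise InvariantError(f"negative branch length {edge.length}")
        for node in self.tree.preorder_node_iter():
            s = getattr(node, "support", None)
            if s is not None and not (0 <= s <= 100):
                raise InvariantError(f"support {s} outside [0, 100]")

    # -- accessors ---------------------------------------------------------
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def root(self):
        return self.tree.seed_node

    def is_rooted(self) -> bool:
        """Rooted in the bifurcating-root sense used for clade extraction."""
        return len(self.root.child_nodes()) == 2

    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.root
        )

    def leaf_set(self, node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def clone(self) -> "PhyloTree":
        t = self.tree.clone(depth=1)
        return PhyloTree.from_dendropy(t, validate=False)


def _parse_support_label(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


def read_tree(path=None, data: str | None = None,
              support_dialect: str = "internal-node-label") -> PhyloTree:
    """Read a Newick tree.

    ``support_dialect`` is ``internal-node-label`` (RAxML convention: the
    bootstrap value is stored as the internal node label) or
    ``branch-metadata`` (``[&support=...]`` comment annotations).
    """
    if support_dialect not in ("internal-node-label", "branch-metadata"):
        raise InputError(f"unknown support dialect {support_dialect!r}")
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
        extract_comment_metadata=(support_dialect == "branch-metadata"),
    )
    try:
        if data is not None:
            tree = dendropy.Tree.get(data=data, **kwargs)
        else:
            tree = dendropy.Tree.get(path=str(path), **kwargs)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise InputError(f"malformed Newick: {exc}") from exc

    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.support = None
            continue
        if support_dialect == "internal-node-label":
            node.support = _parse_support_label(node.label)
        else:
            val = node.annotations.get_value("support")
            if val is None and node.edge is not None:
                val = node.edge.annotations.get_value("support")
            node.support = float(val) if val is not None else None
    return PhyloTree.from_dendropy(tree)


def write_tree(ptree: PhyloTree, path=None,
               support_dialect: str = "internal-node-label") -> str:
    """Write Newick with supports as internal node labels (RAxML style).

    Returns the Newick string; also writes to ``path`` when given.
    """
    if support_dialect != "internal-node-label":
        raise InputError("only the internal-node-label dialect is written")
    tree = ptree.tree.clone(depth=1)
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            s = getattr(node, "support", None)
            node.label = (f"{s:g}" if s is not None else None)
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class ResidueRecord:
    number: int
    icode: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self):
        """Residue identifier: plain number when no insertion code."""
        return self.number if not self.icode.strip() else f"{self.number}{self.icode}"


@dataclass
class StructureModel:
    """Chains of residues with heavy-atom coordinates (Angstrom)."""

    chains: dict[str, list[ResidueRecord]]

    def __post_init__(self) -> None:
        for chain_id, residues in self.chains.items():
            keys = [r.key for r in residues]
            if len(set(keys)) != len(keys):
                raise InvariantError(f"duplicate residue ids in chain {chain_id}")
            for res in residues:
                for atom in res.atoms:
                    if not all(map(math.isfinite, (atom.x, atom.y, atom.z))):
                        raise InvariantError(
                            f"non-finite coordinates in {chain_id}/{res.key}"
                        )

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        if chain_id not in self.chains:
            raise InputError(
                f"chain {chain_id!r} not in structure "
                f"(available: {sorted(self.chains)})"
            )
        return self.chains[chain_id]


def read_structure(path) -> StructureModel:
    """Read a PDB (or mmCIF) file into a StructureModel (first model only)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise InputError(f"no models in structure file {path}")
    chains: dict[str, list[ResidueRecord]] = {}
    model = st[0]
    for chain in model:
        residues = []
        for res in chain:
            atoms = [
                AtomRecord(
                    name=a.name, element=a.element.name,
                    x=a.pos.x, y=a.pos.y, z=a.pos.z,
                )
                for a in res
            ]
            residues.append(
                ResidueRecord(
                    number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    name=res.name,
                    atoms=atoms,
                )
            )
        chains[chain.name] = residues
    return StructureModel(chains=chains)


def write_structure(model: StructureModel, path) -> None:
    """Write a StructureModel as a minimal PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = "nlrdiv"
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gc = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Attribute / annotation files
# ---------------------------------------------------------------------------

def write_attribute_file(
    values: Mapping,
    target: str,
    path,
    attribute_name: str = "shannonEntropy",
) -> None:
    """Write per-residue (Chimera) or per-leaf (iTOL) scores.

    ``chimera``: the standard ``defattr`` layout — a header naming the
    attribute then one ``\\t:<resnum>\\t<value>`` line per residue, residue
    order ascending.  ``itol``: a gradient-dataset annotation block with one
    ``id<TAB>value`` row per entry.
    """
    if not values:
        raise InputError("empty value map")
    for k, v in values.items():
        if not math.isfinite(float(v)):
            raise InputError(f"non-finite score for {k!r}")
    if target == "chimera":
        for k in values:
            if not (isinstance(k, int) and k > 0):
                raise InputError(f"chimera residue numbers must be positive ints, got {k!r}")
        lines = [
            f"attribute: {attribute_name}",
            "match mode: 1-to-1",
            "recolor: false",
        ]
        for resnum in sorted(values):
            lines.append(f"\t:{resnum}\t{float(values[resnum]):g}")
    elif target == "itol":
        lines = [
            "DATASET_GRADIENT",
            "SEPARATOR TAB",
            f"DATASET_LABEL\t{attribute_name}",
            "COLOR\t#2a6fbb",
            "COLOR_MIN\t#d4e6f9",
            "COLOR_MAX\t#08306b",
            "DATA",
        ]
        for key in values:
            lines.append(f"{key}\t{float(values[key]):g}")
    else:
        raise InputError(f"unknown attribute target {target!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_tsv(frame, path, index: bool = False) -> None:
    """Uniform TSV export for tabular results (pandas DataFrame)."""
    frame.to_csv(path, sep="\t", index=index)
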