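"""Taxonomy-aware ZooMS peptide-marker database.

Covers in-silico tryptic digestion, marker m/z prediction from COL1
sequences, diagnostic-rank assignment via lowest common ancestors, and a
flat TSV serialization of the marker table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._masses import (
    DEAMIDATION_SHIFT,
    HYDROXYLATION_SHIFT,
    MONOISOTOPIC_RESIDUE_MASS,
    PROTON_MASS,
    WATER_MASS,
)

RANKS = ("species", "genus", "subfamily", "family", "superfamily", "order", "class")
_RANK_LEVEL = {r: i for i, r in enumerate(RANKS)}
_ROOT_RANK = "class"

_VALID_RESIDUES = set(MONOISOTOPIC_RESIDUE_MASS) | {"X"}


@dataclass(eq=False)
class TaxonNode:
    """A node in the reference taxonomy."""

    name: str
    rank: str
    parent: "TaxonNode | None" = None

    def __post_init__(self) -> None:
        if self.rank not in _RANK_LEVEL:
            raise ValueError(f"unknown rank {self.rank!r}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaxonNode({self.name!r}, {self.rank!r})"

    @property
    def level(self) -> int:
        return _RANK_LEVEL[self.rank]

    def path_to_root(self) -> list["TaxonNode"]:
        """Nodes from self up to and including the root."""
        out, node = [], self
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def is_ancestor_or_self(self, other: "TaxonNode") -> bool:
        """True if ``self`` lies on ``other``'s path to the root."""
        return self in other.path_to_root()


class Taxonomy:
    """A rooted tree of :class:`TaxonNode` with unique names."""

    def __init__(self, root: TaxonNode):
        self.root = root
        self._by_name: dict[str, TaxonNode] = {root.name: root}

    def add(self, name: str, rank: str, parent: str) -> TaxonNode:
        if name in self._by_name:
            raise ValueError(f"duplicate taxon name {name!r}")
        parent_node = self[parent]
        node = TaxonNode(name, rank, parent_node)
        if node.level >= parent_node.level:
            raise ValueError(
                f"rank {rank!r} of {name!r} does not refine parent rank "
                f"{parent_node.rank!r}"
            )
        self._by_name[name] = node
        return node

    def __getitem__(self, name: str) -> TaxonNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"taxon {name!r} not in taxonomy") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def children(self, node: TaxonNode) -> list[TaxonNode]:
        return [n for n in self if n.parent is node]

    def lca(self, nodes: Iterable[TaxonNode]) -> TaxonNode:
        nodes = list(nodes)
        if not nodes:
            raise ValueError("cannot take the LCA of an empty set")
        common = set(nodes[0].path_to_root())
        for node in nodes[1:]:
            common &= set(node.path_to_root())
        # smallest level = most specific rank
        return min(common, key=lambda n: n.level)

    # -- serialization -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        lines = ["child\tparent\trank"]
        for node in self:
            parent = node.parent.name if node.parent else ""
            lines.append(f"{node.name}\t{parent}\t{node.rank}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["child", "parent", "rank"]:
                raise ValueError(f"unexpected taxonomy header {header}")
            for line in fh:
                if line.strip():
                    rows.append(line.rstrip("\n").split("\t"))
        roots = [r for r in rows if not r[1]]
        if len(roots) != 1:
            raise ValueError("taxonomy TSV must contain exactly one root")
        tax = cls(TaxonNode(roots[0][0], roots[0][2]))
        pending = [r for r in rows if r[1]]
        while pending:
            progressed = []
            for name, parent, rank in pending:
                if parent in tax:
                    tax.add(name, rank, parent)
                else:
                    progressed.append((name, parent, rank))
            if len(progressed) == len(pending):
                raise ValueError(f"unresolvable parents in taxonomy: {progressed}")
            pending = progressed
        return tax


def lowest_consistent_taxon(matched: Iterable[TaxonNode]) -> TaxonNode:
    """Most specific taxon consistent with a set of matched diagnostic taxa.

    If the matched nodes all lie on a single root-to-tip path the deepest
    one is returned; conflicting nodes collapse to their lowest common
    ancestor.
    """
    nodes = list(matched)
    if not nodes:
        raise ValueError("matched taxon set is empty")
    deepest = min(nodes, key=lambda n: n.level)
    chain = set(deepest.path_to_root())
    if all(n in chain for n in nodes):
        return deepest
    common = set(nodes[0].path_to_root())
    for node in nodes[1:]:
        common &= set(node.path_to_root())
    return min(common, key=lambda n: n.level)


# ---------------------------------------------------------------------------
# Digestion and mass prediction
# ---------------------------------------------------------------------------


def digest_sequence(
    sequence: str, min_length: int = 6, max_missed_cleavages: int = 1
) -> list[str]:
    """Tryptic peptides of ``sequence``: cleave after K/R unless followed by P.

    Peptides shorter than ``min_length`` are dropped; variants with up to
    ``max_missed_cleavages`` internal cleavage sites are included.
    """
    for pos, aa in enumerate(sequence):
        if aa not in _VALID_RESIDUES:
            raise ValueError(f"invalid residue {aa!r} at position {pos + 1}")
    fragments: list[str] = []
    start = 0
    for i, aa in enumerate(sequence):
        next_aa = sequence[i + 1] if i + 1 < len(sequence) else ""
        if aa in "KR" and next_aa != "P":
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])
    peptides = []
    for i in range(len(fragments)):
        for j in range(i, min(i + max_missed_cleavages + 1, len(fragments))):
            peptide = "".join(fragments[i : j + 1])
            if len(peptide) >= min_length:
                peptides.append(peptide)
    return peptides


def peptide_mz(
    sequence: str,
    n_hydroxylations: int = 0,
    n_deamidations: int = 0,
    charge: int = 1,
) -> float:
    """Monoisotopic m/z of a peptide ion with the given modification counts."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    _check_modifications(sequence, n_hydroxylations, n_deamidations)
    mass = WATER_MASS
    for pos, aa in enumerate(sequence):
        try:
            mass += MONOISOTOPIC_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"invalid residue {aa!r} at position {pos + 1}") from None
    mass += n_hydroxylations * HYDROXYLATION_SHIFT
    mass += n_deamidations * DEAMIDATION_SHIFT
    return (mass + charge * PROTON_MASS) / charge


def _check_modifications(sequence: str, n_hyd: int, n_deam: int) -> None:
    if n_hyd < 0 or n_deam < 0:
        raise ValueError("modification counts must be non-negative")
    if n_hyd > sequence.count("P"):
        raise ValueError(
            f"{n_hyd} hydroxylations exceed {sequence.count('P')} prolines"
        )
    n_nq = sequence.count("N") + sequence.count("Q")
    if n_deam > n_nq:
        raise ValueError(f"{n_deam} deamidations exceed {n_nq} N/Q residues")


# ---------------------------------------------------------------------------
# Marker records
# ---------------------------------------------------------------------------


@dataclass
class MarkerRecord:
    """One peptide marker with its diagnostic taxon."""

    label: str
    sequence: str | None
    n_hydroxylations: int
    n_deamidations: int
    mz_MH: float
    diagnostic_taxon: TaxonNode
    source: str = "predicted"

    def __post_init__(self) -> None:
        if self.mz_MH <= 0:
            raise ValueError("mz_MH must be positive")
        if self.source not in ("measured", "predicted"):
            raise ValueError(f"invalid source {self.source!r}")
        if self.sequence is not None:
            _check_modifications(
                self.sequence, self.n_hydroxylations, self.n_deamidations
            )
            expected = peptide_mz(
                self.sequence, self.n_hydroxylations, self.n_deamidations
            )
            if abs(expected - self.mz_MH) > 0.05:
                raise ValueError(
                    f"mz_MH {self.mz_MH:.4f} inconsistent with sequence "
                    f"({expected:.4f} computed)"
                )

    @property
    def key(self) -> tuple:
        return (
            self.label,
            self.diagnostic_taxon.name,
            self.n_hydroxylations,
            self.n_deamidations,
        )


_DB_HEADER = ["label", "sequence", "n_hyd", "n_deam", "mz_MH", "taxon", "rank", "source"]


@dataclass
class MarkerDatabase:
    taxonomy: Taxonomy
    markers: list[MarkerRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for m in self.markers:
            if m.diagnostic_taxon.name not in self.taxonomy:
                raise ValueError(
                    f"marker taxon {m.diagnostic_taxon.name!r} not in taxonomy"
                )
            if m.key in seen:
                raise ValueError(f"duplicate marker {m.key}")
            seen.add(m.key)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(_DB_HEADER)]
        for m in self.markers:
            lines.append(
                "\t".join(
                    [
                        m.label,
                        m.sequence or "",
                        str(m.n_hydroxylations),
                        str(m.n_deamidations),
                        f"{m.mz_MH:.4f}",
                        m.diagnostic_taxon.name,
                        m.diagnostic_taxon.rank,
                        m.source,
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, taxonomy: Taxonomy) -> "MarkerDatabase":
        markers = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _DB_HEADER:
                raise ValueError(f"unexpected marker DB header {header}")
            for line in fh:
                if not line.strip():
                    continue
                label, seq, n_hyd, n_deam, mz, taxon, rank, source = line.rstrip(
                    "\n"
                ).split("\t")
                node = taxonomy[taxon]
                if node.rank != rank:
                    raise ValueError(
                        f"rank mismatch for {taxon!r}: TSV says {rank!r}, "
                        f"taxonomy says {node.rank!r}"
                    )
                markers.append(
                    MarkerRecord(
                        label=label,
                        sequence=seq or None,
                        n_hydroxylations=int(n_hyd),
                        n_deamidations=int(n_deam),
                        mz_MH=float(mz),
                        diagnostic_taxon=node,
                        source=source,
                    )
                )
        return cls(taxonomy, markers)


def predict_markers(
    col1_sequences: Mapping[str, str],
    taxonomy: Taxonomy,
    hydroxylation_range: Sequence[int] = (0, 1, 2, 3),
    min_length: int = 6,
    max_missed_cleavages: int = 0,
) -> MarkerDatabase:
    """Predict a marker database from per-taxon COL1 sequences.

    Each distinct (peptide mass, hydroxylation state) is tagged diagnostic at
    the LCA of the taxa whose digests produce it; taxon-unique masses become
    markers at that taxon.
    """
    for name in col1_sequences:
        if name not in taxonomy:
            raise KeyError(f"taxon {name!r} not in taxonomy")
    # group peptides by base (unmodified) mass across taxa
    by_mass: dict[int, dict] = {}
    for taxon, seq in col1_sequences.items():
        for pep in set(digest_sequence(seq, min_length, max_missed_cleavages)):
            if "X" in pep:
                continue
            base = peptide_mz(pep, 0, 0)
            mkey = round(base * 1000)
            entry = by_mass.setdefault(mkey, {"taxa": set(), "peptides": {}})
            entry["taxa"].add(taxon)
            entry["peptides"][taxon] = pep
    markers: list[MarkerRecord] = []
    used_labels: set[str] = set()
    for mkey in sorted(by_mass):
        entry = by_mass[mkey]
        nodes = [taxonomy[t] for t in sorted(entry["taxa"])]
        diag = nodes[0] if len(nodes) == 1 else taxonomy.lca(nodes)
        pep = entry["peptides"][sorted(entry["taxa"])[0]]
        n_prolines = pep.count("P")
        base_label = f"P{round(peptide_mz(pep, 0, 0))}"
        label = base_label
        suffix = ord("b")
        while label in used_labels:  # distinct peptides, same nominal mass
            label = f"{base_label}{chr(suffix)}"
            suffix += 1
        used_labels.add(label)
        for n_hyd in hydroxylation_range:
            if n_hyd > n_prolines:
                continue
            mz = peptide_mz(pep, n_hyd, 0)
            markers.append(
                MarkerRecord(
                    label=label,
                    sequence=pep,
                    n_hydroxylations=n_hyd,
                    n_deamidations=0,
                    mz_MH=mz,
                    diagnostic_taxon=diag,
                    source="predicted",
                )
            )
    return MarkerDatabase(taxonomy, markers)


def taxon_marker_set(
    db: MarkerDatabase, col1_sequence: str, hydroxylation_range: Sequence[int],
    min_length: int = 6, max_missed_cleavages: int = 0,
) -> list[MarkerRecord]:
    """Markers of ``db`` whose mass occurs in the digest of ``col1_sequence``."""
    masses = set()
    for pep in set(digest_sequence(col1_sequence, min_length, max_missed_cleavages)):
        if "X" in pep:
            continue
        for n_hyd in hydroxylation_range:
            if n_hyd > pep.count("P"):
                continue
            masses.add(round(peptide_mz(pep, n_hyd, 0) * 1000))
    return [m for m in db if round(m.mz_MH * 1000) in masses]
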