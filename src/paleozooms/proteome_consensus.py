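"""PSM ingestion, target-decoy FDR filtering, majority-consensus protein
reconstruction and concatenated alignment assembly."""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

GAP = "-"
UNKNOWN = "X"

_MOD_RE = re.compile(r"\(([^)]*)\)|[a-z0-9.+-]")


@dataclass
class PSMRecord:
    """One peptide-spectrum match row from a search-engine export."""

    peptide: str
    protein_id: str
    start: int  # 1-based inclusive
    score: float
    is_decoy: bool = False
    spectral_count: int = 1
    modifications: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if not self.peptide:
            raise ValueError("empty peptide")
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be positive")


@dataclass
class ConsensusProtein:
    protein_id: str
    # (residue|X|-, support, runner_up_support) per reference position
    positions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(p[0] for p in self.positions)


@dataclass
class ConcatenatedAlignment:
    taxa: list[str]
    matrix: list[str]  # one row string per taxon, all equal length
    partitions: dict[str, tuple[int, int]]  # protein -> 1-based inclusive cols

    def __post_init__(self) -> None:
        lengths = {len(row) for row in self.matrix}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    def row(self, taxon: str) -> str:
        return self.matrix[self.taxa.index(taxon)]


def strip_modifications(peptide: str) -> str:
    """Remove in-line modification annotations like ``GVQ(+.98)GPPGPAGPR``."""
    return re.sub(r"\([^)]*\)", "", peptide).strip().upper()


def read_psm_csv(path: str | Path) -> list[PSMRecord]:
    """Read a search-engine style ``protein-peptides`` CSV export.

    Expected columns (case-insensitive): protein accession, peptide, start,
    score (or -10lgP), spectral count (or #spec), optional decoy flag.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}

    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"missing column {names[0]!r} in {path}")

    records = []
    decoy_col = next((cols[c] for c in ("is_decoy", "decoy") if c in cols), None)
    count_col = next(
        (cols[c] for c in ("spectral_count", "#spec", "spec_count") if c in cols), None
    )
    for _, row in df.iterrows():
        raw_peptide = str(row[col("peptide")])
        records.append(
            PSMRecord(
                peptide=strip_modifications(raw_peptide),
                protein_id=str(row[col("protein accession", "protein_id", "accession")]),
                start=int(row[col("start")]),
                score=float(row[col("score", "-10lgp")]),
                is_decoy=bool(row[decoy_col]) if decoy_col else False,
                spectral_count=int(row[count_col]) if count_col else 1,
                modifications=raw_peptide,
            )
        )
    return records


def filter_fdr(
    psms: Sequence[PSMRecord], fdr: float = 0.005, passthrough: bool = False
) -> list[PSMRecord]:
    """Target-decoy q-value filtering.

    q at each score threshold is decoys/targets at-or-above that score,
    monotonized from the bottom of the score ranking; targets with
    q <= ``fdr`` are returned.
    """
    targets = [p for p in psms if not p.is_decoy]
    decoys = [p for p in psms if p.is_decoy]
    if not decoys:
        if passthrough:
            return list(targets)
        raise ValueError(
            "no decoy PSMs present; supply decoys or use passthrough mode"
        )
    if not targets:
        return []
    ranked = sorted(psms, key=lambda p: p.score, reverse=True)
    n_target = 0
    n_decoy = 0
    raw_q = []  # parallel to ranked
    for p in ranked:
        if p.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        raw_q.append(n_decoy / max(n_target, 1))
    # monotonize: q(i) = min over j >= i
    q = list(raw_q)
    for i in range(len(q) - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    return [p for p, qv in zip(ranked, q) if not p.is_decoy and qv <= fdr]


def build_consensus(
    psms: Sequence[PSMRecord],
    reference_length: int,
    min_peptides: int = 5,
    weight_by_spectral_count: bool = True,
) -> ConsensusProtein | None:
    """Majority-consensus sequence for one protein.

    Rejected (returns ``None``) when fewer than ``min_peptides`` distinct
    peptide sequences support the protein. Per position the residue with the
    largest summed peptide count wins; ties give X; uncovered positions give
    a gap.
    """
    if not psms:
        return None
    protein_ids = {p.protein_id for p in psms}
    if len(protein_ids) != 1:
        raise ValueError(f"mixed protein_ids: {sorted(protein_ids)}")
    protein_id = protein_ids.pop()
    if len({(p.peptide, p.start) for p in psms}) < min_peptides:
        return None
    votes: list[dict[str, int]] = [dict() for _ in range(reference_length)]
    for psm in psms:
        end = psm.start - 1 + len(psm.peptide)
        if end > reference_length:
            raise ValueError(
                f"peptide {psm.peptide!r} at {psm.start} overruns reference "
                f"length {reference_length}"
            )
        weight = psm.spectral_count if weight_by_spectral_count else 1
        for offset, residue in enumerate(psm.peptide):
            pos = psm.start - 1 + offset
            votes[pos][residue] = votes[pos].get(residue, 0) + weight
    positions: list[tuple[str, int, int]] = []
    for counter in votes:
        if not counter:
            positions.append((GAP, 0, 0))
            continue
        ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        top_residue, top = ranked[0]
        runner_up = ranked[1][1] if len(ranked) > 1 else 0
        if runner_up == top:
            positions.append((UNKNOWN, top, runner_up))
        else:
            positions.append((top_residue, top, runner_up))
    return ConsensusProtein(protein_id, positions)


@dataclass
class IsoformEdit:
    """One coordinate edit applied to a taxon's protein before concatenation."""

    taxon: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    action: str  # delete | mask | insert_unknowns

    def __post_init__(self) -> None:
        if self.action not in ("delete", "mask", "insert_unknowns"):
            raise ValueError(f"unknown edit action {self.action!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid edit interval")


def load_edits(path: str | Path) -> list[IsoformEdit]:
    data = json.loads(Path(path).read_text())
    return [IsoformEdit(**entry) for entry in data]


def _apply_edits(sequence: str, edits: list[IsoformEdit]) -> str:
    intervals = sorted((e.start, e.end) for e in edits)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping edits at {s1}-{e1} and {s2}-{e2}")
    for edit in sorted(edits, key=lambda e: -e.start):
        i, j = edit.start - 1, edit.end  # python slice
        if edit.action == "delete":
            sequence = sequence[:i] + sequence[j:]
        elif edit.action == "mask":
            sequence = sequence[:i] + UNKNOWN * (j - i) + sequence[j:]
        elif edit.action == "insert_unknowns":
            # unknowns occupy start..end of the edited sequence, i.e. they
            # are inserted before original position `start`
            n = edit.end - edit.start + 1
            sequence = sequence[:i] + UNKNOWN * n + sequence[i:]
    return sequence


def concatenate(
    proteomes: Mapping[str, Mapping[str, str]],
    protein_order: Sequence[str],
    edits: Iterable[IsoformEdit] = (),
) -> ConcatenatedAlignment:
    """Concatenate per-taxon protein sequences into one partitioned matrix.

    ``proteomes`` maps taxon -> protein_id -> sequence. Edits are applied
    first; per protein, shorter sequences are right-padded with gaps to the
    protein's maximum length so the matrix stays rectangular.
    """
    taxa = sorted(proteomes)
    edit_index: dict[tuple[str, str], list[IsoformEdit]] = {}
    for edit in edits:
        edit_index.setdefault((edit.taxon, edit.protein_id), []).append(edit)
    edited: dict[str, dict[str, str]] = {t: {} for t in taxa}
    for taxon in taxa:
        for protein in protein_order:
            seq = proteomes[taxon].get(protein, "")
            seq = _apply_edits(seq, edit_index.get((taxon, protein), []))
            edited[taxon][protein] = seq
    partitions: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    cursor = 1
    for protein in protein_order:
        width = max(len(edited[t][protein]) for t in taxa)
        for taxon in taxa:
            seq = edited[taxon][protein]
            rows[taxon].append(seq + GAP * (width - len(seq)))
        partitions[protein] = (cursor, cursor + width - 1)
        cursor += width
    return ConcatenatedAlignment(
        taxa=taxa,
        matrix=["".join(rows[t]) for t in taxa],
        partitions=partitions,
    )


def coverage_stats(
    alignment: ConcatenatedAlignment, taxon: str
) -> tuple[int, float]:
    """(reconstructed positions, percentage of total columns to 1 decimal)."""
    row = alignment.row(taxon)
    n = sum(1 for c in row if c not in (GAP, UNKNOWN))
    return n, coverage_fraction(n, alignment.n_columns)


def coverage_fraction(positions_reconstructed: int, total_columns: int) -> float:
    """Percentage of an alignment covered, rounded to one decimal place."""
    from .fauna_stats import round_half_away

    return round_half_away(100.0 * positions_reconstructed / total_columns, 1)


def write_alignment_fasta(
    alignment: ConcatenatedAlignment, fasta_path: str | Path, partitions_path: str | Path
) -> None:
    with open(fasta_path, "w") as fh:
        for taxon, row in zip(alignment.taxa, alignment.matrix):
            fh.write(f">{taxon}\n{row}\n")
    with open(partitions_path, "w") as fh:
        for protein, (start, end) in alignment.partitions.items():
            fh.write(f"{protein} = {start}-{end}\n")
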