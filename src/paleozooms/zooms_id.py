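"""Taxonomic identification of consensus spectra against a marker database."""

from __future__ import annotations

from dataclasses import dataclass, field

from .markerdb import MarkerDatabase, MarkerRecord, TaxonNode, lowest_consistent_taxon
from .spectra import ConsensusPeakList

QUALITIES = ("secure", "tentative", "unidentifiable")


@dataclass
class MarkerMatch:
    marker: MarkerRecord
    observed_mz: float
    delta: float
    intensity: float


@dataclass
class TaxonAssignment:
    specimen_id: str
    assigned_taxon: TaxonNode | None
    matches: list[MarkerMatch] = field(default_factory=list)
    n_markers_at_assigned_rank: int = 0
    ambiguity_set: list[TaxonNode] = field(default_factory=list)
    quality: str = "unidentifiable"


def match_markers(
    peaks: ConsensusPeakList, db: MarkerDatabase, tol: float = 0.2
) -> list[MarkerMatch]:
    """All (peak, marker) pairs within ``tol`` Da; ambiguity is preserved."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    if len(db) == 0:
        raise ValueError("marker database is empty")
    matches = []
    for mz, intensity, _support in peaks.peaks:
        for marker in db:
            delta = mz - marker.mz_MH
            if abs(delta) <= tol:
                matches.append(MarkerMatch(marker, mz, delta, intensity))
    matches.sort(key=lambda m: (m.observed_mz, m.marker.diagnostic_taxon.name))
    return matches


def _distinct_markers(matches: list[MarkerMatch]) -> dict[tuple, MarkerMatch]:
    """Dedupe matches so chemically identical satellites count once.

    Deamidated forms of a marker (same label and taxon, different
    n_deamidations) are the same peptide and collapse to one unit of
    evidence.
    """
    distinct: dict[tuple, MarkerMatch] = {}
    for m in matches:
        key = (m.marker.label, m.marker.diagnostic_taxon.name, m.marker.n_hydroxylations)
        if key not in distinct or abs(m.delta) < abs(distinct[key].delta):
            distinct[key] = m
    return distinct


def assign_taxon(
    matches: list[MarkerMatch],
    min_markers: int = 3,
    specimen_id: str = "",
) -> TaxonAssignment:
    """Assign the most specific taxon consistent with the matched markers.

    The matched diagnostic taxa are combined through
    :func:`lowest_consistent_taxon`; marker support at or below the
    assignment plus conflict with sibling lineages determines whether the
    call is secure or tentative.
    """
    if not matches:
        return TaxonAssignment(specimen_id, None, [], 0, [], "unidentifiable")
    distinct = _distinct_markers(matches)
    counts: dict[TaxonNode, int] = {}
    for m in distinct.values():
        node = m.marker.diagnostic_taxon
        counts[node] = counts.get(node, 0) + 1

    # each matched taxon is a candidate supported by every matched marker on
    # its root path; the best-supported path wins
    taxa = list(counts)

    def path_support(candidate: TaxonNode) -> int:
        return sum(
            c for node, c in counts.items() if node.is_ancestor_or_self(candidate)
        )

    best_support = max(path_support(n) for n in taxa)
    best = [n for n in taxa if path_support(n) == best_support]
    # nested equal-support candidates collapse to the deepest one
    deepest_level = min(n.level for n in best)
    best = [n for n in best if n.level == deepest_level]

    if len(best) > 1:
        assigned = lowest_consistent_taxon(best)
        ambiguity = sorted(best, key=lambda n: n.name)
    else:
        assigned = best[0]
        ambiguity = []

    n_at = sum(
        c for node, c in counts.items() if assigned.is_ancestor_or_self(node)
    )
    conflict_counts = [
        c
        for node, c in counts.items()
        if not (
            assigned.is_ancestor_or_self(node) or node.is_ancestor_or_self(assigned)
        )
    ]
    max_conflict = max(conflict_counts, default=0)
    if n_at >= min_markers and max_conflict < n_at / 2 and not ambiguity:
        quality = "secure"
    else:
        quality = "tentative"
    return TaxonAssignment(
        specimen_id=specimen_id,
        assigned_taxon=assigned,
        matches=list(matches),
        n_markers_at_assigned_rank=n_at,
        ambiguity_set=ambiguity,
        quality=quality,
    )


def identify(
    peaks: ConsensusPeakList,
    db: MarkerDatabase,
    tol: float = 0.2,
    min_markers: int = 3,
) -> TaxonAssignment:
    """Match then assign, in one call."""
    matches = match_markers(peaks, db, tol)
    return assign_taxon(matches, min_markers, specimen_id=peaks.specimen_id)
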