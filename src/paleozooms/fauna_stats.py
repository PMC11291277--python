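"""Faunal-assemblage statistics: combined identifications, NISP tables,
bone-surface-modification percentages and per-layer diversity indices."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markerdb import TaxonNode, Taxonomy

logger = logging.getLogger(__name__)

MODIFICATION_CATEGORIES = (
    "cut_mark",
    "percussion",
    "notch",
    "burning",
    "rodent_gnaw",
    "carnivore_gnaw",
    "fresh_break",
    "trampling",
)

ANTHROPOGENIC = {"cut_mark", "percussion", "notch", "burning", "fresh_break"}

# identifications at these ranks are too coarse for the community table
_EXCLUDED_RANKS = {"order", "class"}


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (not banker's rounding)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class SpecimenRecord:
    specimen_id: str
    layer: str
    morpho_taxon: TaxonNode | None = None
    zooms_taxon: TaxonNode | None = None
    bone_type: str = ""
    modifications: set[str] = field(default_factory=set)
    weathering_stage: int | None = None
    resolved_taxon: TaxonNode | None = None
    conflict: bool = False
    excluded: bool = False

    def __post_init__(self) -> None:
        unknown = self.modifications - set(MODIFICATION_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown modification codes {sorted(unknown)}")
        if self.weathering_stage is not None and not 1 <= self.weathering_stage <= 4:
            raise ValueError("weathering_stage must be in 1..4")


def _coarsen_to_group(node: TaxonNode, groups: set[str]) -> TaxonNode:
    """Walk up to the nearest ancestor-or-self that is a ZooMS group level."""
    for ancestor in node.path_to_root():
        if ancestor.name in groups:
            return ancestor
    return node


def combine_identifications(
    records: Iterable[SpecimenRecord],
    taxonomy: Taxonomy,
    zooms_groups: set[str],
    excluded_clades: set[str] = frozenset(),
) -> list[SpecimenRecord]:
    """Unite morphological and ZooMS identifications at ZooMS group levels.

    When both identifications are present and nested, the ZooMS group level
    wins; conflicting pairs are flagged and resolved to their LCA. Records
    resolving inside excluded clades (e.g. birds, rodents) or only to
    order/class level are marked ``excluded`` for the community table.
    """
    excluded_nodes = {taxonomy[name] for name in excluded_clades}
    out = []
    for rec in records:
        morpho, zooms = rec.morpho_taxon, rec.zooms_taxon
        resolved: TaxonNode | None
        conflict = False
        if morpho is not None and zooms is not None:
            if morpho.is_ancestor_or_self(zooms) or zooms.is_ancestor_or_self(morpho):
                deeper = morpho if morpho.level <= zooms.level else zooms
                resolved = _coarsen_to_group(deeper, zooms_groups)
            else:
                resolved = taxonomy.lca([morpho, zooms])
                conflict = True
        elif morpho is not None:
            resolved = _coarsen_to_group(morpho, zooms_groups)
        elif zooms is not None:
            resolved = _coarsen_to_group(zooms, zooms_groups)
        else:
            resolved = None
        excluded = False
        if resolved is not None:
            if resolved.rank in _EXCLUDED_RANKS:
                excluded = True
            if any(e.is_ancestor_or_self(resolved) for e in excluded_nodes):
                excluded = True
        rec.resolved_taxon = resolved
        rec.conflict = conflict
        rec.excluded = excluded
        out.append(rec)
    return out


def nisp_table(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    """Layer x taxon NISP counts over resolved, non-excluded specimens."""
    rows = [
        {"layer": r.layer, "taxon": r.resolved_taxon.name}
        for r in records
        if r.resolved_taxon is not None and not r.excluded
    ]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return df.groupby(["layer", "taxon"]).size().unstack(fill_value=0)


def modification_percentages(
    records: Sequence[SpecimenRecord],
    denominator: str = "identified",
) -> pd.DataFrame:
    """Per-category modification counts and percentages.

    ``denominator``: "identified" restricts the population to taxonomically
    resolved specimens; "all_observed" uses every record.
    """
    if denominator == "identified":
        population = [r for r in records if r.resolved_taxon is not None]
    elif denominator == "all_observed":
        population = list(records)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if not population:
        raise ValueError("denominator population is empty")
    total = len(population)
    rows = []
    for category in MODIFICATION_CATEGORIES:
        n = sum(1 for r in population if category in r.modifications)
        rows.append((category, n, percentage(n, total)))
    n_anthro = sum(1 for r in population if r.modifications & ANTHROPOGENIC)
    rows.append(("anthropogenic", n_anthro, percentage(n_anthro, total)))
    return pd.DataFrame(rows, columns=["category", "n", "percent"])


def percentage(n: int, total: int) -> float:
    """100*n/total, rounded half away from zero to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * n / total, 1)


def shannon_index(counts: Sequence[float]) -> float:
    """Shannon-Weaver H = -sum p ln p (natural log)."""
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("empty count vector")
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def simpson_index(counts: Sequence[float], variant: str = "gini") -> float:
    """Simpson diversity; default Gini-Simpson 1 - sum p^2."""
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("empty count vector")
    p = arr / arr.sum()
    ss = float((p**2).sum())
    if variant == "gini":
        return 1.0 - ss
    if variant == "inverse":
        return 1.0 / ss
    raise ValueError(f"unknown Simpson variant {variant!r}")


def diversity_indices(
    table: pd.DataFrame, n_boot: int = 1000, seed: int = 42
) -> pd.DataFrame:
    """Per-layer Shannon and Simpson indices with 2.5-97.5% bootstrap CIs.

    Bootstrap resamples each layer's specimens from the multinomial implied
    by its NISP composition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for layer, counts in table.iterrows():
        counts = counts.to_numpy(dtype=float)
        total = int(counts.sum())
        if total < 1:
            continue
        h = shannon_index(counts)
        d = simpson_index(counts)
        if total == 1:
            logger.warning("layer %s has a single specimen; degenerate CI", layer)
            rows.append((layer, total, h, h, h, d, d, d))
            continue
        p = counts / counts.sum()
        boot_h = np.empty(n_boot)
        boot_d = np.empty(n_boot)
        samples = rng.multinomial(total, p, size=n_boot)
        for i, sample in enumerate(samples):
            boot_h[i] = shannon_index(sample) if sample.sum() else 0.0
            boot_d[i] = simpson_index(sample) if sample.sum() else 0.0
        h_lo, h_hi = np.percentile(boot_h, [2.5, 97.5])
        d_lo, d_hi = np.percentile(boot_d, [2.5, 97.5])
        rows.append((layer, total, h, h_lo, h_hi, d, d_lo, d_hi))
    return pd.DataFrame(
        rows,
        columns=[
            "layer",
            "nisp",
            "shannon",
            "shannon_ci_2_5",
            "shannon_ci_97_5",
            "simpson",
            "simpson_ci_2_5",
            "simpson_ci_97_5",
        ],
    )
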