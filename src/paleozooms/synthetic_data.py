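"""Ground-truthed synthetic inputs for every pipeline stage.

Generates COL1-like sequences over a known taxonomy (with guaranteed
diagnostic markers), triplicate MALDI peak lists, PSM tables with decoys,
and alignments evolved under the Dayhoff model — all seeded and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._masses import ISOTOPE_SPACING
from .deamidation import DEAMIDATION_PEPTIDES, theoretical_envelope
from .markerdb import Taxonomy, TaxonNode, digest_sequence, peptide_mz
from .phylo import Node, RateModel, simulate_sites
from .proteome_consensus import PSMRecord
from .spectra import ConsensusPeakList, PeakList


@dataclass
class SimConfig:
    seed: int = 42
    n_taxa: int = 8
    n_specimens_per_layer: int = 25
    layers: tuple[str, ...] = ("L3", "L4", "L6", "L10")
    mz_noise_sd: float = 0.02
    noise_peaks_per_spectrum: int = 5
    dropout: float = 0.0
    deamidation_by_layer: dict[str, float] = field(
        default_factory=lambda: {"L3": 0.8, "L4": 0.7, "L6": 0.5, "L10": 0.2}
    )
    peptide_error_rate: float = 0.0
    coverage_depth: int = 6
    site_count: int = 2000
    hydroxylation_range: tuple[int, ...] = (0, 1)


# ---------------------------------------------------------------------------
# COL1-like sequences over a known taxonomy
# ---------------------------------------------------------------------------

# species -> (genus, family); 8 species over 6 genera and 4 families so LCA
# logic is exercised at species, genus and family ranks
_DEFAULT_TAXA = {
    "SpA1": ("GenA", "Fam1"),
    "SpA2": ("GenA", "Fam1"),
    "SpB1": ("GenB", "Fam1"),
    "SpC1": ("GenC", "Fam2"),
    "SpC2": ("GenC", "Fam2"),
    "SpD1": ("GenD", "Fam3"),
    "SpE1": ("GenE", "Fam3"),
    "SpF1": ("GenF", "Fam4"),
}

# substitution palette: original residue -> replacement (mass-shifting, never
# touching K/R/P so the digest pattern is stable)
_SUBSTITUTIONS = {
    "G": "A", "A": "V", "S": "T", "V": "I", "L": "F", "T": "S",
    "E": "D", "D": "E", "N": "Q", "Q": "N", "F": "L",
}


def default_taxonomy() -> Taxonomy:
    tax = Taxonomy(TaxonNode("Mammalia", "class"))
    seen_families, seen_genera = set(), set()
    for species, (genus, family) in _DEFAULT_TAXA.items():
        if family not in seen_families:
            tax.add(family, "family", "Mammalia")
            seen_families.add(family)
        if genus not in seen_genera:
            tax.add(genus, "genus", family)
            seen_genera.add(genus)
        tax.add(species, "species", genus)
    return tax


def _base_peptides(rng: np.random.Generator, n_variable: int = 52) -> list[str]:
    """Collagen-flavoured tryptic peptides; the first two are the conserved
    deamidation peptides, the rest are mutable marker slots."""
    peptides = [
        DEAMIDATION_PEPTIDES["COL1a1 508-519"],
        DEAMIDATION_PEPTIDES["COL1a1 435-453"],
    ]
    residues = np.array(list("GASVLTEDQNF"))
    lengths = rng.integers(8, 15, size=n_variable)
    for length in lengths:
        body = "".join(rng.choice(residues, size=length - 1))
        terminus = "R" if rng.random() < 0.5 else "K"
        peptides.append(body + terminus)
    return peptides


def simulate_col1_taxa(
    config: SimConfig,
) -> tuple[dict[str, str], Taxonomy, dict[str, list[int]]]:
    """Per-species COL1-like sequences with >=3 diagnostic peptides each.

    Returns (sequences, taxonomy, truth) where truth maps each taxon name to
    the indices of the peptides it mutates.
    """
    if config.n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(config.seed)
    taxonomy = default_taxonomy()
    peptides = _base_peptides(rng)
    species = list(_DEFAULT_TAXA)[: config.n_taxa]

    # dedicate 2 peptide slots to every family/genus and 3 to every species
    slots = iter(range(2, len(peptides)))
    node_slots: dict[str, list[int]] = {}
    families = sorted({f for _, f in _DEFAULT_TAXA.values()})
    genera = sorted({g for g, _ in _DEFAULT_TAXA.values()})
    for name in families + genera:
        node_slots[name] = [next(slots) for _ in range(2)]
    for name in species:
        node_slots[name] = [next(slots) for _ in range(3)]

    def mutate(peptide: str, offset: int) -> str:
        chars = list(peptide)
        mutable = [i for i, c in enumerate(chars) if c in _SUBSTITUTIONS]
        if not mutable:
            raise RuntimeError("peptide has no mutable site")
        i = mutable[offset % len(mutable)]
        chars[i] = _SUBSTITUTIONS[chars[i]]
        return "".join(chars)

    # one fixed mutated variant per (lineage, slot) so every descendant
    # species inherits the identical substitution
    all_nodes = families + genera + species
    node_offset = {name: i for i, name in enumerate(all_nodes)}
    mutated: dict[tuple[str, int], str] = {}
    for name in all_nodes:
        for slot_idx, slot in enumerate(node_slots[name]):
            mutated[(name, slot)] = mutate(
                peptides[slot], node_offset[name] + slot_idx
            )

    sequences: dict[str, str] = {}
    for sp in species:
        genus, family = _DEFAULT_TAXA[sp]
        own = list(peptides)
        for lineage in (family, genus, sp):
            for slot in node_slots[lineage]:
                own[slot] = mutated[(lineage, slot)]
        sequences[sp] = "".join(own)
    truth = {name: node_slots[name] for name in node_slots}
    return sequences, taxonomy, truth


# ---------------------------------------------------------------------------
# MALDI spectra
# ---------------------------------------------------------------------------


def _taxon_marker_masses(
    sequence: str, hydroxylation_range: Sequence[int]
) -> list[float]:
    masses = []
    for pep in set(digest_sequence(sequence, min_length=6, max_missed_cleavages=0)):
        for n_hyd in hydroxylation_range:
            if n_hyd > pep.count("P"):
                continue
            masses.append(peptide_mz(pep, n_hyd, 0))
    return sorted(masses)


def deamidation_peak_block(
    peptide_name: str,
    q: float,
    base_intensity: float = 500.0,
    n_hydroxylations: int = 1,
    n_isotopes: int = 5,
) -> list[tuple[float, float]]:
    """Peaks of a q:(1-q) mixture of Q and deamidated isotope envelopes."""
    sequence = DEAMIDATION_PEPTIDES[peptide_name]
    env_q = theoretical_envelope(sequence, n_hydroxylations, 0, n_isotopes)
    env_d = theoretical_envelope(sequence, n_hydroxylations, 1, n_isotopes)
    raw = []
    for k, abundance in enumerate(env_q.relative_abundances):
        intensity = base_intensity * q * abundance
        if intensity > 0:
            raw.append((env_q.base_mz + k * ISOTOPE_SPACING, intensity))
    for k, abundance in enumerate(env_d.relative_abundances):
        intensity = base_intensity * (1.0 - q) * abundance
        if intensity > 0:
            raw.append((env_d.base_mz + k * ISOTOPE_SPACING, intensity))
    raw.sort()
    # the Q(k+1) and deamidated(k) peaks sit 0.019 Da apart, far below
    # MALDI-TOF resolution: emit one centroid per unresolved multiplet
    peaks: list[tuple[float, float]] = []
    for mz, intensity in raw:
        if peaks and mz - peaks[-1][0] < 0.1:
            prev_mz, prev_i = peaks[-1]
            total = prev_i + intensity
            peaks[-1] = ((prev_mz * prev_i + mz * intensity) / total, total)
        else:
            peaks.append((mz, intensity))
    return peaks


def make_deamidation_peaklist(
    q: float,
    peptide_name: str = "COL1a1 508-519",
    specimen_id: str = "synthetic",
    protocol: str = "acid",
    intensity_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ConsensusPeakList:
    """Consensus peak list carrying one peptide's deamidation mixture."""
    peaks = deamidation_peak_block(peptide_name, q)
    if intensity_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        peaks = [
            (mz, i * float(np.exp(rng.normal(0.0, intensity_noise_sd))))
            for mz, i in peaks
        ]
    return ConsensusPeakList(
        specimen_id, protocol, [(mz, i, 3) for mz, i in peaks], n_replicates=3
    )


@dataclass
class SpecimenTruth:
    specimen_id: str
    taxon: str
    layer: str
    q_true: float


def simulate_spectra(
    config: SimConfig,
    sequences: Mapping[str, str],
    protocol: str = "acid",
) -> tuple[dict[str, list[PeakList]], list[SpecimenTruth]]:
    """Triplicate peak lists per synthetic specimen, plus the truth table.

    Marker peaks follow each specimen's taxon; the two conserved deamidation
    peptides carry q:(1-q) split isotope envelopes according to the
    specimen's layer.
    """
    rng = np.random.default_rng(config.seed + 1)
    taxa = sorted(sequences)
    replicates: dict[str, list[PeakList]] = {}
    truths: list[SpecimenTruth] = []
    counter = 0
    for layer in config.layers:
        q = config.deamidation_by_layer.get(layer, 0.5)
        for _ in range(config.n_specimens_per_layer):
            taxon = taxa[int(rng.integers(len(taxa)))]
            counter += 1
            specimen = f"BSY-{counter:04d}"
            masses = _taxon_marker_masses(sequences[taxon], config.hydroxylation_range)
            # the conserved deamidation peptides are emitted as full isotope
            # envelopes below; keep their fit windows free of marker peaks so
            # the layer-level deamidation truth stays exact
            windows = [
                (peptide_mz(seq, 1, 0) - 0.3, peptide_mz(seq, 1, 0) + 5 * ISOTOPE_SPACING + 0.3)
                for seq in DEAMIDATION_PEPTIDES.values()
            ]
            masses = [
                m for m in masses
                if not any(lo <= m <= hi for lo, hi in windows)
            ]
            deam_peaks = [
                p
                for name in DEAMIDATION_PEPTIDES
                for p in deamidation_peak_block(name, q)
            ]
            reps = []
            for rep_id in range(1, 4):
                peaks = []
                for mass in masses:
                    if rng.random() < config.dropout:
                        continue
                    mz = mass + rng.normal(0.0, config.mz_noise_sd)
                    peaks.append((mz, float(rng.uniform(100, 1000))))
                for mz, inten in deam_peaks:
                    peaks.append(
                        (mz + rng.normal(0.0, config.mz_noise_sd), inten)
                    )
                for _ in range(config.noise_peaks_per_spectrum):
                    peaks.append(
                        (float(rng.uniform(800, 3500)), float(rng.uniform(50, 300)))
                    )
                reps.append(PeakList(specimen, rep_id, protocol, sorted(peaks)))
            replicates[specimen] = reps
            truths.append(SpecimenTruth(specimen, taxon, layer, q))
    return replicates, truths


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------


def simulate_psm_table(
    config: SimConfig,
    true_proteome: Mapping[str, str],
    peptide_length: int = 12,
) -> list[PSMRecord]:
    """Tile error-prone peptides over proteins, with reversed-sequence decoys.

    Target scores are drawn well above decoy scores so FDR filtering at
    stringent thresholds retains targets.
    """
    if config.coverage_depth < 1:
        raise ValueError("coverage_depth must be >= 1")
    rng = np.random.default_rng(config.seed + 2)
    alphabet = np.array(list("ARNDCQEGHILKMFPSTWYV"))
    records: list[PSMRecord] = []
    for protein_id in sorted(true_proteome):
        sequence = true_proteome[protein_id]
        n = len(sequence)
        for _ in range(config.coverage_depth):
            start = 1
            while start <= n:
                length = min(int(rng.integers(9, peptide_length + 4)), n - start + 1)
                if length < 6:
                    break
                peptide = list(sequence[start - 1 : start - 1 + length])
                for i in range(len(peptide)):
                    if rng.random() < config.peptide_error_rate:
                        choices = alphabet[alphabet != peptide[i]]
                        peptide[i] = str(rng.choice(choices))
                records.append(
                    PSMRecord(
                        peptide="".join(peptide),
                        protein_id=protein_id,
                        start=start,
                        score=float(rng.normal(60.0, 8.0)),
                        is_decoy=False,
                        spectral_count=int(rng.geometric(0.5)),
                    )
                )
                start += length
    # reversed-peptide decoys with much lower scores, ~1 per 4 targets
    n_decoys = max(2, len(records) // 4)
    targets = [r for r in records if not r.is_decoy]
    for i in range(n_decoys):
        template = targets[int(rng.integers(len(targets)))]
        records.append(
            PSMRecord(
                peptide=template.peptide[::-1],
                protein_id=f"DECOY_{template.protein_id}",
                start=1,
                score=float(rng.normal(20.0, 8.0)),
                is_decoy=True,
                spectral_count=1,
            )
        )
    return records


def write_psm_csv(records: Sequence[PSMRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "protein accession": [r.protein_id for r in records],
            "peptide": [r.peptide for r in records],
            "start": [r.start for r in records],
            "score": [r.score for r in records],
            "spectral_count": [r.spectral_count for r in records],
            "is_decoy": [r.is_decoy for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Alignments under the Dayhoff model
# ---------------------------------------------------------------------------


def simulate_alignment(
    config: SimConfig,
    tree: Node,
    model: RateModel,
    masked_taxon: str | None = None,
    coverage: float = 1.0,
) -> dict[str, str]:
    """Evolve sequences along ``tree``; optionally gap-mask one taxon down to
    ``coverage`` fraction of sites."""
    if len(tree.leaves()) < 4:
        raise ValueError("tree needs >= 4 leaves")
    rng = np.random.default_rng(config.seed + 3)
    sequences = simulate_sites(tree, model, config.site_count, rng)
    if masked_taxon is not None:
        if masked_taxon not in sequences:
            raise KeyError(f"taxon {masked_taxon!r} not on tree")
        if coverage <= 0.0:
            raise ValueError(
                "coverage 0 leaves no data for the masked taxon; placement undefined"
            )
        n = config.site_count
        n_keep = int(round(coverage * n))
        keep = rng.choice(n, size=n_keep, replace=False)
        mask = np.full(n, True)
        mask[keep] = False
        seq = np.array(list(sequences[masked_taxon]))
        seq[mask] = "-"
        sequences[masked_taxon] = "".join(seq)
    return sequences
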