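"""Glutamine deamidation quantification from MALDI isotope envelopes.

The non-deamidated (Q) and deamidated (+0.984 Da) forms of a peptide have
overlapping isotope envelopes at MALDI-TOF resolution. The observed
intensities over the combined isotope grid are decomposed into a
non-negative linear combination of the two theoretical envelopes; the
fitted weight fraction of the Q form is the reported value (1 = no
deamidation, 0 = complete deamidation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from ._masses import (
    DEAMIDATION_SHIFT,
    ELEMENT_ISOTOPE_ABUNDANCES,
    ISOTOPE_SPACING,
    peptide_composition,
)
from .markerdb import peptide_mz
from .spectra import ConsensusPeakList

# The two collagen peptides used for deamidation screening; both carry one
# glutamine and are observed with one proline hydroxylation in ZooMS spectra.
DEAMIDATION_PEPTIDES = {
    "COL1a1 508-519": "GVQGPPGPAGPR",
    "COL1a1 435-453": "DGEAGAQGPPGPAGPAGER",
}
PEPTIDE_ALIASES = {"P1105": "COL1a1 508-519", "P1706": "COL1a1 435-453"}


@dataclass
class IsotopeEnvelope:
    base_mz: float
    relative_abundances: list[float]

    def __post_init__(self) -> None:
        if len(self.relative_abundances) < 4:
            raise ValueError("envelope needs at least 4 isotope positions")
        total = sum(self.relative_abundances)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


@dataclass
class DeamidationEstimate:
    specimen_id: str
    peptide: str
    protocol: str
    value: float
    fit_residual: float


@dataclass
class LayerDeamidationSummary:
    layer: str
    peptide: str
    n: int
    mean: float
    interval_68: tuple[float, float]


def isotope_distribution(composition: Mapping[str, int], n_isotopes: int) -> np.ndarray:
    """Aggregated isotope distribution of a formula by polynomial convolution."""
    dist = np.array([1.0])
    for element, count in composition.items():
        if count <= 0:
            continue
        single = np.array(ELEMENT_ISOTOPE_ABUNDANCES[element])
        # exponentiation by repeated convolution, truncated to keep it cheap
        power = np.array([1.0])
        base = single
        n = count
        while n:
            if n & 1:
                power = np.convolve(power, base)[: n_isotopes + 4]
            base = np.convolve(base, base)[: n_isotopes + 4]
            n >>= 1
        dist = np.convolve(dist, power)[: n_isotopes + 4]
    dist = dist[:n_isotopes]
    return dist / dist.sum()


def theoretical_envelope(
    sequence: str,
    n_hydroxylations: int = 0,
    n_deamidations: int = 0,
    n_isotopes: int = 5,
) -> IsotopeEnvelope:
    """Theoretical [M+H]+ isotope envelope of a modified peptide."""
    if n_isotopes < 4:
        raise ValueError("n_isotopes must be >= 4")
    comp = peptide_composition(sequence, n_hydroxylations, n_deamidations)
    abundances = isotope_distribution(comp, n_isotopes)
    base = peptide_mz(sequence, n_hydroxylations, n_deamidations, charge=1)
    return IsotopeEnvelope(base, [float(a) for a in abundances])


def estimate_deamidation(
    peaks: ConsensusPeakList,
    peptide: str,
    tol: float = 0.1,
    n_hydroxylations: int = 1,
    n_isotopes: int = 5,
) -> DeamidationEstimate | None:
    """Fit Q vs deamidated envelope weights for one peptide.

    Returns ``None`` when no isotope peaks of the peptide are present in
    the spectrum ("peptide not detected").
    """
    name = PEPTIDE_ALIASES.get(peptide, peptide)
    sequence = DEAMIDATION_PEPTIDES.get(name)
    if sequence is None:
        raise KeyError(f"unknown deamidation peptide {peptide!r}")
    env_q = theoretical_envelope(sequence, n_hydroxylations, 0, n_isotopes)
    env_d = theoretical_envelope(sequence, n_hydroxylations, 1, n_isotopes)

    # shared integer isotope grid: slot k covers both the Q form's isotope k
    # and the deamidated form's isotope k-1 (0.98 vs 1.00 Da are unresolved)
    n_slots = n_isotopes + 1
    grid = env_q.base_mz + ISOTOPE_SPACING * np.arange(n_slots)
    mz = peaks.mz
    intensity = peaks.intensity
    observed = np.zeros(n_slots)
    found = False
    for k in range(n_slots):
        lo = grid[k] - (ISOTOPE_SPACING - DEAMIDATION_SHIFT) - tol
        hi = grid[k] + tol
        mask = (mz >= lo) & (mz <= hi)
        if mask.any():
            observed[k] = float(intensity[mask].sum())
            found = True
    if not found or observed.sum() <= 0:
        return None

    design = np.zeros((n_slots, 2))
    design[:n_isotopes, 0] = env_q.relative_abundances
    design[1 : n_isotopes + 1, 1] = env_d.relative_abundances
    scale = observed.sum()
    coef, rnorm = nnls(design, observed / scale)
    alpha, beta = float(coef[0]), float(coef[1])
    if alpha + beta <= 0:
        return None
    value = alpha / (alpha + beta)
    return DeamidationEstimate(
        specimen_id=peaks.specimen_id,
        peptide=name,
        protocol=peaks.protocol,
        value=value,
        fit_residual=float(rnorm**2),
    )


def summarize_by_layer(
    estimates: Sequence[DeamidationEstimate],
    layer_map: Mapping[str, str],
    n_boot: int = 1000,
    seed: int = 42,
) -> list[LayerDeamidationSummary]:
    """Per-layer/peptide means with 68.2% bootstrap percentile intervals."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[float]] = {}
    for est in estimates:
        layer = layer_map.get(est.specimen_id)
        if layer is None:
            continue
        groups.setdefault((layer, est.peptide), []).append(est.value)
    out = []
    for (layer, peptide), values in sorted(groups.items()):
        arr = np.asarray(values)
        n = len(arr)
        boot_means = rng.choice(arr, size=(n_boot, n), replace=True).mean(axis=1)
        lo, hi = np.percentile(boot_means, [15.9, 84.1])
        out.append(
            LayerDeamidationSummary(
                layer=layer,
                peptide=peptide,
                n=n,
                mean=float(arr.mean()),
                interval_68=(float(lo), float(hi)),
            )
        )
    return out
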