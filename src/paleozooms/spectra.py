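"""MALDI-TOF peak-list handling: reading, peak picking and replicate merging.

Replicate spectra of one specimen/protocol are merged by single-linkage
clustering of peak m/z values; clusters seen in enough replicates survive
into the consensus list.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._mzml import read_mzml_peaks

logger = logging.getLogger(__name__)

PROTOCOLS = ("AmBic", "acid")

_FILENAME_RE = re.compile(r"(?P<specimen>.+)_(?P<protocol>AmBic|acid)_rep(?P<rep>\d+)")


@dataclass
class PeakList:
    """Centroided peaks of one replicate spectrum."""

    specimen_id: str
    replicate_id: int
    protocol: str
    peaks: list[tuple[float, float]] = field(default_factory=list)
    snr: list[float] | None = None

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative intensity")
        self._sort_and_dedupe()

    def _sort_and_dedupe(self) -> None:
        order = sorted(range(len(self.peaks)), key=lambda k: self.peaks[k][0])
        peaks = [self.peaks[k] for k in order]
        snr = [self.snr[k] for k in order] if self.snr else None
        deduped, dsnr = [], []
        for idx, (mz, inten) in enumerate(peaks):
            if deduped and abs(mz - deduped[-1][0]) < 1e-6:
                logger.warning(
                    "collapsing duplicate peak at m/z %.6f in %s", mz, self.specimen_id
                )
                deduped[-1] = (deduped[-1][0], deduped[-1][1] + inten)
                continue
            deduped.append((mz, inten))
            if snr:
                dsnr.append(snr[idx])
        self.peaks = deduped
        self.snr = dsnr if snr else None

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class ConsensusPeakList:
    """Merged peaks with per-peak replicate support."""

    specimen_id: str
    protocol: str
    peaks: list[tuple[float, float, int]] = field(default_factory=list)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for _, _, support in self.peaks:
            if not 1 <= support <= self.n_replicates:
                raise ValueError("support outside 1..n_replicates")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def parse_peaklist_filename(path: str | Path) -> tuple[str, str, int]:
    """``<specimen>_<protocol>_rep<k>`` metadata from a file name."""
    stem = Path(path).stem
    m = _FILENAME_RE.fullmatch(stem)
    if not m:
        raise ValueError(
            f"cannot parse specimen/protocol/replicate from file name {stem!r}"
        )
    return m.group("specimen"), m.group("protocol"), int(m.group("rep"))


def read_peaklist(
    path: str | Path,
    dialect: str = "tsv",
    specimen_id: str | None = None,
    protocol: str | None = None,
    replicate_id: int | None = None,
) -> PeakList:
    """Read a peak list from a 2/3-column TSV or an mzML file.

    Metadata defaults to whatever the ``<specimen>_<protocol>_rep<k>`` file
    name pattern provides.
    """
    path = Path(path)
    if specimen_id is None or protocol is None or replicate_id is None:
        specimen_id, protocol, replicate_id = parse_peaklist_filename(path)
    if dialect == "mzml":
        raw = read_mzml_peaks(path)
        peaks = [(float(mz), float(i)) for mz, i in raw]
        snr = None
    elif dialect == "tsv":
        peaks, snr = [], []
        for line_no, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("mz"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected >=2 columns")
            mz, inten = float(parts[0]), float(parts[1])
            if inten < 0:
                raise ValueError(f"{path}:{line_no}: negative intensity {inten}")
            peaks.append((mz, inten))
            if len(parts) >= 3:
                snr.append(float(parts[2]))
        snr = snr if len(snr) == len(peaks) else None
        if not peaks:
            logger.warning("empty peak list %s", path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return PeakList(specimen_id, replicate_id, protocol, peaks, snr)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    lines = ["mz\tintensity"]
    for mz, inten in peaklist.peaks:
        lines.append(f"{mz:.4f}\t{inten:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def pick_peaks(
    profile: PeakList,
    snr_threshold: float = 3.0,
    baseline_window: int = 200,
    smooth_window: int = 5,
    half_window: int = 10,
) -> PeakList:
    """Pick centroids from a profile-mode spectrum.

    Square-root intensity transform, moving-average smoothing, moving-median
    baseline subtraction, then local maxima with SNR >= threshold where the
    noise scale is the median absolute deviation of the residual signal.

    Input that already carries per-peak SNR values is treated as centroided:
    only the SNR gate is applied, which makes the operation idempotent.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    if profile.snr is not None:
        kept = [
            (peak, s) for peak, s in zip(profile.peaks, profile.snr)
            if s >= snr_threshold
        ]
        return PeakList(
            profile.specimen_id,
            profile.replicate_id,
            profile.protocol,
            [p for p, _ in kept],
            [s for _, s in kept],
        )
    if len(profile) < 5:
        raise ValueError("need at least 5 raw points to pick peaks")
    mz = profile.mz
    signal = np.sqrt(np.maximum(profile.intensity, 0.0))
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(signal, kernel, mode="same")
    else:
        smoothed = signal
    half = max(1, baseline_window // 2)
    n = len(smoothed)
    baseline = np.array(
        [np.median(smoothed[max(0, i - half) : min(n, i + half + 1)]) for i in range(n)]
    )
    residual = smoothed - baseline
    noise = np.median(np.abs(residual - np.median(residual)))
    if noise <= 0:
        noise = max(1e-12, np.std(residual))
    picked, snrs = [], []
    for i in range(1, n - 1):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        window = residual[lo:hi]
        # maximum of its neighbourhood, strictly above the next point
        # (plateaus emit their rightmost point once) and not a flat stretch
        if residual[i] != window.max():
            continue
        if residual[i] <= residual[i + 1] or residual[i] <= window.min():
            continue
        snr = residual[i] / noise
        if snr >= snr_threshold:
            picked.append((float(mz[i]), float(profile.intensity[i])))
            snrs.append(float(snr))
    return PeakList(
        profile.specimen_id, profile.replicate_id, profile.protocol, picked, snrs
    )


def merge_replicates(
    replicates: Sequence[PeakList], tol: float = 0.2, min_support: int = 2
) -> ConsensusPeakList:
    """Merge replicate peak lists into a consensus list.

    Peaks are single-linkage clustered within ``tol``; a cluster supported
    by >= ``min_support`` distinct replicates is emitted with an
    intensity-weighted mean m/z and the mean of its per-replicate
    intensities.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates to merge")
    specimens = {r.specimen_id for r in replicates}
    if len(specimens) != 1:
        raise ValueError(f"mixed specimen_ids in merge: {sorted(specimens)}")
    protocols = {r.protocol for r in replicates}
    if len(protocols) != 1:
        raise ValueError(f"mixed protocols in merge: {sorted(protocols)}")
    entries = []  # (mz, intensity, replicate_id)
    for rep in replicates:
        for mz, inten in rep.peaks:
            entries.append((mz, inten, rep.replicate_id))
    entries.sort()
    clusters: list[list[tuple[float, float, int]]] = []
    for entry in entries:
        if clusters and entry[0] - clusters[-1][-1][0] <= tol:
            clusters[-1].append(entry)
        else:
            clusters.append([entry])
    out = []
    for cluster in clusters:
        support = len({rep for _, _, rep in cluster})
        if support < min_support:
            continue
        weights = np.array([i for _, i, _ in cluster])
        mzs = np.array([m for m, _, _ in cluster])
        if weights.sum() > 0:
            mean_mz = float(np.average(mzs, weights=weights))
        else:
            mean_mz = float(mzs.mean())
        out.append((mean_mz, float(weights.mean()), support))
    out.sort()
    return ConsensusPeakList(
        replicates[0].specimen_id,
        replicates[0].protocol,
        out,
        n_replicates=len(replicates),
    )
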