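"""Turn raw peak lists into comparable grid spectra.

Pipeline order is fixed: proportional 0.1 Da binning -> matrix-peak removal
-> total-integral normalization -> replicate averaging.  Averaging spectra
that were each normalized to the same total leaves that total unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .masses import EO_MASS_MONO
from .spectra_io import RawPeakList

logger = logging.getLogger(__name__)


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum has no intensity to work with."""


@dataclass
class GridSpectrum:
    """A spectrum resampled onto a uniform m/z grid.

    ``intensities[i]`` is the count attributed to the bin centred at
    ``grid_start + i * grid_step``.
    """

    grid_start: float
    grid_step: float
    intensities: np.ndarray
    sample_id: str = ""
    type_label: str = ""
    n_replicates_averaged: int = 1

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError(f"grid_step must be positive, got {self.grid_step}")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size < 2:
            raise ValueError("grid spectrum needs at least 2 bins")
        if np.any(self.intensities < 0):
            raise ValueError("negative bin intensity")

    @property
    def mz_grid(self) -> np.ndarray:
        return self.grid_start + self.grid_step * np.arange(self.intensities.size)

    def bin_mz(self, index: int) -> float:
        return self.grid_start + self.grid_step * index

    @property
    def total(self) -> float:
        return float(self.intensities.sum())

    def copy(self) -> "GridSpectrum":
        return replace(self, intensities=self.intensities.copy())


@dataclass
class PreprocessConfig:
    """Run configuration for the preprocessing stage."""

    grid_step: float = 0.1
    mz_range: tuple[float, float] = (400.0, 4000.0)
    matrix_mz: tuple[float, ...] = ()
    matrix_window: float = 0.3
    matrix_spacing: float = EO_MASS_MONO
    normalization_total: float = 1.0


def bin_to_grid(
    raw: RawPeakList,
    grid_step: float = 0.1,
    mz_range: tuple[float, float] = (400.0, 4000.0),
    sample_id: str = "",
    type_label: str = "",
) -> GridSpectrum:
    """Distribute each centroid count over the two flanking grid bins.

    A count ``c`` at mass ``m`` with flanking bin centres ``b_lo <= m <= b_hi``
    contributes ``c*(b_hi-m)/step`` to ``b_lo`` and ``c*(m-b_lo)/step`` to
    ``b_hi``, so total intensity is conserved exactly.  Entries outside
    ``mz_range`` are dropped (logged).
    """
    if grid_step <= 0:
        raise ValueError(f"grid_step must be positive, got {grid_step}")
    lo, hi = mz_range
    n_bins = int(round((hi - lo) / grid_step)) + 1
    inside = (raw.mz >= lo) & (raw.mz <= hi)
    dropped = int((~inside).sum())
    if dropped:
        logger.info("bin_to_grid: dropped %d entries outside [%g, %g]", dropped, lo, hi)
    mz = raw.mz[inside]
    counts = raw.intensity[inside]
    # Rounding guards against centroids that sit on a bin centre up to float
    # error leaking a sliver of intensity into the neighbouring bin.
    pos = np.round((mz - lo) / grid_step, 9)
    i_lo = np.minimum(np.floor(pos).astype(int), n_bins - 2)
    frac = pos - i_lo
    intensities = np.zeros(n_bins)
    np.add.at(intensities, i_lo, counts * (1.0 - frac))
    np.add.at(intensities, i_lo + 1, counts * frac)
    return GridSpectrum(lo, grid_step, intensities, sample_id=sample_id, type_label=type_label)


def remove_matrix_peaks(
    spec: GridSpectrum,
    matrix_mz,
    spacing: float = EO_MASS_MONO,
    window: float = 0.3,
) -> GridSpectrum:
    """Replace matrix-peak regions by the mean of the bins one repeat unit away.

    For each listed matrix mass, every bin within ``±window`` is replaced by
    the mean of the corresponding bins at ``±spacing``.  At the grid edge the
    single available neighbour is used.
    """
    out = spec.copy()
    n = out.intensities.size
    step = out.grid_step
    off = int(round(spacing / step))
    w = int(round(window / step))
    replacement = spec.intensities  # read from the unmodified input
    for p in matrix_mz:
        centre = int(round((p - out.grid_start) / step))
        for b in range(max(0, centre - w), min(n - 1, centre + w) + 1):
            neighbours = [b - off, b + off]
            vals = [replacement[j] for j in neighbours if 0 <= j < n]
            if vals:
                out.intensities[b] = float(np.mean(vals))
    return out


def normalize_total(spec: GridSpectrum, total: float = 1.0) -> GridSpectrum:
    """Scale the spectrum so its bin intensities sum to ``total``."""
    s = spec.total
    if s <= 0:
        raise DegenerateSpectrumError(f"degenerate spectrum: total intensity {s}")
    out = spec.copy()
    out.intensities *= total / s
    return out


def average_replicates(specs: list[GridSpectrum]) -> GridSpectrum:
    """Per-bin arithmetic mean of replicate spectra on identical grids."""
    if not specs:
        raise ValueError("no spectra to average")
    first = specs[0]
    for s in specs[1:]:
        if (
            s.grid_start != first.grid_start
            or s.grid_step != first.grid_step
            or s.intensities.size != first.intensities.size
        ):
            raise ValueError("replicates are on mismatched grids")
        if s.sample_id != first.sample_id:
            raise ValueError(
                f"mixed sample_ids in replicate set: {s.sample_id!r} vs {first.sample_id!r}"
            )
    mean = np.mean([s.intensities for s in specs], axis=0)
    out = first.copy()
    out.intensities = mean
    out.n_replicates_averaged = len(specs)
    return out


def preprocess_replicates(
    raws: list[RawPeakList],
    cfg: PreprocessConfig,
    sample_id: str = "",
    type_label: str = "",
) -> GridSpectrum:
    """Full preprocessing of one sample's replicate peak lists."""
    specs = []
    for raw in raws:
        g = bin_to_grid(raw, cfg.grid_step, cfg.mz_range, sample_id=sample_id, type_label=type_label)
        g = remove_matrix_peaks(g, cfg.matrix_mz, cfg.matrix_spacing, cfg.matrix_window)
        g = normalize_total(g, cfg.normalization_total)
        specs.append(g)
    return average_replicates(specs)


def write_grid_csv(spec: GridSpectrum, path) -> None:
    """Persist a grid spectrum as two-column CSV (bin m/z, intensity)."""
    import pandas as pd

    pd.DataFrame({"mz": spec.mz_grid, "intensity": spec.intensities}).to_csv(
        path, index=False
    )


def read_grid_csv(path, sample_id: str = "") -> GridSpectrum:
    """Read a grid spectrum written by :func:`write_grid_csv`."""
    import pandas as pd

    frame = pd.read_csv(path)
    mz = frame["mz"].to_numpy(dtype=float)
    step = float(np.median(np.diff(mz)))
    return GridSpectrum(float(mz[0]), step, frame["intensity"].to_numpy(dtype=float),
                        sample_id=sample_id)
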