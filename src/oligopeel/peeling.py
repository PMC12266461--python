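"""Iterative detection and removal ("peeling") of repeat-unit-spaced peak combs.

An ethoxylated constituent appears in a MALDI spectrum as a comb of peaks one
ethylene-oxide unit (44.0262 Da monoisotopic) apart, whose envelope is
bell-shaped.  The most intense bin in the spectrum marks the apex of the most
abundant constituent's distribution; the comb is tracked outward in both
directions, its member intensities recorded and then zeroed, and the process
repeats on the residual until the remaining maximum falls below a stopping
threshold.

Two intensity notions coexist deliberately:

* the *detection* intensity — the residual maximum bin at detection time —
  which orders records and drives the stopping thresholds; it is exactly
  non-increasing over the peel sequence;
* the *member* intensity — the sum of bins within ``±peak_halfwidth`` of a
  member's bin — which is insensitive to a centroid being split across two
  grid bins by proportional binning.  The recorded distribution features
  (apex m/z, apex intensity, width, ratio to the main distribution) are all
  computed on member intensities, i.e. on the distribution envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .masses import EO_MASS_MONO
from .preprocess import GridSpectrum


@dataclass
class PeelConfig:
    """Tunable thresholds of the peeling algorithm.

    spacing            repeat-unit mass (44.0262 EO, 58.0419 PO)
    track_window       +- window (Da) around the expected next member position
    apex_stop_fraction stop peeling when the residual max falls below this
                       fraction of the original global maximum
    apex_stop_abs      absolute floor for the same stop rule (the effective
                       threshold is the max of both); lets a residual be
                       re-peeled under the original spectrum's threshold
    member_stop_fraction stop extending a comb when the candidate bin falls
                       below this fraction of the comb's apex bin
    member_noise_floor absolute intensity floor for comb members;
                       auto-estimated from the spectrum when None
    peak_halfwidth     minimum half-width (Da) of the bin footprint summed per
                       member and zeroed on removal
    peak_max_halfwidth hard cap (Da) on the adaptively grown footprint; must
                       stay below the 1.0034 Da isotope-satellite offset
    peak_growth_stop   footprint growth stops once a bin falls below this
                       fraction of the member bin (absorbs peak broadening
                       from replicate averaging under residual mass drift)
    """

    spacing: float = EO_MASS_MONO
    track_window: float = 0.3
    apex_stop_fraction: float = 0.05
    apex_stop_abs: float = 0.0
    member_stop_fraction: float = 0.02
    member_noise_floor: float | None = None
    peak_halfwidth: float = 0.2
    peak_max_halfwidth: float = 0.5
    peak_growth_stop: float = 0.1

    def __post_init__(self) -> None:
        for name in ("spacing", "track_window", "peak_halfwidth", "peak_max_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_max_halfwidth < self.peak_halfwidth:
            raise ValueError("peak_max_halfwidth must be >= peak_halfwidth")
        if not 0 < self.peak_growth_stop < 1:
            raise ValueError("peak_growth_stop must be in (0, 1)")
        for name in ("apex_stop_fraction", "member_stop_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class Comb:
    """One tracked comb: member positions and intensities, ascending in m/z."""

    member_mz: np.ndarray
    member_intensity: np.ndarray  # footprint sums (the envelope)
    member_bin_intensity: np.ndarray
    member_bins: np.ndarray  # bin index of each member
    member_lo: np.ndarray  # inclusive footprint bounds per member (bin indices)
    member_hi: np.ndarray
    apex_index: int  # envelope apex: argmax of member_intensity (ties -> lower m/z)
    detection_index: int  # member found at the residual-maximum bin
    spacing: float

    def __len__(self) -> int:
        return int(self.member_mz.size)

    @property
    def total_intensity(self) -> float:
        return float(self.member_intensity.sum())


@dataclass
class DistributionRecord:
    """Features of one peeled distribution in one spectrum.

    ``apex_mz`` / ``apex_intensity`` describe the envelope maximum (member
    with the largest footprint intensity); ``detection_intensity`` is the
    residual-maximum bin that triggered detection and is non-increasing over
    the peel sequence.
    """

    apex_mz: float
    apex_intensity: float  # envelope apex (footprint sum of the apex member)
    width_half_height: float
    ratio_to_main: float
    members: Comb
    local_rank: int
    total_intensity: float
    detection_mz: float = 0.0
    detection_intensity: float = 0.0

    def to_dict(self) -> dict:
        return {
            "apex_mz": self.apex_mz,
            "apex_intensity": self.apex_intensity,
            "detection_mz": self.detection_mz,
            "detection_intensity": self.detection_intensity,
            "width_half_height": self.width_half_height,
            "ratio_to_main": self.ratio_to_main,
            "local_rank": self.local_rank,
            "total_intensity": self.total_intensity,
            "member_mz": self.members.member_mz.tolist(),
            "member_intensity": self.members.member_intensity.tolist(),
        }


def estimate_noise_floor(spec: GridSpectrum) -> float:
    """Robust noise floor: median + 3 * MAD of the bin intensities.

    The median/MAD pair is dominated by baseline bins, so isolated signal
    peaks do not inflate the estimate; on a sparse noiseless spectrum (mostly
    zero bins) the floor collapses to zero and the fractional thresholds in
    :class:`PeelConfig` take over.
    """
    x = spec.intensities
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med + 3.0 * mad


def find_apex(intensities: np.ndarray) -> tuple[int, float] | None:
    """Index and value of the global maximum; ties break toward lower m/z.

    Returns ``None`` for an all-zero residual ("no apex").
    """
    idx = int(np.argmax(intensities))  # argmax returns the first (lowest-m/z) tie
    val = float(intensities[idx])
    if val <= 0:
        return None
    return idx, val


def _footprint(x: np.ndarray, i: int, hw_bins: int, max_bins: int, stop_frac: float) -> tuple[int, int]:
    """Inclusive bin bounds of one peak's footprint around member bin ``i``.

    Always covers ``±hw_bins``; beyond that it grows while bins stay above
    ``stop_frac`` of the member bin (peaks broadened by replicate averaging
    under small mass drift), hard-capped at ``±max_bins`` so the footprint
    can never swallow the isotope satellite one mass unit away.
    """
    n = x.size
    ref = stop_frac * x[i]
    lo = max(0, i - hw_bins)
    hi = min(n - 1, i + hw_bins)
    while lo > 0 and i - lo < max_bins and x[lo - 1] >= ref:
        lo -= 1
    while hi < n - 1 and hi - i < max_bins and x[hi + 1] >= ref:
        hi += 1
    return lo, hi


def track_comb(
    spec: GridSpectrum,
    apex_bin: int,
    cfg: PeelConfig,
    noise_floor: float = 0.0,
    intensities: np.ndarray | None = None,
) -> Comb:
    """Walk outward from the apex in steps of one repeat unit.

    At each step the expected position is the last-found member's m/z plus or
    minus ``cfg.spacing``; the candidate is the most intense bin within
    ``±cfg.track_window`` of it.  Re-anchoring each step on the found member
    absorbs calibration drift.  A direction stops when the candidate bin
    falls below ``max(member_stop_fraction * apex_bin_intensity, noise_floor)``.
    """
    x = spec.intensities if intensities is None else intensities
    n = x.size
    step = spec.grid_step
    hw_bins = int(round(cfg.peak_halfwidth / step))
    win_bins = int(round(cfg.track_window / step))
    spacing_bins = cfg.spacing / step

    apex_intensity = float(x[apex_bin])
    stop = max(cfg.member_stop_fraction * apex_intensity, noise_floor)

    def walk(direction: int) -> list[int]:
        found = []
        last = float(apex_bin)
        while True:
            expected = last + direction * spacing_bins
            lo = int(np.ceil(expected - win_bins))
            hi = int(np.floor(expected + win_bins))
            lo, hi = max(lo, 0), min(hi, n - 1)
            if lo > hi:
                break
            window = x[lo : hi + 1]
            cand = lo + int(np.argmax(window))
            if float(x[cand]) < stop:
                break
            found.append(cand)
            last = float(cand)  # re-anchor on the found member
        return found

    down = walk(-1)
    up = walk(+1)
    bins = np.array(list(reversed(down)) + [apex_bin] + up, dtype=int)
    max_bins = int(round(cfg.peak_max_halfwidth / step))
    bounds = [_footprint(x, int(b), hw_bins, max_bins, cfg.peak_growth_stop) for b in bins]
    member_intensity = np.array([float(x[lo : hi + 1].sum()) for lo, hi in bounds])
    return Comb(
        member_mz=spec.grid_start + step * bins.astype(float),
        member_intensity=member_intensity,
        member_bin_intensity=x[bins].astype(float).copy(),
        member_bins=bins,
        member_lo=np.array([b[0] for b in bounds], dtype=int),
        member_hi=np.array([b[1] for b in bounds], dtype=int),
        apex_index=int(np.argmax(member_intensity)),
        detection_index=len(down),
        spacing=cfg.spacing,
    )


def compute_width_half_height(comb: Comb) -> float:
    """Width (Da) of the member envelope at half the apex member intensity.

    The envelope is the piecewise-linear interpolation through
    (member m/z, member intensity).  On each side of the apex the width
    contribution is the distance from the apex to the half-maximum crossing;
    if the envelope never drops below half maximum on a side, the distance to
    the outermost member is used.  A single-member comb has width 0.
    """
    if len(comb) <= 1:
        return 0.0
    mz = comb.member_mz
    y = comb.member_intensity
    a = comb.apex_index
    half = y[a] / 2.0

    def half_crossing(indices) -> float:
        # walk from the apex outward; indices are successive member positions
        prev = a
        for i in indices:
            if y[i] < half:
                # crossing between prev (>= half) and i (< half)
                frac = (y[prev] - half) / (y[prev] - y[i])
                return abs((mz[prev] + frac * (mz[i] - mz[prev])) - mz[a])
            prev = i
        return abs(mz[indices[-1]] - mz[a]) if indices else 0.0

    left = half_crossing(list(range(a - 1, -1, -1)))
    right = half_crossing(list(range(a + 1, len(comb))))
    return left + right


def peel_distribution(
    spec: GridSpectrum,
    cfg: PeelConfig,
    noise_floor: float = 0.0,
    residual: np.ndarray | None = None,
) -> tuple[DistributionRecord, np.ndarray]:
    """Detect the most intense comb, record it and zero its member footprints.

    Returns the record and the residual intensity vector; the residual total
    equals the input total minus the record's member total exactly (member
    footprints of one comb do not overlap for any spacing >> peak width).
    """
    x = spec.intensities.copy() if residual is None else residual
    apex = find_apex(x)
    if apex is None:
        raise DegenerateResidualError("no apex: all-zero residual")
    apex_bin, apex_val = apex
    comb = track_comb(spec, apex_bin, cfg, noise_floor=noise_floor, intensities=x)
    for lo, hi in zip(comb.member_lo, comb.member_hi):
        x[lo : hi + 1] = 0.0
    record = DistributionRecord(
        apex_mz=float(comb.member_mz[comb.apex_index]),
        apex_intensity=float(comb.member_intensity[comb.apex_index]),
        width_half_height=compute_width_half_height(comb),
        ratio_to_main=1.0,  # set by peel_all
        members=comb,
        local_rank=0,  # set by peel_all
        total_intensity=comb.total_intensity,
        detection_mz=float(comb.member_mz[comb.detection_index]),
        detection_intensity=apex_val,
    )
    return record, x


class DegenerateResidualError(ValueError):
    pass


@dataclass
class PeelResult:
    """Everything produced by one peeling run on one spectrum."""

    records: list[DistributionRecord]
    residual: GridSpectrum
    stop_threshold: float  # absolute apex stop used (carry into re-peels)
    noise_floor: float


def peel_spectrum(spec: GridSpectrum, cfg: PeelConfig | None = None) -> PeelResult:
    """Peel distributions until the residual maximum drops below threshold.

    The effective stop threshold is
    ``max(apex_stop_fraction * original_max, apex_stop_abs)``; it is returned
    in the result so that re-peeling the residual under the *same* threshold
    (which yields no further records) is expressible.  Records come out in
    detection order; ``ratio_to_main`` is each envelope apex intensity
    divided by the first record's.  A zero spectrum yields no records.
    """
    cfg = cfg or PeelConfig()
    residual = spec.intensities.copy()
    original_max = float(residual.max())
    records: list[DistributionRecord] = []
    floor = cfg.member_noise_floor
    if floor is None:
        floor = estimate_noise_floor(spec)
    threshold = max(cfg.apex_stop_fraction * original_max, cfg.apex_stop_abs)
    if original_max > 0:
        while float(residual.max()) >= threshold and threshold > 0:
            record, residual = peel_distribution(spec, cfg, noise_floor=floor, residual=residual)
            records.append(record)
    for rank, r in enumerate(records, start=1):
        r.local_rank = rank
        r.ratio_to_main = r.apex_intensity / records[0].apex_intensity
    out = spec.copy()
    out.intensities = residual
    return PeelResult(records, out, threshold, floor)


def peel_all(
    spec: GridSpectrum,
    cfg: PeelConfig | None = None,
    return_residual: bool = False,
):
    """Convenience wrapper over :func:`peel_spectrum` returning the records."""
    result = peel_spectrum(spec, cfg)
    if return_residual:
        return result.records, result.residual
    return result.records
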