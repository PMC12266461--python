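"""Synthetic ethoxylate MALDI-TOF peak-list generator with ground truth.

A spectrum is a sum of constituent series: component ``i`` contributes a comb
of oligomer peaks at ``base + n*EO + adduct`` whose intensities follow a
bell-shaped envelope over the EO count ``n`` (Poisson by default — the
natural shape for living alkoxylation — or Gaussian), plus 13C isotope
satellites at ``+k*1.0034`` with Poisson(isotope_lambda) weights, matrix
peaks, and additive half-normal baseline noise on a fine m/z grid.  Peak
centroids are jittered slightly so that downstream proportional binning is
exercised.  Every generated spectrum is accompanied by a ground-truth record
for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .masses import EO_MASS_MONO, ISOTOPE_SPACING, SODIUM_MONO
from .spectra_io import RawPeakList


@dataclass
class SimComponent:
    """One constituent series in a simulated product."""

    name: str
    base_mass: float
    abundance: float = 1.0
    adduct_mass: float = SODIUM_MONO
    envelope: str = "poisson"  # poisson | gaussian
    mean_eo: float = 18.0
    sigma_eo: float | None = None  # gaussian only
    isotope_lambda: float = 0.0  # expected 13C count; 0 disables satellites

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if self.mean_eo <= 0:
            raise ValueError("mean_eo must be positive")
        if self.envelope not in ("poisson", "gaussian"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if self.envelope == "gaussian" and not self.sigma_eo:
            raise ValueError("gaussian envelope needs sigma_eo")

    def envelope_weights(self, n: np.ndarray) -> np.ndarray:
        if self.envelope == "poisson":
            return stats.poisson.pmf(n, self.mean_eo)
        return np.exp(-((n - self.mean_eo) ** 2) / (2.0 * self.sigma_eo**2))


@dataclass
class ComponentTruth:
    name: str
    base_mass: float
    adduct_mass: float
    abundance: float
    mean_eo: float
    apex_n: int
    apex_mz: float  # exact (jitter-free) apex position
    peaks_mz: np.ndarray  # generated peaks incl. jitter and satellites
    peaks_intensity: np.ndarray
    total_intensity: float


@dataclass
class SimTruth:
    components: list[ComponentTruth]
    seed: int
    noise_sd: float
    replicate_cv: float

    def component(self, name: str) -> ComponentTruth:
        return next(c for c in self.components if c.name == name)


def simulate_spectrum(
    components: list[SimComponent],
    noise_sd: float = 1e-4,
    matrix_peaks: tuple = (),
    replicate_cv: float = 0.0,
    seed: int = 0,
    mz_range: tuple[float, float] = (500.0, 3000.0),
    mz_jitter: float = 0.02,
    calibration_shift: float = 0.0,
    eo_mass: float = EO_MASS_MONO,
) -> tuple[RawPeakList, SimTruth]:
    """Generate one replicate spectrum and its ground truth.

    Baseline noise is half-normal with scale ``noise_sd`` at every 0.05 Da
    position of ``mz_range``; ``replicate_cv`` applies independent lognormal
    intensity jitter (coefficient of variation) per peak;
    ``calibration_shift`` displaces the whole mass axis (residual external
    calibration error of the acquisition).  Deterministic for a fixed seed.
    """
    if not components:
        raise ValueError("empty component list")
    rng = np.random.default_rng(seed)
    lo, hi = mz_range
    all_mz: list[np.ndarray] = []
    all_int: list[np.ndarray] = []
    truths: list[ComponentTruth] = []
    for comp in components:
        n_max = int(comp.mean_eo + 15 * max(np.sqrt(comp.mean_eo), comp.sigma_eo or 0)) + 5
        n = np.arange(0, n_max + 1)
        w = comp.envelope_weights(n)
        keep = w >= 1e-6 * w.max()
        n, w = n[keep], w[keep]
        mz0 = comp.base_mass + n * eo_mass + comp.adduct_mass
        inside = (mz0 >= lo) & (mz0 <= hi)
        n, w, mz0 = n[inside], w[inside], mz0[inside]
        if n.size == 0:
            truths.append(
                ComponentTruth(comp.name, comp.base_mass, comp.adduct_mass, comp.abundance,
                               comp.mean_eo, 0, np.nan, np.empty(0), np.empty(0), 0.0)
            )
            continue
        inten = comp.abundance * w
        if replicate_cv > 0:
            sigma = np.sqrt(np.log1p(replicate_cv**2))
            inten = inten * rng.lognormal(-sigma**2 / 2.0, sigma, size=inten.size)
        jitter = rng.uniform(-mz_jitter, mz_jitter, size=mz0.size)
        mz = mz0 + jitter + calibration_shift
        comp_mz, comp_int = [mz], [inten]
        if comp.isotope_lambda > 0:
            p = stats.poisson.pmf([0, 1, 2], comp.isotope_lambda)
            comp_int[0] = inten * p[0]
            for k in (1, 2):
                comp_mz.append(mz + k * ISOTOPE_SPACING)
                comp_int.append(inten * p[k])
        peaks_mz = np.concatenate(comp_mz)
        peaks_int = np.concatenate(comp_int)
        # ties (e.g. Poisson pmf(mean-1) == pmf(mean) at integer mean) break
        # to the lower EO count; compare with a relative tolerance so the
        # identity is not lost to floating-point evaluation order
        apex_i = int(np.argmax(w >= w.max() * (1.0 - 1e-9)))
        truths.append(
            ComponentTruth(
                name=comp.name,
                base_mass=comp.base_mass,
                adduct_mass=comp.adduct_mass,
                abundance=comp.abundance,
                mean_eo=comp.mean_eo,
                apex_n=int(n[apex_i]),
                apex_mz=float(mz0[apex_i]),
                peaks_mz=peaks_mz,
                peaks_intensity=peaks_int,
                total_intensity=float(peaks_int.sum()),
            )
        )
        all_mz.append(peaks_mz)
        all_int.append(peaks_int)
    for pos, height in matrix_peaks:
        all_mz.append(np.array([pos]))
        all_int.append(np.array([height]))
    if noise_sd > 0:
        grid = np.arange(lo, hi, 0.05)
        all_mz.append(grid)
        all_int.append(np.abs(rng.normal(0.0, noise_sd, size=grid.size)))
    if not all_mz:
        raise ValueError("no peaks generated inside mz_range")
    peaklist = RawPeakList.from_arrays(
        np.concatenate(all_mz), np.concatenate(all_int), source_id=f"sim:{seed}"
    )
    return peaklist, SimTruth(truths, seed, noise_sd, replicate_cv)


@dataclass
class SimDesign:
    """Per-class component tables plus shared acquisition parameters."""

    classes: dict[str, list[SimComponent]]
    noise_sd: float = 1e-4
    replicate_cv: float = 0.10
    abundance_cv: float = 0.10  # sample-to-sample (batch) abundance variation
    matrix_peaks: tuple = ()
    mz_range: tuple[float, float] = (500.0, 3000.0)
    mz_jitter: float = 0.02
    # Per-replicate global m/z offset (Da).  Exported peak lists are assumed
    # to have been aligned upstream, so the default emulates aligned data;
    # set > 0 to emulate residual calibration error.
    calibration_shift_sd: float = 0.0


@dataclass
class SimDataset:
    manifest: pd.DataFrame
    peaklists: dict[tuple[str, int], RawPeakList]  # (sample_id, replicate) -> peaks
    truths: dict[str, list[SimTruth]]  # sample_id -> per-replicate truths
    sample_components: dict[str, list[SimComponent]]  # realized (jittered) abundances
    design: SimDesign

    def replicates_for(self, sample_id: str) -> list[RawPeakList]:
        reps = sorted(k[1] for k in self.peaklists if k[0] == sample_id)
        return [self.peaklists[(sample_id, r)] for r in reps]


def simulate_dataset(
    design: SimDesign,
    n_samples_per_class: int,
    n_replicates: int = 4,
    seed: int = 0,
) -> SimDataset:
    """Generate a batch-structured dataset: samples x replicates per class.

    Each sample draws its component abundances with lognormal batch variation
    (``design.abundance_cv``); each replicate then gets independent per-peak
    lognormal jitter (``design.replicate_cv``) and fresh noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    peaklists: dict[tuple[str, int], RawPeakList] = {}
    truths: dict[str, list[SimTruth]] = {}
    sample_components: dict[str, list[SimComponent]] = {}
    for class_label, components in design.classes.items():
        for s in range(n_samples_per_class):
            sample_id = f"{class_label}_s{s:02d}"
            if design.abundance_cv > 0:
                sigma = np.sqrt(np.log1p(design.abundance_cv**2))
                comps = [
                    replace(c, abundance=c.abundance * rng.lognormal(-sigma**2 / 2.0, sigma))
                    for c in components
                ]
            else:
                comps = [replace(c) for c in components]
            sample_components[sample_id] = comps
            truths[sample_id] = []
            for rep in range(1, n_replicates + 1):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                shift = (
                    float(rng.normal(0.0, design.calibration_shift_sd))
                    if design.calibration_shift_sd > 0
                    else 0.0
                )
                pl, truth = simulate_spectrum(
                    comps,
                    noise_sd=design.noise_sd,
                    matrix_peaks=design.matrix_peaks,
                    replicate_cv=design.replicate_cv,
                    seed=rep_seed,
                    mz_range=design.mz_range,
                    mz_jitter=design.mz_jitter,
                    calibration_shift=shift,
                )
                peaklists[(sample_id, rep)] = pl
                truths[sample_id].append(truth)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "product_label": "simulated",
                        "type_label": class_label,
                        "replicate_index": rep,
                        "path": f"{sample_id}_r{rep}.csv",
                    }
                )
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "product_label", "type_label", "replicate_index", "path"]
    )
    return SimDataset(manifest, peaklists, truths, sample_components, design)


# ---------------------------------------------------------------------------
# Shipped study designs (used by tests, the CLI examples and scripts)

GLYCEROL_MONO = 92.0473  # C3H8O3
WATER_MONO = 18.0106  # H2O (free PEG base)
OLEYL_MONO = 268.2766  # C18H36O
CETYL_MONO = 242.2610  # C16H34O


def peg_castor_design(ratio_contrast: float = 1.5) -> SimDesign:
    """Two PEG-castor-oil-like classes differing in glycerol:PEG abundance ratio.

    Type 1 has glycerol:PEG = 0.4, Type 2 has that ratio multiplied by
    ``ratio_contrast`` (default 1.5x).  Envelope means (18 EO for PEG,
    29 EO for ethoxylated glycerol) put the apexes near m/z 834 and 1392.
    """
    def comps(glycerol_abundance: float) -> list[SimComponent]:
        return [
            SimComponent("PEG", WATER_MONO, abundance=1.0, mean_eo=18.0, isotope_lambda=0.39),
            SimComponent(
                "glycerol-EO", GLYCEROL_MONO, abundance=glycerol_abundance,
                mean_eo=29.0, isotope_lambda=0.65,
            ),
        ]

    return SimDesign(
        classes={"Type1": comps(0.4), "Type2": comps(0.4 * ratio_contrast)},
        matrix_peaks=((552.3, 0.05), (569.2, 0.08)),
        mz_range=(500.0, 2200.0),
    )


def oleth_design() -> SimDesign:
    """Three Oleth-20-like classes: R1 shifted +2 EO; R3 with more cetyl alcohol."""
    def comps(oleyl_eo: float, cetyl_abundance: float) -> list[SimComponent]:
        return [
            SimComponent("oleyl-EO", OLEYL_MONO, abundance=1.0, mean_eo=oleyl_eo,
                         isotope_lambda=0.41),
            SimComponent("cetyl-EO", CETYL_MONO, abundance=cetyl_abundance, mean_eo=20.0,
                         isotope_lambda=0.39),
        ]

    return SimDesign(
        classes={
            "R1": comps(22.0, 0.12),
            "R2": comps(20.0, 0.12),
            "R3": comps(20.0, 0.35),
        },
        mz_range=(500.0, 2400.0),
    )
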