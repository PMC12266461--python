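"""Assignment of peeled distributions to ethoxylated constituent series.

A constituent series is a base compound (water for free PEG, glycerol, a
fatty alcohol, ...) carrying ``n`` ethylene-oxide units and a cationizing
adduct: ``m/z(n) = base + n * EO + adduct``.  Candidate series tables are
enumerated from a user-supplied base-compound dictionary, apex masses are
matched to the nearest table entry within a tolerance (default 0.5 m/z), and
distributions that are merely the 13C isotope satellite of another
distribution are folded into their parent before reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import masses
from .masses import ISOTOPE_SPACING

logger = logging.getLogger(__name__)


@dataclass
class ConstituentSeries:
    """One homologous series: base compound + n EO units + adduct."""

    name: str
    base_mass: float
    adduct_mass: float
    eo_mass: float
    n_range: tuple[int, int] = (0, 80)
    mass_mode: str = "average"

    def mz(self, n: int) -> float:
        return self.base_mass + n * self.eo_mass + self.adduct_mass

    def table(self) -> pd.DataFrame:
        ns = np.arange(self.n_range[0], self.n_range[1] + 1)
        return pd.DataFrame({"n": ns, "mz": [self.mz(int(n)) for n in ns]})

    def nearest_n(self, mz: float) -> int:
        n = int(round((mz - self.base_mass - self.adduct_mass) / self.eo_mass))
        return int(np.clip(n, self.n_range[0], self.n_range[1]))


def enumerate_series(
    bases,
    adduct: str = "Na",
    n_range: tuple[int, int] = (0, 80),
    mass_mode: str = "average",
) -> list[ConstituentSeries]:
    """Build constituent series from base compounds.

    ``bases`` is a list of ``(name, formula)`` pairs (elemental formula such
    as ``"C3H8O3"``) or ``(name, {"monoisotopic": m, "average": m})`` with
    explicit masses.
    """
    eo = masses.eo_mass(mass_mode)
    add = masses.adduct_mass(adduct, mass_mode)
    series = []
    for name, base in bases:
        if isinstance(base, str):
            base_mass = masses.formula_mass(base, mass_mode)
        elif isinstance(base, dict):
            base_mass = float(base[mass_mode])
        else:
            base_mass = float(base)
        series.append(
            ConstituentSeries(
                name=name,
                base_mass=base_mass,
                adduct_mass=add,
                eo_mass=eo,
                n_range=n_range,
                mass_mode=mass_mode,
            )
        )
    return series


@dataclass
class Assignment:
    """Match of one distribution apex to a constituent series."""

    dist_id: int | None
    series_name: str | None
    n_at_apex: int | None
    mass_error: float | None
    status: str  # assigned | ambiguous | unassigned | isotope_satellite
    satellite_of: int | None = None
    candidates: list = field(default_factory=list)  # (series, n, |error|) ranked

    def to_dict(self) -> dict:
        return {
            "dist_id": self.dist_id,
            "series": self.series_name,
            "n_at_apex": self.n_at_apex,
            "mass_error": self.mass_error,
            "status": self.status,
            "satellite_of": self.satellite_of,
            "candidates": [
                {"series": s, "n": n, "abs_error": e} for s, n, e in self.candidates
            ],
        }


def assign_distribution(
    apex_mz: float,
    series_list: list[ConstituentSeries],
    tolerance: float = 0.5,
    dist_id: int | None = None,
) -> Assignment:
    """Assign an apex m/z to the nearest series oligomer within tolerance.

    If two or more series have a candidate within tolerance the assignment is
    ambiguous (isobaric ethoxylated species) and all candidates are reported
    ranked by absolute mass error.
    """
    best = []
    for series in series_list:
        n = series.nearest_n(apex_mz)
        err = apex_mz - series.mz(n)
        best.append((series.name, n, abs(err), err))
    best.sort(key=lambda t: t[2])
    within = [b for b in best if b[2] <= tolerance]
    candidates = [(name, n, abs_err) for name, n, abs_err, _ in within]
    if not within:
        return Assignment(dist_id, None, None, None, "unassigned", candidates=candidates)
    name, n, _, err = within[0]
    status = "ambiguous" if len(within) > 1 else "assigned"
    return Assignment(dist_id, name, n, err, status, candidates=candidates)


def assign_catalog(
    apex_by_id: dict[int, float],
    series_list: list[ConstituentSeries],
    tolerance: float = 0.5,
) -> dict[int, Assignment]:
    """Assign every catalogued distribution apex."""
    return {
        gid: assign_distribution(apex, series_list, tolerance, dist_id=gid)
        for gid, apex in apex_by_id.items()
    }


def merge_isotope_satellites(
    apex_by_id: dict[int, float],
    intensity_by_id: dict[int, float],
    assignments: dict[int, Assignment],
    iso_spacing: float = ISOTOPE_SPACING,
    iso_tol: float = 0.15,
    comb_spacing: float = 44.026214749699996,
    max_shift_units: int = 5,
) -> tuple[dict[int, Assignment], dict[int, float]]:
    """Fold isotope-satellite distributions into their parents.

    An id whose apex sits ``k * iso_spacing`` (k = 1 or 2) above another id's
    apex — compared modulo the comb spacing, since near a flat envelope top
    the reported apex may flick to an adjacent comb member — within
    ``iso_tol``, with lower mean intensity, is relabelled as that parent's
    isotope satellite; its intensity is added to the parent's in the returned
    combined-intensity map.  A putative satellite *more* intense than its
    parent is left alone (and logged): a genuine 13C satellite is always
    weaker than its monoisotopic parent.
    """
    combined = dict(intensity_by_id)
    out = dict(assignments)
    satellite_parent: dict[int, int] = {}

    def phase_offset(delta: float, k: int) -> float:
        r = (delta - k * iso_spacing) % comb_spacing
        return r - comb_spacing if r > comb_spacing / 2 else r

    # parents considered strongest-first; a satellite attaches to the most
    # intense id whose phase it sits k isotope units above
    by_intensity = sorted(apex_by_id, key=lambda g: (-intensity_by_id[g], g))
    for parent in by_intensity:
        if parent in satellite_parent:
            continue
        for cand in by_intensity:
            if cand == parent or cand in satellite_parent:
                continue
            delta = apex_by_id[cand] - apex_by_id[parent]
            if abs(delta) > max_shift_units * comb_spacing:
                continue
            if any(abs(phase_offset(delta, k)) <= iso_tol for k in (1, 2)):
                if intensity_by_id[cand] < intensity_by_id[parent]:
                    satellite_parent[cand] = parent
                else:
                    logger.warning(
                        "id %d sits %.4f above id %d but is more intense; not merged",
                        cand, delta, parent,
                    )
    for gid, parent in satellite_parent.items():
        prev = out.get(gid)
        out[gid] = Assignment(
            dist_id=gid,
            series_name=prev.series_name if prev else None,
            n_at_apex=prev.n_at_apex if prev else None,
            mass_error=prev.mass_error if prev else None,
            status="isotope_satellite",
            satellite_of=parent,
        )
        combined[parent] = combined.get(parent, 0.0) + intensity_by_id[gid]
        combined.pop(gid, None)
    return out, combined


def assignments_to_frame(assignments: dict[int, Assignment]) -> pd.DataFrame:
    rows = [a.to_dict() for _, a in sorted(assignments.items())]
    return pd.DataFrame(rows).drop(columns=["candidates"])
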