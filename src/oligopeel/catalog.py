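"""Global matching of distributions across spectra and ratio-scaled features.

Distributions detected per spectrum are matched into global IDs: the first
spectrum seeds IDs in its detection order, and each later spectrum's records
are greedily matched (smallest apex distance first) to IDs whose comb phase
agrees; unmatched records open new IDs.  The per-sample feature table
(4 features per ID) is then unit-variance scaled and weighted by each
distribution's average-intensity ratio to the first major distribution
("ratio-scaling"), so that features from abundant distributions carry more
weight than features from distributions near the noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masses import EO_MASS_MONO
from .peeling import DistributionRecord

FEATURES = ("apex_mz", "apex_intensity", "width_half_height", "ratio_to_main")


@dataclass
class DistributionCatalog:
    """Mapping global id -> {sample_id -> DistributionRecord}."""

    entries: dict[int, dict[str, DistributionRecord]]
    ref_apex: dict[int, float]  # first-seen apex m/z per id
    sample_ids: list[str]
    spacing: float = EO_MASS_MONO

    @property
    def ids(self) -> list[int]:
        return sorted(self.entries)

    def mean_apex(self, gid: int) -> float:
        return float(np.mean([r.apex_mz for r in self.entries[gid].values()]))

    def representative_apex(self, gid: int) -> float:
        """Most frequent observed apex position of an id (intensity-weighted ties).

        Near a flat envelope top the apex can alternate between two adjacent
        comb members across samples, so the across-sample *mean* apex falls
        between comb positions; for mass matching the modal observed apex is
        the meaningful statistic.
        """
        recs = list(self.entries[gid].values())
        positions: dict[float, tuple[int, float]] = {}
        for r in recs:
            key = round(r.apex_mz, 1)
            n, w = positions.get(key, (0, 0.0))
            positions[key] = (n + 1, w + r.apex_intensity)
        best = max(positions.items(), key=lambda kv: (kv[1][0], kv[1][1]))
        return float(best[0])

    def mean_intensity(self, gid: int) -> float:
        """Mean apex intensity over the samples the id occurs in."""
        return float(np.mean([r.apex_intensity for r in self.entries[gid].values()]))


def _phase_residue(delta: float, spacing: float) -> float:
    """Residue of ``delta`` modulo ``spacing`` mapped nearest zero."""
    r = delta % spacing
    return r - spacing if r > spacing / 2 else r


def match_across_spectra(
    per_spectrum: dict[str, list[DistributionRecord]],
    spacing: float = EO_MASS_MONO,
    phase_tol: float = 0.5,
    max_shift_EO: int = 5,
) -> DistributionCatalog:
    """Match per-spectrum distribution records into global IDs.

    Two records belong to the same constituent series when their apexes sit on
    the same comb phase (apex difference reduced modulo the spacing is within
    ``phase_tol``) and are at most ``max_shift_EO`` repeat units apart (the
    apex itself may shift a few EO units between product types).
    """
    if not per_spectrum:
        raise ValueError("no spectra to match")
    sample_ids = list(per_spectrum)
    entries: dict[int, dict[str, DistributionRecord]] = {}
    ref_apex: dict[int, float] = {}
    next_id = 1
    for s_index, sid in enumerate(sample_ids):
        records = per_spectrum[sid]
        if s_index == 0:
            for rec in records:
                entries[next_id] = {sid: rec}
                ref_apex[next_id] = rec.apex_mz
                next_id += 1
            continue
        # candidate (distance, record order, id) pairs satisfying the phase
        # and shift constraints, consumed greedily by smallest distance
        candidates = []
        for r_idx, rec in enumerate(records):
            for gid, apex in ref_apex.items():
                d = abs(rec.apex_mz - apex)
                if d <= max_shift_EO * spacing and abs(
                    _phase_residue(rec.apex_mz - apex, spacing)
                ) <= phase_tol:
                    candidates.append((d, r_idx, gid))
        candidates.sort()
        matched_records: set[int] = set()
        matched_ids: set[int] = set()
        for d, r_idx, gid in candidates:
            if r_idx in matched_records or gid in matched_ids:
                continue
            entries[gid][sid] = records[r_idx]
            matched_records.add(r_idx)
            matched_ids.add(gid)
        for r_idx, rec in enumerate(records):
            if r_idx not in matched_records:
                entries[next_id] = {sid: rec}
                ref_apex[next_id] = rec.apex_mz
                next_id += 1
    return DistributionCatalog(entries, ref_apex, sample_ids, spacing=spacing)


@dataclass
class FeatureTable:
    """Samples x (distribution x feature) matrix with per-id weights.

    Columns are named ``d<ID>_<feature>``.  ``weights`` is populated by
    :func:`ratio_scale`; ``scaled`` records whether scaling was applied.
    """

    data: pd.DataFrame  # index: sample_id
    ids: list[int]
    weights: pd.Series | None = None
    scaled: bool = False
    labels: pd.Series | None = None  # type label per sample, when known

    def columns_for(self, gid: int) -> list[str]:
        return [f"d{gid}_{f}" for f in FEATURES]

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def build_feature_table(
    catalog: DistributionCatalog,
    labels: pd.Series | dict | None = None,
) -> FeatureTable:
    """Assemble the unscaled per-sample feature table from the catalog.

    Where an id is absent from a sample, apex intensity and ratio are 0 (the
    distribution is genuinely not there) while apex m/z and width are imputed
    with the id's across-sample mean (a placeholder zero would fabricate
    variance on a mass scale).
    """
    ids = catalog.ids
    assert ids, "catalog has no distributions"
    columns: dict[str, list[float]] = {}
    for gid in ids:
        recs = catalog.entries[gid]
        assert recs, f"id {gid} occurs in no sample"
        mean_mz = float(np.mean([r.apex_mz for r in recs.values()]))
        mean_width = float(np.mean([r.width_half_height for r in recs.values()]))
        col_mz, col_int, col_w, col_ratio = [], [], [], []
        for sid in catalog.sample_ids:
            r = recs.get(sid)
            if r is None:
                col_mz.append(mean_mz)
                col_int.append(0.0)
                col_w.append(mean_width)
                col_ratio.append(0.0)
            else:
                col_mz.append(r.apex_mz)
                col_int.append(r.apex_intensity)
                col_w.append(r.width_half_height)
                col_ratio.append(r.ratio_to_main)
        columns[f"d{gid}_apex_mz"] = col_mz
        columns[f"d{gid}_apex_intensity"] = col_int
        columns[f"d{gid}_width_half_height"] = col_w
        columns[f"d{gid}_ratio_to_main"] = col_ratio
    data = pd.DataFrame(columns, index=pd.Index(catalog.sample_ids, name="sample_id"))
    if labels is not None:
        labels = pd.Series(labels).reindex(data.index)
    return FeatureTable(data=data, ids=ids, labels=labels)


def ratio_scale(table: FeatureTable) -> FeatureTable:
    """Unit-variance scale every column, then weight by intensity ratio to id 1.

    ``weight(id) = mean_s apex_intensity(id, s) / mean_s apex_intensity(1, s)``,
    computed on the *unscaled* intensities before any column is touched.  Each
    of an id's four columns is mean-centred, divided by its standard deviation
    (n-1 denominator) and multiplied by the id's weight, so that afterwards
    ``sd(column) == weight(id)``.  Zero-variance columns become all zeros.
    """
    if table.scaled:
        raise ValueError("table is already scaled")
    if len(table.data) < 2:
        raise ValueError("variance undefined: ratio scaling needs at least 2 samples")
    main_id = table.ids[0]
    main_mean = table.data[f"d{main_id}_apex_intensity"].mean()
    if main_mean <= 0:
        raise ValueError("main distribution has zero mean intensity")
    weights = pd.Series(
        {gid: table.data[f"d{gid}_apex_intensity"].mean() / main_mean for gid in table.ids}
    )
    scaled = table.data.copy()
    for gid in table.ids:
        w = weights[gid]
        for col in table.columns_for(gid):
            x = scaled[col].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                scaled[col] = 0.0
            else:
                scaled[col] = (x - x.mean()) / sd * w
    return FeatureTable(
        data=scaled, ids=list(table.ids), weights=weights, scaled=True, labels=table.labels
    )


def uv_scale(table: FeatureTable) -> FeatureTable:
    """Plain unit-variance scaling (every column gets weight 1) for comparison."""
    if len(table.data) < 2:
        raise ValueError("variance undefined: scaling needs at least 2 samples")
    scaled = table.data.copy()
    for col in scaled.columns:
        x = scaled[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        scaled[col] = 0.0 if sd == 0 else (x - x.mean()) / sd
    weights = pd.Series({gid: 1.0 for gid in table.ids})
    return FeatureTable(
        data=scaled, ids=list(table.ids), weights=weights, scaled=True, labels=table.labels
    )
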