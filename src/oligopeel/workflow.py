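"""End-to-end orchestration: peak lists -> features -> classification.

Thin glue over the per-stage modules so that the CLI, the test-suite and
scripts exercise the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import DistributionCatalog, FeatureTable, build_feature_table, match_across_spectra, ratio_scale
from .chemometrics import CVResult, cross_validate
from .peeling import DistributionRecord, PeelConfig, peel_all
from .preprocess import GridSpectrum, PreprocessConfig, preprocess_replicates
from .simulate import SimDataset
from .spectra_io import RawPeakList


@dataclass
class PipelineResult:
    spectra: dict[str, GridSpectrum]
    records: dict[str, list[DistributionRecord]]
    catalog: DistributionCatalog
    features: FeatureTable  # unscaled
    features_scaled: FeatureTable
    labels: pd.Series | None


def run_pipeline(
    replicates_by_sample: dict[str, list[RawPeakList]],
    pre_cfg: PreprocessConfig | None = None,
    peel_cfg: PeelConfig | None = None,
    labels: pd.Series | dict | None = None,
) -> PipelineResult:
    """Preprocess, peel, match and ratio-scale a whole dataset."""
    pre_cfg = pre_cfg or PreprocessConfig()
    peel_cfg = peel_cfg or PeelConfig()
    spectra: dict[str, GridSpectrum] = {}
    records: dict[str, list[DistributionRecord]] = {}
    for sample_id, raws in replicates_by_sample.items():
        spec = preprocess_replicates(raws, pre_cfg, sample_id=sample_id)
        spectra[sample_id] = spec
        records[sample_id] = peel_all(spec, peel_cfg)
    catalog = match_across_spectra(records, spacing=peel_cfg.spacing)
    features = build_feature_table(catalog, labels=labels)
    scaled = ratio_scale(features)
    return PipelineResult(spectra, records, catalog, features, scaled, features.labels)


def run_pipeline_on_dataset(
    dataset: SimDataset,
    pre_cfg: PreprocessConfig | None = None,
    peel_cfg: PeelConfig | None = None,
) -> PipelineResult:
    """Run the pipeline on an in-memory simulated dataset."""
    if pre_cfg is None:
        pre_cfg = PreprocessConfig(
            mz_range=dataset.design.mz_range,
            matrix_mz=tuple(p for p, _ in dataset.design.matrix_peaks),
        )
    replicates = {
        sid: dataset.replicates_for(sid) for sid in dataset.manifest["sample_id"].unique()
    }
    labels = dataset.manifest.groupby("sample_id", sort=False)["type_label"].first()
    return run_pipeline(replicates, pre_cfg, peel_cfg, labels=labels)


def classify_features(
    result: PipelineResult,
    k: int = 3,
    seed: int = 0,
    n_components: int | str = "auto",
) -> CVResult:
    """Cross-validated PLS classification on the ratio-scaled feature table."""
    if result.labels is None:
        raise ValueError("pipeline was run without class labels")
    return classify_table(result.features_scaled, result.labels, k=k, seed=seed,
                          n_components=n_components)


def classify_table(table: FeatureTable, labels: pd.Series, k: int = 3, seed: int = 0,
                   n_components: int | str = "auto") -> CVResult:
    y = labels.reindex(table.data.index).to_numpy()
    return cross_validate(table.X, y, k=k, seed=seed, n_components=n_components)


def full_spectrum_matrix(result: PipelineResult) -> pd.DataFrame:
    """Samples x bins matrix of the preprocessed grid spectra.

    The "full spectrum" route: every 0.1 Da bin is a variable, with no
    distribution extraction.  Used as the baseline the extracted ratio-scaled
    features are compared against.
    """
    sample_ids = list(result.spectra)
    rows = [result.spectra[sid].intensities for sid in sample_ids]
    cols = result.spectra[sample_ids[0]].mz_grid
    return pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"), columns=cols)


def classify_full_spectrum(result: PipelineResult, k: int = 3, seed: int = 0,
                           n_components: int | str = "auto") -> CVResult:
    """Cross-validated PLS classification on the full binned spectra."""
    if result.labels is None:
        raise ValueError("pipeline was run without class labels")
    X = full_spectrum_matrix(result)
    y = result.labels.reindex(X.index).to_numpy()
    return cross_validate(X.to_numpy(), y, k=k, seed=seed, n_components=n_components)
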