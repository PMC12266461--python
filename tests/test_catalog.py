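"""Cross-spectrum distribution matching, the feature table and ratio-scaling."""

import itertools

import numpy as np
import pytest

from oligopeel.catalog import (
    build_feature_table,
    match_across_spectra,
    ratio_scale,
    uv_scale,
)
from oligopeel.masses import EO_MASS_MONO
from oligopeel.peeling import Comb, DistributionRecord


def record(apex_mz, apex_intensity=1.0, width=100.0, ratio=1.0, rank=1):
    z = np.zeros(1, dtype=int)
    comb = Comb(np.array([apex_mz]), np.array([apex_intensity]),
                np.array([apex_intensity]), z, z.copy(), z.copy(), 0, 0, EO_MASS_MONO)
    return DistributionRecord(apex_mz, apex_intensity, width, ratio, comb, rank,
                              apex_intensity, apex_mz, apex_intensity)


class TestMatching:
    def test_identical_spectra_share_all_ids(self):
        recs = [record(834.0, 1.0), record(1392.0, 0.4)]
        catalog = match_across_spectra({"a": recs, "b": [record(834.0, 1.0), record(1392.0, 0.4)]})
        assert catalog.ids == [1, 2]
        assert set(catalog.entries[1]) == {"a", "b"}
        assert set(catalog.entries[2]) == {"a", "b"}

    def test_two_repeat_unit_shift_still_matches_main_id(self):
        # apex shifted by exactly 2 EO units keeps the comb phase
        shifted = record(834.0 + 2 * EO_MASS_MONO, 1.0)
        catalog = match_across_spectra({"a": [record(834.0, 1.0)], "b": [shifted]})
        assert catalog.ids == [1]
        assert set(catalog.entries[1]) == {"a", "b"}

    def test_distribution_only_in_later_spectrum_opens_next_id(self):
        catalog = match_across_spectra(
            {"a": [record(834.0, 1.0)], "b": [record(834.0, 1.0), record(1392.0, 0.3)]}
        )
        assert catalog.ids == [1, 2]
        assert set(catalog.entries[2]) == {"b"}

    def test_same_mass_region_different_phase_not_matched(self):
        # 10 Da apart: within the shift budget but on a different comb phase
        catalog = match_across_spectra({"a": [record(834.0)], "b": [record(844.0)]})
        assert catalog.ids == [1, 2]

    def test_matching_stable_under_spectrum_permutation(self):
        spectra = {
            "a": [record(834.0, 1.0), record(1392.0, 0.4)],
            "b": [record(834.1, 0.9), record(1391.9, 0.5)],
            "c": [record(833.9, 1.1), record(1392.1, 0.3), record(1171.5, 0.2)],
        }
        def partition(catalog):
            return {
                frozenset((sid, round(r.apex_mz, 1)) for sid, r in recs.items())
                for recs in catalog.entries.values()
            }
        reference = partition(match_across_spectra(spectra))
        for order in itertools.permutations(["b", "c"]):
            perm = {"a": spectra["a"], **{k: spectra[k] for k in order}}
            assert partition(match_across_spectra(perm)) == reference


class TestFeatureTable:
    def test_column_count_is_four_per_id(self):
        catalog = match_across_spectra(
            {"a": [record(834.0), record(1392.0), record(1171.5)],
             "b": [record(834.0), record(1392.0), record(1171.5)]}
        )
        table = build_feature_table(catalog)
        assert table.data.shape == (2, 12)

    def test_absent_id_imputed(self):
        catalog = match_across_spectra(
            {"a": [record(834.0, 1.0), record(1392.0, 0.5, width=80.0)],
             "b": [record(834.0, 1.0)]}
        )
        table = build_feature_table(catalog)
        row = table.data.loc["b"]
        assert row["d2_apex_intensity"] == 0.0
        assert row["d2_ratio_to_main"] == 0.0
        assert row["d2_apex_mz"] == pytest.approx(1392.0)  # across-sample mean
        assert row["d2_width_half_height"] == pytest.approx(80.0)

    def test_single_sample_table_is_verbatim(self):
        catalog = match_across_spectra({"a": [record(834.0, 0.7, width=120.0, ratio=1.0)]})
        table = build_feature_table(catalog)
        assert table.data.loc["a", "d1_apex_mz"] == 834.0
        assert table.data.loc["a", "d1_apex_intensity"] == 0.7
        assert table.data.loc["a", "d1_width_half_height"] == 120.0


class TestRatioScale:
    def make_table(self):
        rng = np.random.default_rng(0)
        spectra = {}
        for s in range(6):
            main = record(834.0 + rng.normal(0, 0.1), 1.0 + rng.normal(0, 0.05))
            minor = record(1392.0 + rng.normal(0, 0.1), 0.5 + rng.normal(0, 0.05),
                           width=90 + rng.normal(0, 5), ratio=0.5, rank=2)
            spectra[f"s{s}"] = [main, minor]
        return build_feature_table(match_across_spectra(spectra))

    def test_main_id_weight_is_exactly_one(self):
        scaled = ratio_scale(self.make_table())
        assert scaled.weights[1] == 1.0

    def test_column_sd_equals_weight_and_mean_zero(self):
        scaled = ratio_scale(self.make_table())
        for gid in scaled.ids:
            w = scaled.weights[gid]
            for col in scaled.columns_for(gid):
                x = scaled.data[col].to_numpy()
                if np.allclose(x, 0):
                    continue  # zero-variance column convention
                assert x.mean() == pytest.approx(0.0, abs=1e-9)
                assert x.std(ddof=1) == pytest.approx(w, rel=1e-9)

    def test_half_intensity_id_gets_half_weight(self):
        scaled = ratio_scale(self.make_table())
        assert scaled.weights[2] == pytest.approx(0.5, rel=0.1)

    def test_constant_column_becomes_zeros(self):
        table = self.make_table()
        col = "d1_ratio_to_main"  # identically 1 for the main distribution
        assert table.data[col].nunique() == 1
        scaled = ratio_scale(table)
        assert (scaled.data[col] == 0).all()

    def test_single_sample_is_an_error(self):
        table = build_feature_table(match_across_spectra({"a": [record(834.0)]}))
        with pytest.raises(ValueError, match="variance"):
            ratio_scale(table)

    def test_weights_invariant_to_global_intensity_rescaling(self):
        table = self.make_table()
        rescaled = table.data.copy()
        for col in rescaled.columns:
            if col.endswith("apex_intensity"):
                rescaled[col] *= 37.0
        from oligopeel.catalog import FeatureTable

        table2 = FeatureTable(data=rescaled, ids=list(table.ids))
        w1 = ratio_scale(table).weights
        w2 = ratio_scale(table2).weights
        np.testing.assert_allclose(w1.to_numpy(), w2.to_numpy(), rtol=1e-12)

    def test_uv_scale_gives_unit_weights(self):
        scaled = uv_scale(self.make_table())
        assert (scaled.weights == 1.0).all()
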