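"""Assay statistics: dilution arithmetic, fingerprint calls, MTT, MIC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tsnap.assays import (
    active_concentrations,
    activity_score,
    dilution_series,
    filter_fingerprint_columns,
    mic_from_curves,
    mtt_viability,
    percent_inhibition,
)
from tsnap.fixtures import FixtureSpec, synth_assay_plates


class TestDilutionSeries:
    def test_biomap_series_terminates_at_3_91_nM(self):
        series = dilution_series(128.0, 16, 2.0)
        assert series.lowest_nM == 3.90625
        assert f"{series.lowest_nM:.2f}" == "3.91"
        assert series.concentrations_uM[0] == 128.0
        assert len(series.concentrations_uM) == 16

    def test_single_point(self):
        series = dilution_series(100.0, 1, 2.0)
        assert list(series.concentrations_uM) == [100.0]

    def test_96uM_series_ends_at_2_93_nM(self):
        # a 16-point two-fold series from 96 uM cannot reach 1.5 nM;
        # the geometric arithmetic puts the endpoint at 2.93 nM
        series = dilution_series(96.0, 16, 2.0)
        assert series.lowest_nM == pytest.approx(2.9296875)

    def test_exact_geometric_law(self):
        series = dilution_series(50.0, 8, 3.0)
        for k, c in enumerate(series.concentrations_uM):
            assert c == pytest.approx(50.0 / 3.0 ** k)

    @pytest.mark.parametrize("kwargs", [
        dict(start_uM=0.0, n_points=4, factor=2.0),
        dict(start_uM=10.0, n_points=0, factor=2.0),
        dict(start_uM=10.0, n_points=4, factor=1.0),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            dilution_series(**kwargs)


class TestFingerprintFilter:
    def make_table(self, rng, n_wells=5, n_feat=4, conc=1.0):
        data = {f"f{j}": rng.normal(0, 1, n_wells) for j in range(n_feat)}
        data["concentration_uM"] = conc
        return pd.DataFrame(data)

    def test_constant_column_never_removed(self):
        rng = np.random.default_rng(0)
        table = self.make_table(rng)
        table["f0"] = 3.3
        out = filter_fingerprint_columns(table)
        assert out["f0"].notna().all()

    def test_planted_outlier_column_removed(self):
        # a single outlier inflates its own column SD, so it is only
        # detectable with enough outlier-free wells (> 10)
        rng = np.random.default_rng(1)
        table = self.make_table(rng, n_wells=12)
        table.loc[2, "f1"] += 50.0
        out = filter_fingerprint_columns(table)
        assert out["f1"].isna().all()
        for col in ("f0", "f2", "f3"):
            assert out[col].notna().all()

    def test_exactly_flagged_columns_removed_vs_direct_scan(self):
        rng = np.random.default_rng(2)
        table = self.make_table(rng, n_wells=5, n_feat=6)
        table.loc[0, "f4"] += 40.0
        out = filter_fingerprint_columns(table)
        # independent per-column scan of the stated rule
        for col in [c for c in table.columns if c.startswith("f")]:
            vals = table[col]
            flag = (vals > vals.median() + 3 * vals.std(ddof=1)).any()
            assert out[col].isna().all() == flag

    def test_single_well_concentration_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        table = pd.concat([self.make_table(rng, conc=1.0),
                           self.make_table(rng, n_wells=1, conc=2.0)], ignore_index=True)
        table.loc[table.concentration_uM == 2.0, "f0"] = 1e6
        with pytest.warns(UserWarning, match="single well"):
            out = filter_fingerprint_columns(table)
        assert out.loc[out.concentration_uM == 2.0, "f0"].notna().all()

    def test_removal_is_per_concentration_slice(self):
        rng = np.random.default_rng(4)
        t1 = self.make_table(rng, n_wells=12, conc=1.0)
        t2 = self.make_table(rng, n_wells=12, conc=10.0)
        t2.loc[t2.index[0], "f0"] += 50.0
        out = filter_fingerprint_columns(pd.concat([t1, t2], ignore_index=True))
        assert out.loc[out.concentration_uM == 1.0, "f0"].notna().all()
        assert out.loc[out.concentration_uM == 10.0, "f0"].isna().all()


class TestActivityScore:
    def test_null_profile(self):
        assert activity_score(np.zeros(10)) == 0.0

    def test_euclidean_norm(self):
        assert activity_score(np.array([3.0, 4.0])) == pytest.approx(5.0)

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_positive_homogeneity(self, c):
        row = np.array([1.0, -2.0, 0.5, 3.0])
        assert activity_score(c * row) == pytest.approx(c * activity_score(row))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        row = rng.normal(0, 1, 12)
        assert activity_score(row) == pytest.approx(activity_score(row[::-1]))

    def test_nan_features_ignored(self):
        assert activity_score(np.array([3.0, np.nan, 4.0])) == pytest.approx(5.0)


class TestActiveConcentrations:
    def test_threshold_arithmetic(self):
        result = active_concentrations({10.0: 6.0, 1.0: 4.0}, np.array([1.0, 1.0]))
        assert result == 10.0

    def test_none_when_nothing_clears_threshold(self):
        assert active_concentrations({10.0: 4.9}, np.array([1.0])) is None

    def test_zero_negatives_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            result = active_concentrations({1.0: 0.1}, np.array([0.0, 0.0]))
        assert result == 1.0

    def test_median_mode(self):
        negatives = np.array([1.0, 1.0, 10.0])  # mean 4, median 1
        scores = {5.0: 6.0}
        assert active_concentrations(scores, negatives, center="mean") is None
        assert active_concentrations(scores, negatives, center="median") == 5.0

    def test_empty_negatives_error(self):
        with pytest.raises(ValueError):
            active_concentrations({1.0: 2.0}, np.array([]))


class TestMttViability:
    def test_treatment_at_dmso_level_is_100(self):
        assert mtt_viability(0.9, np.array([0.1]), np.array([0.9])) == pytest.approx(100.0)

    def test_treatment_at_background_is_0(self):
        assert mtt_viability(0.1, np.array([0.1]), np.array([0.9])) == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        # 100 * (0.7 - 0.1) / (0.9 - 0.1) = 75
        assert mtt_viability(0.7, np.array([0.1]), np.array([0.9])) == pytest.approx(75.0)

    def test_empty_controls_error(self):
        with pytest.raises(ValueError):
            mtt_viability(0.5, np.array([]), np.array([0.9]))


def growth_frame(concentrations, inhibited_mask, vehicle_growth=0.5):
    rows = [dict(role="vehicle", concentration_uM=0.0, od600_t0=0.05,
                 od600_t20=0.05 + vehicle_growth),
            dict(role="blank", concentration_uM=0.0, od600_t0=0.04, od600_t20=0.04)]
    for conc, dead in zip(concentrations, inhibited_mask):
        growth = 0.0 if dead else vehicle_growth
        rows.append(dict(role="treatment", concentration_uM=conc,
                         od600_t0=0.05, od600_t20=0.05 + growth))
    return pd.DataFrame(rows)


class TestMic:
    concs = dilution_series(128.0, 8, 2.0).concentrations_uM

    def test_complete_kill_gives_lowest_tested(self):
        frame = growth_frame(self.concs, [True] * 8)
        result = mic_from_curves(frame)
        assert result.value_uM == pytest.approx(self.concs[-1])
        assert not result.censored

    def test_no_inhibition_censored(self):
        frame = growth_frame(self.concs, [False] * 8)
        result = mic_from_curves(frame)
        assert result.censored
        assert str(result) == ">128 uM"

    @pytest.mark.parametrize("step", [0, 3, 7])
    def test_planted_cutover_recovered(self, step):
        mask = [k <= step for k in range(8)]
        result = mic_from_curves(growth_frame(self.concs, mask))
        assert result.value_uM == pytest.approx(self.concs[step])

    def test_non_monotone_inhibition_not_called_below_gap(self):
        # inhibition at high concs, a gap, then an isolated low-conc dip:
        # the isolated dip must not set the MIC
        mask = [True, True, False, True, False, False, False, False]
        result = mic_from_curves(growth_frame(self.concs, mask))
        assert result.value_uM == pytest.approx(self.concs[1])

    def test_no_vehicle_error(self):
        frame = growth_frame(self.concs, [True] * 8)
        with pytest.raises(ValueError, match="vehicle"):
            mic_from_curves(frame[frame.role != "vehicle"])


class TestPercentInhibition:
    @pytest.mark.parametrize("treated,expected", [(0.1, 100.0), (0.5, 0.0), (0.3, 50.0)])
    def test_linear_interpolation(self, treated, expected):
        assert percent_inhibition(treated, 0.5, 0.1) == pytest.approx(expected)

    def test_growth_promotion_reported_negative(self):
        assert percent_inhibition(0.9, 0.5, 0.1) == pytest.approx(-100.0)

    def test_below_blank_clamped_to_100(self):
        assert percent_inhibition(0.05, 0.5, 0.1) == 100.0

    def test_degenerate_vehicle_error(self):
        with pytest.raises(ValueError):
            percent_inhibition(0.3, 0.1, 0.1)


class TestScaleInvariance:
    def test_activity_calls_invariant_under_table_rescaling(self):
        spec = FixtureSpec(seed=9, n_assay_compounds=2, n_features=10)
        plates = synth_assay_plates(spec)
        fp = plates["fingerprints"]
        feat = [c for c in fp.columns if c.startswith("f")]

        def calls(table):
            filtered = filter_fingerprint_columns(
                table[~table.is_negative_control][feat + ["concentration_uM"]])
            neg = table[table.is_negative_control][feat].apply(activity_score, axis=1).values
            out = {}
            for cpd in table.compound.unique():
                if cpd == "DMSO":
                    continue
                sub = table[table.compound == cpd]
                scores = {
                    conc: filtered.loc[g.index, feat].apply(activity_score, axis=1).mean()
                    for conc, g in sub.groupby("concentration_uM")
                }
                out[cpd] = active_concentrations(scores, neg)
            return out

        scaled = fp.copy()
        scaled[feat] = scaled[feat] * 7.0
        assert calls(fp) == calls(scaled)
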