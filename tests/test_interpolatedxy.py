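import numpy as np
import pandas as pd
import pytest

from methylnorm import (
    adjusted_normalize,
    build_quantile_function,
    dasen,
    estimate_ranks,
    interpolate_sex_values,
)
from methylnorm.normalize_core import NormalizationError

from conftest import make_annotation, make_intensities, make_sheet


class TestEstimateRanks:
    def test_exact_coincidence_gets_integer_rank(self):
        est = estimate_ranks([10.0, 20.0, 30.0], [20.0])
        assert est.fractional_rank[0] == 2.0
        assert not est.clamped_low[0] and not est.clamped_high[0]

    def test_midway_value_gets_fractional_rank(self):
        est = estimate_ranks([10.0, 20.0, 30.0], [15.0])
        assert est.fractional_rank[0] == pytest.approx(1.5)

    def test_below_minimum_clamps_to_rank_one(self):
        est = estimate_ranks([10.0, 20.0, 30.0], [5.0])
        assert est.fractional_rank[0] == 1.0
        assert est.clamped_low[0]

    def test_above_maximum_clamps_to_rank_k(self):
        est = estimate_ranks([10.0, 20.0, 30.0], [99.0])
        assert est.fractional_rank[0] == 3.0
        assert est.clamped_high[0]

    def test_ties_share_average_rank(self):
        est = estimate_ranks([10.0, 20.0, 20.0, 30.0], [20.0])
        assert est.fractional_rank[0] == pytest.approx(2.5)

    def test_missing_query_yields_missing_rank(self):
        est = estimate_ranks([10.0, 20.0], [np.nan, 15.0])
        assert np.isnan(est.fractional_rank[0])
        assert np.isfinite(est.fractional_rank[1])

    def test_rank_monotone_in_query(self, rng):
        auto = rng.normal(0, 1, 50)
        q = np.sort(rng.normal(0, 1.5, 30))
        fr = estimate_ranks(auto, q).fractional_rank
        assert np.all(np.diff(fr) >= 0)


class TestQuantileFunction:
    def test_midpoint(self):
        f = build_quantile_function([100.0, 200.0])
        assert f(1.5) == pytest.approx(150.0)

    def test_endpoints_exact(self):
        f = build_quantile_function([200.0, 100.0])
        assert f(1.0) == 100.0
        assert f(2.0) == 200.0

    def test_piecewise_interpolation(self):
        f = build_quantile_function([0.0, 10.0, 40.0])
        assert f(2.25) == pytest.approx(17.5)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(NormalizationError):
            build_quantile_function([5.0])


class TestInterpolateSexValues:
    def test_coincident_raw_value_reproduces_corrected_value(self, rng):
        raw = rng.permutation(np.arange(20, dtype=float))
        corrected = np.sort(rng.normal(100, 10, 20))[np.argsort(np.argsort(raw))]
        out = interpolate_sex_values(raw, corrected, raw[[3, 7]])
        np.testing.assert_array_equal(out, corrected[[3, 7]])

    def test_hand_oracle_midpoint(self):
        out = interpolate_sex_values([10.0, 20.0], [100.0, 200.0], [15.0])
        np.testing.assert_allclose(out, [150.0])

    def test_clamping_to_extreme_corrected_values(self):
        out = interpolate_sex_values([10.0, 20.0], [100.0, 200.0], [5.0, 99.0])
        np.testing.assert_allclose(out, [100.0, 200.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(NormalizationError):
            interpolate_sex_values([1.0, 2.0], [1.0], [1.5])

    def test_monotonicity_and_range_containment(self, rng):
        for _ in range(100):
            k = rng.integers(5, 60)
            raw = rng.normal(0, 1, k)
            corrected = np.sort(rng.normal(50, 5, k))[np.argsort(np.argsort(raw))]
            q = rng.normal(0, 2, 12)
            out = interpolate_sex_values(raw, corrected, q)
            order = np.argsort(q)
            assert np.all(np.diff(out[order]) >= 0), "monotone in the query value"
            assert out.min() >= corrected.min() and out.max() <= corrected.max()


@pytest.fixture(scope="module")
def adjusted_setup():
    from methylnorm import SimConfig, simulate_dataset
    cfg = SimConfig(n_female=4, n_male=4, n_auto=3000, n_x=90, n_y=20, seed=7)
    d = simulate_dataset(cfg)
    res = adjusted_normalize(d.intensities, d.annotation, stratum_floor=500)
    return d, res


class TestAdjustedNormalize:
    def test_autosomal_output_matches_step_one_exactly(self, adjusted_setup):
        d, res = adjusted_setup
        step_one = dasen(d.intensities, d.annotation, probe_scope="autosomes_only")
        auto_ids = step_one.corrected.probe_index
        assert (res.corrected.meth.loc[auto_ids].to_numpy()
                == step_one.corrected.meth.to_numpy()).all()
        assert (res.beta.values_frame.loc[auto_ids].to_numpy()
                == step_one.beta.values_frame.to_numpy()).all()

    def test_interpolated_probes_are_exactly_the_sex_probes(self, adjusted_setup):
        d, res = adjusted_setup
        sex_ids = set(d.intensities.probe_index[~d.annotation.is_autosomal()])
        assert set(res.interpolated_probes) == sex_ids

    def test_sex_annotation_never_consulted(self, adjusted_setup):
        d, _ = adjusted_setup
        flipped = d.sheet.table.copy()
        flipped["sex"] = np.where(flipped["sex"] == "female", "male", "female")
        from methylnorm import SampleSheet
        res1 = adjusted_normalize(d.intensities, d.annotation, stratum_floor=500,
                                  sample_sheet=d.sheet)
        res2 = adjusted_normalize(d.intensities, d.annotation, stratum_floor=500,
                                  sample_sheet=SampleSheet(flipped))
        assert (res1.beta.values_frame.to_numpy() == res2.beta.values_frame.to_numpy()).all()

    def test_autosome_invariance_vs_mixed_contrast(self, adjusted_setup, rng):
        """Sex-probe values cannot leak into autosomal corrections under the
        two-step method, but do under mixed pooling (the bias mechanism)."""
        d, _ = adjusted_setup
        meth2 = d.intensities.meth.copy()
        unmeth2 = d.intensities.unmeth.copy()
        sex_ids = d.intensities.probe_index[~d.annotation.is_autosomal()]
        meth2.loc[sex_ids] = rng.uniform(0, 30000, size=(len(sex_ids), meth2.shape[1]))
        unmeth2.loc[sex_ids] = rng.uniform(0, 30000, size=(len(sex_ids), meth2.shape[1]))
        from methylnorm import IntensityMatrix
        perturbed = IntensityMatrix(meth2, unmeth2)
        auto_ids = d.intensities.probe_index[d.annotation.is_autosomal()]

        a1 = adjusted_normalize(d.intensities, d.annotation, stratum_floor=500)
        a2 = adjusted_normalize(perturbed, d.annotation, stratum_floor=500)
        diff_adj = np.abs(a1.beta.values_frame.loc[auto_ids].to_numpy()
                          - a2.beta.values_frame.loc[auto_ids].to_numpy())
        assert diff_adj.max() == 0.0

        m1 = dasen(d.intensities, d.annotation, probe_scope="all")
        m2 = dasen(perturbed, d.annotation, probe_scope="all")
        diff_mixed = np.abs(m1.beta.values_frame.loc[auto_ids].to_numpy()
                            - m2.beta.values_frame.loc[auto_ids].to_numpy())
        assert diff_mixed.max() > 0.0

    def test_corrected_sex_values_within_autosomal_range_per_stratum(self, adjusted_setup):
        d, res = adjusted_setup
        ann = d.annotation
        for dt in ("I", "II"):
            sel_auto = ann.is_autosomal() & (ann.design_type() == dt)
            sel_sex = (~ann.is_autosomal()) & (ann.design_type() == dt)
            for frame in (res.corrected.meth, res.corrected.unmeth):
                auto_vals = frame.loc[sel_auto[sel_auto].index]
                sex_vals = frame.loc[sel_sex[sel_sex].index]
                assert (sex_vals.min() >= auto_vals.min() - 1e-12).all()
                assert (sex_vals.max() <= auto_vals.max() + 1e-12).all()

    def test_full_pipeline_coincidence_oracle(self, rng):
        """Sex probes whose raw M and U duplicate autosomal probes must come
        out with exactly those autosomal corrected betas."""
        n_auto = 1200
        meth_auto = rng.uniform(100, 10000, size=(n_auto, 3))
        unmeth_auto = rng.uniform(100, 10000, size=(n_auto, 3))
        twins = rng.choice(n_auto, size=40, replace=False)
        meth = np.vstack([meth_auto, meth_auto[twins]])
        unmeth = np.vstack([unmeth_auto, unmeth_auto[twins]])
        ids = [f"a{i}" for i in range(n_auto)] + [f"x{i}" for i in range(40)]
        x = make_intensities(meth, unmeth, probe_ids=ids)
        ann = make_annotation(n_auto, n_x=40)
        res = adjusted_normalize(x, ann, normalizer_id="quantile", stratum_floor=100)
        beta = res.beta.values_frame
        twin_auto = beta.loc[[f"a{i}" for i in twins]].to_numpy()
        twin_sex = beta.loc[[f"x{i}" for i in range(40)]].to_numpy()
        np.testing.assert_array_equal(twin_sex, twin_auto)

    def test_beta_space_fallback_interpolates_sex_rows(self, rng):
        """The non-canonical beta-space mode: autosomal rows pass through the
        supplied corrected betas; sex rows are rank-interpolated against them."""
        from methylnorm.interpolatedxy import interpolate_sex_betas
        n_auto, n_x = 200, 10
        ids = [f"a{i}" for i in range(n_auto)] + [f"x{i}" for i in range(n_x)]
        raw = pd.DataFrame(rng.uniform(0.01, 0.99, (n_auto + n_x, 3)), index=ids,
                           columns=["s1", "s2", "s3"])
        corrected_auto = raw.iloc[:n_auto] * 0.9 + 0.05
        ann = make_annotation(n_auto, n_x=n_x)
        out = interpolate_sex_betas(raw, ann, corrected_auto)
        pd.testing.assert_frame_equal(out.iloc[:n_auto], corrected_auto)
        sex_out = out.iloc[n_auto:]
        assert ((sex_out >= corrected_auto.min().min())
                & (sex_out <= corrected_auto.max().max())).all().all()

    def test_stratum_floor_enforced(self, rng):
        x = make_intensities(rng.uniform(1, 100, (60, 3)), rng.uniform(1, 100, (60, 3)),
                             probe_ids=[f"a{i}" for i in range(50)] + [f"x{i}" for i in range(10)])
        ann = make_annotation(50, n_x=10)
        with pytest.raises(NormalizationError, match="stratum floor"):
            adjusted_normalize(x, ann, stratum_floor=1000)

    def test_plugin_normalizer_seam(self, rng):
        """Any per-stratum matrix->matrix callable can serve as step one."""
        n_auto, n_x = 300, 12
        ids = [f"a{i}" for i in range(n_auto)] + [f"x{i}" for i in range(n_x)]
        x = make_intensities(rng.uniform(10, 1000, (n_auto + n_x, 3)),
                             rng.uniform(10, 1000, (n_auto + n_x, 3)), probe_ids=ids)
        ann = make_annotation(n_auto, n_x=n_x)

        def halve(matrix, design_type):
            return matrix / 2.0

        res = adjusted_normalize(x, ann, normalizer_id="plugin", plugin=halve,
                                 stratum_floor=100)
        auto_ids = [f"a{i}" for i in range(n_auto)]
        np.testing.assert_allclose(res.corrected.meth.loc[auto_ids].to_numpy(),
                                   x.meth.loc[auto_ids].to_numpy() / 2.0)
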