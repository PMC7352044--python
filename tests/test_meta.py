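"""Effect sizes and fixed/random-effects pooling against hand and formula oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coimeta.errors import (
    DegenerateGroupError,
    MissingGeneError,
    ParameterError,
    VarianceFloorWarning,
)
from coimeta.meta import (
    VARIANCE_FLOOR,
    collapse_duplicate_genes,
    compute_study_effect,
    pool_auto,
    pool_fixed,
    pool_random,
    run_mega,
)
from coimeta.synthetic import ExpressionStudy
from conftest import make_effects, six_studies


def dl_tau2_oracle(ys, vs):
    """Independent single-pass DerSimonian-Laird tau^2."""
    w = [1.0 / v for v in vs]
    sw = sum(w)
    pooled = sum(wi * yi for wi, yi in zip(w, ys)) / sw
    q = sum(wi * (yi - pooled) ** 2 for wi, yi in zip(w, ys))
    c = sw - sum(wi * wi for wi in w) / sw
    return max(0.0, (q - (len(ys) - 1)) / c)


def make_study(case, ctrl, study_id="s1", genes=None):
    case = np.atleast_2d(np.asarray(case, dtype=float))
    ctrl = np.atleast_2d(np.asarray(ctrl, dtype=float))
    genes = genes or [f"g{i}" for i in range(case.shape[0])]
    cols = [f"c{i}" for i in range(ctrl.shape[1])] + [f"t{i}" for i in range(case.shape[1])]
    matrix = pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=cols)
    groups = pd.Series(["control"] * ctrl.shape[1] + ["case"] * case.shape[1], index=cols)
    return ExpressionStudy(study_id=study_id, matrix=matrix, groups=groups)


class TestStudyEffect:
    def test_identical_groups_zero_lfc(self):
        study = make_study([[5.0, 6.0, 7.0]], [[5.0, 6.0, 7.0]])
        e = compute_study_effect(study, "g0")
        assert e.lfc == 0.0

    def test_pure_shift_hits_variance_floor(self):
        study = make_study([[6.0, 6.0, 6.0]], [[5.0, 5.0, 5.0]])
        with pytest.warns(VarianceFloorWarning):
            e = compute_study_effect(study, "g0")
        assert e.lfc == pytest.approx(1.0)
        assert e.variance == VARIANCE_FLOOR
        assert e.floored

    def test_matches_two_pass_oracle(self, rng):
        case = rng.normal(8, 1, size=(4, 7))
        ctrl = rng.normal(8, 1, size=(4, 5))
        study = make_study(case, ctrl)
        for i in range(4):
            e = compute_study_effect(study, f"g{i}")
            mc = sum(case[i]) / 7
            mk = sum(ctrl[i]) / 5
            vc = sum((x - mc) ** 2 for x in case[i]) / 6
            vk = sum((x - mk) ** 2 for x in ctrl[i]) / 4
            assert e.lfc == pytest.approx(mc - mk, abs=1e-10)
            assert e.variance == pytest.approx(vc / 7 + vk / 5, abs=1e-10)

    def test_missing_gene_signals(self):
        study = make_study([[1.0, 2.0]], [[1.0, 2.0]])
        with pytest.raises(MissingGeneError):
            compute_study_effect(study, "absent")

    def test_small_group_rejected(self):
        cols = ["c0", "t0", "t1"]
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"], columns=cols)
        groups = pd.Series(["control", "case", "case"], index=cols)
        study = ExpressionStudy(study_id="s", matrix=matrix, groups=groups)
        with pytest.raises(DegenerateGroupError):
            compute_study_effect(study, "g0")

    def test_duplicate_probes_collapse_to_brightest(self):
        matrix = pd.DataFrame(
            [[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]],
            index=["gA", "gA", "gB"],
            columns=["c0", "c1"],
        )
        out = collapse_duplicate_genes(matrix)
        assert out.loc["gA"].tolist() == [5.0, 5.0]
        assert len(out) == 2


class TestPoolFixed:
    def test_single_study(self):
        (e,) = make_effects([1.7], [0.25])
        r = pool_fixed([e])
        assert r.pooled_lfc == 1.7
        assert r.se == pytest.approx(0.5)
        assert r.weights == {"s1": 1.0}

    def test_hand_computed_two_studies(self):
        """y=[1,3], v=[1,1]: pooled 2.0, se sqrt(1/2), equal weights, Q=2."""
        r = pool_fixed(make_effects([1, 3], [1, 1]))
        assert r.pooled_lfc == pytest.approx(2.0, abs=1e-10)
        assert r.se == pytest.approx(np.sqrt(0.5), abs=1e-10)
        assert r.weights["s1"] == pytest.approx(0.5)
        assert r.weights["s2"] == pytest.approx(0.5)
        assert r.Q == pytest.approx(2.0, abs=1e-10)
        assert r.tau2 == 0.0

    def test_homogeneous_effects(self):
        r = pool_fixed(make_effects([0.7, 0.7, 0.7], [0.1, 0.5, 2.0]))
        assert r.pooled_lfc == pytest.approx(0.7)
        assert r.Q == pytest.approx(0.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            pool_fixed([])

    @given(
        ys=st.lists(st.floats(-5, 5), min_size=2, max_size=8),
        data=st.data(),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_invariants(self, ys, data):
        vs = data.draw(
            st.lists(st.floats(0.01, 10), min_size=len(ys), max_size=len(ys))
        )
        r = pool_fixed(make_effects(ys, vs))
        assert min(ys) - 1e-9 <= r.pooled_lfc <= max(ys) + 1e-9
        assert sum(r.weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0 < w < 1 for w in r.weights.values())


class TestPoolRandom:
    def test_hand_computed_dl(self):
        """y=[0,2], v=[1,1]: Q=2, C=1, tau2=1, pooled=1, se=1."""
        r = pool_random(make_effects([0, 2], [1, 1]))
        assert r.Q == pytest.approx(2.0, abs=1e-12)
        assert r.tau2 == pytest.approx(1.0, abs=1e-12)
        assert r.pooled_lfc == pytest.approx(1.0, abs=1e-12)
        assert r.se == pytest.approx(1.0, abs=1e-12)
        assert r.model_used == "random"

    def test_truncation_boundary_equals_fixed(self):
        effects = make_effects([1.0, 1.01, 0.99], [1, 1, 1])  # Q << k-1
        rr = pool_random(effects)
        rf = pool_fixed(effects)
        assert rr.tau2 == 0.0
        assert rr.pooled_lfc == rf.pooled_lfc
        assert rr.se == rf.se
        assert rr.weights == rf.weights

    def test_single_study_rejected(self):
        with pytest.raises(ParameterError):
            pool_random(make_effects([1.0], [1.0]))

    @given(
        ys=st.lists(st.floats(-5, 5), min_size=2, max_size=8),
        data=st.data(),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_dl_matches_oracle_and_se_dominates_fixed(self, ys, data):
        vs = data.draw(
            st.lists(st.floats(0.01, 10), min_size=len(ys), max_size=len(ys))
        )
        effects = make_effects(ys, vs)
        r = pool_random(effects)
        assert r.tau2 == pytest.approx(dl_tau2_oracle(ys, vs), abs=1e-10, rel=1e-10)
        assert r.se >= pool_fixed(effects).se - 1e-12
        assert sum(r.weights.values()) == pytest.approx(1.0, abs=1e-12)


class TestPoolAuto:
    def test_homogeneous_selects_fixed(self):
        r = pool_auto(make_effects([0.5, 0.5, 0.5], [1, 1, 1]))
        assert r.model_used == "fixed"

    def test_single_study_forced_fixed_with_warning(self):
        with pytest.warns(UserWarning, match="single study"):
            r = pool_auto(make_effects([1.0], [0.5]))
        assert r.model_used == "fixed"
        assert r.k == 1

    def test_planted_heterogeneity_selects_random(self):
        """tau=1 across 6 large studies -> random model in >=90% of 100 replicates."""
        from coimeta.synthetic import ExpressionStudySpec, simulate_expression_studies

        picks = 0
        for rep in range(100):
            specs = [
                ExpressionStudySpec(
                    study_id=f"s{i}",
                    n_case=20,
                    n_control=20,
                    genes=("g",),
                    planted_lfc={"g": 1.0},
                    tau=1.0,
                    noise_sd=0.5,
                    seed=rep * 10 + i,
                )
                for i in range(6)
            ]
            studies = simulate_expression_studies(specs)
            effects = [compute_study_effect(s, "g") for s in studies]
            picks += pool_auto(effects).model_used == "random"
        assert picks >= 90


class TestRunMega:
    def test_k_varies_with_gene_coverage(self):
        """A gene measured in only 4 of 6 studies pools with k=4."""
        full = tuple(f"GENE{i:02d}" for i in range(3))
        reduced = full[:2]  # GENE02 missing from two studies
        from coimeta.synthetic import ExpressionStudySpec, simulate_expression_studies

        specs = [
            ExpressionStudySpec(
                study_id=f"s{i}",
                n_case=5,
                n_control=5,
                genes=full if i < 4 else reduced,
                seed=i,
            )
            for i in range(6)
        ]
        studies = simulate_expression_studies(specs)
        meta, effects = run_mega(studies, full)
        assert meta.set_index("gene").loc["GENE02", "k"] == 4
        assert meta.set_index("gene").loc["GENE00", "k"] == 6

    def test_absent_gene_reported_null(self, studies):
        meta, _ = run_mega(studies, ["GENE00", "NOWHERE"])
        row = meta.set_index("gene").loc["NOWHERE"]
        assert row["k"] == 0
        assert np.isnan(row["pooled_lfc"]) and np.isnan(row["p_value"])

    def test_study_order_invariance(self, studies):
        meta_a, eff_a = run_mega(studies, ["GENE00", "GENE01", "GENE02"])
        meta_b, eff_b = run_mega(studies[::-1], ["GENE00", "GENE01", "GENE02"])
        pd.testing.assert_frame_equal(meta_a, meta_b)
        pd.testing.assert_frame_equal(eff_a, eff_b)

    def test_weights_recorded_per_study(self, studies):
        meta, effects = run_mega(studies, ["GENE00"])
        w = effects[effects["gene"] == "GENE00"]["weight"]
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert ((w > 0) & (w < 1)).all()

    def test_bh_column_is_supplementary_and_monotone(self, studies):
        meta, _ = run_mega(studies, [f"GENE{i:02d}" for i in range(10)])
        ok = meta["p_bh"].notna()
        assert (meta.loc[ok, "p_bh"] >= meta.loc[ok, "p_value"] - 1e-12).all()
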