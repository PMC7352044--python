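"""Three-part significance screen and study-level moderator regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coimeta.errors import DataError, DegenerateDesignWarning, ParameterError
from coimeta.screening import (
    SignificanceCriteria,
    apply_criteria,
    moderator_regression,
)
from test_coincidence import normal_equations_oracle

# the five published candidate-gene rows (model flag, #studies, pooled LFC, p)
FIVE_GENE_TABLE = pd.DataFrame(
    {
        "gene": ["HTRA3", "HOPX", "PCNA", "PPARG", "EFEMP1"],
        "model_used": [0, 1, 0, 0, 0],
        "k": [4, 4, 6, 4, 5],
        "pooled_lfc": [1.00, 0.82, 0.79, -1.24, -2.14],
        "p_value": [3.86e-2, 1.77e-2, 4.50e-8, 4.96e-3, 8.44e-13],
    }
)


def moderator_table(k, regions=None, seed=0):
    rng = np.random.default_rng(seed)
    regions = regions or (["USA"] * (k // 2) + ["Japan"] * (k - k // 2))
    return pd.DataFrame(
        {
            "study_id": [f"s{i + 1}" for i in range(k)],
            "sample_size": rng.integers(8, 40, size=k),
            "region": regions,
            "study_date": rng.integers(2003, 2018, size=k),
        }
    )


class TestApplyCriteria:
    def test_five_gene_replica(self):
        """The published candidate rows split into 3 up-, 2 down-regulated."""
        up, down, rejected = apply_criteria(FIVE_GENE_TABLE)
        assert set(up["gene"]) == {"HTRA3", "HOPX", "PCNA"}
        assert set(down["gene"]) == {"PPARG", "EFEMP1"}
        assert len(rejected) == 0

    @pytest.mark.parametrize(
        "k,p,lfc,reason",
        [
            (2, 0.001, 2.0, "study_count"),
            (6, 0.20, 2.0, "p_value"),
            (6, 0.001, -0.8, "lfc_magnitude"),  # -1 < -0.8: fails asymmetric lower bound
            (6, 0.001, 0.59, "lfc_magnitude"),  # boundary not strict-greater
            (0, np.nan, np.nan, "study_count"),  # gene measured nowhere
        ],
    )
    def test_rejection_reasons(self, k, p, lfc, reason):
        df = pd.DataFrame({"gene": ["g"], "k": [k], "pooled_lfc": [lfc], "p_value": [p]})
        up, down, rejected = apply_criteria(df)
        assert len(up) == 0 and len(down) == 0
        assert rejected["reason"].iloc[0] == reason

    def test_asymmetric_band_admits_moderate_up_only(self):
        df = pd.DataFrame(
            {"gene": ["u", "d"], "k": [6, 6], "pooled_lfc": [0.8, -0.8],
             "p_value": [1e-4, 1e-4]}
        )
        up, down, rejected = apply_criteria(df)
        assert list(up["gene"]) == ["u"]
        assert list(rejected["gene"]) == ["d"]

    @given(data=st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_partition_complete_and_monotone(self, data):
        n = data.draw(st.integers(1, 30))
        df = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "k": data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n)),
                "pooled_lfc": data.draw(
                    st.lists(st.floats(-4, 4), min_size=n, max_size=n)
                ),
                "p_value": data.draw(
                    st.lists(st.floats(1e-12, 1.0), min_size=n, max_size=n)
                ),
            }
        )
        loose = SignificanceCriteria()
        up, down, rejected = apply_criteria(df, loose)
        assert len(up) + len(down) + len(rejected) == n
        assert sorted(
            list(up["gene"]) + list(down["gene"]) + list(rejected["gene"])
        ) == sorted(df["gene"])
        # tightening any single criterion never grows the significant sets
        for tight in (
            SignificanceCriteria(min_studies=4),
            SignificanceCriteria(alpha=0.01),
            SignificanceCriteria(lfc_upper=1.0),
            SignificanceCriteria(lfc_lower=-2.0),
        ):
            u2, d2, _ = apply_criteria(df, tight)
            assert set(u2["gene"]) <= set(up["gene"])
            assert set(d2["gene"]) <= set(down["gene"])

    def test_idempotent_on_accepted_genes(self):
        up, down, _ = apply_criteria(FIVE_GENE_TABLE)
        up2, _, rej2 = apply_criteria(up)
        assert len(up2) == len(up) and len(rej2) == 0

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ParameterError):
            SignificanceCriteria(alpha=1.5)
        with pytest.raises(ParameterError):
            SignificanceCriteria(lfc_lower=0.1)

    def test_missing_columns_rejected(self):
        with pytest.raises(DataError, match="missing"):
            apply_criteria(pd.DataFrame({"gene": ["g"]}))


class TestModeratorRegression:
    def make_effects(self, k, lfc, seed=0):
        return pd.DataFrame(
            {"gene": ["g"] * k, "study_id": [f"s{i + 1}" for i in range(k)], "lfc": lfc}
        )

    def test_noiseless_recovery_in_sample_size(self):
        mods = moderator_table(12, seed=1)
        lfc = 0.05 * mods["sample_size"].to_numpy(dtype=float) + 0.3
        fit = moderator_regression(self.make_effects(12, lfc), mods)
        assert not fit.degenerate
        t = fit.result.table
        assert t.loc["sample_size", "beta"] == pytest.approx(0.05, abs=1e-8)
        assert t.loc["sample_size", "p_value"] < 1e-10
        assert t.loc["study_date", "p_value"] > 0.05

    def test_saturated_design_flagged_not_fatal(self):
        mods = moderator_table(4, regions=["USA", "USA", "Japan", "Japan"])
        with pytest.warns(DegenerateDesignWarning):
            fit = moderator_regression(self.make_effects(4, [0.1, 0.2, 0.3, 0.4]), mods)
        assert fit.degenerate
        assert fit.result is None

    def test_matches_normal_equations_oracle(self, rng):
        mods = moderator_table(15, seed=2)
        lfc = rng.normal(size=15)
        fit = moderator_regression(self.make_effects(15, lfc), mods)
        region = pd.Categorical(mods["region"], categories=sorted(mods["region"].unique()))
        dummies = pd.get_dummies(region, drop_first=True, dtype=float)
        X = np.column_stack(
            [mods["sample_size"].astype(float), dummies.to_numpy(), mods["study_date"].astype(float)]
        )
        beta, lo, hi, pv = normal_equations_oracle(lfc, X)
        assert fit.result.table["beta"].to_numpy() == pytest.approx(beta, abs=1e-8)
        assert fit.result.table["p_value"].to_numpy() == pytest.approx(pv, abs=1e-8)

    def test_null_type_one_error(self):
        """Each factor's rejection rate ~ alpha when effects are independent of
        the moderators (500 replicates)."""
        rng = np.random.default_rng(77)
        k = 20
        rejections = {"sample_size": 0, "study_date": 0}
        n_rep = 500
        for _ in range(n_rep):
            mods = moderator_table(k, seed=int(rng.integers(2**31)))
            lfc = rng.normal(size=k)
            fit = moderator_regression(self.make_effects(k, lfc), mods)
            for term in rejections:
                rejections[term] += fit.result.table.loc[term, "p_value"] < 0.05
        for term, count in rejections.items():
            assert abs(count / n_rep - 0.05) <= 0.03, term

    def test_small_sample_size_rejected(self):
        mods = moderator_table(6)
        mods.loc[0, "sample_size"] = 3
        with pytest.raises(DataError, match="sample_size"):
            moderator_regression(self.make_effects(6, np.zeros(6)), mods)

    def test_unknown_study_rejected(self):
        mods = moderator_table(5)
        eff = self.make_effects(6, np.zeros(6))  # s6 not in the moderator table
        with pytest.raises(DataError, match="s6"):
            moderator_regression(eff, mods)
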