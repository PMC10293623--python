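"""Mixed RM-ANOVA: sums-of-squares partition, Greenhouse-Geisser epsilon,
marginal means and Tukey post-hocs, checked against independent oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from mubeta import (
    ar1_covariance,
    emmeans,
    gg_epsilon,
    mixed_rm_anova,
    posthoc_for_effect,
    simulate_long_design,
    tukey_pairwise,
)
from mubeta.stats import DesignError, _contrasts


# ---------------------------------------------------------------- GG epsilon
class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        k = 6
        cov = 0.4 * np.eye(k) + 0.6 * np.ones((k, k))
        assert gg_epsilon(cov, k) == pytest.approx(1.0)

    def test_rank_one_covariance_hits_lower_bound(self):
        k = 6
        v = np.arange(1.0, k + 1.0)
        cov = np.outer(v, v)
        assert gg_epsilon(cov, k) == pytest.approx(1.0 / (k - 1))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_box_formula(self, seed):
        # independent route: eigenvalues of the double-centred covariance
        k = 6
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(k, k))
        cov = A @ A.T
        H = np.eye(k) - np.ones((k, k)) / k
        lam = np.linalg.eigvalsh(H @ cov @ H)
        expected = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
        assert gg_epsilon(cov, k) == pytest.approx(expected, rel=1e-10)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.eye(1), 1)


# ------------------------------------------------------- projection oracle
def projection_oracle_ss(df):
    """Brute-force SS via sequential orthogonal projections on the balanced
    design: build the effect's full-interaction dummy space, project the data
    onto it, and subtract all contained lower-order projections."""
    factors = {
        "Handedness": sorted(df["handedness"].unique()),
        "Sex": sorted(df["sex"].unique()),
        "ROI": sorted(df["roi"].unique()),
        "Condition": sorted(df["condition"].unique()),
    }
    col_of = {"Handedness": "handedness", "Sex": "sex", "ROI": "roi",
              "Condition": "condition"}
    y = df["erds_percent"].to_numpy()
    n = len(df)

    def cell_projection(names):
        """Projection of y onto the span of indicators of the crossed cells."""
        if not names:
            return np.full(n, y.mean())
        key = df[[col_of[f] for f in names]].astype(str).agg("|".join, axis=1)
        return pd.Series(y).groupby(key.values).transform("mean").to_numpy()

    from itertools import combinations

    all_factors = list(factors)
    ss = {}
    for r in range(1, 5):
        for combo in combinations(all_factors, r):
            proj = cell_projection(combo)
            for rr in range(0, r):
                for sub in combinations(combo, rr):
                    sign = (-1) ** (r - rr)
                    proj = proj + sign * cell_projection(sub)
            ss[frozenset(combo)] = float((proj**2).sum())
    return ss


@pytest.fixture(scope="module")
def table():
    return simulate_long_design(3, seed=21, roi_effect=np.linspace(-2, 2, 6))


class TestMixedAnovaSS:
    def test_fixed_effect_ss_match_projection_oracle(self, table):
        result = mixed_rm_anova(table)
        oracle = projection_oracle_ss(table)
        for _, row in result.effects.iterrows():
            key = frozenset(row["effect"].split("*"))
            assert row["SS"] == pytest.approx(oracle[key], rel=1e-8), row["effect"]

    def test_total_ss_decomposition(self, table):
        result = mixed_rm_anova(table)
        y = table["erds_percent"].to_numpy()
        total = float(((y - y.mean()) ** 2).sum())
        parts = result.effects["SS"].sum() + sum(
            s["ss"] for s in result.strata.values()
        )
        assert parts == pytest.approx(total, rel=1e-8)

    def test_gg_never_increases_significance(self, table):
        # shrinking both dfs by epsilon raises the p-value whenever F >= 1
        # (for F < 1 the correction can move p either way, but those effects
        # are far from significance anyway)
        result = mixed_rm_anova(table)
        rows = result.effects[result.effects["F"] >= 1.0]
        assert not rows.empty
        assert (rows["p_gg"] >= rows["p_uncorrected"] - 1e-12).all()

    def test_unbalanced_design_raises(self, table):
        broken = table.iloc[:-1]
        with pytest.raises(DesignError):
            mixed_rm_anova(broken)

    def test_single_participant_per_cell_raises(self):
        tiny = simulate_long_design(2, seed=3)
        one_each = tiny[~tiny["participant"].isin(["P002", "P004", "P006", "P008"])]
        with pytest.raises(DesignError, match=">= 2"):
            mixed_rm_anova(one_each)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_anova_matches_r_aov(tmp_path):
    """Independent oracle: base R aov() with Error(participant/(roi*condition))."""
    table = simulate_long_design(3, seed=13, roi_effect=np.array([2, 0, -1, 0, 1, 0.5]))
    csv = tmp_path / "design.csv"
    table.to_csv(csv, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        f"""
        d <- read.csv("{csv}")
        for (col in c("participant","handedness","sex","roi","condition"))
            d[[col]] <- factor(d[[col]])
        m <- aov(erds_percent ~ handedness*sex*roi*condition +
                 Error(participant/(roi*condition)), data=d)
        s <- summary(m)
        for (stratum in s) {{
            tab <- stratum[[1]]
            for (i in seq_len(nrow(tab))) {{
                f <- tab[i, "F value"]
                if (!is.na(f))
                    cat(trimws(rownames(tab)[i]), tab[i, "Sum Sq"], f, sep="\t"); cat("\n")
            }}
        }}
        """
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
    r_rows = {}
    for line in out.stdout.strip().splitlines():
        if not line.strip():
            continue
        name, ss, F = line.split("\t")
        key = frozenset(
            {"handedness": "Handedness", "sex": "Sex", "roi": "ROI",
             "condition": "Condition"}[p] for p in name.split(":")
        )
        r_rows[key] = (float(ss), float(F))
    result = mixed_rm_anova(table)
    assert len(r_rows) == len(result.effects)
    for _, row in result.effects.iterrows():
        key = frozenset(row["effect"].split("*"))
        ss_r, f_r = r_rows[key]
        assert row["SS"] == pytest.approx(ss_r, rel=1e-6), row["effect"]
        assert row["F"] == pytest.approx(f_r, rel=1e-6), row["effect"]


# ------------------------------------------------------------------ emmeans
class TestEmmeans:
    def test_constant_table_gives_zero_se(self):
        table = simulate_long_design(2, seed=0)
        table["erds_percent"] = 4.2
        result = mixed_rm_anova(table)
        mm = emmeans(result, "ROI")
        np.testing.assert_allclose(mm["mean"], 4.2)
        np.testing.assert_allclose(mm["se"], 0.0, atol=1e-12)

    def test_between_factor_marginals(self):
        table = simulate_long_design(2, seed=1)
        table["erds_percent"] = np.where(table["handedness"] == "left", 1.0, 3.0)
        result = mixed_rm_anova(table)
        mm = emmeans(result, "Handedness").set_index("Handedness")
        assert mm.loc["left", "mean"] == pytest.approx(1.0)
        assert mm.loc["right", "mean"] == pytest.approx(3.0)

    @pytest.mark.parametrize("effect", ["ROI", "Condition", "Handedness", "ROI*Condition"])
    def test_matches_groupby_means_on_random_tables(self, effect):
        cols = {"ROI": ["roi"], "Condition": ["condition"],
                "Handedness": ["handedness"], "ROI*Condition": ["roi", "condition"]}[effect]
        for seed in range(10):
            table = simulate_long_design(2, seed=100 + seed)
            result = mixed_rm_anova(table)
            mm = emmeans(result, effect)
            oracle = table.groupby(cols)["erds_percent"].mean()
            for _, row in mm.iterrows():
                key = tuple(row[f] for f in effect.split("*"))
                key = key[0] if len(key) == 1 else key
                assert row["mean"] == pytest.approx(oracle.loc[key], rel=1e-10)

    def test_unknown_effect_raises(self):
        result = mixed_rm_anova(simulate_long_design(2, seed=2))
        with pytest.raises(KeyError):
            emmeans(result, "Lateralization")


# -------------------------------------------------------------------- Tukey
class TestTukey:
    def test_identical_means_give_p_one(self):
        means = pd.DataFrame({"level": ["a", "b", "c"], "mean": [1.0, 1.0, 1.0],
                              "se": 0.0, "n": 10})
        out = tukey_pairwise(means, error_df=20, error_ms=2.0, n_per_mean=10)
        np.testing.assert_allclose(out["p_tukey"], 1.0, atol=1e-9)

    def test_two_levels_equal_two_sided_t(self):
        means = pd.DataFrame({"level": ["a", "b"], "mean": [0.0, 1.7], "se": 0.1, "n": 8})
        df_err, ms = 14.0, 1.3
        out = tukey_pairwise(means, error_df=df_err, error_ms=ms, n_per_mean=8)
        t = abs(out["t"].iloc[0])
        p_t = 2 * t_dist.sf(t, df_err)
        assert out["p_tukey"].iloc[0] == pytest.approx(p_t, rel=1e-5)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        means = pd.DataFrame({"level": list("abcd"), "mean": rng.normal(0, 2, 4),
                              "se": 0.1, "n": 6})
        out1 = tukey_pairwise(means, 20, 1.0, 6)
        shuffled = means.iloc[[2, 0, 3, 1]].reset_index(drop=True)
        out2 = tukey_pairwise(shuffled, 20, 1.0, 6)
        p1 = {frozenset((r.level_a, r.level_b)): r.p_tukey for r in out1.itertuples()}
        p2 = {frozenset((r.level_a, r.level_b)): r.p_tukey for r in out2.itertuples()}
        assert all(p1[k] == pytest.approx(p2[k], rel=1e-12) for k in p1)

    def test_posthoc_runs_for_within_and_between_effects(self):
        result = mixed_rm_anova(simulate_long_design(2, seed=8))
        for effect in ("ROI", "Condition", "Handedness"):
            out = posthoc_for_effect(result, effect)
            k = len(result.levels[effect])
            assert len(out) == k * (k - 1) // 2
            assert ((out["p_tukey"] >= 0) & (out["p_tukey"] <= 1)).all()


def test_contrast_matrix_is_orthonormal():
    C = _contrasts(6)
    np.testing.assert_allclose(C @ C.T, np.eye(5), atol=1e-12)
    np.testing.assert_allclose(C @ np.ones(6), 0.0, atol=1e-12)


def test_ar1_covariance_is_positive_definite():
    S = ar1_covariance(6, 0.5, 1.0, 2.5)
    assert np.linalg.eigvalsh(S).min() > 0
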