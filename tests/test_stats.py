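import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from glyphcomplexity.stats import (
    DEFAULT_PRIOR_SCALE,
    ancestry_differentials,
    idiosyncratic_model,
    jzs_bayes_factor,
    jzs_bf_null,
    order_models,
    size_model,
    variance_partition,
)


def bf01_g_mixture(t, n, r=DEFAULT_PRIOR_SCALE):
    """Independent JZS oracle: the g-mixture (inverse-gamma) formulation."""
    nu = n - 1

    def num(g):
        return (
            (1 + n * g * r * r) ** -0.5
            * (1 + t * t / ((1 + n * g * r * r) * nu)) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1 / (2 * g))
        )

    numerator, _ = integrate.quad(num, 0, np.inf, limit=400)
    return (1 + t * t / nu) ** (-(nu + 1) / 2) / numerator


class TestJzsBayesFactor:
    @pytest.mark.parametrize("t,n", [(0.0, 29), (1.0, 29), (2.5, 29), (4.0, 15), (1.5, 100)])
    def test_matches_independent_quadrature_oracle(self, t, n):
        assert jzs_bf_null(t, n) == pytest.approx(bf01_g_mixture(t, n), rel=0.01)

    def test_matches_pingouin(self):
        import pingouin as pg

        for t, n in [(0.5, 20), (2.0, 40)]:
            ref = 1.0 / float(pg.bayesfactor_ttest(t, n, paired=True))
            assert jzs_bf_null(t, n) == pytest.approx(ref, rel=0.01)

    def test_null_favored_at_t_zero(self):
        for n in (5, 29, 200):
            assert jzs_bf_null(0.0, n) > 1

    def test_monotone_decreasing_in_abs_t(self):
        vals = [jzs_bf_null(t, 29) for t in np.linspace(0, 6, 13)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_large_t_drives_bf_to_zero(self):
        assert jzs_bf_null(15.0, 30) < 1e-6

    def test_from_data_and_errors(self):
        rng = np.random.default_rng(2)
        res = jzs_bayes_factor(rng.normal(0, 1, 25))
        assert res.n == 25 and res.bf_null > 0
        with pytest.raises(ValueError):
            jzs_bayes_factor([1.0])
        with pytest.raises(ValueError):
            jzs_bayes_factor([2.0, 2.0, 2.0])


def _script_means(rows):
    return pd.DataFrame(rows, columns=["script", "ancestor", "value"])


class TestAncestry:
    def test_identical_descendants_support_null(self):
        rows = [("Anc1", None, 5.0), ("Des1", "Anc1", 5.0), ("Des2", "Anc1", 5.0),
                ("Anc2", None, 7.0), ("Des3", "Anc2", 7.0)]
        diffs, bayes, _ = ancestry_differentials(_script_means(rows))
        assert all(d.mean_differential == 0 for d in diffs)
        assert bayes.bf_null > 1

    def test_prolific_ancestor_contributes_once(self):
        rows = [("Brah", None, 3.0)] + [
            (f"D{i:03d}", "Brah", 3.0 + i) for i in range(25)
        ] + [("Phnx", None, 2.0), ("Grek", "Phnx", 2.5)]
        diffs, _, _ = ancestry_differentials(_script_means(rows))
        assert len(diffs) == 2
        by_anc = {d.ancestor: d for d in diffs}
        assert by_anc["Brah"].mean_differential == pytest.approx(12.0)
        assert by_anc["Phnx"].mean_differential == pytest.approx(0.5)

    def test_unmeasured_ancestor_skipped(self):
        rows = [("Des1", "Ghost", 4.0), ("Anc1", None, 1.0), ("Des2", "Anc1", 2.0)]
        diffs, _, _ = ancestry_differentials(_script_means(rows))
        assert [d.ancestor for d in diffs] == ["Anc1"]

    def test_simulated_null_typically_favors_null(self):
        # 29 ancestors with pure-noise differentials: the Bayes factor
        # should favor the null in most replicates
        rng = np.random.default_rng(5)
        bfs = []
        for _ in range(200):
            diffs = rng.normal(0, 2.0, 29)
            bfs.append(jzs_bayes_factor(diffs).bf_null)
        assert np.median(bfs) > 1

    def test_no_pairs_errors(self):
        with pytest.raises(ValueError):
            ancestry_differentials(_script_means([("Solo", None, 1.0)]))


def _synthetic_half_table(seed=0, n_scripts=12, n_chars=20, order_effect=0.0, rl_share=0.3):
    """Half table built directly at the differential level (no images)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_scripts):
        rl = rng.random() < rl_share
        direction = "RL" if rl else "LR"
        fam = f"F{s % 3}"
        stype = f"T{s % 2}"
        for c in range(n_chars):
            first = 5.0 + order_effect + rng.normal(0, 1)
            last = 5.0 + rng.normal(0, 1)
            left, right = (first, last) if direction == "LR" else (last, first)
            d_lr = left - right
            d_fl = first - last
            for side, order, v in (("left", "last" if rl else "first", left),
                                   ("right", "first" if rl else "last", right)):
                rows.append(
                    {
                        "script": f"S{s:02d}", "family": fam, "type": stype,
                        "directionality": direction, "codepoint": f"{c:04X}",
                        "side": side, "order": order, "pc": v,
                        "ac": 100 * v + rng.normal(0, 5),
                        "d_lr_pc": d_lr, "d_lr_ac": 100 * d_lr,
                        "d_fl_pc": d_fl, "d_fl_ac": 100 * d_fl,
                    }
                )
    df = pd.DataFrame(rows)
    z = lambda x: (x - x.mean()) / x.std()
    df["d"] = z(df["pc"]) - z(df["ac"])
    return df


class TestOrderModels:
    def test_recovers_positive_order_intercept(self):
        table = _synthetic_half_table(seed=3, order_effect=1.0)
        suite = order_models(table)
        fit = suite["pc"]["first_last_intercept"]
        assert fit.fe_params["intercept"] > 0.5
        assert fit.pvalues["intercept"] < 0.05
        assert suite["pc"]["order_vs_side_daic"] > 0

    def test_directionality_coefficient_negative_with_order_effect(self):
        # an order effect means RL scripts favor their right halves, which
        # lowers the left-minus-right differential
        table = _synthetic_half_table(seed=4, order_effect=1.0)
        suite = order_models(table)
        fit = suite["ac"]["left_right_direction"]
        assert fit.fe_params["rl"] < 0

    def test_symmetric_corpus_gives_null_intercepts(self):
        table = _synthetic_half_table(seed=5, order_effect=0.0)
        suite = order_models(table)
        for metric in ("pc", "ac"):
            fit = suite[metric]["first_last_intercept"]
            assert fit.pvalues["intercept"] > 0.05

    def test_rows_without_direction_dropped(self):
        table = _synthetic_half_table(seed=6)
        extra = table.iloc[:4].copy()
        extra["directionality"] = "other"
        suite = order_models(pd.concat([table, extra], ignore_index=True))
        assert "pc" in suite and "ac" in suite


class TestVariancePartition:
    def test_type_level_variance_lands_on_type(self):
        rng = np.random.default_rng(6)
        types = np.repeat(np.arange(6), 40)
        scripts = np.repeat(np.arange(24), 10)  # 4 scripts per type
        y = 2.0 * rng.normal(size=6)[types] + rng.normal(size=240)
        shares = variance_partition(y, {"type": types, "script": scripts})
        assert shares["type"] > 0.3
        assert shares["script"] < 0.1
        assert shares["type"] > shares["script"]

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(7)
        g = np.repeat(np.arange(10), 12)
        y = rng.normal(size=120) + 0.5 * g
        shares = variance_partition(y, {"g": g})
        assert sum(shares.values()) == pytest.approx(1.0)


class TestSizeAndIdiosyncraticModels:
    def _char_table(self, seed=0, beta=0.3, n_scripts=30, n_chars=12):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_scripts):
            size = int(rng.integers(20, 400))
            base = np.exp(beta * np.log(size) + rng.normal(0, 0.1))
            for c in range(n_chars):
                rows.append(
                    {
                        "script": f"S{s:02d}", "family": f"F{s % 4}", "type": f"T{s % 3}",
                        "inventory_size": size, "idiosyncratic": s % 7 == 0,
                        "mean_pc": base * np.exp(rng.normal(0, 0.2)),
                    }
                )
        return pd.DataFrame(rows)

    def test_size_effect_recovered_and_informative(self):
        tab = self._char_table(seed=1, beta=0.3)
        null_fit, test_fit, daic = size_model(tab, outcome="mean_pc")
        assert test_fit.fe_params["log_size"] == pytest.approx(0.3, abs=0.1)
        assert daic > 2

    def test_large_script_exclusion_drops_rows(self):
        tab = self._char_table(seed=2)
        _, fit_all, _ = size_model(tab, outcome="mean_pc")
        _, fit_small, _ = size_model(tab, outcome="mean_pc", exclude_large=True)
        assert fit_small.nobs < fit_all.nobs

    def test_null_idiosyncratic_flag_uninformative(self):
        tab = self._char_table(seed=3, beta=0.0)
        null_fit, test_fit, daic = idiosyncratic_model(tab, "mean_pc")
        assert daic < 2
        assert test_fit.pvalues["idio"] > 0.05
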