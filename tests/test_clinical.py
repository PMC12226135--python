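"""Differential expression, survival association, dependency and druggability."""

from __future__ import annotations

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mirscore.clinical import (
    DOWN,
    GOOD,
    NS,
    POOR,
    UP,
    cox_hr_binary,
    dependency_call,
    differential_expression,
    druggability_flag,
    logrank_test_binary,
    moderated_t_two_group,
    survival_association,
    survival_screen,
)
from mirscore.config import ConfigurationError


def _matrix(rng, n_features, n1, n2):
    x = rng.normal(6, 1, (n_features, n1))
    y = rng.normal(6, 1, (n_features, n2))
    return x, y


class TestDifferentialExpression:
    def test_null_groups_give_flat_p_and_zero_lfc(self):
        """Two identically distributed groups: log2FC near 0, p roughly uniform."""
        rng = np.random.default_rng(5)
        x, y = _matrix(rng, 400, 15, 15)
        _, _, p = moderated_t_two_group(x, y)
        diff = x.mean(axis=1) - y.mean(axis=1)
        assert abs(float(np.mean(diff))) < 0.05
        # empirical p CDF within a KS band of uniform
        from scipy import stats

        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_shift_detected(self):
        """A 4-fold (2 log2-unit) shift at n=20+20 is called up-in-tumour."""
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(
            rng.normal(6, 0.5, (100, 40)),
            index=[f"G{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(40)],
        )
        labels = pd.Series(["tumor"] * 20 + ["normal"] * 20, index=expr.columns)
        expr.iloc[0, :20] += 2.0
        res = differential_expression(expr, labels, entity="CT01")
        top = res.iloc[0]
        assert top["direction"] == UP
        assert top["fdr"] < 0.05
        assert top["log2_fold_change"] == pytest.approx(2.0, abs=0.5)

    def test_single_feature_reduces_to_ordinary_t(self):
        """With one feature no prior is estimable; moderated t == Student t."""
        from scipy import stats

        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (1, 30))
        y = rng.normal(0.5, 1, (1, 30))
        _, t_mod, p_mod = moderated_t_two_group(x, y)
        t_ref, p_ref = stats.ttest_ind(x[0], y[0], equal_var=True)
        assert t_mod[0] == pytest.approx(t_ref, abs=1e-6)
        assert p_mod[0] == pytest.approx(p_ref, abs=1e-6)

    def test_matches_limma_reference(self, tmp_path):
        """Moderated t and p agree with the limma reference implementation."""
        rng = np.random.default_rng(1)
        sd = np.sqrt(1 / rng.gamma(4, 1 / 4, 60))
        x = rng.normal(0, 1, (60, 10)) * sd[:, None]
        y = rng.normal(0, 1, (60, 12)) * sd[:, None]
        mat = tmp_path / "m.tsv"
        np.savetxt(mat, np.hstack([x, y]), delimiter="\t")
        _, t_mine, p_mine = moderated_t_two_group(x, y)
        out = tmp_path / "limma.tsv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.table("{mat}", sep="\\t"))
            design <- cbind(Intercept=1, g=c(rep(1,10), rep(0,12)))
            fit <- eBayes(lmFit(m, design))
            write.table(cbind(fit$t[,"g"], fit$p.value[,"g"]),
                        "{out}", sep="\\t", row.names=FALSE, col.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = np.loadtxt(out, delimiter="\t")
        assert np.allclose(t_mine, ref[:, 0], atol=1e-10)
        assert np.allclose(p_mine, ref[:, 1], atol=1e-10)

    def test_direction_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(
            rng.normal(6, 0.5, (50, 30)), index=[f"G{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(30)],
        )
        expr.iloc[:5, :15] += 1.5
        labels = pd.Series(["tumor"] * 15 + ["normal"] * 15, index=expr.columns)
        swapped = labels.map({"tumor": "normal", "normal": "tumor"})
        a = differential_expression(expr, labels)
        b = differential_expression(expr, swapped)
        flip = {UP: DOWN, DOWN: UP, NS: NS}
        assert list(b["direction"]) == [flip[d] for d in a["direction"]]
        assert np.allclose(b["log2_fold_change"], -a["log2_fold_change"], equal_nan=True)

    def test_constant_or_zero_median_feature_undetermined(self):
        expr = pd.DataFrame(
            [[1.0] * 10, [0.0] * 9 + [1.0], list(range(10))],
            index=["constant", "low", "ok"],
            columns=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series(["tumor"] * 5 + ["normal"] * 5, index=expr.columns)
        res = differential_expression(expr, labels).set_index("feature")
        assert res.loc["constant", "undetermined"]
        assert res.loc["low", "undetermined"]
        assert not res.loc["ok", "undetermined"]
        assert pd.isna(res.loc["constant", "p"])

    def test_empty_group_is_configuration_error(self):
        expr = pd.DataFrame(np.ones((3, 4)), columns=[f"s{i}" for i in range(4)])
        labels = pd.Series(["tumor"] * 4, index=expr.columns)
        with pytest.raises(ConfigurationError):
            differential_expression(expr, labels)

    def test_bh_fdr_monotone_and_bounded_below_by_p(self):
        rng = np.random.default_rng(9)
        x, y = _matrix(rng, 200, 10, 10)
        x[:20] += 1.0
        expr = pd.DataFrame(
            np.hstack([x, y]), index=[f"G{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(20)],
        )
        labels = pd.Series(["tumor"] * 10 + ["normal"] * 10, index=expr.columns)
        res = differential_expression(expr, labels).sort_values("p")
        assert (res["fdr"].to_numpy() >= res["p"].to_numpy() - 1e-12).all()
        assert (np.diff(res["fdr"].to_numpy()) >= -1e-12).all()


class TestSurvival:
    @staticmethod
    def _cohort(rng, n=200, hr=3.0, cut=6.0):
        x = rng.normal(6, 1, n)
        lam = 0.1 * np.exp(np.log(hr) * (x > cut))
        t_event = rng.exponential(1 / lam)
        t_cens = rng.uniform(0, 30, n)
        return x, np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int)

    def test_logrank_and_cox_match_lifelines(self):
        """The fast log-rank p and binary-Cox HR equal the lifelines references."""
        from lifelines import CoxPHFitter
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(10)
        x, t, e = self._cohort(rng, n=150)
        high = x > 6.0
        _, p = logrank_test_binary(high, t, e)
        ref = logrank_test(t[high], t[~high], e[high], e[~high])
        assert p == pytest.approx(ref.p_value, rel=1e-9)
        hr = cox_hr_binary(high, t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": high.astype(float)}), "t", "e"
        )
        assert hr == pytest.approx(float(np.exp(cph.params_["x"])), rel=1e-4)

    def test_cutoff_recovery(self):
        """A planted survival split at expression 6.0 is recovered nearby."""
        rng = np.random.default_rng(11)
        x, t, e = self._cohort(rng, n=250, hr=3.0, cut=6.0)
        assoc = survival_association(x, t, e, feature="g")
        assert not assoc.undetermined
        # within the two order statistics flanking the true cutoff is ideal;
        # allow a small neighbourhood since noise shifts the optimum
        assert abs(assoc.cutoff - 6.0) < 0.5
        assert assoc.hazard_ratio > 1
        assert assoc.direction == POOR

    def test_cutoff_within_scanned_quantiles(self):
        rng = np.random.default_rng(12)
        x, t, e = self._cohort(rng)
        assoc = survival_association(x, t, e, scan=(0.25, 0.75))
        assert np.quantile(x, 0.25) <= assoc.cutoff <= np.quantile(x, 0.75)

    def test_group_inversion_reciprocates_hazard_ratio(self):
        """Swapping the high/low labels gives exactly the reciprocal HR."""
        rng = np.random.default_rng(13)
        x, t, e = self._cohort(rng, n=150)
        high = x > 6.0
        hr = cox_hr_binary(high, t, e)
        hr_inv = cox_hr_binary(~high, t, e)
        assert hr_inv == pytest.approx(1.0 / hr, rel=1e-6)

    def test_constant_expression_undetermined(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(10, 50)
        e = np.ones(50, dtype=int)
        assoc = survival_association(np.full(50, 5.0), t, e)
        assert assoc.undetermined
        assert assoc.cutoff is None

    def test_no_events_undetermined(self):
        rng = np.random.default_rng(15)
        assoc = survival_association(
            rng.normal(6, 1, 50), rng.exponential(10, 50), np.zeros(50, dtype=int)
        )
        assert assoc.undetermined

    def test_null_selected_p_is_anticonservative(self):
        """Under exchangeable survival the optimal-cutoff p is stochastically
        smaller than uniform -- the documented inflation, asserted as such."""
        rng = np.random.default_rng(16)
        ps = []
        for _ in range(200):
            n = 60
            x = rng.normal(6, 1, n)
            t = rng.exponential(10, n)
            e = (rng.random(n) < 0.7).astype(int)
            assoc = survival_association(x, t, e)
            if not assoc.undetermined:
                ps.append(assoc.logrank_p)
        ps = np.asarray(ps)
        # stochastically smaller than uniform: mean well below 0.5 and
        # far more small p-values than the nominal rate
        assert np.mean(ps) < 0.45
        assert np.mean(ps < 0.05) > 0.05

    def test_screen_directions_use_fdr(self, small_system):
        surv = small_system["annotations"].survival
        called = surv[surv["direction"] != NS]
        assert (called["fdr"] < 0.05).all()
        poor = called[called["direction"] == POOR]
        good = called[called["direction"] == GOOD]
        assert (poor["hazard_ratio"] > 1).all()
        assert (good["hazard_ratio"] < 1).all()


class TestDependency:
    def test_flag_boundary_inclusive_at_10_percent(self):
        assert dependency_call([-0.6] + [0.0] * 9, "CT01").dependent
        assert not dependency_call([-0.6] * 9 + [0.0] * 91, "CT01").dependent

    def test_exact_effect_threshold_not_counted(self):
        """An effect of exactly -0.5 is not a dependency (strict inequality)."""
        call = dependency_call([-0.5] * 10, "CT01")
        assert call.fraction_dependent == 0.0
        assert not call.dependent

    def test_flag_flips_exactly_at_fraction_for_all_small_n(self):
        """Exhaustive k/n scan, n <= 50: dependent iff k/n >= 0.10."""
        for n in range(1, 51):
            for k in range(n + 1):
                effects = [-0.7] * k + [0.0] * (n - k)
                call = dependency_call(effects, "CT01")
                assert call.dependent == (k / n >= 0.10), (k, n)

    def test_essential_fraction(self):
        call = dependency_call([-1.2, -0.7, -0.3, 0.1], "CT01")
        assert call.fraction_dependent == pytest.approx(0.5)
        assert call.essential_fraction == pytest.approx(0.25)

    def test_empty_line_set_rejected(self):
        with pytest.raises(ConfigurationError):
            dependency_call([], "CT01")


class TestDruggability:
    def test_membership(self):
        assert druggability_flag("CDC7", {"CDC7", "DBF4"})
        assert not druggability_flag("GAPDH", {"CDC7"})

    def test_case_insensitive(self):
        assert druggability_flag("cdc7", {"CDC7"})

    def test_empty_list_warns_and_returns_false(self):
        with pytest.warns(UserWarning, match="empty"):
            assert not druggability_flag("CDC7", set())
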