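"""AUC machinery, factorial tests and SNK letter groupings."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

import pparclock as pc
from pparclock.rhythm import (DesignError, InsufficientReplicationError,
                              _trapezoid_weights, auc_contrasts)
from conftest import make_curve


# --------------------------------------------------------------------------
# independent SNK oracle: a straightforward re-implementation of the
# sequential studentized-range recursion, kept deliberately separate

def oracle_snk_letters(means, ns, mse, df, alpha=0.05):
    order = sorted(range(len(means)), key=lambda i: -means[i])
    m = [means[i] for i in order]
    n = [ns[i] for i in order]
    homog = set()

    def rec(i, j):
        if i >= j:
            return
        se = (mse / 2 * (1 / n[i] + 1 / n[j])) ** 0.5
        q = (m[i] - m[j]) / se if se > 0 else float("inf") * (m[i] > m[j])
        if se == 0 and m[i] == m[j]:
            q = 0.0
        if q <= studentized_range.ppf(1 - alpha, j - i + 1, df):
            homog.add((i, j))
            return
        rec(i, j - 1)
        rec(i + 1, j)

    rec(0, len(m) - 1)
    maximal = [iv for iv in homog
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                          for o in homog)]
    covered = set()
    for i, j in maximal:
        covered.update(range(i, j + 1))
    for i in range(len(m)):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()
    letters = [""] * len(m)
    for idx, (i, j) in enumerate(maximal):
        for k in range(i, j + 1):
            letters[k] += chr(ord("a") + idx)
    return {order[k]: letters[k] for k in range(len(m))}


class TestTrapezoidAuc:
    def test_constant_curve_over_full_period(self):
        t = [6, 10, 14, 18, 22, 26]
        assert pc.trapezoid_auc(t, np.ones(6), "periodic") == pytest.approx(24.0)

    def test_open_triangle(self):
        assert pc.trapezoid_auc([0, 4], [0, 2], "open") == pytest.approx(4.0)

    def test_six_point_hand_example(self):
        """Hand sum: interior trapezoids 6 + 10 + 10 + 6 + 3 over the 4-h
        gaps, plus the periodic closure trapezoid (0.5+1)/2*4 = 3 -> 38."""
        t = [6, 10, 14, 18, 22, 26]
        y = [1, 2, 3, 2, 1, 0.5]
        assert pc.trapezoid_auc(t, y, "periodic") == pytest.approx(38.0)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            pc.trapezoid_auc([6, 6, 10], [1, 2, 3], "open")

    def test_additive_over_adjacent_intervals(self):
        t = np.array([0.0, 3.0, 7.0, 12.0])
        y = np.array([1.0, 4.0, 2.0, 5.0])
        whole = pc.trapezoid_auc(t, y, "open")
        parts = (pc.trapezoid_auc(t[:2], y[:2], "open")
                 + pc.trapezoid_auc(t[1:], y[1:], "open"))
        assert whole == pytest.approx(parts, rel=1e-14)

    def test_scaling_by_constant(self):
        t = [6, 10, 14, 18, 22, 26]
        y = np.array([1, 2, 3, 2, 1, 0.5])
        a1 = pc.trapezoid_auc(t, y, "periodic")
        a3 = pc.trapezoid_auc(t, 3 * y, "periodic")
        assert a3 == pytest.approx(3 * a1)

    def test_weights_reproduce_auc(self):
        t = np.array([6.0, 10, 14, 18, 22, 26])
        y = np.array([1.0, 2, 3, 2, 1, 0.5])
        for closure in ("periodic", "open"):
            w = _trapezoid_weights(t, closure)
            assert w @ y == pytest.approx(pc.trapezoid_auc(t, y, closure))


class TestAucWithError:
    def test_zero_sems_zero_se(self):
        c = make_curve([6, 10, 14, 18, 22], [1, 2, 3, 2, 1])
        rec = pc.auc_with_error(c)
        assert rec.se_auc == 0.0

    def test_single_interior_sem_weight(self):
        # one nonzero SEM s at an interior point of a 4-h grid: weight 4
        sems = [0, 0.5, 0, 0, 0, 0]
        c = make_curve([6, 10, 14, 18, 22, 26], np.ones(6), sems=sems)
        rec = pc.auc_with_error(c, closure="periodic")
        assert rec.se_auc == pytest.approx(4 * 0.5)

    def test_delta_method_matches_monte_carlo(self):
        """Empirical SD of AUC over 1000 resampled mean-curves vs delta SE."""
        spec = pc.cosinor_scenario("null", seed=0, noise_cv=0.10)
        cell = spec.cells[("lean", "control")]
        times = np.array([6.0, 10.0, 14.0, 18.0, 22.0, 26.0])
        mu = cell.mean_at(times)
        n = 4
        sigma = np.sqrt(np.log(1 + 0.10**2))
        rng = np.random.default_rng(11)
        aucs = []
        for _ in range(1000):
            draws = mu[:, None] * rng.lognormal(-sigma**2 / 2, sigma, (6, n))
            aucs.append(pc.trapezoid_auc(times, draws.mean(axis=1), "periodic"))
        true_sem = 0.10 * mu / np.sqrt(n)  # exact SE of each cell mean
        c = make_curve(times, mu, sems=true_sem)
        rec = pc.auc_with_error(c, closure="periodic")
        assert np.std(aucs) == pytest.approx(rec.se_auc, rel=0.10)

    def test_singleton_cells_flag_se_unavailable(self):
        c = make_curve([6, 10, 14, 18], [1, 2, 1, 2], ns=[1, 4, 4, 4])
        assert not pc.auc_with_error(c).se_available

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError):
            pc.auc_with_error(make_curve([6, 10, 14], [1, 2, 1]))


class TestTimepointTtest:
    def _ds(self, lean, obese):
        rows = []
        for g, vals in (("lean", lean), ("obese", obese)):
            for i, v in enumerate(vals):
                rows.append(dict(animal_id=f"{g}{i}", maternal=g,
                                 diet="control", time_h=6.0, gene="G", value=v))
        return pc.TimecourseDataset(pd.DataFrame(rows))

    def test_identical_cells(self):
        res = pc.timepoint_ttest(self._ds([1, 2, 3], [1, 2, 3]), "G", 6.0,
                                 "control")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        res = pc.timepoint_ttest(self._ds([1, 2, 3], [4, 5, 6]), "G", 6.0,
                                 "control")
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.p == pytest.approx(0.0213, abs=2e-3)
        assert res.significant

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientReplicationError):
            pc.timepoint_ttest(self._ds([1], [2, 3]), "G", 6.0, "control")


def balanced_anova_oracle(cells):
    """Closed-form balanced 2x2 ANOVA from cell arrays, hand-coded."""
    ab = {k: np.asarray(v, float) for k, v in cells.items()}
    n = len(next(iter(ab.values())))
    grand = np.mean([v.mean() for v in ab.values()])
    m_lean = (ab[("lean", "control")].mean() + ab[("lean", "HFD")].mean()) / 2
    m_obese = (ab[("obese", "control")].mean() + ab[("obese", "HFD")].mean()) / 2
    m_con = (ab[("lean", "control")].mean() + ab[("obese", "control")].mean()) / 2
    m_hfd = (ab[("lean", "HFD")].mean() + ab[("obese", "HFD")].mean()) / 2
    ss_a = 2 * n * ((m_lean - grand) ** 2 + (m_obese - grand) ** 2)
    ss_b = 2 * n * ((m_con - grand) ** 2 + (m_hfd - grand) ** 2)
    ss_cells = n * sum((v.mean() - grand) ** 2 for v in ab.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = sum(((v - v.mean()) ** 2).sum() for v in ab.values())
    df_e = 4 * (n - 1)
    return (ss_a / (ss_e / df_e), ss_b / (ss_e / df_e),
            ss_ab / (ss_e / df_e), df_e)


class TestTwoWayAnova:
    def _frame(self, cells):
        rows = []
        for (m, d), vals in cells.items():
            for v in vals:
                rows.append(dict(maternal=m, diet=d, value=float(v)))
        return pd.DataFrame(rows)

    def test_additive_means_no_interaction(self):
        # cell means exactly additive; identical within-cell spread, so the
        # interaction sum of squares is exactly zero while MSE is not
        eff = {"lean": 0.0, "obese": 1.0}
        deff = {"control": 0.0, "HFD": 2.0}
        spread = np.array([-1.0, 0.0, 1.0, 0.0])
        cells = {(m, d): 5 + eff[m] + deff[d] + spread
                 for m in ("lean", "obese") for d in ("control", "HFD")}
        tab = pc.two_way_anova(self._frame(cells))
        assert tab.effects["interaction"]["F"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_balanced_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        cells = {(m, d): rng.normal(2 + hash((m, d)) % 3, 1.0, 3)
                 for m in ("lean", "obese") for d in ("control", "HFD")}
        tab = pc.two_way_anova(self._frame(cells))
        Fa, Fb, Fab, df_e = balanced_anova_oracle(cells)
        assert tab.effects["maternal"]["F"] == pytest.approx(Fa, abs=1e-10)
        assert tab.effects["diet"]["F"] == pytest.approx(Fb, abs=1e-10)
        assert tab.effects["interaction"]["F"] == pytest.approx(Fab, abs=1e-10)
        assert tab.df_resid == df_e

    def test_empty_cell_rejected(self):
        cells = {("lean", "control"): [1, 2], ("lean", "HFD"): [1, 2],
                 ("obese", "control"): [1, 2], ("obese", "HFD"): []}
        with pytest.raises(DesignError):
            pc.two_way_anova(self._frame(cells))

    def test_interaction_scenario_detected_with_letters(self):
        ds = pc.synth_dataset(pc.cosinor_scenario("interaction_obese_hfd",
                                                  seed=5))
        at_peak = ds.df[np.isclose(ds.df["time_h"], 10.0)]
        tab = pc.two_way_anova(at_peak.rename(columns={"value": "value"}))
        assert tab.effects["interaction"]["p"] < 0.05
        assert tab.posthoc is not None
        low = tab.posthoc["obese-HFD"]
        others = {tab.posthoc[k] for k in tab.posthoc if k != "obese-HFD"}
        assert low not in others  # deficit group gets its own letter


class TestSnk:
    def test_all_equal_single_letter(self):
        means = {"a1": 2.0, "a2": 2.0, "a3": 2.0, "a4": 2.0}
        ns = {k: 4 for k in means}
        out = pc.snk_posthoc(means, mse=1.0, df=12, ns=ns)
        assert len(set(out.values())) == 1

    def test_two_well_separated_groups(self):
        means = {"lo": 0.0, "hi": 50.0}
        out = pc.snk_posthoc(means, mse=1.0, df=20, ns={"lo": 10, "hi": 10})
        assert out["hi"] != out["lo"]

    @pytest.mark.parametrize("means", [
        (10.0, 10.1, 15.0, 20.0),
        (1.0, 1.0, 1.0, 1.0),
        (0.0, 3.0, 3.2, 9.0),
        (5.0, 5.5, 6.0, 6.5),
    ])
    def test_matches_bruteforce_recursion_oracle(self, means):
        labels = ["g1", "g2", "g3", "g4"]
        mdict = dict(zip(labels, means))
        ns = dict(zip(labels, [4, 4, 4, 4]))
        ours = pc.snk_posthoc(mdict, mse=2.0, df=12, ns=ns)
        oracle = oracle_snk_letters(list(means), [4] * 4, 2.0, 12)
        oracle_named = {labels[i]: L for i, L in oracle.items()}
        # same partition structure: identical sharing pattern between groups
        for i in range(4):
            for j in range(4):
                share_ours = bool(set(ours[labels[i]]) & set(ours[labels[j]]))
                share_orc = bool(set(oracle_named[labels[i]])
                                 & set(oracle_named[labels[j]]))
                assert share_ours == share_orc, (means, ours, oracle_named)

    def test_order_consistency(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            means = dict(zip("abcd", np.sort(rng.uniform(0, 5, 4))))
            ns = {k: 4 for k in means}
            out = pc.snk_posthoc(means, mse=rng.uniform(0.2, 2), df=12, ns=ns)
            labs = sorted(means, key=lambda k: means[k])
            for i in range(4):
                for k in range(i + 2, 4):
                    shared = set(out[labs[i]]) & set(out[labs[k]])
                    for j in range(i + 1, k):
                        if shared:
                            assert shared <= set(out[labs[j]])

    def test_bad_df_rejected(self):
        with pytest.raises(ValueError):
            pc.snk_posthoc({"a": 1.0, "b": 2.0}, mse=1.0, df=0,
                           ns={"a": 3, "b": 3})


class TestAucTable:
    def test_contrasts_require_all_groups(self):
        rec = pc.AucRecord("G", "lean", "control", 10.0, 1.0, "periodic", 6)
        with pytest.raises(DesignError):
            auc_contrasts({("lean", "control"): rec})

    def test_interaction_scenario_lowest_auc_in_obese_hfd(self):
        ds = pc.synth_dataset(pc.cosinor_scenario("interaction_obese_hfd",
                                                  seed=1))
        tab = pc.auc_table(ds, ["BMAL1"])
        row = tab.iloc[0]
        aucs = {g: row[f"auc_{g[0]}-{g[1]}"] for g in pc.GROUPS}
        assert min(aucs, key=aucs.get) == ("obese", "HFD")

    def test_null_scenario_aucs_near_24_times_mesor(self):
        ds = pc.synth_dataset(pc.cosinor_scenario("null", seed=2))
        tab = pc.auc_table(ds, ["BMAL1"])
        row = tab.iloc[0]
        for g in pc.GROUPS:
            assert row[f"auc_{g[0]}-{g[1]}"] == pytest.approx(24.0, rel=0.15)
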