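"""Statistical battery verified against hand-computed closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import eegmicrostates as ems
from eegmicrostates.stats import (
    chi_square_2x2,
    cohens_d,
    fdr_adjust,
    glm_adjusted_two_sample_t,
    oneway_anova_tukey,
    paired_t,
    run_study_comparisons,
    two_sample_t_from_summary,
)


class TestPairedT:
    def test_identical_vectors(self):
        r = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert (r.statistic, r.p, r.cohens_d) == (0.0, 1.0, 0.0)

    def test_constant_nonzero_difference_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t([2.0, 3, 4], [1.0, 2, 3])

    def test_matches_first_principles_on_five_subjects(self):
        a = np.array([5.1, 4.8, 6.0, 5.5, 4.9])
        b = np.array([4.7, 4.9, 5.2, 5.0, 4.6])
        d = a - b
        sd = np.sqrt(((d - d.mean()) ** 2).sum() / 4)
        t_hand = d.mean() / (sd / np.sqrt(5))
        p_hand = 2 * sps.t.sf(abs(t_hand), 4)
        r = paired_t(a, b)
        assert r.statistic == pytest.approx(t_hand, abs=1e-12)
        assert r.p == pytest.approx(p_hand, abs=1e-12)
        assert r.cohens_d == pytest.approx(d.mean() / sd, abs=1e-12)


class TestChiSquare:
    def test_printed_demographics_value(self):
        """11:19 vs 8:12 males:females gives the published 0.057."""
        r = chi_square_2x2([[11, 19], [8, 12]])
        assert round(r.statistic, 3) == 0.057
        assert round(r.p, 3) == 0.812

    def test_proportional_table_is_zero(self):
        assert chi_square_2x2([[10, 20], [5, 10]]).statistic == pytest.approx(0.0)

    def test_matches_cell_by_cell_expansion(self):
        obs = np.array([[6.0, 5.0], [5.0, 5.0]])
        rows, cols, n = obs.sum(1), obs.sum(0), obs.sum()
        chi_hand = sum(
            (obs[i, j] - rows[i] * cols[j] / n) ** 2 / (rows[i] * cols[j] / n)
            for i in range(2) for j in range(2))
        assert chi_square_2x2(obs).statistic == pytest.approx(chi_hand, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestSummaryT:
    def test_printed_age_comparison(self):
        """Pooled t on the published age summaries reproduces -0.398."""
        r = two_sample_t_from_summary(21.7, 1.12, 30, 21.5, 2.40, 20,
                                      direction="2-1")
        # the published inputs are themselves rounded to 3 significant digits
        assert r.statistic == pytest.approx(-0.398, abs=1e-3)
        assert r.df == 48

    def test_equal_means_give_zero(self):
        r = two_sample_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert r.statistic == 0.0

    def test_agrees_with_moment_matched_raw_samples(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(30)
        a = (a - a.mean()) / a.std(ddof=1) * 1.12 + 21.7
        b = rng.standard_normal(20)
        b = (b - b.mean()) / b.std(ddof=1) * 2.40 + 21.5
        t_raw, _p = sps.ttest_ind(b, a, equal_var=True)[:2]
        r = two_sample_t_from_summary(21.7, 1.12, 30, 21.5, 2.40, 20)
        assert r.statistic == pytest.approx(t_raw, abs=1e-9)


class TestCohensD:
    def test_unit_separation(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(4000) + 1.0
        b = rng.standard_normal(4000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.1)

    def test_identical_groups_and_antisymmetry(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20)
        assert cohens_d(x, x.copy()) == 0.0
        a, b = rng.standard_normal(15), rng.standard_normal(10)
        assert cohens_d(a, b) == -cohens_d(b, a)


class TestFDR:
    def test_bh_step_up_arithmetic(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03] * 3)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])

    def test_monotone_and_readjustment_never_decreases(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=20)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(fdr_adjust(adj) >= adj - 1e-15)

    def test_null_calibration(self):
        """Across 1000 all-null families, the empirical FDR at threshold
        0.05 stays at the nominal level (within Monte-Carlo error)."""
        rng = np.random.default_rng(4)
        fdrs = []
        for _ in range(1000):
            p = rng.uniform(size=10)
            rejected = fdr_adjust(p) < 0.05
            fdrs.append(rejected.sum() / max(rejected.sum(), 1))
        mean = np.mean(fdrs)
        se = np.std(fdrs) / np.sqrt(len(fdrs))
        assert mean <= 0.05 + 2 * se


class TestAnovaTukey:
    def test_three_identical_groups(self):
        fam = oneway_anova_tukey([np.array([1.0, 2, 3])] * 3, ["a", "b", "c"])
        omni = fam.results[0]
        assert omni.statistic == pytest.approx(0.0)
        assert omni.p == pytest.approx(1.0)

    def test_constructed_separation_flags_only_third_group(self):
        fam = oneway_anova_tukey(
            [np.array([1.0, 2, 3]), np.array([1.0, 2, 3]), np.array([11.0, 12, 13])],
            ["a", "b", "c"])
        pair = {r.comparison: r for r in fam.results if r.test == "tukey_kramer"}
        assert pair["a vs b"].p > 0.9
        assert pair["a vs c"].p < 0.001 and pair["b vs c"].p < 0.001
        assert pair["a vs c"].direction == -1

    def test_matches_hand_computed_kramer_form(self):
        """Unequal-n Tukey-Kramer p equals the studentized-range tail of the
        hand-computed q with the Kramer standard error."""
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 4), rng.normal(0.8, 1, 6), rng.normal(0.2, 1, 5)]
        fam = oneway_anova_tukey(list(groups), ["a", "b", "c"], alpha=1.1)
        ns = [len(g) for g in groups]
        df = sum(ns) - 3
        msw = sum((len(g) - 1) * g.var(ddof=1) for g in groups) / df
        pairs = [(0, 1, "a vs b"), (0, 2, "a vs c"), (1, 2, "b vs c")]
        got = {r.comparison: r.p for r in fam.results if r.test == "tukey_kramer"}
        for i, j, tag in pairs:
            se = np.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
            q = abs(groups[i].mean() - groups[j].mean()) / se
            p_hand = sps.studentized_range.sf(q, 3, df)
            assert got[tag] == pytest.approx(p_hand, abs=1e-6)

    def test_all_constant_distinct_groups_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova_tukey([np.array([1.0, 1]), np.array([2.0, 2]),
                                np.array([3.0, 3])], ["a", "b", "c"])


class TestGLMAdjustedT:
    def test_orthogonal_covariates_are_a_no_op(self):
        rng = np.random.default_rng(6)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 8)])
        group = np.array([0] * 10 + [1] * 8)
        raw = rng.standard_normal((18, 3))
        basis = np.column_stack([np.ones(18), y, group])
        proj = basis @ np.linalg.lstsq(basis, raw, rcond=None)[0]
        X = raw - proj  # orthogonal to intercept, y, and group
        r = glm_adjusted_two_sample_t(y[:10], y[10:], X[:10], X[10:])
        t_plain, _ = sps.ttest_ind(y[:10], y[10:], equal_var=True)[:2]
        assert r.statistic == pytest.approx(t_plain, abs=1e-9)

    def test_covariate_adjustment_sharpens_a_real_effect(self):
        """When y = group effect + 2*age + noise, removing the age-driven
        variance makes the group contrast sharper: mean |t| grows after
        adjustment over 100 draws."""
        rng = np.random.default_rng(7)
        t_adj, t_raw = [], []
        for _ in range(100):
            age = np.concatenate([rng.normal(21, 2, 12), rng.normal(21, 2, 12)])
            y = 1.5 * np.r_[np.ones(12), np.zeros(12)] + 2 * age \
                + rng.normal(0, 1, 24)
            cov = np.column_stack([age, rng.integers(0, 2, 24), rng.normal(size=24)])
            r = glm_adjusted_two_sample_t(y[:12], y[12:], cov[:12], cov[12:])
            t_adj.append(abs(r.statistic))
            t_raw.append(abs(sps.ttest_ind(y[:12], y[12:], equal_var=True)[0]))
        assert np.mean(t_adj) > np.mean(t_raw)

    def test_power_at_study_sample_sizes(self):
        """A 1-SD group shift is detected with power > 0.8 at n = 30 vs 20
        over 500 simulations."""
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(500):
            age = np.concatenate([rng.normal(21.7, 1.12, 30),
                                  rng.normal(21.5, 2.4, 20)])
            sex = rng.integers(0, 2, 50)
            resting = rng.normal(size=50)
            noise = rng.normal(0, 1, 50)
            y = noise + 0.3 * resting + np.r_[np.ones(30), np.zeros(20)]
            cov = np.column_stack([age, sex, resting])
            r = glm_adjusted_two_sample_t(y[:30], y[30:], cov[:30], cov[30:])
            hits += r.p < 0.05
        assert hits / 500 > 0.8

    def test_collinear_covariate_named(self):
        rng = np.random.default_rng(9)
        age = rng.normal(21, 2, 12)
        cov = np.column_stack([age, 2 * age, rng.normal(size=12)])
        with pytest.raises(ValueError, match="age"):
            glm_adjusted_two_sample_t(rng.normal(size=6), rng.normal(size=6),
                                      cov[:6], cov[6:],
                                      covariate_names=["age", "age2", "rest"])


def synthetic_parameter_table(seed=0, effect=None, n_ai=6, n_ra=5, dur_s=20.0):
    """Parameter tables straight from planted label sequences (no EEG)."""
    import dataclasses

    from eegmicrostates.microstates import Segmentation
    from eegmicrostates.parameters import parameter_table

    truth = ems.default_truth(seed=seed, condition_effects=effect or {})
    rngs = [np.random.default_rng(c)
            for c in np.random.SeedSequence(seed).spawn(n_ai + n_ra)]
    segs, rows = {}, []
    for i in range(n_ai + n_ra):
        rng = rngs[i]
        group = "AI" if i < n_ai else "RA"
        sid = f"{group.lower()}{i}"
        fac = np.exp(rng.normal(0, truth.subject_sd, 4))
        subj_truth = dataclasses.replace(
            truth, duration_mean_ms=truth.duration_mean_ms * fac)
        conds = ems.AI_CONDITIONS if group == "AI" else ems.RA_CONDITIONS
        for cond in conds:
            cond_truth = subj_truth.for_condition(cond)
            labels = ems.simulate_label_sequence(cond_truth, dur_s, 200.0, rng)
            segs[(sid, group, cond)] = Segmentation(labels, 200.0, 4, list("ABCD"))
        rows.append({"subject": sid, "group": group,
                     "age": rng.normal(21.6, 1.5), "sex": int(rng.random() < 0.4)})
    return parameter_table(segs), pd.DataFrame(rows)


class TestStudyBattery:
    def test_missing_group_is_an_error(self):
        table, subjects = synthetic_parameter_table(seed=1, n_ra=1)
        with pytest.raises(ValueError, match="RA"):
            run_study_comparisons(table[table["group"] == "AI"], subjects)

    def test_planted_class_a_effect_detected_with_direction(self):
        table, subjects = synthetic_parameter_table(
            seed=2, effect=ems.table2_preset(), dur_s=60.0, n_ai=8, n_ra=8)
        _fams, summary = run_study_comparisons(table, subjects)
        assert summary.loc["coverage:A", "RA:real_needle vs rest"] == "↗"
        assert summary.loc["duration_ms:A", "AI:imagery_right vs rest"] == "↗"

    def test_null_cohort_rarely_flags(self):
        flagged = []
        for seed in range(20):
            table, subjects = synthetic_parameter_table(seed=seed)
            _fams, summary = run_study_comparisons(table, subjects)
            cells = summary.to_numpy().ravel()
            flagged.append(np.mean(cells != "—"))
        assert np.mean(flagged) <= 0.05
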