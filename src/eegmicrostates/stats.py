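"""Group statistics for microstate parameters.

Three comparison blocks mirror the study design: a one-way ANOVA with
Tukey-Kramer post-hocs across the three imagery-arm conditions; paired
t-tests between rest and needling within the needling arm; and a two-sample
pooled-variance t-test between arms after ordinary-least-squares removal of
age, sex, and the subject's resting-state value of the same parameter.
Cohen's d accompanies every comparison, and Benjamini-Hochberg FDR is applied
within each comparison-block x parameter-panel family (coverage, occurrence,
duration, transitions), mirroring the figure-panel organisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    parameter: str
    comparison: str
    test: str
    statistic: float
    df: float
    p: float
    p_fdr: float = float("nan")
    cohens_d: float = float("nan")
    direction: int = 0  # sign of the effect


@dataclass
class ComparisonFamily:
    tag: str
    results: list[StatResult] = field(default_factory=list)

    def apply_fdr(self) -> None:
        ps = [r.p for r in self.results if np.isfinite(r.p)]
        if not ps:
            return
        adj = iter(fdr_adjust(ps))
        for r in self.results:
            if np.isfinite(r.p):
                r.p_fdr = next(adj)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def cohens_d(values_a, values_b, paired: bool = False) -> float:
    """Standardised mean difference: mean(diff)/sd(diff) when paired,
    (mean_a - mean_b)/pooled SD otherwise."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance of paired differences")
        return float(d.mean() / sd)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def paired_t(values_a, values_b, parameter: str = "", comparison: str = "") -> StatResult:
    """Two-sided paired t-test on matched observations."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need matched vectors of length >= 3")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return StatResult(parameter, comparison, "paired_t", 0.0,
                              len(d) - 1, 1.0, cohens_d=0.0)
        raise ValueError("zero variance of nonzero paired differences")
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2 * sps.t.sf(abs(t), len(d) - 1)
    return StatResult(parameter, comparison, "paired_t", float(t), len(d) - 1,
                      float(p), cohens_d=float(d.mean() / sd),
                      direction=int(np.sign(d.mean())))


def chi_square_2x2(table, parameter: str = "sex") -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("need a nonnegative 2x2 table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("both margins must be positive")
    exp = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(sps.chi2.sf(chi2, 1))
    return StatResult(parameter, "group composition", "chi_square", chi2, 1, p)


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    direction: str = "2-1", parameter: str = "",
) -> StatResult:
    """Pooled-variance two-sample t from summary statistics.

    ``direction`` fixes the sign convention: ``"2-1"`` reports
    (mean2 - mean1), ``"1-2"`` the opposite.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("need positive SDs")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    diff = (mean2 - mean1) if direction == "2-1" else (mean1 - mean2)
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult(parameter, f"summary t ({direction})", "two_sample_t",
                      float(t), df, float(p),
                      cohens_d=float(diff / np.sqrt(sp2)),
                      direction=int(np.sign(diff)))


def _two_sample_pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return float(t), float(df), float(2 * sps.t.sf(abs(t), df))


def oneway_anova_tukey(
    values: list[np.ndarray], conditions: list[str],
    parameter: str = "", alpha: float = 0.05,
) -> ComparisonFamily:
    """Omnibus one-way ANOVA; Tukey-Kramer pairwise tests when it rejects.

    The studentized-range form handles unequal group sizes (Kramer).  The
    omnibus result is always included; pairwise results only when the
    omnibus p < ``alpha``.
    """
    groups = [np.asarray(v, dtype=float) for v in values]
    if len(groups) != len(conditions):
        raise ValueError("one condition tag per group")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 observations per condition")
    if all(g.var(ddof=1) == 0 for g in groups):
        if len({g.mean() for g in groups}) == 1:
            fam = ComparisonFamily(tag=f"anova:{parameter}")
            fam.results.append(StatResult(
                parameter, " vs ".join(conditions), "oneway_anova",
                0.0, len(groups) - 1, 1.0))
            return fam
        raise ValueError("zero within-group variance everywhere")
    f, p = sps.f_oneway(*groups)
    fam = ComparisonFamily(tag=f"anova:{parameter}")
    fam.results.append(StatResult(
        parameter, " vs ".join(conditions), "oneway_anova",
        float(f), len(groups) - 1, float(p)))
    if p < alpha:
        res = sps.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                diff = groups[i].mean() - groups[j].mean()
                fam.results.append(StatResult(
                    parameter, f"{conditions[i]} vs {conditions[j]}",
                    "tukey_kramer", float(res.statistic[i, j]),
                    sum(len(g) for g in groups) - len(groups),
                    float(res.pvalue[i, j]),
                    cohens_d=cohens_d(groups[i], groups[j]),
                    direction=int(np.sign(diff))))
    return fam


def glm_adjusted_two_sample_t(
    y_a, y_b, covariates_a, covariates_b,
    covariate_names: list[str] | None = None,
    parameter: str = "", comparison: str = "",
) -> StatResult:
    """Two-sample pooled t on OLS residuals after covariate removal.

    Covariates (age, sex, resting-state value of the same parameter) are
    regressed out on the pooled sample *without* a group indicator, so a true
    group difference is not absorbed; the residuals are then compared with a
    pooled-variance t-test and Cohen's d on the residual scale.
    """
    a = np.asarray(y_a, dtype=float)
    b = np.asarray(y_b, dtype=float)
    Xa = np.atleast_2d(np.asarray(covariates_a, dtype=float))
    Xb = np.atleast_2d(np.asarray(covariates_b, dtype=float))
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 subjects per group")
    if Xa.shape[0] != len(a) or Xb.shape[0] != len(b):
        raise ValueError("one covariate row per subject")
    X = np.vstack([Xa, Xb])
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(np.concatenate([a, b]))):
        raise ValueError("covariates and responses must be complete")
    names = covariate_names or [f"x{i}" for i in range(X.shape[1])]
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        for j in range(X.shape[1]):
            sub = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"collinear covariate: {names[j]}")
        raise ValueError("collinear covariates")
    import statsmodels.api as sm

    resid = sm.OLS(np.concatenate([a, b]), design).fit().resid
    ra, rb = resid[: len(a)], resid[len(a):]
    t, df, p = _two_sample_pooled_t(ra, rb)
    return StatResult(parameter, comparison or "group A vs group B",
                      "glm_adjusted_t", t, df, p,
                      cohens_d=cohens_d(ra, rb),
                      direction=int(np.sign(ra.mean() - rb.mean())))


# ---------------------------------------------------------------------------
# Full study battery
# ---------------------------------------------------------------------------

PANELS = ("coverage", "occurrence", "duration_ms", "transition")

ARROWS = {1: "↗", -1: "↘", 0: "—"}


def _panel_params(table: pd.DataFrame, panel: str) -> list[tuple[str, str]]:
    """(display name, column or to_-column) pairs for one panel."""
    classes = sorted(table["class"].unique())
    if panel != "transition":
        return [(f"{panel}:{c}", panel) for c in classes]
    return [
        (f"transition:{a}->{b}", f"to_{b}")
        for a in classes for b in classes if a != b
    ]


def _values(table: pd.DataFrame, group: str, condition: str, cls: str,
            column: str) -> pd.Series:
    sel = table[(table["group"] == group) & (table["condition"] == condition)
                & (table["class"] == cls)]
    return sel.set_index("subject")[column]


def run_study_comparisons(
    table: pd.DataFrame,
    subjects: pd.DataFrame,
    alpha: float = 0.05,
    imagery_condition: str = "imagery_right",
) -> tuple[list[ComparisonFamily], pd.DataFrame]:
    """Run the three comparison blocks over every parameter panel.

    ``table`` is the long-format parameter table; ``subjects`` has columns
    ``subject, group, age, sex``.  Returns the FDR-corrected families and a
    sign summary (one row per parameter, arrow columns per comparison).
    """
    for g in ("AI", "RA"):
        if g not in set(table["group"]):
            raise ValueError(f"parameter table is missing group {g}")
    subjects = subjects.set_index("subject")
    families: list[ComparisonFamily] = []
    summary_rows: dict[str, dict[str, str]] = {}

    def note(param: str, comparison: str, r: StatResult | None) -> None:
        row = summary_rows.setdefault(param, {})
        if r is None or not np.isfinite(r.p_fdr) or r.p_fdr >= alpha:
            row[comparison] = ARROWS[0]
        else:
            row[comparison] = ARROWS[int(np.sign(r.direction))]

    ai_conditions = [c for c in ("rest", "imagery_left", "imagery_right")
                     if c in set(table.loc[table["group"] == "AI", "condition"])]
    # --- within imagery arm: one-way ANOVA + Tukey-Kramer ------------------
    for panel in PANELS:
        fam = ComparisonFamily(tag=f"within_AI:{panel}")
        for name, col in _panel_params(table, panel):
            cls = name.split(":")[1].split("->")[0]
            groups, tags = [], []
            for cond in ai_conditions:
                v = _values(table, "AI", cond, cls, col).dropna()
                if len(v) >= 2:
                    groups.append(v.to_numpy())
                    tags.append(cond)
            if len(groups) < 3:
                continue
            try:
                sub = oneway_anova_tukey(groups, tags, parameter=name, alpha=alpha)
            except ValueError:
                continue
            fam.results.extend(sub.results)
        # FDR over the pairwise tests of the panel
        pair = [r for r in fam.results if r.test == "tukey_kramer"]
        for r, p_adj in zip(pair, fdr_adjust([r.p for r in pair]) if pair else []):
            r.p_fdr = p_adj
        families.append(fam)
        for name, _col in _panel_params(table, panel):
            for cond in ai_conditions[1:]:
                hits = [r for r in fam.results
                        if r.parameter == name and r.test == "tukey_kramer"
                        and set(r.comparison.split(" vs ")) == {"rest", cond}]
                r = hits[0] if hits else None
                if r is not None and r.comparison.startswith("rest vs"):
                    # stored as rest - cond; the arrow reports cond - rest
                    r = StatResult(r.parameter, r.comparison, r.test,
                                   -r.statistic, r.df, r.p, r.p_fdr,
                                   -r.cohens_d, -r.direction)
                note(name, f"AI:{cond} vs rest", r)

    # --- within needling arm: paired t -------------------------------------
    for panel in PANELS:
        fam = ComparisonFamily(tag=f"within_RA:{panel}")
        for name, col in _panel_params(table, panel):
            cls = name.split(":")[1].split("->")[0]
            rest = _values(table, "RA", "rest", cls, col)
            needle = _values(table, "RA", "real_needle", cls, col)
            common = rest.index.intersection(needle.index)
            r_v, n_v = rest[common].to_numpy(), needle[common].to_numpy()
            ok = np.isfinite(r_v) & np.isfinite(n_v)
            if ok.sum() < 3:
                continue
            try:
                res = paired_t(n_v[ok], r_v[ok], parameter=name,
                               comparison="real_needle vs rest")
            except ValueError:
                continue
            fam.results.append(res)
        fam.apply_fdr()
        families.append(fam)
        for name, _col in _panel_params(table, panel):
            hits = [r for r in fam.results if r.parameter == name]
            note(name, "RA:real_needle vs rest", hits[0] if hits else None)

    # --- between arms: covariate-adjusted two-sample t ----------------------
    for panel in PANELS:
        fam = ComparisonFamily(tag=f"AI_vs_RA:{panel}")
        for name, col in _panel_params(table, panel):
            cls = name.split(":")[1].split("->")[0]
            y_ai = _values(table, "AI", imagery_condition, cls, col)
            y_ra = _values(table, "RA", "real_needle", cls, col)
            rest_ai = _values(table, "AI", "rest", cls, col)
            rest_ra = _values(table, "RA", "rest", cls, col)
            ai_ids = [s for s in y_ai.index
                      if np.isfinite(y_ai[s]) and s in rest_ai
                      and np.isfinite(rest_ai[s])]
            ra_ids = [s for s in y_ra.index
                      if np.isfinite(y_ra[s]) and s in rest_ra
                      and np.isfinite(rest_ra[s])]
            if len(ai_ids) < 3 or len(ra_ids) < 3:
                continue
            cov_ai = np.column_stack([
                subjects.loc[ai_ids, "age"], subjects.loc[ai_ids, "sex"],
                rest_ai[ai_ids]])
            cov_ra = np.column_stack([
                subjects.loc[ra_ids, "age"], subjects.loc[ra_ids, "sex"],
                rest_ra[ra_ids]])
            try:
                res = glm_adjusted_two_sample_t(
                    y_ai[ai_ids], y_ra[ra_ids], cov_ai, cov_ra,
                    covariate_names=["age", "sex", "resting_value"],
                    parameter=name,
                    comparison=f"AI:{imagery_condition} vs RA:real_needle")
            except (ValueError, np.linalg.LinAlgError):
                continue
            fam.results.append(res)
        fam.apply_fdr()
        families.append(fam)
        for name, _col in _panel_params(table, panel):
            hits = [r for r in fam.results if r.parameter == name]
            note(name, "AI_imagery vs RA_needle", hits[0] if hits else None)

    summary = pd.DataFrame.from_dict(summary_rows, orient="index").fillna(ARROWS[0])
    summary.index.name = "parameter"
    return families, summary


def results_frame(families: list[ComparisonFamily]) -> pd.DataFrame:
    """Flatten families into one tidy results table."""
    rows = []
    for fam in families:
        for r in fam.results:
            rows.append({
                "family": fam.tag, "parameter": r.parameter,
                "comparison": r.comparison, "test": r.test,
                "statistic": r.statistic, "df": r.df, "p": r.p,
                "p_fdr": r.p_fdr, "cohens_d": r.cohens_d,
                "direction": r.direction,
            })
    return pd.DataFrame(rows)
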