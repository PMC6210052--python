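"""Outcome statistics: two-sample tests, Fisher exact, Kaplan-Meier, Cox.

All tests are two-sided.  Two-sample comparisons of per-sample biomarker
means offer both the Welch t-test and the Wilcoxon rank-sum test; Fisher's
exact test covers 2x2 tables exactly (hypergeometric) and r x c tables by
seeded Monte Carlo permutation.  Survival machinery — product-limit curves,
the log-rank test, and univariate Cox regression with Efron tie handling —
delegates to lifelines.  No multiple-testing correction is applied by
default; a Benjamini-Hochberg switch is provided for marker panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleMeans",
    "sample_means",
    "compare_means",
    "fisher_exact",
    "km_logrank",
    "cox_univariate",
    "SurvivalResult",
    "NonIdentifiableError",
]

MARKERS = ("mean_her2_cn", "mean_cent17", "mean_ratio", "mean_er_intensity", "mean_her2_intensity")


class NonIdentifiableError(ValueError):
    """The Cox partial likelihood is monotone (e.g. no events in one group)."""


@dataclass(frozen=True)
class SampleMeans:
    """Per-sample biomarker means over all tumor cells of one sample.

    ``mean_her2_cn`` is the mean per-cell *HER2* probe pixel area (the
    copy-number proxy); ``mean_ratio`` averages per-cell area / cent17 over
    cells with a positive centromere count, with ``n_ratio_skipped`` cells
    excluded for missing or zero cent17.
    """

    patient_id: str
    timepoint: str
    mean_her2_cn: float
    mean_cent17: float
    mean_ratio: float
    mean_er_intensity: float
    mean_her2_intensity: float
    n_cells: int
    n_ratio_skipped: int


def sample_means(cells: pd.DataFrame) -> SampleMeans:
    """Biomarker means for the cells of one (patient, timepoint) sample."""
    if len(cells) == 0:
        raise ValueError("sample_means needs at least one cell")
    pids, tps = cells["patient_id"].unique(), cells["timepoint"].unique()
    if len(pids) > 1 or len(tps) > 1:
        raise ValueError("sample_means expects a single (patient, timepoint) sample")
    area = cells["her2_area_px"].to_numpy(float)
    cent = cells["cent17_count"].to_numpy(float)
    ok = np.isfinite(cent) & (cent > 0)
    return SampleMeans(
        patient_id=str(pids[0]),
        timepoint=str(tps[0]),
        mean_her2_cn=float(area.mean()),
        mean_cent17=float(np.nanmean(cent)) if np.isfinite(cent).any() else float("nan"),
        mean_ratio=float((area[ok] / cent[ok]).mean()) if ok.any() else float("nan"),
        mean_er_intensity=float(cells["er_intensity"].mean()),
        mean_her2_intensity=float(cells["her2_intensity"].mean()),
        n_cells=int(len(cells)),
        n_ratio_skipped=int((~ok).sum()),
    )


def sample_means_table(cells: pd.DataFrame) -> pd.DataFrame:
    """One row of biomarker means per (patient, timepoint) sample."""
    rows = [
        sample_means(grp).__dict__
        for _, grp in cells.groupby(["patient_id", "timepoint"], sort=True)
    ]
    return pd.DataFrame(rows)


def compare_means(
    means: pd.DataFrame,
    grouping: pd.Series,
    test: str = "wilcoxon",
    markers: tuple[str, ...] = MARKERS,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Two-sided two-sample test of each biomarker mean between two groups.

    ``means`` is a per-patient table (rows aligned with ``grouping``, a
    boolean Series).  ``test`` is ``"welch"`` (unequal-variance t-test;
    each group must have >= 2 patients) or ``"wilcoxon"`` (rank-sum /
    Mann-Whitney).  ``bh_correct`` adds Benjamini-Hochberg adjusted q-values
    across the marker panel.
    """
    if test not in ("welch", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    g = grouping.astype(bool).to_numpy()
    if g.all() or not g.any():
        raise ValueError("both groups must be non-empty")
    rows = []
    for m in markers:
        x = means.loc[g, m].dropna().to_numpy(float)
        y = means.loc[~g, m].dropna().to_numpy(float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"marker {m}: a group is empty")
        if test == "welch":
            if len(x) < 2 or len(y) < 2:
                raise ValueError(f"marker {m}: Welch t-test needs >= 2 per group (got {len(x)}, {len(y)})")
            stat, p = scipy.stats.ttest_ind(x, y, equal_var=False)
        else:
            stat, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"marker": m, "statistic": float(stat), "p": float(p), "n1": len(x), "n0": len(y)})
    out = pd.DataFrame(rows)
    if bh_correct:
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def fisher_exact(table: np.ndarray, n_permutations: int = 100_000, seed: int = 0) -> float:
    """Two-sided Fisher exact p-value for an r x c count table.

    2x2 tables are evaluated exactly by hypergeometric enumeration (scipy);
    larger tables use a seeded Monte Carlo generalization — tables with the
    observed margins are sampled and the fraction with probability not
    exceeding the observed table's is reported (the add-one estimator keeps
    the p-value positive and valid).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError(f"need an r x c table with r, c >= 2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has an all-zero margin")
    if t.shape == (2, 2):
        return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])
    rng = np.random.default_rng(seed)
    # probability of a table under the multivariate hypergeometric null, up to
    # the margin-only constant: -sum log(n_ij!)
    obs_stat = -scipy.special.gammaln(t + 1).sum()
    row_labels = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    col_counts = t.sum(axis=0)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(row_labels)
        sim = np.zeros_like(t)
        start = 0
        for j, c in enumerate(col_counts):
            lab, cnt = np.unique(perm[start : start + c], return_counts=True)
            sim[lab, j] = cnt
            start += c
        if -scipy.special.gammaln(sim + 1).sum() <= obs_stat + 1e-12:
            hits += 1
    return float((hits + 1) / (n_permutations + 1))


@dataclass
class SurvivalResult:
    """Survival comparison output: KM curves, log-rank test, Cox fit.

    ``km_curves`` maps group label -> stepwise survival DataFrame (index:
    time, column ``survival``, starting at 1 and non-increasing).  The Cox
    fields are filled by :func:`cox_univariate` only.
    """

    groups: tuple = ()
    km_curves: dict = field(default_factory=dict)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    cox_hr: float | None = None
    cox_ci_low: float | None = None
    cox_ci_high: float | None = None
    cox_p: float | None = None


def km_logrank(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> SurvivalResult:
    """Kaplan-Meier curves per group and the two-sided log-rank test.

    ``times`` are positive follow-up durations, ``events`` boolean event
    indicators (False = censored), ``groups`` the comparison labels (>= 2
    non-empty groups).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if (times <= 0).any():
        raise ValueError("all times must be positive")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if (counts == 0).any():
        raise ValueError("every group must contain at least one subject")
    curves = {}
    for lab in labels:
        m = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m], label=str(lab))
        curves[lab] = kmf.survival_function_.rename(columns={str(lab): "survival"})
    lr = multivariate_logrank_test(times, groups, events)
    return SurvivalResult(
        groups=tuple(labels),
        km_curves=curves,
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
    )


def cox_univariate(times: np.ndarray, events: np.ndarray, covariate: np.ndarray) -> SurvivalResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald 95% CI).

    The covariate may be continuous or binary.  Raises
    :class:`NonIdentifiableError` when the covariate is constant, no events
    occurred, or a binary covariate has all its events in one group (the
    monotone-likelihood case, where the MLE diverges).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    cov = np.asarray(covariate, dtype=float)
    if np.ptp(cov) == 0:
        raise NonIdentifiableError("covariate is constant")
    if not events.any():
        raise NonIdentifiableError("no events observed")
    uniq = np.unique(cov)
    if len(uniq) == 2:
        per_group_events = [events[cov == u].sum() for u in uniq]
        if 0 in per_group_events:
            raise NonIdentifiableError(
                "binary covariate with no events in one group: hazard ratio is not identifiable"
            )
    df = pd.DataFrame({"time": times, "event": events.astype(int), "x": cov})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["x"]
    return SurvivalResult(
        cox_hr=float(s["exp(coef)"]),
        cox_ci_low=float(s["exp(coef) lower 95%"]),
        cox_ci_high=float(s["exp(coef) upper 95%"]),
        cox_p=float(s["p"]),
    )
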