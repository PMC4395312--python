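"""Cohort-level statistics.

Implements the study's statistical policy: unpaired two-tailed Student's
t-test for normally distributed single comparisons, Mann-Whitney U
otherwise (normality gated by Shapiro-Wilk at alpha = 0.05); two-way
repeated-measures ANOVA with the genotype x time interaction as the
significance criterion for longitudinal behavior; ordinary least squares
for the scatter-index vs ladder-rung-performance relation; one-way ANOVA
across groups for per-animal PNN category fractions; and pairwise
t-tests between housing conditions for per-animal mean synapse counts.
The animal is the statistical unit throughout: neuron-level records are
averaged within animal before testing.

No multiple-testing correction is applied by default (each comparison is
reported on its own, as is conventional for this kind of cohort report);
``holm_correct`` is available for callers who want family-wise control.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError

NORMALITY_ALPHA = 0.05
EXACT_MW_MAX_N = 20  # combined sample size up to which the exact U null is used
PNN_CATEGORIES = ("none", "weak", "strong")


@dataclass
class GroupComparison:
    """One group comparison: summaries, the test used, statistic and p."""

    summaries: list                    # [{name, mean, sem, n}, ...]
    test_used: str                     # t | mann_whitney | anova_1way | rm_anova_2way | ols
    statistic: float
    p: float
    normality_p: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")

    def summary_line(self) -> str:
        parts = [
            f"{s['name']}: {s['mean']:.4g} ± {s['sem']:.3g}, N = {s['n']}"
            for s in self.summaries
        ]
        return f"{'; '.join(parts)}; {self.test_used}: p = {self.p:.4g}"


def _summary(name, values) -> dict:
    v = np.asarray(values, float)
    n = v.size
    sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return dict(name=name, mean=float(v.mean()), sem=sem, n=int(n))


def compare_groups(a, b, policy: str = "auto", names=("a", "b")) -> GroupComparison:
    """Two-group comparison under the normality-gated test policy.

    ``policy='auto'``: Shapiro-Wilk on each group at alpha = 0.05; both
    normal -> unpaired two-tailed Student's t; otherwise Mann-Whitney U
    (exact two-tailed null for combined N <= 20 without ties, normal
    approximation with tie correction above).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    summaries = [_summary(names[0], a), _summary(names[1], b)]
    notes = []

    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        notes.append("both groups constant and identical; p = 1 by convention")
        return GroupComparison(summaries, "degenerate", float("nan"), 1.0, notes=notes)

    normality = {}
    if policy == "auto":
        if a.size < 3 or b.size < 3:
            raise InsufficientDataError("auto policy needs N >= 3 per group")
        for name, v in zip(names, (a, b)):
            if np.ptp(v) == 0:
                normality[name] = 0.0  # constant sample: treat as non-normal
            else:
                normality[name] = float(sps.shapiro(v).pvalue)
        use_t = all(p > NORMALITY_ALPHA for p in normality.values())
    elif policy == "t":
        use_t = True
    elif policy == "mann_whitney":
        use_t = False
    else:
        raise ValueError(f"unknown policy {policy!r}")

    if use_t:
        res = sps.ttest_ind(a, b, equal_var=True)
        return GroupComparison(
            summaries, "t", float(res.statistic), float(res.pvalue), normality, notes
        )
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        summaries,
        "mann_whitney",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        normality,
        notes + [f"mann-whitney method: {method}"],
    )


def rm_anova_interaction(
    behavior: pd.DataFrame,
    dv: str = "crossing_time_s",
    between: str = "genotype",
    within: str = "timepoint_weeks",
    subject: str = "animal_id",
) -> GroupComparison:
    """Two-way mixed ANOVA; returns the between x within interaction.

    Subjects missing any timepoint are dropped (complete-case).  No
    sphericity correction is applied to the interaction p by default.
    """
    import pingouin as pg

    df = behavior[[subject, between, within, dv]].dropna()
    n_tp = df[within].nunique()
    complete = df.groupby(subject)[within].nunique()
    keep = complete[complete == n_tp].index
    dropped = sorted(set(df[subject]) - set(keep))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} incomplete subjects: {dropped}")
    df = df[df[subject].isin(keep)]
    cell_counts = df.groupby([between, within])[subject].nunique()
    if df.empty or cell_counts.min() < 2:
        raise InsufficientDataError("need >= 2 complete subjects per cell")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=df, dv=dv, within=within, subject=subject, between=between
        )
    inter = aov[aov["Source"] == "Interaction"].iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    summaries = [
        _summary(f"{g}@{t}wk", sub[dv].to_numpy())
        for (g, t), sub in df.groupby([between, within])
    ]
    return GroupComparison(
        summaries,
        "rm_anova_2way",
        float(inter["F"]),
        float(inter[p_col]),
        notes=["interaction term; no sphericity correction applied"],
    )


def si_behavior_regression(
    si,
    crossing_time,
    orientation: str = "si_on_time",
):
    """OLS relating scatter index and ladder-rung crossing time.

    ``orientation='si_on_time'`` (default) regresses SI on crossing time
    (slope in SI units per second); ``'time_on_si'`` swaps the roles.
    Returns (slope, slope_se, p) with a two-sided t-test of slope = 0.
    """
    si = np.asarray(si, float)
    ct = np.asarray(crossing_time, float)
    if si.size != ct.size:
        raise ValueError("si and crossing_time must have equal length")
    if si.size < 3:
        raise InsufficientDataError("regression needs >= 3 animals")
    if orientation == "si_on_time":
        x, y = ct, si
    elif orientation == "time_on_si":
        x, y = si, ct
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if np.ptp(x) == 0:
        raise InsufficientDataError("zero variance in the predictor")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.stderr), float(res.pvalue)


def category_distribution_compare(
    pnn: pd.DataFrame,
    group_cols=("housing", "genotype"),
    subject: str = "animal_id",
    category_col: str = "category",
) -> dict:
    """One-way ANOVA across groups on per-animal PNN category fractions.

    Returns {category: GroupComparison}.  Animals contribute their
    fraction of neurons in each category; groups with no neurons are
    excluded with a warning.
    """
    group_cols = list(group_cols)
    counts = (
        pnn.groupby([subject, *group_cols, category_col], observed=True)
        .size()
        .unstack(category_col, fill_value=0)
    )
    for cat in PNN_CATEGORIES:
        if cat not in counts:
            counts[cat] = 0
    totals = counts[list(PNN_CATEGORIES)].sum(axis=1)
    empty = totals[totals == 0]
    if len(empty):
        warnings.warn(f"excluding {len(empty)} animals with zero neurons")
        counts = counts[totals > 0]
        totals = totals[totals > 0]
    fractions = counts[list(PNN_CATEGORIES)].div(totals, axis=0).reset_index()
    out = {}
    for cat in PNN_CATEGORIES:
        groups = [
            (name, sub[cat].to_numpy())
            for name, sub in fractions.groupby(group_cols)
        ]
        values = [v for _, v in groups]
        if len(values) < 2:
            raise InsufficientDataError("need >= 2 groups for a one-way ANOVA")
        if np.ptp(np.concatenate(values)) == 0:
            stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = sps.f_oneway(*values)
            if np.isnan(p):  # zero within-group variance, identical means
                stat, p = 0.0, 1.0
        out[cat] = GroupComparison(
            [_summary("/".join(map(str, np.atleast_1d(n))), v) for n, v in groups],
            "anova_1way",
            float(stat),
            float(p),
        )
    return out


def synapse_compare(
    synapse: pd.DataFrame,
    subject: str = "animal_id",
    genotype_col: str = "genotype",
    housing_col: str = "housing",
) -> dict:
    """Pairwise housing-condition t-tests on per-animal mean synapse counts.

    Neuron-level counts are averaged within animal first; comparisons are
    made within genotype, separately for excitatory and inhibitory
    counts.  Returns {(genotype, housing_a, housing_b, kind): GroupComparison}.
    """
    per_animal = (
        synapse.groupby([subject, genotype_col, housing_col], observed=True)[
            ["excitatory_count", "inhibitory_count"]
        ]
        .mean()
        .reset_index()
    )
    out = {}
    for genotype, sub in per_animal.groupby(genotype_col):
        housings = sorted(sub[housing_col].unique())
        for h1, h2 in itertools.combinations(housings, 2):
            for kind in ("excitatory_count", "inhibitory_count"):
                a = sub.loc[sub[housing_col] == h1, kind].to_numpy()
                b = sub.loc[sub[housing_col] == h2, kind].to_numpy()
                if a.size < 3 or b.size < 3:
                    raise InsufficientDataError(
                        f"{genotype} {h1} vs {h2}: need >= 3 animals per group"
                    )
                if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                    out[(genotype, h1, h2, kind)] = GroupComparison(
                        [_summary(f"{genotype}/{h1}", a), _summary(f"{genotype}/{h2}", b)],
                        "degenerate",
                        0.0,
                        1.0,
                        notes=["both groups constant and identical"],
                    )
                    continue
                res = sps.ttest_ind(a, b, equal_var=True)
                out[(genotype, h1, h2, kind)] = GroupComparison(
                    [_summary(f"{genotype}/{h1}", a), _summary(f"{genotype}/{h2}", b)],
                    "t",
                    float(res.statistic),
                    float(res.pvalue),
                )
    return out


def holm_correct(pvalues):
    """Holm step-down adjusted p-values (optional; off by default everywhere)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
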