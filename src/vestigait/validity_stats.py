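"""Validity statistics: normality screening, the discriminant-validity
grid (Kruskal-Wallis with Dunn-Holm post-hocs), convergent-validity
Pearson correlations against the DHI, categorical thresholds, the
relevance synthesis, descriptive medians/IQRs, and a Monte-Carlo
Kruskal-Wallis power simulation.

A parameter/task cell is tiered ``relevant`` when it discriminates between
groups (at least moderate), correlates with the DHI (at least moderate),
and has excellent clinical applicability; ``interesting`` when both
validities hold but applicability is weaker; otherwise ``not-relevant``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .trial_io import SubjectMeta

__all__ = [
    "PAIRS",
    "ComparisonCell",
    "ConvergentCell",
    "CATEGORIES",
    "DEFAULT_APPLICABILITY",
    "shapiro_screen",
    "kruskal_wallis",
    "dunn_holm",
    "build_discriminant_grid",
    "convergent_correlations",
    "categorize",
    "category_at_least",
    "synthesize_relevance",
    "median_iqr",
    "simulate_kw_power",
]

#: Group-pair labels in display order.
PAIRS = ("BV-HS", "UV-HS", "BV-UV")

#: Validity categories from worst to best.
CATEGORIES = ("poor", "fair", "moderate", "good", "excellent")
_CAT_RANK = {c: i for i, c in enumerate(CATEGORIES)}

#: Default clinical-applicability ratings per parameter.  These encode a
#: subjective expert assessment (how easily a clinician can evaluate the
#: parameter without specialized equipment) and are meant to be edited.
DEFAULT_APPLICABILITY: dict[str, str] = {
    "ML_CoM_rom": "excellent",
    "Foot_score": "excellent",
    "Step_width": "excellent",
    "ML_step": "excellent",
    "Walking_speed": "excellent",
    "Step_number": "excellent",
    "Task_time": "excellent",
    "CoM_score": "moderate",
    "Double_support": "moderate",
    "MoS_ML": "poor",
    "MoS_AP": "poor",
    "WBAM_sag": "poor",
    "WBAM_cor": "poor",
    "WBAM_tra": "poor",
    "HeadAI_pitch": "poor",
    "HeadAI_roll": "poor",
    "HeadAI_yaw": "poor",
    "Head_AV": "poor",
    "Trunk_AV": "poor",
    "GaitSD": "poor",
}


@dataclass
class ComparisonCell:
    """Kruskal-Wallis + conditional Dunn post-hoc results for one
    task x parameter cell."""

    task: str
    parameter: str
    kw_h: float
    kw_p: float
    n: dict[str, int]
    strict_flag: bool = False  # kw_p <= 0.01
    dunn_p: dict[str, float] | None = None  # Holm-adjusted, keys PAIRS
    not_relevant: bool = False  # parameter not computed for this task


@dataclass
class ConvergentCell:
    """Pearson correlation of one parameter with the DHI in one patient
    group."""

    task: str
    parameter: str
    group: str
    r: float
    n: int


def shapiro_screen(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Shapiro-Wilk normality screen per group (report only; the pipeline
    always proceeds nonparametrically).  Groups with n < 3 or zero
    variance are flagged and skipped."""
    rows = []
    for name, values in groups.items():
        v = np.asarray(values, float)
        v = v[np.isfinite(v)]
        if len(v) < 3:
            rows.append((name, len(v), np.nan, np.nan, "skipped: n < 3"))
        elif np.ptp(v) == 0:
            rows.append((name, len(v), np.nan, np.nan, "degenerate: constant"))
        else:
            w, p = stats.shapiro(v)
            rows.append((name, len(v), w, p, ""))
    return pd.DataFrame(rows, columns=["group", "n", "W", "p", "note"])


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value
    (df = k - 1)."""
    clean = [np.asarray(g, float)[np.isfinite(np.asarray(g, float))]
             for g in groups]
    if any(len(g) < 2 for g in clean):
        return float("nan"), float("nan")
    if np.ptp(np.concatenate(clean)) == 0:  # constant data: no evidence
        return 0.0, 1.0
    h, p = stats.kruskal(*clean)
    return float(h), float(p)


def dunn_holm(
    groups: dict[str, np.ndarray],
    pairs: tuple[str, ...] = PAIRS,
    kw_p: float | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Dunn's post-hoc test with Holm correction over the group pairs.

    z-statistics are computed from the pooled ranks with tie correction;
    two-sided normal p-values are Holm-adjusted.  The test contract
    requires a significant preceding Kruskal-Wallis test; calling it with
    ``kw_p`` above ``alpha`` raises a ValueError.
    """
    if kw_p is not None and kw_p > alpha:
        raise ValueError("dunn_holm called although Kruskal-Wallis p > alpha")
    names = list(groups)
    values = [np.asarray(groups[g], float) for g in names]
    values = [v[np.isfinite(v)] for v in values]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start : start + len(v)].mean()
        start += len(v)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    raw = []
    for pair in pairs:
        a, b = pair.split("-")
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        if se == 0:
            raw.append(1.0)
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))
    adjusted = multipletests(raw, method="holm")[1]
    return {pair: float(p) for pair, p in zip(pairs, adjusted)}


def build_discriminant_grid(
    table: pd.DataFrame,
    alpha: float = 0.05,
    strict_alpha: float = 0.01,
    all_parameters: list[str] | None = None,
    all_tasks: list[str] | None = None,
) -> list[ComparisonCell]:
    """One :class:`ComparisonCell` per task x parameter of a long-form
    parameter table (columns subject, group, task, parameter, value).

    Dunn post-hocs are run only when the Kruskal-Wallis p is at or below
    ``alpha``.  Task x parameter combinations absent from the table are
    emitted as not-relevant cells.
    """
    cells = []
    tasks = all_tasks or sorted(table["task"].unique())
    params = all_parameters or sorted(table["parameter"].unique())
    finite = table[np.isfinite(table["value"].astype(float))]
    by_cell = {key: sub for key, sub in finite.groupby(["task", "parameter"])}
    for task in tasks:
        for param in params:
            sub = by_cell.get((task, param))
            if sub is None or len(sub) == 0:
                cells.append(ComparisonCell(task, param, np.nan, np.nan, {},
                                            not_relevant=True))
                continue
            groups = {
                g: sub[sub["group"] == g]["value"].to_numpy(float)
                for g in ("BV", "UV", "HS")
            }
            n = {g: len(v) for g, v in groups.items()}
            if any(len(v) < 2 for v in groups.values()):
                cells.append(ComparisonCell(task, param, np.nan, np.nan, n))
                continue
            h, p = kruskal_wallis(*groups.values())
            cell = ComparisonCell(task, param, h, p, n,
                                  strict_flag=bool(p <= strict_alpha))
            if np.isfinite(p) and p <= alpha:
                cell.dunn_p = dunn_holm(groups, kw_p=p, alpha=alpha)
            cells.append(cell)
    return cells


def convergent_correlations(
    table: pd.DataFrame,
    cohort: list[SubjectMeta],
    groups: tuple[str, ...] = ("BV", "UV"),
    min_n: int = 3,
) -> list[ConvergentCell]:
    """Pearson r between each parameter and the DHI score, per patient
    group and task.  Subjects with missing DHI are excluded pairwise; an r
    is reported only with at least ``min_n`` pairs and non-degenerate
    variance."""
    dhi = {s.subject_id: s.dhi for s in cohort}
    out = []
    for (task, param), sub in table.groupby(["task", "parameter"]):
        for group in groups:
            g = sub[sub["group"] == group]
            x, y = [], []
            for _, row in g.iterrows():
                d = dhi.get(row["subject"])
                v = float(row["value"])
                if d is not None and np.isfinite(v):
                    x.append(v)
                    y.append(float(d))
            if len(x) < min_n:
                continue
            x, y = np.asarray(x), np.asarray(y)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = float(stats.pearsonr(x, y)[0])
            out.append(ConvergentCell(task, param, group, r, len(x)))
    return out


def categorize(value: float, kind: str) -> str:
    """Map a discriminant p-value or a correlation coefficient onto the
    five validity categories.

    Discriminant: excellent p <= 0.001, good p <= 0.01, moderate
    p <= 0.05, fair p < 0.1, poor otherwise.  Correlation (on |r|):
    excellent > 0.8, good > 0.6, moderate > 0.4, fair > 0.2, poor
    otherwise.
    """
    if kind == "discriminant":
        p = float(value)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p <= 0.001:
            return "excellent"
        if p <= 0.01:
            return "good"
        if p <= 0.05:
            return "moderate"
        if p < 0.1:
            return "fair"
        return "poor"
    if kind == "correlation":
        r = abs(float(value))
        if r > 1.0 + 1e-12:
            raise ValueError(f"|r| = {r} outside [0, 1]")
        if r > 0.8:
            return "excellent"
        if r > 0.6:
            return "good"
        if r > 0.4:
            return "moderate"
        if r > 0.2:
            return "fair"
        return "poor"
    raise ValueError(f"unknown kind {kind!r}")


def category_at_least(category: str, floor: str) -> bool:
    return _CAT_RANK[category] >= _CAT_RANK[floor]


def _discriminant_p(cell: ComparisonCell) -> float:
    """The p-value feeding the discriminant category: the best Dunn
    post-hoc p when post-hocs were run, else the Kruskal-Wallis p."""
    if cell.dunn_p:
        return min(cell.dunn_p.values())
    return cell.kw_p


def synthesize_relevance(
    grid: list[ComparisonCell],
    correlations: list[ConvergentCell],
    applicability: dict[str, str] | None = None,
) -> pd.DataFrame:
    """The relevance matrix: per (task, parameter), the discriminant and
    convergent categories, the applicability rating and the final tier."""
    applicability = applicability or DEFAULT_APPLICABILITY
    best_r: dict[tuple[str, str], ConvergentCell] = {}
    for c in correlations:
        key = (c.task, c.parameter)
        if key not in best_r or abs(c.r) > abs(best_r[key].r):
            best_r[key] = c
    rows = []
    for cell in grid:
        if cell.parameter not in applicability:
            raise KeyError(
                f"no clinical-applicability entry for {cell.parameter!r}"
            )
        app = applicability[cell.parameter]
        if cell.not_relevant or not np.isfinite(cell.kw_p):
            rows.append((cell.task, cell.parameter, "NR", "NR", app,
                         "not-relevant"))
            continue
        disc = categorize(_discriminant_p(cell), "discriminant")
        conv_cell = best_r.get((cell.task, cell.parameter))
        conv = categorize(conv_cell.r, "correlation") if conv_cell else "poor"
        valid = (category_at_least(disc, "moderate")
                 and category_at_least(conv, "moderate"))
        if valid and app == "excellent":
            tier = "relevant"
        elif valid:
            tier = "interesting"
        else:
            tier = "not-relevant"
        rows.append((cell.task, cell.parameter, disc, conv, app, tier))
    return pd.DataFrame(
        rows,
        columns=["task", "parameter", "discriminant", "convergent",
                 "applicability", "tier"],
    )


def median_iqr(
    values, convention: str = "linear"
) -> tuple[float, float, float]:
    """(median, Q1, Q3) with the configured quantile convention; missing
    values dropped.  The default linear convention interpolates between
    order statistics at (n-1)*q."""
    v = np.asarray([x for x in values if x is not None], float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan"), float("nan")
    med = float(np.percentile(v, 50, method=convention))
    q1 = float(np.percentile(v, 25, method=convention))
    q3 = float(np.percentile(v, 75, method=convention))
    return med, q1, q3


def simulate_kw_power(
    group_specs: list[tuple[float, float, int]],
    alpha: float = 0.05,
    n_sim: int = 20000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the Kruskal-Wallis test.

    Groups are drawn normal with the given (mean, sd, n); the power is the
    proportion of simulated cohorts whose tie-corrected Kruskal-Wallis
    p-value is at or below ``alpha``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    for mean, sd, n in group_specs:
        if sd <= 0 or n < 2:
            raise ValueError("each group needs sd > 0 and n >= 2")
    rng = np.random.default_rng(seed)
    k = len(group_specs)
    sizes = [n for _, _, n in group_specs]
    n_total = sum(sizes)
    data = np.concatenate(
        [rng.normal(mean, sd, size=(n_sim, n)) for mean, sd, n in group_specs],
        axis=1,
    )
    ranks = stats.rankdata(data, axis=1)
    grand = (n_total + 1) / 2.0
    h = np.zeros(n_sim)
    start = 0
    for n in sizes:
        mean_rank = ranks[:, start : start + n].mean(axis=1)
        h += n * (mean_rank - grand) ** 2
        start += n
    h *= 12.0 / (n_total * (n_total + 1))
    # continuous draws: ties have probability zero, no correction needed
    p = stats.chi2.sf(h, df=k - 1)
    return float(np.mean(p <= alpha))
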