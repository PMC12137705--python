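"""Group-level characterization of structure-function coupling.

Covers four analyses: (1) repeated-measures contrasts of brain-average
coupling across conditions or measures, with marginal-mean pairwise
comparisons; (2) per-condition regional patterns -- the measure explaining
the most FC variance (R^2) per region across participants; (3) similarity of
those regional patterns between conditions, with a z-test comparing rest-task
to task-task similarity; and (4) adaptation maps quantifying how far each
task's pattern departs from the intrinsic (resting-state) pattern.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .coupling import BrainAverageCoupling, CouplingTable
from .datatypes import AnalysisConfig, ValidationError

__all__ = [
    "RMContrastResult",
    "RegionalPattern",
    "PatternSimilarityResult",
    "AdaptationMap",
    "condition_contrast",
    "best_measure_pattern",
    "pattern_similarity",
    "adaptation_maps",
]

log = logging.getLogger("couplemap")


# ---------------------------------------------------------------------------
# repeated-measures contrasts

@dataclass
class RMContrastResult:
    """One-way repeated-measures ANOVA plus pairwise marginal-mean contrasts."""

    F: float
    df1: float
    df2: float
    p: float
    sphericity_corrected: bool
    pairwise: pd.DataFrame  # columns A, B, mean_A, mean_B, t, df, p_adj
    means: pd.Series

    @property
    def significant_pairs(self) -> pd.DataFrame:
        return self.pairwise[self.pairwise["p_adj"] < 0.05]


def _pairwise_emm(
    wide: pd.DataFrame, adjust: str
) -> pd.DataFrame:
    """Paired contrasts of estimated marginal means.

    For a balanced within-participant design the marginal means are the
    condition means; each contrast is a paired t-test, adjusted either with a
    Tukey-style studentized-range correction or Bonferroni.
    """
    k = wide.shape[1]
    n = wide.shape[0]
    rows = []
    for a, b in combinations(wide.columns, 2):
        diff = wide[a].to_numpy() - wide[b].to_numpy()
        sd = diff.std(ddof=1)
        se = sd / np.sqrt(n)
        t = diff.mean() / se if se > 0 else (0.0 if diff.mean() == 0 else np.inf)
        df = n - 1
        if adjust == "tukey":
            q = abs(t) * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, k, df))
        elif adjust == "bonferroni":
            p_adj = float(min(1.0, 2.0 * stats.t.sf(abs(t), df) * (k * (k - 1) / 2)))
        else:
            raise ValueError(f"unknown pairwise adjustment {adjust!r}")
        rows.append({
            "A": a, "B": b,
            "mean_A": float(wide[a].mean()), "mean_B": float(wide[b].mean()),
            "t": float(t), "df": df, "p_adj": p_adj,
        })
    return pd.DataFrame(rows)


def condition_contrast(
    ba: BrainAverageCoupling, cfg: AnalysisConfig | None = None
) -> RMContrastResult:
    """Within-participant contrast of brain-average coupling levels.

    One-way repeated-measures ANOVA across the levels of ``ba`` (conditions
    or measures), Greenhouse-Geisser corrected when Mauchly's test indicates
    non-sphericity, followed by all pairwise marginal-mean comparisons.
    """
    cfg = cfg or AnalysisConfig()
    wide = ba.df
    k, n = wide.shape[1], wide.shape[0]
    if k < 2 or n < 3:
        raise ValidationError("need >= 2 levels and >= 3 participants")
    values = wide.to_numpy(dtype=float)
    cell_resid = values - values.mean(axis=1, keepdims=True)
    if float(np.ptp(cell_resid)) < 1e-14:
        # all levels identical within participants: F indistinguishable from 0
        warnings.warn("no within-participant variation across levels; F set to 0")
        pairwise = _pairwise_emm(wide, cfg.pairwise_adjust)
        pairwise["p_adj"] = 1.0
        return RMContrastResult(0.0, float(k - 1), float((k - 1) * (n - 1)), 1.0,
                                False, pairwise, wide.mean())
    long = wide.reset_index(names="participant").melt(
        id_vars="participant", var_name="level", value_name="value"
    )
    corrected = False
    if k > 2:
        spher = pg.sphericity(long, dv="value", within="level",
                              subject="participant")
        corrected = bool(spher.pval < 0.05)
    aov = pg.rm_anova(data=long, dv="value", within="level",
                      subject="participant", correction=corrected, detailed=False)
    row = aov.iloc[0]
    if corrected and "p_GG_corr" in aov.columns and np.isfinite(row["p_GG_corr"]):
        eps = float(row["eps"])
        F, p = float(row["F"]), float(row["p_GG_corr"])
        df1, df2 = eps * (k - 1), eps * (k - 1) * (n - 1)
    else:
        corrected = False
        F, p = float(row["F"]), float(row["p_unc"])
        df1, df2 = float(row["ddof1"]), float(row["ddof2"])
    pairwise = _pairwise_emm(wide, cfg.pairwise_adjust)
    return RMContrastResult(F, df1, df2, p, corrected, pairwise, wide.mean())


# ---------------------------------------------------------------------------
# regional best-measure patterns

@dataclass
class RegionalPattern:
    """Condition-specific group pattern of regional coupling strength.

    ``assignment`` names, per region, the measure whose squared coupling
    (R^2, variance in FC explained) is highest on group average; ``values``
    are the group-mean winning R^2 per region and ``dispersion`` their
    across-participant standard deviations.
    """

    condition: str
    values: np.ndarray
    assignment: list[str]
    dispersion: np.ndarray
    measures: list[str] = field(default_factory=list)


def best_measure_pattern(table: CouplingTable, condition: str) -> RegionalPattern:
    """Group-general region -> measure assignment by explained FC variance.

    Per region, the winner is the measure maximizing the participant-mean
    r_C^2; ties go to the earliest measure in the table's measure order (and
    are logged).
    """
    c = table.conditions.index(condition)
    r2 = table.values[:, c] ** 2  # (part, meas, region)
    mean_r2 = r2.mean(axis=0)  # (meas, region)
    winner = np.argmax(mean_r2, axis=0)
    ties = (mean_r2 == mean_r2[winner, np.arange(mean_r2.shape[1])]).sum(axis=0) > 1
    if ties.any():
        log.info("condition %s: R^2 ties in %d region(s); lowest-index measure wins",
                 condition, int(ties.sum()))
    win_r2 = r2[:, winner, np.arange(r2.shape[2])]  # (part, region)
    return RegionalPattern(
        condition=condition,
        values=win_r2.mean(axis=0),
        assignment=[table.measures[m] for m in winner],
        dispersion=win_r2.std(axis=0, ddof=1),
        measures=list(table.measures),
    )


# ---------------------------------------------------------------------------
# pattern similarity across conditions

@dataclass
class PatternSimilarityResult:
    matrix: pd.DataFrame
    rest_condition: str
    mean_rest_task_r: float
    mean_task_task_r: float
    z: float
    p: float
    significant: bool


def pattern_similarity(
    patterns: list[RegionalPattern],
    rest_condition: str = "RES",
    alpha: float = 0.05,
) -> PatternSimilarityResult:
    """Correlation of regional coupling patterns between all condition pairs.

    Also tests whether the rest pattern is less similar to task patterns than
    task patterns are to each other: a two-sample z-test on Fisher
    z-transformed correlations, using the theoretical variance 1/(N-3) of a
    transformed correlation over N regions.
    """
    if len(patterns) < 3:
        raise ValidationError("need >= 3 condition patterns")
    conds = [p.condition for p in patterns]
    if rest_condition not in conds:
        raise ValidationError(f"no pattern for rest condition {rest_condition!r}")
    vals = np.column_stack([p.values for p in patterns])
    n_regions = vals.shape[0]
    corr = np.corrcoef(vals, rowvar=False)
    matrix = pd.DataFrame(corr, index=conds, columns=conds)
    ri = conds.index(rest_condition)
    tasks = [i for i in range(len(conds)) if i != ri]
    rest_task = np.array([corr[ri, t] for t in tasks])
    task_task = np.array([corr[a, b] for a, b in combinations(tasks, 2)])
    if np.any(np.abs(np.concatenate([rest_task, task_task])) >= 1.0 - 1e-12):
        warnings.warn("degenerate (|r| = 1) pattern correlations; "
                      "rest-vs-task test reported as non-significant")
        return PatternSimilarityResult(matrix, rest_condition,
                                       float(rest_task.mean()),
                                       float(task_task.mean()),
                                       np.nan, 1.0, False)
    z_rt = np.arctanh(rest_task)
    z_tt = np.arctanh(task_task)
    se = np.sqrt((1.0 / len(z_rt) + 1.0 / len(z_tt)) / (n_regions - 3))
    z = float((z_tt.mean() - z_rt.mean()) / se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PatternSimilarityResult(matrix, rest_condition,
                                   float(rest_task.mean()),
                                   float(task_task.mean()),
                                   z, p, p < alpha)


# ---------------------------------------------------------------------------
# adaptation maps

@dataclass
class AdaptationMap:
    """Absolute regional departure of one coupling pattern from a baseline.

    ``relative_pct`` expresses a task map's mean relative to the grand mean
    over task maps of the same kind, in signed percent.
    """

    kind: str
    condition: str | None
    values: np.ndarray
    summary: float = 0.0
    relative_pct: float = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.summary = float(self.values.mean())


def adaptation_maps(
    patterns: list[RegionalPattern], rest_condition: str = "RES"
) -> dict[str, list[AdaptationMap]]:
    """Task-specific and task-general adaptation maps.

    Three kinds: per-task |rest - task| (``task_specific_vs_rest``), one
    |rest - mean over tasks| (``task_general``), and per-task
    |task - mean over remaining tasks| (``task_specific_vs_taskgeneral``,
    leave-one-task-out baseline).  For the per-task kinds, ``relative_pct``
    of task t is 100 * (mean_t - grand mean of task means) / grand mean.
    """
    by_cond = {p.condition: p for p in patterns}
    if rest_condition not in by_cond:
        raise ValidationError(f"no pattern for rest condition {rest_condition!r}")
    rest = by_cond[rest_condition].values
    task_conds = [c for c in by_cond if c != rest_condition]
    if len(task_conds) < 2:
        raise ValidationError("task-general adaptation needs >= 2 task patterns")
    task_vals = {c: by_cond[c].values for c in task_conds}

    def _with_pct(maps: list[AdaptationMap]) -> list[AdaptationMap]:
        grand = float(np.mean([m.summary for m in maps]))
        for m in maps:
            m.relative_pct = (
                100.0 * (m.summary - grand) / grand if grand > 0 else np.nan
            )
        return maps

    vs_rest = _with_pct([
        AdaptationMap("task_specific_vs_rest", c, np.abs(rest - task_vals[c]))
        for c in task_conds
    ])
    task_mean = np.mean(list(task_vals.values()), axis=0)
    general = [AdaptationMap("task_general", None, np.abs(rest - task_mean))]
    vs_general = _with_pct([
        AdaptationMap(
            "task_specific_vs_taskgeneral", c,
            np.abs(task_vals[c] - np.mean(
                [task_vals[o] for o in task_conds if o != c], axis=0)),
        )
        for c in task_conds
    ])
    return {
        "task_specific_vs_rest": vs_rest,
        "task_general": general,
        "task_specific_vs_taskgeneral": vs_general,
    }
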