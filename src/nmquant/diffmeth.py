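"""Differential methylation across conditions.

Replicate summaries (boxplot statistics), heatmap row-centering, Welch's
unequal-variance t-test, and stress-versus-control stoichiometry deltas.

"Relative increase" of methylation is reported as the arithmetic difference
of MethScore (stoichiometry points), not a ratio: responsive sites are nearly
unmethylated under control conditions, where a ratio diverges. A ratio output
is available behind ``as_ratio``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .methscore import MethScoreTable


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ConditionDesign:
    """Sample-to-condition assignment with one control condition.

    ``assignments`` maps sample_id -> (condition, replicate); ``control`` is
    the condition every delta is taken against.
    """

    assignments: Mapping[str, tuple[str, int]]
    control: str

    def __post_init__(self) -> None:
        conds = {c for c, _ in self.assignments.values()}
        if self.control not in conds:
            raise DesignError(f"control condition {self.control!r} has no samples")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c, _ in self.assignments.values():
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, (c, _) in self.assignments.items() if c == condition]

    @classmethod
    def from_table(cls, tsv_path) -> "ConditionDesign":
        """Read a design TSV ``sample_id condition replicate is_control``."""
        tab = pd.read_csv(tsv_path, sep="\t")
        controls = set(tab.loc[tab["is_control"].astype(bool), "condition"])
        if len(controls) != 1:
            raise DesignError(
                f"exactly one condition must be flagged control, got {sorted(controls)}"
            )
        return cls(
            assignments={
                r["sample_id"]: (r["condition"], int(r["replicate"]))
                for _, r in tab.iterrows()
            },
            control=controls.pop(),
        )


def row_center(scores: pd.DataFrame) -> pd.DataFrame:
    """Center each site row to its across-sample mean (heatmap normalization).

    Each entry becomes entry - row mean, NA-ignoring; NA entries stay NA.
    All-NA rows are dropped with a warning. Idempotent.
    """
    all_na = scores.isna().all(axis=1)
    if all_na.any():
        warnings.warn(
            f"dropping {int(all_na.sum())} all-NA row(s) from centered matrix",
            stacklevel=2,
        )
    kept = scores.loc[~all_na]
    return kept.sub(kept.mean(axis=1, skipna=True), axis=0)


def summarize_replicates(
    scores: pd.DataFrame, design: ConditionDesign
) -> pd.DataFrame:
    """Boxplot statistics per (site, condition).

    Returns a long table with mean, min, first/third quartile, max and n per
    site and condition. Quartiles use linear interpolation between order
    statistics — fixed explicitly because conventions differ visibly at
    n = 2-4 replicates. NA replicates are omitted from the statistics.
    """
    missing = [s for s in scores.columns if s not in design.assignments]
    if missing:
        raise DesignError(f"design does not cover samples {missing}")
    rows = []
    for cond in design.conditions:
        cols = [s for s in design.samples_of(cond) if s in scores.columns]
        block = scores[cols]
        for key, vals in block.iterrows():
            v = vals.dropna().to_numpy(dtype=float)
            if len(v) == 0:
                continue
            rows.append(
                {
                    "ref_id": key[0],
                    "position": key[1],
                    "condition": cond,
                    "mean": float(np.mean(v)),
                    "min": float(np.min(v)),
                    "q1": float(np.quantile(v, 0.25)),
                    "q3": float(np.quantile(v, 0.75)),
                    "max": float(np.max(v)),
                    "n": int(len(v)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["ref_id", "position", "condition", "mean", "min", "q1", "q3",
                 "max", "n"],
    )


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's two-tailed unequal-variance t-test.

    Returns (t, Welch-Satterthwaite df, two-tailed p). Requires n >= 2 per
    sample and a nonzero pooled variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DesignError("welch_test needs at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DesignError("degenerate samples: both variances zero")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def delta_vs_control(
    scores: pd.DataFrame,
    design: ConditionDesign,
    as_ratio: bool = False,
    with_tests: bool = False,
) -> pd.DataFrame:
    """Per-site change of each condition versus the control condition.

    delta = condition mean - control mean, in MethScore units (stoichiometry
    points). NA where the control mean is undefined at a site. With
    ``as_ratio`` the ratio of means is reported instead; with ``with_tests``
    a Welch p-value column is added where both groups have >= 2 non-NA
    replicates and non-degenerate variance.
    """
    ctrl_cols = [s for s in design.samples_of(design.control) if s in scores.columns]
    if not ctrl_cols:
        raise DesignError("no control samples present in score table")
    ctrl_mean = scores[ctrl_cols].mean(axis=1, skipna=True)

    rows = []
    for cond in design.conditions:
        if cond == design.control:
            continue
        cols = [s for s in design.samples_of(cond) if s in scores.columns]
        cond_mean = scores[cols].mean(axis=1, skipna=True)
        if as_ratio:
            delta = cond_mean / ctrl_mean
        else:
            delta = cond_mean - ctrl_mean
        for key in scores.index:
            row = {
                "ref_id": key[0],
                "position": key[1],
                "condition": cond,
                "control_mean": float(ctrl_mean.loc[key])
                if np.isfinite(ctrl_mean.loc[key])
                else np.nan,
                "condition_mean": float(cond_mean.loc[key])
                if np.isfinite(cond_mean.loc[key])
                else np.nan,
                "delta": float(delta.loc[key]) if np.isfinite(delta.loc[key]) else np.nan,
            }
            if with_tests:
                xv = scores.loc[key, cols].dropna().to_numpy(dtype=float)
                yv = scores.loc[key, ctrl_cols].dropna().to_numpy(dtype=float)
                if (
                    len(xv) >= 2
                    and len(yv) >= 2
                    and (xv.var(ddof=1) > 0 or yv.var(ddof=1) > 0)
                ):
                    _, _, p = welch_test(xv, yv)
                    row["p_welch"] = p
                else:
                    row["p_welch"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (optional screen-wide correction, off by default)."""
    p = np.asarray(pvalues, dtype=float)
    mask = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if mask.sum():
        q[mask] = stats.false_discovery_control(p[mask], method="bh")
    return q
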