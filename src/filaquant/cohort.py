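"""Condition-level aggregation and testing of cell classifications.

Per image (field of view), the filamented fraction is
``filamented / (filamented + punctuated)`` — ties and cells without
objects are excluded from numerator and denominator.  The image is the
replicate unit; condition means and s.e.m. are taken over images.
Differences between conditions are tested by one-way ANOVA with Tukey HSD
pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionSummary",
    "per_image_fractions",
    "summarize_condition",
    "one_way_anova",
    "tukey_hsd",
    "two_sample_t",
]


@dataclass
class ConditionSummary:
    condition: str
    n_images: int
    n_cells_classified: int
    per_image_fractions: list[float]
    frac_filamented: float     # mean over images
    sem: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_filamented <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")


def per_image_fractions(
    cells: pd.DataFrame, class_column: str = "d_class",
    positive: str = "filamented", negative: str = "punctuated",
) -> pd.DataFrame:
    """Per-image classified counts and filamented fraction.

    ``cells`` needs columns ``image_id``, ``condition`` and the class
    column.  Images where every cell is a tie are dropped (they carry no
    classified cells).
    """
    for col in ("image_id", "condition", class_column):
        if col not in cells.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    for (img, cond), grp in cells.groupby(["image_id", "condition"], sort=True):
        n_pos = int((grp[class_column] == positive).sum())
        n_neg = int((grp[class_column] == negative).sum())
        n_cls = n_pos + n_neg
        if n_cls == 0:
            continue  # all ties: image excluded from the replicate list
        rows.append(
            {
                "image_id": img,
                "condition": cond,
                "n_classified": n_cls,
                "fraction": n_pos / n_cls,
            }
        )
    return pd.DataFrame(rows)


def summarize_condition(
    cells: pd.DataFrame, class_column: str = "d_class",
    positive: str = "filamented", negative: str = "punctuated",
) -> list[ConditionSummary]:
    """Aggregate per-cell classifications into per-condition summaries."""
    frac = per_image_fractions(cells, class_column, positive, negative)
    out = []
    for cond, grp in frac.groupby("condition", sort=True):
        f = grp["fraction"].to_numpy()
        sem = float(np.std(f, ddof=1) / np.sqrt(f.size)) if f.size > 1 else 0.0
        out.append(
            ConditionSummary(
                condition=str(cond),
                n_images=int(f.size),
                n_cells_classified=int(grp["n_classified"].sum()),
                per_image_fractions=f.tolist(),
                frac_filamented=float(np.mean(f)),
                sem=sem,
            )
        )
    return out


def _validate_groups(groups: dict) -> dict:
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions")
    clean = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"condition {name!r} has fewer than 2 replicates")
        clean[name] = arr
    return clean


def one_way_anova(groups: dict) -> dict:
    """One-way fixed-effects ANOVA over per-image fractions by condition.

    Returns ``{"F", "p", "df_between", "df_within", "degenerate"}``.  When
    the within-group variance is exactly zero but groups differ, F is
    infinite and p is reported as 0 with ``degenerate=True`` (rather than
    NaN) so extreme synthetic inputs do not crash pipelines; identical
    groups give F = 0, p = 1.
    """
    gs = _validate_groups(groups)
    all_vals = np.concatenate(list(gs.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in gs.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in gs.values())
    df_b = len(gs) - 1
    df_w = all_vals.size - len(gs)
    if ss_within <= 0:
        if ss_between <= 0:
            return {"F": 0.0, "p": 1.0, "df_between": df_b, "df_within": df_w,
                    "degenerate": True}
        return {"F": np.inf, "p": 0.0, "df_between": df_b, "df_within": df_w,
                "degenerate": True}
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return {"F": float(f_stat), "p": p, "df_between": df_b, "df_within": df_w,
            "degenerate": False}


def tukey_hsd(groups: dict) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (family-wise adjusted p-values).

    Based on the studentised-range distribution with the pooled
    within-group variance.  Returns a table with one row per pair.
    """
    gs = _validate_groups(groups)
    names = list(gs)
    within_ss = sum(((a - a.mean()) ** 2).sum() for a in gs.values())
    res = None
    if within_ss > 0:
        res = stats.tukey_hsd(*[gs[n] for n in names])
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = float(np.mean(gs[names[i]]) - np.mean(gs[names[j]]))
            if res is not None:
                p = float(res.pvalue[i, j])
            else:
                # zero pooled variance: equal means are indistinguishable,
                # unequal means are separated with certainty
                p = 1.0 if diff == 0 else 0.0
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": diff,
                    "p_adj": p,
                }
            )
    return pd.DataFrame(rows)


def two_sample_t(a, b, equal_var: bool = True) -> dict:
    """Plain two-sample t-test (convenience wrapper)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=equal_var)
    return {"t": float(t), "p": float(p)}
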