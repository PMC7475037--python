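"""Post-processing of association summary statistics.

Wald confidence intervals for odds ratios from 2x2 counts, and family-wise
error-rate adjustment (Bonferroni or Holm) across phenotype families.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FWER_METHODS = ("bonferroni", "holm")


class ZeroCellError(ValueError):
    """A 2x2 table contains a zero cell; pass continuity=True to add +0.5 to all cells."""


def odds_ratio_ci(
    a: float,
    b: float,
    c: float,
    d: float,
    alpha: float = 0.05,
    continuity: bool = False,
) -> tuple[float, float, float]:
    """Odds ratio ad/bc with the Wald log-scale confidence interval.

    CI = exp(ln OR -/+ z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d)).
    Zero cells raise :class:`ZeroCellError` unless ``continuity`` adds 0.5
    to every cell (off by default).
    """
    counts = [a, b, c, d]
    if any(x < 0 for x in counts):
        raise ValueError("negative counts rejected")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if any(x == 0 for x in counts):
        if not continuity:
            raise ZeroCellError(
                "zero cell in 2x2 table; use continuity=True to apply the +0.5 correction"
            )
        counts = [x + 0.5 for x in counts]
    elif continuity:
        counts = [x + 0.5 for x in counts]
    a, b, c, d = counts
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(1 - alpha / 2))
    log_or = math.log(or_)
    return or_, math.exp(log_or - z * se), math.exp(log_or + z * se)


def fwer_adjust(
    p_values: Sequence[float],
    method: str = "bonferroni",
    m: int | None = None,
) -> list[float]:
    """Family-wise-error-rate adjusted p-values, order preserved.

    Bonferroni: min(1, m * p). Holm: step-down with running-max monotonicity.
    ``m`` defaults to the number of p-values and may be raised to correct for
    a larger family than was supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if method not in FWER_METHODS:
        raise ValueError(f"method must be one of {FWER_METHODS}")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValueError("family size m cannot be smaller than the number of p-values")
    if method == "bonferroni":
        adjusted = np.minimum(1.0, m * p)
    else:
        order = np.argsort(p, kind="stable")
        adj_sorted = np.minimum(1.0, (m - np.arange(len(p))) * p[order])
        adj_sorted = np.maximum.accumulate(adj_sorted)
        adjusted = np.empty_like(p)
        adjusted[order] = adj_sorted
    return [float(x) for x in adjusted]


def adjust_table(
    table: pd.DataFrame,
    family_column: str | None = "group",
    method: str = "bonferroni",
    alpha: float = 0.05,
    continuity: bool = False,
) -> pd.DataFrame:
    """Annotate an association table with OR confidence intervals and adjusted p.

    Expects columns ``phenotype_id`` and ``p``; optional 2x2 count columns
    ``a, b, c, d`` (rows with all four present get ``or``/``ci_low``/``ci_high``
    recomputed) and an optional family column for per-family adjustment.
    """
    out = table.copy()
    if "p" not in out.columns:
        raise ValueError("table must have a 'p' column of nominal p-values")
    have_counts = all(col in out.columns for col in "abcd")
    for col in ("or", "ci_low", "ci_high"):
        if col not in out.columns:
            out[col] = np.nan
    if have_counts:
        for i, row in out.iterrows():
            cells = [row[col] for col in "abcd"]
            if any(pd.isna(x) for x in cells):
                continue
            or_, lo, hi = odds_ratio_ci(*cells, alpha=alpha, continuity=continuity)
            out.loc[i, ["or", "ci_low", "ci_high"]] = [or_, lo, hi]
    if family_column is not None and family_column in out.columns:
        out["p_adjusted"] = np.nan
        for _, idx in out.groupby(family_column).groups.items():
            out.loc[idx, "p_adjusted"] = fwer_adjust(out.loc[idx, "p"].tolist(), method)
    else:
        out["p_adjusted"] = fwer_adjust(out["p"].tolist(), method)
    return out
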