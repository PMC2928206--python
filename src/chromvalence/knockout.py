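"""In-silico knockouts of marks in fitted expression models.

A knockout sets the named marks' amplitude columns to zero everywhere and
re-evaluates the model; hinge bases are re-evaluated at zero, not dropped,
so h(knot - 0) can stay positive.  Predictions are log2-scale expression, so
the per-observation log2 fold change of wild type over knockout is simply
the prediction difference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KnockoutResult",
    "knockout",
    "knockout_screen",
    "quintile_stratify",
    "site_proportion_profiles",
    "bivalent_heatmap",
    "ExpressionHeatmap",
]


@dataclass
class KnockoutResult:
    marks: tuple[int, ...]
    fold_change: np.ndarray  # per observation, WT - KO (both log2 scale)
    wt_prediction: np.ndarray
    ko_prediction: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.fold_change))

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_change))

    @property
    def quartiles(self) -> tuple[float, float, float]:
        q = np.percentile(self.fold_change, [25, 50, 75])
        return float(q[0]), float(q[1]), float(q[2])


def knockout(model, amplitudes: np.ndarray, marks: tuple[int, ...] | int
             ) -> KnockoutResult:
    """Zero out 1-2 marks and compare predictions.

    ``model`` is anything with a ``predict(amplitudes)`` method operating on
    a genes x marks array (the multilinear and MARS models both qualify).
    """
    if isinstance(marks, (int, np.integer)):
        marks = (int(marks),)
    marks = tuple(int(m) for m in marks)
    A = np.asarray(amplitudes, dtype=float)
    if not 1 <= len(marks) <= 2:
        raise ValueError("knock out 1 or 2 marks")
    for m in marks:
        if not 0 <= m < A.shape[1]:
            raise ValueError(f"unknown mark index {m}")
    wt = model.predict(A)
    ko_A = A.copy()
    ko_A[:, list(marks)] = 0.0
    ko = model.predict(ko_A)
    return KnockoutResult(marks=marks, fold_change=wt - ko,
                          wt_prediction=wt, ko_prediction=ko)


def knockout_screen(model, amplitudes: np.ndarray, pairs: bool = False,
                    mark_names: list[str] | None = None,
                    statistic: str = "median") -> pd.DataFrame:
    """Single (and optionally pairwise) knockouts ranked by log2 fold change.

    Rows are sorted ascending (most repressive first).  Both the median and
    the mean fold change are reported; ``statistic`` picks the sort key.
    """
    A = np.asarray(amplitudes, dtype=float)
    n_marks = A.shape[1]
    combos: list[tuple[int, ...]] = [(m,) for m in range(n_marks)]
    if pairs:
        combos += list(itertools.combinations(range(n_marks), 2))
    rows = []
    for combo in combos:
        res = knockout(model, A, combo)
        name = "-".join(mark_names[m] if mark_names else f"mark{m}"
                        for m in combo)
        rows.append({
            "knockout": name,
            "marks": combo,
            "n_marks": len(combo),
            "median_log2_fc": res.median,
            "mean_log2_fc": res.mean,
        })
    key = "median_log2_fc" if statistic == "median" else "mean_log2_fc"
    return (pd.DataFrame(rows)
            .sort_values(key, kind="stable")
            .reset_index(drop=True))


def quintile_assignments(fold_change: np.ndarray, n_groups: int = 5) -> np.ndarray:
    """Group observations by fold change; QU1 holds the most negative values.

    The most negative WT-KO fold changes are the genes most de-repressed by
    the knockout, so they land in the first group.  Sizes differ by at most
    one; ties at boundaries are broken by stable observation order.
    """
    fc = np.asarray(fold_change, dtype=float)
    n = fc.shape[0]
    order = np.argsort(fc, kind="stable")
    groups = np.empty(n, dtype=int)
    bounds = np.linspace(0, n, n_groups + 1).round().astype(int)
    for g in range(n_groups):
        groups[order[bounds[g]:bounds[g + 1]]] = g
    return groups


def _five_number(x: np.ndarray) -> dict:
    q = np.percentile(x, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def quintile_stratify(result: KnockoutResult, n_groups: int = 5) -> pd.DataFrame:
    """Five-number summaries of WT and KO predictions per fold-change quintile."""
    if result.fold_change.shape[0] < n_groups:
        raise ValueError("need at least one observation per quintile")
    groups = quintile_assignments(result.fold_change, n_groups)
    rows = []
    for g in range(n_groups):
        mask = groups == g
        row = {"quintile": f"QU{g + 1}", "n": int(mask.sum())}
        row.update({f"wt_{k}": v for k, v in
                    _five_number(result.wt_prediction[mask]).items()})
        row.update({f"ko_{k}": v for k, v in
                    _five_number(result.ko_prediction[mask]).items()})
        row["fc_median"] = float(np.median(result.fold_change[mask]))
        rows.append(row)
    return pd.DataFrame(rows)


def site_proportion_profiles(result: KnockoutResult,
                             significant: pd.DataFrame,
                             n_groups: int = 5) -> pd.DataFrame:
    """Per-mark proportion of significant genes within each fold-change quintile.

    ``significant`` is the genes x marks boolean flag table, in the same
    observation order used to compute the knockout.
    """
    flags = significant.to_numpy() if isinstance(significant, pd.DataFrame) else np.asarray(significant)
    if flags.shape[0] != result.fold_change.shape[0]:
        raise ValueError("significance table and knockout cover different genes")
    groups = quintile_assignments(result.fold_change, n_groups)
    cols = (list(significant.columns)
            if isinstance(significant, pd.DataFrame)
            else [f"mark{j}" for j in range(flags.shape[1])])
    out = np.empty((flags.shape[1], n_groups))
    for g in range(n_groups):
        mask = groups == g
        out[:, g] = flags[mask].mean(axis=0)
    return pd.DataFrame(out, index=cols,
                        columns=[f"QU{g + 1}" for g in range(n_groups)])


@dataclass
class ExpressionHeatmap:
    """Mean observed expression over a 2-D amplitude grid."""

    values: np.ndarray  # grid x grid, NaN where empty
    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    x_label: str
    y_label: str

    @property
    def n_cells(self) -> int:
        return int(self.values.size)


def bivalent_heatmap(amplitudes: np.ndarray, expression: np.ndarray,
                     x_mark: int, partner_mark: int, grid: int = 100,
                     mark_names: list[str] | None = None) -> ExpressionHeatmap:
    """Observed expression as a function of one amplitude and a product.

    x-axis: amplitude of ``x_mark``; y-axis: product of ``x_mark`` and
    ``partner_mark`` amplitudes.  Equal-width bins over the observed ranges;
    cells with no occupants are NaN (distinct from an observed zero).
    """
    A = np.asarray(amplitudes, dtype=float)
    y_expr = np.asarray(expression, dtype=float)
    x = A[:, x_mark]
    yv = A[:, x_mark] * A[:, partner_mark]
    x_edges = np.linspace(x.min(), x.max(), grid + 1)
    y_edges = np.linspace(yv.min(), yv.max(), grid + 1)
    xi = np.clip(np.searchsorted(x_edges, x, side="right") - 1, 0, grid - 1)
    yi = np.clip(np.searchsorted(y_edges, yv, side="right") - 1, 0, grid - 1)
    sums = np.zeros((grid, grid))
    counts = np.zeros((grid, grid))
    np.add.at(sums, (xi, yi), y_expr)
    np.add.at(counts, (xi, yi), 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    name = (lambda m: mark_names[m] if mark_names else f"mark{m}")
    return ExpressionHeatmap(
        values=values, counts=counts.astype(int),
        x_edges=x_edges, y_edges=y_edges,
        x_label=name(x_mark),
        y_label=f"{name(x_mark)}*{name(partner_mark)}",
    )
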