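"""Multivariate adaptive regression splines over mark amplitudes.

Bases are products of up to three hinge functions h(x-k)/h(k-x) on distinct
marks.  The forward pass greedily adds the hierarchy-legal (parent basis x
symmetric hinge pair) that maximally reduces the residual sum of squares;
the reverse pass prunes bases one at a time to optimize a generalized
cross-validation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HingeFactor",
    "MarsBasis",
    "MarsModel",
    "hinge",
    "forward_pass",
    "backward_pass",
    "fit_mars",
    "mars_report",
    "synergy_tables",
    "response_surface",
]


def hinge(x: np.ndarray, knot: float, direction: int = 1) -> np.ndarray:
    """max(0, x - knot) for direction +1, max(0, knot - x) for -1."""
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    return np.maximum(0.0, direction * (np.asarray(x, dtype=float) - knot))


@dataclass(frozen=True)
class HingeFactor:
    mark: int
    knot: float
    direction: int  # +1: h(x - knot); -1: h(knot - x)

    def evaluate(self, A: np.ndarray) -> np.ndarray:
        return hinge(A[:, self.mark], self.knot, self.direction)

    def describe(self, names: list[str] | None = None) -> str:
        name = names[self.mark] if names else f"x{self.mark}"
        if self.direction == 1:
            return f"h({name}-{self.knot:g})"
        return f"h({self.knot:g}-{name})"


@dataclass(frozen=True)
class MarsBasis:
    factors: tuple[HingeFactor, ...]

    def __post_init__(self) -> None:
        marks = [f.mark for f in self.factors]
        if len(set(marks)) != len(marks):
            raise ValueError("a basis may not use the same mark twice")
        if not 1 <= len(self.factors) <= 3:
            raise ValueError("basis degree must be 1-3")

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def marks(self) -> frozenset[int]:
        return frozenset(f.mark for f in self.factors)

    def evaluate(self, A: np.ndarray) -> np.ndarray:
        out = self.factors[0].evaluate(A)
        for f in self.factors[1:]:
            out = out * f.evaluate(A)
        return out

    def describe(self, names: list[str] | None = None) -> str:
        return "*".join(f.describe(names) for f in self.factors)


@dataclass
class MarsModel:
    intercept: float
    bases: list[MarsBasis]
    coefficients: np.ndarray  # one per basis
    n_obs: int
    penalty: float
    rss: float = np.nan
    gcv: float = np.nan
    mse: float = np.nan
    r2: float = np.nan
    metadata: dict = field(default_factory=dict)

    def design(self, A: np.ndarray) -> np.ndarray:
        n = np.asarray(A).shape[0]
        cols = [np.ones(n)]
        cols.extend(b.evaluate(np.asarray(A, dtype=float)) for b in self.bases)
        return np.column_stack(cols)

    def predict(self, A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        out = np.full(A.shape[0], self.intercept)
        for b, c in zip(self.bases, self.coefficients):
            out += c * b.evaluate(A)
        return out

    @property
    def n_terms(self) -> int:
        """Total terms T, intercept included."""
        return len(self.bases) + 1

    @property
    def marks_in_model(self) -> set[int]:
        return {m for b in self.bases for m in b.marks}


def effective_parameters(bases: list[MarsBasis], penalty: float) -> float:
    """enp = T + penalty * (number of distinct hinge-pair knots)."""
    knots = {(f.mark, f.knot) for b in bases for f in b.factors}
    return (len(bases) + 1) + penalty * len(knots)


def gcv_score(rss: float, n_obs: int, enp: float) -> float:
    """GCV = (RSS/N) / (1 - enp/N)^2; infinite when enp >= N."""
    if enp >= n_obs:
        return float("inf")
    return (rss / n_obs) / (1.0 - enp / n_obs) ** 2


def _knot_candidates(x: np.ndarray, max_knots: int) -> np.ndarray:
    vals = np.unique(x)
    if vals.size <= max_knots:
        return vals
    qs = np.linspace(0.0, 1.0, max_knots)
    return np.unique(np.quantile(vals, qs, method="nearest"))


def _pair_rss_reduction(Hp: np.ndarray, Hm: np.ndarray, Q: np.ndarray,
                        resid: np.ndarray) -> np.ndarray:
    """RSS reduction from jointly adding each (h+, h-) column pair.

    Hp/Hm are n x K matrices of candidate columns (one per knot), already
    multiplied by the parent basis.  Columns are residualized against the
    current orthonormal basis Q and the 2x2 normal equations solved per knot.
    """
    Hp = Hp - Q @ (Q.T @ Hp)
    Hm = Hm - Q @ (Q.T @ Hm)
    a = np.einsum("ij,ij->j", Hp, Hp)
    c = np.einsum("ij,ij->j", Hm, Hm)
    b = np.einsum("ij,ij->j", Hp, Hm)
    u = Hp.T @ resid
    v = Hm.T @ resid
    det = a * c - b * b
    scale = np.maximum(a * c, 1e-30)
    singular = det <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        joint = (c * u * u - 2.0 * b * u * v + a * v * v) / det
        only_p = np.where(a > 1e-12, u * u / a, 0.0)
        only_m = np.where(c > 1e-12, v * v / c, 0.0)
    red = np.where(singular, np.maximum(only_p, only_m), joint)
    return np.maximum(red, 0.0)


def forward_pass(
    amplitudes: np.ndarray,
    y: np.ndarray,
    max_degree: int = 3,
    max_terms: int = 61,
    min_rss_reduction: float | None = None,
    max_knots: int = 100,
    penalty: float = 3.0,
) -> MarsModel:
    """Greedy forward pass; returns the (deliberately overfit) model.

    Starts from the intercept (the response mean).  Each step multiplies an
    existing basis (or the intercept) by a symmetric hinge pair on a mark not
    already in that basis, keeping the candidate with the largest RSS
    reduction.  Bivalent bases must extend a monovalent basis in the model,
    trivalent ones a bivalent basis.  Stops at ``max_terms`` total terms or
    when the best reduction falls below ``min_rss_reduction`` (default
    1e-4 x initial RSS).
    """
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    A = np.asarray(amplitudes, dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_marks = A.shape
    for j in range(n_marks):
        if np.unique(A[:, j]).size < 2:
            raise ValueError(f"mark {j} has fewer than 2 distinct values")
    knots = [_knot_candidates(A[:, j], max_knots) for j in range(n_marks)]
    hinge_cache = {}  # (mark) -> (n x K h+, n x K h-)
    for j in range(n_marks):
        k = knots[j]
        x = A[:, j][:, None]
        hinge_cache[j] = (np.maximum(0.0, x - k[None, :]),
                          np.maximum(0.0, k[None, :] - x))

    rss0 = float(np.sum((y - y.mean()) ** 2))
    threshold = min_rss_reduction if min_rss_reduction is not None else 1e-4 * rss0

    bases: list[MarsBasis] = []
    B = np.ones((n, 1))
    while len(bases) + 1 < max_terms:
        Q, _ = np.linalg.qr(B)
        resid = y - Q @ (Q.T @ y)
        rss = float(resid @ resid)
        if rss <= max(1e-12 * rss0, 1e-12):
            break
        # parents: the intercept plus any basis below max degree
        parents: list[tuple[MarsBasis | None, np.ndarray]] = [(None, np.ones(n))]
        for b, col in zip(bases, B[:, 1:].T):
            if b.degree < max_degree:
                parents.append((b, col))
        best = None  # (reduction, parent, mark, knot)
        for parent, pcol in parents:
            used = parent.marks if parent else frozenset()
            for j in range(n_marks):
                if j in used:
                    continue
                Hp, Hm = hinge_cache[j]
                if parent is None:
                    Hpj, Hmj = Hp, Hm
                else:
                    Hpj = Hp * pcol[:, None]
                    Hmj = Hm * pcol[:, None]
                red = _pair_rss_reduction(Hpj, Hmj, Q, resid)
                i = int(np.argmax(red))
                if best is None or red[i] > best[0] + 1e-12:
                    best = (float(red[i]), parent, j, float(knots[j][i]))
        if best is None or best[0] < threshold:
            break
        _, parent, j, knot = best
        # adding a pair must leave the model prunable (enp < N)
        if effective_parameters(bases, penalty) + 2 + penalty >= n:
            break
        fp = HingeFactor(j, knot, 1)
        fm = HingeFactor(j, knot, -1)
        pf = parent.factors if parent else ()
        b1, b2 = MarsBasis(pf + (fp,)), MarsBasis(pf + (fm,))
        bases.extend([b1, b2])
        B = np.column_stack([B, b1.evaluate(A), b2.evaluate(A)])
        if len(bases) + 1 >= max_terms:
            break

    beta, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    pred = B @ beta
    rss = float(np.sum((y - pred) ** 2))
    enp = effective_parameters(bases, penalty)
    model = MarsModel(
        intercept=float(beta[0]),
        bases=bases,
        coefficients=beta[1:],
        n_obs=n,
        penalty=penalty,
        rss=rss,
        gcv=gcv_score(rss, n, enp),
        mse=rss / n,
        r2=1.0 - rss / rss0 if rss0 > 0 else 0.0,
        metadata={"max_degree": max_degree, "max_terms": max_terms,
                  "max_knots": max_knots,
                  "min_rss_reduction": threshold,
                  "enp_formula": "T + penalty * n_distinct_knots"},
    )
    return model


def _refit(A: np.ndarray, y: np.ndarray, bases: list[MarsBasis],
           penalty: float) -> tuple[np.ndarray, float, float]:
    n = A.shape[0]
    cols = [np.ones(n)] + [b.evaluate(A) for b in bases]
    B = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    rss = float(np.sum((y - B @ beta) ** 2))
    gcv = gcv_score(rss, n, effective_parameters(bases, penalty))
    return beta, rss, gcv


def backward_pass(model: MarsModel, amplitudes: np.ndarray, y: np.ndarray,
                  penalty: float | None = None) -> MarsModel:
    """Prune bases one at a time, keeping the best-GCV subset encountered.

    Individual members of a hinge pair may be deleted separately.  Raises if
    even the full model has enp >= number of observations.
    """
    A = np.asarray(amplitudes, dtype=float)
    y = np.asarray(y, dtype=float)
    penalty = model.penalty if penalty is None else penalty
    n = A.shape[0]
    if effective_parameters(model.bases, penalty) >= n:
        raise ValueError("model oversized: effective parameters >= observations")

    current = list(model.bases)
    beta, rss, gcv = _refit(A, y, current, penalty)
    best_subset, best_beta, best_rss, best_gcv = list(current), beta, rss, gcv
    while current:
        trial_best = None
        for i in range(len(current)):
            subset = current[:i] + current[i + 1 :]
            b, r, g = _refit(A, y, subset, penalty)
            if trial_best is None or g < trial_best[3]:
                trial_best = (subset, b, r, g)
        current = trial_best[0]
        if trial_best[3] <= best_gcv:
            best_subset, best_beta, best_rss, best_gcv = trial_best
    rss0 = float(np.sum((y - y.mean()) ** 2))
    return MarsModel(
        intercept=float(best_beta[0]),
        bases=best_subset,
        coefficients=best_beta[1:],
        n_obs=n,
        penalty=penalty,
        rss=best_rss,
        gcv=best_gcv,
        mse=best_rss / n,
        r2=1.0 - best_rss / rss0 if rss0 > 0 else 0.0,
        metadata={**model.metadata, "pruned": True},
    )


def fit_mars(
    amplitudes: np.ndarray,
    y: np.ndarray,
    max_degree: int = 3,
    max_terms: int = 61,
    min_rss_reduction: float | None = None,
    max_knots: int = 100,
    penalty: float = 3.0,
) -> MarsModel:
    """Forward pass followed by GCV pruning."""
    fwd = forward_pass(amplitudes, y, max_degree=max_degree,
                       max_terms=max_terms,
                       min_rss_reduction=min_rss_reduction,
                       max_knots=max_knots, penalty=penalty)
    return backward_pass(fwd, amplitudes, y, penalty=penalty)


def mars_report(model: MarsModel, amplitudes: np.ndarray,
                mark_names: list[str] | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-basis table and per-mark 95th-vs-5th-percentile impact table."""
    A = np.asarray(amplitudes, dtype=float)
    rows = [{"coefficient": model.intercept, "basis": "1",
             "n_nonzero": A.shape[0], "degree": 0}]
    for b, c in zip(model.bases, model.coefficients):
        vals = b.evaluate(A)
        rows.append({"coefficient": float(c), "basis": b.describe(mark_names),
                     "n_nonzero": int(np.count_nonzero(vals)),
                     "degree": b.degree})
    basis_table = pd.DataFrame(rows)

    med = np.median(A, axis=0)
    lo = np.percentile(A, 5, axis=0)
    hi = np.percentile(A, 95, axis=0)
    impact_rows = []
    for j in sorted(model.marks_in_model):
        at_hi, at_lo = med.copy(), med.copy()
        at_hi[j], at_lo[j] = hi[j], lo[j]
        impact = float(model.predict(at_hi[None, :])[0]
                       - model.predict(at_lo[None, :])[0])
        impact_rows.append({
            "mark": mark_names[j] if mark_names else f"mark{j}",
            "mark_index": j,
            "impact": impact,
        })
    for j in range(A.shape[1]):
        if j not in model.marks_in_model:
            impact_rows.append({
                "mark": mark_names[j] if mark_names else f"mark{j}",
                "mark_index": j, "impact": 0.0,
            })
    impact_table = (pd.DataFrame(impact_rows)
                    .sort_values("impact").reset_index(drop=True))
    return basis_table, impact_table


def synergy_tables(model: MarsModel, amplitudes: np.ndarray,
                   term_marks: tuple[int, ...],
                   mark_names: list[str] | None = None) -> pd.DataFrame:
    """Predictions at every low/high (5th/95th pct) corner of a mark set."""
    A = np.asarray(amplitudes, dtype=float)
    if not 2 <= len(term_marks) <= 3:
        raise ValueError("term_marks must name 2 or 3 marks")
    for m in term_marks:
        if m not in model.marks_in_model:
            raise ValueError(f"mark {m} does not appear in the model")
    med = np.median(A, axis=0)
    lo = np.percentile(A, 5, axis=0)
    hi = np.percentile(A, 95, axis=0)
    rows = []
    for combo in np.ndindex(*([2] * len(term_marks))):
        point = med.copy()
        for m, level in zip(term_marks, combo):
            point[m] = hi[m] if level else lo[m]
        label = "-".join("high" if level else "low" for level in combo)
        rows.append({"levels": label,
                     "prediction": float(model.predict(point[None, :])[0])})
    out = pd.DataFrame(rows)
    out.attrs["marks"] = [mark_names[m] if mark_names else f"mark{m}"
                          for m in term_marks]
    return out


def response_surface(model: MarsModel, amplitudes: np.ndarray,
                     marks: tuple[int, ...], grid_size: int = 50) -> pd.DataFrame:
    """Prediction grid over 1 or 2 marks' observed ranges, others at median."""
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if not 1 <= len(marks) <= 2:
        raise ValueError("marks must name 1 or 2 marks")
    A = np.asarray(amplitudes, dtype=float)
    med = np.median(A, axis=0)
    axes = [np.linspace(A[:, m].min(), A[:, m].max(), grid_size) for m in marks]
    if len(marks) == 1:
        pts = np.tile(med, (grid_size, 1))
        pts[:, marks[0]] = axes[0]
        return pd.DataFrame({"x": axes[0], "prediction": model.predict(pts)})
    gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
    pts = np.tile(med, (grid_size * grid_size, 1))
    pts[:, marks[0]] = gx.ravel()
    pts[:, marks[1]] = gy.ravel()
    return pd.DataFrame({"x": gx.ravel(), "y": gy.ravel(),
                         "prediction": model.predict(pts)})
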