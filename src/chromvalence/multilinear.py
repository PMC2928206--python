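"""Multivalent stepwise multilinear regression of expression on amplitudes.

Candidate regressors are products of one, two or three distinct mark
amplitudes.  Model search is the classic stepwise loop (forward partial-F
entry at alpha <= 0.05, backward removal at alpha > 0.05) wrapped in the
multi-round protocol: many randomly seeded runs on the full data filtered by
a term-survival cutoff, then 10-fold cross validation with a backward-only
pass on each fold's test data, per-fold best-model selection by test MSE,
retention voting across folds, and trimmed-mean coefficients.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "Term",
    "canonical_term",
    "enumerate_terms",
    "build_design",
    "StepwiseFit",
    "stepwise_fit",
    "round1_survival",
    "FinalMLModel",
    "cv_protocol",
    "term_statistics",
]

Term = tuple[int, ...]

_ALIAS_TOL = 1e-9


def canonical_term(marks) -> Term:
    """Sorted tuple of distinct mark indices (term identity is order-free)."""
    t = tuple(sorted(int(m) for m in marks))
    if not 1 <= len(t) <= 3:
        raise ValueError(f"term must have 1-3 marks, got {marks!r}")
    if len(set(t)) != len(t):
        raise ValueError(f"term has repeated marks: {marks!r}")
    return t


def enumerate_terms(n_marks: int, max_valency: int = 3) -> list[Term]:
    """All C(n,1)+...+C(n,max_valency) canonical terms in deterministic order."""
    if n_marks < 1:
        raise ValueError("n_marks must be >= 1")
    if not 1 <= max_valency <= 3:
        raise ValueError("max_valency must be in 1..3")
    if n_marks < max_valency:
        raise ValueError("n_marks must be >= max_valency")
    terms: list[Term] = []
    for v in range(1, max_valency + 1):
        terms.extend(itertools.combinations(range(n_marks), v))
    return terms


def build_design(amplitudes: np.ndarray, terms: list[Term]) -> np.ndarray:
    """Observations x terms matrix of amplitude products."""
    A = np.asarray(amplitudes, dtype=float)
    cols = np.empty((A.shape[0], len(terms)))
    for i, term in enumerate(terms):
        cols[:, i] = A[:, list(term)].prod(axis=1)
    return cols


@dataclass
class StepwiseFit:
    terms: list[Term]
    beta: np.ndarray  # intercept first, then one per term
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    mse: float
    adj_r2: float
    df_resid: int


def _ols_stats(X: np.ndarray, y: np.ndarray):
    """OLS with intercept prepended; returns beta, se, t, p, sse, df."""
    n = X.shape[0]
    X1 = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    sse = float(resid @ resid)
    df = n - X1.shape[1]
    sigma2 = sse / df if df > 0 else np.nan
    xtx = X1.T @ X1
    try:
        cov = np.linalg.inv(xtx) * sigma2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(X1.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * _stats.t.sf(np.abs(t), df) if df > 0 else np.ones_like(t)
    return beta, se, t, p, sse, df


def _forward_scan(Q: np.ndarray, resid: np.ndarray, sse: float,
                  C: np.ndarray, n: int, p_cur: int):
    """Partial-F p-values of each excluded column given the current basis Q."""
    Cp = C - Q @ (Q.T @ C)
    cn = np.einsum("ij,ij->j", Cp, Cp)
    base = np.einsum("ij,ij->j", C, C)
    valid = cn > _ALIAS_TOL * np.maximum(base, 1.0)
    proj = Cp.T @ resid
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.where(valid, proj**2 / np.where(valid, cn, 1.0), 0.0)
    sse_new = np.maximum(sse - num, 0.0)
    df = n - p_cur - 1
    if df <= 0:
        return np.ones(C.shape[1]), np.zeros(C.shape[1]), valid
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(sse_new > 0, num / (sse_new / df), np.inf)
    pvals = np.where(valid, _stats.f.sf(F, 1, df), 1.0)
    return pvals, F, valid


def _stepwise_select(
    Xc: np.ndarray,
    y: np.ndarray,
    candidates: list[int],
    initial: list[int],
    alpha_enter: float,
    alpha_remove: float,
    max_cycles: int = 200,
) -> list[int]:
    """Run the forward/backward loop; returns included column indices of Xc."""
    n = y.shape[0]
    included = [c for c in dict.fromkeys(initial) if c in set(candidates)]
    cand_set = list(dict.fromkeys(candidates))

    # drop aliased initial columns up front
    if included:
        X0 = np.column_stack([np.ones(n), Xc[:, included]])
        _, R = np.linalg.qr(X0)
        diag = np.abs(np.diag(R))
        keep = diag > _ALIAS_TOL * max(diag.max(), 1.0)
        if not keep.all():
            warnings.warn("dropping aliased initial columns", stacklevel=3)
            included = [c for c, k in zip(included, keep[1:]) if k]

    # an initial model must itself pass the backward test, so start there
    for _ in range(max_cycles):
        changed = False
        # backward: strip insignificant terms, worst first
        while included:
            _, _, _, p, _, _ = _ols_stats(Xc[:, included], y)
            p_terms = p[1:]
            worst = int(np.nanargmax(p_terms))
            if p_terms[worst] > alpha_remove or np.isnan(p_terms[worst]):
                included.pop(worst)
                changed = True
            else:
                break
        # forward: add the most significant excluded candidate
        while True:
            excluded = [c for c in cand_set if c not in set(included)]
            if not excluded:
                break
            X = np.column_stack([np.ones(n), Xc[:, included]]) if included else np.ones((n, 1))
            Q, _ = np.linalg.qr(X)
            resid = y - Q @ (Q.T @ y)
            sse = float(resid @ resid)
            pvals, F, valid = _forward_scan(Q, resid, sse, Xc[:, excluded], n, X.shape[1])
            # ties: smaller p, then larger F, then canonical order
            order = np.lexsort((np.arange(len(excluded)), -F, pvals))
            best = order[0]
            if valid[best] and pvals[best] <= alpha_enter:
                included.append(excluded[best])
                changed = True
            else:
                break
        if not changed:
            break
    return included


def stepwise_fit(
    design: np.ndarray,
    y: np.ndarray,
    candidate_terms: list[Term],
    initial_terms: list[Term] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
) -> StepwiseFit:
    """Stepwise selection over ``candidate_terms`` columns of ``design``.

    ``design`` has one column per candidate term (same order).  Returns the
    converged model: every included term significant at ``alpha_remove`` and
    no excluded candidate enterable at ``alpha_enter``; intercept always
    included.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    initial_terms = initial_terms or []
    if n <= len(initial_terms) + 2:
        raise ValueError("need more observations than initial terms + 2")
    index = {t: i for i, t in enumerate(candidate_terms)}
    init_idx = [index[canonical_term(t)] for t in initial_terms]
    included = _stepwise_select(
        design, y, list(range(len(candidate_terms))), init_idx,
        alpha_enter, alpha_remove,
    )
    terms = [candidate_terms[i] for i in included]
    beta, se, t, p, sse, df = _ols_stats(design[:, included], y)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df if df > 0 else np.nan
    return StepwiseFit(terms=terms, beta=beta, se=se, z=t, p=p,
                       mse=sse / n, adj_r2=adj, df_resid=df)


def round1_survival(
    design: np.ndarray,
    y: np.ndarray,
    candidate_terms: list[Term],
    n_runs: int = 100,
    cutoff: float = 0.35,
    n_initial: int = 30,
    seed: int = 0,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
) -> tuple[pd.Series, list[Term]]:
    """Survival rates of terms over randomly seeded full-data stepwise runs.

    Each run starts from a random subset of ``n_initial`` candidate terms;
    the survival rate of a term is the fraction of converged models that
    contain it.  Terms at or above ``cutoff`` survive to the next round.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n_cand = len(candidate_terms)
    counts = np.zeros(n_cand)
    all_idx = list(range(n_cand))
    for _ in range(n_runs):
        init = list(rng.choice(n_cand, size=min(n_initial, n_cand), replace=False))
        included = _stepwise_select(design, y, all_idx, [int(i) for i in init],
                                    alpha_enter, alpha_remove)
        counts[included] += 1
    rates = pd.Series(counts / n_runs,
                      index=[str(t) for t in candidate_terms], name="survival")
    surviving = [candidate_terms[i] for i in range(n_cand)
                 if counts[i] / n_runs >= cutoff]
    return rates, surviving


@dataclass
class FinalMLModel:
    """Retained terms with trimmed-mean coefficients and fold diagnostics."""

    terms: list[Term]
    intercept: float
    beta: np.ndarray  # one per term
    fold_betas: np.ndarray  # folds x (1 + terms), intercept first
    fold_z: np.ndarray
    fold_p: np.ndarray
    train_mse: np.ndarray
    test_mse: np.ndarray
    train_adj_r2: np.ndarray
    test_adj_r2: np.ndarray
    n_marks: int
    metadata: dict = field(default_factory=dict)

    def predict(self, amplitudes: np.ndarray) -> np.ndarray:
        A = np.asarray(amplitudes, dtype=float)
        if A.shape[1] != self.n_marks:
            raise ValueError(f"expected {self.n_marks} marks, got {A.shape[1]}")
        if not self.terms:
            return np.full(A.shape[0], self.intercept)
        return self.intercept + build_design(A, self.terms) @ self.beta

    @property
    def marks_in_model(self) -> set[int]:
        return {m for t in self.terms for m in t}


def trimmed_mean(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean after dropping the single min and max along ``axis``."""
    v = np.sort(np.asarray(values, dtype=float), axis=axis)
    if v.shape[axis] <= 2:
        return v.mean(axis=axis)
    sl = [slice(None)] * v.ndim
    sl[axis] = slice(1, -1)
    return v[tuple(sl)].mean(axis=axis)


def _adj_r2(y: np.ndarray, pred: np.ndarray, n_params: int) -> float:
    n = y.shape[0]
    sse = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0 or n - n_params <= 0:
        return np.nan
    return 1.0 - (sse / (n - n_params)) / (tss / (n - 1))


def _backward_only(Xc: np.ndarray, y: np.ndarray, included: list[int],
                   alpha_remove: float) -> list[int]:
    included = list(included)
    while included:
        _, _, _, p, _, _ = _ols_stats(Xc[:, included], y)
        p_terms = p[1:]
        worst = int(np.nanargmax(p_terms))
        if p_terms[worst] > alpha_remove or np.isnan(p_terms[worst]):
            included.pop(worst)
        else:
            break
    return included


def cv_protocol(
    amplitudes: np.ndarray,
    y: np.ndarray,
    starting_terms: list[Term],
    candidate_terms: list[Term] | None = None,
    gene_ids: np.ndarray | None = None,
    n_folds: int = 10,
    runs_per_fold: int = 10,
    extra_random_terms: int = 60,
    retention: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> FinalMLModel:
    """Cross-validated stepwise protocol producing the final multilinear model.

    Per fold, ``runs_per_fold`` stepwise fits start from ``starting_terms``
    plus extra random candidates; surviving terms are pruned by a
    backward-only pass on the fold's test data and the lowest-test-MSE model
    is kept.  Terms present in >= ``retention`` of the kept models form the
    final term set, refit per fold; coefficients are trimmed means across
    folds.  Fold assignment is by gene to prevent probe-level leakage.
    """
    A = np.asarray(amplitudes, dtype=float)
    y = np.asarray(y, dtype=float)
    n_obs, n_marks = A.shape
    candidate_terms = candidate_terms or enumerate_terms(
        n_marks, min(3, n_marks))
    candidate_terms = [canonical_term(t) for t in candidate_terms]
    starting_terms = [canonical_term(t) for t in starting_terms]
    index = {t: i for i, t in enumerate(candidate_terms)}
    start_idx = [index[t] for t in starting_terms]
    if n_obs / max(len(starting_terms) + extra_random_terms, 1) < 10:
        warnings.warn("fewer than 10 observations per candidate term",
                      stacklevel=2)

    Xc = build_design(A, candidate_terms)
    rng = np.random.default_rng(seed)

    # fold assignment by gene
    if gene_ids is None:
        gene_ids = np.arange(n_obs)
    gene_ids = np.asarray(gene_ids)
    unique_genes = pd.unique(gene_ids)
    perm = rng.permutation(len(unique_genes))
    fold_of_gene = dict(zip(unique_genes[perm],
                            np.arange(len(unique_genes)) % n_folds))
    fold_assign = np.array([fold_of_gene[g] for g in gene_ids])

    all_idx = list(range(len(candidate_terms)))
    kept_models: list[list[int]] = []
    for fold in range(n_folds):
        test = fold_assign == fold
        train = ~test
        if train.sum() <= len(start_idx) + 2 or test.sum() < 3:
            raise ValueError(f"fold {fold} too small to fit the model")
        best_terms, best_mse = None, np.inf
        for _ in range(runs_per_fold):
            pool = [i for i in all_idx if i not in set(start_idx)]
            n_extra = min(extra_random_terms, len(pool))
            extra = list(rng.choice(pool, size=n_extra, replace=False)) if n_extra else []
            init = start_idx + [int(i) for i in extra]
            included = _stepwise_select(Xc[train], y[train], all_idx, init,
                                        alpha, alpha)
            included = _backward_only(Xc[test], y[test], included, alpha)
            # refit coefficients on train, score on test
            beta, *_ = _ols_stats(Xc[np.ix_(train, included)], y[train]) if included else _ols_stats(np.empty((int(train.sum()), 0)), y[train])
            X_test = np.column_stack([np.ones(int(test.sum())), Xc[np.ix_(test, included)]])
            mse = float(np.mean((y[test] - X_test @ beta) ** 2))
            if mse < best_mse:
                best_mse, best_terms = mse, included
        kept_models.append(best_terms or [])

    votes = pd.Series([i for m in kept_models for i in set(m)]).value_counts()
    retained_idx = sorted(int(i) for i, v in votes.items() if v >= retention)
    terms = [candidate_terms[i] for i in retained_idx]

    n_coef = len(retained_idx) + 1
    fold_betas = np.zeros((n_folds, n_coef))
    fold_z = np.zeros((n_folds, n_coef))
    fold_p = np.ones((n_folds, n_coef))
    train_mse = np.zeros(n_folds)
    test_mse = np.zeros(n_folds)
    train_r2 = np.zeros(n_folds)
    test_r2 = np.zeros(n_folds)
    for fold in range(n_folds):
        test = fold_assign == fold
        train = ~test
        X_tr = Xc[np.ix_(train, retained_idx)]
        beta, se, t, p, sse, df = _ols_stats(X_tr, y[train])
        fold_betas[fold] = beta
        fold_z[fold] = t
        fold_p[fold] = p
        pred_tr = np.column_stack([np.ones(int(train.sum())), X_tr]) @ beta
        X_te = np.column_stack([np.ones(int(test.sum())), Xc[np.ix_(test, retained_idx)]])
        pred_te = X_te @ beta
        train_mse[fold] = float(np.mean((y[train] - pred_tr) ** 2))
        test_mse[fold] = float(np.mean((y[test] - pred_te) ** 2))
        train_r2[fold] = _adj_r2(y[train], pred_tr, n_coef)
        test_r2[fold] = _adj_r2(y[test], pred_te, n_coef)

    final_beta = trimmed_mean(fold_betas, axis=0)
    return FinalMLModel(
        terms=terms,
        intercept=float(final_beta[0]),
        beta=final_beta[1:],
        fold_betas=fold_betas,
        fold_z=fold_z,
        fold_p=fold_p,
        train_mse=train_mse,
        test_mse=test_mse,
        train_adj_r2=train_r2,
        test_adj_r2=test_r2,
        n_marks=n_marks,
        metadata={
            "n_folds": n_folds,
            "runs_per_fold": runs_per_fold,
            "retention": retention,
            "extra_random_terms": extra_random_terms,
            "seed": seed,
            "kept_model_reading": "one lowest-test-MSE model per fold; "
                                  "retention counted across folds",
            "trim_rule": "drop single min and max across folds",
        },
    )


def term_statistics(
    model: FinalMLModel,
    amplitudes: np.ndarray,
    mark_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-term trimmed-mean beta/Z, median p, and IQR impact, sorted by impact.

    Impact = trimmed-mean beta times the inter-quartile range of the term's
    regressor column; positive impact labels a term activating, negative
    repressing.
    """
    A = np.asarray(amplitudes, dtype=float)
    rows = []
    if model.terms:
        X = build_design(A, model.terms)
        iqr = np.subtract(*np.percentile(X, [75, 25], axis=0))
    z_tm = trimmed_mean(model.fold_z, axis=0)
    p_med = np.median(model.fold_p, axis=0)

    def term_name(t: Term) -> str:
        if mark_names:
            return " - ".join(mark_names[m] for m in t)
        return " - ".join(f"mark{m}" for m in t)

    for i, t in enumerate(model.terms):
        beta = float(model.beta[i])
        impact = beta * float(iqr[i])
        rows.append({
            "term": term_name(t),
            "marks": t,
            "valency": len(t),
            "beta": beta,
            "z": float(z_tm[i + 1]),
            "p": float(p_med[i + 1]),
            "impact": impact,
            "label": "a" if impact > 0 else ("r" if impact < 0 else "-"),
        })
    rows.append({
        "term": "Intercept", "marks": (), "valency": 0,
        "beta": model.intercept, "z": float(z_tm[0]), "p": float(p_med[0]),
        "impact": 0.0, "label": "-",
    })
    out = pd.DataFrame(rows).sort_values("impact", ascending=False,
                                         kind="stable")
    return out.reset_index(drop=True)
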