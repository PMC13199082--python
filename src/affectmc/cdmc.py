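"""Covariate-dependent Markov chain (CDMC) model of valence transitions.

The model treats the next emotional state ``X_{t+1}`` as multinomial given
the current state context (order 1: ``X_t``; order 2: ``(X_{t-1}, X_t)``)
and the quality ``Z_t`` of the intervening AI response::

    P(X_{t+1} = j | context = i, Z_t = z)
        = softmax_j( alpha_ij + beta_ij[z] )

with the reference next state's linear predictor fixed at 0 for
identifiability, and quality entering as a categorical covariate with a
reference level (dummy coding).  Two parameterizations are supported:

``saturated``
    one free logit per (context, quality, non-reference next state) cell;
    the MLE is closed form (empirical cell proportions).
``additive``
    context and quality enter as separate dummy effects with no
    interaction — the layout of a standard multinomial regression table
    (current-state dummies, quality dummies, constant).

Defaults follow the study conventions: reference next state = neutral,
reference quality = high, natural logarithms throughout.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    N_QUALITY,
    N_STATES,
    EmotionState,
    InteractionSequence,
    QualityLevel,
    StabilityGroup,
    TransitionData,
    extract_transitions,
)

#: bound applied to coefficients that diverge under quasi-separation
COEF_CAP = 30.0

PARAMETERIZATIONS = ("saturated", "additive")


def all_contexts(order: int, n_states: int = N_STATES) -> list[tuple[EmotionState, ...]]:
    """Enumerate state contexts (oldest first) in lexicographic index order."""
    states = [EmotionState(i) for i in range(n_states)]
    return list(itertools.product(states, repeat=order))


def context_index(context: Sequence[EmotionState], n_states: int = N_STATES) -> int:
    idx = 0
    for s in context:
        idx = idx * n_states + int(s)
    return idx


def count_free_parameters(
    order: int, n_states: int, n_quality: int, parameterization: str
) -> int:
    """Number of unconstrained coefficients of the multinomial-logit CDMC.

    saturated: each of the ``n_states**order`` contexts contributes
    ``(n_states - 1)`` free logits per quality level.  additive:
    per non-reference outcome, one constant plus context dummies plus
    quality dummies.
    """
    if order < 1 or n_states < 2 or n_quality < 1:
        raise ValueError("need order >= 1, n_states >= 2, n_quality >= 1")
    n_ctx = n_states**order
    if parameterization == "saturated":
        return n_ctx * (n_states - 1) * n_quality
    if parameterization == "additive":
        return (n_states - 1) * (1 + (n_ctx - 1) + (n_quality - 1))
    raise ValueError(f"unknown parameterization {parameterization!r}")


@dataclass
class CDMCParameters:
    """Coefficient set of a fitted (or hand-built) CDMC.

    ``coef`` has shape ``(p, n_states - 1)``: one column per non-reference
    next state (in state-index order with the reference removed), one row
    per design feature.  Feature layout by parameterization:

    saturated
        per context ``i``: intercept (quality at reference), then one
        dummy per non-reference quality level — ``n_quality`` rows per
        context.
    additive
        context dummies (all contexts except the first), quality dummies,
        constant — matching the printed regression-table row order.
    """

    order: int
    parameterization: str
    coef: np.ndarray
    n_states: int = N_STATES
    n_quality: int = N_QUALITY
    ref_next: EmotionState = EmotionState.NEUTRAL
    ref_quality: QualityLevel = QualityLevel.HIGH

    def __post_init__(self) -> None:
        if self.parameterization not in PARAMETERIZATIONS:
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        self.coef = np.asarray(self.coef, dtype=float)
        expected = (self.n_features, self.n_states - 1)
        if self.coef.shape != expected:
            raise ValueError(
                f"coef shape {self.coef.shape} != expected {expected} for "
                f"{self.parameterization} order {self.order}"
            )

    # -- layout ------------------------------------------------------------
    @property
    def n_contexts(self) -> int:
        return self.n_states**self.order

    @property
    def n_features(self) -> int:
        if self.parameterization == "saturated":
            return self.n_contexts * self.n_quality
        return (self.n_contexts - 1) + (self.n_quality - 1) + 1

    @property
    def nonref_next(self) -> list[EmotionState]:
        return [EmotionState(j) for j in range(self.n_states) if j != int(self.ref_next)]

    @property
    def nonref_quality(self) -> list[QualityLevel]:
        return [QualityLevel(q) for q in range(self.n_quality) if q != int(self.ref_quality)]

    def feature_names(self) -> list[str]:
        ctxs = all_contexts(self.order, self.n_states)
        def ctx_label(ctx):
            return ",".join(s.label for s in ctx)
        names: list[str] = []
        if self.parameterization == "saturated":
            for ctx in ctxs:
                names.append(f"ctx[{ctx_label(ctx)}]:const")
                for q in self.nonref_quality:
                    names.append(f"ctx[{ctx_label(ctx)}]:Zt={q.label}")
        else:
            for ctx in ctxs[1:]:
                names.append(f"Xt={ctx_label(ctx)}")
            for q in self.nonref_quality:
                names.append(f"Zt={q.label}")
            names.append("const")
        return names

    def design_row(self, context: Sequence[EmotionState], quality: QualityLevel) -> np.ndarray:
        """Feature vector for one (context, quality) cell."""
        if len(context) != self.order:
            raise ValueError(
                f"context length {len(context)} != model order {self.order}"
            )
        i = context_index(context, self.n_states)
        x = np.zeros(self.n_features)
        if self.parameterization == "saturated":
            base = i * self.n_quality
            x[base] = 1.0
            if quality != self.ref_quality:
                x[base + 1 + self.nonref_quality.index(QualityLevel(quality))] = 1.0
        else:
            if i > 0:
                x[i - 1] = 1.0
            off = self.n_contexts - 1
            if quality != self.ref_quality:
                x[off + self.nonref_quality.index(QualityLevel(quality))] = 1.0
            x[-1] = 1.0
        return x

    # -- alpha / beta views ------------------------------------------------
    @property
    def alpha(self) -> np.ndarray:
        """Intercepts: (n_contexts, n_states-1) for saturated; additive
        returns the constant row broadcast is not meaningful, so the
        constant plus context-dummy rows are exposed as-is."""
        if self.parameterization == "saturated":
            rows = [i * self.n_quality for i in range(self.n_contexts)]
            return self.coef[rows, :]
        return self.coef[list(range(self.n_contexts - 1)) + [-1], :]

    @property
    def beta(self) -> np.ndarray:
        """Quality-dummy slopes: saturated (n_contexts, n_quality-1, S-1);
        additive (n_quality-1, S-1) shared across contexts."""
        nq = self.n_quality - 1
        if self.parameterization == "saturated":
            out = np.empty((self.n_contexts, nq, self.n_states - 1))
            for i in range(self.n_contexts):
                base = i * self.n_quality
                out[i] = self.coef[base + 1 : base + 1 + nq, :]
            return out
        off = self.n_contexts - 1
        return self.coef[off : off + nq, :]

    # -- probabilities -----------------------------------------------------
    def linear_predictor(
        self, context: Sequence[EmotionState], quality: QualityLevel
    ) -> np.ndarray:
        """Full-length predictor row with the reference entry fixed at 0."""
        x = self.design_row(context, quality)
        eta_free = x @ self.coef
        eta = np.zeros(self.n_states)
        for a, j in enumerate(self.nonref_next):
            eta[int(j)] = eta_free[a]
        return eta


def transition_probabilities(
    params: CDMCParameters,
    context: Sequence[EmotionState],
    quality: QualityLevel,
) -> np.ndarray:
    """Softmax next-state distribution for one (context, quality) cell."""
    eta = params.linear_predictor(context, quality)
    eta = eta - eta.max()  # guard overflow; softmax is shift-invariant
    w = np.exp(eta)
    return w / w.sum()


def _cell_counts(data: TransitionData, params: CDMCParameters) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate records into per-(context, quality) cell count rows.

    Returns (X, Y): X the (C, p) cell design matrix over the full
    context x quality grid, Y the (C, n_states) count matrix.
    """
    ctxs = all_contexts(params.order, params.n_states)
    quals = [QualityLevel(q) for q in range(params.n_quality)]
    cells = [(ctx, q) for ctx in ctxs for q in quals]
    pos = {
        (context_index(ctx), int(q)): r for r, (ctx, q) in enumerate(cells)
    }
    Y = np.zeros((len(cells), params.n_states))
    for rec in data.records:
        Y[pos[(context_index(rec.context), int(rec.quality))], int(rec.next)] += 1
    X = np.vstack([params.design_row(ctx, q) for ctx, q in cells])
    return X, Y


def log_likelihood(params: CDMCParameters, data: TransitionData) -> float:
    """Sum of log transition probabilities over the records (natural log).

    A record with model probability exactly 0 yields ``-inf`` with a
    warning rather than an exception.
    """
    if data.order != params.order:
        raise ValueError(f"data order {data.order} != model order {params.order}")
    if not data.records:
        return 0.0
    ctxs = all_contexts(params.order, params.n_states)
    total = 0.0
    X, Y = _cell_counts(data, params)
    quals = [QualityLevel(q) for q in range(params.n_quality)]
    cells = [(ctx, q) for ctx in ctxs for q in quals]
    for r, (ctx, q) in enumerate(cells):
        counts = Y[r]
        if counts.sum() == 0:
            continue
        p = transition_probabilities(params, ctx, q)
        if np.any((counts > 0) & (p == 0.0)):
            warnings.warn(
                "observed transition has probability 0 under the model; "
                "log-likelihood is -inf",
                RuntimeWarning,
                stacklevel=2,
            )
            return float("-inf")
        nz = counts > 0
        total += float(counts[nz] @ np.log(p[nz]))
    return total


def information_criteria(logL: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2 logL and BIC = k ln(n) - 2 logL (natural logs)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    aic = 2.0 * k - 2.0 * logL
    bic = k * math.log(n) - 2.0 * logL
    return aic, bic


@dataclass
class FitResult:
    """A fitted CDMC: coefficients, likelihood, information criteria, vcov.

    ``vcov`` is the inverse observed information over the free
    coefficients, flattened outcome-major (all features of the first
    non-reference outcome, then the second), matching ``coef_names``.
    """

    params: CDMCParameters
    logL: float
    k: int
    n: int
    aic: float
    bic: float
    vcov: np.ndarray | None
    converged: bool
    iterations: int = 0
    separation: tuple[str, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        exp_aic, exp_bic = information_criteria(self.logL, self.k, self.n)
        if np.isfinite(self.logL):
            if not (math.isclose(self.aic, exp_aic, rel_tol=0, abs_tol=1e-8)
                    and math.isclose(self.bic, exp_bic, rel_tol=0, abs_tol=1e-8)):
                raise ValueError("aic/bic inconsistent with (logL, k, n)")

    def coef_names(self) -> list[str]:
        feats = self.params.feature_names()
        return [
            f"[Xt+1={j.label}] {f}"
            for j in self.params.nonref_next
            for f in feats
        ]

    def theta(self) -> np.ndarray:
        """Free coefficients flattened outcome-major."""
        return self.params.coef.T.ravel()


def _nll_grad_hess(
    theta: np.ndarray, X: np.ndarray, Y: np.ndarray, params: CDMCParameters,
    want_hess: bool = True,
):
    """Negative log-likelihood, gradient and Hessian on aggregated cells."""
    p_feat = params.n_features
    S1 = params.n_states - 1
    B = theta.reshape(S1, p_feat).T  # (p, S-1)
    eta_free = X @ B  # (C, S-1)
    eta = np.zeros((X.shape[0], params.n_states))
    for a, j in enumerate(params.nonref_next):
        eta[:, int(j)] = eta_free[:, a]
    eta -= eta.max(axis=1, keepdims=True)
    W = np.exp(eta)
    P = W / W.sum(axis=1, keepdims=True)  # (C, S)
    m = Y.sum(axis=1)  # (C,)

    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.log(P)
    nll = -float(np.sum(np.where(Y > 0, Y * logP, 0.0)))

    jn = [int(j) for j in params.nonref_next]
    resid = m[:, None] * P[:, jn] - Y[:, jn]  # (C, S-1)
    grad = (X.T @ resid).T.ravel()  # outcome-major

    if not want_hess:
        return nll, grad, None

    dim = S1 * p_feat
    H = np.empty((dim, dim))
    for a in range(S1):
        for b in range(S1):
            w = m * P[:, jn[a]] * ((1.0 if a == b else 0.0) - P[:, jn[b]])
            block = X.T @ (w[:, None] * X)
            H[a * p_feat:(a + 1) * p_feat, b * p_feat:(b + 1) * p_feat] = block
    return nll, grad, H


def _newton_fit(
    X: np.ndarray, Y: np.ndarray, params: CDMCParameters,
    tol: float, max_iter: int,
) -> tuple[np.ndarray, bool, int]:
    """Newton ascent on the multinomial log-likelihood, zero init.

    Convergence when the gradient infinity-norm drops below ``tol`` or the
    relative log-likelihood change falls below 1e-10.  Step halving guards
    against overshoot; a small ridge handles near-singular information.
    """
    dim = (params.n_states - 1) * params.n_features
    theta = np.zeros(dim)
    nll, grad, H = _nll_grad_hess(theta, X, Y, params)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            return theta, True, it - 1
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(dim), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped line search
        scale = 1.0
        for _ in range(40):
            cand = theta - scale * step
            cand = np.clip(cand, -COEF_CAP, COEF_CAP)
            new_nll, new_grad, new_H = _nll_grad_hess(cand, X, Y, params)
            if new_nll <= nll + 1e-12:
                break
            scale *= 0.5
        rel_change = abs(nll - new_nll) / (abs(nll) + 1.0)
        theta, nll, grad, H = cand, new_nll, new_grad, new_H
        if rel_change < 1e-10:
            return theta, True, it
    return theta, bool(np.max(np.abs(grad)) < tol), max_iter


def _closed_form_saturated(
    X: np.ndarray, Y: np.ndarray, params: CDMCParameters
) -> tuple[np.ndarray, list[str]]:
    """Exact saturated MLE: per-cell log-odds vs the reference next state.

    Cells with a zero count in either numerator or reference produce
    infinite log-odds; those coefficients are capped at +-COEF_CAP and
    flagged (quasi-separation).  Cells with no support at all keep zero
    coefficients and are flagged unsupported.
    """
    nq = params.n_quality
    ctxs = all_contexts(params.order, params.n_states)
    quals = [QualityLevel(q) for q in range(nq)]
    names = params.feature_names()
    flags: list[str] = []
    ref = int(params.ref_next)
    # cell logits l[cell, a] for non-reference outcome a
    L = np.zeros((len(ctxs) * nq, params.n_states - 1))
    for r in range(L.shape[0]):
        counts = Y[r]
        tot = counts.sum()
        ctx, q = ctxs[r // nq], quals[r % nq]
        cell = f"ctx[{','.join(s.label for s in ctx)}],Zt={q.label}"
        if tot == 0:
            flags.append(f"unsupported:{cell}")
            continue
        for a, j in enumerate(params.nonref_next):
            nj, nr = counts[int(j)], counts[ref]
            if nj > 0 and nr > 0:
                L[r, a] = math.log(nj / nr)
            else:
                L[r, a] = COEF_CAP if nj > 0 else -COEF_CAP
                flags.append(f"separation:{cell}:Xt+1={j.label}")
    # map per-cell logits onto [intercept, quality dummies] per context
    B = np.zeros((params.n_features, params.n_states - 1))
    ref_q = int(params.ref_quality)
    for i in range(len(ctxs)):
        base = i * nq
        alpha = L[i * nq + ref_q]
        B[base] = np.clip(alpha, -COEF_CAP, COEF_CAP)
        for d, q in enumerate(params.nonref_quality):
            delta = L[i * nq + int(q)] - alpha
            B[base + 1 + d] = np.clip(delta, -COEF_CAP, COEF_CAP)
    return B, flags


def fit_cdmc(
    data: TransitionData,
    order: int | None = None,
    parameterization: str = "saturated",
    tol: float = 1e-8,
    max_iter: int = 200,
    method: str = "auto",
    ref_next: EmotionState = EmotionState.NEUTRAL,
    ref_quality: QualityLevel = QualityLevel.HIGH,
) -> FitResult:
    """Maximum-likelihood fit of the CDMC.

    ``method='auto'`` uses the closed-form cell-proportion MLE for the
    saturated parameterization and Newton ascent (zero init, analytic
    gradient/Hessian) for the additive one; ``method='newton'`` forces the
    optimizer, which must agree with the closed form on saturated
    structure.  The Wald covariance is the inverse observed information at
    the optimum.
    """
    if not data.records:
        raise ValueError("cannot fit on empty transition data")
    if order is None:
        order = data.order
    if order != data.order:
        raise ValueError(f"data order {data.order} != requested order {order}")
    observed_next = {int(r.next) for r in data.records}
    if len(observed_next) < N_STATES:
        missing = [EmotionState(j).label for j in range(N_STATES) if j not in observed_next]
        raise ValueError(f"next-state categories never observed: {missing}")

    n_feat = count_free_parameters(order, N_STATES, N_QUALITY, parameterization) // (
        N_STATES - 1
    )
    shell = CDMCParameters(
        order=order,
        parameterization=parameterization,
        coef=np.zeros((n_feat, N_STATES - 1)),
        ref_next=ref_next,
        ref_quality=ref_quality,
    )
    X, Y = _cell_counts(data, shell)

    flags: list[str] = []
    if method == "auto":
        method = "closed_form" if parameterization == "saturated" else "newton"
    if method == "closed_form":
        if parameterization != "saturated":
            raise ValueError("closed form applies to the saturated parameterization only")
        B, flags = _closed_form_saturated(X, Y, shell)
        converged, iterations = True, 0
    elif method == "newton":
        theta, converged, iterations = _newton_fit(X, Y, shell, tol, max_iter)
        B = theta.reshape(N_STATES - 1, shell.n_features).T
        if np.any(np.abs(B) >= COEF_CAP - 1e-6):
            flags.append("separation:coefficient at cap")
    else:
        raise ValueError(f"unknown method {method!r}")

    params = CDMCParameters(
        order=order, parameterization=parameterization, coef=B,
        ref_next=ref_next, ref_quality=ref_quality,
    )
    logL = log_likelihood(params, data)
    k = count_free_parameters(order, N_STATES, N_QUALITY, parameterization)
    n = data.n_records
    aic, bic = information_criteria(logL, k, n)

    theta = params.coef.T.ravel()
    _, _, H = _nll_grad_hess(theta, X, Y, params)
    vcov = np.linalg.pinv(H)

    return FitResult(
        params=params, logL=logL, k=k, n=n, aic=aic, bic=bic,
        vcov=vcov, converged=converged, iterations=iterations,
        separation=tuple(flags),
    )


# ---------------------------------------------------------------------------
# empirical matrices
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrixSet:
    """Row-stochastic next-state distributions per (quality, context) cell.

    Rows with zero supporting records (and no smoothing) are marked
    undefined (NaN entries, ``defined`` False) rather than silently
    uniform.
    """

    order: int
    smoothing: float
    matrices: dict
    support: dict
    defined: dict

    def row(self, quality: QualityLevel, context: tuple) -> np.ndarray:
        return self.matrices[(QualityLevel(quality), tuple(context))]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (q, ctx), p in self.matrices.items():
            rec = {
                "quality": q.label,
                "context": ",".join(s.label for s in ctx),
                "n": int(self.support[(q, ctx)].sum()),
                "defined": self.defined[(q, ctx)],
            }
            for j, s in enumerate(EmotionState):
                rec[f"p_{s.label}"] = p[j]
            rows.append(rec)
        return pd.DataFrame(rows)

    def flow_table(self) -> pd.DataFrame:
        """Long-format (source, target, quality, count) rows for flow plots."""
        if self.order != 1:
            raise ValueError("flow table is defined for order-1 matrices")
        rows = []
        for (q, ctx), counts in self.support.items():
            for j, s in enumerate(EmotionState):
                rows.append({
                    "source_state": ctx[0].label,
                    "target_state": s.label,
                    "quality": q.label,
                    "count": int(counts[j]),
                })
        return pd.DataFrame(rows)


def empirical_transition_matrices(
    data: TransitionData, smoothing: float = 0.0
) -> TransitionMatrixSet:
    """Empirical (optionally Laplace-smoothed) transition matrices.

    Row ``j`` of cell ``(context, quality)`` is
    ``(n(i,z,j) + smoothing) / (n(i,z,.) + n_states * smoothing)``.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    ctxs = all_contexts(data.order)
    counts: dict = {
        (QualityLevel(q), ctx): np.zeros(N_STATES)
        for ctx in ctxs for q in range(N_QUALITY)
    }
    for rec in data.records:
        counts[(rec.quality, rec.context)][int(rec.next)] += 1
    matrices, defined = {}, {}
    for key, c in counts.items():
        tot = c.sum() + N_STATES * smoothing
        if tot == 0:
            matrices[key] = np.full(N_STATES, np.nan)
            defined[key] = False
        else:
            matrices[key] = (c + smoothing) / tot
            defined[key] = True
    return TransitionMatrixSet(
        order=data.order, smoothing=smoothing,
        matrices=matrices, support=counts, defined=defined,
    )


def empirical_matrices_by_group(
    data: TransitionData, smoothing: float = 0.0
) -> dict:
    """Per-stability-group empirical matrices (records without a group are skipped)."""
    out = {}
    for g in (StabilityGroup.LOW, StabilityGroup.HIGH):
        sub = data.subset_group(g)
        if sub.records:
            out[g] = empirical_transition_matrices(sub, smoothing)
    return out


# ---------------------------------------------------------------------------
# order selection and Wald inference
# ---------------------------------------------------------------------------

def select_order(
    sequences: Sequence[InteractionSequence],
    orders: Iterable[int] = (1, 2),
    parameterization: str = "saturated",
) -> pd.DataFrame:
    """Fit the CDMC at each Markov order and compare by information criteria.

    For each order the transitions are re-extracted (so each model's ``n``
    is the number of records actually fitted at that order), fitted, and
    tabulated with AIC/BIC and the BIC gap to the best model.  The
    preferred order minimises BIC, ties broken toward the lower order
    (parsimony).
    """
    orders = sorted(set(orders))
    if any(o not in (1, 2) for o in orders):
        raise ValueError("orders must be within {1, 2}")
    rows = []
    for order in orders:
        data = extract_transitions(sequences, order)
        try:
            fit = fit_cdmc(data, order=order, parameterization=parameterization)
        except Exception as exc:  # annotate the failing order
            raise RuntimeError(f"fit failed at order {order}: {exc}") from exc
        rows.append({
            "order": order, "n": fit.n, "k": fit.k,
            "logL": fit.logL, "AIC": fit.aic, "BIC": fit.bic,
        })
    table = pd.DataFrame(rows)
    best = table["BIC"].min()
    table["deltaBIC"] = table["BIC"] - best
    # idxmin takes the first minimum; rows are sorted by ascending order,
    # so ties resolve toward the lower order
    pref = table.loc[table["BIC"].idxmin(), "order"]
    table["preferred"] = table["order"] == pref
    return table


def wald_statistics(fit: FitResult, confidence: float = 0.95) -> pd.DataFrame:
    """Per-coefficient Wald table: estimate, SE, z, two-sided p, CI.

    Coefficients with a non-positive variance estimate (typically
    separation-capped ones) are flagged and their SE/z/p left unset
    instead of propagating NaNs silently.
    """
    if fit.vcov is None:
        raise ValueError("fit carries no covariance matrix")
    if not fit.converged:
        raise ValueError("Wald inference requires a converged fit")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    zcrit = stats.norm.ppf(0.5 * (1 + confidence))
    est = fit.theta()
    var = np.diag(fit.vcov)
    rows = []
    for name, b, v in zip(fit.coef_names(), est, var):
        if v <= 0 or not np.isfinite(v) or abs(b) >= COEF_CAP - 1e-9:
            rows.append({
                "coefficient": name, "estimate": b, "se": np.nan,
                "z": np.nan, "p": np.nan,
                "ci_lower": np.nan, "ci_upper": np.nan, "flagged": True,
            })
            continue
        se = math.sqrt(v)
        z = b / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({
            "coefficient": name, "estimate": b, "se": se, "z": z, "p": p,
            "ci_lower": b - zcrit * se, "ci_upper": b + zcrit * se,
            "flagged": False,
        })
    return pd.DataFrame(rows)
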