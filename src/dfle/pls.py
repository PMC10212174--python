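"""Multi-response partial least squares (PLS2) with cross-validated
component selection and VIP-based variable selection.

The regression extracts latent components that maximise covariance between
the predictor block X (regional indicators) and the response block Y
(health expectancies), via the classic NIPALS iteration.  The number of
components is chosen in two steps, following the convention of the PLS
software family used in small-area ecological work:

1. leave-one-out cross-validation gives PRESS(k), the predicted residual
   sum of squares for k = 0..K_max; k_min is the smallest k attaining the
   minimum;
2. Van der Voet's paired randomization test compares each smaller model's
   held-out squared residuals with k_min's; the selected model is the
   smallest k whose predictions are not significantly worse (p >= alpha).

Variable importance in projection (VIP) scores, whose squares average to 1,
support a two-stage fit: variables with VIP below a threshold (0.8 by
convention) after the first fit are dropped and the model re-selected and
refit on the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Standardizer",
    "standardize",
    "PLSFit",
    "fit_pls",
    "predict",
    "predict_components",
    "PressCurve",
    "loo_press",
    "van_der_voet",
    "VdVResult",
    "select_components",
    "vip",
    "loading_correlations",
    "fig_pair_data",
    "TwoStageResult",
    "two_stage_fit",
    "default_k_max",
]

_NIPALS_TOL = 1e-10
# the weight iteration is a power iteration on (X'Y)(X'Y)'; when two singular
# values nearly tie (common once Y is mostly deflated) it converges slowly or
# not at all, so past the cap the component is resolved from its exact fixed
# point instead (dominant eigenvector of the small q x q cross-block matrix)
_NIPALS_MAX_ITER = 5_000


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    """Per-column mean/SD of a fitted z-scoring; invertible."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, M: np.ndarray) -> np.ndarray:
        return (np.asarray(M, dtype=float) - self.mean) / self.sd

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean


def standardize(M, columns=None) -> tuple[np.ndarray, Standardizer]:
    """Z-score each column (SD with n-1 denominator); constant columns error."""
    if isinstance(M, pd.DataFrame):
        columns = list(M.columns)
        M = M.to_numpy(dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad) > 0:
        name = columns[bad[0]] if columns is not None else f"column {bad[0]}"
        raise ValueError(f"constant column cannot be standardized: {name}")
    return (M - mean) / sd, Standardizer(mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# NIPALS PLS2
# ---------------------------------------------------------------------------

@dataclass
class PLSFit:
    """NIPALS PLS2 decomposition.

    W: X-weights (p x K, unit-norm columns); P: X-loadings; C: Y-loadings;
    T: X-scores (mutually orthogonal columns); B: coefficient matrix
    mapping the (centred/standardized) X given to :func:`fit_pls` to
    predicted Y; frac_x / frac_y: per-component fractions of the X- and
    Y-block sum of squares explained.
    """

    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    T: np.ndarray
    B: np.ndarray
    frac_x: np.ndarray
    frac_y: np.ndarray
    x_names: list = field(default_factory=list)
    y_names: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int,
            x_names=None, y_names=None) -> PLSFit:
    """Fit PLS2 by NIPALS on (already centred/standardized) X and Y.

    Per component: u initialised to the Y column of largest variance, then
    w ~ X'u (unit norm), t = Xw, c = Y't/(t't), u = Yc/(c'c) until the score
    stabilises; p = X't/(t't); both blocks are deflated by t.  Each weight
    column is sign-fixed so its largest-magnitude entry is positive.
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching rows")
    n, p = X.shape
    q = Y.shape[1]
    K = int(n_components)
    if K < 1:
        raise ValueError("need at least one component")
    rank = np.linalg.matrix_rank(X)
    if K > rank:
        raise ValueError(f"requested {K} components but rank(X) = {rank}")

    ssx0 = float(np.sum(X * X))
    ssy0 = float(np.sum(Y * Y))
    if ssy0 == 0:
        raise ValueError("response block has no variance")

    W = np.empty((p, K))
    P = np.empty((p, K))
    C = np.empty((q, K))
    T = np.empty((n, K))
    frac_x = np.empty(K)
    frac_y = np.empty(K)

    for k in range(K):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if not np.any(u):
            u = Y[:, 0] + 1e-12  # fully deflated Y; NIPALS will still converge
        t_old = None
        for _ in range(_NIPALS_MAX_ITER):
            w = X.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                raise ValueError(f"component {k + 1}: X is fully deflated")
            w /= norm_w
            t = X @ w
            tt = float(t @ t)
            if tt == 0:
                raise ValueError(f"component {k + 1}: zero score vector")
            c = Y.T @ t / tt
            cc = float(c @ c)
            if cc == 0:
                raise ValueError(f"component {k + 1}: no Y covariance left")
            u = Y @ c / cc
            if t_old is not None and np.linalg.norm(t - t_old) / np.linalg.norm(t) < _NIPALS_TOL:
                break
            t_old = t
        else:
            # near-degenerate singular values: take the fixed point directly.
            # w solves w ~ (X'Y)(X'Y)' w, i.e. w = A v with v the dominant
            # eigenvector of A'A (q x q), A = X'Y
            A = X.T @ Y
            evals, evecs = np.linalg.eigh(A.T @ A)
            w = A @ evecs[:, -1]
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                raise RuntimeError(f"component {k + 1}: degenerate cross-block matrix")
            w /= norm_w
            t = X @ w

        # sign convention: largest-magnitude weight entry positive
        if w[int(np.argmax(np.abs(w)))] < 0:
            w, t = -w, -t
        tt = float(t @ t)
        c = Y.T @ t / tt
        pvec = X.T @ t / tt
        X = X - np.outer(t, pvec)
        Y = Y - np.outer(t, c)
        W[:, k], P[:, k], C[:, k], T[:, k] = w, pvec, c, t
        frac_x[k] = tt * float(pvec @ pvec) / ssx0
        frac_y[k] = tt * float(c @ c) / ssy0

    B = W @ np.linalg.solve(P.T @ W, C.T)
    return PLSFit(W=W, P=P, C=C, T=T, B=B, frac_x=frac_x, frac_y=frac_y,
                  x_names=list(x_names) if x_names is not None else [],
                  y_names=list(y_names) if y_names is not None else [])


def predict(fit: PLSFit, X: np.ndarray) -> np.ndarray:
    """Predict Y (on the fitted scale) for new rows on the fitted X scale."""
    return np.asarray(X, dtype=float) @ fit.B


def predict_components(fit: PLSFit, X: np.ndarray) -> np.ndarray:
    """Cumulative predictions per component count.

    Returns an array of shape (n_new, q, K) whose slice ``[..., k-1]`` is the
    prediction using the first k components, via the sequential
    score-deflate recursion (exact for any truncation of the fit).
    """
    X = np.array(X, dtype=float)
    n_new = X.shape[0]
    q, K = fit.C.shape
    out = np.empty((n_new, q, K))
    resid = X.copy()
    acc = np.zeros((n_new, q))
    for k in range(K):
        t = resid @ fit.W[:, k]
        acc = acc + np.outer(t, fit.C[:, k])
        resid = resid - np.outer(t, fit.P[:, k])
        out[:, :, k] = acc
    return out


# ---------------------------------------------------------------------------
# leave-one-out PRESS
# ---------------------------------------------------------------------------

@dataclass
class PressCurve:
    """PRESS(k) for k = 0..K_max plus the per-cell held-out residuals.

    ``residuals`` has shape (n, q, K_max + 1); slice k holds the residual of
    the k-component model for every held-out cell, on the scale of the Y
    passed to :func:`loo_press` (fold-internal standardisation is undone
    before residuals are taken).  k = 0 is the training-fold-mean model.
    """

    press: np.ndarray
    residuals: np.ndarray

    @property
    def k_max(self) -> int:
        return len(self.press) - 1

    @property
    def press_by_response(self) -> np.ndarray:
        """(K_max + 1, q) PRESS split per response column."""
        return np.transpose(np.sum(self.residuals ** 2, axis=0))

    @property
    def k_min(self) -> int:
        """Smallest component count attaining the minimum PRESS."""
        return int(np.argmin(self.press))


def loo_press(X, Y, k_max: int) -> PressCurve:
    """Leave-one-out PRESS for component counts 0..k_max.

    Each training fold is re-centred and re-scaled (X and Y) before fitting,
    the held-out row is projected with the fold's scaler, and predictions
    are mapped back to the input scale before residuals are formed — so no
    information from the held-out row leaks into the fit.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    if isinstance(Y, pd.DataFrame):
        Y = Y.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 rows")
    k_max = int(k_max)
    residuals = np.empty((n, q, k_max + 1))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Zx, sx = standardize(X[keep])
        Zy, sy = standardize(Y[keep])
        rank = np.linalg.matrix_rank(Zx)
        if k_max > rank:
            raise ValueError(
                f"fold leaving out row {i}: rank {rank} < requested k_max {k_max}")
        fit = fit_pls(Zx, Zy, k_max)
        xi = sx.transform(X[i:i + 1])
        preds_std = predict_components(fit, xi)[0]          # (q, k_max)
        residuals[i, :, 0] = Y[i] - sy.mean                  # null model: fold means
        for k in range(1, k_max + 1):
            pred = sy.inverse(preds_std[:, k - 1])
            residuals[i, :, k] = Y[i] - pred
    press = np.sum(residuals ** 2, axis=(0, 1))
    return PressCurve(press=press, residuals=residuals)


# ---------------------------------------------------------------------------
# Van der Voet randomization test and component selection
# ---------------------------------------------------------------------------

def van_der_voet(residuals_k: np.ndarray, residuals_ref: np.ndarray,
                 n_rand: int = 1999, seed=None) -> tuple[float, float]:
    """Paired sign-randomization test on held-out squared residuals.

    Per observation, ``d_i`` is the difference in summed (over responses)
    squared residuals between the candidate and the reference model;
    C = sum_i d_i.  Under the null the sign of each d_i is exchangeable, so
    the null distribution of C is obtained by flipping signs — enumerated
    exactly over all 2^n patterns when n <= 20, otherwise by ``n_rand``
    Monte-Carlo draws.  The two-sided p-value counts the observed pattern in
    both numerator and denominator, so p is always in (0, 1].
    """
    a = np.asarray(residuals_k, dtype=float)
    b = np.asarray(residuals_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError("residual arrays must share shape")
    if a.ndim == 1:
        a = a[:, None]
        b = b[:, None]
    d = np.sum(a * a - b * b, axis=1)
    C = float(np.sum(d))
    n = len(d)
    if n <= 20:
        sums = np.zeros(1)
        for di in d:
            sums = np.concatenate([sums + di, sums - di])
        p = float(np.mean(np.abs(sums) >= abs(C) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(int(n_rand), n)) * 2 - 1
        null = signs @ d
        hits = int(np.sum(np.abs(null) >= abs(C) - 1e-12))
        p = (1 + hits) / (1 + int(n_rand))
    return C, p


@dataclass
class VdVResult:
    """Component selection outcome: reference k_min, per-k test, selected k."""

    k_min: int
    selected: int
    table: pd.DataFrame          # columns: k, press, statistic, p_value
    n_rand: int
    alpha: float


def select_components(curve: PressCurve, alpha: float = 0.10,
                      n_rand: int = 1999, seed=None) -> VdVResult:
    """Smallest model not significantly worse than the PRESS-minimal one.

    k_min is the smallest k attaining the minimum PRESS (parsimony on
    ties).  Every k = 0..k_min is tested against k_min with Van der Voet's
    randomization test; the selected count is the smallest k with
    p >= alpha (k_min itself always qualifies, with p = 1).
    """
    if len(curve.press) == 0:
        raise ValueError("empty PRESS curve")
    k_min = curve.k_min
    rng = np.random.default_rng(seed)
    rows = []
    selected = None
    for k in range(k_min + 1):
        stat, p = van_der_voet(curve.residuals[:, :, k], curve.residuals[:, :, k_min],
                               n_rand=n_rand, seed=rng.integers(0, 2**31 - 1))
        rows.append({"k": k, "press": float(curve.press[k]),
                     "statistic": stat, "p_value": p})
        if selected is None and p >= alpha:
            selected = k
    table = pd.DataFrame(rows)
    return VdVResult(k_min=k_min, selected=int(selected), table=table,
                     n_rand=int(n_rand), alpha=float(alpha))


# ---------------------------------------------------------------------------
# VIP, loading correlations, two-stage fit
# ---------------------------------------------------------------------------

def vip(fit: PLSFit) -> pd.Series:
    """Variable importance in projection per explanatory variable.

    VIP_j = sqrt( p * sum_k SSY_k (w_jk / ||w_k||)^2 / sum_k SSY_k ) with
    SSY_k the fraction of Y-variance explained by component k.  Because the
    weight columns are unit-norm, mean_j VIP_j^2 = 1 exactly.
    """
    ssy = fit.frac_y
    total = float(np.sum(ssy))
    if total == 0:
        raise ValueError("no Y-variance explained; VIP undefined")
    p = fit.W.shape[0]
    w2 = fit.W ** 2 / np.sum(fit.W ** 2, axis=0)
    scores = np.sqrt(p * (w2 @ ssy) / total)
    index = fit.x_names if fit.x_names else range(p)
    return pd.Series(scores, index=index, name="vip")


def loading_correlations(fit: PLSFit, X0, Y0) -> pd.DataFrame:
    """Pearson correlation of every variable and response with each score.

    Long format: variable, kind ('explanatory'|'response'), component
    (1-based), correlation.  This is the factor-loading/correlation table
    used to interpret the components.
    """
    x_names = list(X0.columns) if isinstance(X0, pd.DataFrame) else (
        fit.x_names or [f"x{j}" for j in range(np.asarray(X0).shape[1])])
    y_names = list(Y0.columns) if isinstance(Y0, pd.DataFrame) else (
        fit.y_names or [f"y{j}" for j in range(np.asarray(Y0).shape[1])])
    X0 = np.asarray(X0, dtype=float)
    Y0 = np.asarray(Y0, dtype=float)
    if X0.shape[0] != fit.T.shape[0] or Y0.shape[0] != fit.T.shape[0]:
        raise ValueError("matrices and fit must share rows")

    def _corr(col: np.ndarray, t: np.ndarray) -> float:
        tc = t - t.mean()
        cc = col - col.mean()
        st = np.sqrt(tc @ tc)
        sc = np.sqrt(cc @ cc)
        if st == 0:
            raise ValueError("zero-variance score column")
        if sc == 0:
            return np.nan
        return float((cc @ tc) / (sc * st))

    rows = []
    for k in range(fit.n_components):
        t = fit.T[:, k]
        for name, col in zip(x_names, X0.T):
            rows.append({"variable": name, "kind": "explanatory",
                         "component": k + 1, "correlation": _corr(col, t)})
        for name, col in zip(y_names, Y0.T):
            rows.append({"variable": name, "kind": "response",
                         "component": k + 1, "correlation": _corr(col, t)})
    return pd.DataFrame(rows)


def fig_pair_data(loadings: pd.DataFrame,
                  pairs: tuple[tuple[int, int], ...] = ((1, 2), (2, 3), (1, 3))
                  ) -> pd.DataFrame:
    """Paired-component coordinates for correlation/loading plots.

    One row per variable per component pair, with the two correlations as
    x/y coordinates; pairs beyond the fitted component count are skipped.
    """
    avail = set(loadings["component"].unique())
    wide = loadings.pivot(index=["variable", "kind"], columns="component",
                          values="correlation")
    rows = []
    for (ka, kb) in pairs:
        if ka not in avail or kb not in avail:
            continue
        for (variable, kind), r in wide.iterrows():
            rows.append({"pair": f"c{ka}-c{kb}", "variable": variable, "kind": kind,
                         "x_component": ka, "y_component": kb,
                         "x": r[ka], "y": r[kb]})
    return pd.DataFrame(rows)


def default_k_max(n: int, p: int, cap: int = 15) -> int:
    """Default search cap for the component count."""
    return max(1, min(p, n - 2, cap))


@dataclass
class TwoStageResult:
    """VIP-thresholded two-stage PLS: full fit, pruning, refit."""

    stage1: VdVResult
    fit1: PLSFit
    vip1: pd.Series
    retained: list
    stage2: VdVResult
    fit2: PLSFit
    vip2: pd.Series
    curve1: PressCurve
    curve2: PressCurve
    loadings: pd.DataFrame       # stage-2 loading/correlation table
    explained: pd.DataFrame      # stage-2 per-component fracX / fracY


def two_stage_fit(X: pd.DataFrame, Y: pd.DataFrame, vip_threshold: float = 0.8,
                  alpha: float = 0.10, k_max: int | None = None,
                  n_rand: int = 1999, seed=None) -> TwoStageResult:
    """Select components, prune by VIP, re-select and refit.

    Stage 1 runs component selection on all variables and computes VIP from
    the selected fit; variables with VIP >= ``vip_threshold`` are retained.
    Stage 2 repeats selection and fitting on the retained set and produces
    the loading/correlation and explained-variance reports.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    if not isinstance(Y, pd.DataFrame):
        Y = pd.DataFrame(np.asarray(Y, dtype=float))
        Y.columns = [f"y{j}" for j in range(Y.shape[1])]
    n, p = X.shape
    rng = np.random.default_rng(seed)

    def _stage(Xs: pd.DataFrame):
        kmx = default_k_max(n, Xs.shape[1]) if k_max is None else min(k_max, Xs.shape[1])
        curve = loo_press(Xs, Y, kmx)
        sel = select_components(curve, alpha=alpha, n_rand=n_rand,
                                seed=rng.integers(0, 2**31 - 1))
        if sel.selected == 0:
            raise ValueError("component selection chose the null model; no PLS fit possible")
        Zx, _ = standardize(Xs)
        Zy, _ = standardize(Y)
        fit = fit_pls(Zx, Zy, sel.selected, x_names=list(Xs.columns),
                      y_names=list(Y.columns))
        return curve, sel, fit, Zx, Zy

    curve1, sel1, fit1, _, _ = _stage(X)
    vip1 = vip(fit1)
    retained = list(vip1.index[vip1 >= vip_threshold])
    if not retained:
        raise ValueError(f"no variable reaches VIP >= {vip_threshold}")

    curve2, sel2, fit2, Zx2, Zy2 = _stage(X[retained])
    vip2 = vip(fit2)
    loadings = loading_correlations(fit2, pd.DataFrame(Zx2, columns=retained),
                                    pd.DataFrame(Zy2, columns=Y.columns))
    explained = pd.DataFrame({
        "component": np.arange(1, fit2.n_components + 1),
        "frac_x": fit2.frac_x,
        "frac_y": fit2.frac_y,
    })
    return TwoStageResult(stage1=sel1, fit1=fit1, vip1=vip1, retained=retained,
                          stage2=sel2, fit2=fit2, vip2=vip2,
                          curve1=curve1, curve2=curve2,
                          loadings=loadings, explained=explained)
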