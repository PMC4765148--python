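"""L1 and L1+L2 penalized least squares via the LARS homotopy.

The LASSO objective used throughout is the plain squared-error sum

    l(beta) = sum_i (y_i - beta.x_i)^2 + lambda * sum_j |beta_j|,

i.e. the penalty multiplies the *un-halved, un-averaged* residual sum of
squares.  Other conventions differ by a factor: scikit-learn's ``alpha``
equals ``lambda / (2 N)`` and formulations written with ``(1/2)||r||^2``
use ``lambda / 2``.  The elastic net adds ``gamma * sum_j beta_j^2`` and is
solved exactly as a LASSO on data augmented with sqrt(gamma) * I rows
(the "naive" elastic net; no post-hoc coefficient rescaling).

The homotopy traces the full piecewise-linear coefficient path in lambda,
including the LASSO modification that lets variables leave the active set,
so a fit at any lambda is an exact linear interpolation between breakpoints.

Columns are centered and scaled to unit variance and the response centered
by default; the penalty applies on the standardized scale and weights are
mapped back, with the intercept recovered from the centering record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: coefficients below this magnitude (standardized scale) are treated as zero
ZERO_TOL = 1e-12
#: KKT feasibility tolerance on the standardized scale
KKT_TOL = 1e-8


@dataclass
class StandardizationRecord:
    """Per-column mean/scale and response mean used to standardize a problem.

    Constant columns get scale 1 and are flagged; they are excluded from the
    active-set machinery and always receive weight zero.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    constant_columns: np.ndarray  # boolean mask
    standardized: bool = True

    def to_original(self, beta_std: np.ndarray) -> tuple[np.ndarray, float]:
        """Map standardized-scale weights back to the original scale."""
        beta = beta_std / self.x_scale
        beta[self.constant_columns] = 0.0
        intercept = float(self.y_mean - beta @ self.x_mean)
        return beta, intercept


@dataclass
class RegressionProblem:
    """An N x T least-squares design with optional standardization."""

    X: np.ndarray
    y: np.ndarray
    standardize: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise ValueError("X and y must be finite")

    def standardized(self) -> tuple[np.ndarray, np.ndarray, StandardizationRecord]:
        """Return (Xs, ys, record); constant columns are zeroed out."""
        X, y = self.X, self.y
        if self.standardize:
            x_mean = X.mean(axis=0)
            x_scale = X.std(axis=0)
            constant = x_scale <= 0.0
            x_scale = np.where(constant, 1.0, x_scale)
            Xs = (X - x_mean) / x_scale
            Xs[:, constant] = 0.0
            y_mean = float(y.mean())
            ys = y - y_mean
            record = StandardizationRecord(x_mean, x_scale, y_mean, constant, True)
        else:
            constant = X.std(axis=0) <= 0.0
            Xs = X.copy()
            Xs[:, constant] = 0.0
            record = StandardizationRecord(
                np.zeros(X.shape[1]), np.ones(X.shape[1]), 0.0, constant, False
            )
            ys = y.copy()
        return Xs, ys, record


@dataclass
class PenaltyParams:
    """L1 (lambda) and L2 (gamma) penalties, or a shrinkage budget t.

    Exactly one of ``lam`` / ``shrinkage_budget`` drives the L1 constraint:
    the budget form ``sum |beta_j| <= t`` is converted to the equivalent
    lambda on the coefficient path.  ``gamma = 0`` is the pure LASSO.
    """

    lam: float = 0.0
    gamma: float = 0.0
    shrinkage_budget: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lam < 0 or self.gamma < 0:
            raise ValueError("penalties must be non-negative")
        if self.shrinkage_budget is not None:
            if self.shrinkage_budget <= 0:
                raise ValueError("shrinkage budget t must be > 0")
            if self.lam != 0:
                raise ValueError("give either lam or shrinkage_budget, not both")


@dataclass
class SparseFit:
    """A fitted sparse linear model on the original data scale."""

    beta: np.ndarray
    intercept: float
    penalties: PenaltyParams
    active_set: np.ndarray
    beta_std: np.ndarray
    record: StandardizationRecord

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.beta + self.intercept


@dataclass
class LassoPath:
    """Piecewise-linear LASSO path: breakpoints in decreasing lambda order.

    ``coefs[k]`` is the standardized-scale coefficient vector at
    ``lambdas[k]``; between breakpoints coefficients are affine in lambda.
    """

    lambdas: np.ndarray
    coefs: np.ndarray
    record: StandardizationRecord
    penalties_gamma: float = 0.0
    knot_merge_tol: float = 1e-12

    @property
    def lambda_max(self) -> float:
        return float(self.lambdas[0])

    def coef_at(self, lam: float) -> np.ndarray:
        """Standardized-scale coefficients at an arbitrary lambda >= 0."""
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        lambdas, coefs = self.lambdas, self.coefs
        if lam >= lambdas[0]:
            return np.zeros(coefs.shape[1])
        if lam <= lambdas[-1]:
            return coefs[-1].copy()
        # first knot with lambda <= lam (lambdas is strictly decreasing)
        k = int(np.searchsorted(-lambdas, -lam, side="left"))
        hi, lo = lambdas[k - 1], lambdas[k]
        if hi - lo <= self.knot_merge_tol:
            return coefs[k].copy()
        w = (hi - lam) / (hi - lo)
        return (1 - w) * coefs[k - 1] + w * coefs[k]

    def fit_at(self, lam: float, gamma: float | None = None) -> SparseFit:
        beta_std = self.coef_at(lam)
        beta_std[np.abs(beta_std) < ZERO_TOL] = 0.0
        beta, intercept = self.record.to_original(beta_std)
        params = PenaltyParams(
            lam=lam, gamma=self.penalties_gamma if gamma is None else gamma
        )
        return SparseFit(
            beta=beta,
            intercept=intercept,
            penalties=params,
            active_set=np.flatnonzero(beta_std),
            beta_std=beta_std,
            record=self.record,
        )

    def lambda_for_budget(self, t: float) -> float:
        """Smallest-shrinkage lambda whose solution satisfies ||beta||_1 <= t."""
        norms = np.abs(self.coefs).sum(axis=1)
        if t >= norms[-1]:
            return float(self.lambdas[-1])
        # L1 norm is piecewise linear in lambda; find the crossing segment
        k = int(np.searchsorted(norms, t, side="left"))
        if k == 0:
            return float(self.lambdas[0])
        n0, n1 = norms[k - 1], norms[k]
        l0, l1 = self.lambdas[k - 1], self.lambdas[k]
        if n1 - n0 <= 0:
            return float(l1)
        w = (t - n0) / (n1 - n0)
        return float(l0 + w * (l1 - l0))


def _solve_direction(G: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Direction d with G d = s; min-norm solution when G is singular."""
    try:
        d = np.linalg.solve(G, s)
        if np.isfinite(d).all():
            return d
    except np.linalg.LinAlgError:
        pass
    d, *_ = np.linalg.lstsq(G, s, rcond=None)
    return d


def lars_path_raw(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full LASSO homotopy path on data as given (no standardization).

    Returns (lambdas, coefs) with lambdas strictly decreasing from
    lambda_max = 2 max_j |x_j . y| down to 0.  Implements LARS with the
    LASSO modification: variables may leave the active set when their
    coefficient crosses zero.  Ties (two variables reaching the boundary
    simultaneously) admit the lower column index first.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, T = X.shape
    beta = np.zeros(T)
    c = X.T @ y
    lam = 2.0 * float(np.max(np.abs(c))) if T else 0.0
    lambdas = [lam]
    coefs = [beta.copy()]
    if lam <= ZERO_TOL:
        return np.asarray([0.0]), np.asarray([beta.copy()])

    active: list[int] = []
    signs: dict[int, float] = {}
    G_full = X.T @ X  # cached Gram matrix

    # admit the first variable(s) at lambda_max
    boundary = np.flatnonzero(np.abs(c) >= lam / 2 - ZERO_TOL)
    j0 = int(boundary.min())
    active.append(j0)
    signs[j0] = float(np.sign(c[j0]))

    max_iter = 8 * T + 100
    last_dropped: int | None = None
    for _ in range(max_iter):
        A = np.asarray(active, dtype=int)
        s = np.asarray([signs[j] for j in active])
        G = G_full[np.ix_(A, A)]
        d = _solve_direction(G, s)
        # correlation drift for all columns: a = X^T X_A d
        a = G_full[:, A] @ d

        inactive = np.setdiff1d(np.arange(T), A, assume_unique=False)
        t_best = lam / 2.0  # reaching lambda = 0
        event: tuple[str, int] | None = None

        # joining events: |2 c_j(t)| meets the shrinking boundary lambda - 2t.
        # t = 0 is legitimate (a variable exactly at the boundary whose
        # correlation decays slower than the boundary joins immediately).
        for j in inactive:
            # a just-dropped variable sits exactly on the boundary; its
            # immediate (t ~ 0) re-entry is the drop itself and is skipped,
            # but a genuine rejoin later in the segment is allowed
            min_t = 1e-10 if j == last_dropped else -1e-12
            for t_cand in (
                (lam / 2.0 - c[j]) / (1.0 - a[j]) if abs(1.0 - a[j]) > 1e-15 else np.inf,
                (lam / 2.0 + c[j]) / (1.0 + a[j]) if abs(1.0 + a[j]) > 1e-15 else np.inf,
            ):
                if min_t < t_cand < t_best - 1e-15:
                    t_best = max(t_cand, 0.0)
                    event = ("join", int(j))

        # dropping events: an active coefficient crosses zero
        for idx, j in enumerate(active):
            if abs(d[idx]) > 1e-15:
                t_cand = -beta[j] / d[idx]
                if ZERO_TOL < t_cand <= t_best + 1e-15:
                    # drops take precedence over joins at equal t
                    if t_cand < t_best - 1e-15 or event is None or event[0] == "join":
                        t_best = t_cand
                        event = ("drop", int(j))

        beta[A] += t_best * d
        lam_new = lam - 2.0 * t_best
        if event is None or lam_new <= ZERO_TOL:
            lam_new = max(lam_new, 0.0)
            lambdas.append(lam_new)
            coefs.append(beta.copy())
            if lam_new <= ZERO_TOL:
                break
        else:
            kind, j = event
            last_dropped = None
            if kind == "drop":
                beta[j] = 0.0
                active.remove(j)
                del signs[j]
                last_dropped = j
            lambdas.append(lam_new)
            coefs.append(beta.copy())
            if kind == "join":
                active.append(j)
                active.sort()
            lam = lam_new
            c = X.T @ (y - X @ beta)
            for jj in active:
                signs[jj] = float(np.sign(c[jj])) or 1.0
            if not active:
                # support emptied before lambda hit zero; re-admit at boundary
                boundary = np.flatnonzero(np.abs(c) >= lam / 2 - 1e-10)
                if boundary.size == 0:
                    lambdas.append(0.0)
                    coefs.append(beta.copy())
                    break
                j0 = int(boundary.min())
                active.append(j0)
                signs[j0] = float(np.sign(c[j0]))
            continue
        lam = lam_new

    lambdas_arr = np.asarray(lambdas)
    coefs_arr = np.asarray(coefs)
    # enforce strictly decreasing knots (merge numerically equal ones)
    keep = [0]
    for k in range(1, len(lambdas_arr)):
        if lambdas_arr[keep[-1]] - lambdas_arr[k] > 1e-12:
            keep.append(k)
        else:
            coefs_arr[keep[-1]] = coefs_arr[k]
    return lambdas_arr[keep], coefs_arr[keep]


def fit_lasso_path(problem: RegressionProblem) -> LassoPath:
    """Trace the full LASSO coefficient path of a problem."""
    Xs, ys, record = problem.standardized()
    lambdas, coefs = lars_path_raw(Xs, ys)
    return LassoPath(lambdas, coefs, record)


def fit_lasso(problem: RegressionProblem, params: PenaltyParams) -> SparseFit:
    """Minimize sum (y_i - beta.x_i)^2 + lambda sum |beta_j| exactly."""
    if params.gamma != 0:
        raise ValueError("fit_lasso requires gamma = 0; use fit_elastic_net")
    path = fit_lasso_path(problem)
    lam = path.lambda_for_budget(params.shrinkage_budget) if params.shrinkage_budget else params.lam
    fit = path.fit_at(lam)
    fit.penalties = params
    return fit


def fit_elastic_net(problem: RegressionProblem, params: PenaltyParams) -> SparseFit:
    """Minimize sum (y - beta.x)^2 + lambda |beta|_1 + gamma |beta|_2^2.

    Solved as a LASSO on the augmented design [X; sqrt(gamma) I] with the
    response padded by T zeros; gamma = 0 short-circuits to fit_lasso so
    the two are bit-for-bit identical in that case.
    """
    if params.gamma == 0:
        return fit_lasso(problem, PenaltyParams(lam=params.lam, shrinkage_budget=params.shrinkage_budget))
    Xs, ys, record = problem.standardized()
    T = Xs.shape[1]
    Xa = np.vstack([Xs, np.sqrt(params.gamma) * np.eye(T)])
    # keep the augmentation out of the active-set exclusion for constant cols
    Xa[:, record.constant_columns] = 0.0
    ya = np.concatenate([ys, np.zeros(T)])
    lambdas, coefs = lars_path_raw(Xa, ya)
    path = LassoPath(lambdas, coefs, record, penalties_gamma=params.gamma)
    lam = path.lambda_for_budget(params.shrinkage_budget) if params.shrinkage_budget else params.lam
    fit = path.fit_at(lam)
    fit.penalties = params
    return fit


def elastic_net_path(problem: RegressionProblem, gamma: float) -> LassoPath:
    """Full coefficient path of the elastic net at fixed gamma."""
    if gamma == 0:
        return fit_lasso_path(problem)
    Xs, ys, record = problem.standardized()
    T = Xs.shape[1]
    Xa = np.vstack([Xs, np.sqrt(gamma) * np.eye(T)])
    Xa[:, record.constant_columns] = 0.0
    ya = np.concatenate([ys, np.zeros(T)])
    lambdas, coefs = lars_path_raw(Xa, ya)
    return LassoPath(lambdas, coefs, record, penalties_gamma=gamma)


def lambda_max(problem: RegressionProblem) -> float:
    """Smallest lambda for which the LASSO solution is identically zero."""
    Xs, ys, _ = problem.standardized()
    return 2.0 * float(np.max(np.abs(Xs.T @ ys)))


def kkt_violation(
    Xs: np.ndarray, ys: np.ndarray, beta: np.ndarray, lam: float, gamma: float = 0.0
) -> float:
    """Max violation of the stationarity conditions on standardized data.

    For active j: 2 x_j.(y - X beta) - 2 gamma beta_j = lam * sign(beta_j);
    for inactive j: |2 x_j.(y - X beta)| <= lam.
    """
    g = 2.0 * Xs.T @ (ys - Xs @ beta) - 2.0 * gamma * beta
    active = np.abs(beta) > ZERO_TOL
    viol = 0.0
    if active.any():
        viol = float(np.max(np.abs(g[active] - lam * np.sign(beta[active]))))
    if (~active).any():
        viol = max(viol, float(np.max(np.maximum(np.abs(g[~active]) - lam, 0.0))))
    return viol
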