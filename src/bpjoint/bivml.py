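"""Bivariate two-level random-intercept linear model: likelihood and ML fitting.

Model
-----
For woman ``i`` in household ``j`` with covariate row ``x_ij``::

    y1_ij = x_ij' b1 + h1_j + e1_ij      (systolic, mmHg)
    y2_ij = x_ij' b2 + h2_j + e2_ij      (diastolic, mmHg)

    (h1_j, h2_j)  ~ N(0, Sigma_h)        household random intercepts
    (e1_ij,e2_ij) ~ N(0, Sigma_e)        woman-level residuals

Both outcomes share the same design matrix. Stacking the two outcomes within
each woman (outcome-major: SBP then DBP) the marginal covariance of one
household with ``n`` women is the exchangeable block matrix::

    V_n = I_n (x) Sigma_e + J_n (x) Sigma_h

whose log-determinant is ``(n-1) logdet Sigma_e + logdet(Sigma_e + n Sigma_h)``
and whose inverse acts via the mean/deviation split, so the likelihood never
forms a dense ``2n x 2n`` matrix. Because household sizes are tiny integers the
whole log-likelihood reduces to a handful of sufficient statistics per size
class and evaluates in constant time in the number of women.

Fitting is direct maximum likelihood: the fixed effects are profiled out by
generalized least squares at each variance-component iterate, and the two
covariance matrices are optimized in log-Cholesky parameterization with
L-BFGS-B using the analytic profiled gradient. For Gaussian multilevel models
this ML optimum coincides with the IGLS fixed point of the classic multilevel
software, so the two routes estimate the same quantities. REML is not
implemented.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize

__all__ = [
    "VarianceComponents",
    "ModelParams",
    "FitResult",
    "HouseholdCovariance",
    "household_marginal_covariance",
    "log_likelihood",
    "fit_bivariate_multilevel",
    "fit_univariate_multilevel",
    "fit_single_level_multivariate",
]

_LOG2PI = math.log(2.0 * math.pi)
#: Cholesky-diagonal floor for Sigma_h: variances may collapse to ~1e-8 (boundary).
_CHOL_DIAG_FLOOR = math.log(1e-4)
_CHOL_DIAG_CEIL = math.log(1e4)

OUTCOME_COLUMNS = ("sbp", "dbp")


def _as_sym(a) -> np.ndarray:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"matrix must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10 * (1 + np.abs(a).max())):
        raise ValueError("matrix must be symmetric")
    return 0.5 * (a + a.T)


@dataclass(frozen=True)
class VarianceComponents:
    """Household-level covariance ``sigma_h`` and woman-level ``sigma_e`` (mmHg^2).

    For the bivariate model both are 2x2 symmetric matrices; the univariate
    special case uses 1x1 matrices. ``sigma_e`` must be positive definite,
    ``sigma_h`` positive semi-definite.
    """

    sigma_h: np.ndarray
    sigma_e: np.ndarray

    def __post_init__(self) -> None:
        sh = _as_sym(self.sigma_h)
        se = _as_sym(self.sigma_e)
        if sh.shape != se.shape:
            raise ValueError("sigma_h and sigma_e must have the same shape")
        if np.linalg.eigvalsh(sh).min() < -1e-8 * max(1.0, np.abs(sh).max()):
            raise ValueError("sigma_h must be positive semi-definite")
        if np.linalg.eigvalsh(se).min() <= 0:
            raise ValueError("sigma_e must be positive definite")
        object.__setattr__(self, "sigma_h", sh)
        object.__setattr__(self, "sigma_e", se)

    @property
    def n_outcomes(self) -> int:
        return self.sigma_e.shape[0]

    @classmethod
    def from_correlations(cls, var_h: tuple[float, float], rho_h: float,
                          var_e: tuple[float, float], rho_e: float) -> "VarianceComponents":
        """Build 2x2 components from per-outcome variances and level correlations."""
        def mat(v, r):
            off = r * math.sqrt(v[0] * v[1])
            return np.array([[v[0], off], [off, v[1]]])
        return cls(sigma_h=mat(var_h, rho_h), sigma_e=mat(var_e, rho_e))

    def to_dict(self) -> dict:
        return {"sigma_h": self.sigma_h.tolist(), "sigma_e": self.sigma_e.tolist()}


@dataclass(frozen=True)
class ModelParams:
    """Fixed effects per outcome plus the variance components.

    ``beta1`` aligns with the design columns for the first outcome (SBP);
    ``beta2`` likewise for DBP, and is ``None`` for a univariate model.
    """

    beta1: np.ndarray
    beta2: np.ndarray | None
    varcomp: VarianceComponents

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta1", np.asarray(self.beta1, dtype=float))
        if self.beta2 is not None:
            b2 = np.asarray(self.beta2, dtype=float)
            if b2.shape != self.beta1.shape:
                raise ValueError("beta1 and beta2 must have equal length")
            object.__setattr__(self, "beta2", b2)

    @property
    def beta_matrix(self) -> np.ndarray:
        """p x d matrix with one column per outcome."""
        cols = [self.beta1] if self.beta2 is None else [self.beta1, self.beta2]
        return np.column_stack(cols)


@dataclass(frozen=True)
class FitResult:
    """A fitted model: estimates, joint coefficient covariance and fit metadata.

    ``vcov_fixed`` is the covariance of the stacked coefficient vector
    ``(beta1, beta2)`` (or just ``beta1`` for univariate fits), ordered to
    match ``design_labels`` within each outcome block.
    """

    params: ModelParams
    vcov_fixed: np.ndarray
    loglik: float
    n_params: int
    n_women: int
    n_households: int
    converged: bool
    model_tag: str
    design_labels: tuple[str, ...]
    outcome: str | None = None
    boundary_sigma_h: bool = False
    n_multiwoman_households: int = 0
    n_iterations: int = 0
    optimizer_message: str = ""

    @property
    def n_outcomes(self) -> int:
        return self.params.varcomp.n_outcomes

    def stacked_beta(self) -> np.ndarray:
        b = self.params
        return b.beta1 if b.beta2 is None else np.concatenate([b.beta1, b.beta2])

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_fixed))

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "outcome": self.outcome,
            "design_labels": list(self.design_labels),
            "beta1": self.params.beta1.tolist(),
            "beta2": None if self.params.beta2 is None else self.params.beta2.tolist(),
            "varcomp": self.params.varcomp.to_dict(),
            "vcov_fixed": self.vcov_fixed.tolist(),
            "standard_errors": self.standard_errors().tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_women": self.n_women,
            "n_households": self.n_households,
            "n_multiwoman_households": self.n_multiwoman_households,
            "converged": self.converged,
            "boundary_sigma_h": self.boundary_sigma_h,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Exchangeable household covariance operator
# ---------------------------------------------------------------------------

class HouseholdCovariance:
    """Covariance operator ``V = I_n (x) Sigma_e + J_n (x) Sigma_h`` for one household.

    Supplies the log-determinant and quadratic forms without constructing the
    dense ``dn x dn`` matrix. Vectors are stacked outcome-major within woman.
    """

    def __init__(self, varcomp: VarianceComponents, n_women: int):
        if n_women < 1:
            raise ValueError("n_women must be >= 1")
        self.varcomp = varcomp
        self.n = int(n_women)
        self.d = varcomp.n_outcomes
        se, sh = varcomp.sigma_e, varcomp.sigma_h
        self._e_inv = np.linalg.inv(se)
        m = se + self.n * sh
        self._m_inv = np.linalg.inv(m)
        sign_e, ld_e = np.linalg.slogdet(se)
        sign_m, ld_m = np.linalg.slogdet(m)
        if sign_e <= 0 or sign_m <= 0:
            raise ValueError("covariance components are not positive definite")
        self.logdet = (self.n - 1) * ld_e + ld_m

    def _split(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n * self.d:
            raise ValueError(f"expected vector of length {self.n * self.d}")
        return x.reshape(self.n, self.d)

    def solve(self, x: np.ndarray) -> np.ndarray:
        """Return ``V^{-1} x`` via the mean/deviation decomposition."""
        xm = self._split(x)
        xbar = xm.mean(axis=0)
        u = (xm - xbar) @ self._e_inv + xbar @ self._m_inv
        return u.reshape(-1)

    def quad_form(self, x: np.ndarray, y: np.ndarray | None = None) -> float:
        """``x' V^{-1} y`` (defaults to ``y = x``)."""
        y = x if y is None else y
        return float(np.dot(np.asarray(x, dtype=float), self.solve(y)))

    def dense(self) -> np.ndarray:
        """Materialize V (for oracles and tiny households only)."""
        i_n = np.eye(self.n)
        j_n = np.ones((self.n, self.n))
        return np.kron(i_n, self.varcomp.sigma_e) + np.kron(j_n, self.varcomp.sigma_h)

    def log_density(self, resid: np.ndarray) -> float:
        """Gaussian log-density of a stacked residual vector under N(0, V)."""
        q = self.quad_form(resid)
        return -0.5 * (self.n * self.d * _LOG2PI + self.logdet + q)


def household_marginal_covariance(varcomp: VarianceComponents, n_women: int) -> HouseholdCovariance:
    return HouseholdCovariance(varcomp, n_women)


# ---------------------------------------------------------------------------
# Sufficient statistics by household-size class
# ---------------------------------------------------------------------------

class _SizeClassStats:
    """Per-household-size cross-products; everything the likelihood needs."""

    __slots__ = ("n", "m", "c_xx", "c_xy", "c_yy", "t_xx", "t_xy", "t_yy")

    def __init__(self, n, m, c_xx, c_xy, c_yy, t_xx, t_xy, t_yy):
        self.n, self.m = n, m
        self.c_xx, self.c_xy, self.c_yy = c_xx, c_xy, c_yy
        self.t_xx, self.t_xy, self.t_yy = t_xx, t_xy, t_yy


class _SuffStats:
    """Sufficient statistics of (X, Y, household) grouped by household size.

    For households of size n with women rows x_i (p-vector), y_i (d-vector),
    household sums s_j = sum x_i, t_j = sum y_i, stores the within-class sums
    of x x', x y', y y' and of s s', s t', t t'. The exact log-likelihood, the
    GLS normal equations and the analytic score are all linear/quadratic
    functionals of these, so each optimizer step costs O(#size classes).
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, household: np.ndarray):
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.ndim == 2 and y.shape[0] == 1 and x.shape[0] != 1:
            y = y.T
        if y.shape[0] != x.shape[0]:
            raise ValueError("outcomes and design have different numbers of rows")
        codes, _ = pd.factorize(household)
        sizes = np.bincount(codes)
        self.n_women = x.shape[0]
        self.n_households = len(sizes)
        self.n_multiwoman = int((sizes > 1).sum())
        self.p = x.shape[1]
        self.d = y.shape[1]
        self.classes: list[_SizeClassStats] = []
        woman_size = sizes[codes]
        for n in np.unique(sizes):
            sel = woman_size == n
            xs, ys = x[sel], y[sel]
            hh = codes[sel]
            order = np.argsort(hh, kind="stable")
            xs, ys = xs[order], ys[order]
            m = int((sizes == n).sum())
            s = xs.reshape(m, n, self.p).sum(axis=1)
            t = ys.reshape(m, n, self.d).sum(axis=1)
            self.classes.append(_SizeClassStats(
                n=int(n), m=m,
                c_xx=xs.T @ xs, c_xy=xs.T @ ys, c_yy=ys.T @ ys,
                t_xx=s.T @ s, t_xy=s.T @ t, t_yy=t.T @ t,
            ))

    # -- likelihood pieces ---------------------------------------------------

    def _level_inverses(self, sigma_h, sigma_e):
        e_inv = np.linalg.inv(sigma_e)
        sign, ld_e = np.linalg.slogdet(sigma_e)
        if sign <= 0:
            raise np.linalg.LinAlgError("sigma_e not positive definite")
        out = {}
        for c in self.classes:
            m_mat = sigma_e + c.n * sigma_h
            m_inv = np.linalg.inv(m_mat)
            sign_m, ld_m = np.linalg.slogdet(m_mat)
            if sign_m <= 0:
                raise np.linalg.LinAlgError("sigma_e + n*sigma_h not positive definite")
            out[c.n] = (m_inv, ld_m)
        return e_inv, ld_e, out

    def gls(self, sigma_h: np.ndarray, sigma_e: np.ndarray):
        """GLS fixed effects and their covariance at the given components.

        Returns ``(beta_matrix p x d, vcov dp x dp, normal_matrix)`` with the
        stacked order (outcome blocks of p, i.e. column-major vec of B).
        """
        e_inv, _, m_map = self._level_inverses(sigma_h, sigma_e)
        dp = self.d * self.p
        a = np.zeros((dp, dp))
        b = np.zeros((self.p, self.d))
        for c in self.classes:
            m_inv, _ = m_map[c.n]
            w = (m_inv - e_inv) / c.n
            a += np.kron(e_inv, c.c_xx) + np.kron(w, c.t_xx)
            b += c.c_xy @ e_inv + c.t_xy @ w
        beta_vec = np.linalg.solve(a, b.reshape(-1, order="F"))
        vcov = np.linalg.inv(a)
        vcov = 0.5 * (vcov + vcov.T)
        return beta_vec.reshape(self.p, self.d, order="F"), vcov, a

    def _residual_crossprods(self, beta: np.ndarray):
        """Per size class: sums of r r' per woman and of (sum r)(sum r)' per household."""
        out = []
        for c in self.classes:
            srr_w = c.c_yy - beta.T @ c.c_xy - c.c_xy.T @ beta + beta.T @ c.c_xx @ beta
            srr_m = c.t_yy - beta.T @ c.t_xy - c.t_xy.T @ beta + beta.T @ c.t_xx @ beta
            out.append((c, srr_w, srr_m))
        return out

    def loglik(self, beta: np.ndarray, sigma_h: np.ndarray, sigma_e: np.ndarray) -> float:
        e_inv, ld_e, m_map = self._level_inverses(sigma_h, sigma_e)
        total = self.d * self.n_women * _LOG2PI
        for c, srr_w, srr_m in self._residual_crossprods(beta):
            m_inv, ld_m = m_map[c.n]
            total += c.m * ((c.n - 1) * ld_e + ld_m)
            total += float(np.tensordot(e_inv, srr_w))
            total += float(np.tensordot((m_inv - e_inv) / c.n, srr_m))
        return -0.5 * total

    def score_varcomp(self, beta: np.ndarray, sigma_h: np.ndarray, sigma_e: np.ndarray):
        """Gradients of the log-likelihood w.r.t. Sigma_h and Sigma_e (symmetric sense)."""
        e_inv, _, m_map = self._level_inverses(sigma_h, sigma_e)
        g_h = np.zeros_like(sigma_h)
        g_e = np.zeros_like(sigma_e)
        for c, srr_w, srr_m in self._residual_crossprods(beta):
            m_inv, _ = m_map[c.n]
            # trace terms (d logdet)
            g_e -= c.m * ((c.n - 1) * e_inv + m_inv)
            g_h -= c.m * c.n * m_inv
            # quadratic terms (d of r' V^-1 r); u = V^-1 r decomposition
            uu_w = e_inv @ (srr_w - srr_m / c.n) @ e_inv + m_inv @ srr_m @ m_inv / c.n
            uu_m = m_inv @ srr_m @ m_inv
            g_e += uu_w
            g_h += uu_m
        return 0.5 * g_h, 0.5 * g_e


def _make_suffstats(data: pd.DataFrame, design: np.ndarray,
                    outcomes=OUTCOME_COLUMNS) -> _SuffStats:
    y = data.loc[:, list(outcomes)].to_numpy(dtype=float)
    return _SuffStats(y, np.asarray(design, dtype=float), data["household_id"].to_numpy())


def log_likelihood(params: ModelParams, data: pd.DataFrame, design: np.ndarray,
                   outcome: str = "sbp") -> float:
    """Exact log-likelihood of the data under the given parameters.

    Sums, over households, the Gaussian log-density of the stacked residuals
    under the exchangeable household covariance. For univariate params
    (1x1 components) the single modelled outcome column is ``outcome``.
    """
    design = np.asarray(design, dtype=float)
    d = params.varcomp.n_outcomes
    outcomes = OUTCOME_COLUMNS if d == 2 else (outcome,)
    stats = _make_suffstats(data, design, outcomes)
    if design.shape[1] != params.beta1.shape[0]:
        raise ValueError("design columns do not match coefficient length")
    return stats.loglik(params.beta_matrix, params.varcomp.sigma_h, params.varcomp.sigma_e)


# ---------------------------------------------------------------------------
# Log-Cholesky parameterization
# ---------------------------------------------------------------------------

def _chol_to_theta(l_mat: np.ndarray) -> np.ndarray:
    d = l_mat.shape[0]
    theta = []
    for i in range(d):
        for j in range(i + 1):
            theta.append(math.log(max(l_mat[i, i], 1e-4)) if i == j else l_mat[i, j])
    return np.array(theta)


def _theta_to_chol(theta: np.ndarray, d: int) -> np.ndarray:
    l_mat = np.zeros((d, d))
    k = 0
    for i in range(d):
        for j in range(i + 1):
            l_mat[i, j] = math.exp(theta[k]) if i == j else theta[k]
            k += 1
    return l_mat


def _grad_sigma_to_theta(g_sigma: np.ndarray, l_mat: np.ndarray) -> np.ndarray:
    """Chain rule through Sigma = L L' and the log on the diagonal."""
    g_l = 2.0 * g_sigma @ l_mat
    d = l_mat.shape[0]
    out = []
    for i in range(d):
        for j in range(i + 1):
            out.append(g_l[i, i] * l_mat[i, i] if i == j else g_l[i, j])
    return np.array(out)


def _n_tri(d: int) -> int:
    return d * (d + 1) // 2


def _safe_chol(sigma: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Cholesky of a possibly semi-definite start value, eigenvalue-floored."""
    w, v = np.linalg.eigh(_as_sym(sigma))
    w = np.maximum(w, floor)
    return np.linalg.cholesky(v @ np.diag(w) @ v.T)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_design(design: np.ndarray, labels) -> None:
    design = np.asarray(design, dtype=float)
    p = design.shape[1]
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = design.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < p:
        bad = sorted(piv[rank:])
        names = [labels[i] if labels is not None else str(i) for i in bad]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {names}")


def _start_values(stats: _SuffStats):
    """Sigma_e from pooled per-woman OLS residual covariance; Sigma_h by ANOVA moments."""
    beta0, _, _ = _ols(stats)
    # pooled residual covariance (total, woman level)
    srr = sum(srr_w for _, srr_w, _ in stats._residual_crossprods(beta0))
    sigma_tot = srr / stats.n_women
    # between-household moment: E[rbar rbar'] = Sigma_h + Sigma_e / n, rbar = t / n
    crossprods = stats._residual_crossprods(beta0)
    weight = sum(c.m for c, _, _ in crossprods)
    inv_n = sum(c.m / c.n for c, _, _ in crossprods)
    between = sum(srr_m / c.n**2 for c, _, srr_m in crossprods)
    sigma_h0 = between / weight - sigma_tot * (inv_n / weight)
    # floor to PSD; fall back to a small multiple of the total if degenerate
    w, v = np.linalg.eigh(_as_sym(sigma_h0))
    if w.max() <= 0:
        sigma_h0 = 0.05 * sigma_tot
    else:
        sigma_h0 = v @ np.diag(np.maximum(w, 1e-4)) @ v.T
    sigma_e0 = sigma_tot - sigma_h0
    if np.linalg.eigvalsh(sigma_e0).min() <= 1e-6:
        sigma_e0 = sigma_tot
    return _as_sym(sigma_h0), _as_sym(sigma_e0)


def _ols(stats: _SuffStats):
    """Per-outcome least squares (identical to GLS when Sigma_h = 0)."""
    c_xx = sum(c.c_xx for c in stats.classes)
    c_xy = sum(c.c_xy for c in stats.classes)
    c_yy = sum(c.c_yy for c in stats.classes)
    beta = np.linalg.solve(c_xx, c_xy)
    srr = c_yy - beta.T @ c_xy - c_xy.T @ beta + beta.T @ c_xx @ beta
    return beta, c_xx, srr


def _fit_ml(stats: _SuffStats, labels, model_tag: str, outcome: str | None = None,
            max_iter: int = 500) -> FitResult:
    d = stats.d
    n_tri = _n_tri(d)
    sigma_h0, sigma_e0 = _start_values(stats)
    theta0 = np.concatenate([
        _chol_to_theta(_safe_chol(sigma_h0, floor=1e-4)),
        _chol_to_theta(_safe_chol(sigma_e0, floor=1e-3)),
    ])

    diag_idx = [k for k, (i, j) in enumerate(
        (i, j) for i in range(d) for j in range(i + 1)) if i == j]
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * (2 * n_tri)
    for k in diag_idx:
        bounds[k] = (_CHOL_DIAG_FLOOR, _CHOL_DIAG_CEIL)          # Sigma_h diagonal
        bounds[n_tri + k] = (_CHOL_DIAG_FLOOR + math.log(1e-2), _CHOL_DIAG_CEIL)

    def unpack(theta):
        l_h = _theta_to_chol(theta[:n_tri], d)
        l_e = _theta_to_chol(theta[n_tri:], d)
        return l_h, l_e

    def neg_profiled(theta):
        l_h, l_e = unpack(theta)
        sigma_h, sigma_e = l_h @ l_h.T, l_e @ l_e.T
        beta, _, _ = stats.gls(sigma_h, sigma_e)
        ll = stats.loglik(beta, sigma_h, sigma_e)
        g_h, g_e = stats.score_varcomp(beta, sigma_h, sigma_e)
        grad = np.concatenate([
            _grad_sigma_to_theta(g_h, l_h),
            _grad_sigma_to_theta(g_e, l_e),
        ])
        return -ll, -grad

    res = minimize(neg_profiled, theta0, jac=True, method="L-BFGS-B",
                   bounds=bounds,
                   options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6})

    l_h, l_e = unpack(res.x)
    sigma_h = l_h @ l_h.T
    sigma_e = l_e @ l_e.T
    beta, vcov, _ = stats.gls(sigma_h, sigma_e)
    ll = stats.loglik(beta, sigma_h, sigma_e)
    boundary = bool(np.any(res.x[np.array(diag_idx)] <= _CHOL_DIAG_FLOOR + 1e-9))
    varcomp = VarianceComponents(sigma_h=sigma_h, sigma_e=sigma_e)
    params = ModelParams(beta1=beta[:, 0],
                         beta2=beta[:, 1] if d == 2 else None,
                         varcomp=varcomp)
    n_params = d * stats.p + 2 * n_tri
    return FitResult(
        params=params, vcov_fixed=vcov, loglik=float(ll), n_params=n_params,
        n_women=stats.n_women, n_households=stats.n_households,
        converged=bool(res.success), model_tag=model_tag,
        design_labels=tuple(labels) if labels is not None else tuple(
            str(i) for i in range(stats.p)),
        outcome=outcome, boundary_sigma_h=boundary,
        n_multiwoman_households=stats.n_multiwoman,
        n_iterations=int(res.nit), optimizer_message=str(res.message),
    )


def fit_bivariate_multilevel(data: pd.DataFrame, design: np.ndarray,
                             labels=None) -> FitResult:
    """ML fit of the joint SBP/DBP two-level random-intercept model.

    ``data`` must carry ``sbp``, ``dbp`` and ``household_id``; ``design`` is the
    shared covariate matrix (one row per woman). The household covariance
    Sigma_h is identified mainly by multi-woman households, whose count is
    recorded on the result. Non-convergence is reported on the result, never
    silently ignored.
    """
    design = np.asarray(design, dtype=float)
    _check_design(design, labels)
    stats = _make_suffstats(data, design)
    if stats.n_households < 2:
        raise ValueError("need at least 2 households")
    return _fit_ml(stats, labels, model_tag="bivariate_multilevel")


def fit_univariate_multilevel(data: pd.DataFrame, design: np.ndarray,
                              outcome: str, labels=None) -> FitResult:
    """ML fit of the classic one-outcome two-level model for SBP or DBP."""
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {OUTCOME_COLUMNS}")
    design = np.asarray(design, dtype=float)
    _check_design(design, labels)
    y = data[outcome].to_numpy(dtype=float)[:, None]
    stats = _SuffStats(y, design, data["household_id"].to_numpy())
    if stats.n_households < 2:
        raise ValueError("need at least 2 households")
    return _fit_ml(stats, labels, model_tag="univariate_multilevel", outcome=outcome)


def fit_single_level_multivariate(data: pd.DataFrame, design: np.ndarray,
                                  labels=None) -> FitResult:
    """ML fit of the woman-level-only joint model (Sigma_h constrained to zero).

    With no household term and the same design for both outcomes, the ML fixed
    effects are the per-outcome least-squares fits and Sigma_e is the residual
    MLE covariance, so the fit is closed-form. Serves as the null model of the
    likelihood-ratio comparison against the multilevel fit.
    """
    design = np.asarray(design, dtype=float)
    _check_design(design, labels)
    stats = _make_suffstats(data, design)
    beta, c_xx, srr = _ols(stats)
    n = stats.n_women
    sigma_e = _as_sym(srr / n)
    if np.linalg.eigvalsh(sigma_e).min() <= 0:
        raise ValueError("residual covariance is singular")
    d = stats.d
    ll = -0.5 * (d * n * _LOG2PI + n * float(np.linalg.slogdet(sigma_e)[1]) + d * n)
    vcov = np.kron(sigma_e, np.linalg.inv(c_xx))
    varcomp = VarianceComponents(sigma_h=np.zeros((d, d)), sigma_e=sigma_e)
    params = ModelParams(beta1=beta[:, 0], beta2=beta[:, 1], varcomp=varcomp)
    return FitResult(
        params=params, vcov_fixed=vcov, loglik=float(ll),
        n_params=d * stats.p + _n_tri(d),
        n_women=n, n_households=stats.n_households, converged=True,
        model_tag="single_level_multivariate",
        design_labels=tuple(labels) if labels is not None else tuple(
            str(i) for i in range(stats.p)),
        n_multiwoman_households=stats.n_multiwoman,
    )
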