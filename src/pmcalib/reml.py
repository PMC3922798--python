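"""Profiled REML engine for Gaussian linear mixed models with independent
scaled-identity variance components.

The marginal model is

    y = X beta + sum_k Z_k b_k + e,   b_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_w^2 I)

where each Z_k is an (indicator x design-column) matrix for one random effect
(e.g. a city random intercept, a subject random intercept, a city random
slope on the surrogate).  All random effects are assumed independent of each
other, exactly as the calibration models write them; a subject random
intercept induces compound-symmetry (exchangeable) within-subject
correlation, so no separate residual correlation structure is needed.

Estimation profiles out the fixed effects and the residual variance, leaving
an optimisation over log variance ratios r_k = sigma_k^2 / sigma_w^2.  Because
every random effect is nested in a blocking factor (city, or subject for the
single-city model), the marginal covariance is block diagonal and each
criterion evaluation reduces, via the Woodbury identity, to small q x q
solves per block (q = number of random-effect columns in the block), making
simulation studies with thousands of refits practical.

Variance components are constrained positive through the log
parameterisation; estimates that collapse below 1e-8 x var(y) are flagged as
boundary solutions (these feed the 50:50 mixture likelihood-ratio test for
a variance component).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["RandomEffect", "VarianceComponentsModel", "VCFit", "marginal_covariance"]

BOUNDARY_REL_TOL = 1e-8  # sigma_k^2 below this times var(y) counts as boundary
_LOG_R_BOUNDS = (-30.0, 12.0)


@dataclass(frozen=True)
class RandomEffect:
    """One independent variance component.

    groups: integer codes (length n) of the grouping factor; values: the
    random-effect design column (ones for a random intercept, the surrogate
    for a random slope).
    """

    name: str
    groups: np.ndarray
    values: np.ndarray


@dataclass
class VCFit:
    """REML (or ML) fit of a variance-components model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: dict  # effect name -> variance component
    sigma2_resid: float
    llf: float
    reml: bool
    converged: bool
    boundary: list = field(default_factory=list)  # names of components at 0
    n_obs: int = 0
    n_params: int = 0
    message: str = ""
    log_ratios: np.ndarray | None = None


def marginal_covariance(effects, sigma2: dict, sigma2_resid: float, n: int,
                        order=None) -> np.ndarray:
    """Dense marginal covariance V implied by the random-effects structure.

    V = sigma_w^2 I + sum_k sigma_k^2 * (v v' masked to shared groups).
    Used by tests and small-scale diagnostics; the fitter itself never
    materialises V.
    """
    if sigma2_resid < 0 or any(v < 0 for v in sigma2.values()):
        raise ValueError("variance components must be >= 0")
    V = sigma2_resid * np.eye(n)
    for eff in effects:
        s2 = sigma2[eff.name]
        g = np.asarray(eff.groups)
        v = np.asarray(eff.values, dtype=float)
        same = g[:, None] == g[None, :]
        V += s2 * same * np.outer(v, v)
    return V


class VarianceComponentsModel:
    """Low-level profiled-REML fitter (see module docstring).

    Parameters
    ----------
    y, X : response vector and fixed-effects design matrix.
    effects : sequence of :class:`RandomEffect`; may be empty (plain OLS).
    blocks : integer codes of the coarsest grouping factor; every effect's
        groups must be nested within it (rows of different blocks are
        marginally independent).
    """

    def __init__(self, y, X, effects, blocks, xnames=None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.n, self.p = self.X.shape
        if len(self.y) != self.n:
            raise ValueError("y and X have incompatible shapes")
        self.effects = list(effects)
        self.K = len(self.effects)
        self.xnames = list(xnames) if xnames is not None else [
            f"x{j}" for j in range(self.p)
        ]
        blocks = np.asarray(blocks)
        for eff in self.effects:
            pairs = set(zip(np.asarray(eff.groups).tolist(), blocks.tolist()))
            if len(pairs) != len(set(np.asarray(eff.groups).tolist())):
                raise ValueError(
                    f"random effect {eff.name!r} is not nested within the blocks"
                )
        self._precompute(blocks)

    # -- block precomputation ------------------------------------------------

    def _precompute(self, blocks):
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self._blocks = []
        self._col_effect = []  # per block: effect index of each U column
        for b in np.unique(blocks):
            idx = np.flatnonzero(blocks == b)
            cols = []
            col_eff = []
            for k, eff in enumerate(self.effects):
                g = np.asarray(eff.groups)[idx]
                v = np.asarray(eff.values, dtype=float)[idx]
                for lev in np.unique(g):
                    col = np.where(g == lev, v, 0.0)
                    cols.append(col)
                    col_eff.append(k)
            if cols:
                U = np.column_stack(cols)
            else:
                U = np.zeros((len(idx), 0))
            Xb = self.X[idx]
            yb = self.y[idx]
            self._blocks.append(
                {
                    "G": U.T @ U,
                    "UX": U.T @ Xb,
                    "Uy": U.T @ yb,
                    "q": U.shape[1],
                    "n": len(idx),
                }
            )
            self._col_effect.append(np.asarray(col_eff, dtype=int))
        self.group_sizes = [
            np.unique(np.asarray(eff.groups), return_counts=True)[1]
            for eff in self.effects
        ]

    # -- criterion -------------------------------------------------------------

    def _assemble(self, log_ratios):
        """Accumulate logdet(W), X'W^-1X, X'W^-1y, y'W^-1y across blocks."""
        r = np.exp(np.asarray(log_ratios, dtype=float))
        if len(r) != self.K:
            raise ValueError("wrong number of variance ratios")
        A = self.XtX.copy()
        bvec = self.Xty.copy()
        c = self.yty
        logdetW = 0.0
        for blk, col_eff in zip(self._blocks, self._col_effect):
            if blk["q"] == 0:
                continue
            s = np.sqrt(r[col_eff])
            M = blk["G"] * np.outer(s, s)
            M[np.diag_indices_from(M)] += 1.0
            cf = linalg.cho_factor(M, lower=True, check_finite=False)
            logdetW += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            T = s[:, None] * blk["UX"]
            t = s * blk["Uy"]
            MiT = linalg.cho_solve(cf, T, check_finite=False)
            Mit = linalg.cho_solve(cf, t, check_finite=False)
            A -= T.T @ MiT
            bvec -= T.T @ Mit
            c -= float(t @ Mit)
        return A, bvec, c, logdetW

    def profiled_criterion(self, log_ratios, reml: bool = True,
                           return_extra: bool = False):
        """Profiled log-likelihood at variance ratios exp(log_ratios).

        The fixed effects and the residual variance are profiled out
        analytically: beta is the GLS solution at the implied W and
        sigma_w^2 = RSS_gls / (n - p) under REML (RSS_gls / n under ML).
        The REML criterion includes the -(1/2) log|X'W^-1X| adjustment and
        the full 2*pi constants.
        """
        A, bvec, c, logdetW = self._assemble(log_ratios)
        n, p = self.n, self.p
        try:
            cf = linalg.cho_factor(A, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return (-np.inf, None) if return_extra else -np.inf
        beta = linalg.cho_solve(cf, bvec, check_finite=False)
        rss = max(c - float(bvec @ beta), 1e-300)
        if reml:
            dof = n - p
            sigma2 = rss / dof
            logdetA = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            ll = -0.5 * (logdetW + logdetA + dof * (1.0 + math.log(2 * math.pi * sigma2)))
        else:
            sigma2 = rss / n
            ll = -0.5 * (logdetW + n * (1.0 + math.log(2 * math.pi * sigma2)))
        if return_extra:
            Ainv = linalg.cho_solve(cf, np.eye(p), check_finite=False)
            return ll, {"beta": beta, "sigma2": sigma2, "cov_beta": sigma2 * Ainv}
        return ll

    def fixed_effects_at(self, log_ratios, reml: bool = True):
        """GLS fixed effects, their covariance and sigma_w^2 at given ratios."""
        ll, extra = self.profiled_criterion(log_ratios, reml=reml, return_extra=True)
        if extra is None:
            raise linalg.LinAlgError("singular fixed-effects information")
        return extra["beta"], extra["cov_beta"], extra["sigma2"], ll

    # -- fit ---------------------------------------------------------------

    def _start(self):
        """Scale-aware starting ratios: 0.5 / mean(column^2) per effect."""
        x0 = np.empty(self.K)
        for k, eff in enumerate(self.effects):
            msq = float(np.mean(np.asarray(eff.values, dtype=float) ** 2))
            x0[k] = math.log(0.5 / max(msq, 1e-12))
        return x0

    def check_identifiability(self):
        """Names of random intercepts indistinguishable from the residual
        (every group has a single observation)."""
        out = []
        for eff, sizes in zip(self.effects, self.group_sizes):
            if np.all(sizes == 1):
                out.append(eff.name)
        return out

    def fit(self, reml: bool = True, n_restarts: int = 3, seed: int = 0) -> VCFit:
        vary = float(np.var(self.y)) if self.n > 1 else 1.0
        if self.K == 0:
            beta, cov, s2, ll = self.fixed_effects_at(np.empty(0), reml=reml)
            return VCFit(beta, cov, {}, s2, ll, reml, True,
                         n_obs=self.n, n_params=self.p,
                         log_ratios=np.empty(0))

        def neg(theta):
            return -self.profiled_criterion(theta, reml=reml)

        rng = np.random.default_rng(seed)
        best = None
        x0 = self._start()
        message = ""
        for attempt in range(n_restarts + 1):
            start = x0 if attempt == 0 else x0 + rng.normal(0, 1.5, self.K)
            res = optimize.minimize(
                neg, start, method="L-BFGS-B",
                bounds=[_LOG_R_BOUNDS] * self.K,
                options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
                message = str(res.message)
            if best.success and attempt >= 0:
                break
        # boundary polish: a component drifting toward zero can stall the
        # quasi-Newton iteration in a flat region; pin tiny ratios at the
        # bound and re-optimise, keeping whichever solution is better
        tiny = best.x < -3.0
        if tiny.any():
            th2 = best.x.copy()
            th2[tiny] = _LOG_R_BOUNDS[0]
            res2 = optimize.minimize(
                neg, th2, method="L-BFGS-B",
                bounds=[_LOG_R_BOUNDS] * self.K,
                options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
            )
            if res2.fun < best.fun:
                best = res2
        if not best.success:
            # line-search failures near the boundary: refine with a
            # derivative-free simplex polish
            res_nm = optimize.minimize(
                neg, best.x, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
            )
            if res_nm.fun <= best.fun + 1e-12:
                res_nm.x = np.clip(res_nm.x, *_LOG_R_BOUNDS)
                best = res_nm
        theta = best.x
        ll, extra = self.profiled_criterion(theta, reml=reml, return_extra=True)
        if extra is None:
            return VCFit(np.full(self.p, np.nan), np.full((self.p, self.p), np.nan),
                         {e.name: np.nan for e in self.effects}, np.nan,
                         -np.inf, reml, False, n_obs=self.n, n_params=self.p,
                         message="singular fixed-effects information")
        sigma2_resid = extra["sigma2"]
        r = np.exp(theta)
        sigma2 = {eff.name: float(r[k] * sigma2_resid)
                  for k, eff in enumerate(self.effects)}
        boundary = [name for name, v in sigma2.items()
                    if v < BOUNDARY_REL_TOL * max(vary, 1e-300)]
        for name in boundary:
            sigma2[name] = 0.0
        nonident = self.check_identifiability()
        if nonident:
            message = (message + "; " if message else "") + (
                "non-identifiable with the residual variance: "
                + ", ".join(nonident)
            )
        return VCFit(
            beta=extra["beta"],
            cov_beta=extra["cov_beta"],
            sigma2=sigma2,
            sigma2_resid=float(sigma2_resid),
            llf=float(ll),
            reml=reml,
            converged=bool(best.success),
            boundary=boundary,
            n_obs=self.n,
            n_params=self.p,
            message=message,
            log_ratios=theta,
        )
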