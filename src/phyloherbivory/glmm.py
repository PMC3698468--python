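"""Logit-normal-binomial mixed model with crossed random effects.

The model of per-plant leaf damage:

    Damaged_i ~ Binomial(p_i, N_i)
    logit(p_i) = alpha + u_species[i] + u_plot[i] + u_obs[i]
                 + beta_date * DATE + beta_sr * SR + beta_pd * PD
                 + beta_srpd * (SR * PD)
    u_species ~ N(0, s2_species),  u_plot ~ N(0, s2_plot),
    u_obs ~ N(0, s2_obs)           (one level per plant: absorbs over- or
                                    under-dispersion relative to binomial)

Fitting uses the Laplace approximation to the marginal likelihood.  For a
given set of standard deviations the fixed effects and the joint mode of
the (spherical) random effects are found by penalised iteratively
reweighted least squares (PIRLS) — Newton's method on the penalised
binomial log-likelihood — and the outer, derivative-free optimisation runs
only over the log standard deviations.  The observation factor contributes
one latent variable per data row, so the Newton system is solved by
eliminating that diagonal block analytically; what remains is a dense
system of size (n_species + n_plots + n_fixed), tiny for any realistic
survey.

The Laplace log-likelihood at the joint mode (eta*, b*):

    ll(y | eta*) - ||b*||^2 / 2 - log det(Lambda' Z' W Z Lambda + I) / 2

with W the binomial Hessian weights N_i p_i (1 - p_i) and Lambda the
block-diagonal scaling by the three standard deviations.  Wald z values
are estimate / SE with SEs from the fixed-effect block of the inverse
joint Hessian; p-values are deliberately left to the parametric bootstrap.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit, gammaln

__all__ = [
    "FIXED_EFFECTS",
    "TABLE_NAMES",
    "ModelData",
    "FitOptions",
    "VarianceComponents",
    "FittedGLMM",
    "build_model_data",
    "fit_laplace",
    "marginal_loglik",
    "predict_linear",
]

#: Design-matrix column order for the full model.
FIXED_EFFECTS = ("intercept", "date", "sr", "pd", "sr_pd")

#: Human-readable names for reports, one per fixed effect.
TABLE_NAMES = {
    "intercept": "Intercept",
    "date": "Sampling date",
    "sr": "Plant species richness",
    "pd": "Plant phylogenetic diversity (PSE)",
    "sr_pd": "Plant diversity interaction",
}

FACTORS = ("species", "plot", "obs")


class ModelDataError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Carries the optimisation trace for post-mortem diagnostics."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class ModelData:
    """Response, fixed design and grouping factors for one model fit.

    The observation factor is implicit: one level per row.
    """

    y: np.ndarray
    n: np.ndarray
    X: np.ndarray
    colnames: tuple
    species_idx: np.ndarray
    plot_idx: np.ndarray
    species_levels: tuple
    plot_levels: tuple

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.species_idx = np.asarray(self.species_idx, dtype=np.intp)
        self.plot_idx = np.asarray(self.plot_idx, dtype=np.intp)
        nobs = len(self.y)
        if not (
            len(self.n) == nobs
            and self.X.shape[0] == nobs
            and len(self.species_idx) == nobs
            and len(self.plot_idx) == nobs
        ):
            raise ModelDataError("row counts disagree across response/design/factors")
        if np.any(self.y < 0) or np.any(self.y > self.n) or np.any(self.n < 1):
            raise ModelDataError("need 0 <= damaged <= total and total >= 1")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ModelDataError("fixed design matrix is rank deficient")
        S, P = len(self.species_levels), len(self.plot_levels)
        # combined (species, plot) cell index for fast cross-factor sums
        self._sp_idx = self.species_idx * P + self.plot_idx
        # binomial coefficient term, constant in the parameters
        self._logC = float(
            np.sum(gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1))
        )
        yn = self.y / self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            self._ll_sat = float(
                np.sum(
                    np.where(self.y > 0, self.y * np.log(yn), 0.0)
                    + np.where(self.y < self.n, (self.n - self.y) * np.log1p(-yn), 0.0)
                )
            ) + self._logC

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_species(self) -> int:
        return len(self.species_levels)

    @property
    def n_plots(self) -> int:
        return len(self.plot_levels)

    def drop_column(self, name: str) -> "ModelData":
        """A copy of the data with one fixed-effect column removed.

        Used by the parametric bootstrap to form the reduced model; only
        the named column goes, the interaction (if distinct) stays.
        """
        if name not in self.colnames:
            raise ModelDataError(f"no fixed-effect column {name!r}")
        keep = [i for i, c in enumerate(self.colnames) if c != name]
        return ModelData(
            y=self.y,
            n=self.n,
            X=self.X[:, keep],
            colnames=tuple(c for c in self.colnames if c != name),
            species_idx=self.species_idx,
            plot_idx=self.plot_idx,
            species_levels=self.species_levels,
            plot_levels=self.plot_levels,
        )

    def with_response(self, y: np.ndarray) -> "ModelData":
        """A copy with a new damage-count response (same N, design, factors)."""
        return ModelData(
            y=np.asarray(y, dtype=float),
            n=self.n,
            X=self.X,
            colnames=self.colnames,
            species_idx=self.species_idx,
            plot_idx=self.plot_idx,
            species_levels=self.species_levels,
            plot_levels=self.plot_levels,
        )


def build_model_data(plants, predictors, species_levels=None) -> ModelData:
    """Assemble :class:`ModelData` from per-plant records and plot predictors.

    Parameters
    ----------
    plants:
        Sequence of :class:`~phyloherbivory.survey.PlantObservation`.
    predictors:
        :class:`~phyloherbivory.survey.PredictorTable` covering every plot
        that occurs among the plants.
    species_levels:
        Optional closed species list; plants of other species are an
        error.  By default the levels are the species observed.
    """
    frame = predictors.frame
    plots_seen = sorted({p.plot for p in plants})
    orphans = [pl for pl in plots_seen if pl not in frame.index]
    if orphans:
        raise ModelDataError(f"plants reference plots missing from predictors: {orphans}")
    if species_levels is None:
        species_levels = tuple(sorted({p.species for p in plants}))
    else:
        species_levels = tuple(species_levels)
        bad = sorted({p.species for p in plants} - set(species_levels))
        if bad:
            raise ModelDataError(f"plants reference unknown species: {bad}")
    plot_levels = tuple(plots_seen)
    smap = {s: i for i, s in enumerate(species_levels)}
    pmap = {p: i for i, p in enumerate(plot_levels)}

    y = np.array([p.damaged for p in plants], dtype=float)
    n = np.array([p.total for p in plants], dtype=float)
    si = np.array([smap[p.species] for p in plants], dtype=np.intp)
    pi = np.array([pmap[p.plot] for p in plants], dtype=np.intp)
    cols = frame.loc[list(plot_levels), ["date_c", "sr_c", "pd_c", "sr_pd_c"]].to_numpy()
    X = np.column_stack([np.ones(len(plants)), cols[pi]])
    return ModelData(
        y=y,
        n=n,
        X=X,
        colnames=FIXED_EFFECTS,
        species_idx=si,
        plot_idx=pi,
        species_levels=species_levels,
        plot_levels=plot_levels,
    )


@dataclass(frozen=True)
class FitOptions:
    """Tolerances and iteration limits for the Laplace fit.

    ``outer_ftol`` is the convergence tolerance on the (negative) Laplace
    log-likelihood in the derivative-free outer optimisation; the inner
    PIRLS stops when the penalised objective changes by less than
    ``inner_tol`` (relative).  ``sigma_floor`` is the boundary below which
    a fitted standard deviation is reported as exactly zero.
    """

    outer_ftol: float = 1e-8
    outer_xtol: float = 1e-6
    max_outer: int = 400
    restarts: int = 1
    #: edge length of the initial Nelder-Mead simplex in log-sigma space;
    #: None uses the optimizer default.  Small values pay off for warm
    #: starts close to the optimum (bootstrap refits).
    init_step: float | None = None
    #: "nelder-mead" (default, derivative-free) or "l-bfgs-b"
    #: (finite-difference gradients; fewer evaluations from a warm start).
    outer_method: str = "nelder-mead"
    #: projected-gradient tolerance for the l-bfgs-b outer method
    outer_gtol: float = 1e-5
    inner_tol: float = 1e-10
    max_inner: int = 60
    sigma_floor: float = 1e-6
    log_sigma_bounds: tuple = (math.log(1e-7), math.log(50.0))
    separation_eta: float = 20.0


@dataclass(frozen=True)
class VarianceComponents:
    """Latent logit-scale variances for the three factors."""

    species: float
    plot: float
    obs: float

    def as_dict(self) -> dict:
        return {"species": self.species, "plot": self.plot, "obs": self.obs}

    def sigmas(self) -> dict:
        return {k: math.sqrt(v) for k, v in self.as_dict().items()}


@dataclass
class FittedGLMM:
    """Everything a report needs from one Laplace fit."""

    coef: pd.Series
    se: pd.Series
    zvalues: pd.Series
    vc: VarianceComponents
    boundary: dict
    ranef: dict              # factor -> pd.Series of conditional modes (u scale)
    ranef_sd: dict           # factor -> pd.Series of conditional SDs (u scale)
    loglik: float
    deviance: float
    converged: bool
    n_outer: int
    inner_grad_norm: float
    trace: list = field(default_factory=list, repr=False)
    separation: bool = False
    colnames: tuple = FIXED_EFFECTS

    def to_json_dict(self) -> dict:
        return {
            "coefficients": {
                c: {
                    "name": TABLE_NAMES.get(c, c),
                    "estimate": float(self.coef[c]),
                    "se": float(self.se[c]),
                    "z": float(self.zvalues[c]),
                }
                for c in self.colnames
            },
            "variance_components": {k: float(v) for k, v in self.vc.as_dict().items()},
            "boundary": {k: bool(v) for k, v in self.boundary.items()},
            "loglik": float(self.loglik),
            "deviance": float(self.deviance),
            "converged": bool(self.converged),
            "n_outer": int(self.n_outer),
            "separation": bool(self.separation),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_json_dict(), **kwargs)

    def ranef_table(self, factor: str) -> pd.DataFrame:
        """Conditional modes and SDs for one factor as a tidy frame."""
        return pd.DataFrame(
            {"mode": self.ranef[factor], "cond_sd": self.ranef_sd[factor]}
        ).rename_axis("level")


# ----------------------------------------------------------------------
# inner PIRLS: joint mode of (beta, b) at fixed standard deviations
# ----------------------------------------------------------------------


def _group_sum(idx, w, size):
    return np.bincount(idx, weights=w, minlength=size)


def _group_mat(idx, M, size):
    """Column-wise grouped sums: equivalent to Z' M for an indicator Z."""
    out = np.empty((size, M.shape[1]))
    for j in range(M.shape[1]):
        out[:, j] = np.bincount(idx, weights=M[:, j], minlength=size)
    return out


def _assemble(d_s, R_sp, d_p, R_sX=None, R_pX=None, R_XX=None):
    """Symmetric block assembly (diagonal factor blocks) without np.block."""
    S, P = len(d_s), len(d_p)
    p = 0 if R_XX is None else R_XX.shape[0]
    R = np.zeros((S + P + p, S + P + p))
    idx = np.arange(S + P)
    R[idx[:S], idx[:S]] = d_s
    R[idx[S:], idx[S:]] = d_p
    R[:S, S : S + P] = R_sp
    R[S : S + P, :S] = R_sp.T
    if p:
        R[:S, S + P :] = R_sX
        R[S + P :, :S] = R_sX.T
        R[S : S + P, S + P :] = R_pX
        R[S + P :, S : S + P] = R_pX.T
        R[S + P :, S + P :] = R_XX
    return R


def _binom_loglik(data: ModelData, eta: np.ndarray) -> float:
    # y*eta - n*log(1 + e^eta) + log C(n, y), stable via logaddexp
    return float(np.sum(data.y * eta - data.n * np.logaddexp(0.0, eta)) + data._logC)


class _InnerState:
    __slots__ = ("beta", "bs", "bp", "bo")

    def __init__(self, p, S, P, n):
        self.beta = np.zeros(p)
        self.bs = np.zeros(S)
        self.bp = np.zeros(P)
        self.bo = np.zeros(n)

    def copy(self):
        new = _InnerState(0, 0, 0, 0)
        new.beta = self.beta.copy()
        new.bs = self.bs.copy()
        new.bp = self.bp.copy()
        new.bo = self.bo.copy()
        return new


def _eta(data: ModelData, st: _InnerState, sig):
    return (
        data.X @ st.beta
        + sig[0] * st.bs[data.species_idx]
        + sig[1] * st.bp[data.plot_idx]
        + sig[2] * st.bo
    )


def _penalized_obj(data: ModelData, st: _InnerState, sig, eta=None) -> float:
    if eta is None:
        eta = _eta(data, st, sig)
    pen = 0.5 * (st.bs @ st.bs + st.bp @ st.bp + st.bo @ st.bo)
    return _binom_loglik(data, eta) - pen


def _pirls(data: ModelData, sig, st: _InnerState, opts: FitOptions, profile_beta=True):
    """Newton iterations to the joint penalised mode.

    Returns (state, eta, W, obj, grad_norm, n_iter).  When
    ``profile_beta`` is false the fixed effects are held at their current
    values and only the random effects are updated (used when evaluating
    the marginal likelihood at externally supplied coefficients).
    """
    si, pi = data.species_idx, data.plot_idx
    X = data.X
    S, P, p = data.n_species, data.n_plots, X.shape[1]
    ss, sp, so = sig

    eta = _eta(data, st, sig)
    obj = _penalized_obj(data, st, sig, eta)
    grad_norm = np.inf
    for it in range(opts.max_inner):
        mu = expit(eta)
        g = data.y - data.n * mu
        W = np.maximum(data.n * mu * (1.0 - mu), 1e-12)

        gs = ss * _group_sum(si, g, S) - st.bs
        gp = sp * _group_sum(pi, g, P) - st.bp
        go = so * g - st.bo
        gX = X.T @ g if profile_beta else np.zeros(0)
        grad_norm = math.sqrt(
            float(gs @ gs + gp @ gp + go @ go + (gX @ gX if profile_beta else 0.0))
        )
        if grad_norm < 1e-9 * (1.0 + abs(obj)):
            break

        D = so * so * W + 1.0
        wt = W / D
        # reduced Newton system over [bs, bp, (beta)] after eliminating bo;
        # the indicator crossproducts are grouped sums, never dense Z blocks
        wtX = wt[:, None] * X
        d_ss = ss * ss * _group_sum(si, wt, S) + 1.0
        d_pp = sp * sp * _group_sum(pi, wt, P) + 1.0
        R_sp = ss * sp * _group_sum(data._sp_idx, wt, S * P).reshape(S, P)
        if profile_beta:
            R = _assemble(
                d_ss,
                R_sp,
                d_pp,
                ss * _group_mat(si, wtX, S),
                sp * _group_mat(pi, wtX, P),
                X.T @ wtX,
            )
        else:
            R = _assemble(d_ss, R_sp, d_pp)

        c = (so * wt) * go  # = H_Ao D^{-1} grad_o contribution vector
        rhs = [gs - ss * _group_sum(si, c, S), gp - sp * _group_sum(pi, c, P)]
        if profile_beta:
            rhs.append(gX - X.T @ c)
        rhs = np.concatenate(rhs)
        try:
            chol = cho_factor(R, lower=True)
            delta = cho_solve(chol, rhs)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(R + 1e-10 * np.eye(R.shape[0]), rhs)
        ds = delta[:S]
        dp = delta[S : S + P]
        db = delta[S + P :] if profile_beta else np.zeros(p)
        dUa = ss * ds[si] + sp * dp[pi] + (X @ db if profile_beta else 0.0)
        do = (go - so * W * dUa) / D

        # step halving on the penalised objective
        step = 1.0
        for _ in range(30):
            cand = st.copy()
            cand.bs = st.bs + step * ds
            cand.bp = st.bp + step * dp
            cand.bo = st.bo + step * do
            if profile_beta:
                cand.beta = st.beta + step * db
            eta_new = eta + step * (dUa + so * do)
            obj_new = _penalized_obj(data, cand, sig, eta_new)
            if obj_new >= obj - 1e-12:
                break
            step *= 0.5
        improved = obj_new - obj
        st, eta, obj = cand, eta_new, obj_new
        if abs(improved) < opts.inner_tol * (1.0 + abs(obj)):
            mu = expit(eta)
            W = np.maximum(data.n * mu * (1.0 - mu), 1e-12)
            break
    mu = expit(eta)
    W = np.maximum(data.n * mu * (1.0 - mu), 1e-12)
    return st, eta, W, obj, grad_norm, it + 1


def _logdet_ranef_block(data: ModelData, sig, W) -> float:
    """log det(Lambda' Z' W Z Lambda + I) via elimination of the obs block."""
    ss, sp, so = sig
    si, pi = data.species_idx, data.plot_idx
    S, P = data.n_species, data.n_plots
    D = so * so * W + 1.0
    wt = W / D
    M = _assemble(
        ss * ss * _group_sum(si, wt, S) + 1.0,
        ss * sp * _group_sum(data._sp_idx, wt, S * P).reshape(S, P),
        sp * sp * _group_sum(pi, wt, P) + 1.0,
    )
    try:
        chol = np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("random-effect Hessian block not positive definite") from exc
    return float(np.sum(np.log(D)) + 2.0 * np.sum(np.log(np.diag(chol))))


def _laplace_objective(data, sig, st, opts, profile_beta=True):
    st, eta, W, pobj, grad_norm, n_it = _pirls(data, sig, st, opts, profile_beta)
    logdet = _logdet_ranef_block(data, sig, W)
    ll = pobj - 0.5 * logdet  # pobj already holds loglik - penalty
    return ll, st, eta, W, grad_norm


def _laplace_gradient(data: ModelData, sig, st: _InnerState, eta, W, free_idx):
    """d(Laplace log-likelihood)/d(variance) at the joint mode.

    Three pieces per factor m (working first on the SD scale):

    * envelope term ``g' Z_m b_m`` — only the explicit dependence of the
      linear predictor on sigma_m survives at the penalised optimum;
    * log-det term from the scaling matrix,
      ``-(1/sigma_m) * sum_{i in block m} (1 - [G^-1]_ii)``;
    * log-det term from the weights, ``-1/2 sum_i w'_i (d eta_i) h_i``,
      where ``d eta`` solves the joint-Hessian system for the implicit
      shift of the mode and ``h_i`` is the conditional variance of the
      random part of row i.

    The SD-scale derivative is then converted with ``dv = 2 sigma dsigma``;
    sigmas at the boundary are evaluated at a small positive clamp, where
    the variance-scale gradient has a finite nonzero limit.
    """
    si, pi = data.species_idx, data.plot_idx
    X = data.X
    S, P, p = data.n_species, data.n_plots, X.shape[1]
    # caller guarantees sig > 0 and (st, eta, W) solved at this sig; the
    # variance-scale gradient then has a finite, correct value even
    # arbitrarily close to the boundary
    sig = np.asarray(sig, dtype=float)
    ss, sp, so = sig
    mu = expit(eta)
    g = data.y - data.n * mu
    W = np.maximum(data.n * mu * (1.0 - mu), 1e-12)
    wprime = data.n * mu * (1.0 - mu) * (1.0 - 2.0 * mu)

    D = so * so * W + 1.0
    wt = W / D
    wtX = wt[:, None] * X
    d_ss = ss * ss * _group_sum(si, wt, S) + 1.0
    d_pp = sp * sp * _group_sum(pi, wt, P) + 1.0
    R_sp = ss * sp * _group_sum(data._sp_idx, wt, S * P).reshape(S, P)
    R = _assemble(
        d_ss, R_sp, d_pp,
        ss * _group_mat(si, wtX, S),
        sp * _group_mat(pi, wtX, P),
        X.T @ wtX,
    )
    chol = cho_factor(R, lower=True)
    M = _assemble(d_ss, R_sp, d_pp)
    Q = np.linalg.inv(M)

    # diag of G^-1: species/plot from Q, observation block analytically
    q_ss = Q[si, si]
    q_pp = Q[S + pi, S + pi]
    q_sp = Q[si, S + pi]
    a = so * W / D
    quad = ss * ss * q_ss + 2.0 * ss * sp * q_sp + sp * sp * q_pp
    ginv_obs = 1.0 / D + a * a * quad

    # h_i = [Z Lambda]_i G^-1 [Z Lambda]_i' : conditional variance of the
    # random part of eta_i.  Row i of Z Lambda has entries (ss at s_i,
    # sp at p_i, so at obs i); by the Schur inversion the (s,p) block of
    # G^-1 is Q, the cross block is -Q B D^-1 with column i of B equal
    # to so*w_i*(ss e_{s_i} + sp e_{p_i}), and the obs diagonal is
    # ginv_obs, so the quadratic form collapses to scalars per row.
    cross = -(so * wt) * quad
    h = quad + 2.0 * so * cross + so * so * ginv_obs

    z_by = {
        "species": st.bs[si],
        "plot": st.bp[pi],
        "obs": st.bo,
    }
    sig_by = {"species": ss, "plot": sp, "obs": so}

    grad_v = np.zeros(len(free_idx))
    for out_j, m_idx in enumerate(free_idx):
        m = FACTORS[m_idx]
        z_m = z_by[m]
        t1 = float(g @ z_m)

        if m == "species":
            block_ginv = np.diag(Q)[:S]
            n_block = S
        elif m == "plot":
            block_ginv = np.diag(Q)[S:]
            n_block = P
        else:
            block_ginv = ginv_obs
            n_block = data.n_obs
        t2a = -(1.0 / sig_by[m]) * float(n_block - np.sum(block_ginv))

        # implicit mode shift: solve H dpsi = r_m, eliminate obs block
        wz = W * z_m
        r_s = ss * (-_group_sum(si, wz, S))
        r_p = sp * (-_group_sum(pi, wz, P))
        r_o = -so * wz
        r_X = -(X.T @ wz)
        if m == "species":
            r_s += _group_sum(si, g, S)
        elif m == "plot":
            r_p += _group_sum(pi, g, P)
        else:
            r_o += g
        c = r_o / D  # elimination uses H_{A,o} D^-1 r_o with H_{A,o} = sig_o W U'
        rhs = np.concatenate([
            r_s - ss * _group_sum(si, so * W * c, S),
            r_p - sp * _group_sum(pi, so * W * c, P),
            r_X - X.T @ (so * W * c),
        ])
        dA = cho_solve(chol, rhs)
        ds, dp_, db = dA[:S], dA[S : S + P], dA[S + P :]
        dUa = ss * ds[si] + sp * dp_[pi] + X @ db
        do = (r_o - so * W * dUa) / D
        deta = z_m + dUa + so * do

        t2b = -0.5 * float(np.sum(wprime * deta * h))
        grad_v[out_j] = (t1 + t2a + t2b) / (2.0 * sig_by[m])
    return grad_v


def marginal_loglik(data: ModelData, beta, sigmas, opts: FitOptions | None = None) -> float:
    """Laplace marginal log-likelihood at given fixed effects and SDs.

    ``sigmas`` is a 3-sequence of standard deviations in factor order
    (species, plot, obs), or a dict of *variances* keyed by factor name.
    Random effects are set to their conditional mode at the supplied
    ``beta`` (the fixed effects are *not* re-optimised), which is the
    quantity an adaptive-quadrature oracle evaluates.
    """
    opts = opts or FitOptions()
    sig = np.sqrt(np.asarray([sigmas[k] for k in FACTORS], dtype=float)) if isinstance(sigmas, dict) else np.asarray(sigmas, dtype=float)
    st = _InnerState(data.X.shape[1], data.n_species, data.n_plots, data.n_obs)
    st.beta = np.asarray(beta, dtype=float).copy()
    ll, *_ = _laplace_objective(data, sig, st, opts, profile_beta=False)
    return ll


# ----------------------------------------------------------------------
# outer optimisation over log standard deviations
# ----------------------------------------------------------------------


def _glm_start(data: ModelData, opts: FitOptions) -> np.ndarray:
    st = _InnerState(data.X.shape[1], data.n_species, data.n_plots, data.n_obs)
    st, *_ = _pirls(data, np.zeros(3), st, opts)
    return st.beta


def fit_laplace(
    data: ModelData,
    opts: FitOptions | None = None,
    fixed_sigma: dict | None = None,
    start: FittedGLMM | dict | None = None,
) -> FittedGLMM:
    """Maximise the Laplace-approximated marginal likelihood.

    Parameters
    ----------
    data:
        Model data (response, design, factors).
    opts:
        Tolerances; defaults are production settings.
    fixed_sigma:
        Mapping factor name -> fixed standard deviation.  A factor fixed
        at 0 is removed from the latent system; fixing all three yields a
        plain binomial GLM.
    start:
        Warm start: either a previous :class:`FittedGLMM` or a dict with
        keys ``beta`` and ``sigma`` (SD scale).  Used heavily by the
        bootstrap to cut refit cost.

    Returns
    -------
    FittedGLMM
        With boundary flags for SDs that collapsed below
        ``opts.sigma_floor`` (reported as exactly 0).
    """
    opts = opts or FitOptions()
    fixed_sigma = dict(fixed_sigma or {})
    for k in fixed_sigma:
        if k not in FACTORS:
            raise ValueError(f"unknown factor {k!r}")
    free = [k for k in FACTORS if k not in fixed_sigma]

    # starting values
    if isinstance(start, FittedGLMM):
        sig0 = np.sqrt([start.vc.as_dict()[k] for k in FACTORS])
        beta0 = (
            start.coef.reindex(list(data.colnames)).to_numpy()
            if set(data.colnames) <= set(start.colnames)
            else None
        )
    elif isinstance(start, dict):
        sig0 = np.asarray(start.get("sigma", [1.0, 1.0, 1.0]), dtype=float)
        beta0 = start.get("beta")
    else:
        sig0 = np.ones(3)
        beta0 = None

    st = _InnerState(data.X.shape[1], data.n_species, data.n_plots, data.n_obs)
    st.beta = np.asarray(beta0, dtype=float).copy() if beta0 is not None else _glm_start(data, opts)

    lo, hi = opts.log_sigma_bounds
    # the gradient-based path works on the variance scale, where the
    # score does not vanish at a zero variance (log-sigma is flat there
    # and finite-difference gradients stall on the boundary)
    use_grad = opts.outer_method == "l-bfgs-b"
    trace: list[float] = []
    state_box = {"st": st}

    def sig_full(z):
        sig = np.empty(3)
        j = 0
        for i, k in enumerate(FACTORS):
            if k in fixed_sigma:
                sig[i] = float(fixed_sigma[k])
            else:
                # clamp just inside the boundary so the mode, objective
                # and analytic gradient are evaluated consistently
                sig[i] = math.sqrt(max(z[j], 1e-8)) if use_grad else math.exp(z[j])
                j += 1
        return sig

    free_idx = [i for i, k in enumerate(FACTORS) if k not in fixed_sigma]

    def negloglik(z):
        sig = sig_full(z)
        ll, st_new, *_ = _laplace_objective(data, sig, state_box["st"].copy(), opts)
        state_box["st"] = st_new  # warm-start the next evaluation
        trace.append(-ll)
        return -ll

    def negloglik_and_grad(z):
        sig = sig_full(z)
        ll, st_new, eta, W, _ = _laplace_objective(data, sig, state_box["st"].copy(), opts)
        state_box["st"] = st_new
        trace.append(-ll)
        grad = _laplace_gradient(data, sig, st_new, eta, W, free_idx)
        return -ll, -grad

    if free:
        sig_free = np.asarray([sig0[FACTORS.index(k)] for k in free], dtype=float)
        if use_grad:
            z0 = np.clip(sig_free**2, 1e-8, math.exp(hi) ** 2)
            bounds = [(0.0, math.exp(hi) ** 2)] * len(free)
        else:
            z0 = np.clip(np.log(np.clip(sig_free, 1e-6, None)), lo + 1e-9, hi - 1e-9)
            bounds = [(lo, hi)] * len(free)
        best = None
        z_start = z0
        for _ in range(max(1, opts.restarts + 1)):
            if opts.outer_method == "l-bfgs-b":
                options = {
                    "ftol": opts.outer_ftol,
                    "gtol": opts.outer_gtol,
                    "maxfun": opts.max_outer,
                }
                method = "L-BFGS-B"
            else:
                options = {
                    "fatol": opts.outer_ftol,
                    "xatol": opts.outer_xtol,
                    "maxfev": opts.max_outer,
                }
                method = "Nelder-Mead"
                if opts.init_step is not None:
                    simplex = np.tile(z_start, (len(z_start) + 1, 1))
                    for i in range(len(z_start)):
                        simplex[i + 1, i] = min(simplex[i + 1, i] + opts.init_step, hi)
                    options["initial_simplex"] = simplex
            res = minimize(
                negloglik_and_grad if use_grad else negloglik,
                z_start,
                jac=use_grad,
                method=method,
                bounds=bounds,
                options=options,
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
                z_start = res.x
            else:
                break
        z_opt = best.x
        n_outer = len(trace)
        converged = bool(best.success) or n_outer < opts.max_outer * (opts.restarts + 1)
    else:
        z_opt = np.zeros(0)
        n_outer = 1
        converged = True

    sig = sig_full(z_opt)
    boundary = {}
    for i, k in enumerate(FACTORS):
        if k in fixed_sigma:
            boundary[k] = False
        elif sig[i] < opts.sigma_floor:
            sig[i] = 0.0
            boundary[k] = True
        else:
            boundary[k] = False

    # final solve at the optimum, then curvature-based summaries
    st_final, eta, W, pobj, grad_norm, _ = _pirls(data, sig, state_box["st"].copy(), opts)
    logdet = _logdet_ranef_block(data, sig, W)
    loglik = pobj - 0.5 * logdet
    if not np.isfinite(loglik):
        raise ConvergenceError("non-finite Laplace log-likelihood at optimum", trace)
    separation = bool(np.max(np.abs(eta)) > opts.separation_eta)
    if separation:
        warnings.warn(
            "linear predictor extremely large: possible complete separation; "
            "estimates flagged",
            stacklevel=2,
        )

    ss, sp, so = sig
    si, pi = data.species_idx, data.plot_idx
    S, P, p = data.n_species, data.n_plots, data.X.shape[1]
    D = so * so * W + 1.0
    wt = W / D
    wtX = wt[:, None] * data.X
    d_ss = ss * ss * _group_sum(si, wt, S) + 1.0
    d_pp = sp * sp * _group_sum(pi, wt, P) + 1.0
    R_sp = ss * sp * _group_sum(data._sp_idx, wt, S * P).reshape(S, P)
    R = _assemble(
        d_ss, R_sp, d_pp,
        ss * _group_mat(si, wtX, S),
        sp * _group_mat(pi, wtX, P),
        data.X.T @ wtX,
    )
    Rinv = np.linalg.inv(R)
    cov_beta = Rinv[S + P :, S + P :]
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    if np.any(se == 0):
        warnings.warn("zero standard error: degenerate fit", stacklevel=2)

    # conditional SDs: species/plot from the (b_s, b_p) Schur block with
    # beta held fixed; observation block diagonal recovered analytically.
    M = _assemble(d_ss, R_sp, d_pp)
    Q = np.linalg.inv(M)
    cond_var_s = ss * ss * np.diag(Q)[:S]
    cond_var_p = sp * sp * np.diag(Q)[S:]
    a = so * W / D  # per-row loading of the obs latent onto (species, plot)
    q_ss = Q[si, si]
    q_pp = Q[S + pi, S + pi]
    q_sp = Q[si, S + pi]
    quad = ss * ss * q_ss + 2.0 * ss * sp * q_sp + sp * sp * q_pp
    cond_var_o = so * so * (1.0 / D + a * a * quad)

    coef = pd.Series(st_final.beta, index=list(data.colnames))
    se_s = pd.Series(se, index=list(data.colnames))
    z = coef / se_s
    vc = VarianceComponents(species=ss * ss, plot=sp * sp, obs=so * so)
    ranef = {
        "species": pd.Series(ss * st_final.bs, index=list(data.species_levels)),
        "plot": pd.Series(sp * st_final.bp, index=list(data.plot_levels)),
        "obs": pd.Series(so * st_final.bo, index=np.arange(data.n_obs)),
    }
    ranef_sd = {
        "species": pd.Series(np.sqrt(cond_var_s), index=list(data.species_levels)),
        "plot": pd.Series(np.sqrt(cond_var_p), index=list(data.plot_levels)),
        "obs": pd.Series(np.sqrt(cond_var_o), index=np.arange(data.n_obs)),
    }
    deviance = 2.0 * (data._ll_sat - _binom_loglik(data, eta))
    return FittedGLMM(
        coef=coef,
        se=se_s,
        zvalues=z,
        vc=vc,
        boundary=boundary,
        ranef=ranef,
        ranef_sd=ranef_sd,
        loglik=loglik,
        deviance=deviance,
        converged=converged,
        n_outer=n_outer,
        inner_grad_norm=grad_norm,
        trace=trace,
        separation=separation,
        colnames=data.colnames,
    )


# ----------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------


def predict_linear(
    fit: FittedGLMM,
    fixed: dict,
    plots=None,
    species=None,
    observations=None,
) -> np.ndarray:
    """Assemble logit-scale predictions from requested components only.

    Parameters
    ----------
    fit:
        A fitted model.
    fixed:
        Mapping fixed-effect column name -> value(s) on the *centered*
        scale.  Columns not mentioned are excluded from the predictor
        (e.g. omit ``date`` to predict at the mean sampling date).
        ``intercept`` takes the value 1 to include the intercept.
    plots, species, observations:
        Sequences of factor levels whose conditional modes should be
        added, broadcast against the fixed part.  ``None`` excludes the
        factor entirely; an unknown level raises ``KeyError`` — there is
        no implicit zero.
    """
    unknown = set(fixed) - set(fit.colnames)
    if unknown:
        raise KeyError(f"unknown fixed-effect columns: {sorted(unknown)}")
    parts = [np.asarray(v, dtype=float) * fit.coef[k] for k, v in fixed.items()]
    eta = sum(parts) if parts else np.asarray(0.0)
    for factor, levels in (("plot", plots), ("species", species), ("obs", observations)):
        if levels is None:
            continue
        modes = fit.ranef[factor]
        missing = [lv for lv in np.atleast_1d(levels) if lv not in modes.index]
        if missing:
            raise KeyError(f"unknown {factor} level(s): {missing}")
        eta = eta + modes.loc[np.atleast_1d(levels)].to_numpy()
    return np.asarray(eta, dtype=float)
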