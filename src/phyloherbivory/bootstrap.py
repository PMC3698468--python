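"""Parametric-bootstrap significance tests for the fixed effects.

For a fixed factor under test, data are simulated under the *reduced*
model — the observed-data fit with that factor's column removed — by
drawing fresh random effects from their estimated Normal distributions,
forming success probabilities through the logit link, and drawing new
binomial damage counts with the observed leaf totals and predictors held
fixed.  The full model is refit to each simulated dataset and the
factor's Wald z recorded; the p-value is the fraction of simulated |z|
at least as large as the observed |z|.

Removing only the tested column (the interaction stays when a main
effect is tested) is the literal reading of "a simplified model without
the fixed factor of interest"; it ignores marginality conventions, which
is documented behaviour.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import (
    ConvergenceError,
    FitOptions,
    FittedGLMM,
    ModelData,
    fit_laplace,
)

__all__ = ["BootstrapSpec", "BootstrapResult", "simulate_response", "bootstrap_p"]

TESTABLE_FACTORS = ("date", "sr", "pd", "sr_pd")

#: Looser outer tolerance for the B simulation refits: the z statistic is
#: insensitive at this scale and the refit count is large.
REFIT_OPTS = FitOptions(
    outer_ftol=1e-6, restarts=0, inner_tol=1e-9,
    max_outer=250, outer_method="l-bfgs-b", outer_gtol=1e-3,
)


@dataclass(frozen=True)
class BootstrapSpec:
    factor: str
    B: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.factor not in TESTABLE_FACTORS:
            raise ValueError(f"factor must be one of {TESTABLE_FACTORS}, got {self.factor!r}")
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class BootstrapResult:
    factor: str
    z_obs: float
    z_sim: np.ndarray
    p: float
    B: int
    n_failed: int
    seed: int

    def formatted_p(self) -> str:
        """`< 1/B` display form for an exact zero, else the plain value."""
        n_ok = self.B - self.n_failed
        return f"< {1.0 / n_ok:.4g}" if self.p == 0.0 else f"{self.p:.4g}"

    def to_json_dict(self) -> dict:
        return {
            "factor": self.factor,
            "z_obs": float(self.z_obs),
            "p": float(self.p),
            "B": int(self.B),
            "n_failed": int(self.n_failed),
            "seed": int(self.seed),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_json_dict(), **kwargs)

    def z_sim_table(self) -> pd.DataFrame:
        return pd.DataFrame({"replicate": np.arange(1, len(self.z_sim) + 1), "z": self.z_sim})


def simulate_response(fit: FittedGLMM, structure: ModelData, rng) -> np.ndarray:
    """Draw new damage counts from a fitted model's generating distribution.

    Fresh random effects are drawn from Normal(0, sigma_hat^2) for all
    three factors — the conditional modes play no role — and
    ``Damaged_i ~ Binomial(p_i, N_i)`` with the observed ``N_i`` and
    predictors held fixed.
    """
    if rng is None or not isinstance(rng, np.random.Generator):
        raise ValueError("an explicit numpy Generator is required for reproducibility")
    if tuple(structure.colnames) != tuple(fit.colnames):
        raise ValueError("structure's fixed-effect columns do not match the fit")
    sig = fit.vc.sigmas()
    u_s = rng.normal(0.0, sig["species"], structure.n_species)
    u_p = rng.normal(0.0, sig["plot"], structure.n_plots)
    u_o = rng.normal(0.0, sig["obs"], structure.n_obs)
    eta = (
        structure.X @ fit.coef.to_numpy()
        + u_s[structure.species_idx]
        + u_p[structure.plot_idx]
        + u_o
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    return rng.binomial(structure.n.astype(int), p).astype(float)


def bootstrap_p(
    data: ModelData,
    spec: BootstrapSpec,
    opts: FitOptions | None = None,
    refit_opts: FitOptions | None = None,
    full_fit: FittedGLMM | None = None,
) -> BootstrapResult:
    """Parametric-bootstrap p-value for one fixed factor.

    Parameters
    ----------
    data:
        Observed-data model data for the *full* model.
    spec:
        Factor under test, number of simulations B and seed.
    opts:
        Options for the observed-data fits (full and reduced).
    refit_opts:
        Options for the B simulation refits (looser by default).
    full_fit:
        Optional precomputed full-model fit, reused for the observed z
        and as warm start for every refit.
    """
    opts = opts or FitOptions()
    refit_opts = refit_opts or REFIT_OPTS
    if full_fit is None:
        full_fit = fit_laplace(data, opts)
    z_obs = float(full_fit.zvalues[spec.factor])

    reduced_data = data.drop_column(spec.factor)
    try:
        reduced_fit = fit_laplace(reduced_data, opts, start=full_fit)
    except ConvergenceError as exc:
        raise ConvergenceError(
            f"reduced model (without {spec.factor!r}) failed to converge", exc.trace
        ) from exc

    rng = np.random.default_rng(spec.seed)
    z_sim = []
    n_failed = 0
    for _ in range(spec.B):
        y_new = simulate_response(reduced_fit, reduced_data, rng)
        sim_data = data.with_response(y_new)
        try:
            sim_fit = fit_laplace(sim_data, refit_opts, start=full_fit)
            z = float(sim_fit.zvalues[spec.factor])
        except (ConvergenceError, FloatingPointError):
            z = np.nan
        if np.isfinite(z):
            z_sim.append(z)
        else:
            n_failed += 1
    if n_failed > 0.02 * spec.B:
        warnings.warn(
            f"{n_failed} of {spec.B} bootstrap refits failed to converge",
            stacklevel=2,
        )
    z_sim = np.asarray(z_sim)
    n_ok = len(z_sim)
    if n_ok == 0:
        raise ConvergenceError("all bootstrap refits failed")
    p = float(np.sum(np.abs(z_sim) >= abs(z_obs)) / n_ok)
    return BootstrapResult(
        factor=spec.factor,
        z_obs=z_obs,
        z_sim=z_sim,
        p=p,
        B=spec.B,
        n_failed=n_failed,
        seed=spec.seed,
    )
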