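"""Reported quantities: plot- and species-level damage, fitted surface.

Plot-level estimated proportional leaf damage is the back-transformed
combination of the intercept, the plot conditional mode and the plot's
diversity terms,

    p_j = logit^-1(alpha + u_j(plot) + b_pd PD_j + b_sr SR_j
                   + b_srpd (PD*SR)_j),

with sampling date (at its mean, a no-op for centered predictors), the
species effects and the observation effects all excluded.  Species-level
damage conditions the other way: p_k = logit^-1(alpha + u_k(species)).
Display intervals back-transform the conditional mode +/- one conditional
standard deviation, so they are asymmetric on the probability scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .glmm import FittedGLMM, predict_linear
from .survey import PredictorTable

__all__ = [
    "DamageEstimate",
    "plot_damage",
    "species_damage",
    "fitted_surface",
    "estimates_table",
    "write_surface_tsv",
]

#: Species-richness values at which fitted damage lines are drawn,
#: spanning the richness range of the motivating survey.
DEFAULT_SR_LINES = (3, 6, 12, 17)


@dataclass(frozen=True)
class DamageEstimate:
    entity: str
    estimate: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0.0 < self.estimate < 1.0):
            raise ValueError("estimate must lie strictly inside (0, 1)")
        if not self.lower <= self.estimate <= self.upper:
            raise ValueError("interval must bracket the estimate")


def plot_damage(fit: FittedGLMM, predictors: PredictorTable) -> list[DamageEstimate]:
    """Estimated proportional leaf damage per plot (p_j)."""
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to report estimates")
    plots = list(fit.ranef["plot"].index)
    frame = predictors.frame.loc[plots]
    eta = predict_linear(
        fit,
        fixed={
            "intercept": np.ones(len(plots)),
            "sr": frame["sr_c"].to_numpy(),
            "pd": frame["pd_c"].to_numpy(),
            "sr_pd": frame["sr_pd_c"].to_numpy(),
        },
        plots=plots,
    )
    sd = fit.ranef_sd["plot"].loc[plots].to_numpy()
    return [
        DamageEstimate(entity=pl, estimate=float(expit(e)), lower=float(expit(e - s)), upper=float(expit(e + s)))
        for pl, e, s in zip(plots, eta, sd)
    ]


def species_damage(fit: FittedGLMM) -> list[DamageEstimate]:
    """Estimated proportional leaf damage per species (p_k)."""
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to report estimates")
    species = list(fit.ranef["species"].index)
    eta = predict_linear(fit, fixed={"intercept": np.ones(len(species))}, species=species)
    sd = fit.ranef_sd["species"].loc[species].to_numpy()
    return [
        DamageEstimate(entity=sp, estimate=float(expit(e)), lower=float(expit(e - s)), upper=float(expit(e + s)))
        for sp, e, s in zip(species, eta, sd)
    ]


def fitted_surface(
    fit: FittedGLMM,
    predictors: PredictorTable,
    sr_values=DEFAULT_SR_LINES,
    pd_values=None,
) -> pd.DataFrame:
    """Fixed-effects-only damage surface over (SR, PD), raw scales in.

    ``sr_values`` and ``pd_values`` are supplied on the original scale;
    centering uses the predictor table's stored means.  Random terms and
    sampling date are excluded (date at its mean contributes nothing to a
    centered predictor).  Values outside the observed predictor hull get
    a warning, not an error.

    Returns a long-form frame with columns ``sr, pd, logit, fitted_p``.
    """
    if pd_values is None:
        lo, hi = predictors.frame["pd"].min(), predictors.frame["pd"].max()
        pd_values = np.linspace(lo, hi, 50)
    sr_values = np.asarray(sr_values, dtype=float)
    pd_values = np.asarray(pd_values, dtype=float)
    obs_sr = predictors.frame["sr"]
    obs_pd = predictors.frame["pd"]
    if (
        sr_values.min() < obs_sr.min()
        or sr_values.max() > obs_sr.max()
        or pd_values.min() < obs_pd.min()
        or pd_values.max() > obs_pd.max()
    ):
        warnings.warn("surface grid extends outside the observed predictor hull", stacklevel=2)

    sr_grid, pd_grid = np.meshgrid(sr_values, pd_values, indexing="ij")
    sr_c, pd_c, sr_pd_c, _ = predictors.center(sr_grid.ravel(), pd_grid.ravel())
    eta = predict_linear(
        fit,
        fixed={
            "intercept": np.ones(sr_c.size),
            "sr": sr_c,
            "pd": pd_c,
            "sr_pd": sr_pd_c,
        },
    )
    return pd.DataFrame(
        {
            "sr": sr_grid.ravel(),
            "pd": pd_grid.ravel(),
            "logit": eta,
            "fitted_p": expit(eta),
        }
    )


def estimates_table(estimates) -> pd.DataFrame:
    """DamageEstimate list as a tidy frame (entity, estimate, lower, upper)."""
    return pd.DataFrame(
        [(e.entity, e.estimate, e.lower, e.upper) for e in estimates],
        columns=["entity", "estimate", "lower", "upper"],
    )


def write_surface_tsv(surface: pd.DataFrame, path) -> None:
    surface.to_csv(path, sep="\t", index=False)


def render_surface_png(surface: pd.DataFrame, path) -> None:
    """Optional heat-map rendering of the fitted damage surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = surface.pivot(index="pd", columns="sr", values="fitted_p")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(wide.columns, wide.index, wide.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    fig.colorbar(im, ax=ax, label="estimated proportional leaf damage")
    ax.set_xlabel("species richness")
    ax.set_ylabel("phylogenetic diversity (PSE)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_damage_png(estimates, path, label="entity") -> None:
    """Optional bar chart of damage estimates with +/- 1 conditional-SD bounds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(estimates, key=lambda e: e.estimate)
    y = np.arange(len(ordered))
    est = np.array([e.estimate for e in ordered])
    lo = est - np.array([e.lower for e in ordered])
    hi = np.array([e.upper for e in ordered]) - est
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(ordered) + 1.5))
    ax.barh(y, est, xerr=[lo, hi], color="tab:green", alpha=0.8)
    ax.set_yticks(y, [e.entity for e in ordered], fontsize=7)
    ax.set_xlim(0, 1)
    ax.set_xlabel("estimated proportional leaf damage")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
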