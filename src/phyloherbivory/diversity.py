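"""Phylogenetic Species Variability (PSV) and Evenness (PSE).

Both indices measure the expected variance of a hypothetical neutral trait
evolving by Brownian motion over the community phylogeny, standardised by
the same expectation on a star phylogeny, where no evolutionary history is
shared.  PSV treats all present species equally; PSE weights species by
abundance, which is equivalent to placing ``m_i`` individuals of species
*i* at the tip as zero-length branches and asking for the trait variance
among individuals.  Both lie in [0, 1]: 1 for a star phylogeny (and, for
PSE, perfectly even abundances), approaching 0 as the community collapses
onto a single lineage.

With ``C`` the Brownian correlation matrix restricted to the ``n`` present
species, ``m`` their abundances, ``N = sum(m)`` and ``mbar = N / n``:

    PSV = (n * tr(C) - sum(C)) / (n * (n - 1))
    PSE = (N * sum(m_i * C_ii) - m' C m) / (N**2 - N * mbar)

PSE reduces to PSV when all present abundances are equal.  PSE is, by
construction, independent of species richness, which is what lets richness
and phylogenetic diversity enter the herbivory model as separate,
non-collinear predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny, brownian_correlation

__all__ = ["DiversityResult", "psv", "pse", "plot_diversity_table", "diversity_records"]


class DiversityIndexError(ValueError):
    """Index undefined for the given community (e.g. fewer than 2 species)."""


@dataclass(frozen=True)
class DiversityResult:
    """Per-plot diversity summary."""

    plot: str
    sr: int
    psv: float
    pse: float
    n_present: int
    total_abundance: int


def _check_square(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    return C


def psv(C) -> float:
    """Phylogenetic species variability of a present-species correlation matrix.

    With a unit diagonal this is one minus the mean off-diagonal
    correlation: 1 for a star phylogeny, 0 when all species are
    phylogenetically identical.
    """
    C = _check_square(C)
    n = C.shape[0]
    if n < 2:
        raise DiversityIndexError("PSV undefined for fewer than 2 species")
    return float((n * np.trace(C) - C.sum()) / (n * (n - 1)))


def pse(C, abundances) -> float:
    """Abundance-weighted phylogenetic species evenness.

    Parameters
    ----------
    C:
        Brownian correlation matrix over the species in ``abundances``
        (absent species may be included; they are dropped).
    abundances:
        Non-negative integer abundance for each row/column of ``C``.

    Notes
    -----
    Species with abundance 0 are excluded before forming the submatrix:
    the index is a property of the realised community.  At least two
    species must be present.
    """
    C = _check_square(C)
    m = np.asarray(abundances, dtype=float)
    if m.shape != (C.shape[0],):
        raise ValueError("abundance vector length must match matrix dimension")
    if np.any(m < 0) or np.any(m != np.round(m)):
        raise ValueError("abundances must be non-negative integers")
    present = m > 0
    n = int(present.sum())
    if n < 2:
        raise DiversityIndexError("PSE undefined for fewer than 2 present species")
    Cp = C[np.ix_(present, present)]
    mp = m[present]
    N = mp.sum()
    mbar = N / n
    denom = N * N - N * mbar
    if denom <= 0:
        raise DiversityIndexError("degenerate abundances: zero denominator")
    num = N * float(np.diag(Cp) @ mp) - float(mp @ Cp @ mp)
    return float(num / denom)


def plot_diversity_table(
    tree: Phylogeny,
    compositions,
) -> pd.DataFrame:
    """Per-plot SR, PSV, PSE and total abundance.

    Parameters
    ----------
    tree:
        Phylogeny covering (at least) every species that occurs in the
        compositions.
    compositions:
        Iterable of :class:`~phyloherbivory.survey.PlotComposition`.

    Returns
    -------
    DataFrame indexed by plot with columns ``sr, psv, pse, n_present, N``.
    Plots with fewer than two present species get NaN indices and are
    expected to be excluded from modelling by the caller.
    """
    corr = brownian_correlation(tree)
    rows = []
    for comp in compositions:
        present = {sp: a for sp, a in comp.abundances.items() if a > 0}
        missing = sorted(set(present) - set(corr.index))
        if missing:
            raise KeyError(f"species not in tree: {missing}")
        sr = len(present)
        if sr < 2:
            rows.append((comp.plot, sr, np.nan, np.nan, sr, sum(present.values())))
            continue
        labels = sorted(present)
        sub = corr.loc[labels, labels].to_numpy()
        m = np.array([present[sp] for sp in labels], dtype=float)
        rows.append(
            (comp.plot, sr, psv(sub), pse(sub, m), sr, int(m.sum()))
        )
    return pd.DataFrame(
        rows, columns=["plot", "sr", "psv", "pse", "n_present", "N"]
    ).set_index("plot")


def diversity_records(table: pd.DataFrame) -> list[DiversityResult]:
    """Rows of a :func:`plot_diversity_table` frame as typed records."""
    return [
        DiversityResult(
            plot=str(plot),
            sr=int(row["sr"]),
            psv=float(row["psv"]),
            pse=float(row["pse"]),
            n_present=int(row["n_present"]),
            total_abundance=int(row["N"]),
        )
        for plot, row in table.iterrows()
    ]
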