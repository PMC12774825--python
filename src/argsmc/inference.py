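"""Likelihood-ratio curves, recombination-rate MLE and time-sliced Ne posteriors.

These are thin inferential layers over the per-edge SMC likelihood: evaluate
it across a parameter grid (one genomic sweep, then a vectorised pass per
grid point), locate the maximum, or slice the ARG in time and form an
independent grid posterior on the effective population size of each slice.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .arg_core import ArgTables, ParameterError, SliceSpec, time_slice
from .smc_likelihood import LikelihoodEvaluator

__all__ = [
    "CurveResult",
    "SlicePosterior",
    "loglik_curve",
    "mle_r",
    "slice_posterior",
    "log_grid",
]


def log_grid(lo: float, hi: float, k: int) -> np.ndarray:
    """``k`` log-spaced grid points over ``[lo, hi]``."""
    if not (0 < lo < hi):
        raise ParameterError("grid bounds must satisfy 0 < lo < hi")
    return np.geomspace(lo, hi, int(k))


@dataclass
class CurveResult:
    """Log-likelihood over a parameter grid, as ratios against a reference."""

    grid: np.ndarray
    log_lik: np.ndarray
    log_ratio: np.ndarray  # log_lik - log_lik(reference)
    reference: float
    argmax: float  # grid value maximising the log-likelihood

    @property
    def argmin_neg_ratio(self) -> float:
        """Grid location of the minimum of the negative log-ratio curve."""
        return float(self.grid[np.argmin(-self.log_ratio)])


def loglik_curve(
    arg: ArgTables,
    r_grid: np.ndarray,
    Ne: float,
    reference_r: float | None = None,
) -> CurveResult:
    """SMC log-likelihood over a grid of recombination rates, Ne held fixed.

    ``log_ratio`` is relative to ``reference_r`` (default: the grid point
    closest to the middle), with the reference evaluated exactly so its
    ratio is identically zero when it lies on the grid.
    """
    r_grid = np.asarray(r_grid, dtype=np.float64)
    if len(r_grid) == 0 or np.any(r_grid <= 0):
        raise ParameterError("r grid must be non-empty with positive values")
    if np.any(np.diff(r_grid) <= 0):
        raise ParameterError("r grid must be strictly increasing")
    ev = LikelihoodEvaluator(arg)
    log_lik = np.array([ev.log_likelihood(r, Ne).log_likelihood for r in r_grid])
    if reference_r is None:
        reference_r = float(r_grid[len(r_grid) // 2])
    hit = np.flatnonzero(r_grid == reference_r)
    ref_ll = (
        log_lik[hit[0]]
        if len(hit)
        else ev.log_likelihood(reference_r, Ne).log_likelihood
    )
    return CurveResult(
        grid=r_grid,
        log_lik=log_lik,
        log_ratio=log_lik - ref_ll,
        reference=float(reference_r),
        argmax=float(r_grid[np.argmax(log_lik)]),
    )


def mle_r(
    arg: ArgTables,
    Ne: float,
    bracket: tuple[float, float],
    tol_log10: float = 1e-3,
) -> float:
    """Maximum-likelihood recombination rate by scalar optimisation in log r.

    Warns (and returns the boundary) when the maximum sits on an end of
    ``bracket`` — e.g. for ARGs without recombination the likelihood is
    monotone decreasing in r.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ParameterError("bracket must satisfy 0 < lo < hi")
    ev = LikelihoodEvaluator(arg)

    def neg_ll(log10_r: float) -> float:
        return -ev.log_likelihood(10.0 ** log10_r, Ne).log_likelihood

    res = minimize_scalar(
        neg_ll,
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": tol_log10},
    )
    r_hat = float(10.0 ** res.x)
    edge_tol = 2 * tol_log10
    if (
        abs(res.x - np.log10(lo)) < edge_tol
        or abs(res.x - np.log10(hi)) < edge_tol
    ):
        warnings.warn(
            "likelihood maximum lies on the bracket boundary; "
            "no interior maximum found"
        )
    return r_hat


@dataclass
class SlicePosterior:
    """Independent per-slice grid posteriors over Ne (uniform prior)."""

    ne_grid: np.ndarray
    log_lik: np.ndarray  # (num_slices, grid size)
    posterior: np.ndarray  # normalised masses per slice
    modes: np.ndarray
    means: np.ndarray
    breakpoints: tuple[float, ...]


def slice_posterior(
    arg: ArgTables,
    breaks: SliceSpec,
    ne_grid: np.ndarray,
    r: float,
) -> SlicePosterior:
    """Grid posterior on a constant Ne per time slice, each slice independent.

    The ARG is cut at ``breaks``; for each slice the SMC log-likelihood is
    evaluated across ``ne_grid`` with ``r`` fixed, exponentiated under a
    uniform prior and normalised (in log space).  A slice without edges
    yields a flat posterior, with a warning.
    """
    ne_grid = np.asarray(ne_grid, dtype=np.float64)
    if len(ne_grid) == 0 or np.any(ne_grid <= 0):
        raise ParameterError("Ne grid must be non-empty with positive values")
    slices = time_slice(arg, breaks)
    n_slices = len(slices)
    ll = np.zeros((n_slices, len(ne_grid)))
    for i, s in enumerate(slices):
        if s.num_edges == 0:
            warnings.warn(f"slice {i} contains no edges; posterior is flat")
            continue
        ev = LikelihoodEvaluator(s)
        ll[i] = [ev.log_likelihood(r, ne).log_likelihood for ne in ne_grid]
    post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
    modes = ne_grid[np.argmax(post, axis=1)]
    means = post @ ne_grid
    return SlicePosterior(
        ne_grid=ne_grid,
        log_lik=ll,
        posterior=post,
        modes=modes,
        means=means,
        breakpoints=tuple(breaks.breakpoints),
    )
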