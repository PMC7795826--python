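"""Poisson model for the per-patient positive-biopsy count.

The observed relative histogram of positive-biopsy counts is summarised by
a Poisson distribution, fitted by least squares on the probability scale
(matching how the reference analysis adjusted a common distribution to the
histogram) or, as a cross-check, by maximum likelihood (the sample mean).
The fitted distribution, truncated and renormalised on the observable
support 0..n_max, supplies the probabilities q(x) that x of the biopsies
harbour mPM, which the burden inversion consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .cohort import RelativeHistogram

__all__ = ["PoissonFit", "fit_poisson_ls", "fit_poisson_mle", "biopsy_count_pmf"]

logger = logging.getLogger(__name__)

#: Upper bound of the rate search; the support maximum, far above any
#: realistic per-patient positive count in this setting.
LAMBDA_MAX = 13.0


@dataclass(frozen=True)
class PoissonFit:
    """A fitted Poisson rate with its truncated-renormalised pmf on 0..n_max."""

    lam: float
    fitted_pmf: np.ndarray = field(repr=False)
    loss: float
    method: str

    def __post_init__(self) -> None:
        pmf = np.asarray(self.fitted_pmf, dtype=float)
        object.__setattr__(self, "fitted_pmf", pmf)
        if self.lam < 0:
            raise ValueError("Poisson rate must be non-negative")
        if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError("fitted_pmf must be a probability vector")


def _ls_objective(lam: float, freq: np.ndarray) -> float:
    x = np.arange(freq.size)
    return float(np.sum((stats.poisson.pmf(x, lam) - freq) ** 2))


def _truncated_pmf(lam: float, n_max: int) -> np.ndarray:
    if lam == 0.0:
        pmf = np.zeros(n_max + 1)
        pmf[0] = 1.0
        return pmf
    pmf = stats.poisson.pmf(np.arange(n_max + 1), lam)
    return pmf / pmf.sum()


def fit_poisson_ls(hist: RelativeHistogram, lam_max: float = LAMBDA_MAX) -> PoissonFit:
    """Least-squares Poisson fit to a relative histogram.

    Minimises sum_x (pois(x; lam) - freq(x))^2 over lam in [0, lam_max]
    by bounded scalar minimisation.  The degenerate all-mass-at-zero
    histogram yields lam = 0 exactly.
    """
    freq = hist.freq
    if hist.mean() == 0.0:
        logger.info("histogram has all mass at zero; returning lam=0")
        return PoissonFit(
            lam=0.0,
            fitted_pmf=_truncated_pmf(0.0, hist.n_max),
            loss=_ls_objective(0.0, freq),
            method="least_squares",
        )
    res = optimize.minimize_scalar(
        _ls_objective,
        args=(freq,),
        bounds=(0.0, lam_max),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(res.x)
    # bounded minimisation cannot return the endpoint exactly; keep it if better
    if _ls_objective(0.0, freq) <= res.fun:
        lam = 0.0
    return PoissonFit(
        lam=lam,
        fitted_pmf=_truncated_pmf(lam, hist.n_max),
        loss=_ls_objective(lam, freq),
        method="least_squares",
    )


def fit_poisson_mle(hist: RelativeHistogram) -> PoissonFit:
    """Maximum-likelihood Poisson fit: the rate is the histogram mean."""
    lam = hist.mean()
    return PoissonFit(
        lam=lam,
        fitted_pmf=_truncated_pmf(lam, hist.n_max),
        loss=_ls_objective(lam, hist.freq),
        method="mle",
    )


def biopsy_count_pmf(fit: PoissonFit) -> np.ndarray:
    """Probability vector q over 0..n_max that x biopsies harbour mPM."""
    return fit.fitted_pmf.copy()
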