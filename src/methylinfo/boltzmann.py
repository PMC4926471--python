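"""Boltzmann model linking SNP fixation probability to log count uncertainty.

The model: the probability that a SNP is fixed at a site with log2 normalized
supporting count ``LC > 0`` is

    p = 1 - lambda * exp(-beta * LC)

so ``q = lambda * exp(-beta * LC)`` is the Boltzmann-distributed probability
of *not* observing the SNP, and inverting gives the uncertainty

    LC = -(1/beta) * log((1 - p) / lambda).

The distribution implied for LC is defective on (0, inf): a point mass of
``1 - lambda`` sits at LC = 0 (no observable substitution) and, conditional on
LC > 0, LC is exponential with rate ``beta``.  ``fit_boltzmann`` therefore
accepts arrays that may contain zeros; zeros enter the empirical CDF
denominator while the curve is fitted over the positive support.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass
class BoltzmannFit:
    """Fitted (lambda, beta) with CDF-fit diagnostics."""

    lambda_: float
    beta: float
    rss: float
    n: int           # sites used (including zero-LC mass)
    n_positive: int  # positive LC sites the curve was fitted over
    method: str = "cdf"

    def cdf(self, lc):
        return boltzmann_cdf(lc, self.lambda_, self.beta)


def _check_params(lambda_: float, beta: float) -> None:
    if not (lambda_ > 0):
        raise ValueError(f"lambda must be positive, got {lambda_}")
    if not (beta > 0):
        raise ValueError(f"beta must be positive, got {beta}")


def boltzmann_cdf(lc, lambda_: float, beta: float, return_clip_count: bool = False):
    """Probability that a SNP is fixed: ``1 - lambda * exp(-beta * lc)``.

    Values are clipped to [0, 1]; set ``return_clip_count=True`` to also get
    the number of clipped evaluations (nonzero only when ``lambda`` exceeds
    ``exp(beta * lc)`` somewhere on the input).
    """
    _check_params(lambda_, beta)
    arr = np.asarray(lc, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("lc must be positive")
    raw = 1.0 - lambda_ * np.exp(-beta * arr)
    clipped = np.clip(raw, 0.0, 1.0)
    n_clipped = int(np.sum(raw != clipped))
    if np.isscalar(lc) or arr.ndim == 0:
        clipped = float(clipped)
    if return_clip_count:
        return clipped, n_clipped
    return clipped


def lc_from_p(p, lambda_: float, beta: float):
    """Uncertainty of not observing a SNP: exact inverse of the CDF.

    ``lc = -(1/beta) * log((1 - p) / lambda)``; requires
    ``(1 - p)/lambda`` in (0, 1].  ``p = 1`` is signalled as an overflow.
    """
    _check_params(lambda_, beta)
    arr = np.asarray(p, dtype=float)
    if np.any(arr >= 1.0):
        raise OverflowError("p = 1 maps to infinite uncertainty")
    ratio = (1.0 - arr) / lambda_
    if np.any(ratio > 1.0):
        raise ValueError("(1 - p)/lambda exceeds 1: p below the model's range")
    lc = -np.log(ratio) / beta
    if np.isscalar(p) or arr.ndim == 0:
        return float(lc)
    return lc


def _ecdf_at_sorted_positives(lc_sorted_pos: np.ndarray, n_total: int, n_zero: int) -> np.ndarray:
    # plotting positions over the full sample, zero-LC mass included
    k = np.arange(1, len(lc_sorted_pos) + 1)
    return (n_zero + k - 0.5) / n_total


def fit_boltzmann(lc_values, method: str = "cdf") -> BoltzmannFit:
    """Fit (lambda, beta) to observed LC values.

    method="cdf" (default)
        Least squares of the model CDF against the empirical CDF evaluated
        at the sorted positive LC values.  Deterministic multi-start.
    method="mle"
        Closed-form maximum likelihood under the defective-exponential
        reading: ``lambda = n_positive / n`` (1 if no zeros are present) and
        ``beta = 1 / mean(positive LC)``.
    """
    lc = np.asarray(lc_values, dtype=float)
    if np.any(lc < 0) or np.any(~np.isfinite(lc)):
        raise ValueError("lc values must be finite and non-negative")
    pos = np.sort(lc[lc > 0])
    n_total, n_pos = len(lc), len(pos)
    n_zero = n_total - n_pos
    if n_pos < 20:
        raise ValueError(f"need >= 20 positive lc values, got {n_pos}")
    if np.isclose(pos[0], pos[-1]):
        raise ValueError("degenerate (constant) lc values cannot be fitted")

    lam_mle = n_pos / n_total if n_zero else 1.0
    beta_mle = 1.0 / pos.mean()

    if method == "mle":
        resid = boltzmann_cdf(pos, lam_mle, beta_mle) - _ecdf_at_sorted_positives(pos, n_total, n_zero)
        return BoltzmannFit(lam_mle, beta_mle, float(resid @ resid), n_total, n_pos, "mle")
    if method != "cdf":
        raise ValueError(f"unknown method {method!r}")

    ecdf = _ecdf_at_sorted_positives(pos, n_total, n_zero)
    lc_min = pos[0]

    def residuals(params):
        lam, beta = np.exp(params)  # positivity via log-parametrization
        r = (1.0 - lam * np.exp(-beta * pos)) - ecdf
        # keep predicted probabilities in [0, 1] on the observed support
        penalty = 10.0 * max(0.0, lam * np.exp(-beta * lc_min) - 1.0)
        return np.append(r, penalty)

    starts = [
        (lam_mle, beta_mle),
        (1.0, beta_mle),
        (0.5, beta_mle),
        (1.0, 2.0 * beta_mle),
        (1.0, 0.5 * beta_mle),
    ]
    best = None
    for lam0, beta0 in starts:
        sol = least_squares(residuals, np.log([lam0, beta0]), method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    lam_hat, beta_hat = np.exp(best.x)
    r = (1.0 - lam_hat * np.exp(-beta_hat * pos)) - ecdf
    return BoltzmannFit(float(lam_hat), float(beta_hat), float(r @ r), n_total, n_pos, "cdf")


def pp_plot_data(lc_values, fit: BoltzmannFit) -> np.ndarray:
    """Paired (empirical, theoretical) probabilities for a P-P diagnostic.

    Returns an ``(n_positive, 2)`` array sorted by LC; both coordinates lie
    in [0, 1].  The empirical coordinate accounts for any zero-LC mass.
    """
    lc = np.asarray(lc_values, dtype=float)
    pos = np.sort(lc[lc > 0])
    if len(pos) == 0:
        return np.empty((0, 2))
    n_total = len(lc)
    n_zero = n_total - len(pos)
    empirical = (n_zero + np.arange(1, len(pos) + 1)) / (n_total + 1)
    theoretical = np.clip(fit.cdf(pos), 0.0, 1.0)
    return np.column_stack([empirical, theoretical])


def sample_lc(n: int, lambda_: float, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw LC values from the model by inverse transform.

    With probability ``1 - lambda`` a draw lands on the zero-LC atom;
    otherwise it is exponential with rate ``beta``.
    """
    _check_params(lambda_, beta)
    if lambda_ > 1:
        raise ValueError("lambda > 1 does not define a sampling distribution")
    u = rng.uniform(size=n)
    with np.errstate(divide="ignore"):
        lc = -np.log((1.0 - u) / lambda_) / beta
    return np.maximum(lc, 0.0)


def write_fit_report(fit: BoltzmannFit, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"lambda\t{fit.lambda_:.12g}\n")
        fh.write(f"beta\t{fit.beta:.12g}\n")
        fh.write(f"rss\t{fit.rss:.12g}\n")
        fh.write(f"n\t{fit.n}\n")
        fh.write(f"n_positive\t{fit.n_positive}\n")
        fh.write(f"method\t{fit.method}\n")


def write_pp_data(points: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("empirical\ttheoretical\n")
        for e, t in points:
            fh.write(f"{e:.12g}\t{t:.12g}\n")
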