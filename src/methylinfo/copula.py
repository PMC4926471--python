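"""Joint dependence model for paired (IR, LCR) region values.

The marginal of LCR (positive) is modelled as a Weibull, the marginal of IR
(real, asymmetric about a mode) as a skew-Laplace, and the dependence
between the two as a Farlie-Gumbel-Morgenstern (FGM) copula

    c(u, v) = 1 + theta * (1 - 2u) * (1 - 2v),   |theta| <= 1,

a weak-dependence family whose Spearman correlation is theta / 3.  The joint
density follows by Sklar's theorem.  A 2-D kernel density estimate of the
raw pairs is provided for empirical comparison.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gaussian_kde, laplace_asymmetric, spearmanr, weibull_min


# ---------------------------------------------------------------------------
# marginals
# ---------------------------------------------------------------------------

@dataclass
class WeibullMarginal:
    shape: float  # k
    scale: float  # s

    def pdf(self, x):
        return weibull_min.pdf(x, self.shape, scale=self.scale)

    def cdf(self, x):
        return weibull_min.cdf(x, self.shape, scale=self.scale)

    def ppf(self, q):
        return weibull_min.ppf(q, self.shape, scale=self.scale)

    def rvs(self, n, rng):
        return self.ppf(rng.uniform(size=n))


@dataclass
class SkewLaplaceMarginal:
    """Asymmetric Laplace: density (a*b/(a+b)) * exp(a(x-mu)) left of mu and
    (a*b/(a+b)) * exp(-b(x-mu)) right of it."""

    mu: float
    alpha: float   # left-tail rate, > 0
    beta_r: float  # right-tail rate, > 0

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        a, b = self.alpha, self.beta_r
        norm = a * b / (a + b)
        out = np.where(
            x < self.mu,
            norm * np.exp(a * (x - self.mu)),
            norm * np.exp(-b * (x - self.mu)),
        )
        return float(out) if out.ndim == 0 else out

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        a, b = self.alpha, self.beta_r
        out = np.where(
            x < self.mu,
            (b / (a + b)) * np.exp(a * (x - self.mu)),
            1.0 - (a / (a + b)) * np.exp(-b * (x - self.mu)),
        )
        return float(out) if out.ndim == 0 else out

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        a, b = self.alpha, self.beta_r
        split = b / (a + b)
        left = self.mu + np.log(np.maximum(q, 1e-300) / split) / a
        right = self.mu - np.log(np.maximum((1.0 - q), 1e-300) / (1.0 - split)) / b
        out = np.where(q < split, left, right)
        return float(out) if out.ndim == 0 else out

    def rvs(self, n, rng):
        return self.ppf(rng.uniform(size=n))


def fit_weibull(values) -> WeibullMarginal:
    """Maximum-likelihood Weibull fit (location fixed at 0)."""
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Weibull fitting requires strictly positive values")
    shape, _, scale = weibull_min.fit(x, floc=0)
    return WeibullMarginal(float(shape), float(scale))


def fit_skew_laplace(values) -> SkewLaplaceMarginal:
    """Maximum-likelihood asymmetric-Laplace fit.

    Uses the (kappa, loc, scale) parametrization internally and converts:
    left rate alpha = 1/(kappa*scale), right rate beta_r = kappa/scale.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    kappa, loc, scale = laplace_asymmetric.fit(x)
    return SkewLaplaceMarginal(
        mu=float(loc), alpha=float(1.0 / (kappa * scale)), beta_r=float(kappa / scale)
    )


# ---------------------------------------------------------------------------
# FGM copula
# ---------------------------------------------------------------------------

def _check_theta(theta: float) -> None:
    if not (-1.0 <= theta <= 1.0):
        raise ValueError(f"|theta| must be <= 1, got {theta}")


def fgm_density(u, v, theta: float):
    """FGM copula density c(u, v) = 1 + theta (1 - 2u)(1 - 2v) on [0,1]^2."""
    _check_theta(theta)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u < 0) | (u > 1)) or np.any((v < 0) | (v > 1)):
        raise ValueError("u, v must lie in [0, 1]")
    out = 1.0 + theta * (1.0 - 2.0 * u) * (1.0 - 2.0 * v)
    return float(out) if out.ndim == 0 else out


def fgm_cdf(u, v, theta: float):
    """FGM copula C(u, v) = u v [1 + theta (1 - u)(1 - v)]."""
    _check_theta(theta)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    out = u * v * (1.0 + theta * (1.0 - u) * (1.0 - v))
    return float(out) if out.ndim == 0 else out


def sample_fgm(n: int, theta: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (u, v) pairs from the FGM copula by conditional inversion."""
    _check_theta(theta)
    u = rng.uniform(size=n)
    w = rng.uniform(size=n)
    a = theta * (1.0 - 2.0 * u)
    v = np.where(
        np.abs(a) < 1e-12,
        w,
        # solve a v^2 - (1 + a) v + w = 0 for the root in [0, 1]
        (1.0 + a - np.sqrt((1.0 + a) ** 2 - 4.0 * a * w)) / (2.0 * np.where(a == 0, 1.0, a)),
    )
    return u, np.clip(v, 0.0, 1.0)


def fit_fgm_theta(x_values, y_values, method: str = "spearman") -> float:
    """Estimate the FGM dependence parameter from paired data.

    method="spearman" (default)
        Moment inversion of the FGM identity rho_S = theta/3:
        theta = 3 * rho_S, clipped to [-1, 1] (with a warning if clipping
        occurs — the data are then more dependent than FGM can express).
    method="mle"
        Maximize the copula log-likelihood on pseudo-observations (rank
        transforms of the data).
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired arrays must have equal length")
    if method == "spearman":
        rho = spearmanr(x, y).statistic
        theta = 3.0 * rho
        if abs(theta) > 1.0:
            warnings.warn(
                f"theta = 3*rho_S = {theta:.3f} outside [-1, 1]; clipped "
                "(dependence stronger than the FGM family allows)"
            )
        return float(np.clip(theta, -1.0, 1.0))
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")
    n = len(x)
    from scipy.stats import rankdata

    u = rankdata(x) / (n + 1)
    v = rankdata(y) / (n + 1)

    def nll(theta):
        return -np.sum(np.log(1.0 + theta * (1.0 - 2.0 * u) * (1.0 - 2.0 * v)))

    res = minimize_scalar(nll, bounds=(-1.0, 1.0), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@dataclass
class CopulaModel:
    """FGM dependence parameter plus fitted marginals (Weibull for LCR,
    skew-Laplace for IR)."""

    theta: float
    weibull: WeibullMarginal
    skew_laplace: SkewLaplaceMarginal

    def __post_init__(self):
        _check_theta(self.theta)

    def joint_density(self, ir, lcr):
        """Joint PDF via Sklar's theorem:
        c(F_IR(ir), F_LCR(lcr)) * f_IR(ir) * f_LCR(lcr)."""
        u = np.clip(self.skew_laplace.cdf(ir), 0.0, 1.0)
        v = np.clip(self.weibull.cdf(lcr), 0.0, 1.0)
        return fgm_density(u, v, self.theta) * self.skew_laplace.pdf(ir) * self.weibull.pdf(lcr)

    def rvs(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        u, v = sample_fgm(n, self.theta, rng)
        return self.skew_laplace.ppf(u), self.weibull.ppf(v)


def fit_dependence_model(ir_values, lcr_values, theta_method: str = "spearman") -> CopulaModel:
    """Fit the full (IR, LCR) dependence model to paired region values.

    LCR values must be positive for the Weibull marginal; pairs with
    non-positive LCR are dropped (with a warning) before fitting.
    """
    ir = np.asarray(ir_values, dtype=float)
    lcr = np.asarray(lcr_values, dtype=float)
    if ir.shape != lcr.shape:
        raise ValueError("paired arrays must have equal length")
    keep = lcr > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} pairs with non-positive LCR")
    ir, lcr = ir[keep], lcr[keep]
    return CopulaModel(
        theta=fit_fgm_theta(ir, lcr, method=theta_method),
        weibull=fit_weibull(lcr),
        skew_laplace=fit_skew_laplace(ir),
    )


# ---------------------------------------------------------------------------
# kernel density
# ---------------------------------------------------------------------------

def kde2d(
    x_values,
    y_values,
    bandwidth="silverman",
    gridsize: int = 64,
    padding: float = 0.15,
):
    """Gaussian 2-D kernel density estimate on a regular grid.

    Returns ``(x_axis, y_axis, density)`` where ``density[i, j]`` is the
    estimate at ``(x_axis[i], y_axis[j])``.  The grid extends ``padding``
    times the data range beyond the observed min/max so the density
    integrates to ~1 over the grid.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired arrays must have equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 paired observations")
    pad_x = padding * (x.max() - x.min() + 1e-12)
    pad_y = padding * (y.max() - y.min() + 1e-12)
    x_axis = np.linspace(x.min() - pad_x, x.max() + pad_x, gridsize)
    y_axis = np.linspace(y.min() - pad_y, y.max() + pad_y, gridsize)
    if isinstance(bandwidth, (int, float)):
        # fixed factor times the population SD per axis: a deterministic
        # function of the empirical distribution, so duplicating the data
        # leaves the estimate unchanged
        hx = float(bandwidth) * x.std()
        hy = float(bandwidth) * y.std()
        zx = (x_axis[:, None] - x[None, :]) / hx
        zy = (y_axis[:, None] - y[None, :]) / hy
        kx = np.exp(-0.5 * zx**2) / (hx * np.sqrt(2 * np.pi))
        ky = np.exp(-0.5 * zy**2) / (hy * np.sqrt(2 * np.pi))
        density = (kx @ ky.T) / len(x)
    else:
        kde = gaussian_kde(np.vstack([x, y]), bw_method=bandwidth)
        xx, yy = np.meshgrid(x_axis, y_axis, indexing="ij")
        density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(gridsize, gridsize)
    return x_axis, y_axis, density


def write_density_grid(x_axis, y_axis, density, path) -> None:
    """Gridded density as TSV: first row/column carry the axes."""
    with open(path, "w") as fh:
        fh.write("x\\y\t" + "\t".join(f"{v:.12g}" for v in y_axis) + "\n")
        for xv, row in zip(x_axis, density):
            fh.write(f"{xv:.12g}\t" + "\t".join(f"{d:.12g}" for d in row) + "\n")


def write_model_params(model: CopulaModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"theta\t{model.theta:.12g}\n")
        fh.write(f"weibull_shape\t{model.weibull.shape:.12g}\n")
        fh.write(f"weibull_scale\t{model.weibull.scale:.12g}\n")
        fh.write(f"skew_laplace_mu\t{model.skew_laplace.mu:.12g}\n")
        fh.write(f"skew_laplace_alpha\t{model.skew_laplace.alpha:.12g}\n")
        fh.write(f"skew_laplace_beta\t{model.skew_laplace.beta_r:.12g}\n")
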