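"""Rousset's 1-D dispersal-spread estimate and Monte-Carlo error propagation.

In a one-dimensional habitat the regression slope m of linearized F_ST on
distance satisfies m = 1 / (4 De sigma^2), so sigma = (4 De m)^(-1/2).
Uncertainty is propagated by sampling the Nb/Ne ratio and the slope from
normal distributions, Nb from a scaled chi-squared fitted to the jackknife
lower bound, and pushing every draw through the same deterministic chain as
the point estimate (bias adjustment -> Ne -> De -> sigma).

The chi-squared enters reciprocally by default, Nb* = nb_hat * df / X with
X ~ chi2(df): the LD signal r-squared-prime scales as 1/Nb, so it is the
precision-like quantity that carries the chi-squared error, and a reciprocal
scaling gives Nb the heavy upper tail that an unbounded ("infinite upper
limit") jackknife interval implies.  The direct scaling Nb* = nb_hat * X / df
is available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .effective_size import ne_from_nb


@dataclass(frozen=True)
class PropagationConfig:
    nb_hat: float  # breeders (point estimate)
    nb_ci_low: float  # breeders (2.5th percentile target for the sampler)
    ratio_mean: float
    ratio_sd: float
    m_mean: float  # per km
    m_se: float  # per km
    region_length: float  # km
    n_draws: int = 1_000_000
    seed: int | None = None
    chi2_form: str = "inverse"  # "inverse": Nb* = nb_hat * df/X; "direct": nb_hat * X/df
    chi2_fit_level: float = 0.05  # the reported lower bound is read as this quantile

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        for name in ("nb_hat", "ratio_mean", "m_mean", "region_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SigmaEstimate:
    sigma_point: float  # km
    ci_low: float
    ci_high: float
    draws: np.ndarray
    n_draws: int
    n_rejected: int
    seed: int | None

    def exceedance_fraction(self, threshold: float) -> float:
        return exceedance_fraction(self, threshold)

    def draws_to_csv(self, path) -> None:
        """Export the sigma draws as a single-column CSV for audit."""
        np.savetxt(path, self.draws, fmt="%.8g", header="sigma_km", comments="")


def sigma_point(de: float, m: float) -> float:
    """Dispersal-kernel spread sigma = (4 De m)^(-1/2), in km."""
    if m <= 0:
        raise ValueError("IBD slope must be positive for a defined kernel")
    if de <= 0:
        raise ValueError("effective density must be positive")
    return 1.0 / math.sqrt(4.0 * de * m)


def fit_chi2_nb_sampler(
    nb_hat: float, nb_ci_low: float, level: float = 0.025, df_cap: float = 1e6
) -> float:
    """Degrees of freedom of the scaled chi-squared Nb sampler.

    ``df`` is chosen by monotone root-finding so the ``level`` quantile of
    the scaled variable nb_hat * X / df, X ~ chi2(df) (mean nb_hat), equals
    ``nb_ci_low`` — i.e. chi2.ppf(level, df)/df = nb_ci_low/nb_hat.  Returns
    inf (degenerate point sampler) when the required df exceeds ``df_cap``
    (zero-width uncertainty limit).
    """
    if not (0 < nb_ci_low < nb_hat):
        raise ValueError("need 0 < nb_ci_low < nb_hat")
    if not 0 < level < 0.5:
        raise ValueError("level must be in (0, 0.5)")
    target = nb_ci_low / nb_hat

    def f(df: float) -> float:
        return chi2.ppf(level, df) / df - target

    # chi2.ppf(0.025, df)/df is monotone increasing in df, -> 1 as df -> inf
    lo, hi = 1e-3, 10.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > df_cap:
            return math.inf
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-10))


def _sample_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> tuple[np.ndarray, int]:
    """Normal draws with rejection-resampling of non-positive values."""
    if sd == 0:
        return np.full(size, mean), 0
    out = rng.normal(mean, sd, size)
    rejected = 0
    bad = out <= 0
    while bad.any():
        rejected += int(bad.sum())
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out, rejected


def propagate_sigma(cfg: PropagationConfig) -> SigmaEstimate:
    """Monte-Carlo propagation of sigma uncertainty.

    Per draw: ratio ~ N(ratio_mean, ratio_sd), m ~ N(m_mean, m_se), Nb* from
    the fitted chi-squared sampler; non-positive draws and draws outside the
    adjustment's domain (1.26 - 0.323 ratio <= 0) are rejected and redrawn.
    The reported point estimate comes from the deterministic parameters, not
    the draw mean; the CI is the central 95% of the draws.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_draws
    n_rejected = 0

    ratio, rej = _sample_truncated_normal(rng, cfg.ratio_mean, cfg.ratio_sd, n)
    n_rejected += rej
    # reject ratio draws outside the bias-adjustment domain
    bad = 1.26 - 0.323 * ratio <= 0
    while bad.any():
        n_rejected += int(bad.sum())
        redraw, rej = _sample_truncated_normal(
            rng, cfg.ratio_mean, cfg.ratio_sd, int(bad.sum())
        )
        n_rejected += rej
        ratio[bad] = redraw
        bad = 1.26 - 0.323 * ratio <= 0

    m, rej = _sample_truncated_normal(rng, cfg.m_mean, cfg.m_se, n)
    n_rejected += rej

    df = fit_chi2_nb_sampler(cfg.nb_hat, cfg.nb_ci_low, level=cfg.chi2_fit_level)
    if math.isinf(df):
        nb = np.full(n, cfg.nb_hat)
    elif cfg.chi2_form == "direct":
        nb = cfg.nb_hat * rng.chisquare(df, n) / df
    elif cfg.chi2_form == "inverse":
        x = rng.chisquare(df, n)
        zero = x <= 0
        while zero.any():
            n_rejected += int(zero.sum())
            x[zero] = rng.chisquare(df, int(zero.sum()))
            zero = x <= 0
        nb = cfg.nb_hat * df / x
    else:
        raise ValueError("chi2_form must be 'inverse' or 'direct'")

    if n_rejected > 0.1 * n:
        raise ValueError(
            f"rejection rate {n_rejected / n:.1%} exceeds 10%: "
            "inconsistent propagation inputs"
        )

    _, ne = ne_from_nb(nb, ratio)
    de = ne / cfg.region_length
    draws = 1.0 / np.sqrt(4.0 * de * m)

    _, ne_pt = ne_from_nb(cfg.nb_hat, cfg.ratio_mean)
    pt = sigma_point(ne_pt / cfg.region_length, cfg.m_mean)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return SigmaEstimate(
        sigma_point=pt,
        ci_low=float(lo),
        ci_high=float(hi),
        draws=draws,
        n_draws=n,
        n_rejected=n_rejected,
        seed=cfg.seed,
    )


def exceedance_fraction(est: SigmaEstimate, threshold: float) -> float:
    """Fraction of sigma draws >= threshold (km)."""
    if est.draws.size == 0:
        raise ValueError("no draws")
    return float(np.mean(est.draws >= threshold))
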