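"""Estimators and tests for small-cross drive experiments.

Covers the statistics used on per-vial phenotype counts: pooled binomial
rates, a binomial random-intercept GLMM fitted by adaptive Gauss-Hermite
quadrature (vials are batches with their own luck), z-tests between rates,
the sterility-based embryo resistance estimator, Welch t-tests on fecundity,
and two-proportion tests on egg-to-adult viability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "VialRecord",
    "RateEstimate",
    "pooled_rate",
    "glmm_logit_rate",
    "compare_rates_z",
    "embryo_resistance_rate",
    "fecundity_ttest",
    "viability_compare",
]


@dataclass(frozen=True)
class VialRecord:
    """Offspring counts from a single cross vial."""

    vial_id: str
    cross_class: str
    n_offspring: int
    n_drive_carriers: int
    eggs_per_day: tuple[int, ...] | None = None
    n_eggs: int | None = None
    n_adults: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_drive_carriers <= self.n_offspring:
            raise ValueError(
                f"vial {self.vial_id}: need 0 <= carriers <= offspring, "
                f"got {self.n_drive_carriers}/{self.n_offspring}"
            )
        if self.n_eggs is not None and self.n_adults is not None:
            if self.n_adults > self.n_eggs:
                raise ValueError(f"vial {self.vial_id}: n_adults > n_eggs")


@dataclass(frozen=True)
class RateEstimate:
    """A proportion with its uncertainty."""

    estimate: float
    se: float
    ci: tuple[float, float]
    n: int
    method: str  # "pooled" | "glmm"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 1.0:
            raise ValueError("estimate must be a proportion")
        if self.se < 0:
            raise ValueError("SE must be non-negative")


def _counts(vials) -> tuple[np.ndarray, np.ndarray]:
    """(carriers, offspring) arrays from VialRecords or (k, n) pairs."""
    ks, ns = [], []
    for v in vials:
        if isinstance(v, VialRecord):
            ks.append(v.n_drive_carriers)
            ns.append(v.n_offspring)
        else:
            k, n = v
            ks.append(int(k))
            ns.append(int(n))
    return np.asarray(ks), np.asarray(ns)


def pooled_rate(vials, exact_ci: bool = False) -> RateEstimate:
    """Pooled binomial proportion over vials.

    p-hat = sum(k)/sum(n) with SE = sqrt(p(1-p)/sum(n)); Wald 95% CI clipped
    to [0, 1], or Clopper-Pearson when ``exact_ci`` is requested.
    """
    ks, ns = _counts(vials)
    if len(ns) == 0 or ns.sum() == 0:
        raise ValueError("pooled_rate needs at least one vial with offspring")
    n, k = int(ns.sum()), int(ks.sum())
    p = k / n
    se = float(np.sqrt(p * (1 - p) / n))
    if exact_ci:
        lo, hi = stats.binomtest(k, n).proportion_ci(0.95, method="exact")
        ci = (float(lo), float(hi))
    else:
        half = 1.959963984540054 * se
        ci = (max(0.0, p - half), min(1.0, p + half))
    return RateEstimate(p, se, ci, n, "pooled")


# ---------------------------------------------------------------------------
# binomial random-intercept GLMM via adaptive Gauss-Hermite quadrature


def _aghq_loglik(mu: float, sigma: float, ks: np.ndarray, ns: np.ndarray,
                 nodes: np.ndarray, weights: np.ndarray) -> float:
    """Marginal log-likelihood of logit(p_i) = mu + b_i, b_i ~ N(0, sigma^2).

    Per-vial integrals are evaluated with Gauss-Hermite quadrature adapted to
    the mode and curvature of each vial's integrand (Newton on the concave
    per-vial log-joint), which makes a modest node count accurate even for
    large vials.
    """
    lchoose = float(
        np.sum(special.gammaln(ns + 1) - special.gammaln(ks + 1) - special.gammaln(ns - ks + 1))
    )
    if sigma < 1e-6:  # degenerate: no batch effect
        p = special.expit(mu)
        return lchoose + float(
            np.sum(ks * np.log(p + 1e-300) + (ns - ks) * np.log(1 - p + 1e-300))
        )
    var = sigma**2
    b = np.zeros_like(ks, dtype=float)
    for _ in range(50):  # Newton for per-vial modes, vectorised
        p = special.expit(mu + b)
        grad = ks - ns * p - b / var
        hess = -ns * p * (1 - p) - 1.0 / var
        step = grad / hess
        b -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = special.expit(mu + b)
    shat = 1.0 / np.sqrt(ns * p * (1 - p) + 1.0 / var)
    # nodes: (n_vials, n_nodes)
    z = b[:, None] + np.sqrt(2.0) * shat[:, None] * nodes[None, :]
    pz = special.expit(mu + z)
    logint = (
        ks[:, None] * np.log(pz + 1e-300)
        + (ns - ks)[:, None] * np.log(1 - pz + 1e-300)
        - 0.5 * z**2 / var
        - 0.5 * np.log(2 * np.pi * var)
    )
    # exp-normalised quadrature sum per vial
    logw = logint + np.log(weights)[None, :] + nodes[None, :] ** 2
    m = logw.max(axis=1, keepdims=True)
    per_vial = m[:, 0] + np.log(np.sum(np.exp(logw - m), axis=1)) + np.log(
        np.sqrt(2.0) * shat
    )
    return lchoose + float(per_vial.sum())


def glmm_logit_rate(vials, nagq: int = 25) -> RateEstimate:
    """Batch-aware proportion: binomial GLMM with a per-vial random intercept.

    Fits logit(p_vial) = mu + b_vial, b ~ N(0, sigma^2) by maximum marginal
    likelihood with ``nagq``-node adaptive Gauss-Hermite quadrature, and
    reports the population rate expit(mu) with a delta-method SE.  With
    ``nagq`` = 1 the quadrature reduces to the Laplace approximation.  Falls
    back to the pooled estimator (with a warning) on failure.
    """
    ks, ns = _counts(vials)
    if len(ns) < 2:
        raise ValueError("glmm_logit_rate needs >= 2 vials")
    if (ns == 0).any():
        raise ValueError("all vials must have offspring")
    nodes, weights = np.polynomial.hermite.hermgauss(nagq)
    pooled = pooled_rate(vials)
    mu0 = special.logit(np.clip(pooled.estimate, 1e-4, 1 - 1e-4))

    def nll(x):
        mu, log_sigma = x
        return -_aghq_loglik(mu, np.exp(log_sigma), ks, ns, nodes, weights)

    best = None
    for ls0 in (np.log(0.5), np.log(0.1), 0.0):
        res = optimize.minimize(
            nll, x0=[mu0, ls0], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        warnings.warn("GLMM fit failed; falling back to pooled estimate")
        return RateEstimate(
            pooled.estimate, pooled.se, pooled.ci, pooled.n, "glmm",
            extras={"fallback": "pooled", "converged": False},
        )
    mu_hat, log_sigma_hat = best.x
    sigma_hat = float(np.exp(log_sigma_hat))
    # observed information via central differences on (mu, log sigma)
    se_mu = _wald_se_mu(nll, best.x)
    p = float(special.expit(mu_hat))
    se_p = se_mu * p * (1 - p)
    half = 1.959963984540054 * se_p
    return RateEstimate(
        p,
        float(se_p),
        (max(0.0, p - half), min(1.0, p + half)),
        int(ns.sum()),
        "glmm",
        extras={
            "mu": float(mu_hat),
            "se_mu": float(se_mu),
            "sigma": sigma_hat,
            "loglik": float(-best.fun),
            "n_vials": len(ns),
            "converged": bool(best.success),
        },
    )


def _wald_se_mu(nll, x_hat, h: float = 1e-4) -> float:
    """SE of mu from the inverse numerical Hessian at the optimum."""
    H = np.zeros((2, 2))
    for a in range(2):
        for b in range(a, 2):
            ea = np.eye(2)[a] * h
            eb = np.eye(2)[b] * h
            H[a, b] = H[b, a] = (
                nll(x_hat + ea + eb) - nll(x_hat + ea - eb)
                - nll(x_hat - ea + eb) + nll(x_hat - ea - eb)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        v = cov[0, 0]
        if v > 0:
            return float(np.sqrt(v))
    except np.linalg.LinAlgError:
        pass
    # near-degenerate sigma: fall back to the mu-only curvature
    d2 = (nll(x_hat + [h, 0]) - 2 * nll(x_hat) + nll(x_hat - [h, 0])) / h**2
    return float(np.sqrt(1.0 / d2)) if d2 > 0 else float("nan")


# ---------------------------------------------------------------------------
# tests


def _as_estimate(x) -> RateEstimate:
    if isinstance(x, RateEstimate):
        return x
    k, n = x
    return pooled_rate([(k, n)])


def compare_rates_z(a, b) -> tuple[float, float]:
    """Two-sided z-test between two rates, or against a null constant.

    z = (p_a - p_b) / sqrt(SE_a^2 + SE_b^2); for a scalar ``b`` the null
    value has no sampling error.  Inputs may be RateEstimates or (k, n)
    count pairs (scored with pooled binomial SEs).
    """
    ra = _as_estimate(a)
    if isinstance(b, (int, float)) and not isinstance(b, bool):
        diff = ra.estimate - float(b)
        denom = ra.se
    else:
        rb = _as_estimate(b)
        diff = ra.estimate - rb.estimate
        denom = np.hypot(ra.se, rb.se)
    if denom == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("zero standard error with unequal estimates")
    z = diff / denom
    return float(z), float(2 * stats.norm.sf(abs(z)))


def embryo_resistance_rate(records) -> RateEstimate:
    """Embryo resistance from sterility of drive daughters of drive mothers.

    ``records``: iterable of (female_id, sterile_flag).  Under the drive
    model the sterile fraction of drive daughters from a D/W x W/W cross is
    exactly the per-allele embryo cut rate ``e`` — a drive daughter is
    sterile iff her paternal wild-type allele was converted in the embryo.
    """
    flags = [bool(s) for _, s in records]
    if not flags:
        raise ValueError("embryo_resistance_rate needs at least one record")
    return pooled_rate([(sum(flags), len(flags))])


def fecundity_ttest(eggs_a, eggs_b) -> tuple[float, float, float]:
    """Welch two-sample t-test on per-female mean daily egg counts.

    Returns (t, df, two-sided p).
    """
    a = np.asarray(eggs_a, dtype=float)
    b = np.asarray(eggs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 females per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate zero-variance samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def viability_compare(a: dict, b: dict) -> tuple[float, float]:
    """Two-proportion z-test on egg-to-adult survival.

    ``a``, ``b``: mappings with ``n_eggs`` and ``n_adults``.
    """
    for x in (a, b):
        if x["n_adults"] > x["n_eggs"] or x["n_eggs"] <= 0:
            raise ValueError("need 0 <= n_adults <= n_eggs with n_eggs > 0")
    z, p = proportions_ztest(
        [a["n_adults"], b["n_adults"]], [a["n_eggs"], b["n_eggs"]]
    )
    return float(z), float(p)
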