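"""Truncated-normal polygenic-score accuracy model.

Forward model for the expected squared correlation between a p-value-
thresholded polygenic score and a continuous trait, and a maximum-likelihood
inversion that estimates the marker-explained variance ``vg`` (optionally
the null-marker fraction ``pi0``) from observed score-trait test statistics,
with profile-likelihood confidence intervals.

Model assumptions: unit-variance trait; m independent markers on the
standardized-genotype scale; per-marker effect estimates from a training
sample of n1 individuals with sampling variance s^2 = 1/n1; true non-null
effects N(0, vg / (m (1 - pi0))).  A marker enters the score when its
training |z| exceeds the threshold implied by the selection p-value.  With
no selection (p = 1) the expected accuracy reduces to the classical
closed form vg^2 / (vg + m/n1).

A brute-force two-stage simulation (:func:`simulate_two_stage_r2`) with the
same assumptions serves as an independent numerical check of the analytic
forward model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AvengemeModel", "AvengemeEstimate", "ObservedScoreResult",
    "selection_probability", "truncated_second_moment", "expected_r2",
    "expected_ncp", "estimate_vg", "simulate_two_stage_r2",
]

CHI2_95 = 3.841458820694124  # chi^2_1 95% quantile, profile-likelihood cut


@dataclass(frozen=True)
class AvengemeModel:
    """Parameters of the polygenic accuracy forward model."""

    n1: int
    m: int
    vg: float
    pi0: float = 0.0
    p_threshold: float = 1.0
    n2: int | None = None

    def __post_init__(self):
        if self.n1 < 1 or (self.n2 is not None and self.n2 < 1):
            raise ValueError("sample sizes must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 <= self.vg < 1:
            raise ValueError("vg must lie in [0, 1)")
        if not 0 <= self.pi0 <= 1:
            raise ValueError("pi0 must lie in [0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ObservedScoreResult:
    """One observed score-trait result at a given selection threshold.

    Provide either the test-sample z statistic or the observed R^2 (converted
    internally via z = sqrt(n2 R^2 / (1 - R^2)))."""

    p_threshold: float
    n1: int
    n2: int
    m: int
    z: float | None = None
    r2: float | None = None

    def z_value(self) -> float:
        if self.z is not None:
            return float(self.z)
        if self.r2 is None:
            raise ValueError("observed result needs z or r2")
        r2 = min(max(self.r2, 0.0), 1 - 1e-12)
        return float(np.sqrt(self.n2 * r2 / (1 - r2)))


@dataclass
class AvengemeEstimate:
    """Maximum-likelihood estimate of vg with 95% profile-likelihood CI."""

    vg_hat: float
    ci_low: float
    ci_high: float
    pi0_mode: str  # fixed | estimated
    loglik: float
    pi0_hat: float | None = None
    converged: bool = True
    multi_threshold: bool = False


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def selection_probability(v: float, c: float) -> float:
    """P(|X| > c) for X ~ N(0, v)."""
    if v <= 0:
        raise ValueError("variance v must be > 0")
    if c < 0:
        raise ValueError("cut-off c must be >= 0")
    return float(2 * stats.norm.sf(c / np.sqrt(v)))


def truncated_second_moment(v: float, c: float) -> float:
    """E[X^2 1{|X| > c}] for X ~ N(0, v): v * 2 * (Phi(-a) + a phi(a)), a = c/sqrt(v)."""
    if v <= 0:
        raise ValueError("variance v must be > 0")
    if c < 0:
        raise ValueError("cut-off c must be >= 0")
    a = c / np.sqrt(v)
    return float(v * 2 * (stats.norm.sf(a) + a * stats.norm.pdf(a)))


def expected_r2(model: AvengemeModel) -> float:
    """Expected squared score-trait correlation under the forward model.

    The marker's estimated effect X = gamma_hat has variance sigma_g^2 + s^2
    (non-null) or s^2 (null); selection keeps |X| > c with
    c = z_{1 - p/2} * s.  The score-trait covariance shrinks each selected
    estimate by the reliability sigma_g^2 / (sigma_g^2 + s^2).
    """
    s2 = 1.0 / model.n1
    c = stats.norm.isf(model.p_threshold / 2) * np.sqrt(s2)
    m_causal = model.m * (1 - model.pi0)
    sigma_g2 = model.vg / m_causal if m_causal > 0 else 0.0

    var_s = model.m * model.pi0 * truncated_second_moment(s2, c)
    cov = 0.0
    if m_causal > 0:
        v1 = sigma_g2 + s2
        e1 = truncated_second_moment(v1, c)
        var_s += m_causal * e1
        cov = m_causal * (sigma_g2 / v1) * e1
    if var_s <= 0:
        return 0.0
    return float(cov ** 2 / var_s)


def expected_ncp(model: AvengemeModel, n2: int) -> float:
    """Non-centrality of the test-sample score-trait association."""
    if n2 < 1:
        raise ValueError("n2 must be >= 1")
    rho2 = expected_r2(model)
    return float(n2 * rho2 / (1 - rho2))


# ---------------------------------------------------------------------------
# inversion: maximum likelihood for vg (and optionally pi0)
# ---------------------------------------------------------------------------

def _loglik(vg: float, pi0: float, observed) -> float:
    ll = 0.0
    for obs in observed:
        model = AvengemeModel(n1=obs.n1, m=obs.m, vg=vg, pi0=pi0,
                              p_threshold=obs.p_threshold)
        lam = expected_ncp(model, obs.n2)
        ll += float(stats.norm.logpdf(obs.z_value(), loc=np.sqrt(lam), scale=1.0))
    return ll


def estimate_vg(observed, pi0: float | str = 0.0,
                vg_max: float = 0.999) -> AvengemeEstimate:
    """Estimate vg by maximum likelihood from observed score results.

    ``observed`` is a sequence of :class:`ObservedScoreResult`.  Each observed
    statistic is modelled z ~ N(sqrt(lambda(theta)), 1) with lambda the
    forward-model non-centrality.  ``pi0`` is either a fixed value (default 0,
    i.e. all markers causal) or the string ``"estimate"`` (requires results
    at >= 2 thresholds; thresholds are treated as independent, an
    approximation since nested selections are correlated).  The 95% CI is by
    profile likelihood; a boundary estimate at vg = 0 yields a one-sided
    interval with ci_low = 0.
    """
    observed = list(observed)
    if len(observed) == 0:
        raise ValueError("at least one observed result is required")
    estimate_pi0 = isinstance(pi0, str)
    if estimate_pi0:
        if pi0 != "estimate":
            raise ValueError("pi0 must be a number or 'estimate'")
        if len(observed) < 2:
            raise ValueError("estimating pi0 requires results at >= 2 thresholds")

    if estimate_pi0:
        def profile_ll(vg: float) -> tuple:
            res = optimize.minimize_scalar(
                lambda q: -_loglik(vg, q, observed),
                bounds=(0.0, 0.999), method="bounded",
                options={"xatol": 1e-6})
            return -res.fun, float(res.x)
    else:
        pi0_fixed = float(pi0)

        def profile_ll(vg: float) -> tuple:
            return _loglik(vg, pi0_fixed, observed), pi0_fixed

    converged = True
    res = optimize.minimize_scalar(lambda v: -profile_ll(v)[0],
                                   bounds=(0.0, vg_max), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        converged = False
    vg_hat = float(res.x)
    ll_hat, pi0_hat = profile_ll(vg_hat)
    ll0, _ = profile_ll(0.0)
    if ll0 >= ll_hat:  # boundary solution
        vg_hat, ll_hat = 0.0, ll0

    cut = ll_hat - CHI2_95 / 2

    def deficit(v: float) -> float:
        return profile_ll(v)[0] - cut

    # lower bound
    if vg_hat <= 0 or deficit(0.0) >= 0:
        ci_low = 0.0
    else:
        ci_low = float(optimize.brentq(deficit, 0.0, vg_hat, xtol=1e-10))
    # upper bound
    if deficit(vg_max) >= 0:
        ci_high = vg_max
        converged = False
    else:
        lo = vg_hat if vg_hat > 0 else 0.0
        ci_high = float(optimize.brentq(deficit, lo, vg_max, xtol=1e-10))

    return AvengemeEstimate(
        vg_hat=vg_hat, ci_low=ci_low, ci_high=ci_high,
        pi0_mode="estimated" if estimate_pi0 else "fixed",
        pi0_hat=pi0_hat if estimate_pi0 else None,
        loglik=ll_hat, converged=converged,
        multi_threshold=len(observed) > 1,
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def simulate_two_stage_r2(model: AvengemeModel, n2: int, n_reps: int,
                          seed: int = 0) -> np.ndarray:
    """Empirical score-trait R^2 from a full two-stage simulation.

    Per replicate: draw sparse effects, simulate a training sample (n1
    standardized genotypes, unit-variance trait), estimate per-marker
    marginal effects, select at the model's p-value threshold, score an
    independent test sample of size n2 and record the squared correlation
    with its trait.  Replicates with an empty selection contribute R^2 = 0.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    m, n1 = model.m, model.n1
    n_null = int(round(m * model.pi0))
    n_causal = m - n_null
    sigma_g = np.sqrt(model.vg / n_causal) if n_causal > 0 and model.vg > 0 else 0.0
    resid_sd = np.sqrt(max(1.0 - model.vg, 1e-12))
    zc = stats.norm.isf(model.p_threshold / 2)

    out = np.zeros(n_reps)
    for r in range(n_reps):
        beta = np.zeros(m)
        if n_causal > 0:
            beta[:n_causal] = rng.normal(0.0, sigma_g, n_causal)
        G1 = rng.standard_normal((n1, m))
        y1 = G1 @ beta + rng.normal(0.0, resid_sd, n1)
        beta_hat = G1.T @ y1 / n1
        sel = np.abs(beta_hat) * np.sqrt(n1) > zc
        if not sel.any():
            continue
        G2 = rng.standard_normal((n2, m))
        y2 = G2 @ beta + rng.normal(0.0, resid_sd, n2)
        score = G2[:, sel] @ beta_hat[sel]
        sv = score.std()
        if sv == 0:
            continue
        c = np.corrcoef(score, y2)[0, 1]
        out[r] = c * c
    return out
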