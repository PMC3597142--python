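"""Bayesian model selection for the well-positioned-nucleosome signature.

A 150 bp candidate region is summarized by five 30 bp bin counts
y = (y1..y5) grouped into three segments S1 = {y1, y2}, S2 = {y3},
S3 = {y4, y5}.  Counts are Poisson with one rate per segment, and each
segment is in one of two states:

* ``bg`` (background): rate drawn from a Gamma(alpha, beta) prior whose
  hyperparameters are fitted per chromosome by the method of moments, so the
  prior captures the genome-wide, mostly unpositioned read distribution;
* ``en`` (enriched): rate drawn from Uniform(0, lambda_max), lambda_max
  being the maximum corrected bin count of the chromosome, so the prior is
  agnostic about the enrichment level.

The eight assignments of {bg, en} to (S1, S2, S3) form models M0..M7; a
well-positioned nucleosome is the pattern M1 = (bg, en, bg).  Both marginal
likelihoods integrate the Poisson rate analytically: the gamma prior gives
the negative-binomial closed form, the uniform prior a lower incomplete
gamma function.  Everything is computed in log space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.special as sc

from .preprocess import BinnedTrack

logger = logging.getLogger("nucleofinder")

#: bin indices of the three segments within the five-bin window
SEGMENTS = ((0, 1), (2,), (3, 4))

#: segment states (S1, S2, S3) per model; M0 is the all-background null and
#: M1 the positioned-nucleosome signature
MODEL_STATES: dict[str, tuple[str, str, str]] = {
    "M0": ("bg", "bg", "bg"),
    "M1": ("bg", "en", "bg"),
    "M2": ("en", "en", "en"),
    "M3": ("en", "bg", "en"),
    "M4": ("en", "en", "bg"),
    "M5": ("bg", "en", "en"),
    "M6": ("en", "bg", "bg"),
    "M7": ("bg", "bg", "en"),
}
MODEL_IDS = tuple(MODEL_STATES)


@dataclass(frozen=True)
class GammaHyper:
    """Gamma(shape=alpha, rate=beta) prior on the background Poisson rate."""

    alpha: float
    beta: float
    chrom: str = ""

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("gamma hyperparameters must be positive")


@dataclass(frozen=True)
class UniformPrior:
    """Uniform(0, lambda_max) prior on the enriched Poisson rate."""

    lambda_max: float

    def __post_init__(self) -> None:
        if not self.lambda_max > 0:
            raise ValueError("lambda_max must be positive")


@dataclass
class RegionCounts:
    """The five corrected bin counts of one 150 bp candidate region."""

    y: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        y = tuple(int(v) for v in self.y)
        if len(y) != 5 or any(v < 0 for v in y):
            raise ValueError("region counts must be 5 non-negative integers")
        self.y = y


@dataclass
class ModelEvaluation:
    """Per-model log marginal likelihoods, the winner, and log BF(M1:M0)."""

    log_marginals: dict[str, float]
    winner: str
    log_bayes_factor: float


def estimate_gamma_hyperparams(track: BinnedTrack, ddof: int = 1) -> GammaHyper:
    """Method-of-moments fit of the gamma prior to one chromosome's counts.

    The fit targets the Poisson-gamma *marginal* (negative binomial): with
    bin mean mu and variance s2, mu = alpha/beta and
    s2 = (alpha/beta)(1 + 1/beta), hence beta = mu/(s2 - mu), alpha = mu*beta.
    Without overdispersion (s2 <= mu) a flat default (alpha=1,
    beta=1/max(mu, eps)) is returned with a warning.
    """
    counts = track.counts
    if counts.size < 2:
        raise ValueError("need at least 2 bins to estimate hyperparameters")
    mu = float(counts.mean())
    if mu == 0.0:
        raise ValueError(f"empty chromosome {track.chrom}: cannot fit background prior")
    s2 = float(counts.var(ddof=ddof))
    if s2 <= mu:
        warnings.warn(
            f"{track.chrom}: no overdispersion (var {s2:.4g} <= mean {mu:.4g}); "
            "falling back to alpha=1, beta=1/mean",
            RuntimeWarning,
            stacklevel=2,
        )
        return GammaHyper(1.0, 1.0 / max(mu, 1e-12), track.chrom)
    beta = mu / (s2 - mu)
    return GammaHyper(mu * beta, beta, track.chrom)


# ---------------------------------------------------------------------------
# segment marginal likelihoods (shared Poisson rate within a segment)
# ---------------------------------------------------------------------------

def _log_lower_gamma(a, x):
    """log of the lower incomplete gamma function gamma(a, x), elementwise.

    Uses the regularized routine where it does not underflow; for x << a it
    switches to the ascending series
    gamma(a, x) = x^a e^{-x} sum_k x^k / (a (a+1) ... (a+k)).
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    a, x = np.broadcast_arrays(a, x)
    p = sc.gammainc(a, x)
    with np.errstate(divide="ignore"):
        out = sc.gammaln(a) + np.log(p)
    tiny = p < 1e-290
    if np.any(tiny):
        flat = out.reshape(-1)
        af, xf = a.reshape(-1), x.reshape(-1)
        for i in np.nonzero(tiny.reshape(-1))[0]:
            flat[i] = _log_lower_gamma_series(af[i], xf[i])
    return out


def _log_lower_gamma_series(a: float, x: float) -> float:
    if x <= 0:
        return -np.inf
    term = 1.0
    total = 1.0
    k = 0
    while term > 1e-18 * total and k < 10_000:
        k += 1
        term *= x / (a + k)
        total += term
    return a * np.log(x) - x - np.log(a) + np.log(total)


def _gamma_core(n, S, hyper: GammaHyper):
    """Log marginal of a bg segment given bin count n and total S, excluding
    the data-dependent -sum(log y_i!) term (which is common to all models)."""
    S = np.asarray(S, dtype=float)
    a, b = hyper.alpha, hyper.beta
    return a * np.log(b) - sc.gammaln(a) + sc.gammaln(a + S) - (a + S) * np.log(b + n)


def _uniform_core(n, S, lambda_max: float):
    """Log marginal of an en segment (same convention as :func:`_gamma_core`)."""
    S = np.asarray(S, dtype=float)
    return -np.log(lambda_max) - (S + 1.0) * np.log(float(n)) + _log_lower_gamma(S + 1.0, n * lambda_max)


def _check_counts(counts) -> np.ndarray:
    y = np.asarray(counts)
    if y.size == 0:
        raise ValueError("empty count vector")
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
        y = y.astype(np.int64)
        if np.any(y < 0):
            raise ValueError("counts must be non-negative integers")
    return y


def log_marginal_gamma(counts: Sequence[int], hyper: GammaHyper) -> float:
    """Log marginal likelihood of counts sharing one rate under the gamma prior.

    Closed form via Poisson-gamma conjugacy (negative binomial):
    sum_i(-log y_i!) + alpha log beta - log G(alpha) + log G(alpha + S)
    - (alpha + S) log(beta + n).
    """
    y = _check_counts(counts)
    core = _gamma_core(y.size, int(y.sum()), hyper)
    return float(core - sc.gammaln(y + 1.0).sum())


def log_marginal_uniform(counts: Sequence[int], prior: UniformPrior) -> float:
    """Log marginal likelihood under the Uniform(0, lambda_max) prior.

    (1/lambda_max) * integral_0^lambda_max prod_i Pois(y_i | lam) d lam,
    evaluated through the lower incomplete gamma function in log space.
    """
    y = _check_counts(counts)
    core = np.squeeze(_uniform_core(y.size, int(y.sum()), prior.lambda_max))
    return float(core - sc.gammaln(y + 1.0).sum())


class UniformTable:
    """Precomputed en-segment log marginals indexed by (n, S).

    Stores :func:`_uniform_core` values (which exclude the data-dependent
    factorial term) for n in {1..max_bins} and S in 0..max_total; lookups are
    bit-identical to direct evaluation because both run the same code path.
    Out-of-range totals fall back to direct evaluation transparently.
    """

    def __init__(self, prior: UniformPrior, max_total: int, max_bins: int = 2):
        if max_bins < 2:
            raise ValueError("max_bins must be >= 2")
        if max_total < 0:
            raise ValueError("max_total must be >= 0")
        self.prior = prior
        self.max_total = int(max_total)
        self.max_bins = int(max_bins)
        grid = np.arange(self.max_total + 1)
        self._cores = {n: _uniform_core(n, grid, prior.lambda_max) for n in range(1, max_bins + 1)}

    def core(self, n: int, S: int) -> float:
        """Factorial-free en marginal for a segment of n bins totalling S."""
        if n in self._cores and 0 <= S <= self.max_total:
            return float(self._cores[n][S])
        return float(np.squeeze(_uniform_core(n, S, self.prior.lambda_max)))

    def core_array(self, n: int, S: np.ndarray) -> np.ndarray:
        """Vectorized lookup with transparent fallback above max_total."""
        S = np.asarray(S, dtype=np.int64)
        if n in self._cores and (S.size == 0 or int(S.max()) <= self.max_total):
            return self._cores[n][S]
        out = np.empty(S.shape, dtype=float)
        inside = S <= self.max_total
        if n in self._cores:
            out[inside] = self._cores[n][S[inside]]
        else:
            inside = np.zeros_like(inside)
        out[~inside] = _uniform_core(n, S[~inside], self.prior.lambda_max)
        return out

    def log_marginal(self, counts: Sequence[int]) -> float:
        """Full log marginal for a concrete count vector (adds the factorial term)."""
        y = _check_counts(counts)
        return float(self.core(y.size, int(y.sum())) - sc.gammaln(y + 1.0).sum())


def precompute_uniform_table(prior: UniformPrior, max_total: int, max_bins: int = 2) -> UniformTable:
    """Build the (n, S)-indexed uniform-prior marginal table used by the scan."""
    return UniformTable(prior, max_total, max_bins)


def evaluate_models(
    region: RegionCounts | Sequence[int],
    hyper: GammaHyper,
    prior: UniformPrior,
) -> ModelEvaluation:
    """Log marginal likelihood of all eight models for one five-bin region.

    Each model's marginal is the sum over the three segments, with bg
    segments under the gamma prior and en segments under the uniform prior.
    The winner is the argmax (ties resolve to the lowest model index) and
    the score is log BF(M1:M0).
    """
    y = np.asarray(region.y if isinstance(region, RegionCounts) else region, dtype=np.int64)
    if y.size != 5 or np.any(y < 0):
        raise ValueError("region must hold 5 non-negative counts")
    groups = [y[list(seg)] for seg in SEGMENTS]
    bg = [log_marginal_gamma(g, hyper) for g in groups]
    en = [log_marginal_uniform(g, prior) for g in groups]
    log_marginals = {
        mid: sum(en[k] if state == "en" else bg[k] for k, state in enumerate(states))
        for mid, states in MODEL_STATES.items()
    }
    values = [log_marginals[mid] for mid in MODEL_IDS]
    winner = MODEL_IDS[int(np.argmax(values))]
    return ModelEvaluation(
        log_marginals=log_marginals,
        winner=winner,
        log_bayes_factor=log_marginals["M1"] - log_marginals["M0"],
    )


def is_nucleosome(evaluation: ModelEvaluation) -> bool:
    """True iff M1 beats every other model strictly (ties are not calls)."""
    l1 = evaluation.log_marginals["M1"]
    others = max(v for k, v in evaluation.log_marginals.items() if k != "M1")
    return l1 > others
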