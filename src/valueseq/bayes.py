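"""Normal-conjugate beliefs about the unknown mean per-pair INMB.

The unknown is the population mean per-pair incremental net monetary benefit
``W``.  Pair differences are modelled as i.i.d. normal with known sampling SD
``sigma``; the prior on ``W`` is normal with mean ``mu`` and effective prior
sample size ``n_eff`` pairs, so the prior (posterior) SD of ``W`` is
``sigma / sqrt(n_eff)``.  Conjugacy makes the posterior mean a precision
weighted average of the prior mean and the data, with ``n_eff`` growing by
one per observed pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .econ import PairSeries
from .errors import InvalidParameterError


@dataclass(frozen=True)
class Belief:
    """Normal prior/posterior over the mean per-pair INMB.

    ``mu`` is the mean, ``n_eff`` the effective number of observed pairs
    (real-valued: elicited priors need not correspond to integer counts) and
    ``sigma`` the known per-pair sampling SD.
    """

    mu: float
    n_eff: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise InvalidParameterError(f"mu must be finite, got {self.mu}")
        if not self.n_eff > 0:
            raise InvalidParameterError(f"n_eff must be > 0, got {self.n_eff}")
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")

    @property
    def posterior_sd(self) -> float:
        """Current SD of the unknown mean: sigma / sqrt(n_eff)."""
        return self.sigma / math.sqrt(self.n_eff)


def make_prior(mu0: float, n0: float, sigma: float) -> Belief:
    """Construct the prior belief from elicited mean, effective size and SD."""
    return Belief(mu=float(mu0), n_eff=float(n0), sigma=float(sigma))


def update(belief: Belief, diffs) -> Belief:
    """Posterior after observing pair differences ``diffs``.

    ``mu' = (n_eff * mu + sum(diffs)) / (n_eff + n)``, ``n_eff' = n_eff + n``,
    ``sigma`` unchanged.  Batch and sequential updating agree.
    """
    arr = diffs.diffs if isinstance(diffs, PairSeries) else np.asarray(diffs, dtype=float)
    if arr.size == 0:
        return belief
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("pair differences must be finite")
    n = arr.size
    mu_new = (belief.n_eff * belief.mu + float(arr.sum())) / (belief.n_eff + n)
    return replace(belief, mu=mu_new, n_eff=belief.n_eff + n)


def preposterior_sd(belief: Belief, m):
    """SD, viewed from now, of the posterior mean after ``m`` further pairs.

    Equals ``sigma * sqrt(m / (n_eff * (n_eff + m)))``, i.e. the square root
    of the variance reduction ``sigma^2/n_eff - sigma^2/(n_eff + m)``.
    Monotone increasing and concave in ``m``; tends to the current posterior
    SD as ``m -> inf``.  Vectorised over ``m``.
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0):
        raise InvalidParameterError("m must be >= 0")
    out = belief.sigma * np.sqrt(m_arr / (belief.n_eff * (belief.n_eff + m_arr)))
    return float(out) if out.ndim == 0 else out
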