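"""Closed-form value-of-information quantities for the adoption decision.

The decision compares adopting the new technology (population value
``P * W - C`` for unknown mean per-pair INMB ``W``) with keeping the
incumbent (value 0).  With a normal belief over ``W``, EVPI and EVSI have
closed forms in the unit normal loss function; ENBS nets off research costs,
and the optimal one-stage sample size maximises ENBS over the number of
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .bayes import Belief, preposterior_sd
from .econ import EconDesign
from .errors import InvalidParameterError


def unit_normal_loss(z):
    """Standard normal loss integral ``L(z) = phi(z) - z * (1 - Phi(z))``.

    ``L(z) = E[max(X - z, 0)]`` for standard normal ``X``; strictly positive
    and decreasing on ``z >= 0``.  Callers pass ``|z|``.  Vectorised.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise InvalidParameterError("unit_normal_loss requires z >= 0; pass |z|")
    out = norm.pdf(z_arr) - z_arr * norm.sf(z_arr)
    return float(out) if out.ndim == 0 else out


def evpi(belief: Belief, econ: EconDesign) -> float:
    """Expected value of perfect information about the adoption decision.

    With ``d = mu - C/P`` (distance of the belief mean from the adoption
    threshold) and ``s`` the current posterior SD of the mean,
    ``EVPI = P * s * L(|d|/s)``.
    """
    s = belief.posterior_sd
    d = belief.mu - econ.adoption_threshold
    if s == 0.0:
        return 0.0
    return econ.population_size * s * unit_normal_loss(abs(d) / s)


def evsi_fixed(belief: Belief, m, econ: EconDesign):
    """Expected value of sample information from ``m`` further pairs.

    Replaces the posterior SD in the EVPI formula with the preposterior SD
    of the posterior mean after ``m`` pairs: ``P * s_m * L(|d|/s_m)``.
    Zero at ``m = 0``; tends to EVPI as ``m -> inf``.  Vectorised over ``m``.
    """
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    s_m = np.atleast_1d(np.asarray(preposterior_sd(belief, m_arr), dtype=float))
    d = abs(belief.mu - econ.adoption_threshold)
    out = np.zeros_like(s_m)
    pos = s_m > 0
    out[pos] = econ.population_size * s_m[pos] * unit_normal_loss(d / s_m[pos])
    return float(out[0]) if np.ndim(m) == 0 else out


def enbs(belief: Belief, m, econ: EconDesign):
    """Expected net benefit of sampling ``m`` pairs.

    EVSI minus research costs: the per-pair sampling cost ``c * m`` plus the
    fixed trial cost, the latter charged only when a trial is actually run
    (``m > 0``).  Vectorised over ``m``.
    """
    m_arr = np.asarray(m, dtype=float)
    out = (
        np.asarray(evsi_fixed(belief, m_arr, econ), dtype=float)
        - econ.sampling_cost_per_pair * m_arr
        - econ.fixed_trial_cost * (m_arr > 0)
    )
    return float(out) if np.ndim(m) == 0 else out


@dataclass(frozen=True)
class VoiCurve:
    """ENBS profile over candidate one-stage sample sizes (in pairs)."""

    m_grid: np.ndarray
    evsi: np.ndarray
    enbs: np.ndarray
    m_star: int
    enbs_star: float
    evpi: float


def optimal_fixed_n(belief: Belief, econ: EconDesign, m_max: int) -> VoiCurve:
    """Exhaustive integer scan of ENBS over ``m in [0, m_max]``.

    ``m_star`` is the argmax, ties broken toward smaller ``m``; if no
    positive ENBS exists the optimum is ``m_star = 0`` ("run no trial").
    The scan is exhaustive on purpose: ENBS need not be unimodal once the
    fixed cost enters at ``m = 1``.
    """
    if m_max < 1:
        raise InvalidParameterError(f"m_max must be >= 1, got {m_max}")
    m_grid = np.arange(0, int(m_max) + 1)
    evsi_vals = evsi_fixed(belief, m_grid, econ)
    enbs_vals = enbs(belief, m_grid, econ)
    m_star = int(np.argmax(enbs_vals))  # first max -> smallest m on ties
    enbs_star = float(enbs_vals[m_star])
    if enbs_star <= 0.0:
        m_star, enbs_star = 0, float(enbs_vals[0])
    return VoiCurve(
        m_grid=m_grid,
        evsi=np.asarray(evsi_vals, dtype=float),
        enbs=np.asarray(enbs_vals, dtype=float),
        m_star=m_star,
        enbs_star=enbs_star,
        evpi=evpi(belief, econ),
    )
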