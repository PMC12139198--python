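"""Apply a solved boundary to accruing data; simulate and bootstrap trials.

The engine mirrors how a running trial would use the design: at scheduled
interim analyses the posterior mean of the per-pair INMB is compared with
the stopping boundary; the first exit halts recruitment, the pipeline pairs
are followed up (Stage III), and the adoption decision is read off the final
posterior mean.  Whole-trial paths are generated either from a parametric
truth (``simulate_paths``) or by resampling an observed pair series with
replacement (``bootstrap_paths``), and summarised into the operating
characteristics used to compare designs: expected sample size, expected
trial cost, probability the new technology is found cost-effective, and
expected net benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import Belief
from .boundary import Boundary
from .econ import EconDesign, PairSeries, pair_differences
from .errors import InsufficientDataError, InvalidParameterError, ValueSeqError

DECISION_CONTINUE = "continue"
DECISION_STOP_RECRUITMENT = "stop_recruitment"
DECISION_STAGE_III_COMPLETE = "stage_III_complete"


@dataclass(frozen=True)
class TrialPath:
    """One realised (or resampled) trial trajectory."""

    interim_states: tuple  # (n_observed, posterior_mu) at evaluated interims
    n_stop_observed: int
    total_pairs_recruited: int
    final_mu: float
    adopted: str
    trial_cost: float
    skipped_interims: tuple = ()

    @property
    def stage_II_pairs(self) -> int:
        """Pairs whose sampling cost the sequential design controls."""
        return self.n_stop_observed


def _interim_schedule(econ: EconDesign, n_last: int):
    """Scheduled interims (observed-pair counts) and data-sparsity skips."""
    k = econ.interim_every_k
    scheduled = list(range(k, n_last, k))
    skipped = tuple(
        (n, "data sparsity") for n in scheduled if n < econ.min_pairs_first_interim
    )
    interims = [n for n in scheduled if n >= econ.min_pairs_first_interim]
    if not interims or interims[-1] != n_last:
        interims.append(n_last)
    return interims, skipped


def _posterior_mu(prior: Belief, cumsum: np.ndarray, n: int) -> float:
    if n == 0:
        return prior.mu
    return (prior.n_eff * prior.mu + cumsum[n - 1]) / (prior.n_eff + n)


def monitor(boundary: Boundary, series: PairSeries, prior: Belief, econ: EconDesign):
    """Evaluate the stopping rule on an observed pair series.

    Returns ``(decision, path)``.  ``decision`` is ``continue`` while the
    data so far stay inside the continuation region with recruitment open,
    ``stop_recruitment`` once the boundary has been crossed (or the
    continuation region is empty) but pipeline outcomes are still pending,
    and ``stage_III_complete`` when all recruited pairs have been observed.
    Interims run at multiples of ``interim_every_k`` from
    ``min_pairs_first_interim``; earlier scheduled looks are recorded as
    skipped for data sparsity.  Total recruitment is ``n_stop + delay``
    capped at ``max_pairs``.
    """
    diffs = series.diffs if isinstance(series, PairSeries) else np.asarray(series, float)
    b = boundary.econ
    solver_fields = (
        "max_pairs", "delay_pairs", "sampling_cost_per_pair",
        "switching_cost", "population_size",
    )
    mismatched = [f for f in solver_fields if getattr(b, f) != getattr(econ, f)]
    if mismatched or boundary.prior != prior:
        raise ValueSeqError(
            "boundary was solved under a different prior/design than the one "
            f"being monitored (mismatched: {mismatched or ['prior']})"
        )
    T = econ.max_pairs
    if diffs.size > T:
        raise ValueSeqError(
            f"series has {diffs.size} pairs but the design's maximum is {T}"
        )
    N = T - econ.delay_pairs
    interims, skipped = _interim_schedule(econ, N)
    cumsum = np.cumsum(diffs)

    states = []
    n_stop = None
    for n in interims:
        if n > diffs.size:
            break
        mu = _posterior_mu(prior, cumsum, n)
        states.append((n, mu))
        lo, hi = boundary.lower[n], boundary.upper[n]
        crossed = (
            (lo is None and hi is None)
            or (hi is not None and mu >= hi)
            or (lo is not None and mu <= lo)
        )
        if crossed or n == N:
            n_stop = n
            break

    if n_stop is None:
        path = TrialPath(
            interim_states=tuple(states),
            n_stop_observed=-1,
            total_pairs_recruited=-1,
            final_mu=math.nan,
            adopted="",
            trial_cost=math.nan,
            skipped_interims=skipped,
        )
        return DECISION_CONTINUE, path

    total = min(n_stop + econ.delay_pairs, T)
    if diffs.size < total:
        path = TrialPath(
            interim_states=tuple(states),
            n_stop_observed=n_stop,
            total_pairs_recruited=total,
            final_mu=math.nan,
            adopted="",
            trial_cost=econ.sampling_cost_per_pair * total + econ.fixed_trial_cost,
            skipped_interims=skipped,
        )
        return DECISION_STOP_RECRUITMENT, path

    final_mu = _posterior_mu(prior, cumsum, total)
    adopted = "A" if final_mu > econ.adoption_threshold else "B"
    path = TrialPath(
        interim_states=tuple(states),
        n_stop_observed=n_stop,
        total_pairs_recruited=total,
        final_mu=final_mu,
        adopted=adopted,
        trial_cost=econ.sampling_cost_per_pair * total + econ.fixed_trial_cost,
        skipped_interims=skipped,
    )
    return DECISION_STAGE_III_COMPLETE, path


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    # per-replicate stream keyed on (seed, rep): independent of execution order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))


def simulate_paths(
    true_mean,
    sigma: float,
    prior: Belief,
    boundary: Boundary,
    econ: EconDesign,
    n_reps: int,
    seed: int,
) -> list[TrialPath]:
    """Simulate whole trials with i.i.d. normal pair differences.

    ``true_mean`` is the ground-truth mean per-pair INMB; pass ``None`` to
    draw it per replicate from the prior (the prior-predictive rollout used
    to cross-check the dynamic-programming value).  Fully reproducible from
    ``seed``; replicate ``i`` uses an RNG stream derived from ``(seed, i)``.
    """
    if n_reps < 1:
        raise InvalidParameterError(f"n_reps must be >= 1, got {n_reps}")
    paths = []
    for rep in range(n_reps):
        rng = _rep_rng(seed, rep)
        w = true_mean
        if w is None:
            w = rng.normal(prior.mu, prior.posterior_sd)
        diffs = rng.normal(w, sigma, econ.max_pairs)
        decision, path = monitor(boundary, PairSeries(diffs), prior, econ)
        assert decision == DECISION_STAGE_III_COMPLETE
        paths.append(path)
    return paths


def bootstrap_paths(
    records,
    prior: Belief,
    boundary: Boundary,
    econ: EconDesign,
    n_reps: int = 5000,
    seed: int = 0,
) -> list[TrialPath]:
    """Bootstrap whole trials by resampling observed pairs with replacement.

    Each replicate draws ``max_pairs`` pair differences with replacement from
    the empirical pair series (pairs, not individual patients, are the
    resampling unit) and runs the monitoring rule to completion.
    """
    series = pair_differences(records, econ.wtp)
    emp = series.diffs
    if emp.size < 2:
        raise InsufficientDataError(
            f"bootstrap requires >= 2 observed pairs, got {emp.size}"
        )
    paths = []
    for rep in range(n_reps):
        rng = _rep_rng(seed, rep)
        diffs = rng.choice(emp, size=econ.max_pairs, replace=True)
        decision, path = monitor(boundary, PairSeries(diffs), prior, econ)
        assert decision == DECISION_STAGE_III_COMPLETE
        paths.append(path)
    return paths


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregated design performance over simulated/bootstrapped paths."""

    expected_pairs: float
    expected_cost: float
    prob_cost_effective: float
    expected_net_benefit: float
    expected_net_benefit_signed: float
    n_reps: int
    mc_se: dict = field(compare=False)

    def to_dict(self) -> dict:
        return {
            "expected_pairs": self.expected_pairs,
            "expected_cost": self.expected_cost,
            "prob_cost_effective": self.prob_cost_effective,
            "expected_net_benefit": self.expected_net_benefit,
            "expected_net_benefit_signed": self.expected_net_benefit_signed,
            "n_reps": self.n_reps,
            "mc_se": dict(self.mc_se),
        }


def _se(x: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def operating_characteristics(paths, econ: EconDesign) -> OperatingCharacteristics:
    """Summarise paths into the design's operating characteristics.

    Expected net benefit values the decision actually taken on each path:
    ``P * max(final_mu - C/P, 0) - trial_cost`` (a trial that correctly
    rejects a non-cost-effective technology contributes zero population
    benefit minus its costs).  The signed variant ``P * final_mu -
    trial_cost`` is also reported for audit.
    """
    if not paths:
        raise InsufficientDataError("no paths to summarise")
    total = np.array([p.total_pairs_recruited for p in paths], dtype=float)
    cost = np.array([p.trial_cost for p in paths], dtype=float)
    final_mu = np.array([p.final_mu for p in paths], dtype=float)
    thr = econ.adoption_threshold
    P = econ.population_size
    ce = (final_mu > thr).astype(float)
    nb = P * np.maximum(final_mu - thr, 0.0) - cost
    nb_signed = P * final_mu - cost
    return OperatingCharacteristics(
        expected_pairs=float(total.mean()),
        expected_cost=float(cost.mean()),
        prob_cost_effective=float(ce.mean()),
        expected_net_benefit=float(nb.mean()),
        expected_net_benefit_signed=float(nb_signed.mean()),
        n_reps=len(paths),
        mc_se={
            "expected_pairs": _se(total),
            "expected_cost": _se(cost),
            "prob_cost_effective": _se(ce),
            "expected_net_benefit": _se(nb),
            "expected_net_benefit_signed": _se(nb_signed),
        },
    )


def frequentist_oc(
    true_mean_grid,
    sigma: float,
    prior: Belief,
    boundary: Boundary,
    econ: EconDesign,
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Frequentist operating characteristics over a grid of true means.

    For each true mean: probability of adopting A (power / type-I analogue
    at the adoption threshold), expected recruited pairs, and bias of the
    final posterior mean.  Each grid point reuses the same replicate RNG
    streams (common random numbers across grid points).
    """
    grid = np.atleast_1d(np.asarray(true_mean_grid, dtype=float))
    if grid.size == 0:
        raise InvalidParameterError("true_mean_grid must be nonempty")
    rows = []
    for w in grid:
        paths = simulate_paths(float(w), sigma, prior, boundary, econ, n_reps, seed)
        adopt = np.array([p.adopted == "A" for p in paths], dtype=float)
        total = np.array([p.total_pairs_recruited for p in paths], dtype=float)
        final_mu = np.array([p.final_mu for p in paths], dtype=float)
        rows.append(
            {
                "true_mean": float(w),
                "prob_adopt_A": float(adopt.mean()),
                "prob_adopt_A_se": _se(adopt),
                "expected_pairs": float(total.mean()),
                "expected_pairs_se": _se(total),
                "bias_final_mu": float(final_mu.mean() - w),
                "bias_final_mu_se": _se(final_mu),
            }
        )
    return pd.DataFrame(rows)
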