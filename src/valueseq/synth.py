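"""Synthetic two-arm cost/QALY datasets with controlled INMB structure.

Generates patient-level records whose per-pair INMB differences have a
configurable mean and variance, so every other module can be exercised
without any external dataset.  Each arm is modelled by marginal QALY and
cost distributions coupled through a Gaussian copula at a chosen
correlation; costs may be normal or (default in the packaged fixture)
gamma-distributed, matching the right skew of healthcare costs.

The per-pair difference then has

    mean = wtp * (qalyA_mean - qalyB_mean) - (costA_mean - costB_mean)
    var  = var_nmb(A) + var_nmb(B),
    var_nmb = wtp^2 * qaly_sd^2 + cost_sd^2 - 2 * wtp * corr * qaly_sd * cost_sd

which is the moment contract the tests check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .bayes import make_prior
from .econ import ARM_A, ARM_B, EconDesign, PatientRecord
from .errors import ConfigurationError

COST_NORMAL = "normal"
COST_GAMMA = "gamma"


@dataclass(frozen=True)
class ArmModel:
    """Marginal outcome model for one arm: QALY ~ normal, cost ~ normal/gamma."""

    qaly_mean: float
    qaly_sd: float
    cost_mean: float
    cost_sd: float
    cost_qaly_corr: float = 0.0
    cost_family: str = COST_NORMAL

    def __post_init__(self) -> None:
        if self.qaly_sd < 0 or self.cost_sd < 0:
            raise ConfigurationError("qaly_sd and cost_sd must be >= 0")
        if not -1.0 <= self.cost_qaly_corr <= 1.0:
            raise ConfigurationError("cost_qaly_corr must lie in [-1, 1]")
        if self.cost_family not in (COST_NORMAL, COST_GAMMA):
            raise ConfigurationError(
                f"cost_family must be '{COST_NORMAL}' or '{COST_GAMMA}'"
            )
        if self.cost_family == COST_GAMMA and not (self.cost_mean > 0 and self.cost_sd > 0):
            raise ConfigurationError("gamma costs require cost_mean > 0 and cost_sd > 0")

    def nmb_variance(self, wtp: float) -> float:
        """Per-patient NMB variance implied by the marginal moments."""
        return (
            wtp**2 * self.qaly_sd**2
            + self.cost_sd**2
            - 2.0 * wtp * self.cost_qaly_corr * self.qaly_sd * self.cost_sd
        )


def pair_diff_moments(arm_a: ArmModel, arm_b: ArmModel, wtp: float) -> tuple[float, float]:
    """(mean, variance) of the per-pair INMB difference implied by the arms."""
    mean = wtp * (arm_a.qaly_mean - arm_b.qaly_mean) - (arm_a.cost_mean - arm_b.cost_mean)
    return mean, arm_a.nmb_variance(wtp) + arm_b.nmb_variance(wtp)


def _draw_arm(model: ArmModel, n: int, rng: np.random.Generator):
    z = rng.standard_normal((n, 2))
    r = model.cost_qaly_corr
    z_cost = r * z[:, 0] + math.sqrt(max(0.0, 1.0 - r * r)) * z[:, 1]
    qaly = model.qaly_mean + model.qaly_sd * z[:, 0]
    if model.cost_sd == 0:
        cost = np.full(n, model.cost_mean)
    elif model.cost_family == COST_NORMAL:
        cost = model.cost_mean + model.cost_sd * z_cost
    else:
        shape = (model.cost_mean / model.cost_sd) ** 2
        scale = model.cost_sd**2 / model.cost_mean
        u = norm.cdf(z_cost)
        # keep u strictly inside (0, 1) for the inverse-cdf transform
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        cost = gamma_dist.ppf(u, a=shape, scale=scale)
    return qaly, cost


def generate_trial_data(
    arm_A: ArmModel, arm_B: ArmModel, n_pairs: int, seed: int
) -> list[PatientRecord]:
    """Generate ``2 * n_pairs`` records, alternating A/B in recruitment order.

    Members of pair ``i`` share the identifier ``f"{i:05d}"`` so both
    by-order and by-id pairing recover the same series.  Deterministic in
    ``seed``.
    """
    if n_pairs < 1:
        raise ConfigurationError(f"n_pairs must be >= 1, got {n_pairs}")
    rng = np.random.default_rng(seed)
    qa, ca = _draw_arm(arm_A, n_pairs, rng)
    qb, cb = _draw_arm(arm_B, n_pairs, rng)
    records = []
    for i in range(n_pairs):
        pid = f"{i:05d}"
        records.append(PatientRecord(id=pid, arm=ARM_A, qaly=qa[i], cost=ca[i]))
        records.append(PatientRecord(id=pid, arm=ARM_B, qaly=qb[i], cost=cb[i]))
    return records


# ---------------------------------------------------------------------------
# Packaged fixture: a hand-osteoarthritis-scale synthetic trial.
#
# Design parameters printed in the source analyses (WTP 30k/QALY, maximum
# sample 124 pairs, outcome delay 74 pairs, interims every 10 pairs with the
# first skipped for sparsity, prior effective size n0 = 2) are used as-is.
# The remaining economics are synthetic but scale-plausible: population
# ~11,000, pair cost 1,500 and fixed cost 650,000 place the one-stage ENBS
# optimum near ~177 pairs at an indifferent prior, matching the scale of the
# published one-stage design.  No claim of reproducing real trial results.
# ---------------------------------------------------------------------------

HERO_LIKE_SEED = 124_001

HERO_LIKE_ARM_A = ArmModel(
    qaly_mean=0.61, qaly_sd=0.35, cost_mean=1300.0, cost_sd=900.0,
    cost_qaly_corr=-0.3, cost_family=COST_GAMMA,
)
HERO_LIKE_ARM_B = ArmModel(
    qaly_mean=0.60, qaly_sd=0.35, cost_mean=1200.0, cost_sd=850.0,
    cost_qaly_corr=-0.3, cost_family=COST_GAMMA,
)


def hero_like_econ() -> EconDesign:
    return EconDesign(
        wtp=30_000.0,
        population_size=11_000.0,
        sampling_cost_per_pair=1_500.0,
        delay_pairs=74,
        max_pairs=124,
        switching_cost=0.0,
        fixed_trial_cost=650_000.0,
        interim_every_k=10,
        min_pairs_first_interim=20,
    )


def hero_like_fixture():
    """Seed-fixed synthetic dataset + configuration at HERO scale.

    Returns ``(records, config)`` where ``config`` is a dict with keys
    ``econ`` (:class:`EconDesign`) and ``prior`` (:class:`Belief`): a weak
    cost-effectiveness signal (true mean difference 200 against a per-pair
    SD of about 15,000), an indifferent prior at zero with effective size 2,
    and the printed design cadence.  Synthetic stand-in: it mirrors design
    parameters, not results.
    """
    econ = hero_like_econ()
    records = generate_trial_data(
        HERO_LIKE_ARM_A, HERO_LIKE_ARM_B, n_pairs=econ.max_pairs, seed=HERO_LIKE_SEED
    )
    prior = make_prior(mu0=0.0, n0=2.0, sigma=15_000.0)
    return records, {"econ": econ, "prior": prior}
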