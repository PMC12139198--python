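"""Net-monetary-benefit accounting from patient-level two-arm trial data.

A two-arm trial compares a new technology (arm ``A``) against the incumbent
(arm ``B``).  Each participant contributes a health outcome in QALYs and a
health-and-social-care cost.  Valuing one QALY at the decision maker's
willingness to pay (WTP) converts both into a single monetary scale, the net
monetary benefit ``NMB = WTP * QALY - cost``.  The quantity the design works
with is the incremental NMB (INMB) of A over B, per patient and, scaled by
the size ``P`` of the population affected by the adoption decision and net of
any switching cost ``C``, for the population.

All downstream machinery observes the trial one *pairwise allocation* at a
time: one patient per arm, summarised by the difference of their NMBs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError

ARM_A = "A"
ARM_B = "B"
_ARMS = (ARM_A, ARM_B)


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class PatientRecord:
    """One trial participant: arm assignment, QALY outcome and cost."""

    id: str
    arm: str
    qaly: float
    cost: float

    def __post_init__(self) -> None:
        arm = str(self.arm).strip().upper()
        if arm not in _ARMS:
            raise InvalidParameterError(
                f"arm must be one of {_ARMS}, got {self.arm!r}"
            )
        object.__setattr__(self, "arm", arm)
        object.__setattr__(self, "qaly", _require_finite("qaly", self.qaly))
        object.__setattr__(self, "cost", _require_finite("cost", self.cost))


@dataclass(frozen=True)
class EconDesign:
    """Economic and trial-design parameters.

    Parameters
    ----------
    wtp
        Willingness to pay per QALY (currency/QALY, > 0).
    population_size
        ``P``, number of patients affected by the adoption decision (> 0).
    sampling_cost_per_pair
        ``c``, marginal cost of randomising one pair into the trial (> 0).
    delay_pairs
        ``delta``, pairs recruited during one outcome follow-up period; their
        outcomes are observed only after recruitment to them has happened
        ("pipeline" pairs).
    max_pairs
        ``T``, maximum number of pairs the trial may recruit (> delay_pairs).
    switching_cost
        ``C``, one-off cost of adopting A in place of B (>= 0).
    fixed_trial_cost
        Cost incurred by running any trial at all, independent of its size.
    interim_every_k
        Cadence of interim analyses, in observed pairs.
    min_pairs_first_interim
        Earliest interim; interims scheduled before this are skipped for
        data sparsity.  Default 20 skips the 10-pair look under the default
        cadence.
    """

    wtp: float
    population_size: float
    sampling_cost_per_pair: float
    delay_pairs: int
    max_pairs: int
    switching_cost: float = 0.0
    fixed_trial_cost: float = 0.0
    interim_every_k: int = 10
    min_pairs_first_interim: int = 20

    def __post_init__(self) -> None:
        if not self.wtp > 0:
            raise InvalidParameterError(f"wtp must be > 0, got {self.wtp}")
        if not self.population_size > 0:
            raise InvalidParameterError(
                f"population_size must be > 0, got {self.population_size}"
            )
        if not self.sampling_cost_per_pair > 0:
            raise InvalidParameterError(
                f"sampling_cost_per_pair must be > 0, got {self.sampling_cost_per_pair}"
            )
        if self.switching_cost < 0:
            raise InvalidParameterError(
                f"switching_cost must be >= 0, got {self.switching_cost}"
            )
        if self.fixed_trial_cost < 0:
            raise InvalidParameterError(
                f"fixed_trial_cost must be >= 0, got {self.fixed_trial_cost}"
            )
        if self.delay_pairs < 0:
            raise InvalidParameterError(
                f"delay_pairs must be >= 0, got {self.delay_pairs}"
            )
        if not self.max_pairs > self.delay_pairs:
            raise InvalidParameterError(
                "max_pairs must exceed delay_pairs: otherwise there is no "
                "opportunity to stop the trial before it reaches its maximum "
                f"planned sample size (got T={self.max_pairs}, delay={self.delay_pairs})"
            )
        if self.interim_every_k < 1:
            raise InvalidParameterError(
                f"interim_every_k must be >= 1, got {self.interim_every_k}"
            )
        if self.min_pairs_first_interim < 1:
            raise InvalidParameterError(
                f"min_pairs_first_interim must be >= 1, got {self.min_pairs_first_interim}"
            )

    @property
    def adoption_threshold(self) -> float:
        """Per-pair mean INMB above which adopting A beats keeping B: C / P."""
        return self.switching_cost / self.population_size


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm sample summary: size, mean QALY, mean cost and expected NMB."""

    n: int
    mean_qaly: float
    mean_cost: float
    enmb: float


@dataclass(frozen=True)
class PairSeries:
    """Ordered per-pair INMB differences (A-member NMB minus B-member NMB)."""

    diffs: np.ndarray
    pairing_rule: str = "by_order"
    n_unpaired: int = 0

    def __post_init__(self) -> None:
        diffs = np.asarray(self.diffs, dtype=float)
        if diffs.ndim != 1:
            raise InvalidParameterError("diffs must be one-dimensional")
        if diffs.size and not np.all(np.isfinite(diffs)):
            raise InvalidParameterError("diffs must be finite")
        object.__setattr__(self, "diffs", diffs)

    def __len__(self) -> int:
        return int(self.diffs.size)


def nmb(qaly: float, cost: float, wtp: float):
    """Net monetary benefit ``wtp * qaly - cost`` (vectorised)."""
    qaly = np.asarray(qaly, dtype=float)
    cost = np.asarray(cost, dtype=float)
    if not np.all(np.isfinite(qaly)) or not np.all(np.isfinite(cost)):
        raise InvalidParameterError("qaly and cost must be finite")
    if not wtp > 0:
        raise InvalidParameterError(f"wtp must be > 0, got {wtp}")
    out = wtp * qaly - cost
    return float(out) if out.ndim == 0 else out


def _split_arms(records) -> dict[str, list[PatientRecord]]:
    arms: dict[str, list[PatientRecord]] = {ARM_A: [], ARM_B: []}
    for rec in records:
        arms[rec.arm].append(rec)
    return arms


def einmb_per_patient(records, wtp: float):
    """Estimate the per-patient expected INMB of A over B.

    Returns ``(einmb, summaries)`` where ``summaries`` maps each arm label to
    its :class:`ArmSummary`.  The estimator is the difference of arm-level
    expected NMBs computed from sample means.
    """
    arms = _split_arms(records)
    summaries = {}
    for label in _ARMS:
        grp = arms[label]
        if not grp:
            raise InsufficientDataError(f"arm {label} has no records")
        mq = float(np.mean([r.qaly for r in grp]))
        mc = float(np.mean([r.cost for r in grp]))
        summaries[label] = ArmSummary(
            n=len(grp), mean_qaly=mq, mean_cost=mc, enmb=nmb(mq, mc, wtp)
        )
    einmb = summaries[ARM_A].enmb - summaries[ARM_B].enmb
    return einmb, summaries


def population_einmb(einmb_per_patient: float, population_size: float, switching_cost: float) -> float:
    """Population expected INMB: ``P * einmb - C``."""
    if not population_size > 0:
        raise InvalidParameterError(
            f"population_size must be > 0, got {population_size}"
        )
    if switching_cost < 0:
        raise InvalidParameterError(
            f"switching_cost must be >= 0, got {switching_cost}"
        )
    return population_size * einmb_per_patient - switching_cost


def pair_differences(records, wtp: float, pairing_rule: str = "by_order") -> PairSeries:
    """Form the per-pair INMB difference series used by the sequential model.

    ``by_order`` pairs the i-th A patient with the i-th B patient in arrival
    order; unequal arm counts are truncated to complete pairs with a warning
    and the dropped count recorded in ``n_unpaired``.  ``by_id`` pairs records
    sharing the same identifier across arms; records without a cross-arm
    partner are counted as unpaired.
    """
    arms = _split_arms(records)
    if pairing_rule == "by_order":
        a, b = arms[ARM_A], arms[ARM_B]
        n = min(len(a), len(b))
        n_unpaired = abs(len(a) - len(b))
        if n_unpaired:
            warnings.warn(
                f"unequal arm counts ({len(a)} A vs {len(b)} B): truncated to "
                f"{n} complete pairs, {n_unpaired} record(s) unpaired",
                stacklevel=2,
            )
        diffs = [
            nmb(a[i].qaly, a[i].cost, wtp) - nmb(b[i].qaly, b[i].cost, wtp)
            for i in range(n)
        ]
    elif pairing_rule == "by_id":
        by_id_a: dict[str, PatientRecord] = {}
        by_id_b: dict[str, PatientRecord] = {}
        order: list[str] = []
        for rec in records:
            tgt = by_id_a if rec.arm == ARM_A else by_id_b
            if rec.id in tgt:
                raise InvalidParameterError(
                    f"duplicate id {rec.id!r} within arm {rec.arm}"
                )
            tgt[rec.id] = rec
            if rec.id not in order:
                order.append(rec.id)
        diffs = []
        n_unpaired = 0
        for pid in order:
            if pid in by_id_a and pid in by_id_b:
                ra, rb = by_id_a[pid], by_id_b[pid]
                diffs.append(nmb(ra.qaly, ra.cost, wtp) - nmb(rb.qaly, rb.cost, wtp))
            else:
                n_unpaired += 1
        if n_unpaired:
            warnings.warn(
                f"{n_unpaired} id(s) present in only one arm were left unpaired",
                stacklevel=2,
            )
    else:
        raise InvalidParameterError(
            f"pairing_rule must be 'by_order' or 'by_id', got {pairing_rule!r}"
        )
    return PairSeries(np.asarray(diffs, dtype=float), pairing_rule, n_unpaired)


def sampling_sd(series: PairSeries) -> float:
    """Sample SD (n-1 denominator) of the per-pair INMB differences.

    This is the plug-in estimate of the per-pair sampling SD ``sigma`` that
    the Bayesian model treats as known.
    """
    diffs = series.diffs if isinstance(series, PairSeries) else np.asarray(series, float)
    if diffs.size < 2:
        raise InsufficientDataError(
            f"need at least 2 pair differences to estimate a sampling SD, got {diffs.size}"
        )
    return float(np.std(diffs, ddof=1))
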