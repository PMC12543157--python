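"""Synthetic hospital-claims generator with planted morbidity/death structure.

Emulates the shape of Brazilian SIH/SUS-like claims data for an obstetric
population: one episode of care per simulated patient, rare in-hospital
death (default 3 per 10,000 episodes), roughly 1% of episodes split into
two or more chained claims by stay/transfer continuations, and diagnoses
drawn per morbidity item with configurable prevalences, pairwise
co-occurrence tilts, and planted multiplicative death relative risks.

The death model is deliberately multiplicative: an episode carrying items
``S`` dies with probability ``min(1, p0 * prod(rr[i] for i in S))``.  For a
rare single item with relative risk ``r`` (so the marginal death rate is
barely inflated), the lift of the mined single-antecedent rule estimates
``r / (1 + p*(r-1))``, giving a closed-form recovery target.

Every claim carries a childbirth principal diagnosis (the canonical group-10
code) and an obstetric procedure code, so every synthetic episode belongs to
the obstetric cohort; morbidity items are written as canonical ICD-10 codes
that the active mapping resolves back to the intended item label.  Claims
are emitted in shuffled order to force the linkage stage to sort.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import GroupMapping, default_mapping
from .episodes import ClaimRecord, DischargeReason
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

#: Obstetric principal-procedure code stamped on every synthetic claim
#: (SUS-style code for assistance to normal delivery).
SYNTHETIC_OBSTETRIC_PROCEDURE = "0310010039"

#: Canonical childbirth (group 10) principal diagnosis.
CHILDBIRTH_CODE = "O80"

_STUDY_START = date(2014, 1, 1)
_STUDY_DAYS = 2191  # 2014-01-01 .. 2019-12-31

#: Default morbidity-item prevalences per episode (plausible magnitudes for
#: an obstetric admission population; see docs/methods.md).
DEFAULT_PREVALENCES: dict[str, float] = {
    "2a": 0.04,
    "3": 0.02,
    "4a": 0.01,
    "5": 0.06,
    "8a": 0.004,
    "8e": 0.01,
    "11": 0.05,
    "13": 0.03,
}


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ConfigurationError(f"{name} must be a probability in [0,1], got {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a synthetic claims run.

    Parameters
    ----------
    n_patients:
        Number of simulated patients; one episode of care each.
    baseline_death_prob:
        Per-episode death probability for an episode with no risk-modifying
        items (default 3e-4, the order of magnitude of in-hospital death in
        obstetric admissions).
    group_prevalences:
        Item label -> per-episode probability of carrying that morbidity item.
    death_relative_risks:
        Item label -> multiplicative death risk factor (>= 0); items absent
        from the map have risk 1.
    cooccurrence_pairs:
        ``(a, b, m)`` triples: where item ``a`` is present, the odds of item
        ``b`` are multiplied by ``m`` (applied in list order).
    transfer_prob:
        Probability that an episode continues into at least one further
        claim; applied per claim, so claim counts are geometric (default
        0.011, i.e. ~98.9% single-claim episodes).
    gap_days_distribution:
        Distribution over the admissible re-admission gaps {0, 1} days.
    seed:
        Seed for all randomness; identical seed + config give identical
        output across processes.
    """

    n_patients: int
    baseline_death_prob: float = 3e-4
    group_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    death_relative_risks: Mapping[str, float] = field(default_factory=dict)
    cooccurrence_pairs: Sequence[tuple[str, str, float]] = ()
    transfer_prob: float = 0.011
    gap_days_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.5, 1: 0.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_patients) <= 0:
            raise ConfigurationError("n_patients must be a positive integer")
        _check_prob("baseline_death_prob", self.baseline_death_prob)
        _check_prob("transfer_prob", self.transfer_prob)
        for label, p in self.group_prevalences.items():
            _check_prob(f"group_prevalences[{label}]", p)
        for label, r in self.death_relative_risks.items():
            if label not in self.group_prevalences:
                raise ConfigurationError(
                    f"death_relative_risks references unknown item {label!r}"
                )
            if r < 0 or not math.isfinite(r):
                raise ConfigurationError(
                    f"death_relative_risks[{label}] must be finite and >= 0"
                )
        for a, b, m in self.cooccurrence_pairs:
            for lab in (a, b):
                if lab not in self.group_prevalences:
                    raise ConfigurationError(
                        f"cooccurrence_pairs references unknown item {lab!r}"
                    )
            if m <= 0 or not math.isfinite(m):
                raise ConfigurationError("cooccurrence odds multiplier must be > 0")
        if not self.gap_days_distribution:
            raise ConfigurationError("gap_days_distribution must be non-empty")
        if not set(self.gap_days_distribution) <= {0, 1}:
            raise ConfigurationError("gap days must be 0 or 1")
        total = 0.0
        for g, p in self.gap_days_distribution.items():
            _check_prob(f"gap_days_distribution[{g}]", p)
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("gap_days_distribution must sum to 1")


@dataclass(frozen=True)
class DeathRegistryEntry:
    """A deidentified mortality-registry row used for death confirmation."""

    birth_date: date
    municipality: str
    death_date: date

    def __post_init__(self) -> None:
        if self.death_date < self.birth_date:
            raise ConfigurationError("death_date precedes date_of_birth")


def _birth_date_for_age(admission: date, age: int, offset_days: int) -> date:
    """A birth date giving exactly ``age`` completed years at ``admission``."""
    day = min(admission.day, 28)  # sidestep Feb-29 arithmetic
    anniversary = date(admission.year - age, admission.month, day)
    return anniversary - timedelta(days=offset_days)


def generate_claims(
    config: SimulationConfig, mapping: GroupMapping | None = None
) -> list[ClaimRecord]:
    """Generate one episode's worth of claims per simulated patient.

    Raises :class:`ConfigurationError` if a configured item label has no
    canonical code under ``mapping`` (default: the shipped mapping).
    """
    mapping = mapping or default_mapping()
    canon = mapping.canonical_codes()
    labels = sorted(config.group_prevalences)
    for label in labels:
        if label not in canon:
            raise ConfigurationError(
                f"item {label!r} has no canonical ICD code under the mapping"
            )

    n = int(config.n_patients)
    rng = np.random.default_rng(config.seed)
    # independent stream for small per-episode structural choices
    pyrng = random.Random(int(rng.integers(0, 2**63 - 1)))

    # --- item membership, with co-occurrence tilts ---------------------
    prev = np.array([config.group_prevalences[lab] for lab in labels])
    member = rng.random((n, len(labels))) < prev[None, :]
    col = {lab: j for j, lab in enumerate(labels)}
    for a, b, m in config.cooccurrence_pairs:
        pb = prev[col[b]]
        tilted = m * pb / (1.0 - pb + m * pb)
        rows = member[:, col[a]]
        member[rows, col[b]] = rng.random(int(rows.sum())) < tilted

    # --- death outcomes -------------------------------------------------
    log_rr = np.zeros(len(labels))
    zero_risk = np.zeros(len(labels), dtype=bool)
    for j, lab in enumerate(labels):
        r = config.death_relative_risks.get(lab, 1.0)
        if r == 0.0:
            zero_risk[j] = True
        else:
            log_rr[j] = math.log(r)
    death_p = config.baseline_death_prob * np.exp(member @ log_rr)
    death_p[np.any(member & zero_risk[None, :], axis=1)] = 0.0
    np.clip(death_p, 0.0, 1.0, out=death_p)
    died = rng.random(n) < death_p

    # --- episode frame ---------------------------------------------------
    admission_offset = rng.integers(0, _STUDY_DAYS, size=n)
    ages = rng.integers(15, 45, size=n)
    age_offsets = rng.integers(1, 300, size=n)
    los = rng.integers(1, 11, size=n)  # total length of stay, days
    # geometric number of claims: P(k)= (1-q) q^(k-1), q = transfer_prob
    n_claims = (
        rng.geometric(1.0 - config.transfer_prob, size=n)
        if config.transfer_prob > 0
        else np.ones(n, dtype=int)
    )
    muni_codes = [f"M{i:03d}" for i in range(20)]
    hosp_codes = [f"H{i:04d}" for i in range(60)]
    munis = rng.integers(0, len(muni_codes), size=n)
    hosps = rng.integers(0, len(hosp_codes), size=n)

    gaps, gap_probs = zip(*sorted(config.gap_days_distribution.items()))

    claims: list[ClaimRecord] = []
    for i in range(n):
        admission = _STUDY_START + timedelta(days=int(admission_offset[i]))
        birth = _birth_date_for_age(admission, int(ages[i]), int(age_offsets[i]))
        muni = muni_codes[munis[i]]
        k = int(n_claims[i])
        stay = max(int(los[i]), k)  # at least one day per claim
        item_codes = [canon[labels[j]] for j in np.flatnonzero(member[i])]
        # distribute morbidity codes across the episode's claims
        if k == 1:
            assign = {0: item_codes}
        else:
            assign = {c: [] for c in range(k)}
            for code in item_codes:
                assign[pyrng.randrange(k)].append(code)
        seg = stay // k
        hospital = hosp_codes[hosps[i]]
        claim_start = admission
        for c in range(k):
            claim_end = (
                admission + timedelta(days=stay)
                if c == k - 1
                else claim_start + timedelta(days=seg)
            )
            if claim_end < claim_start:
                claim_end = claim_start
            if c == k - 1:
                reason = (
                    DischargeReason.DEATH if died[i] else DischargeReason.ALIVE
                )
                next_hospital = hospital
            elif pyrng.random() < 0.5:
                reason = DischargeReason.STAY
                next_hospital = hospital
            else:
                reason = DischargeReason.TRANSFER
                shift = 1 + pyrng.randrange(len(hosp_codes) - 1)
                next_hospital = hosp_codes[
                    (hosp_codes.index(hospital) + shift) % len(hosp_codes)
                ]
            diagnoses = tuple([CHILDBIRTH_CODE] + assign[c][:11])
            claims.append(
                ClaimRecord(
                    claim_id=f"A{i:08d}-{c}",
                    hospital_code=hospital,
                    municipality=muni,
                    birth_date=birth,
                    admission_date=claim_start,
                    discharge_date=claim_end,
                    discharge_reason=reason,
                    diagnoses=diagnoses,
                    procedure_code=SYNTHETIC_OBSTETRIC_PROCEDURE,
                )
            )
            if c < k - 1:
                gap = pyrng.choices(gaps, weights=gap_probs)[0]
                claim_start = claim_end + timedelta(days=gap)
                hospital = next_hospital

    order = rng.permutation(len(claims))
    shuffled = [claims[j] for j in order]
    logger.info(
        "generated %d claims for %d patients (%d deaths)",
        len(shuffled), n, int(died.sum()),
    )
    return shuffled


def generate_death_registry(
    claims: Sequence[ClaimRecord], coverage: float, seed: int
) -> list[DeathRegistryEntry]:
    """Registry entries for death-discharged episodes, with partial coverage.

    Each claim whose discharge reason is in-hospital death (the final claim
    of a death episode) yields, with probability ``coverage``, an entry
    carrying the episode's birth date and municipality and a death date
    inside that final claim's stay.
    """
    _check_prob("coverage", coverage)
    rng = np.random.default_rng(seed)
    entries: list[DeathRegistryEntry] = []
    for claim in claims:
        if claim.discharge_reason is not DischargeReason.DEATH:
            continue
        if rng.random() >= coverage:
            continue
        span = (claim.discharge_date - claim.admission_date).days
        death_date = claim.admission_date + timedelta(days=int(rng.integers(0, span + 1)))
        entries.append(
            DeathRegistryEntry(
                birth_date=claim.birth_date,
                municipality=claim.municipality,
                death_date=death_date,
            )
        )
    return entries


def write_registry_csv(entries: Sequence[DeathRegistryEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "birth_date": e.birth_date.isoformat(),
                "municipality": e.municipality,
                "death_date": e.death_date.isoformat(),
            }
            for e in entries
        ],
        columns=["birth_date", "municipality", "death_date"],
    ).to_csv(path, index=False)


def read_registry_csv(path) -> list[DeathRegistryEntry]:
    df = pd.read_csv(path, dtype=str)
    return [
        DeathRegistryEntry(
            birth_date=date.fromisoformat(row.birth_date),
            municipality=row.municipality,
            death_date=date.fromisoformat(row.death_date),
        )
        for row in df.itertuples(index=False)
    ]
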