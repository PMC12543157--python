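"""Claim records and deterministic linkage of claims into episodes of care.

A hospitalization billed through a claims system may span several claim
records: when a claim ends in a *stay* (the patient remains in the same
hospital under a new claim) or an *interhospital transfer*, the follow-on
claim is part of the same continuous hospitalization.  This module groups
claim rows into :class:`Episode` objects with a deterministic record-linkage
rule on deidentified variables: claims are blocked on (municipality of
residence, date of birth), sorted by admission date, and chained greedily
whenever the previous claim ended in stay/transfer and the next admission
falls within one day of the previous discharge.  A stay-continuation must be
in the same hospital; a transfer may change hospital.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import InputError

logger = logging.getLogger(__name__)

#: Maximum gap, in days, between a discharge and the chained re-admission.
MAX_CHAIN_GAP_DAYS = 1

#: Number of secondary-diagnosis columns in the claims CSV dialect.
N_SECONDARY_DIAGNOSES = 11

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")


class DischargeReason(str, Enum):
    """Reason-for-discharge classes of a single claim."""

    ALIVE = "alive"
    DEATH = "in_hospital_death"
    TRANSFER = "transfer"
    STAY = "stay"
    OTHER = "other"


class Outcome(str, Enum):
    """Outcome of a whole episode (the last claim's discharge class)."""

    ALIVE = "alive"
    DEATH = "in_hospital_death"
    OTHER = "other"


def normalize_icd10(code: str) -> str:
    """Normalize an ICD-10 code to dotless upper case; raise on bad shape.

    Accepts ``"o14.1"`` and returns ``"O141"``.  Valid shape: one letter,
    two digits, then up to two alphanumeric sub-code characters.
    """
    norm = str(code).strip().upper().replace(".", "")
    if not _ICD10_RE.match(norm):
        raise InputError(f"malformed ICD-10 code: {code!r}")
    return norm


@dataclass(frozen=True)
class ClaimRecord:
    """One hospital-claim row (one AIH-like record).

    ``diagnoses`` holds the principal diagnosis first, followed by up to
    eleven secondary diagnoses, all as normalized ICD-10 codes.
    """

    claim_id: str
    hospital_code: str
    municipality: str
    birth_date: date
    admission_date: date
    discharge_date: date
    discharge_reason: DischargeReason
    diagnoses: tuple[str, ...]
    procedure_code: str = ""

    def __post_init__(self) -> None:
        if self.discharge_date < self.admission_date:
            raise InputError(
                f"claim {self.claim_id}: discharge_date precedes admission_date"
            )
        if self.birth_date >= self.admission_date:
            raise InputError(
                f"claim {self.claim_id}: birth_date not before admission_date"
            )
        if not self.diagnoses:
            raise InputError(f"claim {self.claim_id}: no diagnoses")
        if len(self.diagnoses) > 1 + N_SECONDARY_DIAGNOSES:
            raise InputError(f"claim {self.claim_id}: more than 12 diagnoses")
        object.__setattr__(
            self, "diagnoses", tuple(normalize_icd10(c) for c in self.diagnoses)
        )


def completed_years(birth: date, on: date) -> int:
    """Age in completed years on a reference date."""
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


@dataclass(frozen=True)
class Episode:
    """A maximal chain of claims treated as one hospitalization."""

    claims: tuple[ClaimRecord, ...]

    def __post_init__(self) -> None:
        if not self.claims:
            raise InputError("episode with no claims")

    @property
    def admission_date(self) -> date:
        return self.claims[0].admission_date

    @property
    def discharge_date(self) -> date:
        return self.claims[-1].discharge_date

    @property
    def outcome(self) -> Outcome:
        reason = self.claims[-1].discharge_reason
        if reason is DischargeReason.ALIVE:
            return Outcome.ALIVE
        if reason is DischargeReason.DEATH:
            return Outcome.DEATH
        return Outcome.OTHER

    @property
    def age_years(self) -> int:
        """Completed years of age at episode admission."""
        return completed_years(self.claims[0].birth_date, self.admission_date)

    @property
    def birth_date(self) -> date:
        return self.claims[0].birth_date

    @property
    def municipality(self) -> str:
        return self.claims[0].municipality


def chainable(prev: ClaimRecord, nxt: ClaimRecord) -> bool:
    """Whether ``nxt`` continues the hospitalization ended by ``prev``.

    Both claims are assumed to share the blocking key (municipality and
    date of birth).  The chain holds iff ``prev`` ended in a stay or
    transfer, the re-admission gap is 0 or 1 days, and a stay-continuation
    stays in the same hospital.
    """
    if prev.discharge_reason not in (DischargeReason.STAY, DischargeReason.TRANSFER):
        return False
    gap = (nxt.admission_date - prev.discharge_date).days
    if gap < 0 or gap > MAX_CHAIN_GAP_DAYS:
        return False
    if prev.discharge_reason is DischargeReason.STAY:
        return nxt.hospital_code == prev.hospital_code
    return True


def _claim_sort_key(claim: ClaimRecord) -> tuple:
    return (claim.admission_date, claim.discharge_date, claim.claim_id)


def link_episodes(claims: Iterable[ClaimRecord]) -> list[Episode]:
    """Partition claims into episodes of care.

    Claims are blocked on (municipality, birth_date); within a block they
    are sorted by admission date (ties broken by discharge date, then
    claim id) and chained greedily left to right under :func:`chainable`.
    The result is a partition: every claim lands in exactly one episode,
    and the partition is invariant to the input order of the claims.

    Raises :class:`InputError` on duplicate claim ids.
    """
    claims = list(claims)
    seen: set[str] = set()
    for claim in claims:
        if claim.claim_id in seen:
            raise InputError(f"duplicate claim_id: {claim.claim_id}")
        seen.add(claim.claim_id)

    blocks: dict[tuple[str, date], list[ClaimRecord]] = {}
    for claim in claims:
        blocks.setdefault((claim.municipality, claim.birth_date), []).append(claim)

    episodes: list[Episode] = []
    n_overlaps = 0
    for key in sorted(blocks):
        block = sorted(blocks[key], key=_claim_sort_key)
        n_block_episodes = 1
        current = [block[0]]
        for claim in block[1:]:
            prev = current[-1]
            if chainable(prev, claim):
                current.append(claim)
            else:
                if (
                    prev.discharge_reason
                    in (DischargeReason.STAY, DischargeReason.TRANSFER)
                    and (claim.admission_date - prev.discharge_date).days < 0
                ):
                    n_overlaps += 1
                    logger.warning(
                        "overlapping stays not chained: %s -> %s",
                        prev.claim_id,
                        claim.claim_id,
                    )
                episodes.append(Episode(tuple(current)))
                n_block_episodes += 1
                current = [claim]
        episodes.append(Episode(tuple(current)))
        logger.debug(
            "block %s: %d claims -> %d episodes", key, len(block), n_block_episodes
        )
    logger.info(
        "linked %d claims into %d episodes (%d blocks, %d overlap warnings)",
        len(claims),
        len(episodes),
        len(blocks),
        n_overlaps,
    )
    return episodes


# ---------------------------------------------------------------------------
# Claims CSV dialect
# ---------------------------------------------------------------------------

#: Column order of the claims CSV written and read by this package.
CLAIMS_CSV_COLUMNS = (
    ["claim_id", "hospital_code", "municipality", "birth_date", "admission_date",
     "discharge_date", "discharge_reason", "diag_principal"]
    + [f"diag_sec_{i}" for i in range(1, N_SECONDARY_DIAGNOSES + 1)]
    + ["procedure_code"]
)

#: How the columns of a raw Brazilian SIH/SUS (AIH) extract map onto the
#: claims CSV dialect.  The AIH "motivo de saída" (reason for leaving) codes
#: must additionally be collapsed into the five DischargeReason classes:
#: discharge-alive codes -> "alive", in-hospital-death codes ->
#: "in_hospital_death", transfer codes -> "transfer", continuation/stay
#: ("permanência") codes -> "stay", anything else -> "other".
SIH_COLUMN_ADAPTER = {
    "N_AIH": "claim_id",
    "CNES": "hospital_code",
    "MUNIC_RES": "municipality",
    "NASC": "birth_date",
    "DT_INTER": "admission_date",
    "DT_SAIDA": "discharge_date",
    "COBRANCA": "discharge_reason",
    "DIAG_PRINC": "diag_principal",
    "DIAGSEC1": "diag_sec_1",
    "PROC_REA": "procedure_code",
}


def read_claims_csv(path) -> list[ClaimRecord]:
    """Read claim records from the claims CSV dialect (ISO-8601 dates)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLAIMS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"claims CSV missing columns: {missing}")
    claims = []
    for row in df.itertuples(index=False):
        diagnoses = [row.diag_principal] + [
            getattr(row, f"diag_sec_{i}")
            for i in range(1, N_SECONDARY_DIAGNOSES + 1)
            if getattr(row, f"diag_sec_{i}")
        ]
        try:
            reason = DischargeReason(row.discharge_reason)
        except ValueError as exc:
            raise InputError(
                f"claim {row.claim_id}: unknown discharge_reason "
                f"{row.discharge_reason!r}"
            ) from exc
        claims.append(
            ClaimRecord(
                claim_id=row.claim_id,
                hospital_code=row.hospital_code,
                municipality=row.municipality,
                birth_date=date.fromisoformat(row.birth_date),
                admission_date=date.fromisoformat(row.admission_date),
                discharge_date=date.fromisoformat(row.discharge_date),
                discharge_reason=reason,
                diagnoses=tuple(diagnoses),
                procedure_code=row.procedure_code,
            )
        )
    return claims


def write_claims_csv(claims: Sequence[ClaimRecord], path) -> None:
    """Write claim records in the claims CSV dialect."""
    rows = []
    for claim in claims:
        row = {
            "claim_id": claim.claim_id,
            "hospital_code": claim.hospital_code,
            "municipality": claim.municipality,
            "birth_date": claim.birth_date.isoformat(),
            "admission_date": claim.admission_date.isoformat(),
            "discharge_date": claim.discharge_date.isoformat(),
            "discharge_reason": claim.discharge_reason.value,
            "diag_principal": claim.diagnoses[0],
            "procedure_code": claim.procedure_code,
        }
        for i in range(1, N_SECONDARY_DIAGNOSES + 1):
            row[f"diag_sec_{i}"] = (
                claim.diagnoses[i] if i < len(claim.diagnoses) else ""
            )
        rows.append(row)
    pd.DataFrame(rows, columns=CLAIMS_CSV_COLUMNS).to_csv(path, index=False)
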