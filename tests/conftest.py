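"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

from datetime import date, timedelta

import pytest
from hypothesis import settings

from morbrules import ClaimRecord, DischargeReason, default_mapping

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

_COUNTER = {"i": 0}


def make_claim(
    claim_id: str | None = None,
    hospital: str = "H1",
    municipality: str = "M1",
    birth: date = date(1990, 5, 1),
    admission: date = date(2015, 3, 10),
    stay_days: int = 2,
    reason: DischargeReason = DischargeReason.ALIVE,
    diagnoses: tuple[str, ...] = ("O80",),
    procedure: str = "",
) -> ClaimRecord:
    """Claim builder with sensible defaults and auto-incrementing ids."""
    if claim_id is None:
        _COUNTER["i"] += 1
        claim_id = f"C{_COUNTER['i']:05d}"
    return ClaimRecord(
        claim_id=claim_id,
        hospital_code=hospital,
        municipality=municipality,
        birth_date=birth,
        admission_date=admission,
        discharge_date=admission + timedelta(days=stay_days),
        discharge_reason=reason,
        diagnoses=diagnoses,
        procedure_code=procedure,
    )


@pytest.fixture(scope="session")
def mapping():
    return default_mapping()
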