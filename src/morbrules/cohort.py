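"""Selection of the obstetric study cohort and optional death confirmation.

An episode is obstetric if any claim carries a chapter-XV (``O``) diagnosis
in any diagnostic field, or an obstetric principal care procedure.  The
cohort keeps obstetric episodes of women aged 10-49 completed years at
admission whose episode ended discharged alive or in in-hospital death.
Optionally, death episodes are confirmed against a deidentified mortality
registry; unconfirmed deaths are removed (data-quality exclusion mirroring
linkage to a mortality information system).
"""

from __future__ import annotations

import logging
from datetime import timedelta
from typing import Iterable, Sequence

import pandas as pd

from .episodes import Episode, Outcome
from .exceptions import InputError
from .synthetic import SYNTHETIC_OBSTETRIC_PROCEDURE, DeathRegistryEntry

logger = logging.getLogger(__name__)

#: Inclusive age band (completed years at admission) of the cohort.
AGE_MIN, AGE_MAX = 10, 49

#: Days past discharge a registry death date may fall and still confirm
#: the episode's death (tolerates date-entry lag).
DEATH_MATCH_GRACE_DAYS = 1

#: Obstetric principal-procedure codes recognised by default (SUS-style
#: codes: normal delivery, cesarean section, curettage, delivery in a
#: normal-birth centre).  Extend or replace via a one-column CSV.
DEFAULT_OBSTETRIC_PROCEDURES = frozenset(
    {
        SYNTHETIC_OBSTETRIC_PROCEDURE,  # 0310010039 normal delivery
        "0411010034",  # cesarean section
        "0411010026",  # cesarean with tubal ligation
        "0409060089",  # post-abortion curettage
        "0310010055",  # delivery in normal-birth centre
    }
)


def is_obstetric(episode: Episode, obstetric_procedures: frozenset[str]) -> bool:
    """Any O-chapter diagnosis in any field, or an obstetric procedure."""
    for claim in episode.claims:
        if any(code.startswith("O") for code in claim.diagnoses):
            return True
        if claim.procedure_code in obstetric_procedures:
            return True
    return False


def select_cohort(
    episodes: Iterable[Episode],
    obstetric_procedures: frozenset[str] = DEFAULT_OBSTETRIC_PROCEDURES,
) -> list[Episode]:
    """Keep obstetric, age-10-49, alive-or-death-discharged episodes.

    The three criteria are independent per-episode predicates, so their
    application order is immaterial; removal counts per criterion are
    logged (an episode may fail several).
    """
    episodes = list(episodes)
    kept: list[Episode] = []
    n_not_obstetric = n_age = n_discharge = 0
    for ep in episodes:
        ok = True
        if not is_obstetric(ep, obstetric_procedures):
            n_not_obstetric += 1
            ok = False
        if not (AGE_MIN <= ep.age_years <= AGE_MAX):
            n_age += 1
            ok = False
        if ep.outcome not in (Outcome.ALIVE, Outcome.DEATH):
            n_discharge += 1
            ok = False
        if ok:
            kept.append(ep)
    logger.info(
        "cohort: kept %d of %d episodes (removed: %d non-obstetric, "
        "%d outside ages %d-%d, %d other discharge)",
        len(kept), len(episodes), n_not_obstetric, n_age, AGE_MIN, AGE_MAX,
        n_discharge,
    )
    return kept


def confirm_deaths(
    episodes: Iterable[Episode],
    registry: Sequence[DeathRegistryEntry],
    grace_days: int = DEATH_MATCH_GRACE_DAYS,
) -> list[Episode]:
    """Drop death episodes without a matching mortality-registry entry.

    A match requires equal (birth_date, municipality) and a registry death
    date within [admission_date, discharge_date + grace_days].  Alive
    episodes pass through untouched.
    """
    index: dict[tuple, list] = {}
    for entry in registry:
        index.setdefault((entry.birth_date, entry.municipality), []).append(
            entry.death_date
        )
    kept: list[Episode] = []
    n_removed = 0
    for ep in episodes:
        if ep.outcome is not Outcome.DEATH:
            kept.append(ep)
            continue
        window_end = ep.discharge_date + timedelta(days=grace_days)
        dates = index.get((ep.birth_date, ep.municipality), ())
        if any(ep.admission_date <= d <= window_end for d in dates):
            kept.append(ep)
        else:
            n_removed += 1
    logger.info("death confirmation: removed %d unconfirmed death episodes", n_removed)
    return kept


def read_procedures_csv(path) -> frozenset[str]:
    """Read a one-column CSV of obstetric procedure codes."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] != 1:
        raise InputError("procedures CSV must have exactly one column")
    return frozenset(df.iloc[:, 0].dropna().str.strip())
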