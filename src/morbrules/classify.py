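"""ICD-10 morbidity grouping and episode transactions.

Diagnoses recorded during obstetric hospitalizations are collapsed into a
12-group morbidity scheme (several groups carry lettered subgroups, 20 item
labels in all) adapted from the WHO's ICD-10-based grouping of maternal
deaths: because claims data record morbidity rather than causes of death,
the scheme also absorbs ICD codes that are reasons for admission but never
causes of death, and adds morbidity-only groups.  The shipped default
mapping is an approximation assembled from the group definitions and the
WHO structure; it is a plain CSV (columns ``icd_prefix,item_label``) and is
user-replaceable — pipeline correctness does not depend on any specific
entry.

Classification is longest-prefix matching on dotless codes, so sub-code
splits (O24.4 gestational diabetes vs the rest of O24) override chapter- or
block-level assignments.  Codes matching no prefix fall into the residual
group 13 ("Others").
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable

from .classify_names import GROUP_TITLES, ITEM_NAMES  # re-export convenience
from .episodes import Episode, Outcome, normalize_icd10
from .exceptions import ConfigurationError

__all__ = [
    "CATALOGUE",
    "RESIDUAL_LABEL",
    "OUTCOME_DEATH",
    "OUTCOME_ALIVE",
    "OUTCOME_ITEMS",
    "GROUP_TITLES",
    "ITEM_NAMES",
    "GroupMapping",
    "Transaction",
    "load_mapping",
    "default_mapping",
    "episode_to_transaction",
    "group_of",
]

#: The 20 morbidity item labels (12 numbered groups, some split in subgroups).
CATALOGUE = (
    "1a", "1b", "2a", "2b", "3", "4a", "4b", "5", "7a", "7b",
    "8a", "8b", "8c", "8d", "8e", "9", "10", "11", "12", "13",
)

#: Residual group absorbing every code no prefix claims.
RESIDUAL_LABEL = "13"

OUTCOME_DEATH = "DEATH"
OUTCOME_ALIVE = "ALIVE"
OUTCOME_ITEMS = frozenset({OUTCOME_DEATH, OUTCOME_ALIVE})

_PREFIX_RE = re.compile(r"^[A-Z][0-9A-Z]{0,3}$")

#: Path (within the installed package) of the shipped default mapping CSV.
DEFAULT_MAPPING_RESOURCE = "data/default_mapping.csv"


def group_of(label: str) -> str:
    """Numbered group of an item label: ``"2a" -> "2"``, ``"3" -> "3"``."""
    return label.rstrip("abcdefghij")


@dataclass(frozen=True)
class GroupMapping:
    """Ordered ICD-10 prefix -> item-label lookup with longest-prefix match."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        lookup: dict[str, str] = {}
        for prefix, label in self.entries:
            if not _PREFIX_RE.match(prefix):
                raise ConfigurationError(f"bad ICD prefix in mapping: {prefix!r}")
            if label not in CATALOGUE:
                raise ConfigurationError(f"unknown item label in mapping: {label!r}")
            if lookup.get(prefix, label) != label:
                raise ConfigurationError(
                    f"ambiguous mapping: prefix {prefix!r} maps to both "
                    f"{lookup[prefix]!r} and {label!r}"
                )
            lookup.setdefault(prefix, label)
        object.__setattr__(self, "_lookup", lookup)

    def classify(self, code: str) -> str:
        """Item label of the longest matching prefix; residual if none."""
        norm = normalize_icd10(code)
        lookup = self._lookup  # type: ignore[attr-defined]
        for length in range(min(4, len(norm)), 0, -1):
            label = lookup.get(norm[:length])
            if label is not None:
                return label
        return RESIDUAL_LABEL

    def labels(self) -> frozenset[str]:
        """Labels reachable through this mapping (residual always included)."""
        return frozenset(label for _, label in self.entries) | {RESIDUAL_LABEL}

    def canonical_codes(self) -> dict[str, str]:
        """One representative full ICD-10 code per reachable item label.

        For each label the first entry whose prefix is itself a valid code
        (three or more characters) and classifies back to that label is
        used.  The residual label gets a code no prefix matches.
        """
        canon: dict[str, str] = {}
        for prefix, label in self.entries:
            if label in canon or len(prefix) < 3:
                continue
            try:
                if self.classify(prefix) == label:
                    canon[label] = prefix
            except Exception:  # prefix not a full code shape
                continue
        for probe in ("Z999", "U999", "Q999"):
            if self.classify(probe) == RESIDUAL_LABEL:
                canon.setdefault(RESIDUAL_LABEL, probe)
                break
        return canon


def load_mapping(path) -> GroupMapping:
    """Load and validate a mapping CSV with columns ``icd_prefix,item_label``."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "icd_prefix", "item_label"
        } <= set(reader.fieldnames):
            raise ConfigurationError(
                "mapping CSV must have columns icd_prefix,item_label"
            )
        entries = tuple(
            (row["icd_prefix"].strip().upper(), row["item_label"].strip())
            for row in reader
        )
    if not entries:
        raise ConfigurationError("mapping CSV is empty")
    return GroupMapping(entries)


@lru_cache(maxsize=1)
def default_mapping() -> GroupMapping:
    """The shipped default mapping (cached)."""
    ref = resources.files("morbrules").joinpath(DEFAULT_MAPPING_RESOURCE)
    with resources.as_file(ref) as path:
        return load_mapping(path)


@dataclass(frozen=True)
class Transaction:
    """Deduplicated morbidity-item set of one episode plus its outcome item."""

    items: frozenset[str]
    outcome_item: str

    def __post_init__(self) -> None:
        if self.outcome_item not in OUTCOME_ITEMS:
            raise ConfigurationError(
                f"outcome_item must be one of {sorted(OUTCOME_ITEMS)}"
            )
        if self.items & OUTCOME_ITEMS:
            raise ConfigurationError("outcome items cannot appear among items")

    @property
    def full_itemset(self) -> frozenset[str]:
        return self.items | {self.outcome_item}


def episode_to_transaction(episode: Episode, mapping: GroupMapping) -> Transaction:
    """Classify every diagnosis of every claim; dedupe into one item set."""
    items = frozenset(
        mapping.classify(code)
        for claim in episode.claims
        for code in claim.diagnoses
    )
    outcome = OUTCOME_DEATH if episode.outcome is Outcome.DEATH else OUTCOME_ALIVE
    return Transaction(items=items, outcome_item=outcome)


def episodes_to_transactions(
    episodes: Iterable[Episode], mapping: GroupMapping
) -> list[Transaction]:
    return [episode_to_transaction(e, mapping) for e in episodes]
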