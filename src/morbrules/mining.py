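"""Association-rule mining of morbidity profiles against discharge outcome.

A from-scratch, level-wise Apriori over episode transactions, followed by
rule generation restricted to outcome consequents, redundancy pruning, and
the selection filters used for rare-outcome surveillance.

For a rule X -> Y over a database of ``n`` transactions:

    Supp(X -> Y) = count(X u Y) / n
    Conf(X -> Y) = Supp(X u Y) / Supp(X)
    Lift(X -> Y) = Conf(X -> Y) / Supp(Y)

Lift equals 1 when antecedent and consequent are independent.  Because the
death outcome is very rare, mining runs with a vanishingly small support
floor (default 1e-10, i.e. an absolute count floor of 1 at any realistic
database size) and interesting-but-infrequent rules are instead selected
afterwards by lift, non-redundancy, an absolute count floor, and exclusion
of the uninformative childbirth group from antecedents.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .classify import OUTCOME_ALIVE, OUTCOME_DEATH, OUTCOME_ITEMS, Transaction
from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Absolute tolerance used when verifying the metric identities.
METRIC_ATOL = 1e-12


@dataclass(frozen=True)
class TransactionDatabase:
    """The mined database; ``n`` is the record count in the support formula."""

    transactions: tuple[Transaction, ...]

    @property
    def n(self) -> int:
        return len(self.transactions)

    @classmethod
    def from_transactions(cls, transactions: Iterable[Transaction]) -> "TransactionDatabase":
        return cls(tuple(transactions))

    def profile_weights(self) -> Counter:
        """Multiset of full itemsets (items + outcome), for weighted counting."""
        return Counter(t.full_itemset for t in self.transactions)


@dataclass(frozen=True)
class ItemsetCount:
    itemset: frozenset[str]
    count: int


@dataclass(frozen=True)
class AssociationRule:
    """X -> Y with its occurrence count and the three mined metrics."""

    antecedent: frozenset[str]
    consequent: str
    count: int
    support: float
    confidence: float
    lift: float

    def sort_key(self) -> tuple:
        return (len(self.antecedent), tuple(sorted(self.antecedent)), self.consequent)


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and filters of the mining stage."""

    min_support: float = 1e-10
    min_confidence: float = 1e-10
    min_lift: float = 1.1
    min_count: int = 4
    excluded_items: frozenset[str] = frozenset({"10"})
    consequents: frozenset[str] = frozenset({OUTCOME_DEATH, OUTCOME_ALIVE})

    def __post_init__(self) -> None:
        for name in ("min_support", "min_confidence", "min_lift"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.min_count < 1:
            raise ConfigurationError("min_count must be >= 1")
        if not frozenset(self.consequents) <= OUTCOME_ITEMS:
            raise ConfigurationError(
                f"consequents must be outcome items {sorted(OUTCOME_ITEMS)}"
            )
        object.__setattr__(self, "excluded_items", frozenset(self.excluded_items))
        object.__setattr__(self, "consequents", frozenset(self.consequents))


def _count_floor(min_support: float, n: int) -> int:
    # a support threshold of s means "count >= ceil(s*n)", never below 1
    return max(1, math.ceil(min_support * n - 1e-12))


def frequent_itemsets(
    db: TransactionDatabase, min_support: float = 1e-10
) -> list[ItemsetCount]:
    """All itemsets whose count meets the support floor, level-wise.

    Classic Apriori: candidates of size k are joins of frequent (k-1)-sets
    sharing their first k-2 items, pruned unless every (k-1)-subset is
    frequent (counts are anti-monotone).  Counting enumerates the k-subsets
    of each *unique* transaction profile, weighted by its multiplicity.
    Itemsets are returned in canonical order (size, then sorted labels).
    """
    if db.n < 1:
        raise InputError("cannot mine an empty database")
    floor = _count_floor(min_support, db.n)
    weights = db.profile_weights()

    counts_1: Counter = Counter()
    for profile, w in weights.items():
        for item in profile:
            counts_1[(item,)] += w
    frequent: dict[tuple[str, ...], int] = {
        t: c for t, c in counts_1.items() if c >= floor
    }
    result: dict[tuple[str, ...], int] = dict(frequent)

    k = 2
    while frequent:
        prev_keys = sorted(frequent)
        prev_set = set(prev_keys)
        candidates: set[tuple[str, ...]] = set()
        for a, b in combinations(prev_keys, 2):
            if a[:-1] != b[:-1]:
                continue
            cand = a + (b[-1],)
            if all(
                cand[:i] + cand[i + 1:] in prev_set for i in range(len(cand))
            ):
                candidates.add(cand)
        if not candidates:
            break
        counts_k: Counter = Counter()
        for profile, w in weights.items():
            if len(profile) < k:
                continue
            for combo in combinations(sorted(profile), k):
                if combo in candidates:
                    counts_k[combo] += w
        frequent = {t: c for t, c in counts_k.items() if c >= floor}
        result.update(frequent)
        k += 1

    out = [ItemsetCount(frozenset(t), c) for t, c in result.items()]
    out.sort(key=lambda ic: (len(ic.itemset), tuple(sorted(ic.itemset))))
    logger.info(
        "frequent itemsets: %d (count floor %d, n=%d)", len(out), floor, db.n
    )
    return out


def generate_rules(
    itemsets: Sequence[ItemsetCount],
    db: TransactionDatabase,
    config: MiningConfig = MiningConfig(),
) -> list[AssociationRule]:
    """Rules (itemset minus outcome) -> outcome for every frequent itemset
    containing exactly one outcome item among the configured consequents.

    Metrics follow the support/confidence/lift definitions; rules whose
    confidence falls below ``min_confidence`` are dropped.  A consequent
    absent from every transaction has Supp(Y)=0, its rules are undefined
    and skipped with a warning.
    """
    n = db.n
    counts = {ic.itemset: ic.count for ic in itemsets}
    for outcome in sorted(config.consequents):
        if counts.get(frozenset({outcome}), 0) == 0:
            logger.warning(
                "consequent %r absent from all transactions; its rules are "
                "undefined and skipped", outcome,
            )
    rules: list[AssociationRule] = []
    for itemset, count_xy in counts.items():
        outcome_part = itemset & config.consequents
        if len(outcome_part) != 1:
            continue
        consequent = next(iter(outcome_part))
        antecedent = itemset - {consequent}
        if not antecedent:
            continue
        count_x = counts[antecedent]  # anti-monotonicity: present & >= count_xy
        count_y = counts.get(frozenset({consequent}), 0)
        if count_y == 0:
            continue
        support = count_xy / n
        confidence = count_xy / count_x
        lift = confidence / (count_y / n)
        if confidence < config.min_confidence:
            continue
        rules.append(
            AssociationRule(
                antecedent=antecedent,
                consequent=consequent,
                count=count_xy,
                support=support,
                confidence=confidence,
                lift=lift,
            )
        )
    rules.sort(key=AssociationRule.sort_key)
    logger.info("generated %d rules", len(rules))
    return rules


def prune_redundant(rules: Sequence[AssociationRule]) -> list[AssociationRule]:
    """Remove rules improved upon by a strictly simpler rule.

    A rule is redundant when some rule in the input with the same
    consequent and a proper subset of its antecedent reaches confidence
    greater than or equal to its own.  Checking against the *input* set
    makes the operation idempotent.
    """
    by_consequent: dict[str, dict[frozenset, float]] = {}
    for rule in rules:
        by_consequent.setdefault(rule.consequent, {})[rule.antecedent] = rule.confidence

    def redundant(rule: AssociationRule) -> bool:
        table = by_consequent[rule.consequent]
        items = sorted(rule.antecedent)
        for size in range(1, len(items)):
            for sub in combinations(items, size):
                conf = table.get(frozenset(sub))
                if conf is not None and conf >= rule.confidence:
                    return True
        return False

    return [r for r in rules if not redundant(r)]


def filter_rules(
    rules: Sequence[AssociationRule], config: MiningConfig = MiningConfig()
) -> list[AssociationRule]:
    """Apply the selection filters: lift, redundancy, count, item exclusion."""
    step = [r for r in rules if r.lift >= config.min_lift]
    logger.info("lift >= %g removed %d rules", config.min_lift, len(rules) - len(step))

    pruned = prune_redundant(step)
    logger.info("redundancy pruning removed %d rules", len(step) - len(pruned))

    counted = [r for r in pruned if r.count >= config.min_count]
    logger.info(
        "count >= %d removed %d rules", config.min_count, len(pruned) - len(counted)
    )

    kept = [r for r in counted if not (r.antecedent & config.excluded_items)]
    logger.info(
        "excluded-item filter (%s) removed %d rules",
        sorted(config.excluded_items), len(counted) - len(kept),
    )
    return kept


def mine_rules(
    db: TransactionDatabase, config: MiningConfig = MiningConfig()
) -> list[AssociationRule]:
    """Full mining pass: frequent itemsets -> rules -> selection filters."""
    itemsets = frequent_itemsets(db, config.min_support)
    rules = generate_rules(itemsets, db, config)
    return filter_rules(rules, config)


# ---------------------------------------------------------------------------
# Rules CSV
# ---------------------------------------------------------------------------

RULES_CSV_COLUMNS = ["antecedent", "consequent", "count", "support", "confidence", "lift"]


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "antecedent": ";".join(sorted(r.antecedent)),
                "consequent": r.consequent,
                "count": r.count,
                "support": r.support,
                "confidence": r.confidence,
                "lift": r.lift,
            }
            for r in rules
        ],
        columns=RULES_CSV_COLUMNS,
    )


def write_rules_csv(rules: Sequence[AssociationRule], path) -> None:
    """Write rules at full precision (support in scientific notation)."""
    df = rules_to_frame(rules)
    df["support"] = df["support"].map(lambda v: format(v, ".12e"))
    df.to_csv(path, index=False)


def read_rules_csv(path) -> list[AssociationRule]:
    df = pd.read_csv(path)
    return [
        AssociationRule(
            antecedent=frozenset(str(row["antecedent"]).split(";")),
            consequent=row["consequent"],
            count=int(row["count"]),
            support=float(row["support"]),
            confidence=float(row["confidence"]),
            lift=float(row["lift"]),
        )
        for row in df.to_dict("records")
    ]
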