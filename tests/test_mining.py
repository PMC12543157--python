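"""Apriori mining, rule metrics, redundancy pruning and selection filters."""

import math
import random
from itertools import chain, combinations

import pytest

from morbrules import (
    AssociationRule,
    InputError,
    MiningConfig,
    OUTCOME_ALIVE,
    OUTCOME_DEATH,
    Transaction,
    TransactionDatabase,
    filter_rules,
    frequent_itemsets,
    generate_rules,
    prune_redundant,
    read_rules_csv,
    write_rules_csv,
)

ITEM_POOL = ["1a", "2a", "2b", "3", "4a", "5", "8a", "8c", "8e", "11"]


def tx(*items, death=False):
    return Transaction(
        items=frozenset(items),
        outcome_item=OUTCOME_DEATH if death else OUTCOME_ALIVE,
    )


def random_db(rnd: random.Random, n_tx: int, n_items: int) -> TransactionDatabase:
    items = ITEM_POOL[:n_items]
    transactions = [
        tx(*(i for i in items if rnd.random() < 0.4), death=rnd.random() < 0.3)
        for _ in range(n_tx)
    ]
    return TransactionDatabase.from_transactions(transactions)


def bruteforce_itemsets(db: TransactionDatabase, min_support: float) -> dict:
    """Exhaustive power-set enumeration over all observed items."""
    universe = sorted(set().union(*(t.full_itemset for t in db.transactions)))
    floor = max(1, math.ceil(min_support * db.n - 1e-12))
    result = {}
    for size in range(1, len(universe) + 1):
        for combo in combinations(universe, size):
            s = frozenset(combo)
            count = sum(1 for t in db.transactions if s <= t.full_itemset)
            if count >= floor:
                result[s] = count
    return result


class TestFrequentItemsets:
    def test_single_transaction_enumerates_all_subsets(self):
        db = TransactionDatabase.from_transactions([tx("2a", death=True)])
        got = {(tuple(sorted(ic.itemset)), ic.count)
               for ic in frequent_itemsets(db, 1e-10)}
        assert got == {
            (("2a",), 1),
            ((OUTCOME_DEATH,), 1),
            (("2a", OUTCOME_DEATH), 1),
        }

    def test_support_floor_excludes_unique_items(self):
        db = TransactionDatabase.from_transactions(
            [tx("2a"), tx("3"), tx("5", death=True)]
        )
        # floor of ceil(0.5*3)=2: only the outcome item repeats
        got = {tuple(sorted(ic.itemset)) for ic in frequent_itemsets(db, 0.5)}
        assert got == {(OUTCOME_ALIVE,)}

    def test_empty_database_rejected(self):
        with pytest.raises(InputError):
            frequent_itemsets(TransactionDatabase(()), 1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_enumeration(self, seed):
        rnd = random.Random(seed)
        db = random_db(rnd, n_tx=rnd.randint(20, 200), n_items=rnd.randint(2, 10))
        min_support = rnd.choice([1e-10, 0.05, 0.2])
        got = {ic.itemset: ic.count for ic in frequent_itemsets(db, min_support)}
        assert got == bruteforce_itemsets(db, min_support)

    @pytest.mark.parametrize("seed", range(3))
    def test_anti_monotonicity(self, seed):
        db = random_db(random.Random(seed + 50), 120, 6)
        counts = {ic.itemset: ic.count for ic in frequent_itemsets(db, 1e-10)}
        for s, c in counts.items():
            for item in s:
                sub = s - {item}
                if sub:
                    assert counts[sub] >= c

    def test_canonical_ordering(self):
        db = random_db(random.Random(3), 60, 5)
        out = frequent_itemsets(db, 1e-10)
        keys = [(len(ic.itemset), tuple(sorted(ic.itemset))) for ic in out]
        assert keys == sorted(keys)


class TestGenerateRules:
    def lenient(self):
        return MiningConfig()

    def test_worked_example_support_from_counts(self):
        """113 profile-with-death episodes in 2,742,467 give support 4.12e-5."""
        n, count_xy, n_deaths = 2_742_467, 113, 831
        transactions = (
            [tx("3", death=True)] * count_xy
            + [tx(death=True)] * (n_deaths - count_xy)
            + [tx()] * (n - n_deaths)
        )
        db = TransactionDatabase.from_transactions(transactions)
        rules = generate_rules(frequent_itemsets(db, 1e-10), db, self.lenient())
        (rule,) = [r for r in rules
                   if r.antecedent == frozenset({"3"})
                   and r.consequent == OUTCOME_DEATH]
        assert rule.count == count_xy
        assert float(f"{rule.support:.2e}") == 4.12e-05

    def test_worked_example_confidence_and_lift(self):
        """A profile seen 8 times with 6 deaths, 831 deaths in 2,742,467
        episodes: confidence 0.750, lift 2475.151."""
        n, n_deaths = 2_742_467, 831
        transactions = (
            [tx("1a", "8a", death=True)] * 6
            + [tx("1a", "8a")] * 2
            + [tx(death=True)] * (n_deaths - 6)
            + [tx()] * (n - 8 - (n_deaths - 6))
        )
        db = TransactionDatabase.from_transactions(transactions)
        rules = generate_rules(frequent_itemsets(db, 1e-10), db, self.lenient())
        (rule,) = [r for r in rules
                   if r.antecedent == frozenset({"1a", "8a"})
                   and r.consequent == OUTCOME_DEATH]
        assert round(rule.confidence, 3) == 0.750
        assert round(rule.lift, 3) == 2475.151

    def test_independent_items_have_lift_exactly_one(self):
        db = TransactionDatabase.from_transactions(
            [tx("1a", death=True), tx("1a"), tx("2a", death=True), tx("2a")]
        )
        rules = generate_rules(frequent_itemsets(db, 1e-10), db, self.lenient())
        rule = next(r for r in rules
                    if r.antecedent == frozenset({"1a"})
                    and r.consequent == OUTCOME_DEATH)
        assert rule.lift == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_identities(self, seed):
        """support = count/n, confidence = support/Supp(X),
        lift*Supp(Y) = confidence, all to 1e-12."""
        db = random_db(random.Random(seed + 100), 150, 8)
        itemsets = frequent_itemsets(db, 1e-10)
        counts = {ic.itemset: ic.count for ic in itemsets}
        rules = generate_rules(itemsets, db, self.lenient())
        assert rules
        for r in rules:
            supp_x = counts[r.antecedent] / db.n
            supp_y = counts[frozenset({r.consequent})] / db.n
            assert abs(r.support - r.count / db.n) <= 1e-12
            assert abs(r.confidence - r.support / supp_x) <= 1e-12
            assert abs(r.lift * supp_y - r.confidence) <= 1e-12
            assert 0 <= r.support <= r.confidence <= 1
            assert r.support <= supp_x + 1e-12
            assert r.support <= supp_y + 1e-12

    def test_absent_consequent_skipped_with_warning(self, caplog):
        db = TransactionDatabase.from_transactions([tx("2a"), tx("3")])
        with caplog.at_level("WARNING"):
            rules = generate_rules(frequent_itemsets(db, 1e-10), db,
                                   self.lenient())
        assert not any(r.consequent == OUTCOME_DEATH for r in rules)
        assert any("DEATH" in rec.message for rec in caplog.records)

    def test_restricted_consequents(self):
        db = TransactionDatabase.from_transactions(
            [tx("2a", death=True), tx("2a"), tx()]
        )
        config = MiningConfig(consequents=frozenset({OUTCOME_DEATH}))
        rules = generate_rules(frequent_itemsets(db, 1e-10), db, config)
        assert {r.consequent for r in rules} == {OUTCOME_DEATH}


def rule(antecedent, conf, consequent=OUTCOME_DEATH, count=10, n=1000):
    return AssociationRule(
        antecedent=frozenset(antecedent),
        consequent=consequent,
        count=count,
        support=count / n,
        confidence=conf,
        lift=1.5,
    )


class TestPruneRedundant:
    def test_equal_confidence_superset_removed(self):
        simple = rule({"1a"}, 0.5)
        extended = rule({"1a", "2a"}, 0.5)
        assert prune_redundant([simple, extended]) == [simple]

    def test_strict_improvement_kept(self):
        simple = rule({"1a"}, 0.5)
        better = rule({"1a", "2a"}, 0.6)
        assert prune_redundant([simple, better]) == [simple, better]

    def test_different_consequents_do_not_interact(self):
        a = rule({"1a"}, 0.5, consequent=OUTCOME_DEATH)
        b = rule({"1a", "2a"}, 0.4, consequent=OUTCOME_ALIVE)
        assert prune_redundant([a, b]) == [a, b]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadratic_scan_oracle(self, seed):
        rnd = random.Random(seed)
        rules = []
        seen = set()
        for _ in range(rnd.randint(1, 100)):
            ante = frozenset(rnd.sample(ITEM_POOL[:6], rnd.randint(1, 4)))
            consequent = rnd.choice([OUTCOME_DEATH, OUTCOME_ALIVE])
            if (ante, consequent) in seen:
                continue
            seen.add((ante, consequent))
            rules.append(rule(ante, rnd.random(), consequent=consequent))

        def oracle(rules):
            out = []
            for r in rules:
                dominated = any(
                    s.consequent == r.consequent
                    and s.antecedent < r.antecedent
                    and s.confidence >= r.confidence
                    for s in rules
                )
                if not dominated:
                    out.append(r)
            return out

        assert prune_redundant(rules) == oracle(rules)

    def test_idempotent(self):
        rnd = random.Random(99)
        rules = [
            rule(frozenset(rnd.sample(ITEM_POOL[:5], rnd.randint(1, 3))),
                 round(rnd.random(), 2))
            for _ in range(40)
        ]
        once = prune_redundant(rules)
        assert prune_redundant(once) == once


class TestFilterRules:
    def test_low_lift_removed(self):
        low = rule({"1a"}, 0.5)
        low = AssociationRule(low.antecedent, low.consequent, low.count,
                              low.support, low.confidence, lift=1.05)
        assert filter_rules([low], MiningConfig()) == []

    def test_low_count_removed(self):
        scarce = rule({"1a"}, 0.5, count=3)
        assert filter_rules([scarce], MiningConfig()) == []

    def test_excluded_item_removed(self):
        childbirth = rule({"10", "2a"}, 0.9, count=20)
        assert filter_rules([childbirth], MiningConfig()) == []

    def test_passing_rule_survives(self):
        good = rule({"2a"}, 0.9, count=20)
        assert filter_rules([good], MiningConfig()) == [good]


def test_independence_limit_mean_lift_near_one():
    """Outcome drawn independently of items: mean lift over 100 simulated
    databases stays in [0.9, 1.1]."""
    rnd = random.Random(4242)
    lifts = []
    for _ in range(100):
        transactions = [
            tx(*(i for i in ITEM_POOL[:3] if rnd.random() < 0.5),
               death=rnd.random() < 0.3)
            for _ in range(400)
        ]
        db = TransactionDatabase.from_transactions(transactions)
        rules = generate_rules(frequent_itemsets(db, 1e-10), db, MiningConfig())
        lifts.extend(
            r.lift for r in rules
            if len(r.antecedent) == 1 and r.consequent == OUTCOME_DEATH
        )
    mean = sum(lifts) / len(lifts)
    assert 0.9 <= mean <= 1.1


def test_mining_config_validation():
    with pytest.raises(Exception):
        MiningConfig(min_count=0)
    with pytest.raises(Exception):
        MiningConfig(min_lift=-1)
    with pytest.raises(Exception):
        MiningConfig(consequents=frozenset({"2a"}))


def test_rules_csv_round_trip(tmp_path):
    db = random_db(random.Random(5), 150, 6)
    rules = generate_rules(frequent_itemsets(db, 1e-10), db, MiningConfig())
    path = tmp_path / "rules.csv"
    write_rules_csv(rules, path)
    back = read_rules_csv(path)
    assert len(back) == len(rules)
    for a, b in zip(sorted(rules, key=AssociationRule.sort_key),
                    sorted(back, key=AssociationRule.sort_key)):
        assert a.antecedent == b.antecedent
        assert a.consequent == b.consequent
        assert a.count == b.count
        assert math.isclose(a.support, b.support, rel_tol=1e-10)
        assert math.isclose(a.confidence, b.confidence, rel_tol=1e-10)
        assert math.isclose(a.lift, b.lift, rel_tol=1e-10)
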