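"""Report tables and end-to-end pipeline orchestration.

Two summary tables mirror how rare-outcome rule mining is usually read:
a *death profile* of single-antecedent rules (which morbidity groups are,
on their own, associated with in-hospital death, with the share of deaths
they appear in) and a *combination table* of multi-antecedent rules (which
group combinations carry the association).  ``run_pipeline`` chains every
stage — synthetic or supplied claims, episode linkage, cohort selection,
classification, mining, filtering — and writes the tables plus a JSON
run-metadata file with stage counts, thresholds, seed and version.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd

from . import __version__
from .classify import (
    CATALOGUE,
    GROUP_TITLES,
    ITEM_NAMES,
    OUTCOME_DEATH,
    GroupMapping,
    default_mapping,
    episodes_to_transactions,
    group_of,
    load_mapping,
)
from .cohort import (
    DEFAULT_OBSTETRIC_PROCEDURES,
    confirm_deaths,
    read_procedures_csv,
    select_cohort,
)
from .episodes import link_episodes, read_claims_csv, write_claims_csv
from .exceptions import ConfigurationError, InputError
from .mining import (
    AssociationRule,
    MiningConfig,
    TransactionDatabase,
    filter_rules,
    frequent_itemsets,
    generate_rules,
    write_rules_csv,
)
from .synthetic import (
    SimulationConfig,
    generate_claims,
    generate_death_registry,
    read_registry_csv,
    write_registry_csv,
)

logger = logging.getLogger(__name__)


def _label_key(label: str) -> tuple:
    try:
        return (CATALOGUE.index(label),)
    except ValueError:
        return (len(CATALOGUE), label)


def round_sig(value: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, -int(math.floor(math.log10(abs(value)))) + digits - 1)


class DeathProfile(NamedTuple):
    table: pd.DataFrame
    summary: dict


DEATH_PROFILE_COLUMNS = [
    "group", "group_title", "subgroup", "subgroup_name",
    "support", "confidence", "lift", "n_cases", "pct_of_deaths", "group_total",
]


def death_profile_table(
    rules: Sequence[AssociationRule], db: TransactionDatabase
) -> DeathProfile:
    """One row per single-antecedent death rule, plus cohort summary.

    Shares of deaths are printed to 1 decimal place, the death share of
    all episodes to 2; supports keep 3 significant figures, confidence and
    lift 3 decimals.  The ``group_total`` column sums the case counts of
    the subgroups within each numbered group.
    """
    n = db.n
    n_deaths = sum(1 for t in db.transactions if t.outcome_item == OUTCOME_DEATH)
    singles = sorted(
        (
            r for r in rules
            if r.consequent == OUTCOME_DEATH and len(r.antecedent) == 1
        ),
        key=lambda r: _label_key(next(iter(r.antecedent))),
    )
    group_totals: dict[str, int] = {}
    for r in singles:
        g = group_of(next(iter(r.antecedent)))
        group_totals[g] = group_totals.get(g, 0) + r.count
    rows = []
    for r in singles:
        label = next(iter(r.antecedent))
        g = group_of(label)
        rows.append(
            {
                "group": g,
                "group_title": GROUP_TITLES.get(g, ""),
                "subgroup": label,
                "subgroup_name": ITEM_NAMES.get(label, ""),
                "support": round_sig(r.support, 3),
                "confidence": round(r.confidence, 3),
                "lift": round(r.lift, 3),
                "n_cases": r.count,
                "pct_of_deaths": round(100.0 * r.count / n_deaths, 1)
                if n_deaths
                else float("nan"),
                "group_total": group_totals[g],
            }
        )
    table = pd.DataFrame(rows, columns=DEATH_PROFILE_COLUMNS)
    summary = {
        "n_episodes": n,
        "n_deaths": n_deaths,
        "death_pct_of_episodes": round(100.0 * n_deaths / n, 2) if n else None,
    }
    return DeathProfile(table=table, summary=summary)


COMBINATION_COLUMNS = [
    "group_1", "group_2", "group_3", "group_4", "confidence", "lift", "n_cases",
]


def combination_table(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Multi-antecedent death rules, one row each, sorted by antecedent."""
    multis = sorted(
        (
            r for r in rules
            if r.consequent == OUTCOME_DEATH and len(r.antecedent) >= 2
        ),
        key=lambda r: [_label_key(l) for l in sorted(r.antecedent, key=_label_key)],
    )
    size_counts: dict[int, int] = {}
    rows = []
    for r in multis:
        labels = sorted(r.antecedent, key=_label_key)
        size_counts[len(labels)] = size_counts.get(len(labels), 0) + 1
        row = {f"group_{i + 1}": "" for i in range(4)}
        for i, lab in enumerate(labels[:4]):
            row[f"group_{i + 1}"] = lab
        row.update(
            confidence=round(r.confidence, 3),
            lift=round(r.lift, 3),
            n_cases=r.count,
        )
        rows.append(row)
    for size in sorted(size_counts):
        logger.info(
            "%d rules combine %d groups/subgroups", size_counts[size], size
        )
    return pd.DataFrame(rows, columns=COMBINATION_COLUMNS)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one run needs: input source, mapping, filters, output dir."""

    outdir: str = "morbrules-out"
    claims_csv: str | None = None
    simulation: SimulationConfig | None = None
    mapping_csv: str | None = None
    procedures_csv: str | None = None
    registry_csv: str | None = None
    confirm_deaths: bool = False
    registry_coverage: float = 1.0  # used when simulating with confirmation
    mining: MiningConfig = field(default_factory=MiningConfig)

    def __post_init__(self) -> None:
        if (self.claims_csv is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of claims_csv or simulation must be given"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "cooccurrence_pairs" in sim:
                sim["cooccurrence_pairs"] = [
                    tuple(p) for p in sim["cooccurrence_pairs"]
                ]
            if "gap_days_distribution" in sim:
                sim["gap_days_distribution"] = {
                    int(k): v for k, v in sim["gap_days_distribution"].items()
                }
            sim = SimulationConfig(**sim)
        mining = raw.pop("mining", None)
        if mining is not None:
            for key in ("excluded_items", "consequents"):
                if key in mining:
                    mining[key] = frozenset(mining[key])
            mining = MiningConfig(**mining)
        else:
            mining = MiningConfig()
        try:
            return cls(simulation=sim, mining=mining, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"malformed pipeline config: {exc}") from exc

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        if path.suffix.lower() == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        return cls.from_dict(raw)


@dataclass
class PipelineResult:
    episodes: list
    cohort: list
    db: TransactionDatabase
    all_rules: list[AssociationRule]
    rules: list[AssociationRule]
    death_profile: DeathProfile
    combinations: pd.DataFrame
    metadata: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write artifacts under ``config.outdir``.

    Deterministic for a fixed config (the simulation seed covers all
    randomness), so repeated runs produce byte-identical artifacts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mapping: GroupMapping = (
        load_mapping(config.mapping_csv) if config.mapping_csv else default_mapping()
    )
    procedures = (
        read_procedures_csv(config.procedures_csv)
        if config.procedures_csv
        else DEFAULT_OBSTETRIC_PROCEDURES
    )

    registry = None
    if config.simulation is not None:
        claims = generate_claims(config.simulation, mapping)
        write_claims_csv(claims, outdir / "claims.csv")
        if config.confirm_deaths:
            registry = generate_death_registry(
                claims, config.registry_coverage, config.simulation.seed + 1
            )
            write_registry_csv(registry, outdir / "death_registry.csv")
    else:
        path = Path(config.claims_csv)
        if not path.exists():
            raise InputError(f"claims CSV not found: {path}")
        claims = read_claims_csv(path)
        if config.confirm_deaths:
            if not config.registry_csv:
                raise ConfigurationError(
                    "confirm_deaths requires registry_csv for supplied claims"
                )
            registry = read_registry_csv(config.registry_csv)

    episodes = link_episodes(claims)
    cohort = select_cohort(episodes, procedures)
    n_before_confirm = len(cohort)
    if config.confirm_deaths and registry is not None:
        cohort = confirm_deaths(cohort, registry)
    if not cohort:
        raise InputError("empty cohort: no episodes satisfy the selection criteria")

    transactions = episodes_to_transactions(cohort, mapping)
    db = TransactionDatabase.from_transactions(transactions)
    itemsets = frequent_itemsets(db, config.mining.min_support)
    all_rules = generate_rules(itemsets, db, config.mining)
    rules = filter_rules(all_rules, config.mining)

    profile = death_profile_table(rules, db)
    combos = combination_table(rules)

    write_rules_csv(rules, outdir / "rules.csv")
    profile.table.to_csv(outdir / "death_profile.csv", index=False)
    combos.to_csv(outdir / "combination_table.csv", index=False)

    metadata = {
        "version": __version__,
        "seed": config.simulation.seed if config.simulation else None,
        "stage_counts": {
            "claims": len(claims),
            "episodes": len(episodes),
            "cohort": n_before_confirm,
            "cohort_after_death_confirmation": len(cohort),
            "deaths": profile.summary["n_deaths"],
            "frequent_itemsets": len(itemsets),
            "rules_generated": len(all_rules),
            "rules_after_filters": len(rules),
        },
        "mining_config": {
            "min_support": config.mining.min_support,
            "min_confidence": config.mining.min_confidence,
            "min_lift": config.mining.min_lift,
            "min_count": config.mining.min_count,
            "excluded_items": sorted(config.mining.excluded_items),
            "consequents": sorted(config.mining.consequents),
        },
        "summary": profile.summary,
    }
    (outdir / "run_metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
    logger.info("pipeline finished: %s", metadata["stage_counts"])
    return PipelineResult(
        episodes=episodes,
        cohort=cohort,
        db=db,
        all_rules=all_rules,
        rules=rules,
        death_profile=profile,
        combinations=combos,
        metadata=metadata,
    )
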