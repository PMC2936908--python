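"""Species niches, the distinct-niche state catalog, and transition-cost matrices.

A niche is the combination of a larval feeding habit (external folivory,
galling, leaf folding, catkin feeding, berry mining, ...) and the set of
host-plant taxa a species uses.  A species using more than one host taxon
is a *generalist* (oligo-/polyphage).  Each distinct (habit, host-set)
combination observed among ingroup species becomes one state of a single
multistate character; outgroup species are coded as unknown and may take
any state at zero cost during parsimony optimization.

Two step-matrix rules are supported:

``all_one``
    Every change between distinct niches costs one step.

``generalist_zero``
    Moving *into* a generalist state from a specialist (or narrower
    generalist) state whose hosts are contained in the generalist's host
    range, with the same feeding habit, costs zero.  A clear overlap in
    host ranges is taken as evidence against ecological divergence, so
    such transitions are not counted as niche shifts.  All other changes
    cost one step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NicheState",
    "NicheRecord",
    "NicheCoding",
    "build_catalog",
    "build_step_matrix",
    "niches_differ",
    "tip_state_sets",
    "host_character",
    "read_niche_table",
    "write_niche_table",
    "records_from_table",
    "write_step_matrix",
]


@dataclass(frozen=True)
class NicheState:
    """One ecological niche: a feeding habit plus a nonempty host-taxon set."""

    habit: str
    hosts: frozenset[str]

    def __post_init__(self) -> None:
        if not self.hosts:
            raise ValueError("a niche requires at least one host taxon")
        object.__setattr__(self, "hosts", frozenset(self.hosts))

    @property
    def is_generalist(self) -> bool:
        return len(self.hosts) > 1

    def label(self) -> str:
        return f"{self.habit}|{'+'.join(sorted(self.hosts))}"

    def sort_key(self) -> tuple:
        return (self.habit, tuple(sorted(self.hosts)))


@dataclass(frozen=True)
class NicheRecord:
    """A species' row in the niche table."""

    species: str
    habit: str
    hosts: frozenset[str]
    is_outgroup: bool = False

    def state(self) -> NicheState:
        return NicheState(self.habit, self.hosts)


@dataclass
class NicheCoding:
    """Catalog of distinct niche states plus the species -> state assignment.

    ``assignment`` maps every coded (ingroup) species to an index into
    ``catalog``; species in ``unknown_species`` (outgroups) carry no state.
    """

    catalog: list[NicheState]
    assignment: dict[str, int]
    unknown_species: set[str] = field(default_factory=set)

    @property
    def n_states(self) -> int:
        return len(self.catalog)

    @property
    def species(self) -> set[str]:
        return set(self.assignment) | set(self.unknown_species)

    def state_of(self, species: str) -> NicheState | None:
        idx = self.assignment.get(species)
        return None if idx is None else self.catalog[idx]

    def state_labels(self) -> list[str]:
        return [s.label() for s in self.catalog]


def niches_differ(a: NicheState, b: NicheState) -> bool:
    """True when two niches are ecologically distinct.

    Niches differ when the feeding habits differ or the host ranges are
    disjoint; identical or host-overlapping niches within one habit count
    as the same resource.  Symmetric in its arguments.
    """
    return a.habit != b.habit or not (a.hosts & b.hosts)


def build_catalog(records: Iterable[NicheRecord]) -> NicheCoding:
    """Enumerate the distinct niches among ingroup species and code each one.

    The catalog lists each distinct (habit, host-set) combination exactly
    once, sorted by habit then host labels so the state order is stable
    across runs.  Outgroup species are coded unknown.

    Raises ``ValueError`` for duplicate species or an ingroup species with
    no hosts (the latter surfaces as the NicheState constructor error).
    """
    records = list(records)
    seen: set[str] = set()
    for r in records:
        if r.species in seen:
            raise ValueError(f"duplicate species in niche table: {r.species!r}")
        seen.add(r.species)

    ingroup = [r for r in records if not r.is_outgroup]
    states = {r.species: r.state() for r in ingroup}
    catalog = sorted(set(states.values()), key=NicheState.sort_key)
    index = {s: i for i, s in enumerate(catalog)}
    assignment = {sp: index[st] for sp, st in states.items()}
    unknown = {r.species for r in records if r.is_outgroup}
    logger.info(
        "niche catalog: %d distinct states from %d ingroup species (%d unknown)",
        len(catalog), len(ingroup), len(unknown),
    )
    return NicheCoding(catalog=catalog, assignment=assignment, unknown_species=unknown)


def build_step_matrix(
    coding: NicheCoding,
    rule: str = "generalist_zero",
    symmetric_generalist_zero: bool = False,
) -> np.ndarray:
    """Transition-cost matrix over the catalog under the chosen rule.

    Under ``generalist_zero`` the cost from state *i* to state *j* is zero
    when *j* is a generalist sharing *i*'s habit whose host range contains
    all of *i*'s hosts; the matrix is therefore asymmetric (moving back out
    of the generalist state still costs one step) unless
    ``symmetric_generalist_zero`` zeroes the reverse direction too.
    """
    if rule not in {"generalist_zero", "all_one"}:
        raise ValueError(f"unknown step-matrix rule: {rule!r}")
    k = coding.n_states
    costs = np.ones((k, k), dtype=float)
    np.fill_diagonal(costs, 0.0)
    if rule == "generalist_zero":
        for i, si in enumerate(coding.catalog):
            for j, sj in enumerate(coding.catalog):
                if i == j:
                    continue
                if sj.is_generalist and si.habit == sj.habit and si.hosts <= sj.hosts:
                    costs[i, j] = 0.0
                    if symmetric_generalist_zero:
                        costs[j, i] = 0.0
    return costs


def tip_state_sets(
    coding: NicheCoding, species: Iterable[str] | None = None
) -> dict[str, frozenset[int]]:
    """Admissible state sets per species for parsimony optimization.

    Coded species get a singleton set; unknown (outgroup) species get the
    full catalog, i.e. any state at zero cost.
    """
    if species is None:
        species = coding.species
    full = frozenset(range(coding.n_states))
    out: dict[str, frozenset[int]] = {}
    for sp in species:
        if sp in coding.assignment:
            out[sp] = frozenset({coding.assignment[sp]})
        elif sp in coding.unknown_species:
            out[sp] = full
        else:
            raise KeyError(f"species {sp!r} absent from niche coding")
    return out


def host_character(
    records: Iterable[NicheRecord],
) -> tuple[list[str], dict[str, frozenset[int]]]:
    """Host taxa as an unordered multistate character with polymorphic tips.

    Each distinct host taxon used by an ingroup species becomes one state;
    oligo- and polyphagous species are coded with *all* of their host taxa
    (a multi-element admissible set), and outgroups with the full state
    set.  Suitable for uniform-cost parsimony painting of host use.
    """
    records = list(records)
    hosts = sorted({h for r in records if not r.is_outgroup for h in r.hosts})
    index = {h: i for i, h in enumerate(hosts)}
    full = frozenset(range(len(hosts)))
    sets: dict[str, frozenset[int]] = {}
    for r in records:
        if r.is_outgroup:
            sets[r.species] = full
        else:
            sets[r.species] = frozenset(index[h] for h in r.hosts)
    return hosts, sets


# ---------------------------------------------------------------------------
# Tabular I/O.  Niche tables are TSV with columns:
#   species  feeding_habit  hosts (semicolon-separated)  outgroup (0/1)
# Outgroup rows may leave habit/hosts empty.


def read_niche_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"species": str, "feeding_habit": str, "hosts": str}
    )
    required = {"species", "feeding_habit", "hosts", "outgroup"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"niche table missing columns: {sorted(missing)}")
    return df


def write_niche_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def records_from_table(df: pd.DataFrame) -> list[NicheRecord]:
    records = []
    for row in df.itertuples(index=False):
        outgroup = bool(int(row.outgroup))
        hosts_raw = "" if pd.isna(row.hosts) else str(row.hosts)
        hosts = frozenset(h.strip() for h in hosts_raw.split(";") if h.strip())
        habit = "" if pd.isna(row.feeding_habit) else str(row.feeding_habit)
        if not outgroup and not hosts:
            raise ValueError(f"ingroup species {row.species!r} has an empty host set")
        records.append(
            NicheRecord(
                species=str(row.species),
                habit=habit,
                hosts=hosts if hosts else frozenset({"?"}),
                is_outgroup=outgroup,
            )
        )
    return records


def write_step_matrix(costs: np.ndarray, labels: list[str], path) -> None:
    pd.DataFrame(costs, index=labels, columns=labels).to_csv(path, sep="\t")
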