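"""Stage 1: per-donor patient coverage sets via reduced-key joins.

A donor genotype covers a patient genotype when their class-1 mismatch count
is at most ``a`` and their class-2 mismatch count is at most ``b`` (plus any
scenario-specific predicate).  Rather than scanning all donor x patient pairs,
both sides are expanded into *reduced keys*: class-restricted genotype
projections with up to a (class 1) / b (class 2) allele slots dropped.  Two
genotypes share a reduced key with k dropped slots iff their mismatch count in
that class is <= k, so coverage reduces to a hash-join on keys — the inverted
-index realization of a bipartite genotype/key graph in which a donor covers a
patient exactly when a path exists through a shared class-1 key and a shared
class-2 key.

Mismatch semantics: per locus, 2 minus the multiset intersection size of the
two unordered allele pairs, summed over the class's loci (a dropped slot is a
wildcard).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional

from .model import (
    CLASS1_LOCI,
    CLASS2_LOCI,
    LOCUS_ORDER,
    Allele,
    Genotype,
    GenotypePool,
    Locus,
)

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario1Config, Scenario2Config, Scenario3Config

__all__ = [
    "MatchClass",
    "ReducedKey",
    "MatchCriteria",
    "CoverageSets",
    "ConfigurationError",
    "reduce_keys",
    "count_class_mismatches",
    "pair_match_count",
    "build_coverage",
    "oracle_match",
]


class ConfigurationError(ValueError):
    """A scenario was requested without its required parameters."""


class MatchClass(enum.Enum):
    CLASS1 = "class1"
    CLASS2 = "class2"

    @property
    def loci(self) -> tuple[Locus, ...]:
        return CLASS1_LOCI if self is MatchClass.CLASS1 else CLASS2_LOCI

    @property
    def n_slots(self) -> int:
        """z: total allele slots in the class (6 for class 1, 4 for class 2)."""
        return 2 * len(self.loci)


# A key slot holds an Allele or None (the dropped-slot wildcard).
_Slot = Optional[Allele]


@dataclass(frozen=True, slots=True)
class ReducedKey:
    """A class projection of a genotype with ``n_dropped`` slots wildcarded.

    ``slots`` holds one canonical (sorted, wildcard last) pair per class
    locus.  Keys are hashable; equality of keys between a donor and a patient
    certifies a class mismatch count of at most ``n_dropped``.
    """

    class_label: MatchClass
    slots: tuple[tuple[_Slot, _Slot], ...]
    n_dropped: int


def _canon_pair(pair: Iterable[_Slot]) -> tuple[_Slot, _Slot]:
    a, b = sorted(pair, key=lambda x: (x is None, x.name if x is not None else ""))
    return (a, b)


def reduce_keys(g: Genotype, class_label: MatchClass, max_drops: int) -> frozenset[ReducedKey]:
    """All keys obtained by dropping 0..max_drops allele slots from g's class
    projection, canonicalized and deduplicated (homozygous loci make drops of
    either copy coincide)."""
    loci = class_label.loci
    if max_drops > class_label.n_slots:
        raise ValueError(f"max_drops {max_drops} exceeds {class_label.n_slots} slots")
    base = [list(g.pair(locus)) for locus in loci]
    slot_positions = [(i, s) for i in range(len(loci)) for s in (0, 1)]
    keys: set[ReducedKey] = set()
    for k in range(max_drops + 1):
        for dropped in itertools.combinations(slot_positions, k):
            slots: list[list[_Slot]] = [list(pair) for pair in base]
            for i, s in dropped:
                slots[i][s] = None
            keys.add(
                ReducedKey(class_label, tuple(_canon_pair(p) for p in slots), k)
            )
    return frozenset(keys)


def pair_match_count(
    pair_a: tuple[Allele, Allele], pair_b: tuple[Allele, Allele]
) -> int:
    """Multiset intersection size of two unordered allele pairs (0, 1 or 2)."""
    a1, a2 = pair_a
    b1, b2 = pair_b
    if a1 == b1:
        return 2 if a2 == b2 else 1
    # canonical sorting means equal multisets compare slotwise equal
    matches = 0
    remaining = [b1, b2]
    for x in (a1, a2):
        if x in remaining:
            remaining.remove(x)
            matches += 1
    return matches


def count_class_mismatches(d: Genotype, g: Genotype, class_label: MatchClass) -> int:
    """Mismatches between two genotypes within one HLA class; symmetric."""
    return sum(
        2 - pair_match_count(d.pair(locus), g.pair(locus)) for locus in class_label.loci
    )


@dataclass(frozen=True)
class MatchCriteria:
    """Matching condition: mismatch budgets a (class 1) and b (class 2), plus
    an optional clinical scenario that replaces or augments them."""

    a: int = 0
    b: int = 0
    scenario: str = "mismatch_budget"
    scenario1: "Scenario1Config | None" = None
    scenario2: "Scenario2Config | None" = None
    scenario3: "Scenario3Config | None" = None

    def __post_init__(self) -> None:
        if not 0 <= self.a <= MatchClass.CLASS1.n_slots:
            raise ValueError("a must lie in 0..6")
        if not 0 <= self.b <= MatchClass.CLASS2.n_slots:
            raise ValueError("b must lie in 0..4")
        known = ("mismatch_budget", "scenario1", "scenario2", "scenario3")
        if self.scenario not in known:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "scenario1" and self.scenario1 is None:
            raise ConfigurationError("scenario1 requires a Scenario1Config (Bw4 table)")
        if self.scenario == "scenario2" and self.scenario2 is None:
            raise ConfigurationError("scenario2 requires a Scenario2Config")
        if self.scenario == "scenario3" and self.scenario3 is None:
            raise ConfigurationError("scenario3 requires a Scenario3Config")


@dataclass
class CoverageSets:
    """S_j for every donor (or donor variant): the patient indices it covers.

    ``ids`` fixes a deterministic order used for greedy tie-breaking.  For
    scenario 3 the ids enumerate donor *variants* (full and single-allele
    knockouts) with per-variant costs; otherwise one id per donor with unit
    cost.  ``match_counts`` carries the per-pair HLA-A/-B match count needed
    by scenario 2's priority weighting.
    """

    ids: tuple[str, ...]
    sets: dict[str, frozenset[int]]
    donor_of: dict[str, int]
    costs: dict[str, float]
    is_knockout: dict[str, bool]
    match_counts: dict[str, dict[int, int]] | None = None

    def covered_union(self, selected: Iterable[str]) -> set[int]:
        out: set[int] = set()
        for key in selected:
            out |= self.sets[key]
        return out


def _plain_coverage(ids, sets, n_donors=None) -> CoverageSets:
    return CoverageSets(
        ids=tuple(ids),
        sets=sets,
        donor_of={k: int(k[1:]) for k in ids},
        costs={k: 1.0 for k in ids},
        is_knockout={k: False for k in ids},
    )


def _budget_coverage(
    donors: GenotypePool, patients: GenotypePool, a: int, b: int
) -> dict[str, frozenset[int]]:
    idx1: dict[ReducedKey, set[int]] = {}
    idx2: dict[ReducedKey, set[int]] = {}
    for i, (g, _) in enumerate(patients):
        for key in reduce_keys(g, MatchClass.CLASS1, a):
            idx1.setdefault(key, set()).add(i)
        for key in reduce_keys(g, MatchClass.CLASS2, b):
            idx2.setdefault(key, set()).add(i)
    sets: dict[str, frozenset[int]] = {}
    for j, (d, _) in enumerate(donors):
        cand1: set[int] = set()
        for key in reduce_keys(d, MatchClass.CLASS1, a):
            cand1 |= idx1.get(key, set())
        cand2: set[int] = set()
        for key in reduce_keys(d, MatchClass.CLASS2, b):
            cand2 |= idx2.get(key, set())
        sets[f"D{j}"] = frozenset(cand1 & cand2)
    return sets


def _scenario1_coverage(
    donors: GenotypePool, patients: GenotypePool, cfg: "Scenario1Config"
) -> dict[str, frozenset[int]]:
    # Class 1 is unconstrained; class 2 must match fully -> bucket both pools
    # by the exact class-2 projection, then pair opposite Bw4 statuses.
    from .scenarios import bw4_count

    def class2_key(g: Genotype) -> tuple:
        return tuple(g.pair(locus) for locus in MatchClass.CLASS2.loci)

    buckets: dict[tuple, tuple[list[int], list[int]]] = {}
    for i, (g, _) in enumerate(patients):
        pos = bw4_count(g, cfg.bw4_table) >= 1
        bucket = buckets.setdefault(class2_key(g), ([], []))
        bucket[1 if pos else 0].append(i)
    neg_cache: dict[tuple, frozenset[int]] = {}
    pos_cache: dict[tuple, frozenset[int]] = {}
    sets: dict[str, frozenset[int]] = {}
    empty: frozenset[int] = frozenset()
    for j, (d, _) in enumerate(donors):
        key = class2_key(d)
        bucket = buckets.get(key)
        if bucket is None:
            sets[f"D{j}"] = empty
            continue
        donor_pos = bw4_count(d, cfg.bw4_table) >= 1
        if donor_pos:
            if key not in neg_cache:
                neg_cache[key] = frozenset(bucket[0])
            sets[f"D{j}"] = neg_cache[key]
        elif cfg.mismatch_direction == "either":
            if key not in pos_cache:
                pos_cache[key] = frozenset(bucket[1])
            sets[f"D{j}"] = pos_cache[key]
        else:  # donor_positive_patient_negative and donor is Bw4-
            sets[f"D{j}"] = empty
    return sets


def _scenario2_coverage(
    donors: GenotypePool, patients: GenotypePool, cfg: "Scenario2Config"
) -> tuple[dict[str, frozenset[int]], dict[str, dict[int, int]]]:
    # Keys over HLA-A/-B only (class-2 sub-keys removed); drop budget is
    # 4 - min_matches, then the full predicate (required allele, homozygous-
    # donor exclusion) filters the hash-join candidates.
    from .scenarios import scenario2_predicate

    ab_loci = (Locus.A, Locus.B)
    budget = 4 - cfg.min_matches

    def ab_keys(g: Genotype) -> set[tuple]:
        base = [list(g.pair(locus)) for locus in ab_loci]
        positions = [(i, s) for i in range(2) for s in (0, 1)]
        keys: set[tuple] = set()
        for k in range(budget + 1):
            for dropped in itertools.combinations(positions, k):
                slots = [list(p) for p in base]
                for i, s in dropped:
                    slots[i][s] = None
                keys.add(tuple(_canon_pair(p) for p in slots))
        return keys

    idx: dict[tuple, set[int]] = {}
    for i, (g, _) in enumerate(patients):
        if not g.carries(cfg.required_allele):
            continue
        for key in ab_keys(g):
            idx.setdefault(key, set()).add(i)
    sets: dict[str, frozenset[int]] = {}
    counts: dict[str, dict[int, int]] = {}
    for j, (d, _) in enumerate(donors):
        jid = f"D{j}"
        if not d.carries(cfg.required_allele):
            sets[jid] = frozenset()
            counts[jid] = {}
            continue
        cands: set[int] = set()
        for key in ab_keys(d):
            cands |= idx.get(key, set())
        covered: set[int] = set()
        meta: dict[int, int] = {}
        for i in cands:
            ok, mc = scenario2_predicate(d, patients.genotypes[i], cfg)
            if ok:
                covered.add(i)
                meta[i] = mc
        sets[jid] = frozenset(covered)
        counts[jid] = meta
    return sets, counts


def _scenario3_coverage(
    donors: GenotypePool, patients: GenotypePool, cfg: "Scenario3Config"
) -> CoverageSets:
    # Donor variants (full + single-allele knockouts) connect directly to
    # patients: a variant covers a patient iff, per locus, the variant's
    # remaining allele set is a subset of the patient's.  Patients are
    # expanded into all per-locus nonempty allele subsets (<= 3**5 keys) and
    # indexed; each variant is a single lookup.
    from .scenarios import expand_knockouts, variant_id

    idx: dict[tuple, list[int]] = {}
    for i, (g, _) in enumerate(patients):
        per_locus = []
        for pair in g.pairs:
            s = frozenset(pair)
            subsets = [s]
            if len(s) == 2:
                subsets.extend(frozenset((a,)) for a in sorted(s))
            per_locus.append(subsets)
        for combo in itertools.product(*per_locus):
            idx.setdefault(tuple(combo), []).append(i)

    ids: list[str] = []
    sets: dict[str, frozenset[int]] = {}
    donor_of: dict[str, int] = {}
    costs: dict[str, float] = {}
    is_ko: dict[str, bool] = {}
    lookup_cache: dict[tuple, frozenset[int]] = {}
    for j, (d, _) in enumerate(donors):
        for variant in expand_knockouts(d, cfg.cost_ko):
            vid = variant_id(j, variant)
            key = tuple(frozenset(variant.remaining(locus)) for locus in LOCUS_ORDER)
            if key not in lookup_cache:
                lookup_cache[key] = frozenset(idx.get(key, ()))
            ids.append(vid)
            sets[vid] = lookup_cache[key]
            donor_of[vid] = j
            costs[vid] = variant.cost
            is_ko[vid] = variant.knocked_out is not None
    return CoverageSets(tuple(ids), sets, donor_of, costs, is_ko)


def build_coverage(
    donors: GenotypePool, patients: GenotypePool, criteria: MatchCriteria
) -> CoverageSets:
    """Compute S_j for every donor (or donor variant) by reduced-key joins.

    Never an all-pairs scan: candidates come from inverted indexes on shared
    keys, with the scenario predicate applied only to join candidates.
    """
    if len(donors) == 0 or len(patients) == 0:
        raise ValueError("donor and patient pools must be non-empty")
    if criteria.scenario == "mismatch_budget":
        sets = _budget_coverage(donors, patients, criteria.a, criteria.b)
    elif criteria.scenario == "scenario1":
        sets = _scenario1_coverage(donors, patients, criteria.scenario1)
    elif criteria.scenario == "scenario2":
        sets, counts = _scenario2_coverage(donors, patients, criteria.scenario2)
        cov = _plain_coverage([f"D{j}" for j in range(len(donors))], sets)
        cov.match_counts = counts
        return cov
    else:
        return _scenario3_coverage(donors, patients, criteria.scenario3)
    return _plain_coverage([f"D{j}" for j in range(len(donors))], sets)


def oracle_match(d: Genotype, g: Genotype, criteria: MatchCriteria) -> bool:
    """Direct evaluation of the matching condition, with no key construction.

    Used as the independent check of :func:`build_coverage`.  For scenario 3,
    which matches donor *variants*, this answers whether any variant of ``d``
    (full or single-allele knockout) covers ``g``.
    """
    from . import scenarios as sc

    if criteria.scenario == "mismatch_budget":
        return (
            count_class_mismatches(d, g, MatchClass.CLASS1) <= criteria.a
            and count_class_mismatches(d, g, MatchClass.CLASS2) <= criteria.b
        )
    if criteria.scenario == "scenario1":
        return sc.scenario1_predicate(d, g, criteria.scenario1)
    if criteria.scenario == "scenario2":
        ok, _ = sc.scenario2_predicate(d, g, criteria.scenario2)
        return ok
    return any(
        sc.scenario3_predicate(v, g) for v in sc.expand_knockouts(d, criteria.scenario3.cost_ko)
    )
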