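"""Canonical data model for two-field HLA alleles and 5-locus unphased genotypes.

The unit of matching throughout the package is the UMUG (Unphased Multilocus
Unambiguous Genotype): one unordered pair of two-field alleles at each of the
five loci HLA-A, -B, -C, -DQB1 and -DRB1.  Class 1 comprises {A, B, C}
(six allele slots), class 2 comprises {DRB1, DQB1} (four slots).

Genotypes are canonicalized on construction — alleles within a locus are kept
in sorted order — so that equality, hashing and serialization are phase-free
and reproducible.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "LOCUS_ORDER",
    "CLASS1_LOCI",
    "CLASS2_LOCI",
    "Allele",
    "Genotype",
    "GenotypePool",
    "PoolRole",
    "ParseError",
    "parse_allele",
    "parse_genotype",
    "serialize_genotype",
    "is_homozygous_at",
    "merge_genotypes",
]


class ParseError(ValueError):
    """Raised when an allele or genotype string cannot be interpreted."""


class Locus(enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    DQB1 = "DQB1"
    DRB1 = "DRB1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed locus order used for serialization and file layout.
LOCUS_ORDER: tuple[Locus, ...] = (Locus.A, Locus.B, Locus.C, Locus.DQB1, Locus.DRB1)

#: HLA class 1 loci (six allele slots per genotype).
CLASS1_LOCI: tuple[Locus, ...] = (Locus.A, Locus.B, Locus.C)
#: HLA class 2 loci (four allele slots per genotype).
CLASS2_LOCI: tuple[Locus, ...] = (Locus.DRB1, Locus.DQB1)

_LOCUS_BY_TOKEN = {locus.value: locus for locus in Locus}
_LOCUS_INDEX = {locus: i for i, locus in enumerate(LOCUS_ORDER)}


@dataclass(frozen=True, slots=True)
class Allele:
    """A two-field HLA allele, e.g. ``A*02:01``.

    ``name`` is the canonical string and always begins with the locus token
    followed by ``*``; alleles order lexicographically on it.
    """

    locus: Locus
    name: str

    def __lt__(self, other: "Allele") -> bool:
        return self.name < other.name

    def __str__(self) -> str:
        return self.name


def parse_allele(text: str) -> Allele:
    """Parse a two-field allele designation such as ``"A*02:01"``.

    Fields beyond the second (e.g. ``A*02:01:01``) are truncated with a
    warning, since matching operates at two-field resolution.
    """
    token = text.strip()
    if not token or "*" not in token:
        raise ParseError(f"not an HLA allele designation: {text!r}")
    locus_token, _, fields_part = token.partition("*")
    locus = _LOCUS_BY_TOKEN.get(locus_token)
    if locus is None:
        raise ParseError(f"unknown HLA locus {locus_token!r} in {text!r}")
    fields = fields_part.split(":")
    if len(fields) < 2:
        raise ParseError(f"expected two colon-separated fields in {text!r}")
    if len(fields) > 2:
        logger.warning("truncating %r to two-field resolution", token)
        fields = fields[:2]
    if not all(f.isdigit() for f in fields):
        raise ParseError(f"non-numeric allele fields in {text!r}")
    return Allele(locus, f"{locus.value}*{fields[0]}:{fields[1]}")


@dataclass(frozen=True, slots=True)
class Genotype:
    """A 5-locus UMUG: one canonically sorted allele pair per locus.

    ``pairs`` is aligned with :data:`LOCUS_ORDER`.  Construction through
    :meth:`from_mapping`, :func:`parse_genotype` or the synthetic sampler
    guarantees canonical order; equality and hashing are therefore phase-free.
    """

    pairs: tuple[tuple[Allele, Allele], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[Locus, Sequence[Allele]]) -> "Genotype":
        if set(mapping) != set(LOCUS_ORDER):
            missing = set(LOCUS_ORDER) - set(mapping)
            extra = set(mapping) - set(LOCUS_ORDER)
            raise ValueError(f"genotype loci mismatch (missing={missing}, extra={extra})")
        pairs = []
        for locus in LOCUS_ORDER:
            alleles = tuple(mapping[locus])
            if len(alleles) != 2:
                raise ValueError(f"locus {locus} needs exactly two alleles, got {len(alleles)}")
            if any(a.locus is not locus for a in alleles):
                raise ValueError(f"allele from wrong locus in {locus} block: {alleles}")
            pairs.append(tuple(sorted(alleles)))
        return cls(tuple(pairs))

    def pair(self, locus: Locus) -> tuple[Allele, Allele]:
        return self.pairs[_LOCUS_INDEX[locus]]

    def alleles(self) -> Iterator[Allele]:
        for pair in self.pairs:
            yield from pair

    def carries(self, allele: Allele) -> bool:
        return allele in self.pair(allele.locus)

    def __str__(self) -> str:
        return serialize_genotype(self)


def parse_genotype(text: str) -> Genotype:
    """Parse a 5-locus genotype string, e.g. ``"A*01:01+A*02:01^B*..^..."``.

    Locus blocks are separated by ``^`` and the two alleles of a block by
    ``+``.  Blocks may appear in any order but each locus must occur exactly
    once and both alleles of a block must belong to the same locus; the result
    is re-canonicalized (sorted within locus, fixed locus order).
    """
    blocks = [b for b in text.strip().split("^")]
    if len(blocks) != len(LOCUS_ORDER):
        raise ParseError(f"expected {len(LOCUS_ORDER)} locus blocks, got {len(blocks)} in {text!r}")
    mapping: dict[Locus, tuple[Allele, Allele]] = {}
    for block in blocks:
        tokens = block.split("+")
        if len(tokens) != 2:
            raise ParseError(f"locus block {block!r} must contain exactly two alleles")
        a1, a2 = (parse_allele(t) for t in tokens)
        if a1.locus is not a2.locus:
            raise ParseError(f"mixed loci within block {block!r}")
        if a1.locus in mapping:
            raise ParseError(f"duplicate locus {a1.locus} in {text!r}")
        mapping[a1.locus] = (a1, a2)
    if set(mapping) != set(LOCUS_ORDER):
        raise ParseError(f"missing loci {set(LOCUS_ORDER) - set(mapping)} in {text!r}")
    return Genotype.from_mapping(mapping)


def serialize_genotype(g: Genotype) -> str:
    """Canonical string form; ``parse_genotype(serialize_genotype(g)) == g``."""
    return "^".join(f"{p[0].name}+{p[1].name}" for p in g.pairs)


def is_homozygous_at(g: Genotype, locus: Locus) -> bool:
    """True iff both alleles at ``locus`` are identical."""
    a1, a2 = g.pair(locus)
    return a1 == a2


class PoolRole(enum.Enum):
    DONOR = "donor"
    PATIENT = "patient"


@dataclass(frozen=True)
class GenotypePool:
    """Weighted collection of distinct genotypes.

    Weights are occurrence counts (p_i for a patient pool); the total weight
    equals the number of individuals the pool was built from.
    """

    entries: tuple[tuple[Genotype, int], ...]
    role: PoolRole

    def __post_init__(self) -> None:
        seen: set[Genotype] = set()
        for g, w in self.entries:
            if w <= 0:
                raise ValueError("pool weights must be positive integers")
            if g in seen:
                raise ValueError(f"duplicate genotype in pool: {g}")
            seen.add(g)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[Genotype, int]]:
        return iter(self.entries)

    @property
    def genotypes(self) -> tuple[Genotype, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def weights(self) -> tuple[int, ...]:
        return tuple(w for _, w in self.entries)

    @property
    def total_weight(self) -> int:
        return sum(w for _, w in self.entries)


def merge_genotypes(raw: Iterable[Genotype], role: PoolRole) -> GenotypePool:
    """Merge duplicate genotypes into a weighted pool, preserving first-seen order.

    The sum of the resulting weights equals the number of input genotypes.
    """
    counts: Counter[Genotype] = Counter()
    order: list[Genotype] = []
    for g in raw:
        if g not in counts:
            order.append(g)
        counts[g] += 1
    if not order:
        raise ValueError("cannot build a pool from an empty genotype sequence")
    return GenotypePool(tuple((g, counts[g]) for g in order), role)
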