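"""The three clinical matching predicates and the knockout cost model.

Scenario 1 (off-the-shelf NK cells): the donor must be KIR-Bw4-ligand
mismatched to the patient and fully matched in class 2; class 1 is otherwise
unconstrained.  Bw4 status is binary — two genotypes "match in KIR" when both
carry at least one Bw4+ allele or neither does, regardless of copy number.

Scenario 2 (neoantigen-specific TCR T cells restricted to HLA-A*02:01): both
donor and patient must carry the restricting allele; a donor homozygous at
any locus excludes patients who carry that allele (GvHD safeguard); and the
pair must match at >= min_matches of the four HLA-A/-B slots, with an
optional selection priority for full 4/4 matches.

Scenario 3 (polyclonal T-cell infusion): every allele expressed by the donor
product must be present in the patient (the converse need not hold).  A
single donor allele may be knocked out by gene editing to rescue a near-miss,
at a cost of ``cost_ko`` extra donors; selection then minimizes total cost
rather than donor count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import LOCUS_ORDER, Allele, Genotype, Locus, is_homozygous_at, parse_allele
from .matching import MatchClass, count_class_mismatches, pair_match_count
from .population import Bw4Table

__all__ = [
    "Scenario1Config",
    "Scenario2Config",
    "Scenario3Config",
    "DonorVariant",
    "bw4_count",
    "scenario1_predicate",
    "ab_match_count",
    "scenario2_predicate",
    "expand_knockouts",
    "scenario3_predicate",
    "variant_id",
]


@dataclass(frozen=True)
class Scenario1Config:
    bw4_table: Bw4Table
    #: "either": Bw4 presence statuses differ in either direction (default);
    #: "donor_positive_patient_negative": the one-sided missing-ligand rule.
    mismatch_direction: str = "either"

    def __post_init__(self) -> None:
        if self.mismatch_direction not in ("either", "donor_positive_patient_negative"):
            raise ValueError(f"unknown mismatch_direction {self.mismatch_direction!r}")


@dataclass(frozen=True)
class Scenario2Config:
    required_allele: Allele = field(default_factory=lambda: parse_allele("A*02:01"))
    min_matches: int = 3
    prior4: float = 1.0

    def __post_init__(self) -> None:
        if self.min_matches not in (3, 4):
            raise ValueError("min_matches must be 3 or 4")
        if self.prior4 < 1:
            raise ValueError("prior4 must be >= 1")


@dataclass(frozen=True)
class Scenario3Config:
    #: A knockout product costs cost_ko + 1 (one knockout "is worth"
    #: cost_ko regular donors on top of the donor itself).
    cost_ko: float = 10.0

    def __post_init__(self) -> None:
        if self.cost_ko <= 0:
            raise ValueError("cost_ko must be positive")


def bw4_count(g: Genotype, table: Bw4Table) -> int:
    """Number of the four HLA-A/-B allele slots flagged Bw4+ (0..4)."""
    return sum(
        1
        for locus in (Locus.A, Locus.B)
        for allele in g.pair(locus)
        if allele in table
    )


def scenario1_predicate(d: Genotype, g: Genotype, cfg: Scenario1Config) -> bool:
    """KIR-Bw4 ligand mismatch plus full class-2 match; class 1 is free."""
    d_pos = bw4_count(d, cfg.bw4_table) >= 1
    g_pos = bw4_count(g, cfg.bw4_table) >= 1
    if cfg.mismatch_direction == "either":
        mismatched = d_pos != g_pos
    else:
        mismatched = d_pos and not g_pos
    return mismatched and count_class_mismatches(d, g, MatchClass.CLASS2) == 0


def ab_match_count(d: Genotype, g: Genotype) -> int:
    """Matched allele slots over HLA-A and HLA-B (0..4); symmetric."""
    return pair_match_count(d.pair(Locus.A), g.pair(Locus.A)) + pair_match_count(
        d.pair(Locus.B), g.pair(Locus.B)
    )


def scenario2_predicate(
    d: Genotype, g: Genotype, cfg: Scenario2Config
) -> tuple[bool, int]:
    """(eligible, A/B match count).  The count is returned regardless of
    eligibility so callers can use it for priority weighting."""
    matches = ab_match_count(d, g)
    if not (d.carries(cfg.required_allele) and g.carries(cfg.required_allele)):
        return False, matches
    for locus in LOCUS_ORDER:
        if is_homozygous_at(d, locus):
            x = d.pair(locus)[0]
            if x in g.pair(locus):
                return False, matches
    return matches >= cfg.min_matches, matches


@dataclass(frozen=True)
class DonorVariant:
    """A donor product: the genotype as-is, or with one allele knocked out."""

    base: Genotype
    knocked_out: Allele | None
    cost: float

    def __post_init__(self) -> None:
        if self.knocked_out is not None and not self.base.carries(self.knocked_out):
            raise ValueError(f"{self.knocked_out} does not occur in the donor genotype")

    def remaining(self, locus: Locus) -> tuple[Allele, ...]:
        """Alleles expressed at ``locus`` after the (optional) knockout."""
        pair = self.base.pair(locus)
        if self.knocked_out is not None and self.knocked_out.locus is locus:
            # remove a single copy
            return (pair[1],) if pair[0] == self.knocked_out else (pair[0],)
        return pair


def expand_knockouts(d: Genotype, cost_ko: float = 10.0) -> tuple[DonorVariant, ...]:
    """The full variant (cost 1) plus one variant per distinct allele slot
    with that allele removed (cost cost_ko + 1).

    A fully heterozygous donor yields 1 + 10 variants; homozygous loci make
    removals of either copy coincide, so fewer distinct knockouts arise.
    """
    variants = [DonorVariant(d, None, 1.0)]
    seen: set[Allele] = set()
    for locus in LOCUS_ORDER:
        for allele in d.pair(locus):
            if allele not in seen:
                seen.add(allele)
                variants.append(DonorVariant(d, allele, cost_ko + 1.0))
    return tuple(variants)


def scenario3_predicate(v: DonorVariant, g: Genotype) -> bool:
    """True iff every allele expressed by the variant occurs in the patient
    at the same locus; extra patient alleles are permitted."""
    for locus in LOCUS_ORDER:
        patient = g.pair(locus)
        for allele in v.remaining(locus):
            if allele not in patient:
                return False
    return True


def variant_id(donor_index: int, v: DonorVariant) -> str:
    """Stable identifier: ``D12`` for the full product, ``D12!B*05:01`` for a
    knockout of B*05:01."""
    if v.knocked_out is None:
        return f"D{donor_index}"
    return f"D{donor_index}!{v.knocked_out.name}"
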