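"""Genetic model primitives for an F2 intercross.

The toolkit works on diploid F2 populations derived from a cross between two
fully homozygous parents, one carrying the dominant and the other the
recessive allele at every scored locus (the Oregon Wolfe Barley design).
Genotypes are therefore encoded as the *dose* of the dominant-parent allele,
an integer in {0, 1, 2}.  A single dose integer supports both the dominance
collapse (dose >= 1 -> dominant phenotype) and the codominant 1:2:1 marker
classes.

This module holds the domain types (loci, epistasis rules, molecular markers)
and the deterministic genotype -> phenotype classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

from .errors import (
    ConfigError,
    InvalidGenotypeError,
    InvalidInputError,
    InvalidProbabilityError,
)

#: genotype code for a missing observation in call tables
MISSING = "-"

#: marker class labels
SSR_CODOMINANT = "SSR-codominant"
PCR_DOMINANT = "PCR-dominant"


@dataclass(frozen=True)
class LocusSpec:
    """One Mendelian locus with two alleles and complete dominance.

    Parameters
    ----------
    name:
        Gene symbol, e.g. ``"Zeo"`` or ``"Vrs1"``.
    chromosome:
        Chromosome label, e.g. ``"2H"``.
    dominant_allele, recessive_allele:
        Allele symbols (must differ).
    dominant_phenotype, recessive_phenotype:
        Free-text phenotype class labels (must differ), e.g.
        ``"dense spike"`` / ``"lax spike"``.
    """

    name: str
    chromosome: str
    dominant_allele: str
    recessive_allele: str
    dominant_phenotype: str
    recessive_phenotype: str

    def __post_init__(self) -> None:
        if self.dominant_allele == self.recessive_allele:
            raise ConfigError(
                f"locus {self.name!r}: dominant and recessive allele symbols "
                f"must differ (both {self.dominant_allele!r})"
            )
        if self.dominant_phenotype == self.recessive_phenotype:
            raise ConfigError(
                f"locus {self.name!r}: phenotype labels must be distinct"
            )


@dataclass(frozen=True)
class Genotype:
    """Multi-locus genotype: dose of the dominant-parent allele per locus."""

    doses: Mapping[str, int]

    def __post_init__(self) -> None:
        for locus, dose in self.doses.items():
            _check_dose(dose, locus)

    def __getitem__(self, locus: str) -> int:
        return self.doses[locus]


@dataclass(frozen=True)
class EpistasisRule:
    """Recessive epistasis between two unlinked-or-linked loci (9:3:4).

    The epistatic locus (``Lks2`` in barley) masks the hypostatic one
    (``Kap``): a homozygous-recessive epistatic genotype always expresses
    ``masked_phenotype`` regardless of the hypostatic genotype.  Among
    individuals carrying at least one dominant epistatic allele, the
    hypostatic locus segregates normally, giving the 9:3:4 three-class ratio.

    ``leakage_prob`` models the small fraction of double-dominant individuals
    that nevertheless express ``hypostatic_recessive_phenotype`` (10/179 in
    the barley population); it is a per-individual Bernoulli event.
    """

    epistatic_locus: LocusSpec
    hypostatic_locus: LocusSpec
    double_dominant_phenotype: str = "hooded"
    hypostatic_recessive_phenotype: str = "normal-long"
    masked_phenotype: str = "normal-short"
    leakage_prob: float = 10.0 / 179.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.leakage_prob <= 1.0:
            raise InvalidProbabilityError(
                f"leakage_prob must lie in [0, 1], got {self.leakage_prob}"
            )
        labels = {
            self.double_dominant_phenotype,
            self.hypostatic_recessive_phenotype,
            self.masked_phenotype,
        }
        if len(labels) != 3:
            raise ConfigError("epistasis phenotype labels must be distinct")

    @property
    def class_map(self) -> Mapping[Tuple[str, str], str]:
        """The four two-locus genotype classes -> phenotype labels.

        Keys are ``(hypostatic class, epistatic class)`` with classes written
        ``"D_"`` (at least one dominant allele) or ``"dd"``.
        """
        return {
            ("D_", "D_"): self.double_dominant_phenotype,
            ("dd", "D_"): self.hypostatic_recessive_phenotype,
            ("D_", "dd"): self.masked_phenotype,
            ("dd", "dd"): self.masked_phenotype,
        }


@dataclass(frozen=True)
class MarkerSpec:
    """A molecular marker assayed by PCR product length.

    ``SSR-codominant`` markers resolve all three genotype classes (both
    homozygotes and the heterozygote give distinct band patterns);
    ``PCR-dominant`` markers only score presence of the dominant-parent
    allele, so the heterozygote is indistinguishable from the dominant
    homozygote and ``allele_size_R`` is absent.
    """

    name: str
    marker_class: str
    allele_size_D: float
    allele_size_R: Optional[float]
    chromosome: str
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.marker_class not in (SSR_CODOMINANT, PCR_DOMINANT):
            raise ConfigError(
                f"marker {self.name!r}: unknown class {self.marker_class!r}"
            )
        if self.allele_size_D is None or self.allele_size_D <= 0:
            raise ConfigError(f"marker {self.name!r}: allele sizes must be positive")
        if self.marker_class == SSR_CODOMINANT:
            if self.allele_size_R is None or self.allele_size_R <= 0:
                raise ConfigError(
                    f"codominant marker {self.name!r} needs a positive R-allele size"
                )
        elif self.allele_size_R is not None:
            raise ConfigError(
                f"dominant marker {self.name!r} cannot carry an R-allele size "
                "(no distinguishable heterozygote)"
            )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise InvalidProbabilityError(
                f"marker {self.name!r}: missing_rate must lie in [0, 1]"
            )

    @property
    def is_dominant(self) -> bool:
        return self.marker_class == PCR_DOMINANT

    def valid_codes(self) -> frozenset:
        """Genotype-call codes admissible in a column for this marker."""
        if self.is_dominant:
            return frozenset({"D", "B", MISSING})
        return frozenset({"A", "H", "B", MISSING})


def _check_dose(dose: int, where: str = "locus") -> int:
    if dose not in (0, 1, 2):
        raise InvalidGenotypeError(
            f"{where}: allele dose must be 0, 1 or 2, got {dose!r}"
        )
    return int(dose)


def classify_single_locus(genotype_dose: int, locus: LocusSpec) -> str:
    """Phenotype of a single completely dominant locus.

    Dose 1 and 2 are indistinguishable (complete dominance); only the
    homozygous recessive (dose 0) expresses the recessive phenotype.
    """
    dose = _check_dose(genotype_dose, locus.name)
    return locus.dominant_phenotype if dose >= 1 else locus.recessive_phenotype


def classify_awn(
    kap_dose: int,
    lks2_dose: int,
    rule: EpistasisRule,
    leakage_draw: Optional[float] = None,
) -> str:
    """Three-class awn phenotype under recessive epistasis.

    Rules (doses are counts of the dominant allele):

    * ``lks2`` homozygous recessive (dose 0) masks everything ->
      ``masked_phenotype`` ("normal-short");
    * ``kapkap`` with at least one ``Lks2`` allele -> "normal-long";
    * double dominant -> "hooded", unless the leakage event fires
      (``leakage_draw < leakage_prob``), in which case "normal-long".

    In deterministic mode (``leakage_draw is None``) leakage never fires.
    """
    kap = _check_dose(kap_dose, rule.hypostatic_locus.name)
    lks2 = _check_dose(lks2_dose, rule.epistatic_locus.name)
    if lks2 == 0:
        return rule.masked_phenotype
    if kap == 0:
        return rule.hypostatic_recessive_phenotype
    if leakage_draw is not None and leakage_draw < rule.leakage_prob:
        return rule.hypostatic_recessive_phenotype
    return rule.double_dominant_phenotype


def collapse_codominant(counts: Sequence[int]) -> Tuple[int, int]:
    """Convert codominant 1:2:1 class counts to dominant-scored 3:1 counts.

    ``counts`` is ``(n_DD, n_het, n_RR)``; the dominant class pools the
    dominant homozygote with the heterozygote.  Total count is conserved and
    the operation is idempotent on already-collapsed data (with n_het = 0).
    """
    if len(counts) != 3:
        raise InvalidInputError(
            f"expected three codominant class counts, got {len(counts)}"
        )
    n_dd, n_het, n_rr = counts
    for value in (n_dd, n_het, n_rr):
        if int(value) != value or value < 0:
            raise InvalidInputError(
                f"class counts must be non-negative integers, got {counts!r}"
            )
    return int(n_dd) + int(n_het), int(n_rr)
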