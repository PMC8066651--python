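"""Synthetic F2 population generator.

Populations are produced by simulating meiosis along a linkage map: each
gamete starts on a uniformly chosen parental strand per chromosome and
switches strand between adjacent loci with the interval's recombination
fraction, independently per interval (no crossover interference).  Two
independent gametes fuse into each F2 individual.  Because the cross design
puts every dominant allele into one parent, the F1 phase is pure coupling:
one haplotype carries all dominant alleles, the other all recessive ones.

On top of the genotypes the generator lays the observation model of a real
teaching population: dominance (and recessive epistasis with a small leakage
probability) for the morphological traits, codominant A/H/B or dominant D/B
read-out for the molecular markers, a single-major-locus Gaussian mixture for
the quantitative traits, optional per-locus viability weights (segregation
distortion), and missing-completely-at-random masking per column.

:func:`owb_default_config` packages the statistical structure of the Oregon
Wolfe Barley F2 teaching population (n = 303): seven morphological loci,
three codominant SSRs (one mildly distorted) and one dominant PCR marker,
the Vrs1-Zeo-Wst and Lks2-Nud linkage clusters, and bimodal spike-length /
plant-height mixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError
from .genmodel import (
    MISSING,
    PCR_DOMINANT,
    SSR_CODOMINANT,
    EpistasisRule,
    LocusSpec,
    MarkerSpec,
)

#: phenotype-table column names for the two awn observations
AWN_TYPE = "awn_type"
AWN_LENGTH = "awn_length"


@dataclass(frozen=True)
class LinkageMapSpec:
    """Ordered loci per chromosome with adjacent recombination fractions.

    ``chromosomes`` maps a chromosome label to its ordered locus/marker
    names; ``adjacent_r`` gives the recombination fraction for each
    consecutive pair (one fewer than the loci).  Loci on different
    chromosomes assort independently.
    """

    chromosomes: Mapping[str, Tuple[str, ...]]
    adjacent_r: Mapping[str, Tuple[float, ...]]

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for chrom, loci in self.chromosomes.items():
            r = self.adjacent_r.get(chrom)
            if r is None or len(r) != max(len(loci) - 1, 0):
                raise ConfigError(
                    f"chromosome {chrom!r}: need {max(len(loci) - 1, 0)} "
                    f"adjacent r values for {len(loci)} loci"
                )
            for value in r:
                if not 0.0 <= value <= 0.5:
                    raise ConfigError(
                        f"chromosome {chrom!r}: adjacent r {value} outside [0, 0.5]"
                    )
            for name in loci:
                if name in seen:
                    raise ConfigError(
                        f"locus {name!r} appears on both {seen[name]!r} and {chrom!r}"
                    )
                seen[name] = chrom

    @property
    def loci(self) -> Tuple[str, ...]:
        """All map item names in chromosome order."""
        return tuple(n for loci in self.chromosomes.values() for n in loci)

    def chromosome_of(self, name: str) -> str:
        for chrom, loci in self.chromosomes.items():
            if name in loci:
                return chrom
        raise ConfigError(f"{name!r} is not on the linkage map")


@dataclass(frozen=True)
class QuantTraitSpec:
    """Single-major-locus Gaussian mixture for a quantitative trait.

    The trait value of an individual is the mean of its major-locus
    phenotype class (dominant or recessive) plus zero-mean Gaussian noise
    with ``sd_within`` (within-class standard deviation, same units as the
    means).
    """

    name: str
    major_locus: str
    mean_dominant: float
    mean_recessive: float
    sd_within: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.sd_within <= 0:
            raise ConfigError(
                f"quant trait {self.name!r}: sd_within must be positive"
            )


@dataclass(frozen=True)
class F2Population:
    """A simulated (or loaded) F2 population.

    All tables share the same individual index.  ``genotypes`` holds the
    true allele doses (simulation only; absent-as-empty for loaded data),
    ``phenotypes`` the qualitative class labels, ``markers`` the genotype
    calls (A/H/B for codominant, D/B for dominant, "-" missing) and
    ``quantitative`` the numeric trait values (NaN missing).
    """

    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    markers: pd.DataFrame
    quantitative: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.phenotypes.index
        for name, table in (
            ("genotypes", self.genotypes),
            ("markers", self.markers),
            ("quantitative", self.quantitative),
        ):
            if len(table) and not table.index.equals(idx):
                raise InvalidInputError(
                    f"{name} table index does not match phenotype table"
                )

    @property
    def n(self) -> int:
        return len(self.phenotypes)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to simulate (or analyse) one population.

    ``trait_names`` maps a locus name to its phenotype-table column (e.g.
    ``Zeo -> spike_type``); loci without an entry use their own name.  Loci
    consumed by the epistasis rule are reported through the two awn columns
    instead.  ``missing_rates`` is keyed by phenotype/quantitative column
    name; marker missingness lives on each :class:`MarkerSpec`.
    ``viability`` maps a map item to three genotype-class weights (dose 0,
    1, 2) that multiply the sampling probabilities — the segregation
    distortion option; absent means neutral.
    """

    loci: Tuple[LocusSpec, ...]
    linkage_map: LinkageMapSpec
    markers: Tuple[MarkerSpec, ...] = ()
    epistasis: Optional[EpistasisRule] = None
    quant: Tuple[QuantTraitSpec, ...] = ()
    trait_names: Mapping[str, str] = field(default_factory=dict)
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    viability: Mapping[str, Tuple[float, float, float]] = field(default_factory=dict)
    n: int = 303
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        map_items = set(self.linkage_map.loci)
        for locus in self.loci:
            if locus.name not in map_items:
                raise ConfigError(f"locus {locus.name!r} missing from the map")
            if self.linkage_map.chromosome_of(locus.name) != locus.chromosome:
                raise ConfigError(
                    f"locus {locus.name!r} declared on {locus.chromosome!r} but "
                    f"mapped on {self.linkage_map.chromosome_of(locus.name)!r}"
                )
        for marker in self.markers:
            if marker.name not in map_items:
                raise ConfigError(f"marker {marker.name!r} missing from the map")
            if self.linkage_map.chromosome_of(marker.name) != marker.chromosome:
                raise ConfigError(
                    f"marker {marker.name!r} declared on {marker.chromosome!r} but "
                    f"mapped on {self.linkage_map.chromosome_of(marker.name)!r}"
                )
        if self.epistasis is not None:
            for locus in (
                self.epistasis.epistatic_locus,
                self.epistasis.hypostatic_locus,
            ):
                if locus.name not in {l.name for l in self.loci}:
                    raise ConfigError(
                        f"epistasis references unknown locus {locus.name!r}"
                    )
        for qt in self.quant:
            if qt.major_locus not in {l.name for l in self.loci}:
                raise ConfigError(
                    f"quant trait {qt.name!r} references unknown locus "
                    f"{qt.major_locus!r}"
                )
        for name, weights in self.viability.items():
            if name not in map_items:
                raise ConfigError(f"viability weight for unmapped item {name!r}")
            if len(weights) != 3 or any(w < 0 for w in weights) or max(weights) <= 0:
                raise ConfigError(
                    f"viability weights for {name!r} must be three non-negative "
                    "values with a positive maximum"
                )
        for rate in self.missing_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("missing rates must lie in [0, 1]")

    def locus(self, name: str) -> LocusSpec:
        for locus in self.loci:
            if locus.name == name:
                return locus
        raise ConfigError(f"unknown locus {name!r}")

    def trait_column(self, locus_name: str) -> str:
        return dict(self.trait_names).get(locus_name, locus_name)

    def epistatic_locus_names(self) -> Tuple[str, ...]:
        if self.epistasis is None:
            return ()
        return (
            self.epistasis.hypostatic_locus.name,
            self.epistasis.epistatic_locus.name,
        )


def coupling_phase(
    lmap: LinkageMapSpec,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """F1 parental phase for the fully coupling cross design.

    One haplotype carries the dominant allele (coded 1) at every locus, the
    other the recessive allele (coded 0).
    """
    return {
        chrom: (np.ones(len(loci), dtype=int), np.zeros(len(loci), dtype=int))
        for chrom, loci in lmap.chromosomes.items()
    }


def simulate_gamete(
    parent_phase: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    lmap: LinkageMapSpec,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Draw one gamete: per chromosome, a mosaic of the two parental strands.

    The starting strand is uniform; between adjacent loci the strand switches
    with the interval's recombination fraction, independently per interval.
    """
    gamete: Dict[str, np.ndarray] = {}
    for chrom, loci in lmap.chromosomes.items():
        hap0, hap1 = parent_phase[chrom]
        hap0 = np.asarray(hap0)
        hap1 = np.asarray(hap1)
        if hap0.shape != (len(loci),) or hap1.shape != (len(loci),):
            raise InvalidInputError(
                f"chromosome {chrom!r}: phase haplotypes must have "
                f"{len(loci)} loci"
            )
        r = np.asarray(lmap.adjacent_r[chrom], dtype=float)
        strands = np.empty(len(loci), dtype=int)
        strands[0] = rng.integers(0, 2)
        if r.size:
            strands[1:] = rng.random(r.size) < r
            strands = np.cumsum(strands) % 2
        gamete[chrom] = np.where(strands == 0, hap0, hap1)
    return gamete


def _gamete_block(
    lmap: LinkageMapSpec, m: int, rng: np.random.Generator
) -> np.ndarray:
    """m coupling-phase gametes as an (m, n_loci) 0/1 allele matrix."""
    cols: List[np.ndarray] = []
    for chrom, loci in lmap.chromosomes.items():
        r = np.asarray(lmap.adjacent_r[chrom], dtype=float)
        start = rng.integers(0, 2, size=(m, 1))
        if r.size:
            switches = (rng.random((m, r.size)) < r).astype(np.int64)
            strands = np.cumsum(np.hstack([start, switches]), axis=1) % 2
        else:
            strands = start
        cols.append(1 - strands)  # strand 0 carries the dominant haplotype
    return np.hstack(cols)


def _dose_block(
    lmap: LinkageMapSpec,
    m: int,
    rng: np.random.Generator,
    viability: Mapping[str, Tuple[float, float, float]],
) -> np.ndarray:
    """m individuals' doses, thinned by viability weights when configured."""
    doses = _gamete_block(lmap, m, rng) + _gamete_block(lmap, m, rng)
    if not viability:
        return doses
    names = lmap.loci
    weights = np.ones(m)
    for i, name in enumerate(names):
        w = viability.get(name)
        if w is not None:
            weights *= np.asarray(w, dtype=float)[doses[:, i]]
    cap = 1.0
    for w in viability.values():
        cap *= max(w)
    accept = rng.random(m) < weights / cap
    return doses[accept]


def _classify_awn_vec(
    kap: np.ndarray,
    lks2: np.ndarray,
    rule: EpistasisRule,
    leak_draws: Optional[np.ndarray],
) -> np.ndarray:
    """Vectorized three-class awn phenotype; mirrors genmodel.classify_awn."""
    out = np.full(kap.shape, rule.double_dominant_phenotype, dtype=object)
    if leak_draws is not None:
        out[leak_draws < rule.leakage_prob] = rule.hypostatic_recessive_phenotype
    out[kap == 0] = rule.hypostatic_recessive_phenotype
    out[lks2 == 0] = rule.masked_phenotype
    return out


def simulate_f2(
    n: int,
    lmap: LinkageMapSpec,
    loci: Sequence[LocusSpec] = (),
    epistasis: Optional[EpistasisRule] = None,
    markers: Sequence[MarkerSpec] = (),
    quant: Sequence[QuantTraitSpec] = (),
    missing_rates: Optional[Mapping[str, float]] = None,
    viability: Optional[Mapping[str, Tuple[float, float, float]]] = None,
    trait_names: Optional[Mapping[str, str]] = None,
    seed: int = 0,
) -> F2Population:
    """Simulate an F2 population of ``n`` individuals.

    Each individual is the fusion of two independent gametes drawn from the
    coupling-phase F1.  Phenotypes follow the dominance classifiers (the two
    epistasis loci are reported as the awn type/length pair, with the leakage
    Bernoulli applied to double-dominant individuals), codominant markers
    report A/H/B dose classes and dominant markers D/B, quantitative traits
    are class-mean + Gaussian noise, and every observation is independently
    masked to "-" (NaN for quantitative values) with its column's missing
    rate.  The same seed and configuration give a bit-identical population.
    """
    if n < 1:
        raise InvalidInputError(f"population size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    missing_rates = dict(missing_rates or {})
    viability = dict(viability or {})
    trait_names = dict(trait_names or {})
    names = lmap.loci
    col_of = {name: i for i, name in enumerate(names)}

    blocks: List[np.ndarray] = []
    total = 0
    while total < n:
        block = _dose_block(lmap, max(n, 64), rng, viability)
        blocks.append(block)
        total += len(block)
    doses = np.vstack(blocks)[:n]
    index = pd.RangeIndex(1, n + 1, name="id")
    genotypes = pd.DataFrame(doses, index=index, columns=list(names))

    # --- qualitative phenotypes -------------------------------------------
    phen: Dict[str, np.ndarray] = {}
    epi_names = set()
    if epistasis is not None:
        kap_locus = epistasis.hypostatic_locus
        lks_locus = epistasis.epistatic_locus
        epi_names = {kap_locus.name, lks_locus.name}
        kap = doses[:, col_of[kap_locus.name]]
        lks = doses[:, col_of[lks_locus.name]]
        leak = rng.random(n) if epistasis.leakage_prob > 0 else None
        awn3 = _classify_awn_vec(kap, lks, epistasis, leak)
        hooded = awn3 == epistasis.double_dominant_phenotype
        awn_type = np.where(
            hooded, kap_locus.dominant_phenotype, kap_locus.recessive_phenotype
        ).astype(object)
        awn_length = np.full(n, MISSING, dtype=object)
        awn_length[awn3 == epistasis.hypostatic_recessive_phenotype] = (
            lks_locus.dominant_phenotype
        )
        awn_length[awn3 == epistasis.masked_phenotype] = (
            lks_locus.recessive_phenotype
        )
        phen[AWN_TYPE] = awn_type
        phen[AWN_LENGTH] = awn_length
    for locus in loci:
        if locus.name in epi_names:
            continue
        d = doses[:, col_of[locus.name]]
        phen[trait_names.get(locus.name, locus.name)] = np.where(
            d >= 1, locus.dominant_phenotype, locus.recessive_phenotype
        ).astype(object)
    phenotypes = pd.DataFrame(phen, index=index, dtype=object)

    # --- quantitative traits ----------------------------------------------
    qcols: Dict[str, np.ndarray] = {}
    for qt in quant:
        d = doses[:, col_of[qt.major_locus]]
        means = np.where(d >= 1, qt.mean_dominant, qt.mean_recessive)
        qcols[qt.name] = means + rng.normal(0.0, qt.sd_within, size=n)
    quantitative = pd.DataFrame(qcols, index=index, dtype=float)

    # --- molecular markers -------------------------------------------------
    mcols: Dict[str, np.ndarray] = {}
    for marker in markers:
        d = doses[:, col_of[marker.name]]
        if marker.is_dominant:
            calls = np.where(d >= 1, "D", "B").astype(object)
        else:
            calls = np.array(["B", "H", "A"], dtype=object)[d]
        mcols[marker.name] = calls
    marker_table = pd.DataFrame(mcols, index=index, dtype=object)

    # --- missingness (MCAR), one mask draw per column in declared order ----
    for col in phenotypes.columns:
        rate = missing_rates.get(col, 0.0)
        if rate > 0:
            mask = rng.random(n) < rate
            phenotypes.loc[mask, col] = MISSING
    if epistasis is not None:
        # a spike missing the type observation cannot have a length record
        phenotypes.loc[phenotypes[AWN_TYPE] == MISSING, AWN_LENGTH] = MISSING
    for col in quantitative.columns:
        rate = missing_rates.get(col, 0.0)
        if rate > 0:
            mask = rng.random(n) < rate
            quantitative.loc[mask, col] = np.nan
    for marker in markers:
        if marker.missing_rate > 0:
            mask = rng.random(n) < marker.missing_rate
            marker_table.loc[mask, marker.name] = MISSING

    return F2Population(genotypes, phenotypes, marker_table, quantitative)


def simulate_population(
    config: SimulationConfig,
    seed: Optional[int] = None,
    n: Optional[int] = None,
) -> F2Population:
    """Simulate from a bundled :class:`SimulationConfig`."""
    return simulate_f2(
        n=config.n if n is None else n,
        lmap=config.linkage_map,
        loci=config.loci,
        epistasis=config.epistasis,
        markers=config.markers,
        quant=config.quant,
        missing_rates=config.missing_rates,
        viability=config.viability,
        trait_names=config.trait_names,
        seed=config.seed if seed is None else seed,
    )


def within_class_sd(
    pooled_sd: float,
    mean_dominant: float,
    mean_recessive: float,
    p_dominant: float = 0.75,
) -> float:
    """Back-solve the within-class SD of a two-class mixture.

    Pooled variance decomposes as within-class variance plus between-class
    variance ``p (1-p) (mu_D - mu_R)^2`` under class weights ``p : 1-p``
    (3:1 for a dominant major locus in an F2).
    """
    between = p_dominant * (1.0 - p_dominant) * (mean_dominant - mean_recessive) ** 2
    within_var = pooled_sd**2 - between
    if within_var <= 0:
        raise ConfigError(
            "pooled SD is too small for the class-mean separation "
            f"(pooled {pooled_sd}, means {mean_dominant}/{mean_recessive})"
        )
    return math.sqrt(within_var)


# ---------------------------------------------------------------------------
# Oregon Wolfe Barley F2 defaults
# ---------------------------------------------------------------------------

def owb_default_config() -> SimulationConfig:
    """Configuration emulating the OWB barley F2 teaching population.

    Seven morphological loci (five plain 3:1 dominants plus the Kap/Lks2
    recessive-epistasis pair), three codominant SSRs and one dominant PCR
    marker; pairwise recombination fractions estimated in that population
    (Vrs1-Zeo 0.398, Zeo-Wst 0.251, Lks2-Nud 0.10, HVM40-Knox 0.329,
    Knox-Bmac 0.375); leakage 10/179 on the hooded class; quantitative
    spike-length and plant-height mixtures on Zeo with within-class SDs
    back-solved from the published pooled SDs; missing rates and the mild
    Bmac 0310 distortion matched to the observed class counts.
    """
    zeo = LocusSpec("Zeo", "2H", "Zeo", "zeo", "dense spike", "lax spike")
    vrs1 = LocusSpec(
        "Vrs1", "2H", "Vrs1", "vrs1", "two-rowed spike", "six-rowed spike"
    )
    kap = LocusSpec("Kap", "4H", "Kap", "kap", "hooded awn", "normal awn")
    lks2 = LocusSpec("Lks2", "7H", "Lks2", "lks2", "long awn", "short awn")
    nud = LocusSpec(
        "Nud", "7H", "Nud", "nud", "covered caryopsis", "naked caryopsis"
    )
    wst = LocusSpec(
        "Wst", "2H", "Wst", "wst", "non-variegated leaf", "variegated leaf"
    )
    hsh = LocusSpec(
        "Hsh", "4H", "Hsh", "hsh", "hairy leaf sheath", "non-hairy leaf sheath"
    )
    markers = (
        MarkerSpec("Bmac 0310", SSR_CODOMINANT, 176, 138, "4H", 3 / 303),
        MarkerSpec("Bmag 0211", SSR_CODOMINANT, 187, 198, "1H", 5 / 303),
        MarkerSpec("HVM40", SSR_CODOMINANT, 175, 146, "4H", 2 / 303),
        MarkerSpec("Knox-dup", PCR_DOMINANT, 325, None, "4H", 0.0),
    )
    lmap = LinkageMapSpec(
        chromosomes={
            "2H": ("Vrs1", "Zeo", "Wst"),
            "7H": ("Lks2", "Nud"),
            # Knox-dup is completely linked to Kap; Hsh segregates freely
            # from its 4H neighbours in the emulated population (r = 0.5)
            "4H": ("HVM40", "Knox-dup", "Kap", "Bmac 0310", "Hsh"),
            "1H": ("Bmag 0211",),
        },
        adjacent_r={
            "2H": (0.398, 0.251),
            "7H": (0.10,),
            "4H": (0.329, 0.0, 0.375, 0.5),
            "1H": (),
        },
    )
    epistasis = EpistasisRule(
        epistatic_locus=lks2, hypostatic_locus=kap, leakage_prob=10 / 179
    )
    quant = (
        QuantTraitSpec(
            "spike_length_mm",
            "Zeo",
            mean_dominant=54.16,
            mean_recessive=111.95,
            sd_within=within_class_sd(28.54, 54.16, 111.95),
            units="mm",
        ),
        QuantTraitSpec(
            "plant_height_cm",
            "Zeo",
            mean_dominant=87.11,
            mean_recessive=123.80,
            sd_within=within_class_sd(26.57, 87.11, 123.80),
            units="cm",
        ),
    )
    # Bmac 0310 distortion: weights proportional to observed/expected class
    # frequencies in the emulated population ((76, 167, 57) for doses 0/1/2
    # out of 300 against 1:2:1), normalised to a unit maximum
    obs = np.array([76.0, 167.0, 57.0])
    exp = 300.0 * np.array([0.25, 0.5, 0.25])
    w = obs / exp
    w = tuple(float(v) for v in w / w.max())
    return SimulationConfig(
        loci=(zeo, vrs1, kap, lks2, nud, wst, hsh),
        linkage_map=lmap,
        markers=markers,
        epistasis=epistasis,
        quant=quant,
        trait_names={
            "Zeo": "spike_type",
            "Vrs1": "row_number",
            "Nud": "grain_type",
            "Wst": "leaf_variegation",
            "Hsh": "stem_pubescence",
        },
        missing_rates={
            AWN_TYPE: 1 / 303,
            "grain_type": 1 / 303,
            "stem_pubescence": 47 / 303,
        },
        viability={"Bmac 0310": w},
        n=303,
        seed=0,
        alpha=0.05,
    )
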