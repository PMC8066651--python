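"""Goodness-of-fit analysis of segregation ratios.

Observed phenotype (or marker genotype) class counts are tested against
hypothesised Mendelian ratios (3:1, 1:2:1, 9:7, 9:3:4, 9:3:3:1, ...) with the
uncorrected Pearson chi-square statistic.  No Yates continuity correction is
applied anywhere: the classical teaching treatment, and back-computation of
published barley F2 statistics, both use the plain Pearson form.

Reported chi-square values are conventionally rounded to two decimals in
reports; all functions here return full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateRatioError,
    EmptyTableError,
    InconsistentRecordError,
    InvalidInputError,
    InvalidProbabilityError,
)
from .genmodel import MISSING


@dataclass(frozen=True)
class PhenotypeCountTable:
    """Observed class counts for one trait/marker.

    ``labels`` and ``counts`` are aligned; counts are non-negative integers.
    For four-class two-locus tables the counts play the role of the classical
    a1..a4 categories feeding both the chi-square test and recombination
    estimation.
    """

    labels: Tuple[str, ...]
    counts: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise InvalidInputError("labels and counts must have equal length")
        for c in self.counts:
            if int(c) != c or c < 0:
                raise InvalidInputError(
                    f"counts must be non-negative integers, got {self.counts!r}"
                )

    @property
    def n(self) -> int:
        """Total number of classified individuals (N)."""
        return int(sum(self.counts))

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.labels), name="count")


@dataclass(frozen=True)
class SegregationResult:
    """Chi-square goodness-of-fit result against one hypothesised ratio."""

    table: PhenotypeCountTable
    ratio: Tuple[float, ...]
    chi2: float
    df: int
    p_value: float

    @property
    def label(self) -> str:
        return significance_label(self.p_value)

    def ratio_text(self) -> str:
        return ":".join(f"{w:g}" for w in self.ratio)


def chisq_gof(
    observed: PhenotypeCountTable, ratio: Sequence[float]
) -> SegregationResult:
    """Pearson chi-square test of observed counts against a segregation ratio.

    Expected counts are ``N * ratio_i / sum(ratio)``; the statistic is
    ``sum((obs - exp)^2 / exp)`` with ``df = classes - 1`` and an upper-tail
    chi-square p-value.  A ratio weight of zero on any class is refused
    (the statistic would be undefined).
    """
    ratio = tuple(float(w) for w in ratio)
    if len(ratio) != len(observed.counts):
        raise InvalidInputError(
            f"ratio has {len(ratio)} classes but table has {len(observed.counts)}"
        )
    if any(w < 0 for w in ratio) or sum(ratio) <= 0:
        raise DegenerateRatioError(f"ratio weights must be non-negative, got {ratio}")
    if observed.n == 0:
        raise EmptyTableError("cannot test an empty count table (N = 0)")
    if any(w == 0 for w in ratio):
        raise DegenerateRatioError(
            f"ratio {ratio} puts zero expectation on a class"
        )
    obs = np.asarray(observed.counts, dtype=float)
    expected = observed.n * np.asarray(ratio) / sum(ratio)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(observed, ratio, chi2, df, p)


def significance_label(p: float) -> str:
    """Star notation for a p-value: ``***``, ``**``, ``*`` or ``n.s.``.

    Thresholds: p < 0.001 -> ``***``; p < 0.01 -> ``**``; p < 0.05 -> ``*``;
    otherwise non-significant.
    """
    if not 0.0 <= p <= 1.0 or not np.isfinite(p):
        raise InvalidProbabilityError(f"p-value must lie in [0, 1], got {p!r}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def epistasis_reclassify(
    awn_type: Sequence[str],
    awn_length: Sequence[str],
    hooded_label: str = "hooded awn",
    long_label: str = "long awn",
    short_label: str = "short awn",
    class_labels: Tuple[str, str, str] = ("hooded", "normal-long", "normal-short"),
) -> PhenotypeCountTable:
    """Combine awn type and awn length into the three epistatic classes.

    Awn length is defined only for normal-awned individuals; a length record
    on a hooded individual is an inconsistent observation and raises.
    Individuals with missing awn type are dropped; normal individuals with
    missing length are dropped (unclassifiable).  The resulting three-class
    table feeds :func:`chisq_gof` with ratio 9:3:4.
    """
    t = pd.Series(list(awn_type), dtype=object)
    l = pd.Series(list(awn_length), dtype=object)
    if len(t) != len(l):
        raise InvalidInputError("awn type and awn length differ in length")
    t_missing = t.isna() | (t == MISSING)
    l_missing = l.isna() | (l == MISSING)
    bad = (t == hooded_label) & ~l_missing
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise InconsistentRecordError(
            f"individual {idx}: awn length {l.iloc[idx]!r} recorded for a "
            f"hooded spike"
        )
    hooded = int(((t == hooded_label) & ~t_missing).sum())
    normal = ~t_missing & (t != hooded_label)
    n_long = int((normal & (l == long_label)).sum())
    n_short = int((normal & (l == short_label)).sum())
    return PhenotypeCountTable(class_labels, (hooded, n_long, n_short))


def two_locus_dissection(
    marker_calls: Sequence[str],
    awn_class: Sequence[str],
    class_labels: Tuple[str, str, str] = ("hooded", "normal-long", "normal-short"),
) -> PhenotypeCountTable:
    """Dissect the awn epistasis with a completely linked dominant marker.

    ``marker_calls`` are dominant-marker codes ({D, B, -}) for a marker fully
    linked to the hypostatic locus (Knox-dup for *Kap*); ``awn_class`` is the
    three-class awn phenotype.  Individuals are assigned to the four two-locus
    genotype classes expected to segregate 9:3:3:1:

    * ``D_ Lks2_``: marker D and awn hooded *or* long (leaky individuals
      carry the dominant hypostatic allele and are pooled here);
    * ``dd Lks2_``: marker B and awn long;
    * ``D_ lks2lks2``: marker D and awn short;
    * ``dd lks2lks2``: marker B and awn short.
    """
    m = pd.Series(list(marker_calls), dtype=object)
    a = pd.Series(list(awn_class), dtype=object)
    if len(m) != len(a):
        raise InvalidInputError("marker and awn vectors differ in length")
    hooded, long_lbl, short_lbl = class_labels
    ok = m.isin(["D", "B"]) & a.isin(list(class_labels))
    m, a = m[ok], a[ok]
    dom = m == "D"
    lks_dom = a.isin([hooded, long_lbl])
    counts = (
        int((dom & lks_dom).sum()),
        int((~dom & lks_dom).sum()),
        int((dom & ~lks_dom).sum()),
        int((~dom & ~lks_dom).sum()),
    )
    labels = ("D_ Lks2_", "dd Lks2_", "D_ lks2lks2", "dd lks2lks2")
    return PhenotypeCountTable(labels, counts)


def g_statistic(observed: PhenotypeCountTable, ratio: Sequence[float]) -> float:
    """Likelihood-ratio G statistic against a segregation ratio.

    Asymptotically equivalent to the Pearson chi-square; used as an internal
    sanity cross-check, not as the reported statistic.
    """
    obs = np.asarray(observed.counts, dtype=float)
    ratio = np.asarray([float(w) for w in ratio])
    expected = observed.n * ratio / ratio.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    return float(2.0 * terms.sum())
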