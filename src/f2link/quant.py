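"""Quantitative-trait description and major-locus contrasts.

A trait influenced by one major locus in an F2 appears as a mixture of two
phenotype-class distributions in 3:1 proportion (e.g. spike length in the
barley population: short dense-spike plants vs long lax-spike plants, a
clearly bimodal distribution).  The module provides the descriptive summary,
histogram preparation for that mixture, and the Welch two-sample t contrast
between the dominant- and recessive-class individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyVectorError,
    InsufficientDataError,
    InvalidInputError,
)
from .genmodel import MISSING


@dataclass(frozen=True)
class QuantSummary:
    """Descriptive summary of one quantitative trait."""

    mean: float
    se: float
    sd: float
    range: float
    minimum: float
    maximum: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t test between two genotype classes."""

    group_labels: Tuple[str, str]
    group_means: Tuple[float, float]
    group_ns: Tuple[int, int]
    t: float
    df: float
    p_value: float


def _clean(values: Sequence) -> np.ndarray:
    s = pd.Series(list(values), dtype=object)
    s = s.where(s != MISSING)
    arr = pd.to_numeric(s, errors="coerce").to_numpy(dtype=float)
    return arr[np.isfinite(arr)]


def summarize(values: Sequence) -> QuantSummary:
    """Mean, SE, SD (n-1 denominator), range, min, max and N.

    Missing entries (NaN or "-") are dropped; an all-missing vector raises.
    """
    arr = _clean(values)
    if arr.size == 0:
        raise EmptyVectorError("no non-missing values to summarize")
    n = int(arr.size)
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return QuantSummary(
        mean=float(arr.mean()),
        se=sd / np.sqrt(n),
        sd=sd,
        range=float(arr.max() - arr.min()),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        n=n,
    )


def genotype_contrast(
    values: Sequence,
    classes: Sequence[str],
    group_labels: Optional[Tuple[str, str]] = None,
) -> TTestResult:
    """Welch unequal-variance t test of a trait between two phenotype classes.

    ``classes`` assigns each individual to one of two class labels (e.g. the
    dominant and recessive phenotype at the major locus); pairs with either
    the value or the class missing are dropped.  The Welch statistic with
    Welch-Satterthwaite degrees of freedom (possibly non-integer) and a
    two-sided p-value are returned; each group needs at least two values.
    """
    vals = pd.Series(list(values), dtype=object)
    vals = pd.to_numeric(vals.where(vals != MISSING), errors="coerce")
    cls = pd.Series(list(classes), dtype=object)
    cls = cls.where(cls != MISSING)
    if len(vals) != len(cls):
        raise InvalidInputError("values and classes differ in length")
    keep = vals.notna() & cls.notna()
    vals, cls = vals[keep], cls[keep]
    labels = tuple(group_labels) if group_labels else tuple(sorted(cls.unique()))
    if len(labels) != 2:
        raise InvalidInputError(
            f"exactly two class labels required, got {labels!r}"
        )
    g1 = vals[cls == labels[0]].to_numpy(dtype=float)
    g2 = vals[cls == labels[1]].to_numpy(dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise InsufficientDataError(
            f"each class needs >= 2 values (got {len(g1)} {labels[0]!r}, "
            f"{len(g2)} {labels[1]!r})"
        )
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return TTestResult(
        group_labels=labels,
        group_means=(float(g1.mean()), float(g2.mean())),
        group_ns=(len(g1), len(g2)),
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def histogram_bins(
    values: Sequence,
    bin_width: Optional[float] = None,
    bins: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram covering [min, max]; counts conserve N.

    Exactly one of ``bin_width`` or ``bins`` may be given (default: 10 bins).
    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1``.
    """
    arr = _clean(values)
    if arr.size == 0:
        raise EmptyVectorError("no non-missing values to bin")
    if bin_width is not None and bins is not None:
        raise InvalidInputError("give either bin_width or bins, not both")
    lo, hi = float(arr.min()), float(arr.max())
    if bin_width is not None:
        if bin_width <= 0:
            raise InvalidInputError(f"bin width must be positive, got {bin_width}")
        # extend past the maximum so a value on the last edge gets its own bin
        n_bins = int(np.floor((hi - lo) / bin_width)) + 1 if hi > lo else 1
        edges = lo + bin_width * np.arange(n_bins + 1)
    else:
        if bins is None:
            bins = 10
        if bins <= 0:
            raise InvalidInputError(f"bin count must be positive, got {bins}")
        edges = np.linspace(lo, hi if hi > lo else lo + 1.0, bins + 1)
    counts, edges = np.histogram(arr, bins=edges)
    return edges, counts
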