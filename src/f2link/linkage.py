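"""Two-point linkage analysis and map assembly for F2 intercross data.

Linkage between a pair of loci is detected with a Pearson chi-square test of
independence on the joint classification table (2x2 for two dominant-scored
items, 2x3 / 3x3 when codominant markers keep their three genotype classes).

For a significant pair the recombination fraction r is estimated by maximum
likelihood in coupling phase.  With both items scored dominantly the four
joint phenotype classes (a1 = dominant/dominant, a2 and a3 = mixed,
a4 = double recessive, N = a1+a2+a3+a4) have expected F2 frequencies

    (2 + x)/4,  (1 - x)/4,  (1 - x)/4,  x/4        with x = (1 - r)^2.

Setting the score function to zero shows the ML estimate of x is the
non-negative root of the quadratic

    N x^2 + (-a1 + 2 a2 + 2 a3 + a4) x - 2 a4 = 0,

and r = 1 - sqrt(x).  The product of the roots is -2 a4 / N <= 0, so at most
one root is positive; when a4 = 0 the admissible root is max(0, -b/N).
Estimates with r > 0.5 (x below 0.25) indicate repulsion-phase or distorted
data; they are clamped to 0.5 and flagged.

Codominant markers are collapsed to dominant scoring before r estimation so
a single estimator serves every pair; the independence test, by contrast,
keeps the full table (information-preserving default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateMarginError,
    EmptyTableError,
    EstimationFailureError,
    InvalidInputError,
    UndefinedCoincidenceError,
)
from .genmodel import MISSING
from .segregation import significance_label

#: call codes counted as the dominant class when collapsing to 2x2
_DOMINANT_CODES = ("A", "H", "D")
#: canonical row/column orders
_ORDER_3 = ("A", "H", "B")
_ORDER_2 = ("D", "B")


@dataclass(frozen=True)
class ContingencyTable:
    """Joint classification counts for a pair of loci/markers."""

    row_name: str
    col_name: str
    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]
    counts: Tuple[Tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise InvalidInputError("count matrix shape does not match labels")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise InvalidInputError("counts must be non-negative integers")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def n(self) -> int:
        return int(self.array.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.array, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def collapse_to_2x2(self) -> "ContingencyTable":
        """Pool dominant-class codes (A/H or D) on each axis.

        Idempotent on already 2x2 dominant-coded tables.
        """
        frame = self.as_frame()
        row_dom = [l for l in self.row_labels if l in _DOMINANT_CODES]
        col_dom = [l for l in self.col_labels if l in _DOMINANT_CODES]
        if not row_dom or not col_dom:
            raise InvalidInputError(
                "cannot collapse a table without dominant-class codes"
            )
        rows = pd.Series(
            ["D" if l in _DOMINANT_CODES else "B" for l in self.row_labels],
            index=frame.index,
        )
        cols = pd.Series(
            ["D" if l in _DOMINANT_CODES else "B" for l in self.col_labels],
            index=frame.columns,
        )
        pooled = frame.groupby(rows).sum().T.groupby(cols).sum().T
        pooled = pooled.reindex(index=list(_ORDER_2), columns=list(_ORDER_2)).fillna(0)
        return ContingencyTable(
            self.row_name,
            self.col_name,
            _ORDER_2,
            _ORDER_2,
            tuple(tuple(int(v) for v in row) for row in pooled.to_numpy()),
        )

    def coupling_counts(self) -> Tuple[int, int, int, int]:
        """(a1, a2, a3, a4) from the collapsed 2x2 table."""
        arr = self.collapse_to_2x2().array
        return int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1])


@dataclass(frozen=True)
class RecombinationEstimate:
    """Coupling-phase ML estimate of the recombination fraction.

    ``x`` is the admissible quadratic root (expected frequency parameter,
    x = (1-r)^2 at the optimum); ``r`` is the clamped estimate in [0, 0.5];
    ``r_unclamped`` retains the raw value and ``repulsion_warning`` marks
    estimates that exceeded 0.5 before clamping.  Both quadratic roots are
    kept for diagnostics.
    """

    a1: int
    a2: int
    a3: int
    a4: int
    x: float
    r: float
    r_unclamped: float
    roots: Tuple[float, float]
    repulsion_warning: bool

    @property
    def n(self) -> int:
        return self.a1 + self.a2 + self.a3 + self.a4


@dataclass(frozen=True)
class LinkageResult:
    """Pairwise independence test, optionally with an r estimate."""

    pair: Tuple[str, str]
    table: ContingencyTable
    chi2: float
    df: int
    p_value: float
    estimate: Optional[RecombinationEstimate] = None

    @property
    def label(self) -> str:
        return significance_label(self.p_value)

    def involves(self, name: str) -> bool:
        return name in self.pair

    def other(self, name: str) -> str:
        a, b = self.pair
        return b if name == a else a


@dataclass(frozen=True)
class LinkageGroup:
    """One connected component of the pairwise-linkage graph."""

    loci: Tuple[str, ...]
    order: Optional[Tuple[str, ...]]
    edges: Tuple[Tuple[str, str, Optional[float]], ...]  # (a, b, r or None)


@dataclass(frozen=True)
class MapAssembly:
    """Linkage groups with per-group ordering and pairwise r annotations."""

    groups: Tuple[LinkageGroup, ...]
    alpha: float

    def group_of(self, name: str) -> Optional[LinkageGroup]:
        for g in self.groups:
            if name in g.loci:
                return g
        return None


def build_contingency(
    calls1: Sequence[str],
    calls2: Sequence[str],
    name1: str = "locus1",
    name2: str = "locus2",
) -> ContingencyTable:
    """Cross-classify two call vectors, dropping pairwise-missing individuals.

    Calls use the marker coding: ``A``/``H``/``B`` for codominant classes,
    ``D``/``B`` for dominant scoring, ``-`` for missing.  Rows follow the
    first vector.  Individuals missing either call are excluded pairwise.
    """
    s1 = pd.Series(list(calls1), dtype=object)
    s2 = pd.Series(list(calls2), dtype=object)
    if len(s1) != len(s2):
        raise InvalidInputError("call vectors differ in length")
    keep = ~(s1.isna() | s2.isna() | (s1 == MISSING) | (s2 == MISSING))
    s1, s2 = s1[keep], s2[keep]
    if len(s1) == 0:
        raise EmptyTableError(
            f"no jointly observed individuals for {name1} x {name2}"
        )
    tab = pd.crosstab(s1, s2)
    tab = tab.reindex(
        index=_canonical_order(tab.index), columns=_canonical_order(tab.columns)
    )
    return ContingencyTable(
        name1,
        name2,
        tuple(tab.index),
        tuple(tab.columns),
        tuple(tuple(int(v) for v in row) for row in tab.to_numpy()),
    )


def _canonical_order(labels: Iterable[str]) -> List[str]:
    labels = list(labels)
    for order in (_ORDER_3, _ORDER_2):
        if set(labels) <= set(order):
            return [l for l in order if l in labels]
    return sorted(labels)


def chisq_independence(table: ContingencyTable) -> Tuple[float, int, float, str]:
    """Pearson chi-square test of independence (no continuity correction).

    Expected cell counts are ``row_i * col_j / N``; df = (rows-1)(cols-1).
    Tables with an empty row or column margin are refused: independence is
    untestable when a class is unobserved.
    """
    arr = table.array
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateMarginError(
            f"{table.row_name} x {table.col_name}: table must be at least 2x2"
        )
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DegenerateMarginError(
            f"{table.row_name} x {table.col_name}: empty row/column margin"
        )
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p), significance_label(float(p))


def estimate_r_coupling(
    a1: int, a2: int, a3: int, a4: int
) -> RecombinationEstimate:
    """ML recombination fraction from a coupling-phase 2x2 dominant table.

    Solves ``N x^2 + (-a1 + 2 a2 + 2 a3 + a4) x - 2 a4 = 0`` for the root in
    [0, 1] and returns r = 1 - sqrt(x), clamped to [0, 0.5] with
    ``repulsion_warning`` set when the raw estimate exceeds 0.5.
    """
    counts = (a1, a2, a3, a4)
    for c in counts:
        if int(c) != c or c < 0:
            raise InvalidInputError(
                f"joint class counts must be non-negative integers, got {counts!r}"
            )
    a1, a2, a3, a4 = (int(c) for c in counts)
    n = a1 + a2 + a3 + a4
    if n == 0:
        raise EmptyTableError("cannot estimate r from an empty table")
    b = float(-a1 + 2 * a2 + 2 * a3 + a4)
    c = float(-2 * a4)
    disc = b * b - 4.0 * n * c  # = b^2 + 8*N*a4 >= b^2
    sqrt_disc = math.sqrt(disc)
    root_hi = (-b + sqrt_disc) / (2.0 * n)
    root_lo = (-b - sqrt_disc) / (2.0 * n)
    x = root_hi if root_hi > 0 else max(root_hi, 0.0)
    # product of roots is -2*a4/N <= 0: root_hi is the only candidate in [0,1]
    if not -1e-9 <= x <= 1.0 + 1e-9:
        raise EstimationFailureError(
            f"no quadratic root in [0, 1] for counts {counts!r} (roots "
            f"{root_lo:.6g}, {root_hi:.6g})"
        )
    x = min(max(x, 0.0), 1.0)
    r_raw = 1.0 - math.sqrt(x)
    r = min(max(r_raw, 0.0), 0.5)
    return RecombinationEstimate(
        a1, a2, a3, a4, x, r, r_raw, (root_lo, root_hi), r_raw > 0.5
    )


def estimate_r_from_table(table: ContingencyTable) -> RecombinationEstimate:
    """Collapse to 2x2 coupling counts and estimate r."""
    return estimate_r_coupling(*table.coupling_counts())


def analyze_pair(
    calls1: Sequence[str],
    calls2: Sequence[str],
    name1: str,
    name2: str,
    alpha: float = 0.05,
    estimate: bool = True,
) -> LinkageResult:
    """Full two-point analysis of one pair of call vectors.

    The recombination fraction is attached only when the independence test is
    significant at ``alpha`` (estimating r for unlinked pairs is meaningless)
    and ``estimate`` is not disabled (e.g. for epistatic traits whose joint
    phenotype frequencies do not follow the coupling model).
    """
    table = build_contingency(calls1, calls2, name1, name2)
    chi2, df, p, _ = chisq_independence(table)
    est = None
    if estimate and p < alpha:
        est = estimate_r_from_table(table)
    return LinkageResult((name1, name2), table, chi2, df, p, est)


def pairwise_linkage(
    calls: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    no_r_for: Iterable[str] = (),
) -> List[LinkageResult]:
    """All-pairs two-point analysis over a dict of call vectors.

    Pairs with degenerate tables (a class unobserved after pairwise deletion)
    are reported as results with ``chi2 = nan`` and ``p = 1`` so downstream
    map assembly treats them as non-significant rather than failing the scan.
    """
    no_r = set(no_r_for)
    results: List[LinkageResult] = []
    for name1, name2 in combinations(calls.keys(), 2):
        try:
            results.append(
                analyze_pair(
                    calls[name1],
                    calls[name2],
                    name1,
                    name2,
                    alpha=alpha,
                    estimate=name1 not in no_r and name2 not in no_r,
                )
            )
        except (DegenerateMarginError, EmptyTableError):
            empty = ContingencyTable(name1, name2, ("D",), ("D",), ((0,),))
            results.append(
                LinkageResult((name1, name2), empty, float("nan"), 0, 1.0, None)
            )
    return results


def infer_central_locus(
    pair_results: Sequence[LinkageResult], alpha: float = 0.05
) -> Optional[Tuple[str, str, str]]:
    """Order three loci from their three pairwise linkage results.

    * Exactly two significant pairs: the locus shared by both is central
      (classical argument: the outer pair is too far apart to detect).
    * All three significant: the pair with the largest estimated r flanks the
      group, so the remaining locus is central (requires r on all pairs).
    * Fewer than two significant pairs: no ordering (returns None).
    """
    if len(pair_results) != 3:
        raise InvalidInputError("exactly three pairwise results are required")
    loci = sorted({name for res in pair_results for name in res.pair})
    if len(loci) != 3:
        raise InvalidInputError(
            f"results must cover exactly three loci, got {loci}"
        )
    sig = [res for res in pair_results if res.p_value < alpha]
    if len(sig) < 2:
        return None
    if len(sig) == 2:
        shared = set(sig[0].pair) & set(sig[1].pair)
        if len(shared) != 1:
            return None
        central = shared.pop()
        return (sig[0].other(central), central, sig[1].other(central))
    # all three significant: widest pair (largest r) is the outer pair
    with_r = [res for res in sig if res.estimate is not None]
    if len(with_r) != 3:
        return None
    outer = max(with_r, key=lambda res: res.estimate.r)
    central = (set(loci) - set(outer.pair)).pop()
    return (outer.pair[0], central, outer.pair[1])


def coincidence_interference(
    r_ab: float, r_bc: float, r_ac: float
) -> Tuple[float, float]:
    """Coefficient of coincidence and interference for an ordered triple A-B-C.

    Under independent crossovers the outer recombination fraction is
    ``r_ac = r_ab + r_bc - 2 r_ab r_bc``; the coincidence coefficient scales
    the observed shortfall: ``c = (r_ab + r_bc - r_ac) / (2 r_ab r_bc)`` and
    interference is ``I = 1 - c`` (c = 1 means no interference; c = 0 means
    complete interference, additive r).
    """
    for r in (r_ab, r_bc, r_ac):
        if not 0.0 <= r <= 0.5:
            raise InvalidInputError(
                f"recombination fractions must lie in [0, 0.5], got {r}"
            )
    denom = 2.0 * r_ab * r_bc
    if denom == 0.0:
        raise UndefinedCoincidenceError(
            "coincidence undefined when a flanking interval has r = 0"
        )
    c = (r_ab + r_bc - r_ac) / denom
    return c, 1.0 - c


def assemble_map(
    results: Sequence[LinkageResult], alpha: float = 0.05
) -> MapAssembly:
    """Build linkage groups from all pairwise results.

    Loci become graph nodes; pairs significant at ``alpha`` become edges
    annotated with r (when estimated).  Connected components are the linkage
    groups; three-locus components are ordered with
    :func:`infer_central_locus`.  Loci with no significant partner form
    singleton groups.
    """
    graph = nx.Graph()
    by_pair: Dict[frozenset, LinkageResult] = {}
    for res in results:
        graph.add_nodes_from(res.pair)
        by_pair[frozenset(res.pair)] = res
        if res.p_value < alpha:
            r_val = res.estimate.r if res.estimate is not None else None
            graph.add_edge(*res.pair, r=r_val)
    groups = []
    for component in nx.connected_components(graph):
        loci = tuple(sorted(component))
        edges = tuple(
            (a, b, graph.edges[a, b]["r"])
            for a, b in graph.subgraph(component).edges
        )
        order = None
        if len(loci) == 3:
            triple = [
                by_pair[frozenset(pair)]
                for pair in combinations(loci, 2)
                if frozenset(pair) in by_pair
            ]
            if len(triple) == 3:
                order = infer_central_locus(triple, alpha=alpha)
        groups.append(LinkageGroup(loci, order, edges))
    groups.sort(key=lambda g: (-len(g.loci), g.loci))
    return MapAssembly(tuple(groups), alpha)
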