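"""Shared test helpers: independent oracles and small cross builders."""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

from f2link.genmodel import LocusSpec
from f2link.linkage import build_contingency, estimate_r_from_table
from f2link.simulate import LinkageMapSpec, simulate_f2

LOCUS_A = LocusSpec("A", "1", "A", "a", "dom-A", "rec-a")
LOCUS_B = LocusSpec("B", "1", "B", "b", "dom-B", "rec-b")


def two_locus_map(r: float) -> LinkageMapSpec:
    return LinkageMapSpec({"1": ("A", "B")}, {"1": (r,)})


def simulate_two_locus(n: int, r: float, seed: int):
    """Simulated population with two linked dominant loci."""
    return simulate_f2(n, two_locus_map(r), loci=[LOCUS_A, LOCUS_B], seed=seed)


def dominant_table(pop):
    """Collapsed 2x2 contingency table of the two-locus population."""
    d = pop.genotypes
    calls1 = np.where(d["A"] >= 1, "D", "B")
    calls2 = np.where(d["B"] >= 1, "D", "B")
    return build_contingency(calls1, calls2, "A", "B")


def rhat_two_locus(n: int, r: float, seed: int) -> float:
    return estimate_r_from_table(dominant_table(simulate_two_locus(n, r, seed))).r


def grid_ml_r(a1: int, a2: int, a3: int, a4: int) -> float:
    """Grid-search maximiser of the coupling-phase multinomial likelihood.

    Independent oracle for the quadratic-root estimator: maximises
    a1*log(2+x) + (a2+a3)*log(1-x) + a4*log(x) over x in [0, 1] on a coarse
    grid, refines around the argmax, and returns r = 1 - sqrt(x) clamped to
    [0, 0.5].
    """
    xs = np.linspace(0.0, 1.0, 20001)
    ll = xlogy(a1, 2 + xs) + xlogy(a2 + a3, 1 - xs) + xlogy(a4, xs)
    i = int(np.argmax(ll))
    lo = max(xs[i] - 1e-4, 0.0)
    hi = min(xs[i] + 1e-4, 1.0)
    xf = np.linspace(lo, hi, 20001)
    llf = xlogy(a1, 2 + xf) + xlogy(a2 + a3, 1 - xf) + xlogy(a4, xf)
    x_hat = float(xf[int(np.argmax(llf))])
    return float(min(max(1.0 - np.sqrt(x_hat), 0.0), 0.5))


def random_count_vectors(n_vectors: int, seed: int) -> np.ndarray:
    """Random valid (a1, a2, a3, a4) joint count vectors."""
    rng = np.random.default_rng(seed)
    out = rng.integers(0, 151, size=(n_vectors, 4))
    empty = out.sum(axis=1) == 0
    out[empty, 0] = 1
    return out
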