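"""Two-point linkage tests, the quadratic ML estimator and map assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    LOCUS_A,
    LOCUS_B,
    dominant_table,
    grid_ml_r,
    rhat_two_locus,
    simulate_two_locus,
    two_locus_map,
)

from f2link.errors import (
    ConfigError,
    DegenerateMarginError,
    EmptyTableError,
    InvalidInputError,
    UndefinedCoincidenceError,
)
from f2link.genmodel import LocusSpec
from f2link.linkage import (
    ContingencyTable,
    LinkageResult,
    assemble_map,
    build_contingency,
    chisq_independence,
    coincidence_interference,
    estimate_r_coupling,
    infer_central_locus,
    pairwise_linkage,
    analyze_pair,
)
from f2link.simulate import LinkageMapSpec, coupling_phase, simulate_f2, simulate_gamete


class TestBuildContingency:
    def test_two_dominant_items_give_2x2(self):
        t = build_contingency(["D", "D", "B", "B"], ["D", "B", "D", "B"])
        assert t.array.shape == (2, 2)
        assert t.n == 4

    def test_codominant_column_gives_2x3(self):
        t = build_contingency(
            ["D", "D", "B", "B", "D", "B"],
            ["A", "H", "B", "A", "H", "B"],
            "trait",
            "ssr",
        )
        assert t.array.shape == (2, 3)
        assert t.col_labels == ("A", "H", "B")

    def test_pairwise_deletion(self):
        t = build_contingency(["D", "-", "B", "D"], ["D", "D", "-", "B"])
        assert t.n == 2

    def test_no_joint_observations_is_an_error(self):
        with pytest.raises(EmptyTableError):
            build_contingency(["D", "-"], ["-", "B"])

    def test_collapse_is_idempotent_and_conserves_total(self):
        t = build_contingency(
            ["A", "H", "B", "A", "H", "B"], ["D", "D", "D", "B", "B", "B"]
        )
        c = t.collapse_to_2x2()
        assert c.n == t.n
        assert c.collapse_to_2x2().array.tolist() == c.array.tolist()
        assert c.array.sum(axis=1).tolist() == [4, 2]  # A+H pooled


class TestChisqIndependence:
    def test_proportional_table_gives_zero(self):
        t = ContingencyTable("x", "y", ("D", "B"), ("D", "B"), ((90, 30), (30, 10)))
        chi2, df, p, label = chisq_independence(t)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert label == "n.s."

    def test_df_for_2x3(self):
        t = ContingencyTable(
            "x", "y", ("D", "B"), ("A", "H", "B"), ((40, 80, 20), (10, 20, 30))
        )
        _, df, _, _ = chisq_independence(t)
        assert df == 2

    def test_zero_margin_refused(self):
        t = ContingencyTable("x", "y", ("D", "B"), ("D", "B"), ((5, 0), (7, 0)))
        with pytest.raises(DegenerateMarginError):
            chisq_independence(t)

    def test_single_joint_class_refused(self):
        with pytest.raises(DegenerateMarginError):
            chisq_independence(build_contingency(["D", "D"], ["D", "D"]))

    @given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
    @settings(max_examples=100, derandomize=True)
    def test_2x2_equals_squared_phi_coefficient(self, cells):
        """On a 2x2 table, chi2 = N * phi^2 (standardised difference)."""
        a, b, c, d = cells
        t = ContingencyTable("x", "y", ("D", "B"), ("D", "B"), ((a, b), (c, d)))
        chi2, _, _, _ = chisq_independence(t)
        n = a + b + c + d
        phi2 = (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert chi2 == pytest.approx(n * phi2, rel=1e-9)

    def test_power_at_close_linkage(self):
        """Coupling at r = 0.1, n = 300 is detected essentially always."""
        detected = 0
        for seed in range(50):
            t = dominant_table(simulate_two_locus(300, 0.1, seed))
            _, _, p, _ = chisq_independence(t)
            detected += p < 0.001
        assert detected >= 49


class TestEstimateRCoupling:
    def test_independence_anchor(self):
        """Exact 9:3:3:1 counts: the quadratic factors to x = 1/4, r = 1/2."""
        est = estimate_r_coupling(90, 30, 30, 10)
        assert est.x == pytest.approx(0.25, abs=1e-12)
        assert est.r == pytest.approx(0.5, abs=1e-12)
        assert not est.repulsion_warning

    def test_complete_coupling_anchor(self):
        est = estimate_r_coupling(75, 0, 0, 25)
        assert est.x == pytest.approx(1.0, abs=1e-12)
        assert est.r == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        assert estimate_r_coupling(140, 30, 30, 20).r == pytest.approx(
            0.347, abs=5e-4
        )

    @pytest.mark.parametrize("x_pct", [4, 16, 25, 36, 49, 64, 81, 100])
    def test_exact_recovery_from_expected_counts(self, x_pct):
        """Counts at the model's expected frequencies return the generating
        x exactly (r clamps to 0.5 for x below 1/4)."""
        x = x_pct / 100
        n = 400
        a1 = round(n * (2 + x))  # counts scaled by 4N so all are integral
        a2 = a3 = round(n * (1 - x))
        a4 = round(n * x)
        est = estimate_r_coupling(a1, a2, a3, a4)
        assert est.x == pytest.approx(x, abs=1e-12)
        expected_r = min(1 - np.sqrt(x), 0.5)
        assert est.r == pytest.approx(expected_r, abs=1e-12)

    def test_repulsion_pattern_clamped_with_warning(self):
        est = estimate_r_coupling(10, 40, 40, 10)
        assert est.repulsion_warning
        assert est.r == 0.5
        assert est.r_unclamped > 0.5

    def test_monotone_decreasing_in_double_recessives(self):
        """More double recessives means tighter coupling (smaller r),
        holding N and a1 fixed with a2 = a3."""
        previous = 1.0
        for a4 in range(2, 51, 2):
            mixed = (50 - a4) // 2
            est = estimate_r_coupling(150, mixed, mixed, a4)
            assert est.r_unclamped < previous
            previous = est.r_unclamped

    def test_matches_grid_search_likelihood_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            counts = rng.integers(0, 151, size=4)
            if counts.sum() == 0:
                counts[0] = 1
            est = estimate_r_coupling(*(int(c) for c in counts))
            assert est.r == pytest.approx(
                grid_ml_r(*(int(c) for c in counts)), abs=1e-4
            )

    def test_empty_counts_rejected(self):
        with pytest.raises(EmptyTableError):
            estimate_r_coupling(0, 0, 0, 0)
        with pytest.raises(InvalidInputError):
            estimate_r_coupling(-1, 2, 3, 4)

    def test_estimator_consistency(self):
        """Mean absolute bias shrinks with n (consistency check)."""
        bias_small = np.mean(
            [abs(rhat_two_locus(300, 0.25, s) - 0.25) for s in range(40)]
        )
        bias_large = np.mean(
            [abs(rhat_two_locus(3000, 0.25, s) - 0.25) for s in range(40)]
        )
        assert bias_large < bias_small
        # RMSE scales roughly as 1/sqrt(n): expect ~sqrt(10) improvement
        assert bias_large < bias_small / 2


class TestThreePoint:
    @staticmethod
    def _result(a, b, p, r=None):
        est = None
        if r is not None:
            # synthesize counts whose estimate lands at the requested r
            x = (1 - r) ** 2
            n = 400
            est = estimate_r_coupling(
                int(n * (2 + x)), int(n * (1 - x)), int(n * (1 - x)), int(n * x)
            )
        t = ContingencyTable(a, b, ("D",), ("D",), ((0,),))
        return LinkageResult((a, b), t, 10.0, 1, p, est)

    def test_two_significant_pairs_identify_shared_locus(self):
        results = [
            self._result("Vrs1", "Zeo", 0.01, 0.398),
            self._result("Zeo", "Wst", 1e-6, 0.251),
            self._result("Vrs1", "Wst", 0.4),
        ]
        assert infer_central_locus(results) == ("Vrs1", "Zeo", "Wst")

    def test_all_significant_orders_by_largest_r(self):
        results = [
            self._result("A", "B", 1e-4, 0.10),
            self._result("B", "C", 1e-4, 0.20),
            self._result("A", "C", 1e-4, 0.28),
        ]
        assert infer_central_locus(results) == ("A", "B", "C")

    def test_insufficient_significance_gives_no_order(self):
        results = [
            self._result("A", "B", 0.9),
            self._result("B", "C", 0.8),
            self._result("A", "C", 0.7),
        ]
        assert infer_central_locus(results) is None

    def test_wrong_number_of_results_rejected(self):
        with pytest.raises(InvalidInputError):
            infer_central_locus([self._result("A", "B", 0.5)])


class TestCoincidence:
    def test_no_interference(self):
        c, i = coincidence_interference(0.1, 0.2, 0.26)
        assert c == pytest.approx(1.0, abs=1e-12)
        assert i == pytest.approx(0.0, abs=1e-12)

    def test_complete_interference_additive_r(self):
        c, i = coincidence_interference(0.1, 0.2, 0.30)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert i == pytest.approx(1.0, abs=1e-12)

    def test_zero_interval_undefined(self):
        with pytest.raises(UndefinedCoincidenceError):
            coincidence_interference(0.0, 0.2, 0.2)

    def test_against_double_recombinant_counting(self):
        """The simulator's meioses have no interference: counted double
        recombinants match the product expectation and c is near 1."""
        lmap = LinkageMapSpec(
            {"1": ("A", "B", "C")}, {"1": (0.2, 0.3)}
        )
        phase = coupling_phase(lmap)
        rng = np.random.default_rng(5)
        n = 40_000
        rec_ab = rec_bc = rec_ac = doubles = 0
        for _ in range(n):
            g = simulate_gamete(phase, lmap, rng)["1"]
            r1 = g[0] != g[1]
            r2 = g[1] != g[2]
            rec_ab += r1
            rec_bc += r2
            rec_ac += g[0] != g[2]
            doubles += r1 and r2
        r_ab, r_bc, r_ac = rec_ab / n, rec_bc / n, rec_ac / n
        assert doubles / n == pytest.approx(0.2 * 0.3, abs=0.005)
        c, _ = coincidence_interference(r_ab, r_bc, r_ac)
        assert c == pytest.approx(1.0, abs=0.1)


class TestAssembleMap:
    def test_published_significance_pattern_groups(self):
        """The barley Table-6 starring pattern yields the 2H trio with the
        central locus resolved, a 7H pair, and singletons elsewhere."""
        sig = {
            ("Vrs1", "Zeo"): 0.398,
            ("Zeo", "Wst"): 0.251,
            ("Lks2", "Nud"): 0.10,
        }
        names = ["Vrs1", "Zeo", "Wst", "Lks2", "Nud", "Hsh"]
        results = []
        from itertools import combinations

        for a, b in combinations(names, 2):
            r = sig.get((a, b)) or sig.get((b, a))
            if r is not None:
                results.append(TestThreePoint._result(a, b, 1e-5, r))
            else:
                results.append(TestThreePoint._result(a, b, 0.5))
        asm = assemble_map(results, alpha=0.05)
        groups = {g.loci: g for g in asm.groups}
        assert ("Vrs1", "Wst", "Zeo") in groups
        trio = groups[("Vrs1", "Wst", "Zeo")]
        assert trio.order is not None and trio.order[1] == "Zeo"
        assert ("Lks2", "Nud") in groups
        assert ("Hsh",) in groups

    def test_no_significant_pairs_gives_singletons(self):
        results = [
            TestThreePoint._result("A", "B", 0.9),
            TestThreePoint._result("B", "C", 0.9),
            TestThreePoint._result("A", "C", 0.9),
        ]
        asm = assemble_map(results, alpha=0.05)
        assert sorted(g.loci for g in asm.groups) == [("A",), ("B",), ("C",)]

    def test_recovers_simulated_five_locus_chain(self):
        """A 5-locus chromosome at n = 2000 is recovered as one group."""
        names = ("L1", "L2", "L3", "L4", "L5")
        loci = [
            LocusSpec(n, "1", n, n.lower(), f"dom-{n}", f"rec-{n}") for n in names
        ]
        lmap = LinkageMapSpec({"1": names}, {"1": (0.1, 0.2, 0.15, 0.25)})
        recovered = 0
        for seed in range(20):
            pop = simulate_f2(2000, lmap, loci=loci, seed=seed)
            calls = {
                n: np.where(pop.genotypes[n] >= 1, "D", "B") for n in names
            }
            asm = assemble_map(pairwise_linkage(calls, alpha=0.001), alpha=0.001)
            recovered += any(set(g.loci) == set(names) for g in asm.groups)
        assert recovered >= 18

    def test_pair_result_attaches_estimate_only_when_significant(self):
        linked = simulate_two_locus(400, 0.1, seed=3)
        res = analyze_pair(
            np.where(linked.genotypes["A"] >= 1, "D", "B"),
            np.where(linked.genotypes["B"] >= 1, "D", "B"),
            "A",
            "B",
        )
        assert res.p_value < 0.001 and res.estimate is not None
        unlinked = simulate_two_locus(400, 0.5, seed=12)
        res2 = analyze_pair(
            np.where(unlinked.genotypes["A"] >= 1, "D", "B"),
            np.where(unlinked.genotypes["B"] >= 1, "D", "B"),
            "A",
            "B",
        )
        if res2.p_value >= 0.05:
            assert res2.estimate is None
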