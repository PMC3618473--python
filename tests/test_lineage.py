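import numpy as np
import pytest
from scipy import stats as sps

from conftest import manual_call
from coselect.catalog import EventMatrix, LineageMap
from coselect.lineage import (
    LineageInteraction,
    ResidualAssociationResult,
    enumerate_event_lineage_pairs,
    lineage_independence_summary,
    subtract_and_retest,
)
from coselect.lineage import test_event_lineage_association as event_lineage_association


def matrix_from(cells, loci, carriers, lineages):
    values = np.zeros((len(cells), len(loci)), dtype=bool)
    for g, who in carriers.items():
        j = loci.index(g)
        for c in who:
            values[cells.index(c), j] = True
    return EventMatrix(cells, loci, values, LineageMap(lineages))


class TestEnumeratePairs:
    def test_full_cross_product(self):
        cells = [f"L{i}" for i in range(6)]
        lineages = {c: ("colon" if i < 3 else "lung") for i, c in enumerate(cells)}
        carriers = {g: cells for g in ("A", "B", "C")}
        m = matrix_from(cells, ["A", "B", "C"], carriers, lineages)
        pairs = enumerate_event_lineage_pairs(m)
        assert len(pairs) == 6
        assert pairs[("A", "colon")] == 3

    def test_unoccupied_pair_absent(self):
        cells = ["L0", "L1"]
        m = matrix_from(
            cells, ["A"], {"A": ["L0"]}, {"L0": "colon", "L1": "lung"}
        )
        pairs = enumerate_event_lineage_pairs(m)
        assert ("A", "lung") not in pairs

    def test_counts_match_cross_tabulation(self, rng):
        from conftest import random_event_matrix

        m = random_event_matrix(rng, n=50, g=5, lineages=["a", "b", "c"])
        pairs = enumerate_event_lineage_pairs(m)
        for (locus, lin), count in pairs.items():
            expected = sum(
                1
                for c in m.cell_lines
                if m.has_event(c, locus) and m.lineage[c] == lin
            )
            assert count == expected

    def test_requires_lineage_annotations(self, rng):
        from conftest import random_event_matrix

        m = random_event_matrix(rng, n=10, g=2)
        with pytest.raises(ValueError):
            enumerate_event_lineage_pairs(m)


def braf_melanoma_panel():
    """261 tested lines split 154 S / 107 R; 14 melanoma carriers, all S."""
    cells = [f"L{i:03d}" for i in range(261)]
    sensitive = set(cells[:154])
    lineages = {c: ("melanoma" if i < 14 else "other") for i, c in enumerate(cells)}
    m = matrix_from(cells, ["BRAF"], {"BRAF": cells[:14]}, lineages)
    return m, manual_call(cells, sensitive)


class TestLineageAssociationTest:
    def test_all_sensitive_carriers_reach_significance(self):
        # hand-computed oracle: m=14, expected_S=14*154/261=8.2605,
        # chi2=(14-8.2605)^2*(1/8.2605+1/5.7395)=9.73
        m, call = braf_melanoma_panel()
        res = event_lineage_association(m, call, ("BRAF",), "melanoma")
        assert res.count_S == 14 and res.count_R == 0
        chi2_oracle = 9.7276
        chi2 = sps.chi2.isf(res.p_value, 1)
        assert chi2 == pytest.approx(chi2_oracle, abs=0.01)
        assert res.p_value < 0.01 and res.significant

    def test_exactly_proportional_split_gives_p_one(self):
        cells = [f"L{i:02d}" for i in range(20)]
        sensitive = set(cells[:10])
        carriers = cells[8:12]  # 2 in S, 2 in R matches the 10/10 split
        m = matrix_from(
            cells, ["A"], {"A": carriers}, {c: "colon" for c in cells}
        )
        res = event_lineage_association(m, manual_call(cells, sensitive), ("A",), "colon")
        assert res.p_value == pytest.approx(1.0)

    def test_expected_counts_sum_to_carriers(self):
        m, call = braf_melanoma_panel()
        res = event_lineage_association(m, call, ("BRAF",), "melanoma")
        assert res.expected_S + res.expected_R == pytest.approx(res.total)

    def test_min_carriers_gate(self):
        cells = [f"L{i:02d}" for i in range(30)]
        m = matrix_from(
            cells, ["A"], {"A": cells[:2]}, {c: "colon" for c in cells}
        )
        res = event_lineage_association(
            m, manual_call(cells, set(cells[:10])), ("A",), "colon"
        )
        assert not res.tested and res.p_value is None

    def test_null_models_agree_on_direction(self, rng):
        """Both null options point the same way on small carrier tables."""
        for _ in range(40):
            n_s, n_r = int(rng.integers(20, 80)), int(rng.integers(20, 80))
            m_carriers = int(rng.integers(3, 21))
            c_s = int(rng.integers(0, m_carriers + 1))
            cells = [f"L{i:03d}" for i in range(n_s + n_r)]
            sensitive = set(cells[:n_s])
            carriers = cells[:c_s] + cells[n_s : n_s + (m_carriers - c_s)]
            m = matrix_from(
                cells, ["A"], {"A": carriers}, {c: "colon" for c in cells}
            )
            call = manual_call(cells, sensitive)
            gof = event_lineage_association(m, call, ("A",), "colon",
                                                 null="proportional_gof")
            fisher = event_lineage_association(m, call, ("A",), "colon",
                                                    null="fisher_2x2")
            expected_s = m_carriers * n_s / (n_s + n_r)
            gof_dir = np.sign(gof.count_S - expected_s)
            fisher_dir = np.sign(c_s / n_s - (m_carriers - c_s) / n_r)
            if gof_dir != 0 and fisher_dir != 0:
                assert gof_dir == fisher_dir


class TestSubtractAndRetest:
    def test_carriers_confined_to_removed_lineage(self):
        cells = [f"L{i:02d}" for i in range(40)]
        lineages = {c: ("melanoma" if i < 10 else "other") for i, c in enumerate(cells)}
        m = matrix_from(cells, ["A"], {"A": cells[:8]}, lineages)
        call = manual_call(cells, set(cells[:8]))
        res = subtract_and_retest(m, call, ("A",), {"melanoma"})
        assert res.count_S == res.count_R == 0
        assert not res.powered

    def test_subtraction_soundness(self):
        cells = [f"L{i:02d}" for i in range(40)]
        lineages = {c: ("melanoma" if i < 10 else "colon") for i, c in enumerate(cells)}
        m = matrix_from(cells, ["A"], {"A": cells[:20]}, lineages)
        call = manual_call(cells, set(cells[:8]))
        res = subtract_and_retest(m, call, ("A",), {"melanoma"})
        removed_lines = [c for c in cells if lineages[c] == "melanoma"]
        assert res.n_remaining + len(removed_lines) == len(cells)

    def test_anti_leakage_no_removed_lineage_contributes(self):
        cells = [f"L{i:02d}" for i in range(40)]
        lineages = {c: ("melanoma" if i < 10 else "colon") for i, c in enumerate(cells)}
        m = matrix_from(cells, ["A"], {"A": cells}, lineages)
        call = manual_call(cells, set(cells[:15]))
        res = subtract_and_retest(m, call, ("A",), {"melanoma"})
        # every remaining carrier is non-melanoma: counts bounded by colon lines
        assert res.count_S + res.count_R == 30

    def test_empty_remainder_is_unpowered_not_an_error(self):
        cells = [f"L{i:02d}" for i in range(20)]
        m = matrix_from(cells, ["A"], {"A": cells[:5]}, {c: "colon" for c in cells})
        call = manual_call(cells, set(cells[:5]))
        res = subtract_and_retest(m, call, ("A",), {"colon"})
        assert res.n_remaining == 0 and not res.powered

    def test_uniform_lineage_p_values_are_flat(self, rng):
        """With no lineage structure the per-pair p-value distribution is
        approximately uniform (KS < 0.1 pooled over replicates)."""
        ps = []
        for _ in range(100):
            n = 120
            cells = [f"L{i:03d}" for i in range(n)]
            lineage = {c: str(rng.choice(["a", "b", "c", "d"])) for c in cells}
            f = float(rng.uniform(0.3, 0.5))
            carriers = [c for c in cells if rng.random() < f]
            m = matrix_from(cells, ["G"], {"G": carriers}, lineage)
            sens = set(rng.choice(cells, size=40, replace=False))
            call = manual_call(cells, sens)
            for lin in "abcd":
                res = event_lineage_association(m, call, ("G",), lin)
                if res.tested and res.p_value is not None:
                    ps.append(res.p_value)
        ks = sps.kstest(ps, "uniform").statistic
        assert ks < 0.1


class TestIndependenceSummary:
    def _residual(self, loci, p):
        return ResidualAssociationResult(
            loci, "d", frozenset(), 100, 10, 10, p, True, "none", p <= 0.05
        )

    def test_printed_composition(self):
        results = [
            self._residual((f"G{i}", "X"), 0.01 if i < 9 else 0.5) for i in range(27)
        ]
        table = lineage_independence_summary(results, alphas=(0.05,))
        row = table.iloc[0]
        assert row.n_powered == 27 and row.n_significant == 9
        assert row.fraction == pytest.approx(1 / 3)

    def test_empty_exclusion_changes_nothing(self):
        results = [self._residual((f"G{i}",), 0.04) for i in range(5)]
        a = lineage_independence_summary(results)
        b = lineage_independence_summary(results, exclude_loci=[])
        assert a.equals(b)

    def test_exclusion_removes_tuples_containing_locus(self):
        results = [
            self._residual(("TP53", "A"), 0.01),
            self._residual(("B", "C"), 0.01),
        ]
        table = lineage_independence_summary(results, exclude_loci=["TP53"])
        assert table.iloc[0].n_powered == 1

    def test_fractions_match_brute_force(self, rng):
        results = [
            self._residual((f"G{i}",), float(rng.uniform())) for i in range(40)
        ]
        table = lineage_independence_summary(results, alphas=(0.05, 0.10))
        for _, row in table.iterrows():
            expected = sum(1 for r in results if r.p_value <= row.alpha)
            assert row.n_significant == expected


class TestLineageInteractionModel:
    def test_fit_runs_tests_and_subtraction(self, rng):
        cells = [f"L{i:03d}" for i in range(60)]
        lineages = {c: ("melanoma" if i < 15 else f"lin{i % 3}") for i, c in enumerate(cells)}
        carriers = cells[:12] + cells[30:34]
        m = matrix_from(cells, ["BRAF"], {"BRAF": carriers}, lineages)
        call = manual_call(cells, set(cells[:12]))
        res = LineageInteraction(m, call).fit([("BRAF",)])
        assert len(res.residual_results) == 1
        assert ("melanoma") in {r.lineage for r in res.pair_results}
        frame = res.residual_frame()
        assert "removed_lineages" in frame.columns
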