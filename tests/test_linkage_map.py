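"""Two-point estimation, grouping and map ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dartmap import linkage_map as lm
from dartmap import synthetic_data as sd


class TestKosambi:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.25, 25 * np.log(3)), (0.1, 25 * np.log(1.5))],
    )
    def test_values(self, r, expected):
        assert lm.kosambi_cm(r) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            lm.kosambi_cm(0.5)
        with pytest.raises(ValueError):
            lm.kosambi_cm(-0.01)

    @given(st.floats(0.0, 0.49))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, r):
        assert lm.kosambi_r(lm.kosambi_cm(r)) == pytest.approx(r, abs=1e-12)


def _testcross_pair(n, recombinants):
    a = ["1"] * (n // 2) + ["0"] * (n - n // 2)
    b = list(a)
    for i in range(recombinants):
        b[i] = "0" if b[i] == "1" else "1"
    return a, b


class TestEstimateTwoPoint:
    def test_coupling_closed_form(self):
        a, b = _testcross_pair(100, 20)
        est = lm.estimate_two_point(a, b, sd.TESTCROSS_P1, sd.TESTCROSS_P1)
        assert est.r_hat == pytest.approx(0.20, abs=1e-4)
        assert est.lod == pytest.approx(8.3708, abs=1e-3)
        assert "coupling" in est.phase

    def test_identical_vectors(self):
        a, _ = _testcross_pair(100, 0)
        est = lm.estimate_two_point(a, a, sd.TESTCROSS_P1, sd.TESTCROSS_P1)
        assert est.r_hat == pytest.approx(0.0, abs=1e-9)
        assert est.lod == pytest.approx(100 * np.log10(2), abs=1e-6)

    def test_independent_vectors(self):
        a, b = _testcross_pair(100, 50)
        est = lm.estimate_two_point(a, b, sd.TESTCROSS_P1, sd.TESTCROSS_P1)
        assert est.r_hat == pytest.approx(0.5, abs=1e-3)
        assert est.lod == pytest.approx(0.0, abs=1e-6)

    def test_repulsion_phase_detected(self):
        a, b = _testcross_pair(100, 90)
        est = lm.estimate_two_point(a, b, sd.TESTCROSS_P1, sd.TESTCROSS_P1)
        assert est.r_hat == pytest.approx(0.10, abs=1e-4)
        assert "repulsion" in est.phase

    def test_cross_parent_dominant_pair_uninformative(self):
        a, b = _testcross_pair(100, 20)
        est = lm.estimate_two_point(a, b, sd.TESTCROSS_P1, sd.TESTCROSS_P2)
        assert not est.informative
        assert est.lod == 0.0

    def test_too_few_shared_raises(self):
        a, b = _testcross_pair(10, 2)
        with pytest.raises(ValueError):
            lm.estimate_two_point(a, b, sd.TESTCROSS_P1, sd.TESTCROSS_P1)

    def test_mixed_type_pair_recovers_linkage(self):
        """A 3:1 x 1:1 coupling pair carries distance signal through the
        shared parent; a simulated tight pair estimates a small r."""
        lengths = {"Chr01": 2_000_000}  # 4 cM
        spec = sd.CrossSimSpec(
            n_progeny=400, markers_per_chromosome=40, fraction_3to1=0.5,
            fraction_codominant=0.0, missing_rate=0.0, error_rate=0.0,
            kbp_per_cm_truth=500.0, seed=40,
        )
        cross = sd.simulate_cross(lengths, spec)
        truth = cross.truth
        mixed = None
        ids = list(truth.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if {truth.loc[a, "seg_type"], truth.loc[b, "seg_type"]} == {
                    sd.TESTCROSS_P1, sd.INTERCROSS
                } and abs(truth.loc[a, "cm"] - truth.loc[b, "cm"]) < 1.0:
                    mixed = (a, b)
                    break
            if mixed:
                break
        assert mixed is not None
        cols = cross.progeny_columns
        est = lm.estimate_two_point(
            cross.genotypes.loc[mixed[0], cols].tolist(),
            cross.genotypes.loc[mixed[1], cols].tolist(),
            truth.loc[mixed[0], "seg_type"],
            truth.loc[mixed[1], "seg_type"],
        )
        assert est.informative
        assert est.r_hat < 0.1


class TestTwoPointTable:
    def test_agrees_with_scalar_estimator(self, noisy_cross, noisy_two_point):
        tab = noisy_two_point
        cols = noisy_cross.progeny_columns
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(200):
            if checked >= 20:
                break
            i, j = rng.integers(0, len(tab.markers), 2)
            if i == j:
                continue
            ma, mb = tab.markers[i], tab.markers[j]
            est = lm.estimate_two_point(
                noisy_cross.genotypes.loc[ma, cols].tolist(),
                noisy_cross.genotypes.loc[mb, cols].tolist(),
                tab.seg_types[i], tab.seg_types[j],
                error_rate=0.01, min_shared=10,
            )
            if not est.informative:
                assert tab.lod[i, j] == 0.0
                continue
            # the supported likelihood must agree everywhere; the argmax
            # location is only identifiable when the likelihood is peaked
            assert tab.lod[i, j] == pytest.approx(est.lod, abs=0.1, rel=0.02)
            if est.lod >= 3.0:
                assert tab.r_hat[i, j] == pytest.approx(est.r_hat, abs=2e-3)
                checked += 1
        assert checked >= 15  # enough well-identified pairs spot-checked

    def test_symmetric(self, noisy_two_point):
        assert np.allclose(noisy_two_point.r_hat, noisy_two_point.r_hat.T)
        assert np.allclose(noisy_two_point.lod, noisy_two_point.lod.T)


class TestGrouping:
    def _toy_table(self, lod, r):
        m = len(lod)
        return lm.TwoPointTable(
            markers=[f"M{i}" for i in range(m)],
            seg_types=[sd.TESTCROSS_P1] * m,
            r_hat=np.array(r, dtype=float),
            lod=np.array(lod, dtype=float),
            n_shared=np.full((m, m), 100),
            phase_code=np.zeros((m, m), dtype=np.int8),
        )

    def test_transitive_closure(self):
        lod = [[0, 20, 3], [20, 0, 18], [3, 18, 0]]
        r = [[0, 0.1, 0.3], [0.1, 0, 0.1], [0.3, 0.1, 0]]
        groups, singles = lm.group_markers(self._toy_table(lod, r))
        assert groups == [["M0", "M1", "M2"]]
        assert singles == []

    def test_weak_marker_is_singleton(self):
        lod = [[0, 20, 3], [20, 0, 3], [3, 3, 0]]
        r = [[0, 0.1, 0.3], [0.1, 0, 0.3], [0.3, 0.3, 0]]
        groups, singles = lm.group_markers(self._toy_table(lod, r))
        assert groups == [["M0", "M1"]]
        assert singles == ["M2"]

    def test_r_max_gate(self):
        lod = [[0, 20], [20, 0]]
        r = [[0, 0.45], [0.45, 0]]
        groups, singles = lm.group_markers(self._toy_table(lod, r))
        assert groups == [] and set(singles) == {"M0", "M1"}

    def test_simulated_groups_match_chromosomes(self, clean_cross):
        tab = lm.two_point_table(clean_cross.genotypes, clean_cross.truth["seg_type"])
        groups, singles = lm.group_markers(tab)
        big = [g for g in groups if len(g) >= 10]
        assert len(big) == 3
        grouped = 0
        for g in big:
            chroms = clean_cross.truth.loc[g, "chromosome"].unique()
            assert len(chroms) == 1  # never mixes chromosomes
            grouped += len(g)
        assert grouped >= 0.9 * len(tab.markers)


class TestOrdering:
    @pytest.fixture(scope="class")
    def triple(self):
        n = 100
        a = ["1"] * 50 + ["0"] * 50

        def flip(v, idxs):
            w = list(v)
            for i in idxs:
                w[i] = "0" if w[i] == "1" else "1"
            return w

        b = flip(a, range(0, 10))
        c = flip(b, [0] + list(range(10, 19)))
        geno = pd.DataFrame(
            [["1", "0"] + a, ["1", "0"] + b, ["1", "0"] + c],
            index=["A", "B", "C"],
            columns=["P1", "P2"] + [f"I{i}" for i in range(n)],
        )
        types = pd.Series({m: sd.TESTCROSS_P1 for m in "ABC"})
        return lm.two_point_table(geno, types)

    def test_three_marker_order_and_length(self, triple):
        lg = lm.order_group(["A", "B", "C"], triple, mode="full")
        assert lg.markers in (["A", "B", "C"], ["C", "B", "A"])
        assert lg.length_cm == pytest.approx(2 * lm.kosambi_cm(0.1), rel=0.03)

    def test_reversed_input_same_length(self, triple):
        a = lm.order_group(["A", "B", "C"], triple, mode="full")
        b = lm.order_group(["C", "B", "A"], triple, mode="full")
        assert a.length_cm == pytest.approx(b.length_cm, abs=0.2)

    def test_two_marker_group(self, triple):
        lg = lm.order_group(["A", "B"], triple, mode="full")
        assert lg.length_cm == pytest.approx(lm.kosambi_cm(0.0998), abs=0.2)

    def test_singleton_group(self, triple):
        lg = lm.order_group(["A"], triple, mode="full")
        assert lg.markers == ["A"]
        assert lg.positions_cm.tolist() == [0.0]

    def test_positions_non_decreasing_from_zero(self, noisy_two_point):
        groups, _ = lm.group_markers(
            noisy_two_point, lm.MappingParams(assay_error_rate=0.01)
        )
        lg = lm.order_group(
            groups[0], noisy_two_point, mode="full",
            params=lm.MappingParams(assay_error_rate=0.01),
        )
        assert lg.positions_cm[0] == 0.0
        assert (np.diff(lg.positions_cm) >= -1e-9).all()


class TestRecovery:
    @pytest.fixture(scope="class")
    def mapped(self, noisy_cross, noisy_two_point):
        params = lm.MappingParams(assay_error_rate=0.01)
        groups, _ = lm.group_markers(noisy_two_point, params)
        big = [g for g in groups if len(g) >= 20]
        full = [
            lm.order_group(g, noisy_two_point, mode="full", params=params)
            for g in big
        ]
        framework = [
            lm.order_group(g, noisy_two_point, mode="framework", params=params)
            for g in big
        ]
        return full, framework

    def test_order_recovery(self, noisy_cross, mapped):
        full, _ = mapped
        assert len(full) == 3
        for lg in full:
            truth_cm = noisy_cross.truth.loc[lg.markers, "cm"].to_numpy()
            rho = abs(stats.spearmanr(lg.positions_cm, truth_cm).statistic)
            assert rho >= 0.95

    def test_map_length_recovery(self, noisy_cross, mapped):
        full, _ = mapped
        for lg in full:
            truth_cm = noisy_cross.truth.loc[lg.markers, "cm"]
            planted = truth_cm.max() - truth_cm.min()
            assert lg.length_cm == pytest.approx(planted, rel=0.25)

    def test_framework_subset_of_full(self, mapped):
        full, framework = mapped
        for f, w in zip(full, framework):
            assert len(w.markers) <= len(f.markers)
            assert set(w.markers) <= set(f.markers)
            assert set(w.deferred) | set(w.markers) == set(f.markers)

    def test_framework_reduces_short_gaps(self, mapped):
        full, framework = mapped
        gaps_full = np.concatenate([np.diff(f.positions_cm) for f in full])
        gaps_fw = np.concatenate([np.diff(w.positions_cm) for w in framework])
        assert (gaps_fw < 1.0).mean() < (gaps_full < 1.0).mean()
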