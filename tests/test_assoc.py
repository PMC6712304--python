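import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from assocnet import (
    BinaryDataset,
    BinaryFeature,
    ContingencyTable,
    association_scan,
    contingency,
    fisher_exact,
    fisher_pvalue,
    mutual_information,
    pearson_test,
    sign_of_association,
    spearman_test,
)
from assocnet.feature_io import MICROBIAL, MOLECULAR, FeatureTable
from helpers import fisher_oracle

import pandas as pd


def bf(fid, samples, kind=MOLECULAR, mz=None):
    return BinaryFeature(fid, frozenset(samples), kind, mz)


class TestContingency:
    UNIVERSE = [str(i) for i in range(1, 9)]

    def test_identical_sets(self):
        t = contingency(bf("x", "1234"), bf("y", "1234"), self.UNIVERSE)
        assert (t.a, t.b, t.c, t.d) == (4, 0, 0, 4)

    def test_disjoint_sets(self):
        t = contingency(bf("x", "12"), bf("y", "34"), ["1", "2", "3", "4"])
        assert (t.a, t.b, t.c, t.d) == (0, 2, 2, 0)

    def test_empty_molecule(self):
        t = contingency(bf("x", ""), bf("y", "123"), self.UNIVERSE)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 3, 5)

    def test_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            contingency(bf("x", "zz"), bf("y", "1"), self.UNIVERSE)


tables = st.tuples(*(st.integers(0, 12) for _ in range(4)))


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [((4, 0, 0, 4), 2 / 70), ((10, 0, 0, 10), 2 / 184756)],
    )
    def test_perfect_cooccurrence_spot_values(self, table, expected):
        assert fisher_pvalue(ContingencyTable(*table)) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_margin_gives_one(self):
        # molecule present everywhere: only one table fits the margins
        assert fisher_pvalue(ContingencyTable(5, 3, 0, 0)) == pytest.approx(1.0)
        assert fisher_pvalue(ContingencyTable(0, 0, 0, 9)) == pytest.approx(1.0)

    def test_odds_ratio_estimate(self):
        odds, _ = fisher_exact(ContingencyTable(6, 2, 3, 9))
        assert odds == pytest.approx(9.0)
        assert fisher_exact(ContingencyTable(4, 0, 0, 4))[0] == np.inf

    @given(tables)
    def test_matches_exact_enumeration(self, table):
        p = fisher_pvalue(ContingencyTable(*table))
        assert p == pytest.approx(float(fisher_oracle(*table)), rel=1e-9, abs=1e-12)

    @given(tables)
    def test_matches_scipy(self, table):
        a, b, c, d = table
        expected = stats.fisher_exact([[a, b], [c, d]])[1]
        assert fisher_pvalue(ContingencyTable(a, b, c, d)) == pytest.approx(expected, rel=1e-9)

    @given(tables)
    def test_transpose_symmetry(self, table):
        a, b, c, d = table
        assert fisher_pvalue(ContingencyTable(a, b, c, d)) == pytest.approx(
            fisher_pvalue(ContingencyTable(a, c, b, d)), rel=1e-12
        )


class TestSign:
    def test_cooccurrence_is_positive(self):
        assert sign_of_association(ContingencyTable(4, 0, 0, 4)) == "positive"

    def test_avoidance_is_negative(self):
        assert sign_of_association(ContingencyTable(0, 2, 2, 0)) == "negative"

    def test_tie_goes_positive(self):
        assert sign_of_association(ContingencyTable(1, 1, 1, 1)) == "positive"


class TestContinuousTests:
    def test_affine_relation_r_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        r, p = pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_reversed_r_minus_one(self):
        r, _ = pearson_test([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_worked_pearson_example(self):
        r, p = pearson_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)
        assert p == pytest.approx(0.10408803866182778, rel=1e-9)  # 2*P(t_3 > 2.3094)

    def test_constant_vector_skipped(self):
        r, p = pearson_test([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(p)

    def test_spearman_monotone_invariance(self):
        x = np.array([0.1, 1.0, 2.5, 3.0, 7.0])
        rho, _ = spearman_test(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_spearman_worked_example(self):
        rho, p = spearman_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)
        assert p == pytest.approx(0.10408803866182778, rel=1e-9)

    @given(st.lists(st.floats(-100, 100).filter(lambda v: v == 0 or abs(v) > 1e-3),
                    min_size=4, max_size=15, unique=True),
           st.floats(0.1, 5.0))
    def test_spearman_invariant_under_cubing(self, xs, scale):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        y = rng.normal(size=len(xs))
        x = np.asarray(xs) * scale
        if np.ptp(y) == 0:
            return
        rho1, _ = spearman_test(x, y)
        rho2, _ = spearman_test(x**3, y)  # strictly monotone transform
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert pearson_test(x, y) == pytest.approx(stats.pearsonr(x, y), rel=1e-9)
            rho, p = spearman_test(x, y)
            s = stats.spearmanr(x, y)
            assert (rho, p) == pytest.approx((s.statistic, s.pvalue), rel=1e-9)


class TestMutualInformation:
    UNIVERSE = [str(i) for i in range(1, 9)]

    def test_identical_half_cover_is_one_bit(self):
        x = bf("x", "1234")
        y = bf("y", "1234", kind=MICROBIAL)
        assert mutual_information(x, y, self.UNIVERSE) == pytest.approx(1.0)

    def test_empirically_independent_is_zero(self):
        x = bf("x", "1234")
        y = bf("y", "1256", kind=MICROBIAL)
        assert mutual_information(x, y, self.UNIVERSE) == pytest.approx(0.0, abs=1e-12)

    def test_empty_set_zero(self):
        assert mutual_information(bf("x", ""), bf("y", "123"), self.UNIVERSE) == 0.0

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(2)
        universe = [str(i) for i in range(30)]
        for _ in range(25):
            sx = frozenset(rng.choice(universe, rng.integers(0, 30), replace=False))
            sy = frozenset(rng.choice(universe, rng.integers(0, 30), replace=False))
            x, y = bf("x", sx), bf("y", sy, kind=MICROBIAL)
            mi = mutual_information(x, y, universe)
            assert mi >= 0.0
            assert mi == pytest.approx(mutual_information(y, x, universe), rel=1e-12)


class TestAssociationScan:
    def _dataset(self, n=40, present=15):
        samples = tuple(f"s{i}" for i in range(n))
        shared = frozenset(samples[:present])
        mol = BinaryFeature("m", shared, MOLECULAR, 100.0)
        mic = BinaryFeature("a", shared, MICROBIAL)
        return BinaryDataset(samples=samples, molecules=[mol], microbes=[mic])

    def test_identical_features_make_one_positive_edge(self):
        edges = association_scan(self._dataset(), test="fisher", threshold=1e-10)
        assert len(edges) == 1
        (e,) = edges
        assert e.sign == "positive"
        # oracle: table (15, 0, 0, 25)
        assert e.p_value == pytest.approx(float(fisher_oracle(15, 0, 0, 25)), rel=1e-9)

    def test_threshold_zero_keeps_nothing(self):
        assert association_scan(self._dataset(), test="fisher", threshold=0.0) == []

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            association_scan(self._dataset(), test="chi2")

    def test_deterministic_rerun(self, planted_dataset):
        *_, dataset, _ = planted_dataset
        e1 = association_scan(dataset, test="fisher", threshold=1e-4)
        e2 = association_scan(dataset, test="fisher", threshold=1e-4)
        assert [(e.molecule_id, e.microbe_id, e.p_value) for e in e1] == [
            (e.molecule_id, e.microbe_id, e.p_value) for e in e2
        ]
        assert e1 == sorted(e1, key=lambda e: (e.molecule_id, e.microbe_id))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_pure_null_finds_nothing_at_stringent_threshold(self, seed):
        from assocnet import SimulationConfig, make_binary_dataset, simulate

        cfg = SimulationConfig(seed=seed)  # 200 samples, 100x50, no planting
        microbial, molecular, _ = simulate(cfg)
        dataset = make_binary_dataset(microbial, molecular, 0, 0)
        assert association_scan(dataset, test="fisher", threshold=1e-10) == []

    def test_continuous_scan_matches_per_pair_scipy(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(15)]
        mol = FeatureTable(
            data=pd.DataFrame(rng.lognormal(2, 1, (4, 15)), index=list("wxyz"),
                              columns=samples),
            kind=MOLECULAR,
            meta=pd.DataFrame({"mz": [100.0, 200.0, 300.0, 400.0]},
                              index=list("wxyz")),
        )
        mic = FeatureTable(
            data=pd.DataFrame(rng.lognormal(2, 1, (3, 15)), index=list("abc"),
                              columns=samples),
            kind=MICROBIAL,
        )
        for test, func in (("pearson", stats.pearsonr), ("spearman", stats.spearmanr)):
            edges = association_scan(
                test=test, threshold=None, molecular_table=mol, microbial_table=mic
            )
            assert len(edges) == 12
            for e in edges:
                ref = func(mol.data.loc[e.molecule_id], mic.data.loc[e.microbe_id])
                assert e.statistic == pytest.approx(ref[0], rel=1e-9)
                assert e.p_value == pytest.approx(ref[1], rel=1e-9)

    def test_mi_scan_agrees_with_scalar_mi(self, planted_dataset):
        *_, dataset, _ = planted_dataset
        edges = association_scan(dataset, test="mutual_information", threshold=0.2)
        assert edges, "planted pairs should clear 0.2 bits"
        for e in edges[:5]:
            mol = next(m for m in dataset.molecules if m.feature_id == e.molecule_id)
            mic = next(m for m in dataset.microbes if m.feature_id == e.microbe_id)
            assert e.statistic == pytest.approx(
                mutual_information(mol, mic, dataset.samples), rel=1e-12
            )
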