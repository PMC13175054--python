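"""Weir-Cockerham variance components, multilocus theta and pairwise F_ST."""

import numpy as np
import pytest

from strpopgen.fstats import (
    PairwiseFst,
    VarianceComponents,
    _counts_by_population,
    ht_hs_fst,
    multilocus_theta,
    pairwise_fst,
    wc_components,
    wc_components_from_counts,
    wc_f_within,
)
from strpopgen.simulate import Locus, SimulationConfig, simulate

from .conftest import build_table


def wc84_loop_oracle(genos, pops):
    """Independent scalar transcription of the WC84 per-allele estimators."""
    labels = sorted(set(pops))
    r = len(labels)
    alleles = sorted({a for g in genos for a in g})
    n = [sum(1 for p in pops if p == lab) for lab in labels]
    N = sum(n)
    nbar = N / r
    nc = (N - sum(ni * ni for ni in n) / N) / (r - 1)
    A = B = C = 0.0
    for al in alleles:
        p_i, h_i = [], []
        for lab, ni in zip(labels, n):
            g = [genos[k] for k in range(len(genos)) if pops[k] == lab]
            cnt = sum(int(x == al) + int(y == al) for x, y in g)
            p_i.append(cnt / (2 * ni))
            h_i.append(sum(1 for x, y in g if x != y and al in (x, y)) / ni)
        pbar = sum(ni * pi for ni, pi in zip(n, p_i)) / N
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_i)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h_i)) / N
        A += (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        B += (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        C += hbar / 2
    return A, B, C


TOY_POP1 = [(100, 100), (100, 102), (102, 102), (100, 100), (100, 102)]
TOY_POP2 = [(102, 102), (100, 102), (102, 102), (102, 102), (100, 102)]


def toy_table():
    rows = [(f"p1_{i}", 2001, "F", ("X", "X"), [g]) for i, g in enumerate(TOY_POP1)]
    rows += [(f"p2_{i}", 2002, "F", ("X", "X"), [g]) for i, g in enumerate(TOY_POP2)]
    return build_table(["L"], rows)


class TestComponents:
    def test_hand_computed_toy_frozen_values(self):
        """2 pops x 5 individuals, 2 alleles: values fixed by an independent
        scalar evaluation of the WC84 formulas."""
        table = toy_table()
        vc = wc_components(table, "L", table.birth_years)
        assert vc.a == pytest.approx(0.11, abs=1e-12)
        assert vc.b == pytest.approx(0.05, abs=1e-12)
        assert vc.c == pytest.approx(0.40, abs=1e-12)
        assert vc.theta == pytest.approx(0.1964285714285714, abs=1e-12)
        f = wc_f_within(table, "L", table.birth_years)
        assert f == pytest.approx(1 - 0.40 / 0.45, abs=1e-12)

    def test_matches_loop_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            npop = int(rng.integers(2, 5))
            genos, pops = [], []
            for p in range(npop):
                for _ in range(int(rng.integers(3, 12))):
                    genos.append(tuple(sorted(rng.integers(0, 5, size=2))))
                    pops.append(p)
            n, ac, hc = _counts_by_population(np.array(genos), np.array(pops))
            got = wc_components_from_counts(n, ac, hc)
            want = wc84_loop_oracle(genos, pops)
            assert got == pytest.approx(want, abs=1e-12)

    def test_theta_invariant_under_relabeling_and_permutation(self):
        table = toy_table()
        base = wc_components(table, "L", table.birth_years).theta
        # permute individuals
        rng = np.random.default_rng(1)
        perm = rng.permutation(table.n_records)
        shuffled = table.subset(perm)
        assert wc_components(shuffled, "L", shuffled.birth_years).theta == pytest.approx(
            base, abs=1e-14
        )
        # relabel alleles (order-reversing map to check label independence)
        relabeled = table.copy()
        a = relabeled.alleles
        swapped = np.where(a == 100, 300, np.where(a == 102, 100, a))
        relabeled.alleles[:] = np.sort(swapped, axis=-1)
        assert wc_components(
            relabeled, "L", relabeled.birth_years
        ).theta == pytest.approx(base, abs=1e-14)

    def test_fixed_differences_give_theta_one(self):
        rows = [(f"a{i}", 2001, "F", ("X", "X"), [(100, 100)]) for i in range(20)]
        rows += [(f"b{i}", 2002, "F", ("X", "X"), [(102, 102)]) for i in range(20)]
        table = build_table(["L"], rows)
        assert wc_components(table, "L", table.birth_years).theta == pytest.approx(
            1.0, abs=1e-12
        )

    def test_all_heterozygote_toy_has_negative_f(self):
        rows = [(f"a{i}", 2001, "F", ("X", "X"), [(100, 102)]) for i in range(10)]
        rows += [(f"b{i}", 2002, "F", ("X", "X"), [(100, 102)]) for i in range(10)]
        table = build_table(["L"], rows)
        assert wc_f_within(table, "L", table.birth_years) < 0

    def test_small_population_excluded_with_warning(self):
        rows = [(f"a{i}", 2001, "F", ("X", "X"), [(100, 102)]) for i in range(5)]
        rows += [(f"b{i}", 2002, "F", ("X", "X"), [(100, 100)]) for i in range(5)]
        rows += [("lone", 2003, "F", ("X", "X"), [(102, 102)])]
        table = build_table(["L"], rows)
        with pytest.warns(UserWarning, match="2003"):
            vc = wc_components(table, "L", table.birth_years)
        assert np.isfinite(vc.theta)
        with pytest.raises(ValueError, match="usable populations"):
            one = table.subset(table.birth_years != 2002)
            wc_components(one, "L", np.where(one.birth_years == 2001, 0, 1))


class TestMultilocus:
    def test_single_locus_identity_and_symmetry(self):
        vc = VarianceComponents("L", 0.1, 0.2, 0.7)
        assert multilocus_theta([vc]) == pytest.approx(vc.theta)
        assert multilocus_theta([vc, vc, vc]) == pytest.approx(vc.theta)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        v1 = VarianceComponents("L1", 0.1, 0.0, 0.9)   # theta 0.1
        v2 = VarianceComponents("L2", 0.3, 0.0, 0.2)   # theta 0.6
        pooled = multilocus_theta([v1, v2])
        assert pooled == pytest.approx(0.4 / 1.5)
        assert pooled != pytest.approx((0.1 + 0.6) / 2)


class TestPairwise:
    def test_null_split_theta_near_zero(self):
        panel = [Locus(f"L{i}", tuple(100 + 2 * j for j in range(8))) for i in range(11)]
        cfg = SimulationConfig(
            seed=9, panel=panel, cohort_sizes={2001: 2000, 2002: 2000},
            dirichlet_alpha=5.0, f_drift=0.0,
        )
        table, _ = simulate(cfg)
        matrix = pairwise_fst(table)
        assert abs(matrix.theta.loc[2001, 2002]) < 0.002

    def test_three_cohorts_symmetric(self):
        panel = [Locus("L", tuple(100 + 2 * j for j in range(4)))]
        cfg = SimulationConfig(
            seed=2, panel=panel,
            cohort_sizes={2001: 50, 2002: 50, 2003: 50}, dirichlet_alpha=3.0,
        )
        table, _ = simulate(cfg)
        matrix = pairwise_fst(table)
        t = matrix.theta
        assert t.shape == (3, 3)
        assert np.allclose(t.values, t.values.T, equal_nan=True)
        assert np.isnan(np.diag(t.values)).all()
        assert len(matrix.per_pair_components) == 3

    def test_single_cohort_is_error(self):
        panel = [Locus("L", (100, 102))]
        cfg = SimulationConfig(seed=3, panel=panel, cohort_sizes={2001: 30})
        table, _ = simulate(cfg)
        with pytest.raises(ValueError, match="cohorts"):
            PairwiseFst().fit(table)

    def test_floor_and_csv_layout(self, tmp_path):
        panel = [Locus("L", tuple(100 + 2 * j for j in range(6)))]
        cfg = SimulationConfig(
            seed=4, panel=panel, cohort_sizes={2001: 300, 2002: 300},
            dirichlet_alpha=5.0,
        )
        table, _ = simulate(cfg)
        matrix = pairwise_fst(table)
        floored = matrix.floored()
        assert (floored.fillna(0).values >= 0).all()
        path = tmp_path / "fst.csv"
        matrix.to_csv(path, floor_negative=True)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("birth_year,2001,2002")
        assert lines[1].split(",")[1] == ""  # blank diagonal

    def test_nei_ratio_tracks_theta_across_drift_grid(self):
        panel = [Locus(f"L{i}", tuple(100 + 2 * j for j in range(8))) for i in range(11)]
        thetas, neis = [], []
        for i, F in enumerate((0.002, 0.01, 0.05)):
            for rep in range(4):
                cfg = SimulationConfig(
                    seed=100 + 10 * i + rep, panel=panel,
                    cohort_sizes={2001: 1500, 2002: 1500},
                    dirichlet_alpha=5.0, f_drift=F,
                )
                table, _ = simulate(cfg)
                thetas.append(pairwise_fst(table).theta.loc[2001, 2002])
                neis.append(ht_hs_fst(table, table.birth_years))
        corr = np.corrcoef(thetas, neis)[0, 1]
        assert corr > 0.99
        # monotone differentiation in the grid means
        means = [np.mean(thetas[i * 4:(i + 1) * 4]) for i in range(3)]
        assert means[0] < means[1] < means[2]
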