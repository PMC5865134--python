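"""Generator correctness: lattices, stratified populations, spatial fields,
and the Poisson count model with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from carmap import (
    DEFAULT_BASELINE_RATES,
    STRATA,
    SimulationTruth,
    case_records,
    generate_covariates,
    generate_lattice,
    generate_population,
    simulate_counts,
    simulate_spatial_effects,
)


class TestLattice:
    @pytest.mark.parametrize(
        "rows,cols,n,degree_checks",
        [
            (2, 2, 4, {0: 3, 3: 3}),            # complete Queen graph on 2x2
            (1, 5, 5, {0: 1, 2: 2, 4: 1}),      # path graph: ends have 1 nbr
            (8, 10, 80, {0: 3, 11: 8}),         # corner 3, interior 8
        ],
    )
    def test_queen_degrees(self, rows, cols, n, degree_checks):
        lat = generate_lattice(rows, cols)
        assert lat.n_regions == n
        assert len(set(lat.region_ids)) == n
        ns = lat.queen_neighbors()
        deg = ns.degrees()
        for idx, expect in degree_checks.items():
            assert deg[idx] == expect

    def test_tiles_without_overlap(self, lattice_2x2):
        total = sum(p.area for p in lattice_2x2.polygons)
        assert total == pytest.approx(4.0)
        assert lattice_2x2.polygons[0].intersection(lattice_2x2.polygons[3]).area == 0.0

    def test_deterministic(self):
        a, b = generate_lattice(3, 3), generate_lattice(3, 3)
        assert a.region_ids == b.region_ids
        assert all(p.equals(q) for p, q in zip(a.polygons, b.polygons))

    @pytest.mark.parametrize("rows,cols", [(0, 5), (3, -1), (1, 3)])
    def test_rejects_bad_dimensions(self, rows, cols):
        with pytest.raises(ValueError):
            generate_lattice(rows, cols)


class TestPopulation:
    def test_deterministic_under_seed(self, lattice_2x2):
        a = generate_population(lattice_2x2, (500, 900), seed=5)
        b = generate_population(lattice_2x2, (500, 900), seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_range_fixes_totals(self, lattice_2x2):
        pop = generate_population(lattice_2x2, (1000, 1000), seed=1)
        assert (pop.sum(axis=1) == 1000).all()

    def test_partition_identity_and_nonnegative(self, lattice_8x10):
        pop = generate_population(lattice_8x10, (100, 5000), seed=2)
        assert list(pop.columns) == list(STRATA)
        assert (pop >= 0).all().all()
        totals = pop.sum(axis=1)
        assert totals.between(100, 5000).all()

    def test_rejects_tiny_totals(self, lattice_2x2):
        with pytest.raises(ValueError):
            generate_population(lattice_2x2, (10, 50), seed=0)


class TestCovariates:
    @staticmethod
    def _neighbour_corr(lattice, values, ns):
        pairs = [
            (values[i], values[j])
            for i in range(ns.n)
            for j in ns.neighbors[i]
            if i < j
        ]
        a = np.array(pairs)
        return np.corrcoef(a[:, 0], a[:, 1])[0, 1]

    def test_independent_field_uncorrelated(self, lattice_8x10):
        ns = lattice_8x10.queen_neighbors()
        rs = [
            self._neighbour_corr(
                lattice_8x10,
                generate_covariates(lattice_8x10, 1, 0.0, seed)["x1"].to_numpy(),
                ns,
            )
            for seed in range(5)
        ]
        assert abs(np.mean(rs)) < 0.2

    def test_smoothed_field_positively_correlated(self, lattice_8x10):
        ns = lattice_8x10.queen_neighbors()
        rs = [
            self._neighbour_corr(
                lattice_8x10,
                generate_covariates(lattice_8x10, 1, 0.9, seed)["x1"].to_numpy(),
                ns,
            )
            for seed in range(5)
        ]
        assert np.mean(rs) > 0.4

    def test_reproducible_and_validated(self, lattice_2x2):
        a = generate_covariates(lattice_2x2, 2, 0.5, seed=9)
        b = generate_covariates(lattice_2x2, 2, 0.5, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            generate_covariates(lattice_2x2, 1, 1.0, seed=0)
        with pytest.raises(ValueError):
            generate_covariates(lattice_2x2, 0, 0.5, seed=0)


class TestSpatialEffects:
    def test_component_sums_zero(self, lattice_8x10):
        ns = lattice_8x10.queen_neighbors()
        u, _ = simulate_spatial_effects(ns, 4.0, 4.0, seed=3)
        assert abs(u.sum()) < 1e-9

    def test_huge_tau_v_kills_noise(self, lattice_2x2):
        _, v = simulate_spatial_effects(lattice_2x2.queen_neighbors(), 1.0, 1e12, seed=4)
        assert np.max(np.abs(v)) < 1e-4

    def test_v_variance_matches_precision(self):
        # pool 10,000 v draws (250 fields on a 40-region lattice)
        lat = generate_lattice(4, 10)
        ns = lat.queen_neighbors()
        tau_v = 5.0
        vs = np.concatenate(
            [simulate_spatial_effects(ns, 1.0, tau_v, seed=s)[1] for s in range(250)]
        )
        assert vs.size == 10_000
        assert np.var(vs) == pytest.approx(1.0 / tau_v, rel=0.10)

    def test_icar_density_matches_dense_oracle(self):
        # On <= 10 regions: -2 log density (up to constant) of a draw must
        # equal tau_u * u'(D-W)u computed from the dense Laplacian.
        lat = generate_lattice(2, 5)
        ns = lat.queen_neighbors()
        tau_u = 3.0
        u, _ = simulate_spatial_effects(ns, tau_u, 1.0, seed=11)
        lap = ns.laplacian()
        quad_dense = float(u @ lap @ u)
        # independent pairwise-difference computation of the quadratic form
        quad_pairs = sum(
            (u[i] - u[j]) ** 2
            for i in range(ns.n)
            for j in ns.neighbors[i]
            if i < j
        )
        assert quad_dense == pytest.approx(quad_pairs, abs=1e-10)
        w, vecs = np.linalg.eigh(lap)
        pos = w > 1e-10
        y = vecs[:, pos].T @ u
        log_dens_unnorm = -0.5 * tau_u * np.sum(w[pos] * y**2)
        assert -2.0 * log_dens_unnorm == pytest.approx(tau_u * quad_dense, abs=1e-9)

    def test_rejects_bad_inputs(self, lattice_2x2):
        ns = lattice_2x2.queen_neighbors()
        with pytest.raises(ValueError):
            simulate_spatial_effects(ns, -1.0, 1.0, seed=0)


def _null_truth(n):
    return SimulationTruth(tau_u=1.0, tau_v=1.0, u=np.zeros(n), v=np.zeros(n))


class TestCounts:
    def test_null_model_centres_on_expected(self, lattice_2x2):
        pop = generate_population(lattice_2x2, (5000, 9000), seed=6)
        truth = _null_truth(4)
        ratios = [
            simulate_counts(pop, truth, None, seed=s).region_table.pipe(
                lambda t: t.observed.sum() / t.expected.sum()
            )
            for s in range(1000)
        ]
        assert 0.98 <= np.mean(ratios) <= 1.02

    def test_zero_expected_gives_zero_observed(self):
        pop = pd.DataFrame(
            [np.zeros(18, dtype=int), np.full(18, 100)],
            index=["A", "B"], columns=list(STRATA),
        )
        sim = simulate_counts(pop, _null_truth(2), None, seed=7)
        row = sim.region_table.set_index("region_id")
        assert row.loc["A", "expected"] == 0.0
        assert row.loc["A", "observed"] == 0

    def test_category_effect_shifts_mean(self, lattice_2x2):
        pop = generate_population(lattice_2x2, (20000, 20000), seed=8)
        beta = 0.5
        truth = SimulationTruth(
            tau_u=1.0, tau_v=1.0, u=np.zeros(4), v=np.zeros(4),
            beta={"g": np.array([0.0, beta])},
        )
        design = pd.DataFrame({"g": [0, 0, 1, 1]}, index=pop.index)
        ratios = []
        for s in range(200):
            t = simulate_counts(pop, truth, design, seed=s).region_table
            exposed = t.observed[2:].sum() / t.expected[2:].sum()
            baseline = t.observed[:2].sum() / t.expected[:2].sum()
            ratios.append(exposed / baseline)
        assert np.mean(ratios) == pytest.approx(np.exp(beta), rel=0.02)

    def test_reproducible_integer_counts(self, lattice_2x2):
        pop = generate_population(lattice_2x2, (1000, 3000), seed=9)
        a = simulate_counts(pop, _null_truth(4), None, seed=10)
        b = simulate_counts(pop, _null_truth(4), None, seed=10)
        pd.testing.assert_frame_equal(a.region_table, b.region_table)
        assert (a.stratum_cases >= 0).all().all()
        assert a.stratum_cases.to_numpy().dtype.kind == "i"
        # aggregates agree both ways
        assert (a.stratum_cases.sum(axis=1).to_numpy() == a.region_table.observed.to_numpy()).all()
        assert (a.stratum_cases.sum(axis=0) == a.state_cases).all()

    def test_null_sir_centred_at_one(self, lattice_8x10):
        pop = generate_population(lattice_8x10, (20000, 60000), seed=12)
        sirs = np.concatenate(
            [
                (lambda t: (t.observed / t.expected).to_numpy())(
                    simulate_counts(pop, _null_truth(80), None, seed=s).region_table
                )
                for s in range(10)
            ]
        )
        mc_se = sirs.std(ddof=1) / np.sqrt(sirs.size)
        assert abs(sirs.mean() - 1.0) < 2 * mc_se

    def test_rejects_negative_rates(self, lattice_2x2):
        pop = generate_population(lattice_2x2, (1000, 1000), seed=1)
        truth = _null_truth(4)
        truth.baseline_rates = DEFAULT_BASELINE_RATES * -1.0
        with pytest.raises(ValueError):
            simulate_counts(pop, truth, None, seed=0)


def test_case_records_match_counts(lattice_2x2):
    pop = generate_population(lattice_2x2, (3000, 5000), seed=2)
    sim = simulate_counts(pop, _null_truth(4), None, seed=3)
    rec = case_records(sim.stratum_cases, seed=4)
    assert len(rec) == sim.region_table.observed.sum()
    assert set(rec.type.unique()) <= {"hypoglycaemia", "hyperglycaemia"}
    assert rec.age.between(0, 99).all()
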