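import numpy as np
import pytest

import brushflow as bf
from brushflow.coating import CoatingConfiguration
from brushflow.structure import (classify_conformation, exposed_far_beads,
                                 gyration_radius, is_exposed, non_normalized_rdf,
                                 orientation_distribution, scaling_exponent)


def make_config(chains, box=(10.0, 10.0, 20.0), a0=0.156):
    return CoatingConfiguration(chains=[np.asarray(c, dtype=float) for c in chains],
                                box=box, wall_z=(0.0, box[2]), graft_lattice_a=2.5,
                                bond_length=0.15, bead_radius=a0, degree=1)


class TestRDF:
    def test_single_pair_single_bin(self):
        config = make_config([[[5, 5, 10], [5.15, 5, 10]]])
        rdf = non_normalized_rdf(config, r_max=1.0, bin_width=0.01)
        nonzero = np.nonzero(rdf.counts)[0]
        assert len(nonzero) == 1
        assert abs(rdf.r[nonzero[0]] - 0.15) <= 0.01

    def test_coating_first_peak_at_bond_length(self, coating14):
        rdf = non_normalized_rdf(coating14, r_max=1.0, bin_width=0.005, r_min=0.05)
        assert rdf.first_peak == pytest.approx(0.15, abs=0.005)

    def test_pair_count_conservation(self, rng):
        # sum over bins recovers the brute-force pair count within r_max
        pts = np.column_stack([rng.uniform(0, 10, 60), rng.uniform(0, 10, 60),
                               rng.uniform(3, 17, 60)])
        config = make_config([pts])
        r_max, bw = 2.0, 0.1
        rdf = non_normalized_rdf(config, r_max=r_max, bin_width=bw)
        shells = 4.0 * np.pi * rdf.r**2 * bw
        recovered = np.sum(rdf.counts * shells) * len(pts) / 2.0
        brute = 0
        for i in range(60):
            for j in range(i + 1, 60):
                d = pts[i] - pts[j]
                d[0] -= 10 * round(d[0] / 10)
                d[1] -= 10 * round(d[1] / 10)
                if np.linalg.norm(d) < r_max:
                    brute += 1
        assert recovered == pytest.approx(brute, abs=1e-9)

    def test_flat_for_uniform_ideal_gas(self, rng):
        # counts per shell volume approximate the number density, flat in r
        n_pts, box = 500, (8.0, 8.0, 15.6)
        pts = np.column_stack([rng.uniform(0, box[0], n_pts),
                               rng.uniform(0, box[1], n_pts),
                               rng.uniform(0, box[2], n_pts)])
        rho = n_pts / (box[0] * box[1] * box[2])
        config = make_config([pts], box=box)
        # shells large enough for decent pair statistics
        rdf = non_normalized_rdf(config, r_max=2.0, bin_width=0.25, r_min=0.75)
        assert np.all(np.abs(rdf.counts / rho - 1.0) < 0.3)
        assert np.mean(rdf.counts) / rho == pytest.approx(1.0, abs=0.12)

    def test_bad_bin_width_rejected(self, coating14):
        with pytest.raises(ValueError):
            non_normalized_rdf(coating14, bin_width=0.0)


class TestOrientation:
    def test_aligned_pairs_fill_first_bin(self):
        chains = [[[x, 5.0, 10.0], [x + 0.15, 5.0, 10.0]] for x in (1.0, 3.0, 5.0)]
        config = make_config(chains)
        dist = orientation_distribution(config, shell_radius=0.15, bins=9)
        assert dist.f[0] > 0
        assert np.all(dist.f[1:] == 0)

    def test_isotropic_directions_give_flat_distribution(self, rng):
        # MC oracle: isotropic unit vectors have a uniform projected angle
        n_pairs = 10000
        side = int(np.ceil(np.sqrt(n_pairs)))
        centers = np.array([(2.0 * (k % side), 2.0 * (k // side), 10.0)
                            for k in range(n_pairs)])
        v = rng.normal(size=(n_pairs, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        chains = [np.array([c, c + 0.15 * d]) for c, d in zip(centers, v)]
        config = make_config(chains, box=(2.0 * side, 2.0 * side, 20.0))
        dist = orientation_distribution(config, shell_radius=0.15, bins=6,
                                        slab_tol=1.0)
        # ~1700 independent pairs per bin -> 3 sigma ~ 0.073
        assert np.all(np.abs(dist.f - 1.0) < 0.08)

    def test_mean_of_normalized_f_is_one(self, coating14):
        dist = orientation_distribution(coating14, shell_radius=0.15)
        assert dist.f.mean() == pytest.approx(1.0)

    def test_empty_shell_warns(self):
        config = make_config([[[1, 1, 10], [1, 1, 12]]])
        with pytest.warns(UserWarning, match="empty"):
            dist = orientation_distribution(config, shell_radius=0.15)
        assert dist.n_pairs == 0


class TestExposure:
    def test_lone_pair_is_exposed(self):
        beads = np.array([[0, 0, 10], [1.0, 0, 10]])
        assert is_exposed(0, 1, beads, (50.0, 50.0), d_occ=0.312)

    def test_midpoint_blocker_occludes(self):
        beads = np.array([[0, 0, 10], [1.0, 0, 10], [0.5, 0, 10]])
        assert not is_exposed(0, 1, beads, (50.0, 50.0), d_occ=0.312)

    def test_blocker_outside_segment_does_not_occlude(self):
        beads = np.array([[0, 0, 10], [1.0, 0, 10], [1.5, 0, 10]])
        assert is_exposed(0, 1, beads, (50.0, 50.0), d_occ=0.312)

    def test_matches_brute_force_oracle(self, rng):
        # exhaustive O(n^3) triple loop over 50 random beads
        beads = np.column_stack([rng.uniform(0, 6, 50), rng.uniform(0, 6, 50),
                                 rng.uniform(5, 11, 50)])
        box_xy = (6.0, 6.0)
        d_occ = 0.312

        def brute(i, j):
            a = beads[i]
            dj = beads[j] - a
            dj[:2] -= np.array(box_xy) * np.round(dj[:2] / np.array(box_xy))
            for k in range(50):
                if k in (i, j):
                    continue
                dk = beads[k] - a
                dk[:2] -= np.array(box_xy) * np.round(dk[:2] / np.array(box_xy))
                L2 = dj @ dj
                t = (dk @ dj) / L2
                if 0.0 < t < 1.0 and np.linalg.norm(dk - t * dj) < d_occ:
                    return False
            return True

        for i in range(50):
            for j in range(i + 1, 50):
                assert is_exposed(i, j, beads, box_xy, d_occ) == brute(i, j)

    def test_symmetric_in_pair_order(self, rng):
        beads = np.column_stack([rng.uniform(0, 5, 30), rng.uniform(0, 5, 30),
                                 rng.uniform(5, 10, 30)])
        for i in range(0, 30, 5):
            for j in range(i + 1, 30, 7):
                assert (is_exposed(i, j, beads, (5.0, 5.0), 0.312)
                        == is_exposed(j, i, beads, (5.0, 5.0), 0.312))

    def test_far_bead_distribution_basics(self, coating14):
        far = exposed_far_beads(coating14, reference_z=1.0, slab_half_width=0.3)
        assert np.all(far.n_far >= 0)
        assert np.all(far.r >= 0.3)
        assert far.n_reference > 0

    def test_empty_slab_rejected(self, coating14):
        with pytest.raises(ValueError, match="reference"):
            exposed_far_beads(coating14, reference_z=10.0, slab_half_width=0.001)


class TestGyration:
    def test_coincident_beads_give_zero(self):
        assert gyration_radius(np.zeros((5, 3))) == 0.0

    def test_dumbbell_gives_half_distance(self):
        chain = np.array([[0, 0, 0], [0, 0, 0.8]])
        assert gyration_radius(chain) == pytest.approx(0.4)

    def test_single_bead_rejected(self):
        with pytest.raises(ValueError):
            gyration_radius(np.array([[0.0, 0, 0]]))


class TestScalingExponent:
    def test_exact_on_noiseless_power_law(self):
        mean_rg = {N: 0.15 * N**0.65 for N in (5, 10, 14, 20, 30, 40)}
        gamma, _ = scaling_exponent(mean_rg)
        assert gamma == pytest.approx(0.65, abs=1e-10)

    def test_round_trip_with_noise(self, rng):
        gammas = []
        for _ in range(20):
            noise = rng.lognormal(0.0, 0.02, size=6)
            mean_rg = {N: 0.15 * N**0.65 * e
                       for N, e in zip((5, 10, 14, 20, 30, 40), noise)}
            gammas.append(scaling_exponent(mean_rg)[0])
        assert np.mean(gammas) == pytest.approx(0.65, abs=0.01)

    def test_too_few_lengths_rejected(self):
        with pytest.raises(ValueError):
            scaling_exponent({5: 1.0, 10: 2.0})


class TestConformationClassification:
    @pytest.mark.parametrize("rg,a,expected", [
        (1.0, 2.5, "mushroom"),
        (3.0, 2.5, "brush"),
        (2.5, 2.5, "crossover"),
    ])
    def test_rule(self, rg, a, expected):
        assert classify_conformation(rg, a) == expected

    def test_crossover_at_n14_for_calibrated_growth_law(self):
        # R_g(N) = b N^0.65 calibrated so R_g(14) = 2.5 nm
        b = 2.5 / 14**0.65
        labels = [classify_conformation(b * N**0.65, 2.5) for N in range(2, 30)]
        assert labels[:12] == ["mushroom"] * 12          # N = 2..13
        assert classify_conformation(b * 14**0.65, 2.5) == "crossover"
        assert all(lab == "brush" for lab in labels[13:])  # N = 15..

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_conformation(0.0, 2.5)
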