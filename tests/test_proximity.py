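"""Surface-distance statistics: brute-force oracle equivalence, slice
densities, cutoff detection, occurrence fractions, and comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memprox import (
    DEFAULT_RC,
    RadialDensity,
    SurfaceDistanceSeries,
    first_minimum_after_peak,
    near_surface_fraction,
    radial_density,
    relative_reduction,
    select_atoms,
    surface_distances,
)
from memprox.ensemble import AtomSelection
from memprox.synthetic import DistanceMixture, SyntheticSystemSpec, build_slab_system

from conftest import make_ensemble


def brute_force_distances(ens, t_idx, m_idx, pbc_xy):
    """Reference O(n*m) double loop with the same floating-point contract."""
    out = np.empty((ens.n_frames, len(t_idx)))
    for f in range(ens.n_frames):
        dx_len, dy_len = ens.box[f, 0], ens.box[f, 1]
        for ti, t in enumerate(t_idx):
            best = math.inf
            for m in m_idx:
                dx = ens.coords[f, t, 0] - ens.coords[f, m, 0]
                dy = ens.coords[f, t, 1] - ens.coords[f, m, 1]
                dz = ens.coords[f, t, 2] - ens.coords[f, m, 2]
                if pbc_xy:
                    dx -= dx_len * np.round(dx / dx_len)
                    dy -= dy_len * np.round(dy / dy_len)
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d < best:
                    best = d
            out[f, ti] = best
    return out


class TestSurfaceDistances:
    def test_single_pair_no_pbc(self):
        ens = make_ensemble([[[0, 0, 10], [0, 0, 0]]])
        sds = surface_distances(
            ens, AtomSelection(np.array([0])), AtomSelection(np.array([1])), pbc_xy=False
        )
        assert sds.distances[0, 0] == pytest.approx(10.0)

    def test_minimum_image_wrap_in_x(self):
        ens = make_ensemble([[[79, 0, 5], [1, 0, 5]]], box=(80, 80, 90))
        sds = surface_distances(
            ens, AtomSelection(np.array([0])), AtomSelection(np.array([1])), pbc_xy=True
        )
        assert sds.distances[0, 0] == pytest.approx(2.0)

    def test_z_never_wrapped(self):
        ens = make_ensemble([[[0, 0, 89], [0, 0, 1]]], box=(80, 80, 90))
        sds = surface_distances(
            ens, AtomSelection(np.array([0])), AtomSelection(np.array([1])), pbc_xy=True
        )
        assert sds.distances[0, 0] == pytest.approx(88.0)

    @pytest.mark.parametrize("pbc", [True, False])
    def test_equals_brute_force_exactly(self, pbc):
        rng = np.random.default_rng(17)
        coords = rng.random((3, 70, 3)) * [80, 80, 90]
        ens = make_ensemble(coords)
        t_idx, m_idx = np.arange(20), np.arange(20, 70)
        sds = surface_distances(
            ens, AtomSelection(t_idx), AtomSelection(m_idx), pbc_xy=pbc
        )
        oracle = brute_force_distances(ens, t_idx, m_idx, pbc)
        np.testing.assert_array_equal(sds.distances, oracle)

    def test_disjointness_required(self):
        ens = make_ensemble(np.zeros((1, 3, 3)))
        with pytest.raises(ValueError, match="disjoint"):
            surface_distances(
                ens, AtomSelection(np.array([0, 1])), AtomSelection(np.array([1, 2]))
            )

    def test_membrane_empty_after_exclusion(self):
        ens = make_ensemble(
            np.zeros((1, 2, 3)), tags=[frozenset(), frozenset({"glycosyl"})]
        )
        with pytest.raises(ValueError, match="empty"):
            surface_distances(
                ens,
                AtomSelection(np.array([0])),
                AtomSelection(np.array([1])),
                exclude_tags={"glycosyl"},
            )


class TestGlycosylExclusion:
    def _system(self):
        spec = SyntheticSystemSpec(
            lipid_grid=10, ion_counts={"O2-": 50}, charges={"O2-": 0.0},
            enrichment={"O2-": DistanceMixture(w_surf=0.6)},
            glycosyl_layer=(8.0, 120), n_frames=2, seed=21,
        )
        return build_slab_system(spec)[0]

    def test_excluded_distances_unchanged_by_glycosyl_atoms(self):
        ens = self._system()
        target = select_atoms(ens, "species:O2-")
        mem_all = select_atoms(ens, "tag:lipid")
        mem_nogly = select_atoms(ens, "tag:lipid AND NOT tag:glycosyl")
        d_excl = surface_distances(ens, target, mem_all, exclude_tags={"glycosyl"})
        d_plain = surface_distances(ens, target, mem_nogly)
        np.testing.assert_array_equal(d_excl.distances, d_plain.distances)

    def test_including_glycosyl_never_increases_distance(self):
        ens = self._system()
        target = select_atoms(ens, "species:O2-")
        mem_all = select_atoms(ens, "tag:lipid")
        d_on = surface_distances(ens, target, mem_all, exclude_tags={"glycosyl"})
        d_off = surface_distances(ens, target, mem_all)
        assert np.all(d_off.distances <= d_on.distances)


def make_rd(density, bin_width=0.2, area=6400.0, n_frames=1, species="", counts=None):
    density = np.asarray(density, dtype=float)
    if counts is None:
        counts = np.rint(density * area * bin_width * n_frames).astype(np.int64)
    return RadialDensity(
        bin_width=bin_width, r_max=bin_width * len(density), counts=counts,
        density=density, area=area, n_frames=n_frames, species=species,
    )


class TestRadialDensity:
    def test_empty_series_all_zero(self):
        sds = SurfaceDistanceSeries(np.full((2, 3), 100.0))  # all beyond r_max
        rd = radial_density(sds, area=6400.0)
        assert rd.counts.sum() == 0
        assert np.all(rd.density == 0)
        assert rd.n_excluded == 6

    def test_hand_arithmetic_single_bin(self):
        # 10 particles at r=1.5 Å, 1 frame, 80x80 box, dr=0.2:
        # D = 10 / (80*80*0.2*1) = 7.8125e-3 Å^-3 in bin [1.4, 1.6)
        sds = SurfaceDistanceSeries(np.full((1, 10), 1.5))
        rd = radial_density(sds, bin_width=0.2, r_max=40.0, area=80.0 * 80.0)
        k = 7  # [1.4, 1.6)
        assert rd.counts[k] == 10
        assert rd.density[k] == pytest.approx(7.8125e-3)
        assert rd.counts.sum() == 10

    def test_doubled_frames_cancel_in_density(self):
        one = SurfaceDistanceSeries(np.full((1, 10), 1.5))
        two = SurfaceDistanceSeries(np.full((2, 10), 1.5))
        rd1 = radial_density(one, area=6400.0)
        rd2 = radial_density(two, area=6400.0)
        np.testing.assert_allclose(rd1.density, rd2.density)
        assert rd2.counts.sum() == 2 * rd1.counts.sum()

    def test_rmax_multiple_of_dr_required(self):
        sds = SurfaceDistanceSeries(np.full((1, 2), 1.0))
        with pytest.raises(ValueError):
            radial_density(sds, bin_width=0.3, r_max=40.0, area=1.0)

    def test_half_open_bins(self):
        sds = SurfaceDistanceSeries(np.array([[0.2]]))  # exactly a bin edge
        rd = radial_density(sds, bin_width=0.2, r_max=1.0, area=1.0)
        assert rd.counts.tolist() == [0, 1, 0, 0, 0]


class TestFirstMinimum:
    def test_scan_finds_first_minimum_after_peak(self):
        rd = make_rd([0, 1, 4, 9, 4, 2, 3, 5, 6, 7])
        r_c, defaulted = first_minimum_after_peak(rd, smooth_window=1)
        assert r_c == pytest.approx(1.2)  # right edge of bin index 5
        assert not defaulted

    def test_monotone_decreasing_defaults_flagged(self):
        rd = make_rd(np.linspace(9, 0, 30), species="Na+")
        r_c, defaulted = first_minimum_after_peak(rd, smooth_window=1)
        assert defaulted and r_c == pytest.approx(DEFAULT_RC["Na+"])

    @pytest.mark.parametrize(
        "species,expected", [("O2-", 3.2), ("K+", 3.2), ("Na+", 2.8), ("Cl-", 3.8)]
    )
    def test_species_default_cutoffs(self, species, expected):
        rd = make_rd(np.linspace(9, 0, 30))
        r_c, defaulted = first_minimum_after_peak(rd, species=species)
        assert defaulted and r_c == pytest.approx(expected)

    def test_no_peak_no_default_raises(self):
        rd = make_rd(np.linspace(9, 0, 30))
        with pytest.raises(ValueError):
            first_minimum_after_peak(rd)

    def test_even_window_rejected(self):
        rd = make_rd([0, 1, 4, 9, 4, 2, 3])
        with pytest.raises(ValueError):
            first_minimum_after_peak(rd, smooth_window=2)


class TestNearSurfaceFraction:
    def test_uniform_density_length_ratio(self):
        rd = make_rd(np.ones(200))  # uniform on [0, 40]
        report = near_surface_fraction(rd, 4.0)
        assert report.R == pytest.approx(10.00)

    def test_all_inside_cutoff(self):
        rd = make_rd(np.concatenate([np.ones(10), np.zeros(190)]))
        assert near_surface_fraction(rd, 4.0).R == pytest.approx(100.0)

    def test_empty_histogram_rejected(self):
        rd = make_rd(np.zeros(200))
        with pytest.raises(ValueError):
            near_surface_fraction(rd, 3.2)

    def test_scale_invariance(self):
        """R is unchanged by rescaling area, bin width (with r grid), or f."""
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=200)
        base = make_rd(counts / (6400 * 0.2 * 4), counts=counts, n_frames=4)
        r0 = near_surface_fraction(base, 3.2).R
        bigger_area = make_rd(counts / (12800 * 0.2 * 4), counts=counts,
                              area=12800.0, n_frames=4)
        more_frames = make_rd(counts * 3 / (6400 * 0.2 * 12), counts=counts * 3,
                              n_frames=12)
        assert near_surface_fraction(bigger_area, 3.2).R == r0
        assert near_surface_fraction(more_frames, 3.2).R == r0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_monotone_in_rc(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=50)
        if counts.sum() == 0:
            counts[0] = 1
        rd = make_rd(counts / (100 * 0.2), counts=counts, area=100.0)
        rcs = np.arange(1, 51) * 0.2
        vals = [near_surface_fraction(rd, rc).R for rc in rcs]
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] == pytest.approx(100.0)

    def test_recovers_expected_fraction_on_synthetic_system(self):
        mix = DistanceMixture(w_surf=0.6, lam=1.5, r_max_exp=8.0, r_max=40.0)
        spec = SyntheticSystemSpec(
            lipid_grid=16, ion_counts={"O2-": 200}, charges={"O2-": 0.0},
            enrichment={"O2-": mix}, n_frames=100, seed=5,
        )
        ens, truth = build_slab_system(spec)
        target = select_atoms(ens, "species:O2-")
        membrane = select_atoms(ens, "tag:lipid")
        sds = surface_distances(ens, target, membrane, species="O2-")
        rd = radial_density(sds, area=80 * 80)
        rc = 3.2
        got = near_surface_fraction(rd, rc).R
        expect = truth.expected_R("O2-", rc)
        n = 200 * 100
        se = 100 * np.sqrt((expect / 100) * (1 - expect / 100) / n)
        assert abs(got - expect) < 3 * se


class TestRelativeReduction:
    @pytest.mark.parametrize(
        "ref,test,printed",
        [(56.89, 35.26, 38.02), (50.79, 39.10, 23.01), (51.61, 42.31, 18.02)],
    )
    def test_printed_reductions(self, ref, test, printed):
        # agreement to one unit in the last printed digit (source rounding)
        assert abs(relative_reduction(ref, test) - printed) <= 0.01

    def test_identity_is_zero(self):
        assert relative_reduction(42.0, 42.0) == 0.0

    def test_increase_is_negative(self):
        assert relative_reduction(35.26, 56.89) < 0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_reduction(0.0, 10.0)
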