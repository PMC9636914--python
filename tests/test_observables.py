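import math

import numpy as np
import pytest

from topogel import (IntegratorParams, SystemState, fit_escape_curve,
                     fit_power_law, mixing_probability,
                     permeabilize_and_release, radial_density,
                     sample_power_law, size_distribution)
from topogel.fixtures import ring_melt_state
from topogel.model import SphericalWall
from topogel.observables import stationarity_check
from topogel.topology import extract_rings


class TestSizeDistribution:
    def test_monodisperse_gives_delta(self):
        frames = [np.full(5, 24) for _ in range(10)]
        dist = size_distribution(frames, log_bins=False, n_bins=6,
                                 fit_lmin=3)
        assert (dist.pdf > 0).sum() == 1

    def test_normalizes_over_support(self):
        rng = np.random.default_rng(0)
        frames = [sample_power_law(40, 1.0, 3, 200, rng) for _ in range(5)]
        dist = size_distribution(frames, fit_lmin=3)
        widths = np.diff(dist.bin_edges)
        assert (dist.pdf * widths).sum() == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_power_law_exponent_recovery(self, alpha):
        """ML estimator recovers the generator exponent within its CI."""
        rng = np.random.default_rng(int(alpha * 10))
        lengths = sample_power_law(10_000, alpha, 3, 500, rng)
        fit = fit_power_law(lengths, lmin=3, lmax=500)
        # CI half-width ~ 3/sqrt(n) for this bounded discrete family
        assert fit.exponent == pytest.approx(alpha, abs=0.08)

    def test_ks_lower_cutoff_selection(self):
        """With a distorted head, the KS rule moves lmin above it."""
        rng = np.random.default_rng(1)
        tail = sample_power_law(4000, 1.0, 10, 300, rng)
        head = np.full(2000, 3)   # spike far off the power law
        fit = fit_power_law(np.concatenate([head, tail]))
        assert fit.lmin > 3
        assert fit.exponent == pytest.approx(1.0, abs=0.15)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            size_distribution([], fit_lmin=3)

    def test_stationarity_check(self):
        rng = np.random.default_rng(2)
        flat = rng.normal(10, 1, size=200)
        trend = flat + np.linspace(0, 8, 200)
        assert stationarity_check(flat)
        assert not stationarity_check(trend)


class TestMixing:
    def test_single_ring_zero(self):
        state = ring_melt_state(n_rings=1, ring_length=12)
        rings = extract_rings(state)
        res = mixing_probability(state, rings, 0, probe_radius=2.0)
        assert res.probability == 0.0

    def test_interleaved_rings_mix_half(self):
        """Two rings alternating on one circle: half the neighbours are
        foreign (uniform-mixture expectation)."""
        n = 32
        t = 2 * np.pi * np.arange(2 * n) / (2 * n)
        r = 0.97 * 2 * n / (2 * np.pi)
        pos = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(2 * n)])
        bonds = set()
        for k in range(2):          # even beads: ring 0; odd: ring 1
            ids = list(range(k, 2 * n, 2))
            for i in range(n):
                a, b = ids[i], ids[(i + 1) % n]
                bonds.add((min(a, b), max(a, b)))
        state = SystemState(pos, np.zeros_like(pos), bonds, 0.0, None)
        rings = extract_rings(state)
        res = mixing_probability(state, rings, 0, probe_radius=2.0)
        assert res.probability == pytest.approx(0.5, abs=0.1)

    def test_empty_neighborhood_flagged(self):
        # geometrically sparse "ring": spacing beyond the probe radius
        t = 2 * np.pi * np.arange(8) / 8
        pos = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros(8)])
        bonds = {(i, (i + 1) % 8) for i in range(8)}
        bonds = {(min(a, b), max(a, b)) for a, b in bonds}
        state = SystemState(pos, np.zeros_like(pos), bonds, 0.0, None)
        rings = extract_rings(state)
        res = mixing_probability(state, rings, 0, probe_radius=2.0)
        assert res.probability == 0.0
        assert res.empty_neighborhoods == 8


class TestRadialDensity:
    def test_uniform_gas_is_flat(self):
        rng = np.random.default_rng(3)
        radius = 6.0
        # uniform points in the ball, chained into one formal ring
        n = 4000
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= radius * rng.random(n)[:, None] ** (1 / 3)
        bonds = {(min(i, (i + 1) % n), max(i, (i + 1) % n)) for i in range(n)}
        state = SystemState(pts, np.zeros((n, 3)), bonds, 0.0,
                            SphericalWall(radius))
        g = radial_density([state], radius, r_bin=1.0)
        inner = g.g[:, 1:-1][g.counts[:, 1:-1] > 50]
        assert np.abs(inner - 1.0).max() < 0.35

    def test_wall_peak(self):
        n = 256
        t = 2 * np.pi * np.arange(n) / n
        radius = 7.0
        pts = np.column_stack([6.8 * np.cos(t), 6.8 * np.sin(t),
                               np.zeros(n)])
        bonds = {(min(i, (i + 1) % n), max(i, (i + 1) % n)) for i in range(n)}
        state = SystemState(pts, np.zeros((n, 3)), bonds, 0.0,
                            SphericalWall(radius))
        g = radial_density([state], radius, r_bin=0.25)
        assert g.g[:, -1].max() > 5.0     # strongly enriched at r ~ R

    def test_mass_conservation(self, melt_k0):
        cfg, _, _, record = melt_k0
        states = [s for s in record.snapshots[-4:] if s is not None]
        g = radial_density(states, cfg.sphere_radius)
        assert g.total_beads() == pytest.approx(
            cfg.n_beads * len(states), rel=1e-9
        )


class TestEscape:
    def test_tiny_pore_traps_everything(self):
        state = ring_melt_state(n_rings=3, ring_length=12, seed=0)
        with pytest.warns(UserWarning, match="below the bead diameter"):
            exp = permeabilize_and_release(
                state, pore_size=0.4, run_length=10.0, sample_interval=2.0,
                ip=IntegratorParams(seed=1),
            )
        assert exp.n_inside[0] == state.n_beads
        assert (exp.n_inside == state.n_beads).all()

    def test_open_mesh_lets_beads_out(self):
        state = ring_melt_state(n_rings=4, ring_length=12, seed=0)
        exp = permeabilize_and_release(
            state, pore_size=4.0, run_length=80.0, sample_interval=5.0,
            ip=IntegratorParams(seed=3),
        )
        assert exp.n_inside[0] == state.n_beads
        assert exp.n_inside.min() < state.n_beads

    def test_requires_confined_state(self):
        state = ring_melt_state(1, 12)
        state.box = None
        with pytest.raises(ValueError):
            permeabilize_and_release(state, 2.0)


class TestEscapeFit:
    def test_recovers_stretched_exponent(self):
        t = np.linspace(0, 200, 80)
        y = 500 * np.exp(-((t / 40.0) ** 0.5))
        fit = fit_escape_curve(t, y)
        assert fit.model == "stretched_exponential"
        assert fit.beta == pytest.approx(0.5, rel=0.05)
        assert fit.tau == pytest.approx(40.0, rel=0.05)

    def test_pure_exponential_limit(self):
        t = np.linspace(0, 100, 60)
        y = 300 * np.exp(-t / 25.0)
        fit = fit_escape_curve(t, y)
        assert fit.beta == pytest.approx(1.0, abs=0.1)

    def test_constant_series_selects_plateau(self):
        t = np.linspace(0, 100, 40)
        y = np.full_like(t, 123.0)
        fit = fit_escape_curve(t, y)
        assert fit.model == "plateau"
        assert fit.plateau_fraction == pytest.approx(1.0)

    def test_rising_series_flagged_unreliable(self):
        t = np.linspace(0, 100, 40)
        y = np.linspace(10, 500, 40)
        fit = fit_escape_curve(t, y)
        assert not fit.reliable
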