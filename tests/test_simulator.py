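"""Phantom construction, pulsatile deformation and the forward model."""

import numpy as np
import pytest
from scipy.signal import hilbert

from aortaus.geometry import RigidTransform2D, TransmitEvent, make_curved_array, transmit_delays
from aortaus.simulator import (
    LABELS,
    PhantomConfig,
    PulsationModel,
    ScattererPhantom,
    SceneConfig,
    analytic_strain,
    deform_phantom,
    make_vessel_phantom,
    simulate_channel_data,
    simulate_cycle,
    sinusoidal_radius_waveform,
    NoiseModel,
)

C = 1540.0
FS = 14.8e6


def single_scatterer(pos=(5.0, 30.0), amp=1.0):
    return ScattererPhantom(
        np.array([pos], float), np.array([amp]), np.array([LABELS["wall"]]),
        np.array([0.0, 30.0]),
    )


class TestPhantom:
    def test_zero_density_is_empty(self):
        cfg = PhantomConfig(wall_density=0.0, background_density=0.0)
        assert make_vessel_phantom(cfg, seed=0).n_scatterers == 0

    def test_seed_determinism(self):
        cfg = PhantomConfig()
        a = make_vessel_phantom(cfg, seed=42)
        b = make_vessel_phantom(cfg, seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_wall_count_poisson_bound(self):
        cfg = PhantomConfig(wall_density=20.0, background_density=0.0)
        ph = make_vessel_phantom(cfg, seed=1)
        area = np.pi * ((cfg.inner_radius + cfg.wall_thickness) ** 2 - cfg.inner_radius**2)
        expected = cfg.wall_density * area
        n_wall = int(ph.select("wall").sum())
        assert abs(n_wall - expected) < 4.0 * np.sqrt(expected)
        # all wall scatterers inside the annulus
        r = np.linalg.norm(ph.positions - ph.vessel_center, axis=1)
        assert r.min() >= cfg.inner_radius and r.max() <= cfg.inner_radius + cfg.wall_thickness

    def test_background_excludes_vessel_disc(self):
        cfg = PhantomConfig(wall_density=0.0, background_density=2.0)
        ph = make_vessel_phantom(cfg, seed=2)
        r = np.linalg.norm(ph.positions - ph.vessel_center, axis=1)
        assert r.min() > cfg.inner_radius + cfg.wall_thickness

    def test_spine_overlap_rejected(self):
        cfg = PhantomConfig(spine=True, spine_depth_offset=5.0)
        with pytest.raises(ValueError):
            make_vessel_phantom(cfg, seed=0)


class TestDeformation:
    def model(self, r=10.0, rt=10.2):
        return PulsationModel(r, np.array([r, rt]), kinematics="incompressible_ring")

    def test_rest_frame_is_static(self):
        ph = make_vessel_phantom(PhantomConfig(), seed=3)
        _, disp, strain = deform_phantom(ph, self.model(), 0)
        assert np.all(disp == 0)
        assert np.all(strain["eps_circ"] == 0)

    def test_inner_boundary_motion(self):
        ph = single_scatterer(pos=(10.0 + 0.0, 30.0))  # r = 10 about (0, 30)
        ph.vessel_center = np.array([0.0, 30.0])
        ph.positions = np.array([[10.0, 30.0]])
        new, disp, strain = deform_phantom(ph, self.model(), 1)
        r_new = np.linalg.norm(new.positions[0] - ph.vessel_center)
        assert np.isclose(r_new, 10.2)
        assert np.isclose(strain["eps_circ"][0], 0.02)

    def test_mid_wall_analytic_and_finite_difference(self):
        # scatterer at rest radius 11.7 under a 10 -> 10.2 inner pulsation
        model = self.model()
        r = 11.7
        expected = np.sqrt(r**2 + 10.2**2 - 10.0**2)
        er, ec = analytic_strain(model, 1, np.array([r]))
        assert np.isclose(ec[0], expected / r - 1.0)
        # finite-difference of the mapping r -> r'
        h = 1e-5
        rp = lambda x: np.sqrt(x**2 + 10.2**2 - 10.0**2)
        assert np.isclose(er[0], (rp(r + h) - rp(r - h)) / (2 * h) - 1.0, atol=1e-8)

    def test_incompressible_area_conserved(self):
        cfg = PhantomConfig(wall_density=30.0, background_density=0.0)
        ph = make_vessel_phantom(cfg, seed=4)
        model = PulsationModel(10.0, sinusoidal_radius_waveform(10.0, 0.4, 5))
        # the annulus [r_in(t), r_out(t)] keeps its area under the ring map
        for k in range(5):
            ri = model.radius_waveform[k]
            ro = np.sqrt((10.0 + 1.7) ** 2 + ri**2 - 100.0)
            area = np.pi * (ro**2 - ri**2)
            assert abs(area - np.pi * (11.7**2 - 10.0**2)) / area < 1e-3

    def test_wall_collapse_rejected(self):
        model = PulsationModel(10.0, np.array([10.0, 0.0]))
        ph = make_vessel_phantom(PhantomConfig(), seed=5)
        with pytest.raises(ValueError):
            deform_phantom(ph, model, 1)

    def test_frame_out_of_range(self):
        ph = make_vessel_phantom(PhantomConfig(), seed=5)
        with pytest.raises(ValueError):
            deform_phantom(ph, self.model(), 7)


class TestForwardModel:
    def test_empty_phantom_zero_samples(self):
        g = make_curved_array(4)
        empty = ScattererPhantom(np.zeros((0, 2)), np.zeros(0), np.zeros(0, int), np.zeros(2))
        ev = transmit_delays(g, 0.0)
        cd = simulate_channel_data(empty, g, g, RigidTransform2D(), ev, FS, C, n_t=256)
        assert np.all(cd.samples == 0)

    def test_linearity_superposition(self):
        g = make_curved_array(8)
        ev = transmit_delays(g, 0.0, tukey_alpha=0.0)
        p1 = single_scatterer((3.0, 25.0), 1.3)
        p2 = single_scatterer((-4.0, 33.0), -0.7)
        both = ScattererPhantom(
            np.vstack([p1.positions, p2.positions]),
            np.concatenate([p1.amplitudes, p2.amplitudes]),
            np.concatenate([p1.labels, p2.labels]),
            p1.vessel_center,
        )
        kw = dict(fs=FS, c=C, n_t=1024)
        a = simulate_channel_data(p1, g, g, RigidTransform2D(), ev, **kw)
        b = simulate_channel_data(p2, g, g, RigidTransform2D(), ev, **kw)
        ab = simulate_channel_data(both, g, g, RigidTransform2D(), ev, **kw)
        assert np.allclose(ab.samples, a.samples + b.samples, atol=1e-9)

    def test_envelope_peak_at_round_trip_time(self):
        g = make_curved_array(2)
        ev = transmit_delays(g, 0.0, tukey_alpha=0.0)
        ph = single_scatterer((5.0, 30.0))
        cd = simulate_channel_data(ph, g, g, RigidTransform2D(), ev, FS, C)
        env = np.abs(hilbert(cd.samples, axis=1))
        for i in range(2):
            d_tx = min(
                ev.element_delays[j]
                + np.linalg.norm(ph.positions[0] - g.element_positions[j]) / (C * 1e3)
                for j in range(2)
            )
            d_rx = np.linalg.norm(ph.positions[0] - g.element_positions[i]) / (C * 1e3)
            t_peak = cd.t0 + env[i].argmax() / FS
            assert abs(t_peak - (d_tx + d_rx)) < 1.0 / FS

    @pytest.mark.parametrize("tx_model", ["first_arrival", "full"])
    def test_channel_level_reciprocity(self, tx_model):
        # force single-element transmits by pushing the other elements' delays
        # out of the record, then swap the transmit and receive roles
        g1 = make_curved_array(2, label=1)
        g2 = make_curved_array(2, label=2)
        T2 = RigidTransform2D(12.0, 4.0, 40.0)
        big = 1.0
        ev1 = TransmitEvent(0.0, np.array([0.0, big]), np.ones(2), np.array([0.0, -49.57]))
        ev2 = TransmitEvent(0.0, np.array([0.0, big]), np.ones(2), np.array([0.0, -49.57]))
        ph = single_scatterer((6.0, 28.0))
        kw = dict(fs=FS, c=C, n_t=1024, tx_model=tx_model)
        a = simulate_channel_data(ph, g1, g2, T2, ev1, T_tx=RigidTransform2D(), **kw)
        b = simulate_channel_data(ph, g2, g1, RigidTransform2D(), ev2, T_tx=T2, **kw)
        assert np.allclose(a.samples[0], b.samples[0], atol=1e-9)

    def test_nyquist_guard(self):
        g = make_curved_array(4)
        ev = transmit_delays(g, 0.0)
        with pytest.raises(ValueError):
            simulate_channel_data(single_scatterer(), g, g, RigidTransform2D(), ev, fs=7e6, c=C)

    def test_noise_at_configured_snr(self):
        g = make_curved_array(8)
        ev = transmit_delays(g, 0.0, tukey_alpha=0.0)
        rng = np.random.default_rng(0)
        clean = simulate_channel_data(
            single_scatterer(), g, g, RigidTransform2D(), ev, FS, C, n_t=2048
        )
        noisy = simulate_channel_data(
            single_scatterer(), g, g, RigidTransform2D(), ev, FS, C, n_t=2048,
            noise=NoiseModel(snr_db=20.0), rng=rng,
        )
        resid = noisy.samples - clean.samples
        snr = 20 * np.log10(np.sqrt(np.mean(clean.samples**2)) / np.std(resid))
        assert abs(snr - 20.0) < 1.0


class TestCycle:
    def tiny(self, n_frames):
        cfg = SceneConfig(
            n_elements=8,
            steering_angles=(0.0,),
            n_frames=n_frames,
            phantom=PhantomConfig(wall_density=1.0, background_density=0.0),
        )
        return cfg

    def test_four_pairings_each_frame(self):
        cyc = simulate_cycle(self.tiny(2), seed=0)
        assert len(cyc.frames) == 2
        assert set(cyc.frames[0]) == {(1, 1), (1, 2), (2, 1), (2, 2)}
        n_t = {cd.samples.shape[1] for f in cyc.frames for l in f.values() for cd in l}
        assert len(n_t) == 1  # shared time axis across all events

    def test_periodic_cycle_closes(self):
        cyc = simulate_cycle(self.tiny(5), seed=1)
        assert np.allclose(cyc.truth_displacements[0], 0.0)
        assert np.allclose(cyc.truth_displacements[-1], 0.0, atol=1e-9)

    def test_single_frame_cycle_matches_rest(self):
        cyc = simulate_cycle(self.tiny(1), seed=2)
        assert len(cyc.frames) == 1
        assert np.allclose(cyc.truth_displacements[0], 0.0)
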