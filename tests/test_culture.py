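"""Culture generators, cascade dynamics, rendering and damage operators."""

import numpy as np
import pytest

from cultnet.culture import (
    DISC_RADIUS_MM,
    apply_cut,
    apply_node_removal,
    coupling_factor,
    generate_aggregated_culture,
    generate_homogeneous_culture,
    homeostatic_recovery,
    render_fluorescence,
    simulate_activity,
    Excitability,
    SpikeTrains,
)
from cultnet.metrics import modularity


class TestAggregatedGenerator:
    def test_node_count_and_positions(self):
        m = generate_aggregated_culture(n_aggregates=100, modules=5, seed=0)
        assert m.n_nodes == 100
        r = np.hypot(m.nodes["x"], m.nodes["y"])
        assert (r <= DISC_RADIUS_MM).all()

    def test_zero_probabilities_zero_edges(self):
        m = generate_aggregated_culture(20, 2, p_within=0.0, p_between=0.0)
        assert (m.weights == 0).all()

    def test_planted_partition_beats_random(self):
        m = generate_aggregated_culture(
            30, 3, p_within=0.8, p_between=0.05, seed=1
        )
        adj = (m.weights > 0).astype(np.int8)
        planted = m.nodes["module"].to_numpy()
        rng = np.random.default_rng(0)
        q_rand = modularity(adj, rng.permutation(planted))
        assert modularity(adj, planted) > q_rand

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_aggregated_culture(0, 1)
        with pytest.raises(ValueError):
            generate_aggregated_culture(10, 20)
        with pytest.raises(ValueError):
            generate_aggregated_culture(10, 2, p_within=1.5)

    def test_deterministic(self):
        a = generate_aggregated_culture(25, 5, seed=7)
        b = generate_aggregated_culture(25, 5, seed=7)
        assert np.array_equal(a.weights, b.weights)
        assert a.nodes.equals(b.nodes)


class TestHomogeneousGenerator:
    def test_grid_40_roi_count(self):
        m = generate_homogeneous_culture(grid=40, seed=0)
        # circular field mask keeps ~ pi/4 of the 1600 tiles
        assert m.n_nodes == pytest.approx(1600 * np.pi / 4, rel=0.02)

    def test_full_disconnection_at_h3(self):
        m = generate_homogeneous_culture(grid=12, h=3.0)
        on_disc = (m.nodes["region"] != "surroundings").to_numpy()
        cross = on_disc[:, None] != on_disc[None, :]
        assert m.weights[cross].sum() == 0.0

    def test_coupled_at_h07(self):
        m = generate_homogeneous_culture(grid=12, h=0.7)
        on_disc = (m.nodes["region"] != "surroundings").to_numpy()
        cross = on_disc[:, None] != on_disc[None, :]
        assert m.weights[cross].sum() > 0.0

    def test_height_factor_monotone(self):
        f = [coupling_factor(h) for h in (0.7, 1.5, 2.0, 3.0, 4.0)]
        assert f[0] == 1.0 and f[3] == 0.0 and f[4] == 0.0
        assert all(a >= b for a, b in zip(f, f[1:]))

    def test_surroundings_removed(self):
        m = generate_homogeneous_culture(grid=12, surroundings_removed=True)
        assert (m.nodes["region"] != "surroundings").all()

    def test_region_labels_by_radius(self):
        m = generate_homogeneous_culture(grid=20)
        r = np.hypot(m.nodes["x"], m.nodes["y"]).to_numpy()
        reg = m.nodes["region"].to_numpy()
        assert (r[reg == "surroundings"] > DISC_RADIUS_MM).all()
        assert (r[reg != "surroundings"] <= DISC_RADIUS_MM).all()
        # contour is the outermost disc ring
        assert r[reg == "contour"].min() > r[reg == "disc"].max() - 0.4


class TestSimulation:
    def test_no_drive_no_spikes(self, small_aggregated):
        silent = Excitability(spontaneous_rate_hz=0.0, transmission_scale=0.3)
        spikes = simulate_activity(small_aggregated, 10.0, silent, seed=0)
        assert len(spikes) == 0

    def test_determinism(self, small_aggregated):
        a = simulate_activity(small_aggregated, 30.0, seed=5)
        b = simulate_activity(small_aggregated, 30.0, seed=5)
        assert np.array_equal(a.roi, b.roi)
        assert np.array_equal(a.time, b.time)

    def test_spike_times_in_range(self, small_homogeneous):
        spikes = simulate_activity(small_homogeneous, 20.0, seed=3)
        assert len(spikes) > 0
        assert spikes.time.min() >= 0 and spikes.time.max() < 20.0
        assert (np.diff(spikes.time) >= 0).all()

    def test_removed_nodes_stay_silent(self, small_aggregated):
        m = apply_node_removal(small_aggregated, 4)
        spikes = simulate_activity(m, 60.0, seed=2)
        assert 4 not in set(spikes.roi.tolist())

    def test_refractory_enforced(self, small_aggregated):
        spikes = simulate_activity(small_aggregated, 120.0, seed=9)
        for roi in np.unique(spikes.roi):
            t = spikes.time[spikes.roi == roi]
            if t.size > 1:
                assert np.diff(np.sort(t)).min() >= 0.1


class TestRendering:
    def test_no_spikes_flat_baseline(self):
        spikes = SpikeTrains(roi=[], time=[], duration=2.0, n_rois=3)
        traces = render_fluorescence(spikes, noise_sd=0.0, baseline=100.0)
        assert traces.values == pytest.approx(np.full((3, 100), 100.0))

    def test_single_spike_kernel_shape(self):
        spikes = SpikeTrains(roi=[0], time=[1.0], duration=8.0, n_rois=1)
        traces = render_fluorescence(spikes, noise_sd=0.0, rise=0.1, decay=1.0)
        v = traces.values[0]
        peak = int(np.argmax(v))
        assert 1.0 <= peak / 50.0 <= 1.1  # max within [t, t+rise]
        after = v[peak:]
        assert (np.diff(after) <= 1e-9).all()  # monotone decay

    def test_frame_period_20ms(self):
        spikes = SpikeTrains(roi=[], time=[], duration=1.0, n_rois=1)
        traces = render_fluorescence(spikes, fps=50.0)
        assert traces.n_frames == 50
        assert 1.0 / traces.fps == pytest.approx(0.020)

    def test_negative_noise_rejected(self):
        spikes = SpikeTrains(roi=[], time=[], duration=1.0, n_rois=1)
        with pytest.raises(ValueError):
            render_fluorescence(spikes, noise_sd=-0.1)


class TestNodeRemoval:
    def test_isolated_node_no_matrix_change(self):
        m = generate_aggregated_culture(10, 2, p_within=0.0, p_between=0.0)
        out = apply_node_removal(m, 3)
        assert np.array_equal(out.weights, m.weights)
        assert out.nodes.loc[3, "removed"]

    def test_zeroes_exactly_known_degrees(self):
        import pandas as pd
        from cultnet.culture import CultureModel

        w = np.zeros((6, 6))
        # node 0 has 5 outgoing and 5 incoming couplings
        w[0, 1:] = 1.0
        w[1:, 0] = 2.0
        w[1, 2] = 3.0  # unrelated coupling survives
        nodes = pd.DataFrame(
            {
                "id": range(6),
                "x": 0.0,
                "y": 0.0,
                "region": "disc",
                "removed": False,
            }
        )
        m = CultureModel(nodes=nodes, weights=w, kind="aggregated")
        out = apply_node_removal(m, 0)
        assert (out.weights[0, :] == 0).all() and (out.weights[:, 0] == 0).all()
        assert out.weights[1, 2] == 3.0
        assert int((m.weights > 0).sum() - (out.weights > 0).sum()) == 10

    def test_idempotent(self, small_aggregated):
        once = apply_node_removal(small_aggregated, 7)
        twice = apply_node_removal(once, 7)
        assert np.array_equal(once.weights, twice.weights)
        assert once.nodes.equals(twice.nodes)

    def test_unknown_node(self, small_aggregated):
        with pytest.raises(KeyError):
            apply_node_removal(small_aggregated, 999)


class TestCut:
    def test_requires_homogeneous(self, small_aggregated):
        with pytest.raises(ValueError):
            apply_cut(small_aggregated)

    def test_zero_width_severs_only_line_crossings(self):
        m = generate_homogeneous_culture(grid=12, h=3.0, seed=0)
        out = apply_cut(m, angle=0.0, width_um=0.0)
        assert not out.nodes["removed"].any()  # zero-width band holds no ROI
        y = m.nodes["y"].to_numpy()
        surr = (m.nodes["region"] == "surroundings").to_numpy()
        crossing = (
            ((y[:, None] < 0) & (y[None, :] > 0))
            | ((y[:, None] > 0) & (y[None, :] < 0))
        ) & ~surr[:, None] & ~surr[None, :]
        assert (out.weights[crossing] == 0).all()
        assert np.array_equal(out.weights[~crossing], m.weights[~crossing])

    def test_positions_conserved(self, small_homogeneous):
        out = apply_cut(small_homogeneous)
        assert out.nodes[["x", "y"]].equals(small_homogeneous.nodes[["x", "y"]])

    def test_opposite_side_coupling_severed(self, small_homogeneous):
        m = small_homogeneous
        out = apply_cut(m, angle=0.0, width_um=500.0)
        y = m.nodes["y"].to_numpy()
        reg = m.nodes["region"].to_numpy()
        on_disc = reg != "surroundings"
        cross = (
            (y[:, None] < -0.25)
            & (y[None, :] > 0.25)
            & on_disc[:, None]
            & on_disc[None, :]
        )
        assert out.weights[cross | cross.T].sum() == 0.0

    def test_surroundings_untouched(self, small_homogeneous):
        m = small_homogeneous
        out = apply_cut(m)
        s = (m.nodes["region"] == "surroundings").to_numpy()
        assert np.array_equal(out.weights[np.ix_(s, s)], m.weights[np.ix_(s, s)])
        assert not out.nodes.loc[s, "removed"].any()

    def test_in_band_couplings_survive_only_within_band_halfplane(self):
        # no coupling entirely on one side of the band may be severed
        m = generate_homogeneous_culture(grid=16, h=3.0, seed=1)
        out = apply_cut(m, angle=0.0, width_um=500.0)
        y = m.nodes["y"].to_numpy()
        removed = out.nodes["removed"].to_numpy()
        same_side = (
            ((y[:, None] > 0.25) & (y[None, :] > 0.25))
            | ((y[:, None] < -0.25) & (y[None, :] < -0.25))
        ) & ~removed[:, None] & ~removed[None, :]
        assert np.array_equal(out.weights[same_side], m.weights[same_side])

    def test_disc_splits_into_two_components(self):
        m = generate_homogeneous_culture(
            grid=40, h=3.0, surroundings_removed=True, seed=0
        )
        out = apply_cut(m, angle=0.0, width_um=500.0)
        import networkx as nx

        live = out.live
        adj = (out.weights > 0)[np.ix_(live, live)]
        g = nx.from_numpy_array(adj)
        comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        assert len(comps) == 2
        assert comps[1] / comps[0] > 0.8  # approximately equal halves

    def test_trauma_depresses_disc_couplings(self, small_homogeneous):
        plain = apply_cut(small_homogeneous)
        hurt = apply_cut(small_homogeneous, trauma_factor=0.5)
        on_disc = (small_homogeneous.nodes["region"] != "surroundings").to_numpy()
        touched = on_disc[:, None] | on_disc[None, :]
        np.testing.assert_allclose(
            hurt.weights[touched], 0.5 * plain.weights[touched]
        )


class TestRecovery:
    def test_zero_strength_noop(self, small_aggregated):
        damaged = apply_node_removal(small_aggregated, 0)
        out = homeostatic_recovery(damaged, 0.0, seed=1)
        assert np.array_equal(out.weights, damaged.weights)

    def test_full_strength_restores_input_sums(self, small_aggregated):
        damaged = apply_node_removal(small_aggregated, 0)
        out = homeostatic_recovery(damaged, 1.0, seed=1, sprout_prob=0.0)
        live = damaged.live
        restored = out.weights[:, live].sum(axis=0)
        target = damaged.baseline_in[live]
        lost = target - damaged.weights[:, live].sum(axis=0)
        np.testing.assert_allclose(
            restored[lost > 0], target[lost > 0], rtol=1e-9
        )

    def test_invalid_strength(self, small_aggregated):
        with pytest.raises(ValueError):
            homeostatic_recovery(small_aggregated, 1.5)

    def test_positions_conserved(self, small_aggregated):
        damaged = apply_node_removal(small_aggregated, 2)
        out = homeostatic_recovery(damaged, 0.8, seed=3)
        assert out.nodes[["x", "y"]].equals(damaged.nodes[["x", "y"]])

    def test_no_sprouting_onto_removed_nodes(self, small_aggregated):
        damaged = apply_node_removal(small_aggregated, 5)
        out = homeostatic_recovery(damaged, 1.0, seed=4)
        assert out.weights[5, :].sum() == 0.0
        assert out.weights[:, 5].sum() == 0.0


class TestBurstCalibration:
    def test_aggregated_participation_band(self):
        from cultnet.bursts import detect_network_bursts
        from cultnet.calcium import binarize_traces

        parts = []
        for seed in range(3):
            m = generate_aggregated_culture(seed=seed)
            spikes = simulate_activity(m, 300.0, seed=100 + seed)
            traces = render_fluorescence(
                spikes, roi_meta=m.nodes, seed=200 + seed
            )
            seq = detect_network_bursts(
                binarize_traces(traces), mode="aggregated"
            )
            parts.append(seq.participation.mean())
        assert 0.10 <= np.mean(parts) <= 0.20

    def test_homogeneous_bursts_near_network_wide(self):
        from cultnet.bursts import detect_network_bursts
        from cultnet.calcium import binarize_traces

        m = generate_homogeneous_culture(grid=40, h=0.7, seed=0)
        spikes = simulate_activity(m, 120.0, seed=1)
        traces = render_fluorescence(spikes, roi_meta=m.nodes, seed=2)
        seq = detect_network_bursts(binarize_traces(traces), mode="homogeneous")
        assert len(seq) >= 2
        assert (seq.participation >= 0.9).all()
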