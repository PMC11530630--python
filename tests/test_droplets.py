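"""Droplet resistance coupling, branch selection, and event sequences."""

import random

import pytest

from chipflow import (
    DropletSpec,
    SimulationConfig,
    channel_resistance,
    droplet_resistance,
    run_simulation,
    select_branch,
    solve_flow,
)
from chipflow.droplets import (
    DropletError,
    DropletState,
    effective_resistances,
    extract_paths,
    injection_times_from_distances,
)
from chipflow.fixtures import make_parallel_pair, make_ring_network, make_series_chain

from _oracles import oracle_droplet_run


def ring_with(specs):
    return make_ring_network(1, droplet_specs=specs)


HEADER = DropletSpec("header", 8e-4, 3.0, "c_in", 0.0)
PAYLOAD = DropletSpec("payload", 3e-4, 3.0, "c_in", 0.005)


class TestDropletResistance:
    def test_unit_b_full_length_equals_channel(self):
        # with b = 1 and l_droplet = l, the droplet increment is exactly the
        # continuous-phase channel resistance
        r_c = channel_resistance(1e-4, 5e-5, 1e-3, 1e-3)
        r_d = droplet_resistance(1e-3, 1.0, 1e-4, 5e-5, 1e-3)
        assert r_d == pytest.approx(r_c, rel=1e-14)

    def test_linear_in_b(self):
        r1 = droplet_resistance(2e-4, 1.0, 1e-4, 5e-5, 1e-3)
        r3 = droplet_resistance(2e-4, 3.0, 1e-4, 5e-5, 1e-3)
        assert r3 == pytest.approx(3 * r1, rel=1e-14)

    def test_direct_formula_oracle(self):
        # frozen value from an independent one-line evaluation
        r = droplet_resistance(2e-4, 2.5, 1e-4, 3.3e-5, 1e-3)
        assert r == pytest.approx(2105448032519.0789, rel=1e-12)

    def test_oversized_droplet_rejected(self):
        with pytest.raises(DropletError):
            droplet_resistance(2e-3, 3.0, 1e-4, 5e-5, 1e-3, channel_length=1e-3)


class TestEffectiveResistance:
    def test_no_droplets_is_base(self):
        net = make_series_chain(2)
        base = net.base_resistances()
        assert effective_resistances(net, [], base) == base

    def test_two_identical_droplets_add_twice(self):
        net = make_series_chain(1)
        base = net.base_resistances()
        d = lambda i: DropletState(f"d{i}", 2e-4, 3.0, status="in_channel",
                                   channel="c1", pos=0.2 * i)
        one = effective_resistances(net, [d(1)], base)["c1"]
        two = effective_resistances(net, [d(1), d(2)], base)["c1"]
        assert two - base["c1"] == pytest.approx(2 * (one - base["c1"]), rel=1e-12)

    def test_mixed_sizes_sum_individually(self):
        net = make_series_chain(1)
        base = net.base_resistances()
        c = net.channels["c1"]
        drops = [DropletState("a", 1e-4, 2.0, status="in_channel", channel="c1"),
                 DropletState("b", 3e-4, 4.5, status="in_channel", channel="c1")]
        expect = base["c1"] + sum(
            droplet_resistance(d.length, d.b, c.width, c.height, 1e-3)
            for d in drops)
        assert effective_resistances(net, drops, base)["c1"] == pytest.approx(
            expect, rel=1e-14)


class TestSelectBranch:
    def test_highest_flow_wins(self):
        net = make_parallel_pair(lengths=(1e-3, 3e-3))  # c1 carries more
        fs = solve_flow(net)
        assert select_branch(net, "inlet", fs) == "c1"

    def test_tie_breaks_by_channel_id(self):
        net = make_parallel_pair(lengths=(1e-3, 1e-3))
        fs = solve_flow(net)
        assert select_branch(net, "inlet", fs) == "c1"

    def test_dead_end_rejected(self):
        net = make_series_chain(2)
        net.add_node("dead")
        net.add_channel("cd", "n1", "dead", 1e-4, 5e-5, 1e-3)
        fs = solve_flow(net)
        with pytest.raises(DropletError):
            select_branch(net, "dead", fs)

    def test_resident_droplet_flips_selection(self):
        """A header parked in the preferred branch redirects the next droplet."""
        net = ring_with([])
        fs_free = solve_flow(net)
        assert select_branch(net, "j0", fs_free, arriving_from="c_in") == "bypass0"
        header = DropletState("h", 8e-4, 3.0, status="in_channel",
                              channel="bypass0", pos=0.5)
        fs_blocked = solve_flow(net, effective_resistances(net, [header]))
        assert select_branch(net, "j0", fs_blocked, arriving_from="c_in") == "module0"


class TestDropletRuns:
    def test_droplet_free_solution_reproduced(self):
        """With no droplets the flow equals the base-module solution exactly."""
        net = ring_with([])
        assert solve_flow(net, effective_resistances(net, [])).channel_flows == \
            solve_flow(net).channel_flows

    def test_droplet_reduces_branch_flow_share(self):
        net = make_parallel_pair()
        fs0 = solve_flow(net)
        d = DropletState("d", 3e-4, 3.0, status="in_channel", channel="c1", pos=0.5)
        fs1 = solve_flow(net, effective_resistances(net, [d]))
        assert fs1.channel_flows["c1"] < fs0.channel_flows["c1"]
        assert fs1.channel_flows["c2"] > fs0.channel_flows["c2"]

    def test_traversal_time_equals_volume_over_flow(self):
        """Droplet speed is Q/(w h): crossing a channel takes exactly V/Q."""
        net = ring_with([DropletSpec("d", 3e-4, 3.0, "c_in", 0.0)])
        rs = run_simulation(net, SimulationConfig(max_time=10.0))
        inj = [e for e in rs.event_log if e.kind == "injection"][0]
        first_cross = [e for e in rs.event_log if e.kind == "droplet_boundary"][0]
        c = net.channels["c_in"]
        q = rs.records[0].channel_flows["c_in"]
        assert first_cross.time - inj.time == pytest.approx(c.volume / q, rel=1e-9)

    def test_terminates_when_droplets_exit(self):
        net = ring_with([HEADER, PAYLOAD])
        rs = run_simulation(net, SimulationConfig(max_time=1e6))
        assert rs.records[-1].time < 1.0  # horizon untouched
        assert rs.event_log[-1].kind == "termination"

    def test_header_flips_payload_path(self):
        rs = run_simulation(ring_with([HEADER, PAYLOAD]),
                            SimulationConfig(max_time=10.0))
        paths = extract_paths(rs)
        assert paths["header"] == ["c_in", "bypass0", "link0"]
        assert paths["payload"] == ["c_in", "module0", "link0"]

    def test_solo_payload_takes_bypass(self):
        rs = run_simulation(ring_with([DropletSpec("payload", 3e-4, 3.0, "c_in", 0.0)]),
                            SimulationConfig(max_time=10.0))
        assert extract_paths(rs)["payload"] == ["c_in", "bypass0", "link0"]

    def test_paths_deterministic_across_reruns(self):
        runs = [run_simulation(ring_with([HEADER, PAYLOAD]),
                               SimulationConfig(max_time=10.0)) for _ in range(3)]
        assert runs[0].droplet_paths == runs[1].droplet_paths == runs[2].droplet_paths
        assert [e.time for e in runs[0].event_log] == [e.time for e in runs[1].event_log]


def random_ring_schedule(rng: random.Random):
    """A randomized ring network and droplet schedule (<= 6 channels, <= 3 droplets)."""
    bypass = rng.uniform(0.8e-3, 1.5e-3)
    module = bypass * rng.uniform(1.8, 3.5)
    specs = []
    n_drops = rng.randint(1, 3)
    t = 0.0
    min_len = min(bypass, 2e-3)
    for i in range(n_drops):
        specs.append(DropletSpec(
            f"d{i}",
            rng.uniform(0.2, 0.75) * min_len,
            rng.uniform(2.0, 5.0),
            "c_in",
            t,
        ))
        t += rng.uniform(0.002, 0.02)
    return make_ring_network(1, bypass_length=bypass, module_length=module,
                             droplet_specs=specs)


class TestAgainstBruteForceEnumerator:
    def test_event_sequence_and_paths_match_oracle(self, rng):
        """The engine's droplet event sequence equals an exhaustive enumerator
        that re-solves the dense circuit after every candidate event."""
        for _ in range(20):
            net = random_ring_schedule(rng)
            rs = run_simulation(net, SimulationConfig(max_time=1e4))
            got = [(e.kind, e.payload, e.time) for e in rs.event_log
                   if e.kind in ("injection", "droplet_boundary")]
            want_events, want_paths = oracle_droplet_run(net)
            assert len(got) == len(want_events)
            for (k1, p1, t1), (k2, p2, t2) in zip(got, want_events):
                assert (k1, p1) == (k2, p2)
                assert t1 == pytest.approx(t2, rel=1e-9, abs=1e-12)
            assert extract_paths(rs) == want_paths


class TestInjectionSchedule:
    def test_distances_to_times(self):
        # t_i = t_{i-1} + d_i * w * h / Q
        times = injection_times_from_distances([1e-3, 2e-3], 1e-9, 1e-4, 5e-5)
        dt1 = 1e-3 * 1e-4 * 5e-5 / 1e-9
        assert times == pytest.approx([0.0, dt1, dt1 + 2 * dt1])

    def test_negative_spacing_rejected(self):
        with pytest.raises(DropletError):
            injection_times_from_distances([-1.0], 1e-9, 1e-4, 5e-5)
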