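import math

import pytest

from antnav.engine import (AgentInit, FoodSource, Intervention, Scenario,
                           Simulation, TrajectoryLog)
from antnav.geometry import PolarVector, Position
from antnav.landmarks import Gates, RouteLandmarkElement
from antnav.scenarios import (FOOD_A, FOOD_B, NEST, canonical, random_world,
                              scenario_from_dict, scenario_to_dict)

from conftest import events_of


def bare_scenario(**kwargs):
    """Two food sources, no landmarks: pure vector navigation."""
    defaults = dict(
        name="bare",
        nest=NEST,
        food_sources=[FoodSource("A", FOOD_A), FoodSource("B", FOOD_B)],
        reference_vectors={"A": PolarVector.between(NEST, FOOD_A),
                           "B": PolarVector.between(NEST, FOOD_B)},
        agent=AgentInit(position=NEST,
                        motivations={"forage": 1.0, "outbound": 1.0,
                                     "sourceA": 1.0}),
        max_steps=200,
        seed=0,
    )
    defaults.update(kwargs)
    return Scenario(**defaults)


class TestStep:
    def test_straight_line_without_landmarks(self):
        """No catchment touched: the agent walks the straight nest-to-food
        line under pure path integration, then straight home."""
        log = Simulation(bare_scenario()).run()
        bearing = math.atan2(FOOD_A.y, FOOD_A.x)
        outbound = [r for r in log.records
                    if r["activations"]["outbound"] >= 0.5][:20]
        for r in outbound:
            assert r["heading"] == pytest.approx(bearing, abs=1e-9)
        assert "food_found" in events_of(log)
        assert "entered_nest" in events_of(log)

    def test_catchment_entry_bends_path(self, canonical_run):
        log = canonical_run("two_food_route_a")
        winners = [r["winner"] for r in log.records]
        assert "rLM_Aout1" in winners
        i = winners.index("rLM_Aout1")
        assert log.records[i]["heading"] != \
            pytest.approx(log.records[0]["heading"])

    def test_step_after_terminal_raises(self):
        sim = Simulation(bare_scenario())
        sim.run()
        with pytest.raises(RuntimeError):
            sim.step()


class TestDisplace:
    def test_passive_transport_preserves_current_vector(self):
        sim = Simulation(bare_scenario())
        for _ in range(5):
            sim.step()
        before = sim.world.current.vector
        sim.displace(Position(1000, 1000), reset_current=False)
        assert sim.world.current.vector == before
        assert sim.world.position == Position(1000, 1000)

    def test_zero_vector_release_resets_current(self):
        sim = Simulation(bare_scenario())
        for _ in range(5):
            sim.step()
        sim.displace(Position(50, 50), reset_current=True)
        assert sim.world.current.length == 0.0

    def test_displace_to_current_position_is_noop(self):
        sim = Simulation(bare_scenario())
        for _ in range(3):
            sim.step()
        pos, cv = sim.world.position, sim.world.current.vector
        sim.displace(pos, reset_current=False)
        assert sim.world.position == pos
        assert sim.world.current.vector == cv


class TestRun:
    def test_same_seed_identical_logs(self):
        sc = canonical("zero_vector_search", 5)
        sc.max_steps = 150
        a = Simulation(sc, 5).run()
        b = Simulation(sc, 5).run()
        assert a.positions() == b.positions()
        assert a.winners() == b.winners()

    def test_checkpoint_restore_is_bit_exact(self):
        """Interrupting and restoring mid-run reproduces the uninterrupted
        trajectory, RNG state included."""
        sc = canonical("zero_vector_search", 7)
        sc.max_steps = 120
        ref = Simulation(sc, 7).run()
        sim = Simulation(sc, 7)
        for _ in range(60):
            sim.step()
        chk = sim.checkpoint()
        for _ in range(10):   # wander off, then restore
            sim.step()
        sim.restore(chk)
        log = sim.run()
        assert log.positions() == ref.positions()
        assert log.winners() == ref.winners()

    @pytest.mark.parametrize("name", [
        "two_food_route_a", "two_food_route_b",
        "shortcut_a_to_b", "bee_displacement",
    ])
    def test_terminal_closure_at_nest(self, canonical_run, name):
        """Every canonical experiment ends with the agent at the nest and
        the integrator reset."""
        log = canonical_run(name)
        last = log.records[-1]
        assert math.hypot(last["x"], last["y"]) <= 10.0
        assert last["cv_length"] <= 10.0
        assert "entered_nest" in events_of(log)

    def test_direction_gating_in_winner_log(self, canonical_run):
        """Outbound-gated elements never win control during inbound legs
        and vice versa, in any canonical run."""
        for name in ("two_food_route_a", "two_food_route_b",
                     "shortcut_a_to_b"):
            log = canonical_run(name)
            for r in log.records:
                w = r["winner"]
                if w is None or not w.startswith(("rLM", "fLM", "hLM")):
                    continue
                inbound = r["activations"]["inbound"] >= 0.5
                if w.endswith(("out1", "out2", "out3")) or \
                        w.startswith("fLM"):
                    assert not inbound, f"{w} won while inbound in {name}"
                if w.endswith(("in1", "in2", "in3")) or w == "hLM":
                    assert inbound, f"{w} won while outbound in {name}"

    def test_intervention_validation(self):
        with pytest.raises(ValueError):
            Intervention(action="displace")  # neither step nor event
        with pytest.raises(ValueError):
            Intervention(action="explode", step=1)


class TestScenarioValidation:
    def test_duplicate_source_ids_rejected(self):
        with pytest.raises(ValueError):
            bare_scenario(food_sources=[FoodSource("A", FOOD_A),
                                        FoodSource("A", FOOD_B)])

    def test_unknown_reference_id_rejected(self):
        with pytest.raises(ValueError):
            bare_scenario(reference_vectors={"Z": PolarVector(0, 10)})

    def test_negative_radius_rejected(self):
        lm = RouteLandmarkElement(
            id="bad", catchment_center=Position(1, 1), local_angle=0.0,
            catchment_radius=-5.0,
            gates=Gates(source="A", direction="outbound"))
        with pytest.raises(ValueError):
            bare_scenario(route_landmarks=[lm])


class TestSerialization:
    def test_yaml_round_trip_reproduces_trajectory(self, tmp_path):
        from antnav.scenarios import load_scenario, save_scenario
        sc = canonical("shortcut_a_to_b", 3)
        path = tmp_path / "scenario.yaml"
        save_scenario(sc, path)
        sc2 = load_scenario(path)
        a = Simulation(sc, 3).run()
        b = Simulation(sc2, 3).run()
        assert a.positions() == b.positions()

    def test_dict_round_trip_is_stable(self):
        d = scenario_to_dict(canonical("bee_displacement", 1))
        d2 = scenario_to_dict(scenario_from_dict(d))
        assert d == d2

    def test_trajectory_csv_round_trip(self, tmp_path, canonical_run):
        log = canonical_run("two_food_route_a")
        path = tmp_path / "log.csv"
        log.save_csv(path)
        loaded = TrajectoryLog.load_csv(path)
        assert len(loaded) == len(log)
        assert loaded.records[5]["winner"] == log.records[5]["winner"]
        assert loaded.records[5]["x"] == pytest.approx(log.records[5]["x"])


class TestRandomWorlds:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_world_runs(self, seed):
        sc = random_world(seed)
        sc.max_steps = 150
        log = Simulation(sc, seed).run()
        assert len(log) > 0

    def test_random_world_respects_requested_counts(self):
        sc = random_world(11, n_food_sources=2, n_route_landmarks=12)
        assert len(sc.food_sources) == 2
        assert len(sc.route_landmarks) == 12
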