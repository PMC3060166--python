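import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antnav.geometry import RngStream
from antnav.motivation import (GATE_THRESHOLD, PAIRS, UNITS,
                               HabituationParams, MotivationState,
                               MotivationWeights, apply_event,
                               motivation_step, relax)

W = MotivationWeights()

FORAGING_ATTRACTOR = {"forage": 1.0, "sourceA": 1.0, "outbound": 1.0}


def state(**activations):
    return MotivationState.from_dict(activations)


class TestMotivationStep:
    def test_foraging_attractor_is_fixed_point(self):
        st0 = state(**FORAGING_ATTRACTOR)
        st1 = motivation_step(st0, W)
        assert np.allclose(st0.activations, st1.activations)

    def test_activations_stay_bounded(self):
        rng = np.random.default_rng(3)
        s = MotivationState(rng.uniform(0, 1, len(UNITS)))
        for _ in range(50):
            drives = {u: float(rng.uniform(-3, 3)) for u in UNITS}
            s = motivation_step(s, W, drives)
            assert (s.activations >= 0).all() and (s.activations <= 1).all()

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=8, max_size=8))
    def test_bounded_for_any_drive(self, drive_values):
        s = state(**FORAGING_ATTRACTOR)
        drives = dict(zip(UNITS, drive_values))
        for _ in range(10):
            s = motivation_step(s, W, drives)
        assert (s.activations >= 0).all() and (s.activations <= 1).all()


class TestRelax:
    def test_wta_slight_favourite_wins_from_neutral(self):
        """Equal drive pulses with a tiny edge for sourceA: the lateral
        inhibition amplifies the difference to a full decision.  Oracle:
        direct iteration of the two-unit update to convergence."""
        drives = {"forage": 1.0, "sourceA": 0.5 + 1e-6, "sourceB": 0.5,
                  "outbound": 1.5}
        res = relax(state(forage=1.0), W, drives)
        assert res.converged
        assert res.state["sourceA"] >= 0.9
        assert res.state["sourceB"] <= 0.1
        # independent two-unit oracle with the same coupling constants
        a = b = 0.0
        for _ in range(500):
            a, b = (min(1, max(0, 0.8 * a - 1.2 * b + 0.3 + 0.5 + 1e-6)),
                    min(1, max(0, 0.8 * b - 1.2 * a + 0.3 + 0.5)))
        assert res.state["sourceA"] == pytest.approx(a, abs=1e-6)
        assert res.state["sourceB"] == pytest.approx(b, abs=1e-6)

    def test_stay_collapses_foraging_branch(self):
        res = relax(state(**FORAGING_ATTRACTOR), W, {"stay": 1.5})
        assert res.state["stay"] >= 0.9
        for unit in ("forage", "sourceA", "sourceB", "outbound", "inbound"):
            assert res.state[unit] <= 0.1

    def test_exact_symmetric_tie_flagged(self):
        res = relax(state(forage=1.0), W,
                    {"forage": 1.0, "sourceA": 0.5, "sourceB": 0.5})
        assert not res.converged
        assert ("sourceA", "sourceB") in res.ties
        assert res.state["sourceA"] == pytest.approx(res.state["sourceB"])

    def test_random_starts_resolve_one_winner_per_pair(self):
        """From 100 random initial conditions (with the seeded tie-break
        noise the architecture prescribes) each driven pair relaxes to a
        strict winner."""
        rng = np.random.default_rng(12)
        noise = RngStream(12)
        for _ in range(100):
            s = MotivationState(rng.uniform(0, 1, len(UNITS)))
            s.set("forage", 1.0)
            s.set("stay", 0.0)
            drives = apply_event({"start_foraging": True}, rng=noise)
            res = relax(s, W, drives)
            assert res.converged
            for a, b in (("sourceA", "sourceB"), ("outbound", "inbound")):
                hi, lo = sorted((res.state[a], res.state[b]), reverse=True)
                assert hi >= 0.9 and lo <= 0.1

    def test_habituation_oscillates_instead_of_converging(self):
        """With habituating inhibition and both trip directions driven,
        the inbound/outbound pair alternates rather than settling."""
        s = state(forage=1.0, sourceA=1.0, inbound=1.0)
        hab = HabituationParams()
        drives = {"inbound": 0.2, "outbound": 0.2, "forage": 0.5}
        signs = []
        for _ in range(200):
            s = motivation_step(s, W, drives, hab)
            d = s["inbound"] - s["outbound"]
            if abs(d) > 1e-3:
                signs.append(np.sign(d))
        changes = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
        assert changes >= 2


class TestApplyEvent:
    def test_food_absent_flips_source(self):
        s = state(**FORAGING_ATTRACTOR)
        drives = apply_event({"food_absent_at": "A"})
        res = relax(s, W, drives)
        assert res.state["sourceB"] >= 0.9
        assert res.state["sourceA"] <= 0.1

    def test_food_found_flips_to_inbound(self):
        s = state(**FORAGING_ATTRACTOR)
        res = relax(s, W, apply_event({"food_found": True}))
        assert res.state["inbound"] >= 0.9
        assert res.state["outbound"] <= 0.1

    def test_landmark_sum_drives_acs_off(self):
        s = state(**FORAGING_ATTRACTOR)
        res = relax(s, W, apply_event({"landmark_sum": 2.0, "acs_gain": 1.0}))
        assert res.state["ACSoff"] >= GATE_THRESHOLD
        assert res.state["ACSon"] <= 0.1

    def test_acs_on_tracks_gain(self):
        """ACSon must follow the graded search gain, not saturate."""
        s = state(**FORAGING_ATTRACTOR)
        for gain in (0.0, 0.3, 0.7, 1.0):
            res = relax(s, W, apply_event({"acs_gain": gain,
                                           "landmark_sum": 0.0}))
            assert res.state["ACSon"] == pytest.approx(gain, abs=1e-6)

    def test_acs_drives_gated_by_forage(self):
        drives = apply_event({"acs_gain": 1.0, "landmark_sum": 1.0},
                             forage_active=False)
        assert drives.get("ACSon", 0.0) == 0.0
        assert drives.get("ACSoff", 0.0) == 0.0

    def test_no_events_state_persists(self):
        s = state(**FORAGING_ATTRACTOR)
        res = relax(s, W, apply_event({}))
        assert np.allclose(res.state.activations, s.activations)

    def test_unknown_event_rejected(self):
        with pytest.raises(KeyError):
            apply_event({"teleported": True})


class TestGatingSoundness:
    def test_source_pair_never_both_above_threshold_after_relax(self):
        """Under the event-style drives the engine actually issues, the
        source pair is exclusive at every relaxed attractor."""
        rng = np.random.default_rng(5)
        noise = RngStream(5)
        for _ in range(50):
            s = MotivationState(rng.uniform(0, 1, len(UNITS)))
            s.set("forage", 1.0)
            event = ({"select_source": rng.choice(["A", "B"])}
                     if rng.uniform() < 0.5 else
                     {"food_absent_at": rng.choice(["A", "B"])})
            res = relax(s, W, apply_event(event, rng=noise))
            assert not (res.state["sourceA"] > GATE_THRESHOLD
                        and res.state["sourceB"] > GATE_THRESHOLD)


def test_weight_matrix_structure():
    """Pair connections inhibitory, forage/child excitation symmetric in
    sign, self-excitation on the diagonal."""
    M = W.matrix()
    from antnav.motivation import UNIT_INDEX
    for a, b in PAIRS:
        assert M[UNIT_INDEX[a], UNIT_INDEX[b]] < 0
        assert M[UNIT_INDEX[b], UNIT_INDEX[a]] < 0
    f = UNIT_INDEX["forage"]
    for child in W.children:
        c = UNIT_INDEX[child]
        assert M[c, f] > 0 and M[f, c] > 0
    with pytest.raises(ValueError):
        MotivationWeights(pair_inhibition=0.5)
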