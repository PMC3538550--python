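"""Twist schedule, sequence assignment and all-atom instantiation."""

import math

import numpy as np
import pytest

from dnaxis import (BASE_PAIR_TEMPLATES, Frame, InputError, assign_sequence,
                    build_dna, instantiate_base_pair, twist_schedule)

from conftest import circle_path_of_length, straight_path

TWO_PI = 2 * math.pi


class TestTwistSchedule:
    def test_default_helix_open(self):
        sch = twist_schedule(21)
        np.testing.assert_allclose(
            sch.angles, np.arange(21) * TWO_PI / 10.4, atol=1e-12
        )
        assert sch.bp_per_turn == 10.4

    def test_single_constraint_extends_constant(self):
        sch = twist_schedule(21, {11: 0.5})
        np.testing.assert_allclose(sch.offsets, 0.5, atol=1e-12)

    def test_linear_blend_between_constraints(self):
        sch = twist_schedule(21, {1: 0.0, 11: 1.0})
        assert sch.offsets[5] == pytest.approx(0.5)  # pair 6, midway
        np.testing.assert_allclose(sch.offsets[:11], np.arange(11) / 10, atol=1e-12)
        np.testing.assert_allclose(sch.offsets[11:], 1.0, atol=1e-12)

    def test_offsets_piecewise_linear_and_exact_at_constraints(self):
        cons = {3: 0.2, 9: -0.4, 15: 0.6}
        sch = twist_schedule(20, cons)
        for i, a in cons.items():
            assert sch.offsets[i - 1] == pytest.approx(a, abs=1e-12)
        # piecewise linear in index: second differences vanish everywhere
        # except at the constraint pairs themselves (the kinks)
        second = np.diff(sch.offsets, n=2)
        for i, value in enumerate(second):
            bp = i + 2  # second difference centred on pair i+2
            if bp not in cons:
                assert abs(value) < 1e-9

    def test_constraint_out_of_range_rejected(self):
        with pytest.raises(InputError):
            twist_schedule(10, {11: 0.1})

    def test_closed_default_twist_is_integer_turns(self):
        sch = twist_schedule(29, closed=True)
        total_turns = len(sch) * sch.step / TWO_PI
        assert total_turns == pytest.approx(round(total_turns), abs=1e-9)
        assert round(total_turns) == round(29 / 10.4)

    def test_unwinding_nets_zero_relative_twist(self):
        # offsets that exactly cancel the default twist between pairs p and q
        p, q = 5, 15
        cons = {p: 0.0, q: -(q - p) * TWO_PI / 10.4}
        sch = twist_schedule(21, cons)
        assert sch.angles[q - 1] == pytest.approx(sch.angles[p - 1], abs=1e-9)


class TestSequence:
    def test_generic_repeat(self):
        assert assign_sequence(6) == ["AT", "CG", "TA", "GC", "AT", "CG"]

    def test_single_pair(self):
        assert assign_sequence(1) == ["AT"]

    def test_user_sequence_with_complements(self):
        assert assign_sequence(4, "AATT") == ["AT", "AT", "TA", "TA"]

    def test_bad_user_sequence_rejected(self):
        with pytest.raises(InputError):
            assign_sequence(4, "AAT")
        with pytest.raises(InputError):
            assign_sequence(4, "AAXT")


class TestInstantiation:
    def test_identity_frame_zero_twist_is_noop(self):
        tpl = BASE_PAIR_TEMPLATES["CG"]
        f = Frame.from_tn([0, 0, 0], [0, 0, 1], [1, 0, 0])
        atoms = instantiate_base_pair(tpl, f, 0.0)
        got = np.array([a.position for a in atoms])
        np.testing.assert_allclose(got, tpl.coords, atol=1e-12)

    def test_full_turn_equals_zero_twist(self):
        tpl = BASE_PAIR_TEMPLATES["AT"]
        f = Frame.from_tn([5, -3, 2], [1, 0, 0], [0, 1, 0])
        a0 = np.array([a.position for a in instantiate_base_pair(tpl, f, 0.0)])
        a1 = np.array([a.position for a in instantiate_base_pair(tpl, f, TWO_PI)])
        np.testing.assert_allclose(a1, a0, atol=1e-9)

    def test_rigid_motion_preserves_distances(self, rng):
        tpl = BASE_PAIR_TEMPLATES["TA"]
        t = rng.normal(size=3)
        t /= np.linalg.norm(t)
        n = np.cross(t, rng.normal(size=3))
        n /= np.linalg.norm(n)
        f = Frame.from_tn(rng.normal(0, 20, 3), t, n)
        pos = np.array(
            [a.position for a in instantiate_base_pair(tpl, f, 1.234)]
        )
        ref = tpl.coords
        d_new = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        np.testing.assert_allclose(d_new, d_ref, atol=1e-9)


class TestBuildDna:
    def test_straight_340A_has_101_pairs(self):
        model = build_dna(straight_path(340.0))
        assert model.n_base_pairs == 101

    def test_atom_count_sums_templates(self):
        model = build_dna(straight_path(34.0))
        expected = sum(
            BASE_PAIR_TEMPLATES[p].n_atoms for p in model.sequence
        )
        assert model.n_atoms == expected == 11 * 41

    def test_no_constraint_twist_step_is_exact(self):
        model = build_dna(straight_path(68.0))
        steps = np.diff(model.schedule.angles)
        np.testing.assert_allclose(steps, TWO_PI / 10.4, atol=1e-12)

    def test_rise_between_consecutive_pairs(self):
        model = build_dna(straight_path(340.0))
        rises = np.linalg.norm(np.diff(model.frames.origins, axis=0), axis=1)
        assert np.abs(rises - 3.4).max() < 1e-3

    def test_closed_strand_seam_step_matches_interior(self):
        model = build_dna(circle_path_of_length(100.0))
        sch = model.schedule
        n = len(sch)
        turns = round(n / 10.4)
        interior = sch.step
        wrap = (sch.angles[0] + TWO_PI * turns) - sch.angles[-1]
        assert wrap == pytest.approx(interior, abs=1e-9)

    def test_lazy_model_stores_no_atom_arrays(self):
        model = build_dna(straight_path(3400.0))
        assert model.n_base_pairs == 1001
        per_pair = {id(v): v for v in vars(model).values()}
        for v in per_pair.values():
            if isinstance(v, np.ndarray):
                assert v.size < 100 * model.n_base_pairs
        # atoms come from the shared templates on demand
        c1 = model.pair_coords(500)
        c2 = model.pair_coords(500)
        assert c1 is not c2
        np.testing.assert_array_equal(c1, c2)
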