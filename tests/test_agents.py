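"""Agent layer: movement, shoving geometry, growth/division/sloughing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucosim import (BacterialAgent, SpeciesSpec, displacement_distance,
                     divide, grow, planktonic_move, radius_from_mass,
                     resolve_collisions, shove_iteration, slough)
from mucosim.agents import attach_by_contact, total_biomass

W = 100.0  # domain width used throughout


def agent(i, x, y, mass=4.0, species="s", direction=(1.0, 0.0),
          attached=False):
    return BacterialAgent(i, species, np.array([x, y], dtype=float), mass,
                          direction=np.array(direction), attached=attached)


class TestGeometry:
    def test_radius_mass_relation(self):
        # m = (4/3) pi r^3 at unit density
        assert radius_from_mass(4.0 * math.pi / 3.0) == pytest.approx(1.0)

    def test_displacement_distance_cases(self):
        a = agent(0, 10.0, 5.0, mass=4.19)  # r ~ 1
        b = agent(1, 11.5, 5.0, mass=4.19)
        r = a.radius
        assert displacement_distance(a, b, W) == pytest.approx(2 * r - 1.5)
        # tangent
        b.position = np.array([10.0 + 2 * r, 5.0])
        assert displacement_distance(a, b, W) == pytest.approx(0.0, abs=1e-12)
        # far apart
        b.position = np.array([15.0, 5.0])
        assert displacement_distance(a, b, W) == pytest.approx(2 * r - 5.0)
        # coincident centers -> maximal overlap
        b.position = a.position.copy()
        assert displacement_distance(a, b, W) == pytest.approx(2 * r)

    def test_minimum_image_across_periodic_side(self):
        a = agent(0, 0.5, 5.0)
        b = agent(1, W - 0.5, 5.0)
        d = displacement_distance(a, b, W)
        assert d == pytest.approx(a.radius + b.radius - 1.0)


class TestPlanktonicMove:
    def test_step_length_exact(self, rng):
        a = agent(0, 50.0, 20.0, direction=(0.6, 0.8))
        before = a.position.copy()
        planktonic_move(a, rng, W, step_length=5.0, rotation_sd=0.0)
        assert np.linalg.norm(a.position - before) == pytest.approx(5.0)

    def test_zero_rotation_keeps_straight_line(self, rng):
        a = agent(0, 10.0, 50.0, direction=(1.0, 0.0))
        for _ in range(3):
            planktonic_move(a, rng, W, rotation_sd=0.0)
        assert a.position[1] == pytest.approx(50.0)
        np.testing.assert_allclose(a.direction, [1.0, 0.0], atol=1e-12)

    def test_periodic_wrap(self, rng):
        a = agent(0, W - 1.0, 50.0, direction=(1.0, 0.0))
        planktonic_move(a, rng, W, rotation_sd=0.0)
        assert a.position[0] == pytest.approx(4.0)

    def test_wall_contact_attaches(self, rng):
        a = agent(0, 50.0, 3.0, direction=(0.0, -1.0))
        planktonic_move(a, rng, W, rotation_sd=0.0)
        assert a.attached
        assert a.position[1] == pytest.approx(a.radius)

    def test_attached_agent_rejected(self, rng):
        a = agent(0, 50.0, 3.0, attached=True)
        with pytest.raises(ValueError):
            planktonic_move(a, rng, W)


class TestShoving:
    def test_two_body_symmetric_separation(self):
        a = agent(0, 50.0, 30.0, mass=4.19)
        b = agent(1, 51.0, 30.0, mass=4.19)
        r = a.radius
        agents, it, conv = resolve_collisions([a, b], W)
        assert conv and it == 1
        gap = np.linalg.norm(a.position - b.position)
        assert gap == pytest.approx(2 * r, abs=1e-9)
        # symmetric: both moved equally, centroid fixed
        assert (a.position[0] + b.position[0]) / 2 == pytest.approx(50.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(m1=st.floats(1.0, 60.0), m2=st.floats(1.0, 60.0),
           overlap_frac=st.floats(0.05, 0.95))
    def test_two_body_closed_form_any_radii(self, m1, m2, overlap_frac):
        """One sweep moves each sphere half the overlap apart: final distance
        = r1 + r2 exactly, regardless of radii."""
        a = agent(0, 40.0, 50.0, mass=m1)
        b = agent(1, 40.0, 50.0, mass=m2)
        d0 = (a.radius + b.radius) * (1.0 - overlap_frac)
        b.position = a.position + np.array([d0, 0.0])
        agents, it, conv = resolve_collisions([a, b], W)
        assert conv and it == 1
        assert np.linalg.norm(a.position - b.position) == pytest.approx(
            a.radius + b.radius, abs=1e-9)

    def test_non_overlapping_is_fixed_point(self):
        ags = [agent(i, 10.0 * i + 5.0, 30.0) for i in range(5)]
        before = np.array([a.position for a in ags])
        new = shove_iteration(ags, W)
        np.testing.assert_allclose(new, before)
        _, it, conv = resolve_collisions(ags, W)
        assert conv and it == 0

    def test_wall_stop_clips_downward_shove(self):
        # bottom agent resting on the wall, second overlapping from above:
        # the bottom one may not be pushed through the wall, and the overlap
        # halves per sweep (wall absorbs the downward half)
        a = agent(0, 50.0, 0.0, mass=4.19)
        a.position[1] = a.radius
        b = agent(1, 50.0, a.radius + 0.5, mass=4.19)
        overlap0 = displacement_distance(a, b, W)
        resolve_collisions([a, b], W, max_iter=10)
        assert a.position[1] >= a.radius - 1e-9
        assert displacement_distance(a, b, W) <= overlap0 / 2 ** 9
        # at a mechanical tolerance the pair counts as resolved
        _, _, conv = resolve_collisions([a, b], W, max_iter=10, tol=1e-3)
        assert conv

    def test_positions_only_masses_conserved(self, rng):
        ags = [agent(i, rng.uniform(0, W), rng.uniform(1, 20), mass=8.0)
               for i in range(40)]
        mass_before = total_biomass(ags)
        radii_before = [a.radius for a in ags]
        resolve_collisions(ags, W)
        assert total_biomass(ags) == mass_before
        assert [a.radius for a in ags] == radii_before

    def test_translation_equivariance_along_periodic_axis(self, rng):
        pts = [(rng.uniform(0, W), rng.uniform(1, 15)) for _ in range(30)]
        ags1 = [agent(i, x, y, mass=8.0) for i, (x, y) in enumerate(pts)]
        dx = 37.5
        ags2 = [agent(i, (x + dx) % W, y, mass=8.0)
                for i, (x, y) in enumerate(pts)]
        resolve_collisions(ags1, W)
        resolve_collisions(ags2, W)
        for a1, a2 in zip(ags1, ags2):
            expected = (a1.position[0] + dx) % W
            diff = abs(a2.position[0] - expected)
            diff = min(diff, W - diff)
            assert diff < 1e-6
            assert a2.position[1] == pytest.approx(a1.position[1], abs=1e-9)

    def test_dense_growth_overlaps_resolve_within_budget(self):
        """A relaxed dense bed whose surface layer grew (overlaps <= 10% of
        a radius) relaxes within the 10-sweep budget at the mechanical
        tolerance the simulation loop uses."""
        from mucosim.fixtures import post_growth_biofilm
        ags, width = post_growth_biofilm(seed=3, n=200, domain_width=120.0)
        r_min = min(a.radius for a in ags)
        _, it, conv = resolve_collisions(ags, width, max_iter=10,
                                         tol=1e-3 * r_min)
        assert conv
        assert it <= 10


class TestAttachment:
    def test_contact_propagates_through_chain(self):
        r = radius_from_mass(4.0)
        base = agent(0, 50.0, r, attached=True)
        mid = agent(1, 50.0, 3 * r - 0.01)     # touches base
        top = agent(2, 50.0, 5 * r - 0.02)     # touches mid
        free = agent(3, 50.0, 40.0)            # far away
        n = attach_by_contact([base, mid, top, free], W)
        assert n == 2
        assert mid.attached and top.attached and not free.attached

    def test_wall_contact_attaches(self):
        a = agent(0, 10.0, radius_from_mass(4.0))
        assert attach_by_contact([a], W) == 1
        assert a.attached


class TestGrowthDivision:
    def test_zero_growth_identity(self):
        a = agent(0, 10, 10, mass=5.0)
        grow(a, 0.0, 1.0)
        assert a.mass == 5.0

    def test_doubling_identity(self):
        a = agent(0, 10, 10, mass=5.0)
        grow(a, math.log(2.0), 1.0)
        assert a.mass == pytest.approx(10.0)

    def test_radius_scales_cube_root(self):
        a = agent(0, 10, 10, mass=5.0)
        r0 = a.radius
        grow(a, math.log(2.0), 1.0)
        assert a.radius == pytest.approx(r0 * 2 ** (1 / 3))

    def _spec(self):
        from mucosim import make_producer, UptakeKinetics
        return SpeciesSpec("s", make_producer(),
                           UptakeKinetics({"glucose": (10.0, 0.5)}),
                           initial_mass=4.0, division_radius=2.0)

    def test_division_conserves_mass(self, rng):
        a = agent(0, 50.0, 20.0, mass=40.0)  # r > 2
        kids = divide(a, rng, self._spec(), next_id=10, domain_width=W)
        assert kids is not None
        ka, kb = kids
        assert ka.mass == kb.mass == pytest.approx(20.0)
        assert ka.mass + kb.mass == pytest.approx(40.0)
        assert {ka.id, kb.id} == {10, 11}
        # children adjacent to the parent center, one child radius away
        assert np.linalg.norm(ka.position - kb.position) <= 2 * ka.radius \
            + 1e-9

    def test_below_threshold_no_division(self, rng):
        a = agent(0, 50.0, 20.0, mass=4.0)
        assert divide(a, rng, self._spec(), 10, W) is None

    def test_children_overlap_removed_by_shoving(self, rng):
        a = agent(0, 50.0, 20.0, mass=40.0)
        ka, kb = divide(a, rng, self._spec(), 10, W)
        ags, _, conv = resolve_collisions([ka, kb], W)
        assert conv
        assert displacement_distance(ka, kb, W) <= 1e-6

    def test_mass_threshold_override(self, rng):
        from mucosim import make_producer, UptakeKinetics
        spec = SpeciesSpec("s", make_producer(),
                           UptakeKinetics({"glucose": (10.0, 0.5)}),
                           initial_mass=4.0, division_mass=6.0)
        a = agent(0, 50.0, 20.0, mass=6.5)
        assert divide(a, rng, spec, 10, W) is not None


class TestSlough:
    def test_all_below_identity(self):
        ags = [agent(i, 10.0 * i, 5.0) for i in range(4)]
        kept, removed = slough(ags, max_height=50.0)
        assert len(kept) == 4 and removed == {}

    def test_single_agent_above_removed(self):
        a = agent(0, 10.0, 60.0)
        kept, removed = slough([a], max_height=50.0)
        assert kept == [] and removed == {"s": 1}

    def test_matches_brute_force_filter(self, rng):
        ags = [agent(i, rng.uniform(0, W), rng.uniform(1, 80),
                     mass=rng.uniform(2, 30)) for i in range(60)]
        limit = 40.0
        kept, removed = slough(ags, limit)
        expected_removed = [a for a in ags if a.position[1] - a.radius > limit]
        assert len(kept) + len(expected_removed) == 60
        assert sum(removed.values()) == len(expected_removed)
        assert all(a.position[1] - a.radius <= limit for a in kept)
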