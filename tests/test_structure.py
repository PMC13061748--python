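"""Mingling, dominance, uniform angle, NN1 edge filter, summaries."""

import math

import numpy as np
import pytest

from diebackmap import (
    ProcessSpec,
    MarkSpec,
    assign_marks,
    dominance,
    k_nearest_neighbors,
    mingling,
    nn1_reference_filter,
    simulate_pattern,
    structural_summary,
    uniform_angle,
)

from conftest import make_pattern


def pattern_with_ring(azimuths_deg, radius=50.0, center=(500.0, 500.0)):
    """Reference at the centre, neighbours on a ring at given azimuths."""
    cx, cy = center
    coords = [(cx, cy)] + [
        (cx + radius * math.cos(math.radians(a)),
         cy + radius * math.sin(math.radians(a)))
        for a in azimuths_deg
    ]
    return make_pattern(coords)


class TestKNearestNeighbors:
    def test_forced_set_collinear(self):
        p = make_pattern([(100, 500), (300, 500), (500, 500), (700, 500), (900, 500)])
        ns = k_nearest_neighbors(p, 2, k=4)
        assert set(ns.neighbor_ids) == {0, 1, 3, 4}
        assert ns.distances == tuple(sorted(ns.distances))

    def test_distance_tie_broken_by_lower_id(self):
        # plants 3 and 4 are both exactly 100 cm from the reference; only one
        # fourth slot remains and the lower id must win.
        p = make_pattern(
            [(500, 500), (510, 500), (520, 500), (500, 600), (600, 500),
             (530, 500)]
        )
        ns = k_nearest_neighbors(p, 0, k=4)
        assert 3 in ns.neighbor_ids and 4 not in ns.neighbor_ids

    def test_matches_exhaustive_sort(self):
        rng = np.random.default_rng(17)
        p = make_pattern(rng.uniform(0, 1000, size=(30, 2)))
        for ref in range(30):
            ns = k_nearest_neighbors(p, ref, k=4)
            d = np.hypot(p.x - p.x[ref], p.y - p.y[ref])
            ids = [i for i in np.argsort(d, kind="stable") if i != ref][:4]
            assert list(ns.neighbor_ids) == [int(i) for i in ids]

    def test_too_few_plants(self):
        p = make_pattern([(1, 1), (2, 2), (3, 3)])
        with pytest.raises(ValueError):
            k_nearest_neighbors(p, 0, k=4)


class TestMingling:
    @pytest.mark.parametrize(
        "neighbor_species, expected",
        [
            (["A. verus"] * 4, 0.0),
            (["sp01", "sp02", "sp03", "sp04"], 1.0),
            (["A. verus", "A. verus", "sp01", "sp02"], 0.5),
        ],
    )
    def test_proportion_heterospecific(self, neighbor_species, expected):
        p = pattern_with_ring([0, 90, 180, 270])
        p = p.with_marks(species=np.array(["A. verus"] + neighbor_species,
                                          dtype=object))
        ns = k_nearest_neighbors(p, 0, k=4)
        assert mingling(p, ns) == expected


class TestDominance:
    def make(self, ref_crown, neighbor_crowns):
        p = pattern_with_ring([0, 90, 180, 270])
        return p.with_marks(crown=np.array([ref_crown] + neighbor_crowns))

    def test_all_neighbors_smaller_gives_zero(self):
        p = self.make(60.0, [30, 40, 50, 55])
        ns = k_nearest_neighbors(p, 0, k=4)
        assert dominance(p, ns) == 0.0

    def test_all_neighbors_larger_gives_one(self):
        p = self.make(30.0, [40, 50, 60, 70])
        ns = k_nearest_neighbors(p, 0, k=4)
        assert dominance(p, ns) == 1.0

    def test_equal_crown_counts_as_not_smaller(self):
        p = self.make(50.0, [50, 30, 30, 30])
        ns = k_nearest_neighbors(p, 0, k=4)
        assert dominance(p, ns) == 0.25

    def test_flipped_convention(self):
        p = self.make(60.0, [30, 40, 50, 70])
        ns = k_nearest_neighbors(p, 0, k=4)
        assert dominance(p, ns) == 0.25
        assert dominance(p, ns, larger_counts_as=0.0) == 0.75

    def test_missing_crown_raises(self):
        p = self.make(np.nan, [30, 40, 50, 55])
        ns = k_nearest_neighbors(p, 0, k=4)
        with pytest.raises(ValueError, match="crown"):
            dominance(p, ns)


class TestUniformAngle:
    def test_perfect_cross_gives_zero(self):
        # gaps all 90 degrees, none below the 72-degree standard angle
        p = pattern_with_ring([0, 90, 180, 270])
        assert uniform_angle(p, k_nearest_neighbors(p, 0, k=4)) == 0.0

    def test_tight_fan_gives_three_quarters(self):
        # gaps 10, 10, 10, 330: three below 72 degrees
        p = pattern_with_ring([0, 10, 20, 30])
        assert uniform_angle(p, k_nearest_neighbors(p, 0, k=4)) == 0.75

    def test_standard_angle_is_72_degrees(self):
        # gaps 71.9 (three times) then the wrap gap: W picks up exactly the
        # sub-72 gaps, so the threshold sits at 360/(k+1)
        p = pattern_with_ring([0, 71.9, 143.8, 215.7])
        assert uniform_angle(p, k_nearest_neighbors(p, 0, k=4)) == 0.75
        p = pattern_with_ring([0, 72.1, 144.2, 216.3])
        assert uniform_angle(p, k_nearest_neighbors(p, 0, k=4)) == 0.0

    def test_coincident_neighbor_rejected(self):
        p = make_pattern([(500, 500), (500, 500), (600, 500), (500, 600),
                          (400, 500)])
        ns = k_nearest_neighbors(p, 0, k=4)
        with pytest.raises(ValueError, match="coincident"):
            uniform_angle(p, ns)


class TestNN1Filter:
    def test_center_plant_retained(self):
        p = pattern_with_ring([0, 90, 180, 270], radius=100.0)
        assert 0 in nn1_reference_filter(p, k=4)

    def test_edge_plant_excluded(self):
        # plant 0 sits 10 cm from the edge with its fourth neighbour 200 cm
        # away; the central cluster keeps the retained set non-empty
        coords = [(10, 500), (500, 500), (520, 500), (500, 520), (480, 500),
                  (500, 480)]
        p = make_pattern(coords)
        retained = nn1_reference_filter(p, k=4)
        assert 0 not in retained and 1 in retained

    def test_empty_retained_set_raises(self):
        # every plant hugs the boundary with far-flung neighbours
        coords = [(5, 5), (995, 5), (995, 995), (5, 995), (500, 2)]
        p = make_pattern(coords)
        with pytest.raises(ValueError, match="larger plot"):
            nn1_reference_filter(p, k=4)

    def test_retained_fraction_grows_with_window(self):
        from diebackmap import Window

        fractions = []
        for size, n in ((500.0, 50), (1000.0, 200), (2000.0, 800)):
            # fixed intensity: n scales with area
            rng = np.random.default_rng(int(size))
            p = make_pattern(
                rng.uniform(0, size, size=(n, 2)), window=Window(size, size)
            )
            fractions.append(len(nn1_reference_filter(p, k=4)) / n)
        assert fractions[0] < fractions[1] < fractions[2]


class TestStructuralSummary:
    @pytest.fixture
    def csr_marked(self):
        p = simulate_pattern(ProcessSpec("csr", n=300), seed=9)
        spec = MarkSpec(
            species_probs={"A. verus": 0.5, "sp01": 0.25, "sp02": 0.25},
            status_model=("random_labeling", 0.4),
        )
        return assign_marks(p, spec, seed=10)

    def test_surface_totals_equal_reference_count(self, csr_marked):
        summ = structural_summary(csr_marked, "all")
        for tab in summ.surfaces.values():
            assert tab.to_numpy().sum() == summ.n_references
        for marg in summ.marginal.values():
            assert marg.sum() == summ.n_references

    def test_indices_live_on_quarter_lattice(self, csr_marked):
        summ = structural_summary(csr_marked, "all")
        for col in ("m", "u", "w"):
            vals = summ.records[col].to_numpy()
            assert np.allclose(vals * 4, np.round(vals * 4))
            assert np.all((vals >= 0) & (vals <= 1))

    def test_modal_w_bin_is_half_under_csr(self, csr_marked):
        summ = structural_summary(csr_marked, "all")
        assert summ.marginal["w"].idxmax() == 0.5

    def test_subgroup_restricts_references(self, csr_marked):
        live = structural_summary(csr_marked, "live")
        dead = structural_summary(csr_marked, "dead")
        allr = structural_summary(csr_marked, "all")
        assert live.n_references + dead.n_references == allr.n_references

    def test_missing_subgroup_raises(self):
        p = pattern_with_ring([0, 90, 180, 270], radius=100.0)
        p = p.with_marks(
            status=np.array(["live"] * 5, dtype=object),
            crown=np.full(5, 40.0),
        )
        with pytest.raises(ValueError, match="dead"):
            structural_summary(p, "dead")
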