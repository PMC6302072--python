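"""Generators: epithelium geometry, division-track mixture, walks, kymographs."""

import numpy as np
import pytest
from scipy import stats

from psbdiv.geometry import signed_area
from psbdiv.polarity import shape_tensor
from psbdiv.synthetic import (
    DivisionMixtureSpec,
    EpitheliumSpec,
    RecoilSpec,
    TrackTimingConfig,
    WalkSpec,
    fold_axis_angle,
    frame_to_snapshots,
    gen_centrosome_walk,
    gen_division_tracks,
    gen_epithelium,
    gen_kymograph,
)


class TestEpithelium:
    def test_noise_free_lattice_is_regular_hexagons(self):
        epi = gen_epithelium(EpitheliumSpec(n_columns=4, n_rows=4))
        for cell in epi.cells:
            assert len(cell.polygon) == 6
            assert signed_area(cell.polygon) > 0
            edge = np.linalg.norm(np.diff(cell.polygon, axis=0, append=cell.polygon[:1]),
                                  axis=1)
            assert np.allclose(edge, edge[0])
            assert shape_tensor(cell).eta < 1e-9

    def test_full_straightening_makes_boundary_vertices_collinear(self):
        epi = gen_epithelium(
            EpitheliumSpec(n_columns=4, n_rows=5, boundary_column=1,
                           boundary_straightening=1.0)
        )
        bc = [c for c in epi.cells if c.is_boundary_cell]
        assert bc, "boundary cells must be flagged"
        line_x = epi.boundary_polyline[0, 0]
        assert np.allclose(epi.boundary_polyline[:, 0], line_x)
        # every interior boundary cell contributes >= 3 collinear vertices on
        # the line (tissue-edge cells lose interface vertices at the margin)
        interior = [c for c in bc
                    if 0 < int(c.cell_id.split("_")[1]) < 4]
        assert interior
        for cell in interior:
            on_line = cell.polygon[np.isclose(cell.polygon[:, 0], line_x)]
            assert len(on_line) >= 3
            for i in range(len(on_line) - 2):
                a, b, c = on_line[i : i + 3]
                cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                assert abs(cross) < 1e-9

    def test_tricellular_vertices_are_shared_by_three_cells(self):
        epi = gen_epithelium(EpitheliumSpec(n_columns=4, n_rows=4))
        counts = {}
        for cell in epi.cells:
            for v in cell.polygon:
                counts[tuple(np.round(v, 9))] = counts.get(tuple(np.round(v, 9)), 0) + 1
        for cell in epi.cells:
            for idx in cell.tricellular:
                assert counts[tuple(np.round(cell.polygon[idx], 9))] == 3

    def test_seeded_noise_is_reproducible(self):
        spec = EpitheliumSpec(n_columns=3, n_rows=3, shape_noise_sd=0.1, seed=77)
        a = gen_epithelium(spec)
        b = gen_epithelium(spec)
        for ca, cb in zip(a.cells, b.cells):
            assert np.array_equal(ca.polygon, cb.polygon)
        c = gen_epithelium(EpitheliumSpec(n_columns=3, n_rows=3,
                                          shape_noise_sd=0.1, seed=78))
        assert not np.allclose(a.cells[0].polygon, c.cells[0].polygon)

    @pytest.mark.parametrize("bad", [
        dict(n_columns=1), dict(cell_circumradius=0.0),
        dict(boundary_straightening=1.2),
        dict(boundary_column=5, n_columns=4),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            EpitheliumSpec(**bad)


@pytest.fixture(scope="module")
def small_world():
    epi = gen_epithelium(
        EpitheliumSpec(n_columns=6, n_rows=6, boundary_column=2,
                       boundary_straightening=1.0, seed=5)
    )
    mix = DivisionMixtureSpec(seed=5)
    timing = TrackTimingConfig(n_events=10, n_distractors=4)
    return gen_division_tracks(epi, mix, timing)


class TestDivisionTracks:
    def test_no_events_means_no_lineage_splits(self):
        epi = gen_epithelium(EpitheliumSpec(n_columns=3, n_rows=3))
        tracks = gen_division_tracks(
            epi, DivisionMixtureSpec(seed=1), TrackTimingConfig(n_events=0)
        )
        assert tracks.table.empty or tracks.table["parent_id"].isna().all()

    def test_degenerate_mixture_pins_boundary_divisions_to_ap(self):
        epi = gen_epithelium(
            EpitheliumSpec(n_columns=6, n_rows=6, boundary_column=2,
                           boundary_straightening=1.0, seed=2)
        )
        mix = DivisionMixtureSpec(p_boundary_bias=1.0, boundary_angle_sd_deg=1e-9,
                                  seed=2)
        tracks = gen_division_tracks(epi, mix, TrackTimingConfig(n_events=20))
        bc_truth = [t for t in tracks.truth if t["is_boundary_cell"]]
        assert bc_truth
        for t in bc_truth:
            assert t["component"] == "boundary"
            assert t["alpha_true_deg"] == pytest.approx(0.0, abs=1e-6)

    def test_mixture_fraction_matches_binomial_expectation(self):
        """Latent boundary-component draws among BC events stay inside a
        99.9% binomial interval around p_boundary_bias."""
        p = 0.7
        n_bc = 0
        n_boundary_component = 0
        for seed in range(6):
            epi = gen_epithelium(
                EpitheliumSpec(n_columns=8, n_rows=8, boundary_column=3,
                               boundary_straightening=1.0, seed=seed)
            )
            mix = DivisionMixtureSpec(p_boundary_bias=p, seed=seed)
            tracks = gen_division_tracks(epi, mix, TrackTimingConfig(n_events=60))
            for t in tracks.truth:
                if t["is_boundary_cell"]:
                    n_bc += 1
                    n_boundary_component += t["component"] == "boundary"
        assert n_bc >= 50
        lo, hi = stats.binom.interval(0.999, n_bc, p)
        assert lo <= n_boundary_component <= hi

    def test_true_division_has_full_morphological_signature(self, small_world):
        snaps = frame_to_snapshots(small_world.table)
        truth = {t["cell_id"]: t for t in small_world.truth}
        mother_id = next(t["cell_id"] for t in small_world.truth if t["is_true_event"])
        track = sorted((s for s in snaps if s.cell_id == mother_id),
                       key=lambda s: s.frame)
        areas = np.array([s.area for s in track])
        times = np.array([s.time_min for s in track])
        grow = (times >= -10.0) & (times < 0.0)
        assert np.polyfit(times[grow], areas[grow], 1)[0] > 0
        daughters = [s for s in snaps
                     if s.parent_id == mother_id and s.frame == track[-1].frame + 1]
        assert len(daughters) == 2
        for d in daughters:
            assert 0.35 < d.area / areas[-1] < 0.65
        axis = daughters[0].centroid - daughters[1].centroid
        alpha = fold_axis_angle(np.degrees(np.arctan2(axis[1], axis[0])))
        assert alpha == pytest.approx(truth[mother_id]["alpha_true_deg"], abs=1e-6)

    def test_all_generated_polygons_are_simple_and_positive(self, small_world):
        from shapely.geometry import Polygon

        snaps = frame_to_snapshots(small_world.table)
        for s in snaps:
            assert signed_area(s.polygon) > 0
            assert Polygon(s.polygon).is_valid

    def test_track_table_round_trips_through_snapshots(self, small_world):
        snaps = frame_to_snapshots(small_world.table)
        ids = {s.cell_id for s in snaps}
        assert ids == set(small_world.table["cell_id"].unique())


class TestCentrosomeWalks:
    def test_pure_drift_is_straight(self):
        spec = WalkSpec(n_steps=10, step_sd=0.0, drift=(0.5, 0.2, 0.0))
        track = gen_centrosome_walk(spec, seed=0)
        steps = np.diff(track.positions, axis=0)
        assert np.allclose(steps, steps[0])

    def test_full_tether_pins_the_track(self):
        spec = WalkSpec(n_steps=30, step_sd=0.4, tether_point=(1.0, 2.0, 0.0),
                        tether_strength=1.0)
        track = gen_centrosome_walk(spec, seed=3)
        assert np.allclose(track.positions, track.positions[0])

    def test_seeded_walk_reproducible(self):
        spec = WalkSpec(n_steps=25, step_sd=0.3)
        a = gen_centrosome_walk(spec, seed=9)
        b = gen_centrosome_walk(spec, seed=9)
        assert np.array_equal(a.positions, b.positions)

    def test_too_short_walk_rejected(self):
        with pytest.raises(ValueError):
            WalkSpec(n_steps=1)


class TestKymographs:
    def test_zero_velocity_is_flat(self):
        k = gen_kymograph(RecoilSpec(v0=0.0, noise_sd=0.0))
        assert np.allclose(k.separation_um, k.separation_um[0])

    def test_infinite_tau_limit_is_linear(self):
        k = gen_kymograph(RecoilSpec(v0=0.5, tau=1e9, noise_sd=0.0, dt=1.0))
        slopes = np.diff(k.separation_um) / np.diff(k.times_s)
        assert np.allclose(slopes, 0.5, atol=1e-6)

    def test_exponential_relaxation_decelerates(self):
        """d(t) = d0 + v0*tau*(1-exp(-t/tau)): successive first differences
        shrink by the factor exp(-dt/tau)."""
        spec = RecoilSpec(v0=0.5, tau=10.0, dt=1.0, n_frames=15, noise_sd=0.0)
        k = gen_kymograph(spec)
        diffs = np.diff(k.separation_um)
        assert np.all(np.diff(diffs) < 0)
        assert np.allclose(diffs[1:] / diffs[:-1], np.exp(-spec.dt / spec.tau))

    def test_seeded_noise_reproducible(self):
        spec = RecoilSpec(noise_sd=0.05, seed=21)
        assert np.array_equal(gen_kymograph(spec).separation_um,
                              gen_kymograph(spec).separation_um)

    @pytest.mark.parametrize("bad", [dict(v0=-0.1), dict(tau=0.0), dict(dt=0.0)])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            RecoilSpec(**bad)
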