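"""Development engine: initialization, triggering, events, full development,
dormancy classification, and equivalence with the brute-force reference."""

import itertools

import numpy as np
import pytest

from epitrack import (
    CellKind,
    EngineConfig,
    EventType,
    GeneticUnit,
    Genome,
    RightPart,
    Switch,
    apply_apoptosis,
    apply_proliferation,
    change_volume,
    develop,
    dormant_mocs,
    encode_counter_as_seq,
    init_embryo,
    phenotype_signature,
    triggered_events,
)
from epitrack.errors import ConfigError
from epitrack.fixtures import (
    dormant_driver_genome,
    grow_then_carve_genome,
    one_unit_proliferation_genome,
)

from conftest import make_random_genome
from reference_interpreter import reference_develop


def unit(mos, tm, event=EventType.PROLIFERATION, radius=1, color=1, sw=Switch.ACTIVE):
    return GeneticUnit(sw, mos, tm, RightPart(event, radius, color))


def founder_moc(config):
    return encode_counter_as_seq(0, config.moc_length, config.alphabet_size)


class TestInitEmbryo:
    def test_single_founder_driver_with_zero_code(self, config_3d):
        embryo = init_embryo(config_3d)
        assert embryo.n_cells() == 1
        cell = embryo.cells[config_3d.center]
        assert cell.kind is CellKind.DRIVER
        assert cell.moc == founder_moc(config_3d)
        assert embryo.moc_counter == 1 and embryo.stage == 0


class TestChangeVolume:
    def test_interior_cube_count(self, config_3d):
        vol = change_volume(config_3d.center, 1, config_3d)
        assert len(vol) == 27

    def test_corner_clips_by_brute_force(self, config_3d):
        # independent enumeration of all grid sites within max-norm radius
        for corner in [(0, 0, 0), (20, 20, 20), (0, 20, 0)]:
            for radius in (1, 2):
                expected = {
                    p
                    for p in itertools.product(range(21), repeat=3)
                    if max(abs(a - b) for a, b in zip(p, corner)) <= radius
                }
                assert set(change_volume(corner, radius, config_3d)) == expected

    def test_corner_radius1_has_8_positions(self, config_3d):
        assert len(change_volume((0, 0, 0), 1, config_3d)) == 8

    def test_radius_zero_is_an_error(self, config_3d):
        with pytest.raises(ConfigError):
            change_volume(config_3d.center, 0, config_3d)


class TestTriggering:
    def test_inactive_switch_blocks(self, config_3d):
        embryo = init_embryo(config_3d)
        g = Genome((unit(founder_moc(config_3d), 1, sw=Switch.INACTIVE),))
        assert triggered_events(embryo, g, 1) == []

    def test_timer_mismatch_blocks(self, config_3d):
        embryo = init_embryo(config_3d)
        g = Genome((unit(founder_moc(config_3d), 2),))
        assert triggered_events(embryo, g, 1) == []

    def test_lowest_index_wins_ties(self, config_3d):
        embryo = init_embryo(config_3d)
        moc = founder_moc(config_3d)
        g = Genome((unit(moc, 1, color=0), unit(moc, 1, color=3)))
        assert triggered_events(embryo, g, 1) == [(config_3d.center, 0)]

    def test_sorted_by_driver_position(self, small_config_3d):
        g = Genome((unit(founder_moc(small_config_3d), 1, radius=2),))
        embryo, _ = develop(g, small_config_3d)
        # many drivers now exist; their trigger list must be position-sorted
        g2 = Genome(
            tuple(
                unit(encode_counter_as_seq(c, small_config_3d.moc_length, 10), 1)
                for c in range(5)
            )
        )
        events = triggered_events(embryo, g2, 1)
        assert events == sorted(events)


class TestProliferation:
    def test_fills_cube_preserving_trigger(self, config_3d):
        embryo = init_embryo(config_3d)
        embryo.stage = 1
        u = unit(founder_moc(config_3d), 1, radius=1)
        _, n_created = apply_proliferation(embryo, config_3d.center, u)
        assert embryo.n_cells() == 27
        assert n_created == 26
        center_cell = embryo.cells[config_3d.center]
        assert center_cell.kind is CellKind.DRIVER
        assert center_cell.moc == founder_moc(config_3d)

    def test_new_driver_codes_assigned_in_position_order(self):
        cfg = EngineConfig(dims=2, grid_extent=(21, 21), driver_spacing=2)
        embryo = init_embryo(cfg)
        embryo.stage = 1
        u = unit(founder_moc(cfg), 1, radius=2)
        apply_proliferation(embryo, cfg.center, u)
        # spacing-2 sublattice within radius 2: offsets {-2, 0, 2}^2
        new_drivers = [
            (pos, cell.moc)
            for pos, cell in sorted(embryo.cells.items())
            if cell.kind is CellKind.DRIVER and pos != cfg.center
        ]
        assert len(new_drivers) == 8
        expected = [
            encode_counter_as_seq(c, cfg.moc_length, cfg.alphabet_size)
            for c in range(1, 9)
        ]
        assert [moc for _, moc in new_drivers] == expected

    def test_reapplication_preserves_all_drivers(self, config_3d):
        embryo = init_embryo(config_3d)
        embryo.stage = 1
        u = unit(founder_moc(config_3d), 1, radius=1)
        apply_proliferation(embryo, config_3d.center, u)
        drivers_before = {
            p: c.moc for p, c in embryo.cells.items() if c.kind is CellKind.DRIVER
        }
        embryo.stage = 2
        apply_proliferation(embryo, config_3d.center, u)
        drivers_after = {
            p: c.moc for p, c in embryo.cells.items() if c.kind is CellKind.DRIVER
        }
        assert drivers_after == drivers_before
        assert embryo.n_cells() == 27


class TestApoptosis:
    def test_empty_volume_is_a_no_op(self, config_3d):
        embryo = init_embryo(config_3d)
        u = unit(founder_moc(config_3d), 1, event=EventType.APOPTOSIS, radius=2)
        _, n_removed = apply_apoptosis(embryo, (0, 0, 0), u)
        assert n_removed == 0 and embryo.n_cells() == 1

    def test_removes_everything_including_trigger(self, config_3d):
        embryo = init_embryo(config_3d)
        embryo.stage = 1
        grow = unit(founder_moc(config_3d), 1, radius=2)
        apply_proliferation(embryo, config_3d.center, grow)
        total_before = embryo.n_cells()
        carve = unit(founder_moc(config_3d), 2, event=EventType.APOPTOSIS, radius=1)
        in_volume = sum(
            1
            for p in change_volume(config_3d.center, 1, config_3d)
            if p in embryo.cells
        )
        _, n_removed = apply_apoptosis(embryo, config_3d.center, carve)
        assert n_removed == in_volume == 27
        assert embryo.n_cells() == total_before - n_removed
        assert config_3d.center not in embryo.cells


class TestDevelop:
    def test_empty_genome_changes_nothing(self, config_3d):
        embryo, record = develop(Genome(), config_3d)
        assert embryo.n_cells() == 1
        assert record.events == []

    def test_one_unit_genome_grows_27_cells_and_stops(self, config_3d):
        g = one_unit_proliferation_genome(config_3d)
        embryo, record = develop(g, config_3d)
        assert embryo.n_cells() == 27
        assert len(record.events) == 1
        # no further change after stage 1 (no other driver ever matches)
        totals = dict(record.stage_totals)
        assert totals[1] == 27 and totals[config_3d.n_stages] == 27

    def test_grow_then_carve_removes_cells_at_stage_2(self, config_2d):
        g = grow_then_carve_genome(config_2d)
        _, record = develop(g, config_2d)
        stage2 = [e for e in record.events if e.stage == 2]
        assert len(stage2) == 1
        assert stage2[0].event_type is EventType.APOPTOSIS
        assert stage2[0].n_removed > 0

    def test_determinism_voxel_for_voxel(self, small_config_3d):
        rng = np.random.default_rng(0)
        g = make_random_genome(small_config_3d, rng, n_units=4)
        a, _ = develop(g, small_config_3d)
        b, _ = develop(g, small_config_3d)
        assert phenotype_signature(a) == phenotype_signature(b)

    def test_stem_cells_relabel_normal_next_stage(self, config_3d):
        g = one_unit_proliferation_genome(config_3d)
        embryo, _ = develop(g, config_3d)
        kinds = {c.kind for c in embryo.cells.values()}
        # born at stage 1, relabeled by stage 2; 15 stages elapse
        assert CellKind.STEM not in kinds
        assert CellKind.NORMAL in kinds

    def test_driver_mocs_always_distinct(self, small_config_3d):
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = make_random_genome(small_config_3d, rng)
            embryo, _ = develop(g, small_config_3d)
            mocs = [
                c.moc for c in embryo.cells.values() if c.kind is CellKind.DRIVER
            ]
            assert len(mocs) == len(set(mocs))

    def test_counter_equals_total_drivers_created(self, small_config_3d):
        d = small_config_3d.driver_spacing
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = make_random_genome(small_config_3d, rng)
            embryo, record = develop(g, small_config_3d, record_positions=True)
            drivers_written = sum(
                all((p - q) % d == 0 for p, q in zip(pos, e.driver_pos))
                for e in record.events
                if e.event_type is EventType.PROLIFERATION
                for pos in e.created_positions
            )
            assert embryo.moc_counter == 1 + drivers_written
            assert record.total_drivers_created == embryo.moc_counter

    def test_matches_reference_on_random_genomes(self, small_config_3d):
        rng = np.random.default_rng(3)
        n_with_events = 0
        for _ in range(20):
            g = make_random_genome(small_config_3d, rng)
            embryo, record = develop(g, small_config_3d)
            assert phenotype_signature(embryo) == reference_develop(g, small_config_3d)
            n_with_events += bool(record.events)
        assert n_with_events >= 5  # the sample must actually exercise events


class TestDormancy:
    def test_untouched_founder_with_empty_genome_is_dormant(self, config_3d):
        _, record = develop(Genome(), config_3d)
        assert dormant_mocs(record, Genome()) == [founder_moc(config_3d)]

    def test_fired_driver_excluded(self, config_3d):
        g = one_unit_proliferation_genome(config_3d)
        _, record = develop(g, config_3d)
        assert founder_moc(config_3d) not in dormant_mocs(record, g)

    def test_match_by_inactive_unit_excluded(self, config_3d):
        # the founder matches a unit whose switch is off: one germline
        # mutation away from firing, so not a penetration candidate
        g = Genome((unit(founder_moc(config_3d), 1, sw=Switch.INACTIVE),))
        _, record = develop(g, config_3d)
        assert dormant_mocs(record, g) == []

    def test_match_by_out_of_range_timer_excluded(self, config_3d):
        g = Genome((unit(founder_moc(config_3d), config_3d.n_stages + 1),))
        _, record = develop(g, config_3d)
        assert dormant_mocs(record, g) == []

    def test_unmatched_new_drivers_are_dormant(self, config_2d):
        rng = np.random.default_rng(4)
        g = dormant_driver_genome(config_2d, rng)
        embryo, record = develop(g, config_2d)
        pool = dormant_mocs(record, g)
        assert pool, "proliferation must have produced unmatched drivers"
        assert pool == sorted(pool)
        mos_set = g.mos_set()
        assert all(moc not in mos_set for moc in pool)
        assert all(moc not in record.fired_mocs for moc in pool)


class TestBookkeeping:
    def test_conservation_and_containment(self, small_config_3d):
        rng = np.random.default_rng(5)
        for _ in range(15):
            g = make_random_genome(small_config_3d, rng)
            _, record = develop(g, small_config_3d, record_positions=True)
            totals = dict(record.stage_totals)
            for stage in range(1, small_config_3d.n_stages + 1):
                created = sum(e.n_created for e in record.events if e.stage == stage)
                removed = sum(e.n_removed for e in record.events if e.stage == stage)
                assert totals[stage] == totals[stage - 1] - removed + created
            for e in record.events:
                vol = set(change_volume(e.driver_pos, e.radius, small_config_3d))
                assert set(e.created_positions) <= vol
                assert set(e.removed_positions) <= vol
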