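"""Nanowell COM/RDM construction and matrix registration."""

import numpy as np
import pandas as pd
import pytest

from conftest import DEFAULT_GATES, planted_cells_frame
from m6ascope.registration import (DensityMatrix, OccupancyMatrix,
                                   RegistrationError, RegistrationResult,
                                   _correlation_map_fft,
                                   _correlation_map_naive, build_com,
                                   build_rdm, classify_phenotype, detect_cells,
                                   link_single_cells, register_rdm_to_com)
from m6ascope.simulate import simulate_nanowell_scan


class TestDetectCells:
    def test_blank_scan_yields_no_cells(self):
        scan = {"nuclear": np.random.default_rng(0).normal(20, 2, (100, 100)),
                "green": np.zeros((100, 100))}
        cells = detect_cells(scan, (10.0, 10.0), 10.0, (8, 8))
        assert len(cells) == 0

    def test_planted_separated_cells_recovered_at_their_wells(self):
        rng = np.random.default_rng(1)
        grid = (12, 16)
        # 100 wells, every other well occupied -> >= 2 pitches apart
        occupied = [(r, c) for r in range(0, 12, 2) for c in range(0, 16, 2)][:48]
        wells = pd.DataFrame([{"well_row": r, "well_col": c, "green": 200.0,
                               "red": 30.0} for r, c in occupied])
        scan, origin = simulate_nanowell_scan(wells, grid, 12.0,
                                              ["green", "red"], seed=2)
        cells = detect_cells(scan, origin, 12.0, grid)
        assert len(cells) == len(occupied)
        got = {(int(r.well_row), int(r.well_col)) for r in cells.itertuples()}
        assert got == set(occupied)

    def test_two_cells_in_one_well_share_the_well_index(self):
        wells = pd.DataFrame([
            {"well_row": 3, "well_col": 4, "green": 200.0},
            {"well_row": 3, "well_col": 4, "green": 200.0},
        ])
        scan, origin = simulate_nanowell_scan(wells, (8, 8), 14.0, ["green"],
                                              seed=11)
        cells = detect_cells(scan, origin, 14.0, (8, 8))
        assert len(cells) == 2
        assert set(zip(cells.well_row, cells.well_col)) == {(3, 4)}

    def test_missing_nuclear_channel_raises(self):
        with pytest.raises(ValueError, match="nuclear"):
            detect_cells({"green": np.zeros((10, 10))}, (5, 5), 5.0, (2, 2))


class TestClassifyPhenotype:
    def test_gate_assignment(self):
        cells = pd.DataFrame([{"green": 250.0, "red": 20.0},
                              {"green": 20.0, "red": 250.0},
                              {"green": 99.5, "red": 99.5}])
        out = classify_phenotype(cells, DEFAULT_GATES)
        assert list(out.phenotype) == ["K562", "YAC1", "unassigned"]

    def test_overlapping_gates_rejected(self):
        gates = {"a": {"green": (0.0, 100.0)}, "b": {"green": (50.0, 150.0)}}
        with pytest.raises(ValueError, match="overlap"):
            classify_phenotype(pd.DataFrame([{"green": 10.0}]), gates)

    def test_separated_mixture_labelled_correctly(self):
        rng = np.random.default_rng(3)
        n = 500
        truth = rng.random(n) < 0.5
        cells = pd.DataFrame({
            "green": np.where(truth, rng.normal(250, 20, n), rng.normal(30, 10, n)),
            "red": np.where(truth, rng.normal(30, 10, n), rng.normal(250, 20, n)),
        })
        out = classify_phenotype(cells, DEFAULT_GATES)
        labels = np.where(truth, "K562", "YAC1")
        assert (out.phenotype.to_numpy() == labels).mean() >= 0.99


class TestMatrices:
    def test_empty_com_is_zero(self):
        assert build_com(pd.DataFrame(), (5, 7)).counts.sum() == 0

    def test_double_occupancy_counted(self):
        cells = planted_cells_frame(singlets=[], doublets=[(2, 3)])
        com = build_com(cells, (5, 7))
        assert com.counts[2, 3] == 2
        assert com.counts.sum() == 2

    def test_out_of_grid_cells_excluded_with_warning(self):
        cells = pd.DataFrame([{"well_row": 9, "well_col": 9, "in_grid": False},
                              {"well_row": 1, "well_col": 1, "in_grid": True}])
        with pytest.warns(UserWarning, match="outside"):
            com = build_com(cells, (3, 3))
        assert com.counts.sum() == 1
        assert com.n_excluded == 1

    def test_rdm_from_counts_and_missing_fovs(self):
        rdm = build_rdm({(0, 0): (10, 3), (1, 2): (5, 5)}, (2, 3))
        assert rdm.total[0, 0] == 10 and rdm.modified[0, 0] == 3
        assert rdm.missing.sum() == 4
        assert np.all(rdm.modified <= rdm.total)

    def test_rdm_rejects_modified_above_total(self):
        with pytest.raises(ValueError):
            build_rdm({(0, 0): (3, 5)}, (2, 2))


class TestRegister:
    def test_planted_pattern_recovered(self):
        rng = np.random.default_rng(0)
        com = rng.poisson(0.6, (121, 381)).astype(float)
        pat = (rng.random((31, 51)) < 0.5) * 2.0
        com[40:71, 120:171] += pat
        reg = register_rdm_to_com(pat + rng.poisson(0.6, (31, 51)), com)
        assert reg.offset == (40, 120)
        assert reg.correlation == np.nanmax(reg.correlation_map)
        assert reg.valid

    def test_topleft_subset_registers_at_origin(self):
        rng = np.random.default_rng(1)
        com = rng.poisson(1.0, (20, 25)).astype(float)
        reg = register_rdm_to_com(com[:6, :8].copy(), com)
        assert reg.offset == (0, 0)
        assert reg.correlation == pytest.approx(1.0)

    def test_number_of_scored_offsets(self):
        rng = np.random.default_rng(2)
        com = rng.poisson(1.0, (121, 381)).astype(float)
        reg = register_rdm_to_com(rng.poisson(1.0, (31, 51)).astype(float), com)
        assert reg.correlation_map.shape == (121 - 31 + 1, 381 - 51 + 1)

    def test_fft_map_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        com = rng.poisson(1.2, (18, 22)).astype(float)
        rdm = rng.poisson(1.2, (6, 7)).astype(float)
        mask = np.ones((6, 7), bool)
        mask[2, 3] = mask[5, 0] = False  # missing FOVs excluded pairwise
        fft = _correlation_map_fft(rdm, com, mask)
        naive = _correlation_map_naive(rdm, com, mask)
        assert np.allclose(fft, naive, atol=1e-10, equal_nan=True)

    def test_equivariance_under_pattern_shift(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(0.5, (40, 50)).astype(float)
        pat = (rng.random((8, 10)) < 0.5) * 3.0
        for dr, dc in [(0, 0), (5, 7), (12, 20)]:
            com = base.copy()
            com[dr:dr + 8, dc:dc + 10] += pat
            reg = register_rdm_to_com(pat.copy(), com, z_threshold=3.0)
            assert reg.offset == (dr, dc)

    def test_constant_rdm_raises(self):
        com = np.random.default_rng(5).poisson(1.0, (10, 12)).astype(float)
        with pytest.raises(RegistrationError):
            register_rdm_to_com(np.ones((3, 4)), com)

    def test_rdm_must_be_smaller(self):
        with pytest.raises(ValueError, match="smaller"):
            register_rdm_to_com(np.zeros((10, 10)), np.zeros((10, 12)))


def _valid_registration(offset, shape=(20, 20)):
    cmap = np.zeros(shape)
    cmap[offset] = 1.0
    return RegistrationResult(offset=offset, correlation=1.0,
                              correlation_map=cmap, z_score=10.0)


class TestLinkSingleCells:
    def test_singlets_linked_doublets_and_empties_excluded(self):
        singlets = [(2 + i, 3) for i in range(10)]
        doublets = [(0, 0), (0, 1), (0, 2)]
        cells = planted_cells_frame(singlets, doublets)
        com = build_com(cells, (15, 10))
        rdm = DensityMatrix(total=np.full((13, 8), 40.0),
                            modified=np.full((13, 8), 10.0))
        reg = _valid_registration((0, 0), (3, 3))
        linked = link_single_cells(reg, com, cells, rdm)
        assert len(linked) == 10
        assert set(zip(linked.well_row, linked.well_col)) == set(singlets)
        assert (linked.phenotype == "K562").all()

    def test_all_empty_wells_link_nothing(self):
        cells = planted_cells_frame([], [])
        com = build_com(cells, (10, 10))
        rdm = DensityMatrix(total=np.zeros((4, 4)), modified=np.zeros((4, 4)))
        linked = link_single_cells(_valid_registration((0, 0)), com, cells, rdm)
        assert len(linked) == 0

    def test_invalid_registration_refuses_to_link(self):
        reg = RegistrationResult(offset=(0, 0), correlation=0.2,
                                 correlation_map=np.zeros((3, 3)), z_score=1.0)
        with pytest.raises(RegistrationError, match="refusing"):
            link_single_cells(reg, OccupancyMatrix(np.zeros((5, 5), int)),
                              pd.DataFrame(),
                              DensityMatrix(np.zeros((2, 2)), np.zeros((2, 2))))
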