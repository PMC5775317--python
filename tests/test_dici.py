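"""DICI scoring: binarisation, confusion counts, quantile transform, selection."""

import numpy as np
import pandas as pd
import pytest

from tumorica.dici import (
    ComponentScore,
    DICIConfig,
    SelectionResult,
    _pairwise_deltas,
    binarize_component,
    score_component,
    select_from_components,
    write_dici_report,
)
from tumorica.errors import ConfigError, DegenerateTemplateError, NoTumorComponentError
from tumorica.imaging import BinaryMask, Volume3D, VoxelGrid


def brute_force_confusion(bin_data, tmpl_data, brain_data):
    """Independent voxel-by-voxel confusion counter."""
    hit = miss = fa = cr = 0
    for v in np.ndindex(bin_data.shape):
        if not brain_data[v]:
            continue
        if tmpl_data[v]:
            if bin_data[v]:
                hit += 1
            else:
                miss += 1
        else:
            if bin_data[v]:
                fa += 1
            else:
                cr += 1
    return hit, miss, fa, cr


def quantile_oracle(p):
    """Standard-normal quantile via the error-function inverse (sympy-free route)."""
    from scipy.special import erfinv

    return float(np.sqrt(2.0) * erfinv(2.0 * p - 1.0))


class TestBinarize:
    def setup_method(self):
        self.grid = VoxelGrid.isotropic((16, 16, 16), 2.0)

    def _vol(self, data):
        return Volume3D(self.grid, data)

    def test_large_blob_kept_isolated_voxels_removed(self):
        data = np.zeros(self.grid.shape)
        data[2:5, 2:7, 2:4] = 2.0  # 3*5*2 = 30-voxel blob
        for v in [(10, 10, 10), (12, 2, 12), (14, 14, 2), (2, 14, 10), (8, 14, 14)]:
            data[v] = 3.0
        mask = binarize_component(self._vol(data), DICIConfig())
        assert mask.n_voxels == 30
        assert mask.data[3, 4, 3]

    def test_cluster_of_exactly_min_size_removed(self):
        data = np.zeros(self.grid.shape)
        data[2:4, 2:7, 2:4] = 2.0  # exactly 20 voxels
        mask = binarize_component(self._vol(data), DICIConfig(min_cluster_voxels=20))
        assert mask.n_voxels == 0
        # one voxel more survives the strictly-greater rule
        data[4, 2, 2] = 2.0
        mask = binarize_component(self._vol(data), DICIConfig(min_cluster_voxels=20))
        assert mask.n_voxels == 21

    def test_all_zero_map_gives_empty_mask(self):
        mask = binarize_component(self._vol(np.zeros(self.grid.shape)), DICIConfig())
        assert mask.n_voxels == 0

    def test_positive_tail_only(self):
        data = np.zeros(self.grid.shape)
        data[2:6, 2:6, 2:6] = -5.0  # strong negative blob must not survive
        mask = binarize_component(self._vol(data), DICIConfig())
        assert mask.n_voxels == 0

    def test_threshold_is_strict(self):
        data = np.zeros(self.grid.shape)
        data[2:6, 2:6, 2:6] = 1.0
        assert binarize_component(self._vol(data), DICIConfig(z_threshold=1.0)).n_voxels == 0

    def test_connectivity_26_bridges_diagonals(self):
        # two 13-voxel slabs touching only at one corner: one 26-cluster of 26
        data = np.zeros(self.grid.shape)
        data[2:4, 2:4, 2:5] = 2.0          # 12 voxels
        data[4, 4, 4] = 2.0                # corner-adjacent voxel
        data[5:7, 5:7, 4:7] = 2.0          # 12 voxels, corner-adjacent to (4,4,4)
        cfg26 = DICIConfig(min_cluster_voxels=20, connectivity=26)
        cfg6 = DICIConfig(min_cluster_voxels=20, connectivity=6)
        assert binarize_component(self._vol(data), cfg26).n_voxels == 25
        assert binarize_component(self._vol(data), cfg6).n_voxels == 0


class TestScoreComponent:
    def _setup(self, n_brain=1000, n_tmpl=100, n_hit=80, n_fa=10, shape=(10, 10, 10)):
        grid = VoxelGrid.isotropic(shape, 2.0)
        flat_brain = np.zeros(np.prod(shape), bool)
        flat_brain[:n_brain] = True
        flat_tmpl = np.zeros_like(flat_brain)
        flat_tmpl[:n_tmpl] = True
        flat_bin = np.zeros_like(flat_brain)
        flat_bin[:n_hit] = True
        flat_bin[n_tmpl:n_tmpl + n_fa] = True
        mk = lambda f: BinaryMask(grid, f.reshape(shape))
        return mk(flat_bin), mk(flat_tmpl), mk(flat_brain)

    def test_worked_example_matches_quantile_oracle(self):
        # 80 hits / 100 template voxels, 10 false alarms / 900 outside voxels
        b, t, br = self._setup()
        s = score_component(b, t, br)
        assert s.hr == pytest.approx(0.8)
        assert s.far == pytest.approx(10 / 900)
        expected = quantile_oracle(0.8) - quantile_oracle(10 / 900)
        assert s.dici == pytest.approx(expected, abs=1e-9)
        assert s.dici == pytest.approx(3.13, abs=0.01)

    def test_chance_level_gives_zero_dici(self):
        # HR = FAR = 0.5 -> both quantiles cancel
        b, t, br = self._setup(n_brain=300, n_tmpl=100, n_hit=50, n_fa=100)
        s = score_component(b, t, br)
        assert s.hr == pytest.approx(0.5)
        assert s.far == pytest.approx(0.5)
        assert s.dici == pytest.approx(0.0, abs=1e-12)

    def test_empty_bin_marked_invalid(self):
        b, t, br = self._setup(n_hit=0, n_fa=0)
        s = score_component(b, t, br)
        assert not s.valid
        assert np.isfinite(s.dici)  # clamped, never infinite

    def test_perfect_match_clamped_not_infinite(self):
        b, t, br = self._setup(n_hit=100, n_fa=0)
        s = score_component(b, t, br)
        assert s.valid
        assert np.isfinite(s.z_hr) and np.isfinite(s.z_far)
        assert s.hr == pytest.approx(1 - 1 / 200)
        assert s.far == pytest.approx(1 / 1800)

    def test_degenerate_template_rejected(self):
        b, t, br = self._setup()
        empty = BinaryMask(br.grid, np.zeros(br.grid.shape, bool))
        with pytest.raises(DegenerateTemplateError):
            score_component(b, empty, br)
        with pytest.raises(DegenerateTemplateError):
            score_component(b, br, br)  # template covers whole brain

    def test_random_masks_match_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        grid = VoxelGrid.isotropic((12, 12, 12), 2.0)
        brain = BinaryMask(grid, rng.random(grid.shape) < 0.7)
        for _ in range(50):
            tmpl_data = brain.data & (rng.random(grid.shape) < 0.2)
            bin_data = rng.random(grid.shape) < 0.3
            if not tmpl_data.any() or not (brain.data & ~tmpl_data).any():
                continue
            s = score_component(BinaryMask(grid, bin_data),
                                BinaryMask(grid, tmpl_data), brain)
            hit, miss, fa, cr = brute_force_confusion(bin_data, tmpl_data, brain.data)
            n_t, n_o = hit + miss, fa + cr
            hr = hit / n_t if 0 < hit < n_t else s.hr
            far = fa / n_o if 0 < fa < n_o else s.far
            assert s.hr == pytest.approx(hr)
            assert s.far == pytest.approx(far)
            expected = quantile_oracle(s.hr) - quantile_oracle(s.far)
            assert s.dici == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_hr_and_far(self):
        base = None
        for n_hit in (40, 60, 80):
            s = score_component(*self._setup(n_hit=n_hit))
            if base is not None:
                assert s.dici > base
            base = s.dici
        base = None
        for n_fa in (200, 60, 10):
            s = score_component(*self._setup(n_fa=n_fa))
            if base is not None:
                assert s.dici > base
            base = s.dici


def _score(tncs, idx, dici, valid=True):
    return ComponentScore(tncs=tncs, component_index=idx, hr=0.5, far=0.1,
                          z_hr=0.0, z_far=0.0, dici=dici, n_supra_voxels=30,
                          valid=valid)


class _FakeComponentSet:
    """Stand-in decomposition exposing only what selection needs (synthetic)."""

    def __init__(self, grid, blobs):
        # blobs: list of (value, slices) -> one map per component
        self.tncs = len(blobs)
        self.mask = BinaryMask(grid, np.ones(grid.shape, bool))
        self.reproducibility = np.ones(len(blobs))
        self._vols = []
        for val, sl in blobs:
            data = np.zeros(grid.shape)
            data[sl] = val
            self._vols.append(Volume3D(grid, data))

    def map_volume(self, i):
        return self._vols[i]


class TestSelection:
    def _grid(self):
        return VoxelGrid.isotropic((14, 14, 14), 2.0)

    def _template_and_brain(self, grid):
        tmpl = np.zeros(grid.shape, bool)
        tmpl[2:7, 2:7, 2:7] = True  # 125 voxels
        brain = np.ones(grid.shape, bool)
        return BinaryMask(grid, tmpl), BinaryMask(grid, brain)

    def test_argmax_over_tncs_candidates(self):
        grid = self._grid()
        tmpl, brain = self._template_and_brain(grid)
        overlap_good = (slice(2, 7), slice(2, 7), slice(2, 7))
        overlap_part = (slice(2, 7), slice(2, 7), slice(2, 5))
        elsewhere = (slice(8, 13), slice(8, 13), slice(8, 13))
        sets = {
            10: _FakeComponentSet(grid, [(2.0, overlap_part), (2.0, elsewhere)]),
            20: _FakeComponentSet(grid, [(2.0, elsewhere), (2.0, overlap_good)]),
        }
        sel = select_from_components(sets, tmpl, brain, DICIConfig(tncs_grid=(10, 20)),
                                     keep_component_sets=False)
        assert sel.optimal_tncs == 20
        assert sel.best.component_index == 1
        assert sel.best.hr > 0.99  # full template coverage

    def test_tie_breaks_prefer_lower_tncs(self):
        grid = self._grid()
        tmpl, brain = self._template_and_brain(grid)
        blob = (slice(2, 7), slice(2, 7), slice(2, 7))
        sets = {t: _FakeComponentSet(grid, [(2.0, blob)]) for t in (20, 30)}
        sel = select_from_components(sets, tmpl, brain, DICIConfig(tncs_grid=(20, 30)),
                                     keep_component_sets=False)
        assert sel.optimal_tncs == 20

    def test_no_surviving_component_raises(self):
        grid = self._grid()
        tmpl, brain = self._template_and_brain(grid)
        sets = {10: _FakeComponentSet(grid, [(0.5, (slice(2, 7),) * 3)])}  # below z=1
        with pytest.raises(NoTumorComponentError):
            select_from_components(sets, tmpl, brain, DICIConfig(tncs_grid=(10,)),
                                   keep_component_sets=False)

    def test_delta_dici_pairs(self):
        scores = [_score(10, i, d) for i, d in enumerate((3.0, 2.0, 1.5, 0.5))]
        deltas = _pairwise_deltas(scores)
        assert deltas["1st-2nd"] == pytest.approx(1.0)
        assert deltas["2nd-3rd"] == pytest.approx(0.5)
        assert deltas["3rd-4th"] == pytest.approx(1.0)
        assert deltas["1st-4th"] == pytest.approx(2.5)
        assert all(v >= 0 for v in deltas.values())


class TestReport:
    def _selection(self):
        grid = VoxelGrid.isotropic((14, 14, 14), 2.0)
        tmpl = np.zeros(grid.shape, bool)
        tmpl[2:7, 2:7, 2:7] = True
        brain = np.ones(grid.shape, bool)
        blobs = [(2.0, (slice(2, 7), slice(2, 7), slice(2, 7))),
                 (2.0, (slice(8, 13), slice(8, 13), slice(8, 13))),
                 (2.0, (slice(2, 7), slice(8, 13), slice(8, 13))),
                 (2.0, (slice(8, 13), slice(2, 7), slice(2, 5)))]
        sets = {t: _FakeComponentSet(grid, blobs) for t in (10, 20)}
        return select_from_components(sets, BinaryMask(grid, tmpl),
                                      BinaryMask(grid, brain),
                                      DICIConfig(tncs_grid=(10, 20)),
                                      keep_component_sets=False)

    def test_tsv_has_four_rows_per_tncs(self, tmp_path):
        sel = self._selection()
        paths = write_dici_report(sel, tmp_path)
        table = pd.read_csv(paths["tsv"], sep="\t")
        assert len(table) == 8  # 2 TNCs x 4 ranks
        assert set(table["rank"]) == {1, 2, 3, 4}

    def test_summary_consistent_with_table(self, tmp_path):
        import json

        sel = self._selection()
        paths = write_dici_report(sel, tmp_path)
        summary = json.loads((tmp_path / "dici_summary.json").read_text())
        assert summary["optimal_tncs"] == sel.optimal_tncs
        top = sel.top4_per_tncs[sel.optimal_tncs]
        assert summary["delta_dici"]["1st-2nd"] == pytest.approx(
            top[0].dici - top[1].dici)

    def test_report_bytes_deterministic(self, tmp_path):
        sel = self._selection()
        write_dici_report(sel, tmp_path / "a")
        write_dici_report(sel, tmp_path / "b")
        assert (tmp_path / "a" / "dici_report.tsv").read_bytes() == \
               (tmp_path / "b" / "dici_report.tsv").read_bytes()
        assert (tmp_path / "a" / "dici_summary.json").read_bytes() == \
               (tmp_path / "b" / "dici_summary.json").read_bytes()
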