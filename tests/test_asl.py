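"""ASL quantification: subtraction, perfusion splits, FBS maps and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from cerebroflow.asl import (
    FBSTable,
    PerfusionVolume,
    TerritoryArteryMap,
    TerritoryAtlas,
    VSASLStudy,
    NECK_ARTERY_ORDER,
    TERRITORY_NAMES,
    asl_fbs_table,
    fbs_maps,
    perfusion_splits,
    scale_by_efficiency,
    subtract_and_average,
    territory_fbs_stats,
)
from cerebroflow.errors import DegenerateSignalError, FormatError, GridMismatchError


def tiny_atlas(shape=(7, 3, 2)):
    """One territory per x-slab, no background."""
    labels = np.zeros(shape, dtype=np.int16)
    for j in range(7):
        labels[j] = j + 1
    return TerritoryAtlas(labels=labels)


class TestSubtractAndAverage:
    def test_control_equals_label_gives_zero(self):
        img = np.random.default_rng(0).normal(size=(4, 4, 2))
        out = subtract_and_average([img], [img])
        np.testing.assert_array_equal(out.voxels, 0.0)

    def test_two_pair_mean(self):
        z = np.zeros((2, 2, 1))
        out = subtract_and_average([z, z], [z + 2, z + 4])
        np.testing.assert_allclose(out.voxels, 3.0)

    def test_eight_noisy_pairs_match_naive_loop(self):
        rng = np.random.default_rng(7)
        labels = [rng.normal(size=(5, 4, 3)) for _ in range(8)]
        controls = [rng.normal(size=(5, 4, 3)) for _ in range(8)]
        out = subtract_and_average(labels, controls)
        # brute-force per-voxel loop oracle
        expected = np.empty((5, 4, 3))
        for i in range(5):
            for j in range(4):
                for k in range(3):
                    acc = 0.0
                    for p in range(8):
                        acc += controls[p][i, j, k] - labels[p][i, j, k]
                    expected[i, j, k] = acc / 8
        np.testing.assert_allclose(out.voxels, expected, rtol=1e-12)

    def test_mismatched_counts_raise(self):
        z = np.zeros((2, 2, 1))
        with pytest.raises(FormatError):
            subtract_and_average([z, z], [z])

    def test_mismatched_grids_raise(self):
        with pytest.raises(GridMismatchError):
            subtract_and_average([np.zeros((2, 2, 1))], [np.zeros((3, 2, 1))])


class TestPerfusionSplits:
    def test_uniform_signal_equal_territories(self):
        atlas = tiny_atlas()
        perf = PerfusionVolume(voxels=np.ones(atlas.shape))
        ps = perfusion_splits(perf, atlas)
        for t in TERRITORY_NAMES:
            assert ps.ps[t] == pytest.approx(1 / 7, abs=1e-12)

    def test_single_territory_signal(self):
        atlas = tiny_atlas()
        vox = np.zeros(atlas.shape)
        vox[atlas.mask(3)] = 2.5  # RMCA
        ps = perfusion_splits(PerfusionVolume(voxels=vox), atlas)
        assert ps.ps["RMCA"] == pytest.approx(1.0)
        assert sum(abs(ps.ps[t]) for t in TERRITORY_NAMES if t != "RMCA") == 0.0

    def test_matches_bruteforce_summation(self):
        rng = np.random.default_rng(3)
        atlas = tiny_atlas()
        vox = rng.normal(loc=1.0, size=atlas.shape)
        ps = perfusion_splits(PerfusionVolume(voxels=vox), atlas)
        # naive loop oracle
        sums = {t: 0.0 for t in TERRITORY_NAMES}
        total = 0.0
        for idx in np.ndindex(atlas.shape):
            lab = atlas.labels[idx]
            if lab > 0:
                name = atlas.territory_names[int(lab)]
                sums[name] += vox[idx]
                total += vox[idx]
        for t in TERRITORY_NAMES:
            assert ps.ps[t] == pytest.approx(sums[t] / total, rel=1e-12)

    def test_background_excluded(self):
        labels = np.zeros((8, 3, 2), dtype=np.int16)
        for j in range(7):
            labels[j] = j + 1  # slab 7 stays background
        atlas = TerritoryAtlas(labels=labels)
        vox = np.ones((8, 3, 2))
        vox[7] = 100.0  # background signal must not contribute
        ps = perfusion_splits(PerfusionVolume(voxels=vox), atlas)
        for t in TERRITORY_NAMES:
            assert ps.ps[t] == pytest.approx(1 / 7, abs=1e-12)

    def test_zero_total_raises(self):
        atlas = tiny_atlas()
        with pytest.raises(DegenerateSignalError):
            perfusion_splits(PerfusionVolume(voxels=np.zeros(atlas.shape)), atlas)

    def test_grid_mismatch_raises(self):
        atlas = tiny_atlas()
        with pytest.raises(GridMismatchError):
            perfusion_splits(PerfusionVolume(voxels=np.ones((2, 2, 2))), atlas)

    @given(
        vox=hnp.arrays(
            float,
            (7, 3, 2),
            elements=st.floats(-2.0, 5.0, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_splits_always_sum_to_one(self, vox):
        atlas = tiny_atlas()
        if abs(vox[atlas.brain_mask].sum()) < 1e-3:
            return
        ps = perfusion_splits(PerfusionVolume(voxels=vox), atlas)
        assert sum(ps.ps.values()) == pytest.approx(1.0, abs=1e-9)


def make_study(volumes, efficiencies=None):
    eff = efficiencies or {a: 1.0 for a in NECK_ARTERY_ORDER}
    return VSASLStudy(
        volumes={a: PerfusionVolume(voxels=v) for a, v in volumes.items()},
        efficiencies=eff,
    )


class TestScaleByEfficiency:
    def test_unit_efficiency_identity(self):
        v = np.random.default_rng(0).normal(size=(3, 3, 2))
        study = make_study({a: v.copy() for a in NECK_ARTERY_ORDER})
        scaled = scale_by_efficiency(study)
        for a in NECK_ARTERY_ORDER:
            np.testing.assert_array_equal(scaled[a].voxels, v)

    def test_half_efficiency_doubles(self):
        v = np.ones((2, 2, 2))
        study = make_study(
            {a: v.copy() for a in NECK_ARTERY_ORDER},
            {a: 0.5 for a in NECK_ARTERY_ORDER},
        )
        scaled = scale_by_efficiency(study)
        np.testing.assert_allclose(scaled["RICA"].voxels, 2.0)

    def test_per_artery_ratio_check(self):
        rng = np.random.default_rng(5)
        vols = {a: rng.normal(size=(3, 2, 2)) for a in NECK_ARTERY_ORDER}
        effs = dict(zip(NECK_ARTERY_ORDER, [0.8, 0.9, 0.85, 0.95]))
        scaled = scale_by_efficiency(make_study(vols, effs))
        for a in NECK_ARTERY_ORDER:
            # naive per-voxel division oracle
            for idx in np.ndindex((3, 2, 2)):
                assert scaled[a].voxels[idx] == pytest.approx(
                    vols[a][idx] / effs[a], rel=1e-12
                )

    def test_invalid_efficiency_rejected(self):
        v = np.ones((2, 2, 2))
        with pytest.raises(FormatError):
            make_study(
                {a: v for a in NECK_ARTERY_ORDER},
                {a: 0.0 for a in NECK_ARTERY_ORDER},
            )


class TestFBSMaps:
    def test_single_supplier_voxel(self):
        shape = (2, 2, 1)
        vols = {a: np.zeros(shape) for a in NECK_ARTERY_ORDER}
        vols["LICA"][0, 0, 0] = 3.0
        maps, valid = fbs_maps({a: PerfusionVolume(voxels=v) for a, v in vols.items()})
        assert valid[0, 0, 0]
        assert maps["LICA"][0, 0, 0] == pytest.approx(1.0)
        assert maps["RICA"][0, 0, 0] == pytest.approx(0.0)

    def test_hand_fractions(self):
        shape = (1, 1, 1)
        vals = dict(zip(NECK_ARTERY_ORDER, [2.0, 1.0, 1.0, 0.0]))
        maps, valid = fbs_maps(
            {a: PerfusionVolume(voxels=np.full(shape, v)) for a, v in vals.items()}
        )
        expect = dict(zip(NECK_ARTERY_ORDER, [0.5, 0.25, 0.25, 0.0]))
        for a in NECK_ARTERY_ORDER:
            assert maps[a][0, 0, 0] == pytest.approx(expect[a])

    def test_noisy_maps_sum_to_one_at_valid_voxels(self):
        rng = np.random.default_rng(11)
        maps, valid = fbs_maps(
            {
                a: PerfusionVolume(voxels=rng.normal(size=(4, 4, 3)))
                for a in NECK_ARTERY_ORDER
            }
        )
        total = sum(maps[a] for a in NECK_ARTERY_ORDER)
        np.testing.assert_allclose(total[valid], 1.0, rtol=1e-9)

    def test_near_zero_total_masked(self):
        shape = (2, 1, 1)
        vols = {a: np.zeros(shape) for a in NECK_ARTERY_ORDER}
        vols["RICA"][0, 0, 0] = 1.0
        vols["LICA"][0, 0, 0] = 1.0
        # voxel 1 has exactly zero total -> must be invalid, not divided
        maps, valid = fbs_maps({a: PerfusionVolume(voxels=v) for a, v in vols.items()})
        assert valid[0, 0, 0] and not valid[1, 0, 0]
        assert np.isnan(maps["RICA"][1, 0, 0])


class TestTerritoryStats:
    def test_constant_map_zero_mad(self):
        atlas = tiny_atlas()
        maps = {a: np.full(atlas.shape, 0.25) for a in NECK_ARTERY_ORDER}
        table = territory_fbs_stats(maps, atlas)
        assert table.median.loc["RMCA", "RICA"] == pytest.approx(0.25)
        assert table.mad.loc["RMCA", "RICA"] == pytest.approx(0.0)

    def test_hand_median_mad(self):
        labels = np.ones((3, 1, 1), dtype=np.int16)  # RACA territory only...
        labels_full = np.zeros((3, 7, 1), dtype=np.int16)
        for j in range(7):
            labels_full[:, j, 0] = j + 1
        atlas = TerritoryAtlas(labels=labels_full)
        maps = {a: np.zeros(atlas.shape) for a in NECK_ARTERY_ORDER}
        maps["RICA"][:, 0, 0] = [0.1, 0.4, 0.7]
        table = territory_fbs_stats(maps, atlas)
        assert table.median.loc["RACA", "RICA"] == pytest.approx(0.4)
        assert table.mad.loc["RACA", "RICA"] == pytest.approx(0.3)

    def test_negative_values_retained(self):
        labels_full = np.zeros((3, 7, 1), dtype=np.int16)
        for j in range(7):
            labels_full[:, j, 0] = j + 1
        atlas = TerritoryAtlas(labels=labels_full)
        maps = {a: np.zeros(atlas.shape) for a in NECK_ARTERY_ORDER}
        maps["RVA"][:, 1, 0] = [-0.1, -0.05, 0.02]
        table = territory_fbs_stats(maps, atlas)
        assert table.median.loc["LACA", "RVA"] == pytest.approx(-0.05)

    def test_no_valid_voxels_flagged_nan(self):
        atlas = tiny_atlas()
        maps = {a: np.full(atlas.shape, 0.25) for a in NECK_ARTERY_ORDER}
        valid = np.ones(atlas.shape, dtype=bool)
        valid[atlas.mask(1)] = False
        table = territory_fbs_stats(maps, atlas, valid)
        assert np.isnan(table.median.loc["RACA", "RICA"])
        assert table.median.loc["LACA", "RICA"] == pytest.approx(0.25)

    @given(
        data=hnp.arrays(
            float, st.integers(1, 60).map(lambda n: (n,)),
            elements=st.floats(-1.0, 2.0, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_median_mad_match_sort_based_oracle(self, data):
        from cerebroflow.asl import _median_mad

        m, d = _median_mad(data)
        # sort-based brute force
        s = np.sort(data)
        n = s.size
        m_exp = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
        dev = np.sort(np.abs(data - m_exp))
        d_exp = dev[n // 2] if n % 2 else 0.5 * (dev[n // 2 - 1] + dev[n // 2])
        assert m == pytest.approx(m_exp, rel=1e-12, abs=1e-12)
        assert d == pytest.approx(d_exp, rel=1e-12, abs=1e-12)


class TestAtlasValidation:
    def test_label_out_of_range_rejected(self):
        labels = np.full((2, 2, 2), 9, dtype=np.int16)
        with pytest.raises(FormatError):
            TerritoryAtlas(labels=labels)

    def test_float_labels_rejected(self):
        with pytest.raises(FormatError):
            TerritoryAtlas(labels=np.ones((2, 2, 2)))

    def test_empty_territory_rejected(self):
        labels = np.ones((2, 2, 2), dtype=np.int16)  # only label 1 present
        with pytest.raises(FormatError):
            TerritoryAtlas(labels=labels)


class TestTerritoryArteryMap:
    def test_default_cerebellum_split(self):
        tmap = TerritoryArteryMap()
        assert tmap.arteries_of("Cerebellum") == [("RSCA", 0.5), ("LSCA", 0.5)]

    def test_shares_must_sum_to_one(self):
        with pytest.raises(FormatError):
            TerritoryArteryMap(mapping={"RACA": [("RACA", 0.9)]})


class TestFullASLPipeline:
    def test_territory_constant_truth_recovered(self):
        """Noise-free VS-ASL built from a known FBS: medians equal the truth."""
        atlas = tiny_atlas()
        rng = np.random.default_rng(2)
        truth = rng.dirichlet(np.ones(4), size=7)  # territory x artery
        ns = np.zeros(atlas.shape)
        for j in range(7):
            ns[atlas.mask(j + 1)] = 1.0 + j
        effs = dict(zip(NECK_ARTERY_ORDER, [0.8, 0.9, 0.85, 0.95]))
        vols = {}
        for k, a in enumerate(NECK_ARTERY_ORDER):
            v = np.zeros(atlas.shape)
            for j in range(7):
                v[atlas.mask(j + 1)] = ns[atlas.mask(j + 1)] * truth[j, k] * effs[a]
            vols[a] = v
        table = asl_fbs_table(make_study(vols, effs), atlas)
        for j, t in enumerate(TERRITORY_NAMES):
            for k, a in enumerate(NECK_ARTERY_ORDER):
                assert table.median.loc[t, a] == pytest.approx(truth[j, k], abs=1e-9)
                assert table.mad.loc[t, a] == pytest.approx(0.0, abs=1e-9)


class TestFBSTableRoundtrip:
    def test_long_format_roundtrip(self):
        rng = np.random.default_rng(0)
        import pandas as pd

        med = pd.DataFrame(
            rng.random((7, 4)), index=list(TERRITORY_NAMES),
            columns=list(NECK_ARTERY_ORDER),
        )
        table = FBSTable(median=med, mad=med * 0.1, source="asl")
        back = FBSTable.from_long(table.to_long())
        np.testing.assert_allclose(
            back.median.loc[table.territories, table.arteries].values, med.values
        )
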