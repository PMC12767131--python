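"""Spectral unmixing: exact recovery, noise robustness, sO2/HbT algebra."""

import numpy as np
import pytest

from pactdiff.unmix import (
    ChromophoreMaps,
    ExtinctionTable,
    compute_so2_hbt,
    load_default_extinction_table,
    lsq_unmix,
)


def _synthetic_table(rng=None):
    rng = rng or np.random.default_rng(0)
    eps = np.array(
        [[420.0, 1550.0], [560.0, 1330.0], [790.0, 810.0], [1100.0, 710.0]]
    )
    return ExtinctionTable(wavelengths_nm=np.array([730, 756, 796, 866.0]), epsilon=eps)


def _forward(table, c_hbo, c_hbr):
    vols = []
    for k in range(table.epsilon.shape[0]):
        vols.append(table.epsilon[k, 0] * c_hbo + table.epsilon[k, 1] * c_hbr)
    return vols


class TestLsqUnmix:
    def test_exact_recovery_noise_free(self, rng):
        table = _synthetic_table()
        c_hbo = rng.random((5, 6, 7))
        c_hbr = rng.random((5, 6, 7))
        maps = lsq_unmix(_forward(table, c_hbo, c_hbr), table, prefilter=False)
        assert np.max(np.abs(maps.c_hbo - c_hbo)) < 1e-10 * c_hbo.max()
        assert np.max(np.abs(maps.c_hbr - c_hbr)) < 1e-10 * c_hbr.max()

    def test_zero_volumes_give_zero_concentrations(self):
        table = _synthetic_table()
        maps = lsq_unmix([np.zeros((4, 4, 4))] * 4, table, prefilter=False)
        assert np.all(maps.c_hbo == 0) and np.all(maps.c_hbr == 0)

    def test_proportional_spectra_rejected(self):
        eps = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        with pytest.raises(ValueError):
            ExtinctionTable(np.array([730, 756, 796, 866.0]), eps)

    def test_laser_power_normalization_recovers_concentrations(self, rng):
        table = _synthetic_table()
        c_hbo = rng.random((3, 4, 4))
        c_hbr = rng.random((3, 4, 4))
        powers = [0.8, 1.1, 0.9, 1.3]
        vols = [p * v for p, v in zip(powers, _forward(table, c_hbo, c_hbr))]
        maps = lsq_unmix(vols, table, laser_powers=powers, prefilter=False)
        assert np.allclose(maps.c_hbo, c_hbo, atol=1e-10)

    def test_negative_solutions_clamped_and_flagged(self):
        table = _synthetic_table()
        # PA values inconsistent with non-negative concentrations
        vols = [np.full((2, 2, 2), v) for v in (-1000.0, 200.0, 100.0, 50.0)]
        maps = lsq_unmix(vols, table, prefilter=False)
        assert np.all(maps.c_hbo >= 0) and np.all(maps.c_hbr >= 0)
        assert maps.clamped.any()

    def test_wavelength_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lsq_unmix([np.zeros((2, 2, 2))] * 3, _synthetic_table())

    def test_so2_recovery_under_one_percent_noise(self):
        """Median relative sO2 error stays below 5% at 1% additive noise."""
        rng = np.random.default_rng(42)
        table = _synthetic_table()
        shape = (6, 16, 16)
        c_hbo = rng.uniform(0.2, 1.0, shape)
        c_hbr = rng.uniform(0.2, 1.0, shape)
        vols = _forward(table, c_hbo, c_hbr)
        scale = max(v.max() for v in vols)
        noisy = [v + 0.01 * scale * rng.standard_normal(shape) for v in vols]
        maps = compute_so2_hbt(lsq_unmix(noisy, table, prefilter=False))
        so2_true = c_hbo / (c_hbo + c_hbr)
        rel = np.abs(maps.so2[maps.valid] - so2_true[maps.valid]) / so2_true[maps.valid]
        assert np.median(rel) < 0.05


class TestSo2Hbt:
    def test_equal_concentrations_give_half(self):
        maps = ChromophoreMaps(c_hbo=np.full((3, 3, 3), 0.4),
                               c_hbr=np.full((3, 3, 3), 0.4))
        compute_so2_hbt(maps, hbt_floor=0.0)
        assert np.allclose(maps.so2, 0.5)
        assert np.allclose(maps.c_hbt, 0.8)

    def test_pure_oxygenated_gives_one(self):
        maps = ChromophoreMaps(c_hbo=np.ones((2, 2, 2)), c_hbr=np.zeros((2, 2, 2)))
        compute_so2_hbt(maps, hbt_floor=0.0)
        assert np.allclose(maps.so2, 1.0)

    def test_empty_voxels_masked(self):
        c = np.zeros((2, 2, 2))
        c[0, 0, 0] = 1.0
        maps = compute_so2_hbt(ChromophoreMaps(c_hbo=c, c_hbr=c.copy()))
        assert maps.valid[0, 0, 0]
        assert not maps.valid[1, 1, 1]
        assert np.isnan(maps.so2[1, 1, 1])

    def test_hbt_additivity_exact(self, rng):
        hbo = rng.random((4, 4, 4))
        hbr = rng.random((4, 4, 4))
        maps = compute_so2_hbt(ChromophoreMaps(c_hbo=hbo, c_hbr=hbr))
        assert np.array_equal(maps.c_hbt, hbo + hbr)
        assert np.all((maps.so2[maps.valid] >= 0) & (maps.so2[maps.valid] <= 1))

    def test_negative_concentrations_rejected(self):
        with pytest.raises(ValueError):
            compute_so2_hbt(ChromophoreMaps(c_hbo=np.full((2, 2, 2), -1.0),
                                            c_hbr=np.zeros((2, 2, 2))))


def test_default_extinction_table_loads_and_is_full_rank():
    table = load_default_extinction_table()
    assert table.epsilon.shape == (4, 2)
    assert list(table.wavelengths_nm) == [730, 756, 796, 866]
    assert np.linalg.matrix_rank(table.epsilon) == 2
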