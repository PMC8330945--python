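"""Balancing, distance-decay fits, insertion rescaling, insulation and
boundary calling, differential boxes."""

import numpy as np
import pytest

from tgmap import (
    ContactMatrix,
    GenomicInterval,
    balance_matrix,
    call_boundaries,
    differential_box,
    fit_distance_decay,
    insulation_track,
    rescale_for_insertion,
    simulate_hic,
)

WINDOWS = [60_000, 80_000, 120_000, 200_000]


def matrix_from(m, bin_size=10_000, **kw):
    return ContactMatrix(chrom="chrH", bin_size=bin_size, matrix=np.asarray(m, float), **kw)


def test_contact_matrix_validation():
    with pytest.raises(ValueError):
        matrix_from([[1, 2], [3, 1]])  # asymmetric
    with pytest.raises(ValueError):
        matrix_from([[1, -2], [-2, 1]])  # negative
    with pytest.raises(ValueError):
        ContactMatrix("c", 0, np.ones((2, 2)))


def test_coo_round_trip(tmp_path):
    m = simulate_hic(n_bins=30, decay_alpha=-1.0, mean_count=20, seed=3)
    m.masked[4] = True
    path = tmp_path / "m.coo"
    m.to_coo_text(path)
    back = ContactMatrix.from_coo_text(path)
    assert np.allclose(back.matrix, m.matrix)
    assert back.bin_size == m.bin_size and back.chrom == m.chrom
    assert back.masked[4] and back.masked.sum() == 1


def test_balance_constant_matrix_unchanged_up_to_scale():
    m = matrix_from(np.full((20, 20), 5.0))
    b = balance_matrix(m)
    ratio = b.matrix / m.matrix
    assert np.allclose(ratio, ratio[0, 0])


def test_balance_equalises_row_sums():
    rng = np.random.default_rng(2)
    base = simulate_hic(n_bins=40, decay_alpha=-0.8, mean_count=40, seed=7).matrix
    scale = rng.uniform(0.5, 2.0, size=40)
    skewed = matrix_from(base * np.outer(scale, scale))
    b = balance_matrix(skewed)
    sums = b.matrix[~b.masked][:, ~b.masked].sum(axis=1)
    assert np.max(np.abs(sums / sums.mean() - 1)) < 1e-4
    assert np.allclose(b.matrix, b.matrix.T)


def test_balance_masks_sparse_bins():
    m = simulate_hic(n_bins=20, decay_alpha=-1.0, mean_count=30, seed=1).matrix.copy()
    m[5, :] = 0
    m[:, 5] = 0
    b = balance_matrix(matrix_from(m))
    assert b.masked[5]
    assert (b.matrix[5] == 0).all()
    with pytest.raises(ValueError):
        balance_matrix(matrix_from(np.zeros((5, 5))))


def test_decay_fit_flat_matrix_zero_alpha():
    flat = simulate_hic(n_bins=40, decay_alpha=0.0, mean_count=10, noise=False)
    assert fit_distance_decay(flat).alpha == pytest.approx(0.0, abs=1e-9)


def test_decay_fit_noisy_recovery_seed42():
    m = simulate_hic(n_bins=200, decay_alpha=-1.0, mean_count=50, seed=42)
    fit = fit_distance_decay(m)
    assert abs(fit.alpha - (-1.0)) <= 0.05
    assert fit.n_points >= 5
    assert -1.0 <= fit.r_value <= 1.0


def test_decay_fit_region_and_errors():
    m = simulate_hic(n_bins=100, decay_alpha=-0.5, mean_count=50, noise=False)
    region = GenomicInterval("chrH", 200_000, 700_000)
    assert fit_distance_decay(m, region).alpha == pytest.approx(-0.5, abs=0.01)
    with pytest.raises(ValueError):
        fit_distance_decay(m, GenomicInterval("chrH", 0, 50_000))  # < 10 bins


def test_rescale_for_insertion():
    m = simulate_hic(n_bins=40, decay_alpha=-1.0, mean_count=30, noise=False)
    p = 20 * m.bin_size  # insertion at the bin-20 edge
    same = rescale_for_insertion(m, p, delta=50_000, alpha=0.0)
    assert np.allclose(same.matrix, m.matrix)
    # a straddling pair at distance d = delta with alpha = -1 halves
    delta = 100_000
    scaled = rescale_for_insertion(m, p, delta=delta, alpha=-1.0)
    i, j = 15, 25  # mids 155 kb and 255 kb, d = 100 kb, straddle 200 kb
    assert scaled.matrix[i, j] == pytest.approx(0.5 * m.matrix[i, j])
    # non-straddling pairs unchanged
    assert np.allclose(scaled.matrix[:15, :15], m.matrix[:15, :15])
    with pytest.raises(ValueError):
        rescale_for_insertion(m, p, delta=-1, alpha=-1.0)


def test_insulation_uniform_and_blocks():
    uniform = matrix_from(np.full((40, 40), 8.0))
    track = insulation_track(uniform, 60_000)
    vals = track.scores[~np.isnan(track.scores)]
    assert np.allclose(vals, vals[0])
    # two blocks with zero crosstalk: global minimum at the junction bin
    block = np.zeros((40, 40))
    block[:20, :20] = 6.0
    block[20:, 20:] = 6.0
    track2 = insulation_track(matrix_from(block), 60_000)
    assert np.nanargmin(track2.scores) == 20
    with pytest.raises(ValueError):
        insulation_track(uniform, 65_000)  # not a bin multiple
    with pytest.raises(ValueError):
        insulation_track(uniform, 400_000)  # larger than the matrix


def test_boundaries_uniform_matrix_none():
    uniform = matrix_from(np.full((60, 60), 8.0))
    assert call_boundaries(uniform, WINDOWS[:2]) == []


def test_boundaries_two_block_matrix_all_windows():
    rng = np.random.default_rng(9)
    n = 100
    block = np.zeros((n, n))
    block[:50, :50] = 20.0
    block[50:, 50:] = 20.0
    noise = rng.poisson(block)
    m = matrix_from(np.triu(noise) + np.triu(noise, 1).T)
    calls = call_boundaries(m, WINDOWS)
    assert len(calls) == 1
    call = calls[0]
    assert abs(call.bin - 50) <= 1
    assert sorted(call.detected_windows_bp) == sorted(WINDOWS)
    assert call.smallest_window_bp == min(WINDOWS)
    with pytest.raises(ValueError):
        call_boundaries(m, [])


def test_boundary_found_at_simulated_insulation_dip():
    m = simulate_hic(n_bins=200, decay_alpha=-1.0, boundary_bins=[120],
                     insulation_factor=0.5, mean_count=50, seed=4)
    track = insulation_track(m, 60_000)
    assert abs(int(np.nanargmin(track.scores)) - 120) <= 1
    calls = call_boundaries(m, WINDOWS)
    assert any(abs(c.bin - 120) <= 1 for c in calls)


def test_differential_box_formula_exact():
    wt = simulate_hic(n_bins=60, decay_alpha=-1.0, mean_count=40, seed=11)
    mut = ContactMatrix("chrH", 10_000, wt.matrix * 0.61)
    box = (GenomicInterval("chrH", 0, 300_000), GenomicInterval("chrH", 300_000, 600_000))
    res = differential_box(mut, wt, box)
    assert res.fc == pytest.approx(-0.39)
    same = differential_box(wt, wt, box)
    assert same.fc == 0.0 and same.p_value == pytest.approx(1.0)


def test_differential_box_detects_insulation_loss():
    wt = simulate_hic(n_bins=200, decay_alpha=-1.0, mean_count=50, seed=42)
    mut = simulate_hic(n_bins=200, decay_alpha=-1.0, boundary_bins=[100],
                       insulation_factor=0.5, mean_count=50, seed=43)
    box = (GenomicInterval("chrH", 600_000, 1_000_000),
           GenomicInterval("chrH", 1_000_000, 1_400_000))
    res = differential_box(mut, wt, box)
    assert res.fc == pytest.approx(-0.5, abs=0.05)
    assert res.p_value < 1e-3


def test_differential_box_errors():
    wt = simulate_hic(n_bins=30, decay_alpha=-1.0, mean_count=20, seed=1)
    other = simulate_hic(n_bins=30, bin_size=20_000, decay_alpha=-1.0, mean_count=20, seed=1)
    box = (GenomicInterval("chrH", 0, 100_000), GenomicInterval("chrH", 100_000, 200_000))
    with pytest.raises(ValueError):
        differential_box(other, wt, box)
    empty = (GenomicInterval("chrH", 0, 0), GenomicInterval("chrH", 0, 100_000))
    with pytest.raises(ValueError):
        differential_box(wt, wt, empty)
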