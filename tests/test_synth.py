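"""Generator determinism, truth-record consistency and distributional checks."""

import numpy as np
import pytest

from tgmap import (
    GenomicInterval,
    ScenarioConfig,
    default_viewpoint,
    digest,
    fit_distance_decay,
    simulate_4c,
    simulate_ct,
    simulate_depth,
    simulate_hic,
    simulate_long_reads,
    simulate_scenario,
    simulate_tla_reads,
)
from tgmap.synth import random_fragments


def small_config(**kw):
    defaults = dict(
        seed=7,
        host_chrom_length=120_000,
        transgene_length=8_000,
        insertion_point=60_000,
        tsd_length=300,
        n_tla_reads=50,
        tla_neighborhood=15_000,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


def test_scenario_additivity_and_truth():
    cfg = small_config(n_full_copies=1, partial_fraction=0.4, tsd_length=600)
    b = simulate_scenario(cfg)
    tg = cfg.transgene_length
    assert b.truth["added_length"] == int(round(1.4 * tg)) + 600
    assert len(b.truth["junctions"]) == 2
    assert b.mutant.length(cfg.host_chrom) == cfg.host_chrom_length + b.truth["added_length"]


def test_scenario_tandem_junction_count():
    # two full copies plus a full-length "partial" = three tandem components,
    # hence two internal tail-to-head junctions
    cfg = small_config(n_full_copies=2, partial_fraction=1.0)
    b = simulate_scenario(cfg)
    assert b.truth["n_copies"] == 3
    assert b.truth["tandem_junctions_tail_to_head"] == 2
    assert b.truth["added_length"] == 3 * cfg.transgene_length + cfg.tsd_length


def test_scenario_deterministic():
    a = simulate_scenario(small_config())
    b = simulate_scenario(small_config())
    assert a.mutant["chrH"] == b.mutant["chrH"]
    assert a.truth == b.truth


def test_scenario_validation_errors():
    with pytest.raises(ValueError):
        ScenarioConfig(host_chrom_length=1000, transgene_length=5000)
    with pytest.raises(ValueError):
        small_config(insertion_point=10 ** 9)
    with pytest.raises(ValueError):
        small_config(partial_fraction=0.0)


def test_digest_fragments_tile_and_end_with_motif():
    seq = "AACATGGGCATGTT"
    frags = digest(seq, "CATG")
    assert frags == [(0, 6), (6, 12), (12, 14)]
    assert all(seq[s:e].endswith("CATG") for s, e in frags[:-1])


def test_tla_reads_basics(bundle, tla_reads):
    assert simulate_tla_reads(bundle, n_reads=0) == []
    # same seed twice: byte-identical
    again = simulate_tla_reads(bundle)
    assert [r.sequence for r in again] == [r.sequence for r in tla_reads]
    # viewpoint inside the transgene yields junction-straddling reads
    assert sum(r.tags["spans_junction"] for r in tla_reads) > 0
    # each ligation junction retains exactly one motif copy: every fragment
    # of every read ends with the motif or is chromosome-terminal
    read = tla_reads[0]
    for s, e in read.tags["fragments"]:
        frag = bundle.mutant["chrH"][s:e]
        assert "CATG" not in frag[:-4]


def test_tla_reads_require_motif():
    cfg = small_config(restriction_motif="AAAATTTTCCCCGGGG")
    b = simulate_scenario(cfg)
    with pytest.raises(ValueError):
        simulate_tla_reads(b, n_reads=5)


def test_long_reads_error_free_and_on_target(bundle):
    target = GenomicInterval("chrH", 1_150_000, 1_190_000)  # unique host region
    reads = simulate_long_reads(
        bundle, target, n_reads=5, read_length_range=(5_000, 8_000),
        error_rate=0.0, off_target_fraction=0.0, seed=3,
    )
    chrom = bundle.mutant["chrH"]
    for r in reads:
        assert r.tags["on_target"]
        _, s, e = r.tags["origin"]
        raw = chrom[s:e]
        assert r.sequence in (raw, raw.translate(str.maketrans("ACGT", "TGCA"))[::-1])
        assert s >= target.start and e <= target.end


def test_depth_zero_coverage_and_copy_ratio(bundle):
    zeros = simulate_depth(bundle, mean_cov=0.0)
    assert (zeros["test_count"] == 0).all() and (zeros["control_count"] == 0).all()
    depth = simulate_depth(bundle, window=1_000, mean_cov=100.0)
    again = simulate_depth(bundle, window=1_000, mean_cov=100.0)
    assert depth.equals(again)
    four = depth[depth["true_allele_count"] == 4]
    ratio = four["test_count"].mean() / four["control_count"].mean()
    assert ratio == pytest.approx(2.0, rel=0.1)


def test_hic_matrix_properties():
    m = simulate_hic(n_bins=80, decay_alpha=-1.0, boundary_bins=[40],
                     insulation_factor=0.5, mean_count=30, seed=5)
    assert np.array_equal(m.matrix, m.matrix.T)
    # expectation with factor 1 depends on distance only
    e = simulate_hic(n_bins=80, decay_alpha=-1.0, boundary_bins=[40],
                     insulation_factor=1.0, mean_count=30, noise=False)
    d = np.abs(np.subtract.outer(np.arange(80), np.arange(80)))
    assert np.allclose(e.matrix[d == 5], e.matrix[0, 5])
    # alpha = 0: flat expected off-diagonal
    flat = simulate_hic(n_bins=40, decay_alpha=0.0, mean_count=10, noise=False)
    off = flat.matrix[~np.eye(40, dtype=bool)]
    assert np.allclose(off, 10.0)
    # mean linearity in mean_count (expectation matrices)
    e2 = simulate_hic(n_bins=80, decay_alpha=-1.0, mean_count=60, noise=False)
    e1 = simulate_hic(n_bins=80, decay_alpha=-1.0, mean_count=30, noise=False)
    assert np.allclose(e2.matrix, 2 * e1.matrix)


def test_hic_noise_free_decay_recovered_exactly():
    e = simulate_hic(n_bins=200, decay_alpha=-1.0, mean_count=50, noise=False)
    fit = fit_distance_decay(e)
    assert fit.alpha == pytest.approx(-1.0, abs=0.01)
    assert fit.r_value == pytest.approx(-1.0, abs=1e-6)


def test_hic_validation():
    with pytest.raises(ValueError):
        simulate_hic(n_bins=10, decay_alpha=0.5)
    with pytest.raises(ValueError):
        simulate_hic(n_bins=10, bin_size=0)
    with pytest.raises(ValueError):
        simulate_hic(n_bins=10, boundary_bins=[5], insulation_factor=1.5)


def test_4c_expectations():
    rng = np.random.default_rng(0)
    frags = random_fragments(0, 200_000, 2_000, rng)
    vp = 100_000
    # no boundary: expected profile decays monotonically away from viewpoint
    prof = simulate_4c(vp, frags, boundary_positions=[], noise=False)
    mids = prof.midpoints
    right = prof.scores[mids > vp]
    assert (np.diff(right) <= 0).all()
    # symmetric fragments, no boundary: equal expected scores
    sym = simulate_4c(1_000, [(0, 400), (1600, 2000)], noise=False)
    assert sym.scores[0] == pytest.approx(sym.scores[1])
    # boundary on the right reduces the right-hand share
    wall = simulate_4c(vp, frags, boundary_positions=[150_000],
                       insulation_factor=0.5, noise=False)
    sel = mids > 150_000
    assert wall.scores[sel].sum() == pytest.approx(0.5 * prof.scores[sel].sum())
    assert np.allclose(wall.scores[~sel], prof.scores[~sel])


def test_ct_noise_free_recovery():
    table = simulate_ct(
        {"wt": {"tg": 2.0}, "carrier": {"tg": 4.0}},
        reference_target="ref",
        noise_sd=0.0,
        seed=1,
    )
    by = table.groupby(["sample", "target"])["ct"].mean()
    # delta-Ct recovers log2 copy ratios exactly without noise
    d_wt = by[("wt", "tg")] - by[("wt", "ref")]
    d_carrier = by[("carrier", "tg")] - by[("carrier", "ref")]
    assert 2.0 ** (-(d_carrier - d_wt)) * 2.0 == pytest.approx(4.0)
    assert 2.0 ** (-(d_wt - d_wt)) * 2.0 == pytest.approx(2.0)
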