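import math

import numpy as np
import pytest
from scipy.stats import norm

import peaklinks as pl
from peaklinks.core import ConfigError, DegenerateInputError
from peaklinks.scoring import LinkScorer, match_trans_peaks


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_raw_is_identity(tiny_dataset):
    out = pl.normalize_counts(tiny_dataset.atac, "raw")
    assert np.array_equal(out, tiny_dataset.atac.toarray())


def test_normalize_lognorm_closed_form():
    counts = np.array([[10_000.0, 0.0]])
    out = pl.normalize_counts(counts, "lognorm")
    assert out[0, 0] == pytest.approx(math.log(10_001), abs=1e-9)
    assert out[0, 1] == 0.0
    assert np.array_equal(pl.normalize_counts(np.zeros((3, 2))), np.zeros((3, 2)))


def test_normalize_unknown_method():
    with pytest.raises(ConfigError):
        pl.normalize_counts(np.ones((2, 2)), "cpm")


# ---------------------------------------------------------------------------
# elementary link statistics
# ---------------------------------------------------------------------------

def test_pearson_link_against_brute_force_oracle():
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(100):
        n = int(rng.integers(3, 50))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
        worst = max(worst, abs(pl.pearson_link(x, y) - oracle))
    assert worst <= 1e-12


def test_pearson_link_edge_cases():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    assert pl.pearson_link(x, x) == pytest.approx(1.0)
    assert pl.pearson_link(x, -x) == pytest.approx(-1.0)
    assert math.isnan(pl.pearson_link(x, np.ones(4)))
    with pytest.raises(DegenerateInputError):
        pl.pearson_link(x[:2], x[:2])


def test_count_both_nonzero():
    assert pl.count_both_nonzero([1, 0, 2], [0, 5, 3]) == 1
    assert pl.count_both_nonzero([1, 0], [0, 1]) == 0
    assert pl.count_both_nonzero(np.ones(20), np.ones(20)) == 20


@pytest.mark.parametrize(
    "distance,expected",
    [(0, 1.0), (200_000, math.exp(-1)), (500_000, math.exp(-2.5))],
)
def test_distance_weight(distance, expected):
    assert pl.distance_weight(distance) == pytest.approx(expected, rel=1e-12)


def test_distance_weight_rejects_negative():
    with pytest.raises(ConfigError):
        pl.distance_weight(-1)


def test_weighted_pearson_conventions():
    assert pl.weighted_pearson(0.5, 0) == pytest.approx(0.5)
    assert pl.weighted_pearson(-0.5, 0) == pytest.approx(0.5)
    assert pl.weighted_pearson(-0.5, 0, signed=True) == pytest.approx(-0.5)
    assert pl.weighted_pearson(0.4, 200_000) == pytest.approx(0.4 * math.exp(-1))
    # strictly decreasing in distance at fixed R
    ws = [pl.weighted_pearson(0.4, d) for d in (0, 1000, 50_000, 400_000)]
    assert all(a > b for a, b in zip(ws, ws[1:]))


def test_cellular_detection_rates(tiny_dataset):
    cdr_atac, cdr_rna = pl.cellular_detection_rates(tiny_dataset)
    # cdr is the proportion of features with ZERO counts, per the convention
    assert cdr_atac.tolist() == [0.5, 0.0, 1.0, 0.0]
    assert cdr_rna.tolist() == pytest.approx([1 / 3, 2 / 3, 1 / 3, 1 / 3])
    det_atac, _ = pl.cellular_detection_rates(tiny_dataset, complement=True)
    assert np.allclose(det_atac + cdr_atac, 1.0)


def test_write_links_bedpe(tmp_path, small_sim, small_scored):
    _, dataset, _ = small_sim
    _, links = small_scored
    out = tmp_path / "links.bedpe"
    pl.write_links_bedpe(links.head(5), dataset, out)
    lines = out.read_text().strip().splitlines()
    assert len(lines) == 5
    f = lines[0].split("\t")
    assert len(f) == 10 and int(f[1]) < int(f[2]) and int(f[5]) == int(f[4]) + 1


def test_zscore_link_hand_example():
    z, p = pl.zscore_link(0.2, np.array([-0.1, 0.0, 0.1]))
    assert z == pytest.approx(2.0, abs=1e-12)
    assert p == pytest.approx(1 - norm.cdf(2.0), abs=1e-12)
    z0, p0 = pl.zscore_link(0.0, np.array([-0.1, 0.0, 0.1]))
    assert (z0, p0) == (pytest.approx(0.0), pytest.approx(0.5))
    z2, p2 = pl.zscore_link(0.2, np.array([-0.1, 0.0, 0.1]), two_sided=True)
    assert p2 == pytest.approx(2 * (1 - norm.cdf(2.0)), abs=1e-12)


# ---------------------------------------------------------------------------
# matched trans-peak sampling
# ---------------------------------------------------------------------------

def _pool(features):
    return [
        pl.PeakAnnotation(pl.GenomicInterval("chrT1", 10 * i, 10 * i + 5, id=f"t{i}"),
                          gc=gc, log_coverage=lc)
        for i, (gc, lc) in enumerate(features)
    ]


def test_match_uniform_when_features_identical():
    pool = _pool([(0.5, 3.0)] * 20)
    target = pl.PeakAnnotation(pl.GenomicInterval("chr1", 0, 5, id="x"),
                               gc=0.5, log_coverage=3.0)
    counts = np.zeros(20)
    reps = 1000
    rng = np.random.default_rng(0)
    for _ in range(reps):
        ids = match_trans_peaks(target, pool, n_draws=5, seed=rng)
        for pid in ids:
            counts[int(pid[1:])] += 1
    expect = reps * 5 / 20
    sigma = math.sqrt(reps * (5 / 20) * (1 - 5 / 20))
    assert np.all(np.abs(counts - expect) < 3 * sigma + 1e-9)


def test_match_prefers_near_cluster():
    # two clusters >= 5 standardized units apart; target sits in cluster A
    pool = _pool([(0.3, 2.0)] * 50 + [(0.7, 8.0)] * 50)
    target = pl.PeakAnnotation(pl.GenomicInterval("chr1", 0, 5, id="x"),
                               gc=0.3, log_coverage=2.0)
    ids = match_trans_peaks(target, pool, n_draws=40, bandwidth=0.1, seed=1)
    frac_a = np.mean([int(i[1:]) < 50 for i in ids])
    assert frac_a >= 0.95


def test_match_pool_too_small_errors():
    pool = _pool([(0.5, 3.0)] * 5)
    target = pl.PeakAnnotation(pl.GenomicInterval("chr1", 0, 5, id="x"))
    with pytest.raises(ConfigError, match="n_draws"):
        match_trans_peaks(target, pool, n_draws=10)


def test_default_draw_counts():
    from peaklinks.scoring import DEFAULT_N_DRAWS, DIAGNOSTIC_N_DRAWS
    assert DEFAULT_N_DRAWS == 200
    assert DIAGNOSTIC_N_DRAWS == 1000


# ---------------------------------------------------------------------------
# whole-table scoring
# ---------------------------------------------------------------------------

def test_scaled_null_standardized(small_scored):
    scorer, links = small_scored
    r = links.iloc[0]
    null = scorer.build_null(r.peak_id, r.gene_id, n_draws=60)
    assert null.scaled_null.mean() == pytest.approx(0.0, abs=1e-9)
    assert null.scaled_null.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
    assert len(null.matched_peak_ids) == 60
    gene_chrom = {g.gene_id: g.chrom for g in scorer.dataset.genes}[r.gene_id]
    idx = scorer.dataset.peak_index()
    for pid in null.matched_peak_ids:
        assert scorer.dataset.peaks[idx[pid]].interval.chrom != gene_chrom


def test_score_deterministic_and_threshold_nested(small_sim):
    _, dataset, _ = small_sim
    cands = pl.cis_candidates(dataset.peaks, dataset.genes)
    a = pl.score_links(dataset, cands, seed=3, n_draws=50)
    b = pl.score_links(dataset, cands, seed=3, n_draws=50)
    assert a.equals(b)
    loose = pl.score_links(dataset, cands, methods=("pearson",), r_threshold=0.01)
    strict = pl.score_links(dataset, cands, methods=("pearson",), r_threshold=0.1)
    loose_keys = set(zip(loose.peak_id, loose.gene_id))
    strict_keys = set(zip(strict.peak_id, strict.gene_id))
    assert strict_keys <= loose_keys


def test_score_row_order_does_not_change_zscores(small_sim):
    _, dataset, _ = small_sim
    cands = pl.cis_candidates(dataset.peaks, dataset.genes)[:30]
    fwd = pl.score_links(dataset, cands, seed=3, n_draws=50)
    rev = pl.score_links(dataset, cands[::-1], seed=3, n_draws=50)
    merged = fwd.merge(rev, on=["peak_id", "gene_id"], suffixes=("_f", "_r"))
    assert np.allclose(merged.zscore_f, merged.zscore_r, equal_nan=True)


def test_true_link_tops_gene_ranking():
    cfg = pl.SimulationConfig(seed=31, n_cells=800, n_genes=12, link_effect=3.0,
                              link_effect_sigma=0.0, n_trans_peaks=100,
                              frac_true_links=1.0)
    dataset, truth = pl.simulate_multiome(cfg)
    scorer = pl.LinkScorer(dataset, seed=1)
    links = scorer.score(pl.cis_candidates(dataset.peaks, dataset.genes),
                         methods=("pearson",), r_threshold=0.0, min_both_nonzero=0)
    top = links.loc[links.groupby("gene_id").pearson_r.idxmax()]
    hits = sum((p, g) in truth.true_links for p, g in zip(top.peak_id, top.gene_id))
    assert hits >= 0.75 * len(top)


# ---------------------------------------------------------------------------
# ZINB / GLM-NB
# ---------------------------------------------------------------------------

def test_zinb_zero_free_gene_takes_glmnb_path():
    rng = np.random.default_rng(2)
    y = rng.poisson(5.0, size=300) + 1
    fit = pl.fit_zinb_link(y, rng.normal(size=300),
                           rng.uniform(0, 1, 300), rng.uniform(0, 1, 300))
    assert fit.path == "glmnb"
    assert fit.absz >= 0


def test_zinb_recovers_simulated_effect():
    rng = np.random.default_rng(5)
    n = 1500
    cdr_a = rng.uniform(0.3, 0.9, n)
    cdr_r = rng.uniform(0.3, 0.9, n)
    open_ = (rng.random(n) < 0.3).astype(float)
    mu = np.exp(-0.3 + 1.0 * open_ + 0.5 * cdr_a)
    y = rng.poisson(rng.gamma(1.0, mu / 1.0))
    fit = pl.fit_zinb_link(y, open_, cdr_a, cdr_r)
    assert fit.path in ("zinb", "glmnb")
    assert fit.coefficient == pytest.approx(1.0, abs=0.25)
    assert fit.absz > 3


def test_zinb_input_validation():
    rng = np.random.default_rng(0)
    with pytest.raises(DegenerateInputError):
        pl.fit_zinb_link(np.ones(10), np.ones(10), np.ones(10), np.ones(10))
    with pytest.raises(ConfigError):
        pl.fit_zinb_link(rng.normal(size=50), np.ones(50), np.ones(50), np.ones(50))
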