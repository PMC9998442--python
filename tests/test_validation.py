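import numpy as np
import pandas as pd
import pytest

import peaklinks as pl
from peaklinks.core import ConfigError, DegenerateInputError, GenomicInterval
from peaklinks.validation import (
    build_reference_crispr,
    build_reference_pchic,
    build_reference_replicate_intersect,
    compare_methods,
    label_links,
    roc_curve,
    truth_reference,
)


def _tbl(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


# ---------------------------------------------------------------------------
# reference builders
# ---------------------------------------------------------------------------

def test_replicate_intersection():
    t1 = _tbl([("chr1", 0, 10, "g1"), ("chr1", 20, 30, "g2"), ("chr1", 40, 50, "g3")])
    t2 = _tbl([("chr1", 0, 10, "g1"), ("chr1", 20, 30, "g2"), ("chr2", 0, 10, "g4")])
    t3 = _tbl([("chr1", 0, 10, "g1"), ("chr1", 20, 30, "g2")])
    assert len(build_reference_replicate_intersect([t1])) == 3
    shared = build_reference_replicate_intersect([t1, t2, t3])
    assert {(iv.start, g) for iv, g in shared.pairs} == {(0, "g1"), (20, "g2")}
    disjoint = build_reference_replicate_intersect(
        [t1, _tbl([("chr9", 0, 5, "x")])])
    assert len(disjoint) == 0


@pytest.fixture()
def pchic_inputs():
    interactions = pd.DataFrame({
        "bait_chrom": ["chr1"] * 5,
        "bait_start": [1000, 1000, 5000, 9000, 1000],
        "bait_end": [2000, 2000, 6000, 9500, 2000],
        "oe_chrom": ["chr1", "chr1", "chr1", "chr1", "chr2"],
        "oe_start": [50_000, 30_000, 400_000, 50_000, 1000],
        "oe_end": [51_000, 31_000, 401_000, 51_000, 2000],
        "oe_is_bait": [False, True, False, False, False],
        "score_t1": [6.0, 9.0, 8.0, 4.0, 7.0],
        "score_t2": [2.0, 1.0, 1.0, 5.0, 1.0],
    })
    promoters = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1"],
        "start": [1500, 1800, 5500],
        "end": [1700, 1900, 5600],
        "gene_id": ["gA", "gB", "gC"],
    })
    return interactions, promoters


def test_pchic_filters(pchic_inputs):
    interactions, promoters = pchic_inputs
    ref = build_reference_pchic(interactions, promoters)
    # row 0: score > 5 but bait overlaps two promoters (gA, gB) -> excluded
    # row 1: bait-bait -> excluded; row 2: unique promoter gC, within 500 kb -> kept
    # row 3: max score 5 is not > 5 -> excluded; row 4: other chromosome -> excluded
    assert {(iv.start, g) for iv, g in ref.pairs} == {(400_000, "gC")}
    # valid-gene restriction drops the remaining pair
    ref2 = build_reference_pchic(interactions, promoters, valid_genes={"gA"})
    assert len(ref2) == 0


def test_crispr_builder_rules():
    rows = pd.DataFrame({
        "chrom": ["chr1"] * 5,
        "start": [0, 0, 100, 200, 300],
        "end": [50, 50, 150, 250, 350],
        "gene_id": ["g1", "g1", "g2", "g3", "g4"],
        "significant": [True, True, True, False, True],
        "cell_line": ["K562", "HCT116", "K562", "K562", "K562"],
        "include": [True, True, True, True, False],
    })
    positives, tested = build_reference_crispr(rows)
    # duplicate consistent test kept once; excluded row dropped
    assert {(iv.start, g) for iv, g in positives.pairs} == {(0, "g1"), (100, "g2")}
    assert {(iv.start, g) for iv, g in tested.pairs} == {(0, "g1"), (100, "g2"),
                                                         (200, "g3")}
    rows.loc[1, "significant"] = False  # divergent across cell lines -> dropped
    positives2, tested2 = build_reference_crispr(rows)
    assert {(iv.start, g) for iv, g in tested2.pairs} == {(100, "g2"), (200, "g3")}


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def test_label_links_overlap_conventions():
    links = pd.DataFrame({"peak_id": ["p1", "p2", "p3"],
                          "gene_id": ["g", "g", "h"]})
    ivs = {"p1": GenomicInterval("chr1", 100, 200, id="p1"),
           "p2": GenomicInterval("chr1", 100, 200, id="p2"),
           "p3": GenomicInterval("chr1", 100, 200, id="p3")}
    ref = pl.ReferenceLinkSet({(GenomicInterval("chr1", 199, 300), "g")})
    assert label_links(links, ref, ivs).tolist() == [1, 1, 0]  # 1-bp overlap; gene h no
    ref_abut = pl.ReferenceLinkSet({(GenomicInterval("chr1", 200, 300), "g")})
    assert label_links(links, ref_abut, ivs).tolist() == [0, 0, 0]  # half-open abutment


def test_label_links_idempotent_and_order_free():
    links = pd.DataFrame({"peak_id": ["p1"], "gene_id": ["g"]})
    ivs = {"p1": GenomicInterval("chr1", 0, 10, id="p1")}
    pairs = {(GenomicInterval("chr1", 5, 8), "g"), (GenomicInterval("chr1", 9, 20), "g")}
    ref = pl.ReferenceLinkSet(pairs)
    out1 = label_links(links, ref, ivs)
    out2 = label_links(links, pl.ReferenceLinkSet(set(pairs)), ivs)
    assert out1.tolist() == out2.tolist() == [1]


def test_label_links_rejects_foreign_build():
    links = pd.DataFrame({"peak_id": ["p1"], "gene_id": ["g"]})
    ivs = {"p1": GenomicInterval("chr1", 0, 10, id="p1")}
    ref = pl.ReferenceLinkSet({(GenomicInterval("1", 0, 10), "g")})
    with pytest.raises(ConfigError, match="build"):
        label_links(links, ref, ivs)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_perfect_and_tied():
    perfect = roc_curve(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
    assert perfect.auc == pytest.approx(1.0)
    tied = roc_curve(np.array([0.9, 0.5, 0.5, 0.1]), np.array([1, 1, 0, 0]))
    assert tied.auc == pytest.approx(0.875)  # tie contributes half credit
    assert np.all(np.diff(tied.tpr) >= 0) and np.all(np.diff(tied.fpr) >= 0)


def test_roc_random_scores_near_half():
    rng = np.random.default_rng(12)
    scores = rng.normal(size=10_000)
    labels = rng.integers(0, 2, size=10_000)
    assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)


def test_roc_matches_pairwise_probability_oracle():
    rng = np.random.default_rng(13)
    worst = 0.0
    for _ in range(30):
        n = int(rng.integers(10, 200))
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n) or len(np.unique(scores)) < 2:
            continue
        pos, neg = scores[labels == 1], scores[labels == 0]
        oracle = (pos[:, None] > neg[None, :]).mean() \
            + 0.5 * (pos[:, None] == neg[None, :]).mean()
        worst = max(worst, abs(roc_curve(scores, labels).auc - oracle))
    assert worst <= 1e-12


def test_roc_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        roc_curve(np.array([1.0, 2.0]), np.array([1, 1]))
    with pytest.raises(DegenerateInputError):
        roc_curve(np.array([1.0, 1.0]), np.array([1, 0]))


def test_roc_excludes_missing_scores():
    scores = np.array([0.9, np.nan, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    assert roc_curve(scores, labels).auc == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------

def test_compare_methods_surfaces_degenerate_column(small_sim, small_scored):
    _, dataset, truth = small_sim
    _, links = small_scored
    links = links.copy()
    links["abs_r"] = links.pearson_r.abs()
    links["flat"] = 1.0
    ref = truth_reference(dataset, truth.true_links)
    out = compare_methods(links, ref, ["abs_r", "flat"],
                          {p.id: p.interval for p in dataset.peaks})
    out = out.set_index("method")
    assert np.isnan(out.loc["flat", "auc"]) and out.loc["flat", "error"]
    assert 0.0 <= out.loc["abs_r", "auc"] <= 1.0 and not out.loc["abs_r", "error"]


def test_compare_methods_respects_tested_universe(small_sim, small_scored):
    _, dataset, truth = small_sim
    _, links = small_scored
    links = links.copy()
    links["abs_r"] = links.pearson_r.abs()
    ivs = {p.id: p.interval for p in dataset.peaks}
    full_ref = truth_reference(dataset, truth.true_links)
    # tested universe = links of the first half of the peaks only
    half_peaks = set(dataset.peak_ids[: len(dataset.peak_ids) // 2])
    tested = pl.ReferenceLinkSet(
        {(ivs[p], g) for p, g in zip(links.peak_id, links.gene_id)
         if p in half_peaks})
    out = compare_methods(links, full_ref, ["abs_r"], ivs, tested=tested)
    n_used = out.n_pos[0] + out.n_neg[0]
    assert n_used == (links.peak_id.isin(half_peaks)).sum()
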