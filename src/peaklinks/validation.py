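"""Reference enhancer-gene link sets and ROC validation of link statistics.

Three flavors of external truth are supported, mirroring the common public
resources: replicate-intersected predicted links (Epimap-style), promoter
capture Hi-C interactions filtered on interaction confidence and bait
uniqueness (PCHi-C-style), and CRISPR-perturbation tests with an explicit
tested universe (positives are the significant pairs; pairs never tested are
excluded rather than counted as negatives). A simulated dataset's ground
truth plugs into the same interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn.metrics

from .core import ConfigError, DegenerateInputError, GenomicInterval, tss_distance

logger = logging.getLogger("peaklinks")

DEFAULT_CHICAGO_THRESHOLD = 5.0
DEFAULT_MAX_DISTANCE = 500_000


@dataclass
class ReferenceLinkSet:
    """Labeled (element interval, gene) pairs from one truth source."""

    pairs: set[tuple[GenomicInterval, str]]
    source: str = "truth"
    notes: str = ""
    _by_gene: dict[str, list[GenomicInterval]] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for iv, gene in self.pairs:
            if not gene:
                raise ConfigError("reference pair with empty gene id")
        self._by_gene = {}
        for iv, gene in self.pairs:
            self._by_gene.setdefault(gene, []).append(iv)

    def __len__(self) -> int:
        return len(self.pairs)

    def chroms(self) -> set[str]:
        return {iv.chrom for iv, _ in self.pairs}

    def elements_for(self, gene_id: str) -> list[GenomicInterval]:
        return self._by_gene.get(gene_id, [])


@dataclass
class RocResult:
    """A threshold-sweep ROC curve with trapezoid AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _pairs_from_table(df: pd.DataFrame) -> set[tuple[GenomicInterval, str]]:
    required = {"chrom", "start", "end", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"reference table missing columns {sorted(missing)}")
    return {
        (GenomicInterval(str(r.chrom), int(r.start), int(r.end)), str(r.gene_id))
        for r in df.itertuples()
    }


def build_reference_replicate_intersect(
    tables: list[pd.DataFrame], source: str = "epimap_like"
) -> ReferenceLinkSet:
    """Keep only (interval, gene) pairs present in every replicate table."""
    if not tables:
        raise ConfigError("need at least one replicate table")
    sets = [_pairs_from_table(t) for t in tables]
    pairs = set.intersection(*sets)
    if not pairs:
        logger.warning("replicate intersection is empty")
    return ReferenceLinkSet(pairs, source=source,
                            notes=f"intersection of {len(tables)} replicates")


def build_reference_pchic(
    interactions: pd.DataFrame,
    gene_promoters: pd.DataFrame,
    score_threshold: float = DEFAULT_CHICAGO_THRESHOLD,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    valid_genes: set[str] | None = None,
) -> ReferenceLinkSet:
    """Filter promoter-capture interactions into (other-end, gene) pairs.

    Keeps interactions whose maximum per-cell-type confidence score exceeds
    ``score_threshold``, whose bait overlaps exactly one gene promoter, that
    are not bait-bait, whose other end lies within ``max_distance`` of the
    promoter on the same chromosome, and (optionally) whose gene appears in
    the expression matrix. The filters commute, so order is irrelevant.
    """
    score_cols = [c for c in interactions.columns if c.startswith("score")]
    if not score_cols:
        raise ConfigError("interactions table has no score_* columns")
    required = {"bait_chrom", "bait_start", "bait_end", "oe_chrom", "oe_start",
                "oe_end", "oe_is_bait"}
    missing = required - set(interactions.columns)
    if missing:
        raise ConfigError(f"interactions table missing columns {sorted(missing)}")
    promoters = [
        (GenomicInterval(str(r.chrom), int(r.start), int(r.end)), str(r.gene_id))
        for r in gene_promoters.itertuples()
    ]
    pairs: set[tuple[GenomicInterval, str]] = set()
    for r in interactions.itertuples():
        if max(getattr(r, c) for c in score_cols) <= score_threshold:
            continue
        if bool(r.oe_is_bait):
            continue
        bait = GenomicInterval(str(r.bait_chrom), int(r.bait_start), int(r.bait_end))
        hits = [(iv, g) for iv, g in promoters if bait.overlaps(iv)]
        if len(hits) != 1:
            continue
        prom_iv, gene = hits[0]
        if valid_genes is not None and gene not in valid_genes:
            continue
        oe = GenomicInterval(str(r.oe_chrom), int(r.oe_start), int(r.oe_end))
        if oe.chrom != prom_iv.chrom:
            continue
        prom_mid = prom_iv.midpoint
        dist = 0 if (oe.start <= prom_mid < oe.end) else min(
            abs(prom_mid - oe.start), abs(prom_mid - (oe.end - 1))
        )
        if dist > max_distance:
            continue
        pairs.add((oe, gene))
    return ReferenceLinkSet(pairs, source="pchic_like")


def build_reference_crispr(rows: pd.DataFrame) -> tuple[ReferenceLinkSet, ReferenceLinkSet]:
    """CRISPR-perturbation reference: drop excluded rows, collapse duplicate
    tests across cell lines, drop pairs with divergent significance calls;
    returns (positives, tested universe)."""
    required = {"chrom", "start", "end", "gene_id", "significant", "cell_line", "include"}
    missing = required - set(rows.columns)
    if missing:
        raise ConfigError(f"CRISPR table missing columns {sorted(missing)}")
    kept = rows[rows["include"].astype(bool)]
    verdicts: dict[tuple[GenomicInterval, str], set[bool]] = {}
    for r in kept.itertuples():
        key = (GenomicInterval(str(r.chrom), int(r.start), int(r.end)), str(r.gene_id))
        verdicts.setdefault(key, set()).add(bool(r.significant))
    consistent = {k: v for k, v in verdicts.items() if len(v) == 1}
    positives = {k for k, v in consistent.items() if True in v}
    tested = set(consistent)
    return (
        ReferenceLinkSet(positives, source="crispr_like", notes="significant pairs"),
        ReferenceLinkSet(tested, source="crispr_like", notes="tested universe"),
    )


def label_links(
    links: pd.DataFrame,
    reference: ReferenceLinkSet,
    peak_intervals: dict[str, GenomicInterval],
) -> np.ndarray:
    """Binary labels: 1 iff the link's peak overlaps (half-open, >= 1 bp) a
    reference element whose gene matches the link's gene."""
    link_chroms = {peak_intervals[p].chrom for p in links["peak_id"]}
    if len(reference) and not (reference.chroms() & link_chroms):
        raise ConfigError(
            "no reference chromosome appears in the link table; the reference "
            "is likely in a different genome build or naming scheme"
        )
    labels = np.zeros(len(links), dtype=int)
    for i, (pid, gene) in enumerate(zip(links["peak_id"], links["gene_id"])):
        iv = peak_intervals[pid]
        if any(iv.overlaps(el) for el in reference.elements_for(str(gene))):
            labels[i] = 1
    return labels


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Threshold-sweep ROC with trapezoid AUC; tied scores collapse into one
    step; missing scores are excluded (with a logged count)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ConfigError("scores and labels must have equal length")
    ok = np.isfinite(s)
    if not ok.all():
        logger.info("roc_curve: excluding %d links with missing scores",
                    int((~ok).sum()))
        s, y = s[ok], y[ok]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError(
            f"ROC needs both classes (got {n_pos} positives, {n_neg} negatives)"
        )
    if len(np.unique(s)) < 2:
        raise DegenerateInputError("ROC undefined for a constant score column")
    fpr, tpr, thresh = sklearn.metrics.roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresh, tpr, fpr, auc, n_pos, n_neg)


def truth_reference(dataset, true_links: set[tuple[str, str]]) -> ReferenceLinkSet:
    """Wrap a simulation's ground-truth (peak_id, gene_id) pairs as a
    reference link set over the dataset's peak intervals."""
    by_id = {p.id: p.interval for p in dataset.peaks}
    return ReferenceLinkSet(
        {(by_id[pid], gid) for pid, gid in true_links}, source="truth"
    )


def compare_methods(
    link_table: pd.DataFrame,
    reference: ReferenceLinkSet,
    method_columns: list[str],
    peak_intervals: dict[str, GenomicInterval],
    tested: ReferenceLinkSet | None = None,
) -> pd.DataFrame:
    """One ROC per score column on a shared label vector and link universe.

    The universe is restricted to rows where every requested score is present;
    if a ``tested`` set is given (CRISPR-style), only links overlapping a
    tested pair are kept. Degenerate columns are reported with a NaN AUC
    without affecting the others.
    """
    if len(method_columns) < 1:
        raise ConfigError("need at least one score column")
    missing = set(method_columns) - set(link_table.columns)
    if missing:
        raise ConfigError(f"link table lacks score columns {sorted(missing)}")
    universe = link_table.dropna(subset=list(method_columns)).reset_index(drop=True)
    if tested is not None:
        in_tested = label_links(universe, tested, peak_intervals).astype(bool)
        universe = universe[in_tested].reset_index(drop=True)
    labels = label_links(universe, reference, peak_intervals)
    rows = []
    for col in method_columns:
        try:
            roc = roc_curve(universe[col].to_numpy(), labels)
            rows.append({"method": col, "auc": roc.auc, "n_pos": roc.n_pos,
                         "n_neg": roc.n_neg, "error": ""})
        except DegenerateInputError as exc:
            rows.append({"method": col, "auc": float("nan"), "n_pos": int(labels.sum()),
                         "n_neg": int((1 - labels).sum()), "error": str(exc)})
    return pd.DataFrame(rows)
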