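"""Domain types, coordinate arithmetic and format I/O for paired snATAC/snRNA data.

Coordinates are 0-based half-open throughout (BED convention). Peak strings such
as ``chr16-50,684,843-50,685,984`` are parsed verbatim, without basis shifting:
the coordinates are taken "as labeled" to avoid silent off-by-one shifts between
display strings and BED-derived names.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("peaklinks")

DEFAULT_CIS_WINDOW = 500_000  # bp around a gene TSS searched for candidate peaks


class PeakLinksError(Exception):
    """Base class for errors raised by this package."""


class FormatError(PeakLinksError):
    """A file does not conform to its declared format."""


class ConfigError(PeakLinksError):
    """Invalid configuration or arguments."""


class DegenerateInputError(PeakLinksError):
    """Input on which the requested statistic is undefined."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ConfigError("interval chromosome name must be non-empty")
        if not self.start < self.end:
            raise ConfigError(
                f"interval start must be < end, got [{self.start}, {self.end}) "
                f"for {self.id or self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap of >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to the fields link inference needs: id, chromosome, TSS, strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ConfigError(f"TSS must be >= 0, got {self.tss} for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ConfigError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class PeakAnnotation:
    """An ATAC peak with the two matching covariates (GC, log coverage) and the
    broad cell-type classes it was called in."""

    interval: GenomicInterval
    gc: float = 0.5
    log_coverage: float = 0.0
    called_in: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ConfigError(f"GC fraction must be in [0,1], got {self.gc}")
        if self.log_coverage < 0:
            raise ConfigError(f"log coverage must be >= 0, got {self.log_coverage}")
        self.called_in = frozenset(self.called_in)

    @property
    def id(self) -> str:
        return self.interval.id


@dataclass
class MultiomeDataset:
    """Paired cell x peak (ATAC) and cell x gene (RNA) count matrices over one
    ordered cell list, with peak/gene annotations and per-cell type labels."""

    atac: sp.csc_matrix
    rna: sp.csc_matrix
    peaks: list[PeakAnnotation]
    genes: list[GeneAnnotation]
    barcodes: list[str]
    cell_types: np.ndarray  # dtype=object/str, one label per cell

    def __post_init__(self) -> None:
        self.atac = sp.csc_matrix(self.atac)
        self.rna = sp.csc_matrix(self.rna)
        self.cell_types = np.asarray(self.cell_types)
        n = self.atac.shape[0]
        if self.rna.shape[0] != n:
            raise ConfigError(
                f"ATAC and RNA must share the cell axis: {n} vs {self.rna.shape[0]} cells"
            )
        if self.atac.shape[1] != len(self.peaks):
            raise ConfigError(
                f"ATAC has {self.atac.shape[1]} columns but {len(self.peaks)} peaks annotated"
            )
        if self.rna.shape[1] != len(self.genes):
            raise ConfigError(
                f"RNA has {self.rna.shape[1]} columns but {len(self.genes)} genes annotated"
            )
        if len(self.barcodes) != n or len(self.cell_types) != n:
            raise ConfigError("barcodes and cell_types must have one entry per cell")
        if self.atac.nnz and self.atac.data.min() < 0:
            raise ConfigError("ATAC counts must be non-negative")
        if self.rna.nnz and self.rna.data.min() < 0:
            raise ConfigError("RNA counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.atac.shape[0]

    @property
    def peak_ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def peak_index(self) -> dict[str, int]:
        return {p.id: i for i, p in enumerate(self.peaks)}

    def gene_index(self) -> dict[str, int]:
        return {g.gene_id: i for i, g in enumerate(self.genes)}


# ---------------------------------------------------------------------------
# MTX triplet I/O (10x-style matrix.mtx + features.tsv + barcodes.tsv)
# ---------------------------------------------------------------------------

def _read_id_column(path: str | Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_mtx_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> tuple[sp.csc_matrix, list[str], list[str]]:
    """Read a MatrixMarket triplet into cell x feature counts.

    Both orientations on disk are accepted: 10x convention (features as rows)
    and cells-as-rows; the shape is disambiguated against the feature/barcode
    counts. Returns ``(counts, feature_ids, barcodes)`` with cells as rows.
    """
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    try:
        mat = sp.coo_matrix(scipy.io.mmread(str(matrix_path)))
    except Exception as exc:  # noqa: BLE001 - surface file context
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    n_feat, n_bc = len(features), len(barcodes)
    if mat.shape == (n_bc, n_feat) and mat.shape != (n_feat, n_bc):
        cells_by_features = mat
    elif mat.shape == (n_feat, n_bc):
        cells_by_features = mat.T
    else:
        raise FormatError(
            f"matrix {matrix_path} has shape {mat.shape} but {features_path} lists "
            f"{n_feat} features and {barcodes_path} lists {n_bc} barcodes"
        )
    if cells_by_features.nnz and cells_by_features.data.min() < 0:
        raise ConfigError(f"negative counts in {matrix_path}")
    return sp.csc_matrix(cells_by_features), features, barcodes


def write_mtx_triplet(
    counts: sp.spmatrix,
    feature_ids: Sequence[str],
    barcodes: Sequence[str],
    out_dir: str | Path,
) -> None:
    """Write cell x feature counts as a 10x-style triplet (features as MTX rows)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = sp.csc_matrix(counts)
    if counts.shape != (len(barcodes), len(feature_ids)):
        raise ConfigError(
            f"counts shape {counts.shape} does not match {len(barcodes)} barcodes "
            f"x {len(feature_ids)} features"
        )
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(counts.T), field="integer")
    (out / "features.tsv").write_text("".join(f"{f}\n" for f in feature_ids))
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------

_PEAK_RE = re.compile(r"^(?P<chrom>.+?)[-:](?P<start>\d[\d,]*)-(?P<end>\d[\d,]*)$")


def parse_peak_string(s: str) -> GenomicInterval:
    """Parse a peak label like ``chr16-50,684,843-50,685,984`` (en-dashes and
    thousands separators tolerated) into an interval, coordinates verbatim."""
    cleaned = s.strip().replace("–", "-").replace("—", "-")
    m = _PEAK_RE.match(cleaned)
    if m is None:
        raise FormatError(f"cannot parse peak string {s!r}")
    start = int(m["start"].replace(",", ""))
    end = int(m["end"].replace(",", ""))
    if start >= end:
        raise FormatError(f"peak string {s!r} has start >= end ({start} >= {end})")
    return GenomicInterval(m["chrom"], start, end, id=cleaned)


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / (length - #N), case-insensitive; N bases are excluded from
    numerator and denominator."""
    seq = sequence.upper()
    if not seq:
        raise DegenerateInputError("GC fraction of an empty sequence is undefined")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise DegenerateInputError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    n_n = seq.count("N")
    denom = len(seq) - n_n
    if denom == 0:
        raise DegenerateInputError("GC fraction of an all-N sequence is undefined")
    return (seq.count("G") + seq.count("C")) / denom


def peak_log_coverage(atac_counts: sp.spmatrix, peak_index: int) -> float:
    """Natural log of (1 + total counts across cells) for one peak column —
    the coverage covariate used when matching trans peaks."""
    col_sum = float(atac_counts[:, peak_index].sum())
    return float(np.log1p(col_sum))


def tss_distance(
    interval: GenomicInterval, gene: GeneAnnotation, mode: str = "edge"
) -> int:
    """Distance in bp between a peak and a gene TSS.

    ``edge`` (default): 0 when the TSS falls inside the half-open interval,
    otherwise the distance to the nearest interval edge. ``midpoint``: distance
    from the interval midpoint.
    """
    if interval.chrom != gene.chrom:
        raise ConfigError(
            f"tss_distance requires same chromosome: {interval.chrom} vs {gene.chrom}"
        )
    if mode == "midpoint":
        return abs(gene.tss - interval.midpoint)
    if mode != "edge":
        raise ConfigError(f"unknown distance mode {mode!r}")
    if interval.start <= gene.tss < interval.end:
        return 0
    return min(abs(gene.tss - interval.start), abs(gene.tss - (interval.end - 1)))


def cis_candidates(
    peaks: Iterable[PeakAnnotation],
    genes: Iterable[GeneAnnotation],
    window: int = DEFAULT_CIS_WINDOW,
    mode: str = "edge",
) -> list[tuple[str, str]]:
    """All same-chromosome (peak_id, gene_id) pairs with TSS distance <= window."""
    if window <= 0:
        raise ConfigError(f"cis window must be > 0, got {window}")
    peaks = list(peaks)
    genes = list(genes)
    by_chrom: dict[str, list[PeakAnnotation]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    out: list[tuple[str, str]] = []
    for g in genes:
        for p in by_chrom.get(g.chrom, []):
            if tss_distance(p.interval, g, mode=mode) <= window:
                out.append((p.id, g.gene_id))
    return out


# ---------------------------------------------------------------------------
# Annotation tables and dataset assembly
# ---------------------------------------------------------------------------

def read_peaks_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3+ with the 4th column as peak id (generated from coordinates if absent)."""
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{i + 1}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            pid = fields[3] if len(fields) > 3 else f"{chrom}-{start}-{end}"
            intervals.append(GenomicInterval(chrom, start, end, id=pid))
    return intervals


def read_genes_tsv(path: str | Path) -> list[GeneAnnotation]:
    """TSV with header gene_id/chrom/tss/strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"gene_id", "chrom", "tss"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """TSV with header barcode/cell_type."""
    df = pd.read_csv(path, sep="\t")
    missing = {"barcode", "cell_type"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["barcode"].astype(str), df["cell_type"].astype(str)))


def load_multiome(directory: str | Path) -> MultiomeDataset:
    """Load a fixture directory (atac/, rna/, peaks.bed, genes.tsv, labels.tsv,
    optional peak_annotations.tsv with gc/called_in columns)."""
    d = Path(directory)
    atac, peak_ids, bc_a = read_mtx_triplet(
        d / "atac" / "matrix.mtx", d / "atac" / "features.tsv", d / "atac" / "barcodes.tsv"
    )
    rna, gene_ids, bc_r = read_mtx_triplet(
        d / "rna" / "matrix.mtx", d / "rna" / "features.tsv", d / "rna" / "barcodes.tsv"
    )
    if bc_a != bc_r:
        raise FormatError(f"{d}: ATAC and RNA barcodes differ")
    intervals = {iv.id: iv for iv in read_peaks_bed(d / "peaks.bed")}
    genes = read_genes_tsv(d / "genes.tsv")
    order = {g.gene_id: g for g in genes}
    genes = [order[g] for g in gene_ids]
    gc_map: dict[str, float] = {}
    called_map: dict[str, frozenset[str]] = {}
    ann_path = d / "peak_annotations.tsv"
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t")
        gc_map = dict(zip(ann["peak_id"], ann["gc"]))
        called_map = {
            pid: frozenset(str(v).split(",")) if str(v) not in ("", "nan") else frozenset()
            for pid, v in zip(ann["peak_id"], ann.get("called_in", [""] * len(ann)))
        }
    peaks = []
    for j, pid in enumerate(peak_ids):
        if pid not in intervals:
            raise FormatError(f"{d}: peak {pid} in features.tsv but not peaks.bed")
        peaks.append(
            PeakAnnotation(
                intervals[pid],
                gc=float(gc_map.get(pid, 0.5)),
                log_coverage=peak_log_coverage(atac, j),
                called_in=called_map.get(pid, frozenset()),
            )
        )
    labels_path = d / "labels.tsv"
    labels = read_labels_tsv(labels_path) if labels_path.exists() else {}
    cell_types = np.array([labels.get(b, "unknown") for b in bc_a], dtype=object)
    return MultiomeDataset(atac, rna, peaks, genes, bc_a, cell_types)
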