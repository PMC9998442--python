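"""Link statistics for candidate peak-gene pairs.

Implements every score compared in the pipeline:

* **Pearson R** — plain sample correlation of (normalized) accessibility and
  expression across cells.
* **Z-score** — the cis correlation standardized against a null of
  correlations from trans peaks (different chromosome than the gene) matched
  to the cis peak on GC content and log(1 + total counts) coverage.
* **wDist** — exponential distance weight exp(-distance / 200 kb).
* **distance-weighted Pearson** — |R| * wDist (signed variant behind a flag).
* **ZINB |z|** — the Wald z of the accessibility coefficient in a
  zero-inflated negative binomial regression of the gene on the peak with
  cellular detection rate covariates in both components; genes with no zero
  counts fall back to an ordinary negative binomial GLM.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from .core import ConfigError, DegenerateInputError, MultiomeDataset, tss_distance

logger = logging.getLogger("peaklinks")

DISTANCE_SCALE = 200_000       # bp; e-folding scale of the distance weight
DEFAULT_N_DRAWS = 200          # matched trans peaks per null
DIAGNOSTIC_N_DRAWS = 1000      # draws used when testing null modality
DEFAULT_BANDWIDTH = 0.1        # Gaussian matching kernel, standardized units
DEFAULT_R_THRESHOLD = 0.01     # |Pearson R| filter applied before other stats
STRICT_R_THRESHOLD = 0.1       # the more stringent alternative
DEFAULT_MIN_BOTH_NONZERO = 15  # minimum cells with counts in both modalities
MATCH_GUARD_SD = 0.25          # matched-moments warning threshold, sd units

ALL_METHODS = ("pearson", "zscore", "wdist", "wdist_r", "zinb")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def normalize_counts(counts: sp.spmatrix | np.ndarray, method: str = "lognorm") -> np.ndarray:
    """Return a dense real-valued cell x feature matrix.

    ``raw`` passes counts through; ``lognorm`` is log(1 + 1e4 * count / cell
    total). Cells with zero total produce zero rows (with a logged warning).
    """
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    if method == "raw":
        return dense
    if method != "lognorm":
        raise ConfigError(f"unknown normalization method {method!r}")
    totals = dense.sum(axis=1, keepdims=True)
    zero_cells = totals[:, 0] == 0
    if zero_cells.any():
        logger.warning("%d all-zero cells produce zero rows under lognorm",
                       int(zero_cells.sum()))
    safe = np.where(totals == 0, 1.0, totals)
    return np.log1p(1e4 * dense / safe)


def pearson_link(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("pearson_link requires two equal-length vectors")
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 observations for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def count_both_nonzero(peak_counts: np.ndarray, gene_counts: np.ndarray) -> int:
    """Cells with a raw count > 0 in both the peak and the gene."""
    p = np.asarray(peak_counts).ravel()
    g = np.asarray(gene_counts).ravel()
    if p.shape != g.shape:
        raise ConfigError("vectors must have equal length")
    return int(np.count_nonzero((p > 0) & (g > 0)))


def distance_weight(distance: float) -> float:
    """exp(-distance / 200 kb)."""
    if distance < 0:
        raise ConfigError(f"distance must be >= 0, got {distance}")
    return float(np.exp(-distance / DISTANCE_SCALE))


def weighted_pearson(pearson_r: float, distance: float, signed: bool = False) -> float:
    """Distance-weighted Pearson: |R| * exp(-d/200 kb) (signed variant optional)."""
    r = pearson_r if signed else abs(pearson_r)
    return r * distance_weight(distance)


def cellular_detection_rates(
    dataset: MultiomeDataset, complement: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (cdr_atac, cdr_rna): the proportion of features with zero
    counts in each modality — the *dropout* proportion, following the
    convention this workflow glosses. ``complement=True`` returns the usual
    detection rate (proportion of non-zero features) instead; the two are
    affinely equivalent as regression covariates."""
    n_peaks = dataset.atac.shape[1]
    n_genes = dataset.rna.shape[1]
    det_atac = dataset.atac.getnnz(axis=1) / n_peaks
    det_rna = dataset.rna.getnnz(axis=1) / n_genes
    if complement:
        return det_atac, det_rna
    return 1.0 - det_atac, 1.0 - det_rna


def zscore_link(
    r_cis: float, null_r: np.ndarray, two_sided: bool = False
) -> tuple[float, float]:
    """Standardize a cis correlation against its matched null; p from the
    standard normal (one-sided upper tail by default)."""
    null_r = np.asarray(null_r, dtype=float)
    if null_r.size < 2:
        raise DegenerateInputError("need >= 2 null correlations")
    sd = float(null_r.std(ddof=1))
    if sd == 0:
        return float("nan"), float("nan")
    z = (r_cis - float(null_r.mean())) / sd
    p = 2 * norm.sf(abs(z)) if two_sided else norm.sf(z)
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Matched trans-peak sampling
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """A matched trans-peak null for one candidate link."""

    target_peak_id: str
    gene_id: str
    matched_peak_ids: list[str]
    null_r: np.ndarray
    scaled_null: np.ndarray
    n_draws: int


def _match_indices(
    features: np.ndarray,       # pool x 2 standardized (gc, log_coverage)
    target_feature: np.ndarray,  # length-2 standardized
    n_draws: int,
    bandwidth: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Weighted sampling without replacement via Gumbel-top-k on log weights
    (exact sequential/Plackett-Luce sampling; immune to exp() underflow)."""
    d2 = ((features - target_feature) ** 2).sum(axis=1)
    logw = -d2 / (2.0 * bandwidth**2)
    if not np.all(np.isfinite(logw)):
        logger.warning("non-finite matching weights; falling back to uniform sampling")
        logw = np.zeros_like(logw)
    keys = logw + rng.gumbel(size=logw.shape)
    return np.argpartition(-keys, n_draws - 1)[:n_draws]


def match_trans_peaks(
    target,
    pool: list,
    n_draws: int = DEFAULT_N_DRAWS,
    bandwidth: float = DEFAULT_BANDWIDTH,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw ``n_draws`` distinct peaks from ``pool`` weighted by a Gaussian
    kernel on standardized (GC, log coverage) distance to ``target``.

    ``target`` and pool entries are PeakAnnotations; the caller guarantees the
    pool excludes the target and the gene's chromosome.
    """
    if len(pool) < n_draws:
        raise ConfigError(
            f"null pool has {len(pool)} peaks but {n_draws} draws requested; "
            "simulate more trans peaks or reduce n_draws"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    feats = np.array([[p.gc, p.log_coverage] for p in pool], dtype=float)
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats_z = (feats - mean) / sd
    target_z = (np.array([target.gc, target.log_coverage]) - mean) / sd
    idx = _match_indices(feats_z, target_z, n_draws, bandwidth, rng)
    drift = np.abs(feats_z[idx].mean(axis=0) - target_z)
    if np.any(drift > MATCH_GUARD_SD):
        # warn for the first few offenders, then drop to debug to keep large
        # scoring runs readable
        match_trans_peaks._n_drift_warnings += 1
        log = (logger.warning if match_trans_peaks._n_drift_warnings <= 5
               else logger.debug)
        log(
            "matched draws for %s drift from target by (%.2f, %.2f) sd units "
            "(GC, log coverage)", getattr(target, "id", "?"), drift[0], drift[1]
        )
    return [pool[i].id for i in idx]


match_trans_peaks._n_drift_warnings = 0


# ---------------------------------------------------------------------------
# ZINB / GLM-NB
# ---------------------------------------------------------------------------

@dataclass
class ZinbFit:
    """Result of one per-link count regression."""

    absz: float          # |Wald z| of the peak coefficient (NaN when failed)
    path: str            # "zinb", "glmnb" or "failed"
    coefficient: float   # peak coefficient on the log-mean scale
    converged: bool


def fit_zinb_link(
    gene_counts: np.ndarray,
    peak_predictor: np.ndarray,
    cdr_atac: np.ndarray,
    cdr_rna: np.ndarray,
) -> ZinbFit:
    """Fit ``gene ~ peak + cdr_atac + cdr_rna | cdr_atac + cdr_rna`` (ZINB with
    a logit zero component) and return the |Wald z| of the peak coefficient in
    the count component.

    Genes with no zero count anywhere take an ordinary NB GLM
    (``gene ~ peak + cdr_atac + cdr_rna``) since no zero component can be
    modeled. Optimizer non-convergence yields ``path="failed"`` with a NaN
    score — never a silent zero.
    """
    import statsmodels.api as sm
    from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
    from statsmodels.discrete.discrete_model import NegativeBinomial

    y = np.asarray(gene_counts, dtype=float).ravel()
    if len(y) < 30:
        raise DegenerateInputError("need >= 30 cells for a per-link count regression")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ConfigError("gene counts must be non-negative integers")
    exog = pd.DataFrame(
        {
            "const": 1.0,
            "peak": np.asarray(peak_predictor, dtype=float).ravel(),
            "cdr_atac": np.asarray(cdr_atac, dtype=float).ravel(),
            "cdr_rna": np.asarray(cdr_rna, dtype=float).ravel(),
        }
    )
    failed = ZinbFit(float("nan"), "failed", float("nan"), False)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            nb_res = NegativeBinomial(y, exog).fit(disp=0, maxiter=200)
        except Exception:
            nb_res = None
        if not np.any(y == 0):
            return _nb_wald(y, exog, nb_res)

        exog_infl = exog[["const", "cdr_atac", "cdr_rna"]]
        model = ZeroInflatedNegativeBinomialP(y, exog, exog_infl=exog_infl, p=2)
        start = None
        if nb_res is not None and np.all(np.isfinite(nb_res.params)):
            # zero component starts mostly off (logit intercept -5); count part
            # starts at the plain-NB solution
            start = np.r_[[-5.0, 0.0, 0.0], nb_res.params.values]
        # the zero component may legitimately collapse (logit intercept
        # drifting to -inf for genes without excess zeros), leaving its
        # standard errors undefined; only the peak coefficient's Wald z is
        # needed, so require finiteness there alone
        res = None
        for kwargs in (
            {"method": "bfgs", "maxiter": 500, "start_params": start},
            {"method": "nm", "maxiter": 2000},
        ):
            try:
                cand = model.fit(disp=0, **kwargs)
            except Exception:
                continue
            if (cand.mle_retvals.get("converged", False)
                    and np.isfinite(cand.params["peak"])
                    and np.isfinite(cand.bse["peak"]) and cand.bse["peak"] > 0):
                res = cand
                break
        if res is not None:
            z = float(res.params["peak"] / res.bse["peak"])
            if np.isfinite(z):
                return ZinbFit(abs(z), "zinb", float(res.params["peak"]), True)
        # ZINB Wald information can be singular when the zero component
        # collapses to the boundary (the gene has no excess zeros); the model
        # then degenerates to a plain NB, whose Wald z is reported on the
        # glmnb path
        return _nb_wald(y, exog, nb_res)


def _nb_wald(y: np.ndarray, exog: pd.DataFrame, nb_res) -> ZinbFit:
    """Peak Wald z from a plain NB fit, falling back to the Poisson GLM limit
    when the dispersion collapses to its boundary and leaves the NB
    information matrix singular."""
    import statsmodels.api as sm

    if nb_res is not None and np.all(np.isfinite(nb_res.params)):
        se = float(nb_res.bse["peak"])
        if np.isfinite(se) and se > 0:
            return ZinbFit(abs(float(nb_res.params["peak"] / se)), "glmnb",
                           float(nb_res.params["peak"]), True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pois = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
        except Exception:
            return ZinbFit(float("nan"), "failed", float("nan"), False)
    se = float(pois.bse["peak"])
    if not (np.isfinite(se) and se > 0):
        return ZinbFit(float("nan"), "failed", float("nan"), False)
    return ZinbFit(abs(float(pois.params["peak"] / se)), "glmnb",
                   float(pois.params["peak"]), True)


# ---------------------------------------------------------------------------
# Whole-table scoring
# ---------------------------------------------------------------------------

class LinkScorer:
    """Precomputes normalized/standardized matrices and null pools for one
    dataset so individual links score in microseconds."""

    def __init__(
        self,
        dataset: MultiomeDataset,
        normalization: str = "lognorm",
        n_draws: int = DEFAULT_N_DRAWS,
        bandwidth: float = DEFAULT_BANDWIDTH,
        seed: int = 0,
        two_sided: bool = False,
        class_filter_nulls: bool = False,
    ):
        self.dataset = dataset
        self.n_draws = n_draws
        self.bandwidth = bandwidth
        self.seed = seed
        self.two_sided = two_sided
        self.class_filter_nulls = class_filter_nulls
        self.n_cells = dataset.n_cells

        atac_norm = normalize_counts(dataset.atac, normalization)
        rna_norm = normalize_counts(dataset.rna, normalization)
        self.atac_z, self.atac_valid = _standardize(atac_norm)
        self.rna_z, self.rna_valid = _standardize(rna_norm)
        self.atac_nz = np.asarray((dataset.atac > 0).todense())
        self.rna_nz = np.asarray((dataset.rna > 0).todense())
        self.peak_idx = dataset.peak_index()
        self.gene_idx = dataset.gene_index()
        self.peak_chrom = np.array([p.interval.chrom for p in dataset.peaks], dtype=object)
        # matching covariates (GC, log coverage) come from the peak
        # annotations; a missing coverage annotation is filled from the matrix
        cov = np.log1p(np.asarray(dataset.atac.sum(axis=0)).ravel())
        self.peaks = [
            p if p.log_coverage > 0
            else type(p)(p.interval, gc=p.gc, log_coverage=float(cov[j]),
                         called_in=p.called_in)
            for j, p in enumerate(dataset.peaks)
        ]
        self._all_classes = frozenset().union(*(p.called_in for p in self.peaks)) \
            if self.peaks else frozenset()
        self._cdr: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def cdr(self) -> tuple[np.ndarray, np.ndarray]:
        if self._cdr is None:
            self._cdr = cellular_detection_rates(self.dataset)
        return self._cdr

    def pearson(self, peak_id: str, gene_id: str) -> float:
        j, g = self.peak_idx[peak_id], self.gene_idx[gene_id]
        if not (self.atac_valid[j] and self.rna_valid[g]):
            return float("nan")
        return float(np.clip(self.atac_z[:, j] @ self.rna_z[:, g] / (self.n_cells - 1),
                             -1.0, 1.0))

    def _null_pool(self, peak_id: str, gene_chrom: str) -> list:
        pool = [
            p for p in self.peaks
            if p.interval.chrom != gene_chrom and p.id != peak_id
        ]
        if self.class_filter_nulls:
            from .diagnostics import filter_null_pool_by_class

            target = self.peaks[self.peak_idx[peak_id]]
            if target.called_in and self._all_classes:
                pool = filter_null_pool_by_class(pool, target.called_in, self._all_classes)
        return pool

    def build_null(
        self, peak_id: str, gene_id: str,
        n_draws: int | None = None, seed=None,
    ) -> NullDistribution:
        """Matched trans-peak null for one link: draw, correlate, scale."""
        n_draws = n_draws or self.n_draws
        j = self.peak_idx[peak_id]
        gene = self.dataset.genes[self.gene_idx[gene_id]]
        pool = self._null_pool(peak_id, gene.chrom)
        matched = match_trans_peaks(
            self.peaks[j], pool, n_draws=n_draws, bandwidth=self.bandwidth,
            seed=self._rng(peak_id, gene_id) if seed is None else seed,
        )
        cols = np.array([self.peak_idx[m] for m in matched])
        g = self.gene_idx[gene_id]
        null_r = self.atac_z[:, cols].T @ self.rna_z[:, g] / (self.n_cells - 1)
        null_r = np.where(self.atac_valid[cols], null_r, 0.0)
        sd = null_r.std(ddof=1)
        scaled = (null_r - null_r.mean()) / sd if sd > 0 else np.zeros_like(null_r)
        return NullDistribution(peak_id, gene_id, matched, null_r, scaled, n_draws)

    def _rng(self, peak_id: str, gene_id: str) -> np.random.Generator:
        # per-link stream keyed by a stable id hash so scores depend on neither
        # table order nor the process hash seed
        key = zlib.crc32(f"{peak_id}|{gene_id}".encode()) % (2**31)
        return np.random.default_rng([self.seed, key])

    def zscore(self, peak_id: str, gene_id: str, r_cis: float | None = None):
        if r_cis is None:
            r_cis = self.pearson(peak_id, gene_id)
        null = self.build_null(peak_id, gene_id)
        return zscore_link(r_cis, null.null_r, two_sided=self.two_sided)

    def zinb(self, peak_id: str, gene_id: str, normalization_peak: bool = True) -> ZinbFit:
        j, g = self.peak_idx[peak_id], self.gene_idx[gene_id]
        cdr_atac, cdr_rna = self.cdr
        y = np.asarray(self.dataset.rna[:, g].todense()).ravel()
        if normalization_peak:
            # same normalization mode as the correlation input, un-standardized
            x = self.atac_z[:, j]
        else:
            x = np.asarray(self.dataset.atac[:, j].todense()).ravel()
        return fit_zinb_link(y, x, cdr_atac, cdr_rna)

    def score(
        self,
        candidates: list[tuple[str, str]],
        methods: tuple[str, ...] = ("pearson", "zscore", "wdist", "wdist_r"),
        r_threshold: float = DEFAULT_R_THRESHOLD,
        min_both_nonzero: int = DEFAULT_MIN_BOTH_NONZERO,
    ) -> pd.DataFrame:
        unknown = set(methods) - set(ALL_METHODS)
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}")
        rows = []
        n_dropped_r = n_dropped_nz = n_failed = 0
        for peak_id, gene_id in candidates:
            j, g = self.peak_idx[peak_id], self.gene_idx[gene_id]
            gene = self.dataset.genes[g]
            dist = tss_distance(self.peaks[j].interval, gene)
            r = self.pearson(peak_id, gene_id)
            if not np.isfinite(r) or abs(r) <= r_threshold:
                n_dropped_r += 1
                continue
            nnz = int(np.count_nonzero(self.atac_nz[:, j] & self.rna_nz[:, g]))
            if nnz < min_both_nonzero:
                n_dropped_nz += 1
                continue
            row = {
                "peak_id": peak_id,
                "gene_id": gene_id,
                "distance": dist,
                "n_both_nonzero": nnz,
                "pearson_r": r,
            }
            if "zscore" in methods:
                z, p = self.zscore(peak_id, gene_id, r_cis=r)
                row["zscore"], row["z_pvalue"] = z, p
            if "wdist" in methods or "wdist_r" in methods:
                row["wdist"] = distance_weight(dist)
            if "wdist_r" in methods:
                row["wdist_r"] = weighted_pearson(r, dist)
            if "zinb" in methods:
                fit = self.zinb(peak_id, gene_id)
                row["zinb_absz"], row["zinb_path"] = fit.absz, fit.path
                if fit.path == "failed":
                    n_failed += 1
            rows.append(row)
        logger.info(
            "scored %d links (|R| filter dropped %d, both-nonzero filter dropped %d, "
            "%d regression failures)", len(rows), n_dropped_r, n_dropped_nz, n_failed,
        )
        return pd.DataFrame(rows)


def write_links_bedpe(
    links: pd.DataFrame, dataset: MultiomeDataset, path, score: str = "pearson_r"
) -> None:
    """BEDPE export for genome-browser loops: one end is the peak interval,
    the other the gene TSS +-1 bp; the score column defaults to Pearson R."""
    peak_iv = {p.id: p.interval for p in dataset.peaks}
    gene_by_id = {g.gene_id: g for g in dataset.genes}
    with open(path, "w") as fh:
        for r in links.itertuples():
            iv = peak_iv[r.peak_id]
            g = gene_by_id[r.gene_id]
            val = getattr(r, score, float("nan"))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.chrom}\t{g.tss}\t{g.tss + 1}\t"
                f"{r.peak_id}|{r.gene_id}\t{val:.6g}\t.\t{g.strand}\n"
            )


def _standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores with ddof=1; zero-variance columns flagged invalid."""
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    valid = sd > 0
    safe = np.where(valid, sd, 1.0)
    return (mat - mean) / safe, valid


def score_links(
    dataset: MultiomeDataset,
    candidates: list[tuple[str, str]],
    methods: tuple[str, ...] = ("pearson", "zscore", "wdist", "wdist_r"),
    **params,
) -> pd.DataFrame:
    """One-call scoring: build a :class:`LinkScorer` and score ``candidates``."""
    score_kwargs = {
        k: params.pop(k)
        for k in ("r_threshold", "min_both_nonzero")
        if k in params
    }
    return LinkScorer(dataset, **params).score(candidates, methods, **score_kwargs)
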