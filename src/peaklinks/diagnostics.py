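"""Multimodality diagnostics for matched trans-peak null distributions.

A matched null built in a dataset with a dominant cell type often splits into
two modes: one from trans peaks co-accessible with the tested peak's cell type
(correlated with the gene) and one from everything else. The inflated null
spread deflates the link's Z-score. This module fits a two-component Gaussian
mixture by EM (k = 2, tolerance 1e-3 on the log-likelihood) and decides
modality with a parametric-bootstrap likelihood-ratio test of one vs two
components; nulls with p < 0.05 are called multimodal. It also implements the
remedy: removing from the null pool all trans peaks called in the same broad
cell-type class as the tested cis peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError, DegenerateInputError, MultiomeDataset
from .scoring import DIAGNOSTIC_N_DRAWS, LinkScorer, NullDistribution

EM_EPSILON = 1e-3          # stop when the log-likelihood improves by less
EM_MAX_ITER = 300
EM_RESTARTS = 3
SD_FLOOR_FACTOR = 1e-4     # component sd floor, relative to the sample sd
MULTIMODAL_ALPHA = 0.05    # nominal p-value below which a null is multimodal
DEFAULT_N_BOOT = 100


@dataclass
class MixtureFit:
    """A fitted k-component univariate Gaussian mixture, components ordered by
    ascending mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class ModalityVerdict:
    """Outcome of the 1-vs-2-component bootstrap likelihood-ratio test."""

    p_value: float
    multimodal: bool
    lrt_observed: float
    n_boot: int


def _log_mixture_density(x: np.ndarray, w: np.ndarray, mu: np.ndarray,
                         sd: np.ndarray) -> np.ndarray:
    """log sum_j w_j phi(x; mu_j, sd_j), numerically via logsumexp."""
    comp = (
        np.log(w)[None, :]
        - 0.5 * np.log(2 * np.pi)
        - np.log(sd)[None, :]
        - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
    )
    m = comp.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(comp - m).sum(axis=1, keepdims=True))).ravel()


def _em_once(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray,
             epsilon: float, max_iter: int, sd_floor: float):
    n = len(x)
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        comp = (
            np.log(w)[None, :]
            - np.log(sd)[None, :]
            - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
        )
        m = comp.max(axis=1, keepdims=True)
        unnorm = np.exp(comp - m)
        resp = unnorm / unnorm.sum(axis=1, keepdims=True)
        loglik = float(_log_mixture_density(x, w, mu, sd).sum())
        trace.append(loglik)
        if loglik - prev < epsilon and it > 1:
            converged = True
            break
        prev = loglik
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-10)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
    return w, mu, sd, trace[-1], converged, it, np.array(trace)


def em_gaussian_mixture(
    values: np.ndarray,
    k: int = 2,
    epsilon: float = EM_EPSILON,
    max_iter: int = EM_MAX_ITER,
    seed: int | np.random.Generator = 0,
    restarts: int = EM_RESTARTS,
) -> MixtureFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    Multiple restarts (quantile-spread initialization plus jitter) guard
    against label-collapse local optima; the best log-likelihood is kept and
    components are returned in ascending-mean order. For k = 1 the ML solution
    is closed form.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 10 * k:
        raise DegenerateInputError(f"need >= {10 * k} values to fit k={k} components")
    sample_sd = float(x.std())
    if sample_sd == 0:
        raise DegenerateInputError("cannot fit a mixture to constant input")
    if k == 1:
        mu = np.array([x.mean()])
        sd = np.array([sample_sd])  # ML sd
        ll = float(_log_mixture_density(x, np.array([1.0]), mu, sd).sum())
        return MixtureFit(1, np.array([1.0]), mu, sd, ll, True, 0,
                          loglik_trace=np.array([ll]))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd_floor = SD_FLOOR_FACTOR * sample_sd
    best: tuple | None = None
    qs = np.quantile(x, (np.arange(k) + 0.5) / k)
    inits = [qs + rng.normal(scale=0.25 * sample_sd, size=k) if r else qs.copy()
             for r in range(restarts)]
    # degenerate init at the single-Gaussian ML solution: EM cannot decrease
    # the likelihood from there, which guarantees loglik(k) >= loglik(1)
    inits.append(np.full(k, x.mean()))
    for r, mu0 in enumerate(inits):
        sd0 = (np.full(k, sample_sd) if r == len(inits) - 1
               else np.full(k, max(sample_sd / k, sd_floor)))
        w0 = np.full(k, 1.0 / k)
        fit = _em_once(x, w0, mu0.copy(), sd0, epsilon, max_iter, sd_floor)
        if best is None or fit[3] > best[3]:
            best = fit
    w, mu, sd, ll, converged, n_iter, trace = best
    order = np.argsort(mu)
    return MixtureFit(k, w[order], mu[order], sd[order], ll, converged, n_iter,
                      loglik_trace=trace)


def multimodality_test(
    values: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = 0,
    epsilon: float = EM_EPSILON,
) -> ModalityVerdict:
    """Parametric-bootstrap likelihood-ratio test of 1 vs 2 Gaussian
    components.

    LRT_obs = 2(loglik_2 - loglik_1); ``n_boot`` datasets are simulated from
    the fitted single Gaussian, both models refitted on each, and
    p = (1 + #{LRT_b >= LRT_obs}) / (n_boot + 1). A null is flagged multimodal
    when p < 0.05.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 50:
        raise DegenerateInputError("need >= 50 values for the modality test")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fit1 = em_gaussian_mixture(x, k=1, epsilon=epsilon)
    fit2 = em_gaussian_mixture(x, k=2, epsilon=epsilon, seed=rng)
    lrt_obs = max(0.0, 2.0 * (fit2.loglik - fit1.loglik))
    n_ge = 0
    for _ in range(n_boot):
        xb = rng.normal(fit1.means[0], fit1.sds[0], size=len(x))
        b1 = em_gaussian_mixture(xb, k=1, epsilon=epsilon)
        b2 = em_gaussian_mixture(xb, k=2, epsilon=epsilon, seed=rng)
        if max(0.0, 2.0 * (b2.loglik - b1.loglik)) >= lrt_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_boot + 1)
    return ModalityVerdict(p, p < MULTIMODAL_ALPHA, lrt_obs, n_boot)


def filter_null_pool_by_class(
    pool: list,
    cis_called_in: frozenset[str] | set[str],
    all_classes: frozenset[str] | set[str],
) -> list:
    """Remove from a null pool every peak called in any of the cis peak's
    broad cell-type classes.

    A cis peak called in *all* classes is treated as non-specific and the pool
    is returned unchanged; e.g. a peak called only in B cells and Monocytes
    keeps a pool of peaks called exclusively in the remaining classes.
    """
    cis_called_in = frozenset(cis_called_in)
    all_classes = frozenset(all_classes)
    if not cis_called_in:
        raise ConfigError("cis peak has no called_in classes")
    if not cis_called_in <= all_classes:
        raise ConfigError(
            f"cis classes {sorted(cis_called_in - all_classes)} not in the declared set"
        )
    if cis_called_in == all_classes:
        return list(pool)
    filtered = [p for p in pool if not (p.called_in & cis_called_in)]
    if not filtered:
        raise ConfigError(
            "class filtering emptied the null pool; regroup classes more broadly "
            "or fall back to the unfiltered pool"
        )
    return filtered


def diagnose_null(
    dataset: MultiomeDataset | LinkScorer,
    peak_id: str,
    gene_id: str,
    n_draws: int = DIAGNOSTIC_N_DRAWS,
    seed: int = 0,
    n_boot: int = DEFAULT_N_BOOT,
    class_filter: bool = False,
) -> tuple[NullDistribution, ModalityVerdict]:
    """Build a matched null with the diagnostic draw count (1,000 by default),
    scale it and test the scaled values for multimodality.

    Accepts either a dataset or a prebuilt :class:`LinkScorer` (cheaper when
    diagnosing many links of the same dataset).
    """
    scorer = (
        dataset
        if isinstance(dataset, LinkScorer)
        else LinkScorer(dataset, seed=seed, class_filter_nulls=class_filter)
    )
    if class_filter and not scorer.class_filter_nulls:
        raise ConfigError("pass class_filter when constructing the LinkScorer")
    null = scorer.build_null(peak_id, gene_id, n_draws=n_draws)
    rng = np.random.default_rng([seed, null.n_draws])
    verdict = multimodality_test(null.scaled_null, n_boot=n_boot, seed=rng)
    return null, verdict
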