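"""Ago-RIP enrichment calling.

The pipeline mirrors the study's array analysis: quantile-normalize the
Ago-IP and total-RNA channels onto a common scale, fit a two-component
Gaussian mixture to the (bimodal) Ago-channel intensity distribution, call a
gene Ago-bound when its intensity exceeds T1 = mu1 + 3*sigma1 of the
background component (a 0.001 false-positive rate under the background
Gaussian), compute the per-stage Ago enrichment E_n = log2(Ago) - log2(total),
and classify transition-wise released and loaded mRNAs from (E_n, E_{n+1})
with the thresholds T2, T3 and a |dE| cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .config import Thresholds
from .containers import AGO_IP, TOTAL, IntensityMatrix

RELEASED = "released"
LOADED = "loaded"
UNCHANGED = "unchanged"
NOT_ASSESSED = "not_assessed"


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of a frame onto their mean distribution.

    Every column is mapped onto the reference vector of row-means of the
    column-wise sorted matrix.  Tied values within a column receive the mean
    of the reference values at their tied ranks, so the operation is
    idempotent and order-independent.  A single-column frame is returned
    unchanged with a warning.
    """
    if values.shape[1] < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 samples")
        return values.copy()
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        # average ranks handle ties: a rank of k.5 interpolates the two
        # neighbouring reference values
        r = rankdata(arr[:, j], method="average") - 1.0
        lo = np.floor(r).astype(int)
        hi = np.ceil(r).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(
    matrix: IntensityMatrix, within: str | None = "fraction"
) -> IntensityMatrix:
    """Quantile-normalize the arrays of an intensity matrix.

    With ``within='fraction'`` (default) the Ago-IP arrays and the total-RNA
    arrays are each normalized among themselves: the two channels have very
    different marginal shapes (the IP channel is bimodal, the total channel
    is not), and forcing them onto one common distribution distorts the
    enrichment ratio computed between them.  ``within=None`` normalizes all
    arrays jointly.
    """
    values = matrix.values
    if within is None:
        res = quantile_normalize_frame(values)
    elif within == "fraction":
        res = values.copy().astype(float)
        for _frac, grp in matrix.meta.groupby("fraction"):
            cols = list(grp.index)
            res[cols] = quantile_normalize_frame(values[cols])
    else:
        raise ValueError(f"unknown normalization grouping {within!r}")
    return IntensityMatrix(values=res, meta=matrix.meta.copy())


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture (EM)
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture; component 1 is the background (mu1 <= mu2)."""

    pi1: float
    pi2: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    log_likelihood_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.pi1 + self.pi2 - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("mixture sigmas must be positive")
        if self.mu1 > self.mu2:
            raise ValueError("components must be ordered mu1 <= mu2")


def _log_gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi * sigma**2) - (x - mu) ** 2 / (2.0 * sigma**2)


def _em_once(x, pi, mu, sigma, tol, max_iter):
    n = x.size
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        log_resp = np.stack(
            [np.log(pi[k]) + _log_gauss(x, mu[k], sigma[k]) for k in range(2)]
        )
        m = log_resp.max(axis=0)
        log_norm = m + np.log(np.exp(log_resp - m).sum(axis=0))
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_resp - log_norm)
        # M step
        nk = resp.sum(axis=1)
        if (nk < 1e-10).any():
            return None  # a component collapsed to zero weight
        pi = nk / n
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
        if (var < 1e-12).any():
            return None  # sigma -> 0 degeneracy
        sigma = np.sqrt(var)
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
    return pi, mu, sigma, trace, it, converged


def fit_background_mixture(
    values: np.ndarray | pd.Series,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 5,
    seed: int = 0,
    max_retries: int = 5,
) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to log2 intensities.

    Initialization is k-means++ on the 1-D values with 2 centers and
    ``n_init`` restarts; the best start by final log-likelihood wins.  The
    per-iteration log-likelihood trace is recorded (and is non-decreasing, an
    EM guarantee).  Degenerate collapses (a vanishing component or
    sigma -> 0) trigger refits from perturbed starts; after ``max_retries``
    failures an error is raised.  Non-convergence within ``max_iter`` merely
    flags ``converged=False``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values to fit a mixture")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if x.size < 100:
        warnings.warn("fewer than 100 values: mixture fit may be unstable")

    rng = np.random.default_rng(seed)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(x[:, None])
    pi0 = np.array([np.mean(labels == k) for k in range(2)])
    mu0 = km.cluster_centers_.ravel().astype(float)
    sigma0 = np.array(
        [max(x[labels == k].std(), 1e-3) if (labels == k).sum() > 1 else x.std() or 1.0
         for k in range(2)]
    )
    pi0 = np.clip(pi0, 1e-6, None)
    pi0 /= pi0.sum()

    result = None
    for attempt in range(max_retries):
        res = _em_once(x, pi0.copy(), mu0.copy(), sigma0.copy(), tol, max_iter)
        if res is not None:
            result = res
            break
        # perturbed restart after a degenerate collapse
        mu0 = mu0 + rng.normal(0.0, x.std() * 0.1, size=2)
        sigma0 = np.full(2, max(x.std(), 1e-3))
        pi0 = np.array([0.5, 0.5])
    if result is None:
        raise RuntimeError(f"mixture fit degenerate after {max_retries} restarts")

    pi, mu, sigma, trace, n_iter, converged = result
    order = np.argsort(mu)
    pi, mu, sigma = pi[order], mu[order], sigma[order]
    return MixtureFit(
        pi1=float(pi[0]), pi2=float(pi[1]),
        mu1=float(mu[0]), sigma1=float(sigma[0]),
        mu2=float(mu[1]), sigma2=float(sigma[1]),
        log_likelihood=trace[-1], n_iterations=n_iter,
        converged=converged, log_likelihood_trace=trace,
    )


def bound_call_threshold(fit: MixtureFit) -> float:
    """Bound-call cutoff T1 = mu1 + 3*sigma1 of the background component."""
    return fit.mu1 + 3.0 * fit.sigma1


def mixture_vs_single_gaussian_lr(values: np.ndarray, fit: MixtureFit) -> float:
    """Log-likelihood-ratio of the 2-component fit against a single Gaussian.

    Large values reject unimodality; used as a distributional sanity check on
    the Ago channel.
    """
    x = np.asarray(values, dtype=float).ravel()
    mu, sigma = x.mean(), x.std()
    ll1 = float(_log_gauss(x, mu, max(sigma, 1e-12)).sum())
    return fit.log_likelihood - ll1


# ---------------------------------------------------------------------------
# Enrichment and transition classification
# ---------------------------------------------------------------------------

def ago_enrichment(
    matrix: IntensityMatrix,
    t1_by_stage: dict[str, float] | float | None = None,
    mixture_seed: int = 0,
) -> pd.DataFrame:
    """Per-gene, per-stage Ago enrichment E_n and bound calls.

    The matrix is expected to be quantile-normalized already; replicates are
    averaged on the log2 scale.  ``t1_by_stage`` gives the bound-call cutoff
    per stage; a scalar applies to all stages, and ``None`` triggers a
    mixture fit on each stage's averaged Ago channel.  Returns a long table
    with columns ``gene_id, stage, ago, total, E, bound``.
    """
    ago_means = matrix.stage_means(AGO_IP)
    total_means = matrix.stage_means(TOTAL)
    stages = matrix.stages
    if t1_by_stage is None:
        t1_by_stage = {
            s: bound_call_threshold(fit_background_mixture(ago_means[s], seed=mixture_seed))
            for s in stages
        }
    elif np.isscalar(t1_by_stage):
        t1_by_stage = {s: float(t1_by_stage) for s in stages}

    frames = []
    for s in stages:
        frames.append(pd.DataFrame({
            "gene_id": ago_means.index,
            "stage": s,
            "ago": ago_means[s].to_numpy(),
            "total": total_means[s].to_numpy(),
            "E": ago_means[s].to_numpy() - total_means[s].to_numpy(),
            "bound": ago_means[s].to_numpy() >= t1_by_stage[s],
        }))
    return pd.concat(frames, ignore_index=True)


def classify_transitions(
    table: pd.DataFrame,
    thresholds: Thresholds,
    stage_order: list[str] | None = None,
    transitions: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Classify genes as released/loaded/unchanged at each consecutive transition.

    released: bound at stage n, E_n >= T2, E_{n+1} <= T3 and |dE| >= delta_min
    loaded:   bound at stage n+1, E_n <= T3, E_{n+1} >= T2 and |dE| >= delta_min
    Genes bound at neither end of the transition are ``not_assessed``; all
    other genes are ``unchanged``.  All inequalities are inclusive.
    ``transitions`` restricts the output to chosen stage pairs, which must be
    adjacent in ``stage_order``.
    """
    if stage_order is None:
        stage_order = list(dict.fromkeys(table["stage"]))
    if len(stage_order) < 2:
        raise ValueError("need at least two consecutive stages")
    adjacent = list(zip(stage_order[:-1], stage_order[1:]))
    if transitions is None:
        transitions = adjacent
    else:
        for pair in transitions:
            if tuple(pair) not in adjacent:
                raise ValueError(f"stages {pair} are not adjacent in {stage_order}")
    wide_e = table.pivot(index="gene_id", columns="stage", values="E")
    wide_b = table.pivot(index="gene_id", columns="stage", values="bound")
    rows = []
    for a, b in transitions:
        e_n = wide_e[a].to_numpy(float)
        e_n1 = wide_e[b].to_numpy(float)
        b_n = wide_b[a].to_numpy(bool)
        b_n1 = wide_b[b].to_numpy(bool)
        de = e_n1 - e_n
        rel = b_n & (e_n >= thresholds.t2) & (e_n1 <= thresholds.t3) & (np.abs(de) >= thresholds.delta_min)
        loa = b_n1 & (e_n <= thresholds.t3) & (e_n1 >= thresholds.t2) & (np.abs(de) >= thresholds.delta_min)
        call = np.where(rel, RELEASED, np.where(loa, LOADED,
                        np.where(b_n | b_n1, UNCHANGED, NOT_ASSESSED)))
        rows.append(pd.DataFrame({
            "gene_id": wide_e.index,
            "transition": f"{a}->{b}",
            "E_n": e_n, "E_n1": e_n1, "delta_E": de,
            "call": call,
        }))
    return pd.concat(rows, ignore_index=True)
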