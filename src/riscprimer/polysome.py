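"""Ribosome-occupancy (TRAP / polysome-profiling) count analysis.

Counts from ribosome-IP and input libraries are scaled with median-of-ratios
size factors, filtered on expression (mean of 50 normalized counts in at
least one condition) and replicate variability (sd at most 20% of the mean in
every replicated sample group), and summarized per gene as the ribosome
enrichment R = mean IP / mean input per condition and its log2 change between
conditions (log2RiboDeltaE).  Genes with |log2RiboDeltaE| above a threshold
(default 1, strict inequality) are the translationally regulated sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import INPUT, RIBO_IP, CountMatrix


class NormalizationError(RuntimeError):
    """No gene usable for size-factor estimation."""


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene with strictly positive counts in every sample, form the
    ratio of its count in sample j to its geometric mean across samples; s_j
    is the median of those ratios.  Genes with any zero count are excluded
    (the geometric mean would vanish).
    """
    arr = counts.values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise NormalizationError("no gene has all-positive counts across samples")
    sub = arr[eligible]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.values.columns, name="size_factor")


def normalize_counts(counts: CountMatrix, factors: pd.Series | None = None) -> CountMatrix:
    """Divide each sample's counts by its size factor (values become real)."""
    if factors is None:
        factors = size_factors(counts)
    normed = counts.values / factors
    return CountMatrix(values=normed, meta=counts.meta.copy())


def filter_genes(
    counts: CountMatrix,
    min_mean: float = 50.0,
    max_cv: float = 0.20,
    pool_fractions: bool = True,
) -> pd.DataFrame:
    """Expression and variability filters on (normalized) counts.

    A gene is kept iff its mean count reaches ``min_mean`` in at least one
    condition and, in every (condition, fraction) group with >= 2 replicates,
    its sd/mean stays at or below ``max_cv``.  ``pool_fractions`` controls
    whether the condition mean pools IP and input samples (default) or is
    required per fraction.  Returns a per-gene frame with boolean columns
    ``pass_expression``, ``pass_cv`` and ``kept``.
    """
    vals = counts.values
    meta = counts.meta
    conditions = counts.conditions

    cond_ok = np.zeros(len(vals), dtype=bool)
    for cond in conditions:
        if pool_fractions:
            cols = list(meta.index[meta["condition"] == cond])
            cond_ok |= vals[cols].mean(axis=1).to_numpy() >= min_mean
        else:
            for frac in (RIBO_IP, INPUT):
                cols = counts.samples_for(cond, frac)
                if cols:
                    cond_ok |= vals[cols].mean(axis=1).to_numpy() >= min_mean

    cv_ok = np.ones(len(vals), dtype=bool)
    for (cond, frac), grp in meta.groupby(["condition", "fraction"]):
        cols = list(grp.index)
        if len(cols) < 2:
            continue  # CV undefined for singleton groups (kept, as in the study)
        sub = vals[cols].to_numpy(dtype=float)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, sd / mean, np.where(sd > 0, np.inf, 0.0))
        cv_ok &= cv <= max_cv

    return pd.DataFrame(
        {"pass_expression": cond_ok, "pass_cv": cv_ok, "kept": cond_ok & cv_ok},
        index=vals.index,
    )


def ribosome_enrichment(
    counts: CountMatrix,
    kept: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene ribosome enrichment and its log2 change between conditions.

    For each condition, R = mean normalized IP count / mean normalized input
    count; log2RiboDeltaE = log2(R_second) - log2(R_first) over the two
    conditions in matrix order (ES then ELA in the study design).  Genes with
    a zero mean in any required fraction are flagged not assessable (NaN
    enrichment); no pseudocounts are applied.
    """
    vals = counts.values
    conds = counts.conditions
    if len(conds) != 2:
        raise ValueError("ribosome enrichment expects exactly two conditions")
    out = pd.DataFrame(index=vals.index)
    for cond in conds:
        ip_cols = counts.samples_for(cond, RIBO_IP)
        in_cols = counts.samples_for(cond, INPUT)
        if not ip_cols or not in_cols:
            raise ValueError(f"condition {cond!r} lacks an IP or input sample")
        ip_mean = vals[ip_cols].mean(axis=1)
        in_mean = vals[in_cols].mean(axis=1)
        out[f"ip_mean_{cond}"] = ip_mean
        out[f"input_mean_{cond}"] = in_mean
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"R_{cond}"] = np.where(in_mean > 0, ip_mean / in_mean, np.nan)
    if out[[f"input_mean_{c}" for c in conds]].to_numpy().sum() == 0:
        raise RuntimeError("all input means are zero: nothing is assessable")
    r0, r1 = (out[f"R_{c}"].to_numpy(dtype=float) for c in conds)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["log2RiboDeltaE"] = np.where((r0 > 0) & (r1 > 0), np.log2(r1 / r0), np.nan)
    out["passed_filters"] = (
        kept.reindex(vals.index).fillna(False).astype(bool)
        if kept is not None else True
    )
    out["assessable"] = np.isfinite(out["log2RiboDeltaE"])
    return out


def select_translationally_regulated(
    table: pd.DataFrame, threshold: float = 1.0
) -> tuple[set[str], set[str]]:
    """Genes with log2RiboDeltaE strictly above/below +/- ``threshold``.

    Restricted to genes that passed the filters; the boundary value itself is
    excluded (the selection rule is a strict inequality).
    """
    ok = table["passed_filters"] & table["assessable"]
    de = table["log2RiboDeltaE"]
    up = set(table.index[ok & (de > threshold)])
    down = set(table.index[ok & (de < -threshold)])
    return up, down
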