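"""Small-RNA expression, set-D selection and cumulative 3'UTR binding scores.

Set "D" is the ground-state miRNA signature: miRNAs with mean log2 RPM >= 5
over the compared pair of conditions and log2 fold change <= -1 at the
ES->ELA transition (both inequalities inclusive).  Their binding to a gene is
summarized as the cumulative duplex score over all passing hits in the
gene's 3'UTR; gene families are tested against a null score distribution
(scrambled UTRs or a random gene set) with a two-sided rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .align import DuplexHit


def rpm_normalize(
    counts: pd.DataFrame, library_sizes: pd.Series | dict | None = None
) -> pd.DataFrame:
    """Reads-per-million normalization: RPM = count / (library size / 1e6).

    ``library_sizes`` defaults to the column sums (i.e., all reads annotated);
    pass the true sequenced library sizes when only a fraction of reads maps
    to miRNAs.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = pd.Series(library_sizes).reindex(counts.columns)
    if lib.isna().any() or (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    return counts / (lib / 1e6)


def mirna_expression(
    rpm: pd.DataFrame,
    pair: tuple[str, str] = ("ES", "ELA"),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Mean log2 expression and log2 fold change over the compared pair.

    ``log2fc`` is log2((RPM_second + pc) / (RPM_first + pc)); ``mean_log2``
    averages log2(RPM + pc) of the two conditions.  The pseudocount (default
    1) keeps zero counts finite.
    """
    a, b = pair
    la = np.log2(rpm[a] + pseudocount)
    lb = np.log2(rpm[b] + pseudocount)
    return pd.DataFrame({
        "mean_log2": (la + lb) / 2.0,
        "log2fc": lb - la,
    }, index=rpm.index)


def select_set_d(
    expr: pd.DataFrame, min_mean: float = 5.0, max_fc: float = -1.0
) -> set[str]:
    """miRNAs with mean_log2 >= min_mean and log2fc <= max_fc (inclusive)."""
    mask = (expr["mean_log2"] >= min_mean) & (expr["log2fc"] <= max_fc)
    return set(expr.index[mask])


def mirna_zscores(rpm: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA z-scores of RPM across conditions (population sd).

    Rows with zero spread get all-zero z-scores.
    """
    arr = rpm.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population (n) denominator
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (arr - mean) / sd, 0.0)
    return pd.DataFrame(z, index=rpm.index, columns=rpm.columns)


def scramble_utrs(
    utrs: dict[str, str], seed: int | np.random.Generator = 0
) -> dict[str, str]:
    """Uniform random permutation of each UTR's letters.

    Length and mononucleotide composition are preserved exactly; any planted
    complementary sites are destroyed (up to coincidence), giving the
    sequence-composition-matched null for binding scores.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for gid, seq in utrs.items():
        letters = np.array(list(seq))
        out[gid] = "".join(rng.permutation(letters))
    return out


def hits_to_frame(hits: list[DuplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.mirna_id, h.gene_id, h.start, h.end, h.score, h.energy, h.passes)
         for h in hits],
        columns=["mirna_id", "gene_id", "start", "end", "score", "energy", "passes"],
    )


def cumulative_binding_score(
    hits: list[DuplexHit] | pd.DataFrame,
    set_d: set[str],
    gene_ids: list[str],
) -> pd.Series:
    """Per-gene sum of passing-hit scores over set-D miRNAs.

    ``gene_ids`` fixes the score universe: genes without any passing hit
    score 0 (they still enter family statistics).
    """
    frame = hits if isinstance(hits, pd.DataFrame) else hits_to_frame(hits)
    scores = pd.Series(0.0, index=pd.Index(gene_ids, name="gene_id"), name="cumulative_score")
    if len(frame):
        ok = frame["passes"] & frame["mirna_id"].isin(set_d) & frame["gene_id"].isin(scores.index)
        summed = frame[ok].groupby("gene_id")["score"].sum()
        scores[summed.index] = summed
    return scores


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Midranks make the enumeration correct under ties; feasible for groups of
    up to ~10 observations (C(20,10) ~ 1.8e5 assignments).
    """
    from itertools import combinations

    from scipy.stats import rankdata

    n1 = len(x)
    ranks = rankdata(np.concatenate([x, y]), method="average")
    observed = ranks[:n1].sum()
    sums = np.fromiter(
        (sum(c) for c in combinations(ranks, n1)), dtype=float
    )
    eps = 1e-9
    p_lo = np.mean(sums <= observed + eps)
    p_hi = np.mean(sums >= observed - eps)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value.

    Exact null enumeration (tie-aware, via midranks) when both groups have at
    most 10 observations; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= 10 and len(y) <= 10:
        return _exact_rank_sum_p(x, y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return float(res.pvalue)


def family_binding_test(
    scores: pd.Series,
    families: dict[str, list[str]],
    null_scores: np.ndarray | pd.Series,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Per-family rank-sum test of cumulative binding scores against a null.

    ``null_scores`` is the score distribution of the null model (scrambled
    UTRs of the same genes, or a random gene set).  Families with fewer than
    ``min_genes`` scored genes are reported with p = NaN.  The returned frame
    carries the family median, size and p, plus the null median for the
    reference line.
    """
    null = np.asarray(pd.Series(null_scores), dtype=float)
    rows = []
    for name, members in families.items():
        present = [g for g in members if g in scores.index]
        vals = scores[present].to_numpy(dtype=float)
        if len(vals) < min_genes:
            import warnings

            warnings.warn(f"family {name!r}: only {len(vals)} scored genes, p not assessed")
            p = np.nan
        else:
            p = rank_sum_p(vals, null)
        rows.append({
            "family": name,
            "n_genes": len(vals),
            "median_score": float(np.median(vals)) if len(vals) else np.nan,
            "p_value": p,
        })
    out = pd.DataFrame(rows).set_index("family")
    out.attrs["null_median"] = float(np.median(null))
    return out
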