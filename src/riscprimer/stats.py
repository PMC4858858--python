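"""Cross-cutting statistics: sign-test concordance with randomization
controls, the differential-expression gene filter, sample clustering, and
family-level enrichment comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import binomtest, ttest_ind
from statsmodels.stats.multitest import multipletests

from .mirna import rank_sum_p


# ---------------------------------------------------------------------------
# Sign test of fold-change concordance
# ---------------------------------------------------------------------------

@dataclass
class SignTestResult:
    n_concordant: int
    n_discordant: int
    n_excluded: int  # zero fold changes, sign undefined
    p_value: float
    randomization_p: dict[str, dict] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.n_concordant + self.n_discordant + self.n_excluded

    @property
    def concordance_fraction(self) -> float:
        n = self.n_concordant + self.n_discordant
        return self.n_concordant / n if n else np.nan


def sign_test_concordance(fc_ref: pd.Series, fc_test: pd.Series) -> SignTestResult:
    """Concordance of fold-change direction between two datasets.

    A gene is concordant when both fold changes are non-zero and share their
    sign; genes with a zero fold change in either dataset are excluded.  The
    p-value is the exact two-sided binomial test of the concordant count
    against chance (p0 = 0.5).
    """
    common = fc_ref.index.intersection(fc_test.index)
    if len(common) == 0:
        raise ValueError("no genes shared between the two fold-change sets")
    a = np.sign(fc_ref[common].to_numpy(dtype=float))
    b = np.sign(fc_test[common].to_numpy(dtype=float))
    nonzero = (a != 0) & (b != 0)
    conc = int(((a == b) & nonzero).sum())
    disc = int(((a != b) & nonzero).sum())
    excl = int((~nonzero).sum())
    n = conc + disc
    p = float(binomtest(conc, n, 0.5, alternative="two-sided").pvalue) if n else np.nan
    return SignTestResult(conc, disc, excl, p)


def randomized_sign_controls(
    fc_ref: pd.Series,
    fc_test: pd.Series,
    mode: str,
    n_replicates: int = 1000,
    seed: int = 0,
) -> dict:
    """Concordance p-value distribution under a randomization control.

    ``mode='random_gene'`` replaces each test fold change with that of a
    randomly drawn gene (sampling genes with replacement); ``mode=
    'scrambled_order'`` permutes the test fold changes across genes.  Returns
    the replicate p-values plus summary statistics.
    """
    if mode not in ("random_gene", "scrambled_order"):
        raise ValueError(f"unknown randomization mode {mode!r}")
    rng = np.random.default_rng(seed)
    common = fc_ref.index.intersection(fc_test.index)
    test_vals = fc_test[common].to_numpy(dtype=float)
    ps = np.empty(n_replicates)
    fracs = np.empty(n_replicates)
    for r in range(n_replicates):
        if mode == "random_gene":
            rand = test_vals[rng.integers(0, len(test_vals), size=len(test_vals))]
        else:
            rand = rng.permutation(test_vals)
        res = sign_test_concordance(fc_ref[common], pd.Series(rand, index=common))
        ps[r] = res.p_value
        fracs[r] = res.concordance_fraction
    return {
        "mode": mode,
        "n_replicates": n_replicates,
        "p_values": ps,
        "median_p": float(np.median(ps)),
        "mean_concordance": float(np.mean(fracs)),
        "fraction_p_below_0.05": float(np.mean(ps < 0.05)),
    }


# ---------------------------------------------------------------------------
# DE-gene filter
# ---------------------------------------------------------------------------

def de_gene_filter(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    min_abs_fc: float = 1.0,
    alpha: float = 0.05,
    min_expr: float = 7.5,
) -> pd.DataFrame:
    """Differentially expressed genes between two replicated conditions.

    Inputs are log2 expression matrices (genes x replicates) on a common
    scale.  Per gene: log2FC = mean(b) - mean(a); a two-sample t-test p-value
    (Benjamini-Hochberg adjusted across genes) when both conditions have >= 2
    replicates, otherwise the p criterion is skipped and flagged.  Selected
    genes satisfy |log2FC| >= min_abs_fc, adjusted p < alpha and overall mean
    log2 expression >= min_expr (boundary semantics as printed: >=, <, >=).
    """
    if not expr_a.index.equals(expr_b.index):
        raise ValueError("gene universes differ between conditions")
    a = expr_a.to_numpy(dtype=float)
    b = expr_b.to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    mean_expr = np.concatenate([a, b], axis=1).mean(axis=1)
    have_p = a.shape[1] >= 2 and b.shape[1] >= 2
    if have_p:
        pvals = ttest_ind(a, b, axis=1).pvalue
        adj = multipletests(pvals, method="fdr_bh")[1]
    else:
        pvals = np.full(len(log2fc), np.nan)
        adj = pvals
    selected = (np.abs(log2fc) >= min_abs_fc) & (mean_expr >= min_expr)
    if have_p:
        selected &= adj < alpha
    return pd.DataFrame({
        "log2fc": log2fc,
        "p_value": pvals,
        "adj_p": adj,
        "mean_log2_expr": mean_expr,
        "selected": selected,
        "p_tested": have_p,
    }, index=expr_a.index)


# ---------------------------------------------------------------------------
# Hierarchical clustering of samples
# ---------------------------------------------------------------------------

def hierarchical_cluster(
    sample_matrix: pd.DataFrame,
) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage agglomerative clustering on Euclidean distances.

    ``sample_matrix`` is samples x genes (typically restricted to the
    selected DE genes).  Returns the scipy linkage matrix and the leaf
    labels; merge heights are non-decreasing (a complete-linkage guarantee)
    and ties resolve deterministically by leaf index.
    """
    if sample_matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    dist = pdist(sample_matrix.to_numpy(dtype=float), metric="euclidean")
    return linkage(dist, method="complete"), list(sample_matrix.index)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = link[i - n]
        left, right = int(a), int(b)
        return (
            f"({node(left)}:{h - heights[left]:.6g},"
            f"{node(right)}:{h - heights[right]:.6g})"
        )

    for k, (_, _, h, _) in enumerate(link):
        heights[n + k] = h
    return node(n + len(link) - 1) + ";"


# ---------------------------------------------------------------------------
# Family-level enrichment comparison
# ---------------------------------------------------------------------------

def family_enrichment_compare(
    values: pd.Series,
    families: dict[str, list[str]],
    control: str | np.ndarray | pd.Series,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Five-number summaries and rank-sum p per family against a control set.

    ``values`` maps gene id to the measured quantity (Ago enrichment or log2
    ribosome enrichment); ``control`` is either the name of a family to use
    as reference or an explicit value vector (e.g., a random gene set).
    Families with fewer than ``min_genes`` measured genes get p = NaN.
    """
    if isinstance(control, str):
        members = [g for g in families[control] if g in values.index]
        ctrl = values[members].to_numpy(dtype=float)
    else:
        ctrl = np.asarray(pd.Series(control), dtype=float)
    rows = []
    for name, genes in families.items():
        present = [g for g in genes if g in values.index]
        vals = values[present].to_numpy(dtype=float)
        if len(vals):
            q = np.percentile(vals, [0, 25, 50, 75, 100])
        else:
            q = [np.nan] * 5
        p = rank_sum_p(vals, ctrl) if len(vals) >= min_genes else np.nan
        rows.append({
            "family": name, "n_genes": len(vals),
            "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
            "p_value": p,
        })
    return pd.DataFrame(rows).set_index("family")
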