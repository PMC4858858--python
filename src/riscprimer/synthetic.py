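"""Synthetic-data generators with known ground truth.

These emulate the statistical structure of the study's three input types:

* ``simulate_array_experiment`` — Ago-IP and total-RNA log2 intensities over a
  differentiation time course.  The Ago channel is a two-component Gaussian
  mixture (unbound background plus a shifted bound population), and selected
  bound genes carry stage-specific release or load effects on their Ago
  enrichment.
* ``simulate_count_experiment`` — negative-binomial ribosome-IP/input counts
  for two conditions with known per-sample size factors and a planted
  ribosome-occupancy shift on chosen genes.
* ``simulate_mirna_and_utrs`` — a small-RNA count table over four culture
  conditions containing a down-regulated "set D" subpopulation, plus 3'UTR
  sequences in which exact complementary sites of set-D miRNAs are planted,
  enriched in chosen gene families.

All randomness in a call flows from a single :class:`numpy.random.Generator`
derived from ``config.seed``, so identical configurations give bit-identical
outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .containers import (
    AGO_IP,
    INPUT,
    RIBO_IP,
    TOTAL,
    CountMatrix,
    IntensityMatrix,
    PlantedSite,
    SyntheticTruth,
)

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))
_COMPLEMENT_DNA = str.maketrans("ACGTU", "TGCAA")


def gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"gene_{i:0{width}d}" for i in range(1, n + 1)]


def _rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


# ---------------------------------------------------------------------------
# Ago-RIP microarray generator
# ---------------------------------------------------------------------------

def simulate_array_experiment(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Generate Ago-IP/total log2 intensity arrays with planted release/load.

    Model: each gene has a latent per-stage abundance a ~ N(background_mean,
    background_sd); the total channel observes a plus channel noise, the Ago
    channel observes a plus the gene's current Ago enrichment plus noise.
    Unbound genes have enrichment 0 at every stage; stably bound genes have a
    constant enrichment ~ N(bound_shift, bound_sd); genes planted as released
    at transition t carry enrichment ``release_effect`` up to stage t and 0
    afterwards (and symmetrically for loaded genes), so the planted change in
    Ago enrichment is exactly -/+ ``release_effect``.
    """
    rng = _rng(config)
    genes = gene_ids(config.n_genes)
    stages = list(config.stages)
    n_stages = len(stages)

    n_bound = int(round(config.fraction_bound * config.n_genes))
    bound_idx = rng.choice(config.n_genes, size=n_bound, replace=False)
    transitions = [f"{stages[i]}->{stages[i + 1]}" for i in range(n_stages - 1)]
    n_rel = int(round(config.fraction_released * n_bound))
    n_load = int(round(config.fraction_loaded * n_bound))
    need = (n_rel + n_load) * len(transitions)
    if need > n_bound:
        raise ConfigurationError(
            "fraction_released/fraction_loaded leave no stably bound genes"
        )
    shuffled = rng.permutation(bound_idx)
    pos = 0
    released: dict[str, np.ndarray] = {}
    loaded: dict[str, np.ndarray] = {}
    for t in transitions:
        released[t] = shuffled[pos:pos + n_rel]
        pos += n_rel
        loaded[t] = shuffled[pos:pos + n_load]
        pos += n_load
    stable = shuffled[pos:]

    # per-gene, per-stage Ago enrichment (log2 units)
    effect = np.zeros((config.n_genes, n_stages))
    effect[stable] = rng.normal(config.bound_shift, config.bound_sd, size=len(stable))[:, None]
    for ti, t in enumerate(transitions):
        effect[released[t], : ti + 1] = config.release_effect
        effect[loaded[t], ti + 1:] = config.release_effect

    abundance = rng.normal(
        config.background_mean, config.background_sd, size=(config.n_genes, n_stages)
    )

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for si, stage in enumerate(stages):
        for rep in range(1, config.array_replicates + 1):
            noise = rng.normal(0.0, config.channel_noise_sd, size=(config.n_genes, 2))
            name_t = f"{stage}_{TOTAL}_r{rep}"
            name_a = f"{stage}_{AGO_IP}_r{rep}"
            cols[name_a] = abundance[:, si] + effect[:, si] + noise[:, 0]
            cols[name_t] = abundance[:, si] + noise[:, 1]
            meta_rows.append((name_a, stage, AGO_IP, rep))
            meta_rows.append((name_t, stage, TOTAL, rep))

    order = [r[0] for r in meta_rows]
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))[order]
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "stage", "fraction", "replicate"]
    ).set_index("sample")

    truth = SyntheticTruth(seed=config.seed)
    garr = np.asarray(genes)
    truth.bound_genes_per_stage = {
        stage: set(garr[effect[:, si] > 0]) for si, stage in enumerate(stages)
    }
    truth.released_genes = {t: set(garr[idx]) for t, idx in released.items()}
    truth.loaded_genes = {t: set(garr[idx]) for t, idx in loaded.items()}
    truth.validate()
    return IntensityMatrix(values=values, meta=meta), truth


# ---------------------------------------------------------------------------
# Ribosome IP/input count generator
# ---------------------------------------------------------------------------

def _nb_draws(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with var = mu + alpha*mu^2 (Poisson when alpha ~ 0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_count_experiment(
    config: SimulationConfig,
    effect_up: set[str] | None = None,
    effect_down: set[str] | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate ribosome-IP/input NB counts with known size factors.

    ``effect_up``/``effect_down`` optionally name the genes carrying a
    planted +/- ``ribo_effect`` change in ribosome enrichment between the
    first and second condition (the pipeline couples these to the Ago-release
    truth); when omitted, random disjoint subsets of sizes
    ``fraction_ribo_up/down * n_genes`` are drawn.
    """
    rng = _rng(config)
    genes = gene_ids(config.n_genes)
    conds = list(config.conditions)
    if len(conds) != 2:
        raise ConfigurationError("count experiment expects exactly two conditions")

    base = rng.lognormal(config.count_base_log_mean, config.count_base_log_sd,
                         size=config.n_genes)

    garr = np.asarray(genes)
    if effect_up is None and effect_down is None:
        n_up = int(round(config.fraction_ribo_up * config.n_genes))
        n_dn = int(round(config.fraction_ribo_down * config.n_genes))
        picked = rng.choice(config.n_genes, size=n_up + n_dn, replace=False)
        up_mask = np.zeros(config.n_genes, bool)
        dn_mask = np.zeros(config.n_genes, bool)
        up_mask[picked[:n_up]] = True
        dn_mask[picked[n_up:]] = True
    else:
        up_mask = np.isin(garr, sorted(effect_up or set()))
        dn_mask = np.isin(garr, sorted(effect_down or set()))
        if (up_mask & dn_mask).any():
            raise ConfigurationError("effect_up and effect_down overlap")

    # IP mean = input mean in the first condition; in the second condition the
    # IP mean of effect genes is scaled by 2^(+/- ribo_effect).
    ip_scale = {conds[0]: np.ones(config.n_genes), conds[1]: np.ones(config.n_genes)}
    ip_scale[conds[1]][up_mask] = 2.0 ** config.ribo_effect
    ip_scale[conds[1]][dn_mask] = 2.0 ** -config.ribo_effect

    samples = []
    for cond in conds:
        for frac in (RIBO_IP, INPUT):
            for rep in range(1, config.count_replicates + 1):
                samples.append((f"{cond}_{frac}_r{rep}", cond, frac, rep))

    if config.size_factors is not None:
        if len(config.size_factors) != len(samples):
            raise ConfigurationError(
                f"size_factors length {len(config.size_factors)} != {len(samples)} samples"
            )
        sf = np.asarray(config.size_factors, dtype=float)
    else:
        sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))
        sf /= np.exp(np.mean(np.log(sf)))  # geometric mean 1
    if (sf <= 0).any():
        raise ConfigurationError("library size / size factor must be positive")

    cols = {}
    for (name, cond, frac, _rep), s in zip(samples, sf):
        mu = base * s * (ip_scale[cond] if frac == RIBO_IP else 1.0)
        cols[name] = _nb_draws(rng, mu, config.nb_dispersion)
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(samples, columns=["sample", "condition", "fraction", "replicate"]
                        ).set_index("sample")

    truth = SyntheticTruth(seed=config.seed)
    truth.true_size_factors = {name: float(s) for (name, *_), s in zip(samples, sf)}
    truth.ribo_up_genes = set(garr[up_mask])
    truth.ribo_down_genes = set(garr[dn_mask])
    truth.validate()
    return CountMatrix(values=values, meta=meta), truth


# ---------------------------------------------------------------------------
# Small-RNA + 3'UTR generator
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    """DNA reverse complement; U is treated as T on input."""
    return seq.upper().translate(_COMPLEMENT_DNA)[::-1]


def simulate_mirna_and_utrs(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, list[str]], dict[str, str], SyntheticTruth]:
    """Generate miRNA counts, miRNA sequences, gene families and UTRs.

    Returns ``(counts, mirna_seqs, families, utrs, truth)`` where ``counts``
    is a miRNA x condition count table, ``mirna_seqs`` maps miRNA id to its
    5'->3' RNA sequence, ``families`` maps family name to member gene ids,
    and ``utrs`` maps gene id to a DNA 3'UTR sequence.  Set-D miRNAs are
    generated with high naive-state expression and strong down-regulation so
    that the printed selection rule (mean log2 RPM >= 5, log2 FC <= -1)
    recovers them exactly from the emitted table; sites complementary to
    miRNA positions ``site_span`` of randomly chosen set-D miRNAs are planted
    in the UTRs of target-family genes.
    """
    rng = _rng(config)
    n = config.n_mirnas
    mirna_ids = [f"mir_{i:03d}" for i in range(1, n + 1)]
    seqs = {
        mid: "".join(rng.choice(_RNA, size=config.mirna_length)) for mid in mirna_ids
    }

    n_d = int(round(config.set_d_fraction * n))
    d_idx = set(rng.choice(n, size=n_d, replace=False).tolist())

    es_rpm = np.empty(n)
    fc = np.empty(n)
    for i in range(n):
        if i in d_idx:
            es_rpm[i] = np.exp(rng.uniform(np.log(300.0), np.log(2000.0)))
            fc[i] = rng.uniform(-3.5, -1.8)
        else:
            es_rpm[i] = rng.lognormal(np.log(20.0), 1.5)
            fc[i] = rng.uniform(-0.4, 0.6)
    ela_rpm = es_rpm * 2.0 ** fc
    # the hash conditions (2i/LIF-grown counterparts) track their partners
    wobble = rng.lognormal(0.0, 0.15, size=(n, 2))
    rpm_by_cond = {"ES#": es_rpm * wobble[:, 0], "ES": es_rpm,
                   "ELA#": ela_rpm * wobble[:, 1], "ELA": ela_rpm}

    lib = config.mirna_library_size
    cols = {}
    for cond in config.mirna_conditions:
        mu = rpm_by_cond[cond] * (lib / 1e6)
        cols[cond] = _nb_draws(rng, mu, 0.01)
    counts = pd.DataFrame(cols, index=pd.Index(mirna_ids, name="mirna_id"))

    # --- families and UTRs ---
    fam_names = list(config.target_families) + list(config.control_families)
    n_fam_genes = len(fam_names) * config.genes_per_family
    n_utr_genes = n_fam_genes + config.n_background_utr_genes
    if n_utr_genes > config.n_genes:
        raise ConfigurationError("family genes exceed the gene universe")
    all_genes = gene_ids(config.n_genes)
    chosen = rng.choice(config.n_genes, size=n_utr_genes, replace=False)
    utr_genes = [all_genes[i] for i in chosen]
    families = {
        name: utr_genes[i * config.genes_per_family:(i + 1) * config.genes_per_family]
        for i, name in enumerate(fam_names)
    }

    lo, hi = config.utr_length_range
    utrs: dict[str, str] = {}
    for g in utr_genes:
        length = int(rng.integers(lo, hi + 1))
        utrs[g] = "".join(rng.choice(_DNA, size=length))

    a, b = config.site_span
    d_ids = [mirna_ids[i] for i in sorted(d_idx)]
    planted: list[PlantedSite] = []
    if d_ids and config.site_rate > 0:
        for fam in config.target_families:
            for g in families[fam]:
                k = rng.poisson(config.site_rate)
                occupied: list[tuple[int, int]] = []
                seq = list(utrs[g])
                for _ in range(k):
                    mid = d_ids[rng.integers(len(d_ids))]
                    site = reverse_complement(seqs[mid][a - 1:b])
                    if len(site) > len(seq):
                        raise ConfigurationError("UTR shorter than planted site")
                    for _try in range(20):
                        off = int(rng.integers(0, len(seq) - len(site) + 1))
                        if all(off + len(site) <= s or off >= e for s, e in occupied):
                            seq[off:off + len(site)] = list(site)
                            occupied.append((off, off + len(site)))
                            planted.append(PlantedSite(mid, g, off, len(site)))
                            break
                utrs[g] = "".join(seq)

    truth = SyntheticTruth(seed=config.seed)
    truth.set_d_mirnas = {mirna_ids[i] for i in d_idx}
    truth.planted_sites = planted
    truth.target_families = tuple(config.target_families)
    truth.validate(utr_lengths={g: len(s) for g, s in utrs.items()})
    return counts, seqs, families, utrs, truth
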