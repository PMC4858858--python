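"""Shared fixtures: expensive synthetic runs are session-scoped."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from riscprimer import ago, mirna
from riscprimer.align import scan_targets
from riscprimer.config import PipelineConfig, SimulationConfig, Thresholds
from riscprimer.pipeline import run_pipeline
from riscprimer.synthetic import (
    simulate_array_experiment,
    simulate_mirna_and_utrs,
)


@pytest.fixture(scope="session")
def array_run():
    """Default-scale Ago-RIP simulation with normalization, fits and calls."""
    cfg = SimulationConfig(seed=11)
    matrix, truth = simulate_array_experiment(cfg)
    normed = ago.quantile_normalize(matrix)
    enrichment = ago.ago_enrichment(normed, mixture_seed=0)
    calls = ago.classify_transitions(enrichment, Thresholds())
    return {
        "config": cfg,
        "matrix": matrix,
        "truth": truth,
        "normed": normed,
        "enrichment": enrichment,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def mirna_scan():
    """miRNA/UTR simulation plus duplex scans of true and scrambled UTRs."""
    cfg = SimulationConfig(seed=13)
    counts, seqs, families, utrs, truth = simulate_mirna_and_utrs(cfg)
    d_seqs = {m: seqs[m] for m in sorted(truth.set_d_mirnas)}
    hits = mirna.hits_to_frame(scan_targets(d_seqs, utrs))
    scores = mirna.cumulative_binding_score(hits, truth.set_d_mirnas, list(utrs))
    scrambled = mirna.scramble_utrs(utrs, seed=99)
    null_hits = mirna.hits_to_frame(scan_targets(d_seqs, scrambled))
    null_scores = mirna.cumulative_binding_score(null_hits, truth.set_d_mirnas, list(utrs))
    family_tests = mirna.family_binding_test(scores, families, null_scores)
    return {
        "config": cfg,
        "counts": counts,
        "seqs": seqs,
        "families": families,
        "utrs": utrs,
        "truth": truth,
        "hits": hits,
        "scores": scores,
        "null_scores": null_scores,
        "family_tests": family_tests,
    }


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-configuration synthetic pipeline run."""
    out = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(PipelineConfig(), out_dir=out, seed=7)
    return {"report": report, "out": out}


@pytest.fixture()
def small_sim_config():
    """A fast, scaled-down simulation for IO/CLI/determinism tests."""
    return dataclasses.replace(
        SimulationConfig(seed=5),
        n_genes=800,
        genes_per_family=10,
        n_background_utr_genes=20,
        utr_length_range=(120, 250),
        n_mirnas=40,
    )


@pytest.fixture()
def tiny_counts():
    """Hand-checkable count matrix for size-factor arithmetic."""
    return pd.DataFrame(
        {"s1": [2, 8, 4], "s2": [4, 16, 8]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
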