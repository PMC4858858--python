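"""End-to-end orchestration: simulate -> ago -> ribo -> mirna -> stats.

``run_pipeline`` executes the stages on synthetic inputs (or inputs already
on disk), writes every stage's tables under the output directory, and
returns a run report whose counts are all recomputable from the emitted
artifacts.  A single top-level seed deterministically derives per-stage
seeds, so stages can be rerun in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ttest_1samp

from . import __version__, ago, io, mirna, polysome, stats
from .align import encode, scan_targets
from .config import PipelineConfig, Thresholds
from .containers import SyntheticTruth
from .synthetic import (
    simulate_array_experiment,
    simulate_count_experiment,
    simulate_mirna_and_utrs,
)

log = logging.getLogger("riscprimer")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage_log(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Derive reproducible per-stage seeds (< 2^31) from one top-level seed."""
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("array", "counts", "mirna", "stats")
    return {n: int(s % 2**31) for n, s in zip(names, state)}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path = "riscprimer_run",
    seed: int | None = None,
) -> dict:
    """Run all enabled stages on synthetic data and return the run report."""
    if config is None:
        config = PipelineConfig()
    out = Path(out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.simulation.seed
    seeds = derive_stage_seeds(seed)
    report: dict = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": seeds,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "counts": {},
    }
    io.write_config(config, out / "resolved_config.yaml")

    stage = "simulate"
    try:
        _stage_log(stage, "generating synthetic inputs")
        sim = config.simulation
        arr_cfg = dataclasses.replace(sim, seed=seeds["array"])
        intensity, truth_arr = simulate_array_experiment(arr_cfg)
        transition = f"{sim.stages[0]}->{sim.stages[1]}"
        cnt_cfg = dataclasses.replace(sim, seed=seeds["counts"])
        counts, truth_cnt = simulate_count_experiment(
            cnt_cfg,
            effect_up=truth_arr.released_genes[transition],
            effect_down=truth_arr.loaded_genes[transition],
        )
        mir_cfg = dataclasses.replace(sim, seed=seeds["mirna"])
        mir_counts, mir_seqs, families, utrs, truth_mir = simulate_mirna_and_utrs(mir_cfg)
        truth = truth_arr.merge(truth_cnt).merge(truth_mir)
        inp = out / "inputs"
        io.write_intensity(intensity, inp / "intensity.tsv", inp / "intensity_meta.tsv")
        io.write_counts(counts, inp / "ribo_counts.tsv", inp / "ribo_meta.tsv")
        io.write_matrix(mir_counts, inp / "mirna_counts.tsv")
        io.write_fasta(mir_seqs, inp / "mirnas.fasta")
        io.write_fasta(utrs, inp / "utrs.fasta")
        io.write_gmt(families, inp / "families.gmt")
        io.write_truth(truth, inp / "truth.json")
        report["counts"]["n_genes"] = int(sim.n_genes)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    thresholds = config.thresholds.relaxed() if config.relaxed_t3 else config.thresholds
    enrichment = transitions = None
    if config.run_ago:
        stage = "ago"
        try:
            _stage_log(stage, "quantile normalization, mixture fits, transition calls")
            normed = ago.quantile_normalize(intensity)
            enrichment = ago.ago_enrichment(normed, mixture_seed=seeds["stats"])
            transitions = ago.classify_transitions(enrichment, thresholds)
            enrichment.to_csv(out / "ago_enrichment.tsv", sep="\t", index=False)
            transitions.to_csv(out / "ago_transitions.tsv", sep="\t", index=False)
            report["counts"]["bound_per_stage"] = {
                s: int(g["bound"].sum()) for s, g in enrichment.groupby("stage")
            }
            calls = transitions.groupby(["transition", "call"]).size()
            report["counts"]["released_per_transition"] = {
                t: int(calls.get((t, ago.RELEASED), 0))
                for t in transitions["transition"].unique()
            }
            report["counts"]["loaded_per_transition"] = {
                t: int(calls.get((t, ago.LOADED), 0))
                for t in transitions["transition"].unique()
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    ribo_table = None
    if config.run_ribo:
        stage = "ribo"
        try:
            _stage_log(stage, "size factors, filters, ribosome enrichment")
            factors = polysome.size_factors(counts)
            normed_counts = polysome.normalize_counts(counts, factors)
            flags = polysome.filter_genes(
                normed_counts, min_mean=config.ribo_min_mean, max_cv=config.ribo_max_cv
            )
            ribo_table = polysome.ribosome_enrichment(normed_counts, kept=flags["kept"])
            up, down = polysome.select_translationally_regulated(
                ribo_table, threshold=config.ribo_threshold
            )
            factors.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
            ribo_table.to_csv(out / "ribo_enrichment.tsv", sep="\t")
            report["counts"]["ribo_genes_kept"] = int(flags["kept"].sum())
            report["counts"]["ribo_up"] = len(up)
            report["counts"]["ribo_down"] = len(down)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if config.run_mirna:
        stage = "mirna"
        try:
            _stage_log(stage, "set-D selection, UTR scanning, family tests")
            libs = pd.Series(
                float(config.simulation.mirna_library_size), index=mir_counts.columns
            )
            rpm = mirna.rpm_normalize(mir_counts, libs)
            expr = mirna.mirna_expression(rpm)
            set_d = mirna.select_set_d(
                expr, min_mean=config.set_d_min_mean, max_fc=config.set_d_max_fc
            )
            d_seqs = {m: mir_seqs[m] for m in sorted(set_d)}
            hits = mirna.hits_to_frame(scan_targets(d_seqs, utrs, config.aligner))
            scores = mirna.cumulative_binding_score(hits, set_d, list(utrs))
            scrambled = mirna.scramble_utrs(utrs, seed=seeds["mirna"])
            null_hits = mirna.hits_to_frame(scan_targets(d_seqs, scrambled, config.aligner))
            null_scores = mirna.cumulative_binding_score(null_hits, set_d, list(utrs))
            fam_tests = mirna.family_binding_test(scores, families, null_scores)
            expr.assign(in_set_d=expr.index.isin(sorted(set_d))).to_csv(
                out / "mirna_set_d.tsv", sep="\t")
            hits.to_csv(out / "duplex_hits.tsv", sep="\t", index=False)
            scores.to_frame().to_csv(out / "gene_binding_scores.tsv", sep="\t")
            fam_tests.to_csv(out / "family_binding_tests.tsv", sep="\t")
            report["counts"]["n_set_d"] = len(set_d)
            report["counts"]["family_binding_p"] = {
                f: float(p) for f, p in fam_tests["p_value"].items()
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if config.run_stats and enrichment is not None and ribo_table is not None:
        stage = "stats"
        try:
            _stage_log(stage, "Ago-release vs ribosome-enrichment integration")
            tr = transitions[transitions["transition"] == transition].set_index("gene_id")
            integ = pd.DataFrame({
                "delta_E": tr["delta_E"],
                "call": tr["call"],
                "log2RiboDeltaE": ribo_table["log2RiboDeltaE"],
                "ribo_ok": ribo_table["passed_filters"] & ribo_table["assessable"],
            })
            classes = {
                "ago_released": (integ["delta_E"] <= -2) & (tr["call"] != ago.NOT_ASSESSED),
                "ago_loaded": (integ["delta_E"] >= 2) & (tr["call"] != ago.NOT_ASSESSED),
                "ago_stable": integ["delta_E"].abs() <= 1,
            }
            tests = {}
            for name, mask in classes.items():
                vals = integ.loc[mask & integ["ribo_ok"], "log2RiboDeltaE"].dropna()
                if len(vals) >= 3:
                    t = ttest_1samp(vals, 0.0)
                    tests[name] = {
                        "n": int(len(vals)),
                        "mean_log2RiboDeltaE": float(vals.mean()),
                        "t_p_value": float(t.pvalue),
                    }
                integ[name] = mask
            integ.to_csv(out / "integration.tsv", sep="\t")
            report["integration"] = tests
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(
    matrix: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    fastas: dict[str, dict[str, str]] | None = None,
    families: dict[str, list[str]] | None = None,
    gene_universe: set[str] | None = None,
) -> dict:
    """Structural validation of loaded inputs.

    Fatal problems (metadata samples absent from the matrix header) raise;
    recoverable issues (lowercase sequence letters, empty families,
    unresolvable family members) are listed as warnings.
    """
    warnings: list[str] = []
    if matrix is not None and meta is not None:
        missing = [s for s in meta.index if s not in matrix.columns]
        if missing:
            raise ValueError(f"metadata samples absent from matrix header: {missing}")
        extra = [c for c in matrix.columns if c not in meta.index]
        if extra:
            warnings.append(f"matrix columns without metadata: {extra}")
    if fastas:
        for name, seqs in fastas.items():
            for sid, seq in seqs.items():
                if seq != seq.upper():
                    warnings.append(f"{name}:{sid}: lowercase letters canonicalized")
                encode(seq)  # raises on invalid alphabet
    if families is not None:
        for fam, members in families.items():
            if not members:
                warnings.append(f"family {fam!r} is empty and will be skipped")
            elif gene_universe is not None:
                lost = [g for g in members if g not in gene_universe]
                if lost:
                    warnings.append(f"family {fam!r}: {len(lost)} members not in gene universe")
    return {"warnings": warnings, "ok": True}
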