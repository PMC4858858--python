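"""Configuration dataclasses shared across the pipeline stages.

All tunable parameters of the simulators and of the calling/selection rules
live here so that a single resolved configuration fully determines a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


class ConfigurationError(ValueError):
    """Raised when a configuration field violates its documented constraints."""


@dataclass(frozen=True)
class Thresholds:
    """Cutoffs for Ago-bound calling and released/loaded classification.

    t1 is the bound-call intensity cutoff derived from the background mixture
    component (mu1 + 3*sigma1); it is data-dependent and therefore optional
    here.  t2/t3 bound the Ago enrichment E of a gene at the two ends of a
    transition, and delta_min is the cutoff on |dE| = |E_{n+1} - E_n| that
    selects the top regulated genes.
    """

    t1: float | None = None
    t2: float = 2.0
    t3: float = 0.5
    delta_min: float = 1.5

    #: relaxed variant of t3 used for follow-up analyses (GO-style selections)
    T3_RELAXED = 1.2

    def __post_init__(self) -> None:
        if not self.t2 > self.t3:
            raise ConfigurationError(f"t2 ({self.t2}) must exceed t3 ({self.t3})")
        if not self.delta_min > 0:
            raise ConfigurationError(f"delta_min must be positive, got {self.delta_min}")

    def relaxed(self) -> "Thresholds":
        """Return a copy with the relaxed non-enrichment cutoff t3=1.2."""
        return Thresholds(t1=self.t1, t2=self.t2, t3=self.T3_RELAXED, delta_min=self.delta_min)


@dataclass(frozen=True)
class AlignerParams:
    """Scoring parameters of the miRanda-style duplex aligner.

    Pair scores are in dimensionless alignment units; energies in kcal/mol.
    Positions ``seed_start``..``seed_end`` (1-based, from the miRNA 5' end)
    have their pair scores multiplied by ``seed_weight``, reflecting the
    dominant contribution of seed pairing to target recognition.
    """

    match_wc: float = 5.0
    match_wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2
    seed_end: int = 8
    seed_weight: float = 4.0
    energy_gc: float = -2.2
    energy_au: float = -1.1
    energy_gu: float = -0.5
    min_score: float = 140.0
    max_energy: float = -10.0
    #: hits below this score are not reported at all (passing hits need min_score)
    report_floor: float = 80.0

    def __post_init__(self) -> None:
        if self.seed_start < 1 or self.seed_end < self.seed_start:
            raise ConfigurationError("invalid seed span")
        if self.seed_weight <= 0:
            raise ConfigurationError("seed_weight must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic experiment generators.

    The defaults emulate the structure of the study this package models: a
    four-stage neural differentiation time course profiled with Ago-IP and
    total-RNA arrays, a two-condition (naive ES vs primed ELA) ribosome
    IP/input RNA-seq experiment in duplicate, and a small-RNA survey over the
    four culture conditions ES#/ES/ELA#/ELA.
    """

    seed: int = 0
    n_genes: int = 10_000

    # --- microarray (Ago-RIP) channel model, log2 arbitrary units ---
    stages: tuple[str, ...] = ("ES", "ELA", "NPC", "NEU")
    array_replicates: int = 1
    background_mean: float = 6.0
    background_sd: float = 0.5
    channel_noise_sd: float = 0.2
    bound_shift: float = 4.0
    bound_sd: float = 0.25
    fraction_bound: float = 0.25
    fraction_released: float = 0.05  # of bound genes, per transition
    fraction_loaded: float = 0.05
    release_effect: float = 3.0  # |dE| planted on released/loaded genes

    # --- ribosome IP/input negative-binomial count model ---
    conditions: tuple[str, ...] = ("ES", "ELA")
    count_replicates: int = 2
    count_base_log_mean: float = 6.2  # natural-log mean of per-gene base counts
    count_base_log_sd: float = 0.8
    nb_dispersion: float = 0.004  # var = mu + alpha * mu^2
    size_factors: tuple[float, ...] | None = None  # None -> drawn loguniform [0.5, 2]
    fraction_ribo_up: float = 0.02
    fraction_ribo_down: float = 0.02
    ribo_effect: float = 2.0  # planted |log2RiboDeltaE|

    # --- small-RNA and 3'UTR model ---
    n_mirnas: int = 150
    mirna_length: int = 22
    set_d_fraction: float = 0.15
    mirna_conditions: tuple[str, ...] = ("ES#", "ES", "ELA#", "ELA")
    mirna_library_size: int = 2_000_000
    utr_length_range: tuple[int, int] = (200, 1000)
    target_families: tuple[str, ...] = ("DNMT", "KDM", "SWI_SNF")
    control_families: tuple[str, ...] = ("CYP450",)
    genes_per_family: int = 100
    n_background_utr_genes: int = 200
    site_rate: float = 2.0  # expected planted sites per target-family UTR
    site_span: tuple[int, int] = (2, 15)  # 1-based inclusive miRNA positions planted

    def __post_init__(self) -> None:
        positive = [
            "n_genes", "array_replicates", "background_sd", "channel_noise_sd",
            "bound_sd", "count_replicates", "nb_dispersion", "n_mirnas",
            "mirna_length", "mirna_library_size", "genes_per_family",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("fraction_bound", "fraction_released", "fraction_loaded",
                     "set_d_fraction", "fraction_ribo_up", "fraction_ribo_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.site_rate < 0:
            raise ConfigurationError(f"site_rate must be >= 0, got {self.site_rate}")
        if len(self.stages) < 2:
            raise ConfigurationError("need at least two stages")
        lo, hi = self.utr_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"invalid utr_length_range {self.utr_length_range}")
        a, b = self.site_span
        if a < 1 or b < a or b > self.mirna_length:
            raise ConfigurationError(f"invalid site_span {self.site_span}")
        if b - a + 1 > lo:
            raise ConfigurationError("UTR shorter than planted site span")
        if self.size_factors is not None:
            if any(s <= 0 for s in self.size_factors):
                raise ConfigurationError("size_factors must all be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in known:
                raise ConfigurationError(f"unknown configuration field: {k}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration: stage toggles plus all stage parameters."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    aligner: AlignerParams = field(default_factory=AlignerParams)
    relaxed_t3: bool = False
    ribo_min_mean: float = 50.0
    ribo_max_cv: float = 0.20
    ribo_threshold: float = 1.0
    set_d_min_mean: float = 5.0
    set_d_max_fc: float = -1.0
    run_ago: bool = True
    run_ribo: bool = True
    run_mirna: bool = True
    run_stats: bool = True

    def to_dict(self) -> dict:
        return asdict(self)
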