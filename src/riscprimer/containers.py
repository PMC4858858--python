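"""In-memory containers for the pipeline's matrices and the simulation truth."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGO_IP = "ago_ip"
TOTAL = "total"
RIBO_IP = "ribo_ip"
INPUT = "input"


@dataclass
class IntensityMatrix:
    """Log2 microarray intensities, genes x samples, plus sample metadata.

    ``meta`` is indexed by sample name with columns ``stage``, ``fraction``
    (``ago_ip`` or ``total``) and ``replicate``; its index must match the
    columns of ``values`` exactly.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("sample metadata does not match matrix columns")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("intensity matrix contains non-finite values")
        for stage, grp in self.meta.groupby("stage"):
            fracs = set(grp["fraction"])
            if not {AGO_IP, TOTAL} <= fracs:
                raise ValueError(f"stage {stage!r} is missing an ago_ip or total sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.meta["stage"]:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_for(self, stage: str, fraction: str) -> list[str]:
        m = self.meta
        return list(m.index[(m["stage"] == stage) & (m["fraction"] == fraction)])

    def stage_means(self, fraction: str) -> pd.DataFrame:
        """Replicate-averaged log2 intensities: genes x stages for one fraction."""
        cols = {s: self.values[self.samples_for(s, fraction)].mean(axis=1) for s in self.stages}
        return pd.DataFrame(cols)


@dataclass
class CountMatrix:
    """Non-negative integer read counts, genes x samples, with metadata.

    ``meta`` columns: ``condition`` (ES/ELA), ``fraction`` (``ribo_ip`` or
    ``input``) and ``replicate``.  Unbalanced replicate numbers are allowed
    (the study itself dropped one degenerate input replicate).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("sample metadata does not match matrix columns")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.meta["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str, fraction: str) -> list[str]:
        m = self.meta
        return list(m.index[(m["condition"] == condition) & (m["fraction"] == fraction)])


@dataclass(frozen=True)
class PlantedSite:
    """A complementary site planted in a UTR: where and for which miRNA."""

    mirna_id: str
    gene_id: str
    offset: int  # 0-based start within the UTR
    length: int


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic experiment — the recovery oracle.

    Every field can be recomputed from the emitted files plus the generating
    configuration; the truth object merely saves that recomputation.
    """

    seed: int
    bound_genes_per_stage: dict[str, set[str]] = field(default_factory=dict)
    released_genes: dict[str, set[str]] = field(default_factory=dict)  # keyed by "A->B"
    loaded_genes: dict[str, set[str]] = field(default_factory=dict)
    true_size_factors: dict[str, float] = field(default_factory=dict)
    ribo_up_genes: set[str] = field(default_factory=set)
    ribo_down_genes: set[str] = field(default_factory=set)
    set_d_mirnas: set[str] = field(default_factory=set)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    target_families: tuple[str, ...] = ()

    def validate(self, utr_lengths: dict[str, int] | None = None) -> None:
        for t in set(self.released_genes) & set(self.loaded_genes):
            if self.released_genes[t] & self.loaded_genes[t]:
                raise ValueError(f"released and loaded sets overlap at transition {t}")
        if any(s <= 0 for s in self.true_size_factors.values()):
            raise ValueError("size factors must be positive")
        if utr_lengths is not None:
            for site in self.planted_sites:
                if site.offset + site.length > utr_lengths[site.gene_id]:
                    raise ValueError(f"planted site overruns UTR of {site.gene_id}")

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "bound_genes_per_stage": {k: sorted(v) for k, v in self.bound_genes_per_stage.items()},
            "released_genes": {k: sorted(v) for k, v in self.released_genes.items()},
            "loaded_genes": {k: sorted(v) for k, v in self.loaded_genes.items()},
            "true_size_factors": self.true_size_factors,
            "ribo_up_genes": sorted(self.ribo_up_genes),
            "ribo_down_genes": sorted(self.ribo_down_genes),
            "set_d_mirnas": sorted(self.set_d_mirnas),
            "planted_sites": [[s.mirna_id, s.gene_id, s.offset, s.length] for s in self.planted_sites],
            "target_families": list(self.target_families),
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            bound_genes_per_stage={k: set(v) for k, v in d["bound_genes_per_stage"].items()},
            released_genes={k: set(v) for k, v in d["released_genes"].items()},
            loaded_genes={k: set(v) for k, v in d["loaded_genes"].items()},
            true_size_factors=d["true_size_factors"],
            ribo_up_genes=set(d["ribo_up_genes"]),
            ribo_down_genes=set(d["ribo_down_genes"]),
            set_d_mirnas=set(d["set_d_mirnas"]),
            planted_sites=[PlantedSite(*row) for row in d["planted_sites"]],
            target_families=tuple(d["target_families"]),
        )

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        """Combine truths from different generators run under one seed."""
        out = SyntheticTruth(seed=self.seed)
        for name in ("bound_genes_per_stage", "released_genes", "loaded_genes",
                     "true_size_factors"):
            merged = dict(getattr(self, name))
            merged.update(getattr(other, name))
            setattr(out, name, merged)
        out.ribo_up_genes = self.ribo_up_genes | other.ribo_up_genes
        out.ribo_down_genes = self.ribo_down_genes | other.ribo_down_genes
        out.set_d_mirnas = self.set_d_mirnas | other.set_d_mirnas
        out.planted_sites = self.planted_sites + other.planted_sites
        out.target_families = self.target_families or other.target_families
        return out
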