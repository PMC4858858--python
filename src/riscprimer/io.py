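"""Readers and writers for the pipeline's on-disk formats.

Matrices travel as TSV with a ``gene_id`` (or ``mirna_id``) index column plus
a sample-metadata TSV; sequences as FASTA (via Biopython); gene families as
GMT; configurations as YAML; truth and reports as JSON.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import PipelineConfig, SimulationConfig
from .containers import CountMatrix, IntensityMatrix, SyntheticTruth


# --- matrices --------------------------------------------------------------

def write_matrix(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t")


def read_table(path: str | Path, index_col: str | int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_intensity(matrix: IntensityMatrix, values_path, meta_path) -> None:
    write_matrix(matrix.values, values_path)
    matrix.meta.to_csv(meta_path, sep="\t")


def read_intensity(values_path, meta_path) -> IntensityMatrix:
    return IntensityMatrix(values=read_table(values_path), meta=read_table(meta_path))


def write_counts(matrix: CountMatrix, values_path, meta_path) -> None:
    write_matrix(matrix.values, values_path)
    matrix.meta.to_csv(meta_path, sep="\t")


def read_counts(values_path, meta_path) -> CountMatrix:
    return CountMatrix(values=read_table(values_path), meta=read_table(meta_path))


# --- sequences -------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def pick_longest_utrs(records: dict[str, str]) -> dict[str, str]:
    """Resolve multiple 3'UTR variants per gene by keeping the longest.

    Record ids of the form ``gene|variant`` (or plain ``gene``) collapse onto
    the gene id.
    """
    best: dict[str, str] = {}
    for rid, seq in records.items():
        gene = rid.split("|")[0]
        if gene not in best or len(seq) > len(best[gene]):
            best[gene] = seq
    return best


# --- gene families (GMT) ---------------------------------------------------

def write_gmt(families: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in families.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    families: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            families[parts[0]] = [g for g in parts[2:] if g]
    return families


# --- configuration and truth ------------------------------------------------

def write_config(config: SimulationConfig | PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())
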