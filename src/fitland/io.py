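"""Configuration, manifests and table plumbing for the design pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .design import DesignCampaignResult
from .landscape import FitnessDataset, _assign_splits
from .sequences import ProteinVariant

import numpy as np


class AnnealDefaults(BaseModel):
    """Annealing defaults shared by all model/distance combinations."""

    model_config = ConfigDict(extra="forbid")

    T_start: float = 1e3
    T_end: float = 1e-5
    move_size_mean: float = 1.0
    n_steps: int = 50_000
    n_runs: int = 500
    n_clusters: int = 41


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    tag: str
    architecture: str
    seed: int = 0
    hyperparameters: dict = {}

    @field_validator("architecture")
    @classmethod
    def _known_architecture(cls, v: str) -> str:
        from .models import ARCHITECTURES

        if v not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {v!r}")
        return v


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    seed: int = 0
    wild_type_path: str | None = None
    data_path: str | None = None
    checkpoint_dir: str | None = None
    output_dir: str | None = None
    models: list[ModelConfig] = []
    anneal: AnnealDefaults = AnnealDefaults()
    steps_override: dict[str, int] = {}
    distances: list[int] = [5, 10, 20, 30, 40, 50]
    evaluation_budgets: list[int] = [50, 100, 500]

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump()))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Defaults are filled for missing keys; unknown keys raise a ValueError
    naming the offending field.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ValueError(f"invalid configuration {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Design manifests
# ---------------------------------------------------------------------------

def write_design_manifest(
    campaigns: Sequence[DesignCampaignResult],
    out_dir: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
    overwrite: bool = False,
) -> tuple[Path, Path]:
    """Write campaign representatives as FASTA + TSV manifest.

    The manifest has one row per representative with columns ``model``,
    ``k``, ``cluster``, ``mutation_string``, ``predicted_fitness`` and
    ``run_seed``, ordered deterministically by (model, k, cluster).  A
    sidecar ``manifest_meta.json`` records the seed and configuration hash
    needed to regenerate the outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "representatives.fasta"
    tsv_path = out_dir / "manifest.tsv"
    for p in (fasta_path, tsv_path):
        if p.exists() and not overwrite:
            raise FileExistsError(f"output path collision: {p}")
    rows = []
    records: dict[str, str] = {}
    for campaign in sorted(campaigns, key=lambda c: (c.model_tag, c.k)):
        for rep in sorted(campaign.representatives, key=lambda r: r.cluster_id):
            name = f"{campaign.model_tag}_k{campaign.k}_c{rep.cluster_id}"
            rows.append(
                {
                    "model": campaign.model_tag,
                    "k": campaign.k,
                    "cluster": rep.cluster_id,
                    "mutation_string": rep.variant.mutation_string,
                    "predicted_fitness": rep.predicted_fitness,
                    "run_seed": campaign.runs[rep.run_id].seed,
                }
            )
            records[name] = rep.variant.sequence
    manifest = pd.DataFrame(
        rows,
        columns=["model", "k", "cluster", "mutation_string",
                 "predicted_fitness", "run_seed"],
    )
    manifest.to_csv(tsv_path, sep="\t", index=False)
    write_fasta(records, fasta_path)
    meta = {"seed": seed, "config_hash": config_hash, "n_designs": len(rows)}
    (out_dir / "manifest_meta.json").write_text(json.dumps(meta))
    return fasta_path, tsv_path


# ---------------------------------------------------------------------------
# Fitness tables
# ---------------------------------------------------------------------------

def read_fitness_table(
    path: str | Path,
    wild_type: str,
    default_split: str = "train",
    split_fractions: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> FitnessDataset:
    """Parse a TSV of variants and fitness scores into a dataset.

    The table needs a ``fitness`` (or ``score``) column plus a ``variant``
    column (1-based mutation strings, ``WT`` for wild type) and/or a
    ``sequence`` column.  When both encodings are present they are
    cross-validated row by row.  Malformed rows are reported with their
    line numbers.  Missing ``split`` labels are either set to
    ``default_split`` or, if ``split_fractions`` is given, assigned
    randomly with the supplied seed.
    """
    table = pd.read_csv(path, sep="\t")
    if "fitness" not in table.columns and "score" in table.columns:
        table = table.rename(columns={"score": "fitness"})
    if "fitness" not in table.columns:
        raise ValueError("table needs a 'fitness' or 'score' column")
    has_variant = "variant" in table.columns
    has_sequence = "sequence" in table.columns
    if not has_variant and not has_sequence:
        raise ValueError("table needs a 'variant' and/or 'sequence' column")
    errors = []
    variants: list[ProteinVariant] = []
    for row_idx, row in table.iterrows():
        line_no = row_idx + 2  # header is line 1
        try:
            if has_variant:
                v = ProteinVariant.from_mutation_string(wild_type, str(row["variant"]))
                if has_sequence and v.sequence != row["sequence"]:
                    raise ValueError(
                        "sequence column disagrees with mutation string"
                    )
            else:
                v = ProteinVariant.from_sequence(wild_type, str(row["sequence"]))
            variants.append(v)
        except (ValueError, IndexError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise ValueError("malformed fitness table:\n" + "\n".join(errors))
    frame = pd.DataFrame(
        {
            "variant": [v.mutation_string for v in variants],
            "sequence": [v.sequence for v in variants],
            "fitness": table["fitness"].to_numpy(dtype=float),
            "n_mutations": [v.n_mutations for v in variants],
        }
    )
    if "split" in table.columns:
        frame["split"] = table["split"].to_numpy()
    elif split_fractions is not None:
        frame["split"] = _assign_splits(
            len(frame), np.random.default_rng(seed), split_fractions
        )
    else:
        frame["split"] = default_split
    return FitnessDataset(wild_type, frame)
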