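"""Shared readers/writers and pipeline configuration.

AIRR Rearrangement tables travel as tab-separated UTF-8 text with a header
row, no quoting and ``NA`` for missing values; unknown columns are preserved
verbatim.  All thresholds live in :class:`PipelineConfig` with the analysis
defaults used throughout the package.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import pandas as pd
import yaml

MANDATORY_AIRR_COLUMNS = ("sequence_id", "sequence")


class SchemaError(ValueError):
    """An AIRR table is missing a mandatory column."""


def read_airr(path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV; booleans in ``productive`` are decoded."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=["NA"])
    for col in MANDATORY_AIRR_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory AIRR column: {col}")
    if "productive" in df.columns:
        df["productive"] = df["productive"].map({"T": True, "F": False})
    for col in ("duplicate_count", "shm_count", "junction_start"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    if "shm_freq" in df.columns:
        df["shm_freq"] = pd.to_numeric(df["shm_freq"])
    return df


def write_airr(table: pd.DataFrame, path) -> None:
    for col in MANDATORY_AIRR_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"missing mandatory AIRR column: {col}")
    out = table.copy()
    if "productive" in out.columns:
        out["productive"] = out["productive"].map(
            lambda v: "T" if v is True else ("F" if v is False else v)
        )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_peptides(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("peptide", "q_value", "mode"):
        if col not in df.columns:
            raise SchemaError(f"missing peptide column: {col}")
    return df


def write_peptides(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class PipelineConfig:
    """All analysis thresholds, defaulting to the published values."""

    qmin: float = 20.0
    min_reads: int = 5
    max_group_error: float = 0.1
    clone_threshold: float = 0.1
    min_unique: int = 100
    subsample_n: int = 126
    reps: int = 200
    large_clone_min: int = 50
    cdr3_match: float = 0.30
    fdr_dda: float = 0.1
    fdr_dia: float = 0.01
    min_v_identity: float = 0.6
    overlap_denominator: str = "jaccard"
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.max_group_error <= 1:
            raise ValueError("max_group_error must be in [0, 1]")
        if not 0 <= self.clone_threshold <= 1:
            raise ValueError("clone_threshold must be in [0, 1]")
        if not 0 <= self.cdr3_match <= 1:
            raise ValueError("cdr3_match must be in [0, 1]")
        for name in ("fdr_dda", "fdr_dia"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_reads < 1 or self.min_unique < 1 or self.subsample_n < 1:
            raise ValueError("count thresholds must be positive")
        if self.overlap_denominator not in ("jaccard", "bl", "mean"):
            raise ValueError("overlap_denominator must be jaccard|bl|mean")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = cls(**(yaml.safe_load(fh) or {}))
        cfg.validate()
        return cfg
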