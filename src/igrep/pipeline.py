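"""End-to-end orchestration of the simulated-cohort analysis.

``run_pipeline`` drives simulate -> consensus -> annotate -> clones ->
metrics -> overlap -> proteome for one subject and writes every stage's
output as deterministic text tables stamped with the config hash and seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import clones as clones_mod
from . import metrics as metrics_mod
from . import proteome as proteome_mod
from .annotate import annotate_table
from .consensus import run_consensus, unique_sequences_to_frame
from .germline import load_toy_reference
from .io import PipelineConfig, write_airr
from .simulate import (
    SimulationConfig,
    TAG_TO_SUBSET,
    simulate_longitudinal_pair,
    simulate_peptides,
    simulate_reads,
)


def process_reads_to_airr(
    reads,
    subject: str,
    timepoint: str,
    config: PipelineConfig,
    ref=None,
    isotype_map=None,
) -> pd.DataFrame:
    """Consensus + annotation for one read set; returns the annotated table."""
    ref = ref or load_toy_reference()
    uniques, _rejections = run_consensus(
        reads,
        TAG_TO_SUBSET,
        subject,
        timepoint,
        q_threshold=config.qmin,
        max_error=config.max_group_error,
        min_reads=config.min_reads,
    )
    annotated, _failures = annotate_table(
        unique_sequences_to_frame(uniques), ref, isotype_map, config.min_v_identity
    )
    return annotated


def run_pipeline(
    sim_config: SimulationConfig,
    pipe_config: PipelineConfig | None = None,
    out_dir=None,
) -> dict:
    """Simulate one longitudinal subject and run the full analysis.

    Returns a dict of in-memory results; when ``out_dir`` is given, writes
    AIRR tables, the tidy metrics table, overlap results and the proteome
    match report as TSV, each stamped with the config hash and seed.
    """
    pipe_config = pipe_config or PipelineConfig(seed=sim_config.seed)
    pipe_config.validate()
    ref = load_toy_reference()
    rng = np.random.default_rng(sim_config.seed + 1)

    truth_bl, truth_f6, true_overlap = simulate_longitudinal_pair(sim_config)
    isotype_map = {
        m.nt_sequence: m.isotype for m in truth_bl.molecules + truth_f6.molecules
    }

    annotated = {}
    for truth in (truth_bl, truth_f6):
        reads = simulate_reads(truth, sim_config, rng)
        annotated[truth.timepoint] = process_reads_to_airr(
            reads, sim_config.subject, truth.timepoint, pipe_config, ref, isotype_map
        )

    # within-sample clustering per (subject, timepoint, subset)
    per_tp = {
        tp: clones_mod.assign_clones(df, pipe_config.clone_threshold)
        for tp, df in annotated.items()
    }
    metric_tables = [
        metrics_mod.sample_metrics(
            df,
            n=pipe_config.subsample_n,
            reps=pipe_config.reps,
            seed=pipe_config.seed,
            min_unique=pipe_config.min_unique,
            large_clone_min=pipe_config.large_clone_min,
        )
        for df in per_tp.values()
    ]
    metrics_table = pd.concat(metric_tables, ignore_index=True)

    # pooled-timepoint clustering for the overlap analysis
    pooled = clones_mod.assign_clones(
        pd.concat(annotated.values(), ignore_index=True),
        pipe_config.clone_threshold,
        pool_timepoints=True,
    )
    overlaps = []
    for subset, grp in pooled[pooled["clone_id"].notna()].groupby("cell_subset"):
        bl = grp.loc[grp["timepoint"] == "BL", "clone_id"].to_numpy()
        f6 = grp.loc[grp["timepoint"] == "FUP6", "clone_id"].to_numpy()
        if len(bl) < pipe_config.min_unique or len(f6) < pipe_config.min_unique:
            continue
        overlaps.append(
            metrics_mod.clonal_overlap(
                bl, f6,
                n=pipe_config.subsample_n,
                reps=pipe_config.reps,
                seed=pipe_config.seed,
                min_unique=pipe_config.min_unique,
                denominator=pipe_config.overlap_denominator,
                subject=sim_config.subject,
                subset=subset,
            )
        )
    overlap_table = pd.DataFrame(
        [
            {"subject": o.subject, "cell_subset": o.subset,
             "mean_overlap": o.mean_overlap, "sd_overlap": o.sd_overlap,
             "n_reps": o.n_reps, "definition_tag": o.definition_tag}
            for o in overlaps
        ]
    )

    # proteome: peptides observed from the combined BL+FUP6 truth
    db = proteome_mod.build_patient_db(
        per_tp["BL"][per_tp["BL"]["productive"]],
        per_tp["FUP6"][per_tp["FUP6"]["productive"]],
    )
    peptides = simulate_peptides(
        truth_bl, sampling_fraction=0.3, decoy_fraction=0.1, rng=rng, mode="DIA"
    )
    report = proteome_mod.match_report(
        db, peptides, mode="DIA", threshold=pipe_config.cdr3_match
    )

    results = {
        "truth_bl": truth_bl,
        "truth_fup6": truth_f6,
        "true_overlap": true_overlap,
        "annotated": per_tp,
        "pooled": pooled,
        "metrics": metrics_table,
        "overlap": overlap_table,
        "proteome_db": db,
        "proteome_report": report,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = f"# config_hash={pipe_config.config_hash()} seed={pipe_config.seed}\n"
        for tp, df in per_tp.items():
            write_airr(df, out / f"rearrangements_{tp}.tsv")
        write_airr(pooled, out / "rearrangements_pooled.tsv")
        for name, df in (("metrics.tsv", metrics_table),
                         ("overlap.tsv", overlap_table),
                         ("proteome_matches.tsv", report.per_entry)):
            with open(out / name, "w") as fh:
                fh.write(stamp)
                df.to_csv(fh, sep="\t", index=False, na_rep="NA")
        db.to_fasta(out / "patient_db.fasta")
        pipe_config.to_yaml(out / "pipeline_config.yaml")
    return results
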