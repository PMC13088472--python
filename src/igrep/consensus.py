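"""UMI consensus building.

Collapses UMI-tagged VH amplicon reads into validated unique sequences:
mean-quality read filtering (Q >= 20), grouping by (subset index tag, UMI),
per-position Phred-weighted majority consensus with a maximum within-group
mismatch rate of 0.1 and a minimum of five reads per UMI group, and finally
collapsing identical consensus sequences from different UMIs into unique
sequences with copy counts.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass
class SequencingRead:
    """One single-orientation read: 6-nt subset index tag + UMI + VH payload."""

    read_id: str
    index_tag: str
    umi: str
    payload: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.payload) != len(self.qualities):
            raise ValueError(f"{self.read_id}: payload/quality length mismatch")


@dataclass
class ConsensusRecord:
    umi: str
    subset: str
    consensus_nt: str
    read_support: int
    mean_within_group_error: float
    subject: str = ""
    timepoint: str = ""


@dataclass
class ConsensusRejection:
    """A UMI group that failed validation, with a typed reason."""

    index_tag: str
    umi: str
    n_reads: int
    reason: str  # too_few_reads | error_exceeded | length_conflict


@dataclass
class UniqueSequence:
    sequence_id: str
    nt_sequence: str
    duplicate_count: int
    subset: str
    subject: str
    timepoint: str
    umis: list[str] = field(default_factory=list)


def filter_quality(reads: list[SequencingRead], q_threshold: float = 20) -> list[SequencingRead]:
    """Retain reads whose mean payload Phred score is >= ``q_threshold``.

    Mean-read semantics (pRESTO FilterSeq-quality style); input order preserved.
    """
    kept = []
    for read in reads:
        if not read.qualities:
            raise ValueError(f"{read.read_id}: missing qualities")
        if float(np.mean(read.qualities)) >= q_threshold:
            kept.append(read)
    return kept


def group_by_umi(reads: list[SequencingRead]) -> dict[tuple[str, str], list[SequencingRead]]:
    """Partition reads into groups keyed by the exact (index_tag, UMI) pair."""
    groups: dict[tuple[str, str], list[SequencingRead]] = {}
    for read in reads:
        groups.setdefault((read.index_tag, read.umi), []).append(read)
    return groups


def build_consensus(
    group: list[SequencingRead],
    max_error: float = 0.1,
    min_reads: int = 5,
    subset: str = "",
    subject: str = "",
    timepoint: str = "",
) -> ConsensusRecord | ConsensusRejection:
    """Build a Phred-weighted majority consensus for one UMI group.

    Emits a :class:`ConsensusRecord` iff the group has at least ``min_reads``
    reads of equal length and the mean per-read mismatch fraction against the
    consensus (positions called N excluded) is <= ``max_error``; otherwise a
    :class:`ConsensusRejection` with reason ``too_few_reads``,
    ``length_conflict`` or ``error_exceeded``.
    """
    if not group:
        raise ValueError("empty UMI group")
    tag, umi = group[0].index_tag, group[0].umi
    if any((r.index_tag, r.umi) != (tag, umi) for r in group):
        raise ValueError("reads in a group must share (index_tag, umi)")
    if len(group) < min_reads:
        return ConsensusRejection(tag, umi, len(group), "too_few_reads")
    lengths = {len(r.payload) for r in group}
    if len(lengths) > 1:
        return ConsensusRejection(tag, umi, len(group), "length_conflict")

    seqs = np.array([np.frombuffer(r.payload.encode(), dtype=np.uint8) for r in group])
    quals = np.array([r.qualities for r in group], dtype=float)
    # summed Phred per base per position; ties between bases -> N
    weights = np.zeros((4, seqs.shape[1]))
    for bi, base in enumerate(_BASES[:4]):
        weights[bi] = np.where(seqs == base, quals, 0.0).sum(axis=0)
    best = weights.max(axis=0)
    tie = (weights == best).sum(axis=0) > 1
    call = _BASES[np.where(tie, 4, weights.argmax(axis=0))]
    informative = ~tie
    if informative.sum() == 0:
        per_read_err = np.zeros(len(group))
    else:
        mism = (seqs[:, informative] != call[informative]).mean(axis=1)
        per_read_err = mism
    group_error = float(per_read_err.mean())
    if group_error > max_error:
        return ConsensusRejection(tag, umi, len(group), "error_exceeded")
    return ConsensusRecord(
        umi=umi,
        subset=subset,
        consensus_nt=call.tobytes().decode(),
        read_support=len(group),
        mean_within_group_error=group_error,
        subject=subject,
        timepoint=timepoint,
    )


def collapse_duplicates(records: list[ConsensusRecord]) -> list[UniqueSequence]:
    """Merge identical consensus sequences within a (subject, timepoint, subset) stratum.

    The number of merged consensus records (distinct UMIs carrying the same
    sequence) becomes ``duplicate_count`` — the sequence copy number.
    """
    merged: dict[tuple[str, str, str, str], UniqueSequence] = {}
    counter = 0
    for rec in records:
        key = (rec.subject, rec.timepoint, rec.subset, rec.consensus_nt)
        if key in merged:
            merged[key].duplicate_count += 1
            merged[key].umis.append(rec.umi)
        else:
            merged[key] = UniqueSequence(
                sequence_id=f"{rec.subject}_{rec.timepoint}_{rec.subset}_u{counter}",
                nt_sequence=rec.consensus_nt,
                duplicate_count=1,
                subset=rec.subset,
                subject=rec.subject,
                timepoint=rec.timepoint,
                umis=[rec.umi],
            )
            counter += 1
    return list(merged.values())


def run_consensus(
    reads: list[SequencingRead],
    tag_to_subset: dict[str, str],
    subject: str,
    timepoint: str,
    q_threshold: float = 20,
    max_error: float = 0.1,
    min_reads: int = 5,
) -> tuple[list[UniqueSequence], list[ConsensusRejection]]:
    """Full consensus stage: quality filter, UMI grouping, consensus, collapse."""
    kept = filter_quality(reads, q_threshold)
    records, rejections = [], []
    for (tag, _umi), group in sorted(group_by_umi(kept).items()):
        out = build_consensus(
            group,
            max_error=max_error,
            min_reads=min_reads,
            subset=tag_to_subset.get(tag, "?"),
            subject=subject,
            timepoint=timepoint,
        )
        if isinstance(out, ConsensusRecord):
            records.append(out)
        else:
            rejections.append(out)
    return collapse_duplicates(records), rejections


def unique_sequences_to_frame(uniques: list[UniqueSequence]) -> pd.DataFrame:
    """AIRR-style seed table (sequence_id, sequence, duplicate_count, strata)."""
    return pd.DataFrame(
        {
            "sequence_id": [u.sequence_id for u in uniques],
            "sequence": [u.nt_sequence for u in uniques],
            "duplicate_count": [u.duplicate_count for u in uniques],
            "subject": [u.subject for u in uniques],
            "timepoint": [u.timepoint for u in uniques],
            "cell_subset": [u.subset for u in uniques],
        }
    )


def read_fastq(path, umi_length: int, tag_length: int = 6) -> list[SequencingRead]:
    """Read inline-tagged reads (index tag + UMI + payload) from (gzipped) FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            phred = [ord(c) - 33 for c in qual]
            reads.append(
                SequencingRead(
                    read_id=header[1:].split()[0],
                    index_tag=seq[:tag_length],
                    umi=seq[tag_length : tag_length + umi_length],
                    payload=seq[tag_length + umi_length :],
                    qualities=phred[tag_length + umi_length :],
                )
            )
    return reads
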