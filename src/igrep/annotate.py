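"""Germline assignment, junction extraction, SHM and productiveness.

V and J calls are made by maximizing ungapped identity of the germline V
prefix (up to and including its conserved Cys anchor codon) and the germline J
suffix (from its conserved Trp/Phe anchor codon on) over all alignment offsets
in the query; the conserved anchors are projected through the alignment and
delimit the junction (CDR3 plus one anchor residue per side).  Somatic
hypermutation is counted as nucleotide mismatches over the germline-alignable
V region 5' of the junction.

This replaces a full IMGT/IgBLAST annotation with a self-contained aligner
adequate for substitution-only data; externally annotated AIRR tables can be
ingested directly instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from Bio.Seq import Seq

from .germline import GermlineReference
from .proteome import translate_nt


@dataclass
class GermlineAssignment:
    v_call: str
    j_call: str
    v_identity: float
    j_identity: float
    v_offset: int  # query position where the germline V prefix starts
    v_anchor: int  # query position of the conserved Cys codon
    j_anchor: int  # query position of the conserved Trp/Phe codon


class AnnotationFailure(Exception):
    """Raised when no germline V reaches the identity floor."""


def _best_offset(query: np.ndarray, template: np.ndarray) -> tuple[float, int]:
    """Best ungapped identity of ``template`` over all offsets in ``query``."""
    n, m = len(query), len(template)
    if m > n:
        ov = min(n, m)
        ident = float((query[:ov] == template[:ov]).mean())
        return ident, 0
    windows = sliding_window_view(query, m)
    identities = (windows == template).mean(axis=1)
    off = int(identities.argmax())  # ties -> smallest offset
    return float(identities[off]), off


def assign_germline(
    nt_sequence: str, ref: GermlineReference, min_v_identity: float = 0.6
) -> GermlineAssignment:
    """Assign V and J calls and locate the junction anchors.

    Deterministic tie-break: identity desc, then lexicographic segment name.
    Raises :class:`AnnotationFailure` when the best V identity falls below
    ``min_v_identity``.
    """
    query = np.frombuffer(nt_sequence.encode(), dtype=np.uint8)

    best_v = None
    for seg in sorted(ref.by_class("V"), key=lambda s: s.name):
        v_part = np.frombuffer(
            seg.nt_sequence[: seg.anchor_offset + 3].encode(), dtype=np.uint8
        )
        ident, off = _best_offset(query, v_part)
        if best_v is None or ident > best_v[0] + 1e-12:
            best_v = (ident, seg, off)
    v_ident, v_seg, v_off = best_v
    if v_ident < min_v_identity:
        raise AnnotationFailure(
            f"best V identity {v_ident:.3f} below floor {min_v_identity}"
        )
    v_anchor = v_off + v_seg.anchor_offset

    best_j = None
    for seg in sorted(ref.by_class("J"), key=lambda s: s.name):
        j_part = np.frombuffer(
            seg.nt_sequence[seg.anchor_offset :].encode(), dtype=np.uint8
        )
        start = v_anchor + 3
        if start >= len(query):
            continue
        ident, off = _best_offset(query[start:], j_part)
        if best_j is None or ident > best_j[0] + 1e-12:
            best_j = (ident, seg, start + off)
    if best_j is None:
        raise AnnotationFailure("no room for a J segment 3' of the V anchor")
    j_ident, j_seg, j_anchor = best_j

    return GermlineAssignment(
        v_call=v_seg.name,
        j_call=j_seg.name,
        v_identity=v_ident,
        j_identity=j_ident,
        v_offset=v_off,
        v_anchor=v_anchor,
        j_anchor=j_anchor,
    )


def extract_junction(nt_sequence: str, assignment: GermlineAssignment) -> tuple[str, str]:
    """Junction = V anchor codon through J anchor codon inclusive, translated.

    Raises ValueError when the span is not a codon multiple (malformed
    junction; such sequences are non-productive).
    """
    start, end = assignment.v_anchor, assignment.j_anchor + 3
    if end > len(nt_sequence) or (end - start) % 3:
        raise ValueError("junction span is not a codon multiple")
    junction_nt = nt_sequence[start:end]
    junction_aa = str(Seq(junction_nt).translate())
    return junction_nt, junction_aa


def shm_metrics(
    nt_sequence: str, assignment: GermlineAssignment, ref: GermlineReference
) -> tuple[int, float]:
    """Mismatch count and frequency over the aligned V region 5' of the junction."""
    seg = ref[assignment.v_call]
    germ = seg.nt_sequence[: seg.anchor_offset]
    query = nt_sequence[assignment.v_offset : assignment.v_anchor]
    n = min(len(germ), len(query))
    if n == 0:
        return 0, 0.0
    count = sum(1 for a, b in zip(germ[:n], query[:n]) if a != b)
    return count, count / n


def check_productive(nt_sequence: str, assignment: GermlineAssignment) -> bool:
    """In-frame junction and stop-free translation of the VH region."""
    span = assignment.j_anchor + 3 - assignment.v_anchor
    if span <= 0 or span % 3:
        return False
    coding = nt_sequence[assignment.v_offset :]
    return translate_nt(coding) is not None


def annotate_table(
    unique_sequences: pd.DataFrame,
    ref: GermlineReference,
    isotype_map: dict | None = None,
    min_v_identity: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate a unique-sequence table into AIRR Rearrangement rows.

    ``isotype_map`` maps nucleotide sequence to isotype (isotype comes from
    isotype-specific primers, i.e. library metadata, not from the VH sequence
    itself).  Returns (annotated table, failures).
    """
    rows, failures = [], []
    for rec in unique_sequences.itertuples(index=False):
        try:
            asg = assign_germline(rec.sequence, ref, min_v_identity)
            junction_nt, junction_aa = extract_junction(rec.sequence, asg)
        except (AnnotationFailure, ValueError) as exc:
            failures.append({"sequence_id": rec.sequence_id, "reason": str(exc)})
            continue
        shm_count, shm_freq = shm_metrics(rec.sequence, asg, ref)
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "sequence": rec.sequence,
                "v_call": asg.v_call,
                "j_call": asg.j_call,
                "v_family": asg.v_call.split("-")[0].split("*")[0],
                "junction": junction_nt,
                "junction_aa": junction_aa,
                "junction_start": asg.v_anchor,
                "productive": check_productive(rec.sequence, asg),
                "c_call": (isotype_map or {}).get(rec.sequence, "NA"),
                "duplicate_count": rec.duplicate_count,
                "subject": rec.subject,
                "timepoint": rec.timepoint,
                "cell_subset": rec.cell_subset,
                "shm_count": shm_count,
                "shm_freq": shm_freq,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(failures, columns=["sequence_id", "reason"])
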