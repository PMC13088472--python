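"""Proteome-transcriptome CDR3 matching.

Builds a patient-specific protein database from translated VH transcriptome
sequences (baseline and follow-up combined into one database), digests it in
silico with trypsin, maps FDR-filtered identified peptides back onto the
database by exact substring matching, and calls a VH sequence "matched" when
uniquely mapping peptides cover at least 30% of its CDR3 amino-acid span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from pyteomics import parser as _pyt_parser

#: peptide-level FDR cutoffs per acquisition mode
FDR_CUTOFFS = {"DDA": 0.1, "DIA": 0.01}

TRYPSIN_RULE = _pyt_parser.expasy_rules["trypsin"]  # [KR] not before P


def translate_nt(nt_sequence: str) -> str | None:
    """Translate in the V reading frame (frame 0); None if a stop is hit."""
    trimmed = nt_sequence[: len(nt_sequence) // 3 * 3]
    aa = str(Seq(trimmed).translate())
    return None if "*" in aa else aa


@dataclass(frozen=True)
class Peptide:
    """A digest product with 0-based half-open coordinates in its protein."""

    sequence: str
    start: int
    end: int


def digest_tryptic(
    vh_aa: str,
    missed_cleavages: int = 0,
    min_len: int | None = 6,
    max_len: int | None = 40,
) -> list[Peptide]:
    """In-silico tryptic digest (cleave after K/R except before P).

    Coordinates are retained; set ``min_len``/``max_len`` to None to disable
    the length filter (defaults 6-40 AA, standard proteomics practice).
    """
    if not vh_aa:
        raise ValueError("empty protein sequence")
    peptides = []
    for start, pep in _pyt_parser.icleave(
        vh_aa, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=None
    ):
        if min_len is not None and len(pep) < min_len:
            continue
        if max_len is not None and len(pep) > max_len:
            continue
        peptides.append(Peptide(pep, start, start + len(pep)))
    return sorted(peptides, key=lambda p: (p.start, p.end))


@dataclass
class DatabaseEntry:
    entry_id: str
    vh_aa: str
    cdr3_span: tuple  # 0-based half-open AA interval
    source_ids: list = field(default_factory=list)
    provenance: set = field(default_factory=set)  # subset of {"BL", "FUP6"}
    isotypes: set = field(default_factory=set)
    subsets: set = field(default_factory=set)
    clone_ids: set = field(default_factory=set)

    @property
    def cdr3_aa(self) -> str:
        return self.vh_aa[self.cdr3_span[0] : self.cdr3_span[1]]


@dataclass
class ProteinDatabase:
    entries: list

    def __len__(self) -> int:
        return len(self.entries)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                prov = ",".join(sorted(e.provenance))
                fh.write(
                    f">{e.entry_id} provenance={prov} "
                    f"cdr3_span={e.cdr3_span[0]}-{e.cdr3_span[1]}\n{e.vh_aa}\n"
                )


def _cdr3_aa_span(junction_start: int, junction_len: int) -> tuple | None:
    """CDR3 AA span = translated junction minus the two anchor residues."""
    if junction_start % 3 or junction_len % 3:
        return None
    start = junction_start // 3 + 1
    end = (junction_start + junction_len) // 3 - 1
    return (start, end) if end > start else None


def build_patient_db(
    rearrangements_bl: pd.DataFrame, rearrangements_fup6: pd.DataFrame | None = None
) -> ProteinDatabase:
    """Translate annotated VH sequences from both timepoints into one database.

    Identical proteins are merged with union provenance; sequences that do not
    translate cleanly (stop codon, out-of-frame junction) are skipped.
    Expects the annotated AIRR table columns ``sequence``, ``junction`` and
    ``junction_start`` (plus optional ``c_call``/``cell_subset``/``clone_id``).
    """
    frames = [("BL", rearrangements_bl)]
    if rearrangements_fup6 is not None:
        frames.append(("FUP6", rearrangements_fup6))
    merged: dict[str, DatabaseEntry] = {}
    skipped = 0
    for default_tp, frame in frames:
        for row in frame.itertuples(index=False):
            aa = translate_nt(row.sequence)
            span = _cdr3_aa_span(int(row.junction_start), len(row.junction))
            if aa is None or span is None:
                skipped += 1
                continue
            tp = getattr(row, "timepoint", default_tp) or default_tp
            entry = merged.get(aa)
            if entry is None:
                entry = DatabaseEntry(
                    entry_id=f"VH{len(merged):05d}", vh_aa=aa, cdr3_span=span
                )
                merged[aa] = entry
            entry.source_ids.append(row.sequence_id)
            entry.provenance.add(tp)
            if hasattr(row, "c_call") and isinstance(row.c_call, str):
                entry.isotypes.add(row.c_call)
            if hasattr(row, "cell_subset") and isinstance(row.cell_subset, str):
                entry.subsets.add(row.cell_subset)
            if hasattr(row, "clone_id") and isinstance(row.clone_id, str):
                entry.clone_ids.add(row.clone_id)
    db = ProteinDatabase(list(merged.values()))
    db.n_skipped = skipped
    return db


def filter_peptides(observations: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Apply the mode-specific peptide-level FDR cutoff (DDA 0.1, DIA 0.01)."""
    if mode not in FDR_CUTOFFS:
        raise ValueError(f"unknown acquisition mode {mode!r}")
    sub = observations[observations["mode"] == mode]
    return sub[sub["q_value"] <= FDR_CUTOFFS[mode]].reset_index(drop=True)


@dataclass
class PeptideOccurrence:
    peptide: str
    entry_id: str
    start: int
    end: int
    overlaps_cdr3: bool


def _find_occurrences(peptide: str, entry: DatabaseEntry) -> list[PeptideOccurrence]:
    occs = []
    pos = entry.vh_aa.find(peptide)
    while pos != -1:
        end = pos + len(peptide)
        overlaps = pos < entry.cdr3_span[1] and end > entry.cdr3_span[0]
        occs.append(PeptideOccurrence(peptide, entry.entry_id, pos, end, overlaps))
        pos = entry.vh_aa.find(peptide, pos + 1)
    return occs


def map_peptides(
    db: ProteinDatabase, peptides, equate_il: bool = False
) -> tuple[dict, dict]:
    """Exact-substring map of observed peptides onto the database.

    Returns ``(occurrences, unique_flags)``: all occurrences per peptide, and
    a flag marking peptides whose CDR3-overlapping occurrences touch exactly
    one CDR3 group (entries sharing an identical CDR3 AA string pool into one
    group, so clonally related framework-identical entries do not void
    uniqueness).  ``equate_il`` folds Leu onto Ile before matching.
    """
    if not db.entries:
        raise ValueError("empty protein database")
    fold = (lambda s: s.replace("L", "I")) if equate_il else (lambda s: s)
    folded_entries = [(e, fold(e.vh_aa)) for e in db.entries]
    by_id = {e.entry_id: e for e in db.entries}
    occurrences: dict[str, list[PeptideOccurrence]] = {}
    unique_flags: dict[str, bool] = {}
    for pep in dict.fromkeys(peptides):  # preserve order, drop duplicates
        fpep = fold(pep)
        occs: list[PeptideOccurrence] = []
        for entry, faa in folded_entries:
            pos = faa.find(fpep)
            while pos != -1:
                end = pos + len(fpep)
                overlaps = pos < entry.cdr3_span[1] and end > entry.cdr3_span[0]
                occs.append(PeptideOccurrence(pep, entry.entry_id, pos, end, overlaps))
                pos = faa.find(fpep, pos + 1)
        occurrences[pep] = occs
        cdr3_groups = {
            fold(by_id[o.entry_id].cdr3_aa) for o in occs if o.overlaps_cdr3
        }
        unique_flags[pep] = len(cdr3_groups) == 1
    return occurrences, unique_flags


def score_cdr3_coverage(
    entry: DatabaseEntry, unique_occurrences: list, threshold: float = 0.30
) -> tuple[float, bool]:
    """Fraction of the CDR3 AA span covered by the union of unique peptides."""
    c0, c1 = entry.cdr3_span
    if c1 <= c0:
        raise ValueError(f"{entry.entry_id}: zero-length CDR3 span")
    covered: set[int] = set()
    for occ in unique_occurrences:
        if occ.entry_id != entry.entry_id:
            continue
        covered.update(range(max(occ.start, c0), min(occ.end, c1)))
    coverage = len(covered) / (c1 - c0)
    return coverage, coverage >= threshold


@dataclass
class MatchReport:
    per_entry: pd.DataFrame  # entry_id, cdr3_coverage, matched, provenance, ...
    threshold: float

    @property
    def n_matched(self) -> int:
        return int(self.per_entry["matched"].sum())


def match_report(
    db: ProteinDatabase,
    observations: pd.DataFrame,
    mode: str,
    threshold: float = 0.30,
    equate_il: bool = False,
) -> MatchReport:
    """Full proteome matching stage: FDR filter, map, score every entry."""
    kept = filter_peptides(observations, mode)
    occurrences, unique_flags = map_peptides(db, kept["peptide"], equate_il)
    unique_occs = [
        o
        for pep, occs in occurrences.items()
        if unique_flags[pep]
        for o in occs
        if o.overlaps_cdr3
    ]
    rows = []
    for entry in db.entries:
        cov, matched = score_cdr3_coverage(entry, unique_occs, threshold)
        rows.append(
            {
                "entry_id": entry.entry_id,
                "cdr3_coverage": cov,
                "matched": matched,
                "provenance": ",".join(sorted(entry.provenance)),
                "isotypes": ",".join(sorted(entry.isotypes)),
                "subsets": ",".join(sorted(entry.subsets)),
            }
        )
    return MatchReport(pd.DataFrame(rows), threshold)


def rollup_matches(report: MatchReport, by: str) -> pd.DataFrame:
    """Matched-entry counts per category of ``by`` in {timepoint, isotype, subset}.

    An entry with provenance {BL, FUP6} (or several isotypes/subsets) counts
    in every category it belongs to.
    """
    column = {"timepoint": "provenance", "isotype": "isotypes", "subset": "subsets"}
    if by not in column:
        raise ValueError(f"unknown rollup key {by!r}")
    counts: dict[str, int] = {}
    matched = report.per_entry[report.per_entry["matched"]]
    for labels in matched[column[by]]:
        for label in filter(None, labels.split(",")):
            counts[label] = counts.get(label, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=[by, "n_matched"]
    )
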