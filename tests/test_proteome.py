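"""Patient database build, tryptic digest, peptide mapping, CDR3 coverage."""

import numpy as np
import pandas as pd
import pytest

from igrep.proteome import (
    DatabaseEntry,
    ProteinDatabase,
    build_patient_db,
    digest_tryptic,
    filter_peptides,
    map_peptides,
    match_report,
    rollup_matches,
    score_cdr3_coverage,
    translate_nt,
)


def hand_digest(seq):
    """Positionwise oracle: cleave after K/R unless followed by P."""
    peptides, start = [], 0
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            peptides.append((start, seq[start : i + 1]))
            start = i + 1
    if start < len(seq):
        peptides.append((start, seq[start:]))
    return peptides


class TestDigest:
    def test_kp_suppressed_rg_cleaved(self):
        peps = digest_tryptic("AKPRGK", min_len=None, max_len=None)
        assert [p.sequence for p in peps] == ["AKPR", "GK"]
        assert [(p.start, p.end) for p in peps] == [(0, 4), (4, 6)]

    def test_no_cleavage_sites(self):
        peps = digest_tryptic("AAAAAAA", min_len=None, max_len=None)
        assert [p.sequence for p in peps] == ["AAAAAAA"]

    def test_concatenation_reconstructs_input(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
            peps = digest_tryptic(seq, min_len=None, max_len=None)
            assert "".join(p.sequence for p in peps) == seq

    def test_matches_positionwise_oracle(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("AKRPG"), 40))
            ours = [(p.start, p.sequence) for p in digest_tryptic(seq, min_len=None, max_len=None)]
            assert ours == hand_digest(seq)

    def test_length_filter_defaults(self):
        peps = digest_tryptic("AKGGGGGK")  # AK (2) dropped, GGGGGK (6) kept
        assert [p.sequence for p in peps] == ["GGGGGK"]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            digest_tryptic("")


class TestFilterPeptides:
    def _obs(self, rows):
        return pd.DataFrame(rows, columns=["peptide", "q_value", "mode"])

    def test_dda_cutoff(self):
        obs = self._obs([("PEPTIDEK", 0.05, "DDA"), ("PEPTIDER", 0.15, "DDA")])
        assert filter_peptides(obs, "DDA")["peptide"].tolist() == ["PEPTIDEK"]

    def test_dia_cutoff_stricter(self):
        obs = self._obs([("PEPTIDEK", 0.05, "DIA"), ("PEPTIDER", 0.005, "DIA")])
        assert filter_peptides(obs, "DIA")["peptide"].tolist() == ["PEPTIDER"]

    @pytest.mark.parametrize(
        "mode,q,kept", [("DDA", 0.1, True), ("DDA", 0.11, False),
                        ("DIA", 0.01, True), ("DIA", 0.011, False)]
    )
    def test_boundaries_inclusive(self, mode, q, kept):
        obs = self._obs([("PEPK", q, mode)])
        assert (len(filter_peptides(obs, mode)) == 1) is kept

    def test_empty_and_unknown_mode(self):
        assert filter_peptides(self._obs([]), "DDA").empty
        with pytest.raises(ValueError):
            filter_peptides(self._obs([]), "SRM")


def entry(eid, aa, span, **kw):
    return DatabaseEntry(entry_id=eid, vh_aa=aa, cdr3_span=span, **kw)


class TestMapPeptides:
    def test_unique_single_entry(self):
        db = ProteinDatabase([entry("e0", "AAACDEFGHWAAA", (3, 10))])
        occs, uniq = map_peptides(db, ["CDEFG"])
        assert len(occs["CDEFG"]) == 1 and occs["CDEFG"][0].overlaps_cdr3
        assert uniq["CDEFG"]

    def test_framework_peptide_not_cdr3_informative(self):
        entries = [
            entry(f"e{i}", "GGGGGG" + cdr3 + "WGQG", (6, 11))
            for i, cdr3 in enumerate(["ARDYW", "ARDFW", "AKDYW"])
        ]
        db = ProteinDatabase(entries)
        occs, uniq = map_peptides(db, ["GGGGGG"])
        assert all(not o.overlaps_cdr3 for o in occs["GGGGGG"])
        assert not uniq["GGGGGG"]

    def test_shared_cdr3_group_counts_once(self):
        # two entries with identical CDR3 but different framework: still unique
        db = ProteinDatabase([
            entry("e0", "AAAARDYWGGG", (3, 8)),
            entry("e1", "CCCARDYWGGG", (3, 8)),
        ])
        occs, uniq = map_peptides(db, ["ARDYW"])
        assert len(occs["ARDYW"]) == 2
        assert uniq["ARDYW"]

    def test_matches_brute_force_all_substrings(self, rng):
        entries = []
        for i in range(20):
            aa = "".join(rng.choice(list("ACDEFG"), 30))
            entries.append(entry(f"e{i}", aa, (10, 20)))
        db = ProteinDatabase(entries)
        probes = ["".join(rng.choice(list("ACDEFG"), 4)) for _ in range(30)]
        occs, _ = map_peptides(db, probes)
        for pep in probes:
            expected = [
                (e.entry_id, s)
                for e in entries
                for s in range(len(e.vh_aa) - len(pep) + 1)
                if e.vh_aa[s : s + len(pep)] == pep
            ]
            assert [(o.entry_id, o.start) for o in occs[pep]] == expected

    def test_il_equivalence_flag(self):
        db = ProteinDatabase([entry("e0", "AAALDEFGHWAAA", (3, 10))])
        _, uniq_strict = map_peptides(db, ["IDEFG"])
        occs, uniq_folded = map_peptides(db, ["IDEFG"], equate_il=True)
        assert not map_peptides(db, ["IDEFG"])[0]["IDEFG"]
        assert occs["IDEFG"] and uniq_folded["IDEFG"]


class TestCoverage:
    def _occ(self, eid, start, end):
        from igrep.proteome import PeptideOccurrence

        return PeptideOccurrence("X", eid, start, end, True)

    def test_exactly_30pct_matches(self):
        e = entry("e0", "A" * 40, (10, 20))
        cov, matched = score_cdr3_coverage(e, [self._occ("e0", 7, 13)])
        assert cov == pytest.approx(0.30) and matched

    def test_29pct_unmatched(self):
        e = entry("e0", "A" * 110, (0, 100))
        cov, matched = score_cdr3_coverage(e, [self._occ("e0", 0, 29)])
        assert cov == pytest.approx(0.29) and not matched

    def test_no_overlap_zero(self):
        e = entry("e0", "A" * 40, (10, 20))
        cov, matched = score_cdr3_coverage(e, [])
        assert cov == 0.0 and not matched

    def test_union_not_sum(self):
        e = entry("e0", "A" * 30, (0, 10))
        occs = [self._occ("e0", 0, 4), self._occ("e0", 2, 6)]
        cov, _ = score_cdr3_coverage(e, occs)
        assert cov == pytest.approx(0.6)

    def test_interval_union_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(8, 25))
            e = entry("e0", "A" * 60, (20, 20 + L))
            occs = []
            covered = set()
            for _ in range(int(rng.integers(0, 6))):
                s = int(rng.integers(0, 50))
                t = s + int(rng.integers(3, 12))
                occs.append(self._occ("e0", s, t))
                covered |= set(range(max(s, 20), min(t, 20 + L)))
            cov, matched = score_cdr3_coverage(e, occs)
            assert cov == pytest.approx(len(covered) / L)
            assert matched is (cov >= 0.30)

    def test_monotone_in_added_peptides(self, rng):
        e = entry("e0", "A" * 60, (20, 40))
        occs = []
        prev = 0.0
        for _ in range(10):
            s = int(rng.integers(0, 50))
            occs.append(self._occ("e0", s, s + 8))
            cov, _ = score_cdr3_coverage(e, occs)
            assert cov >= prev
            prev = cov

    def test_zero_length_span_error(self):
        e = entry("e0", "A" * 10, (5, 5))
        with pytest.raises(ValueError):
            score_cdr3_coverage(e, [])


class TestPatientDatabase:
    def _frame(self, seqs_meta, timepoint):
        rows = []
        for i, (nt, jstart, jlen) in enumerate(seqs_meta):
            rows.append(
                {
                    "sequence_id": f"{timepoint}_s{i}",
                    "sequence": nt,
                    "junction": nt[jstart : jstart + jlen],
                    "junction_start": jstart,
                    "timepoint": timepoint,
                }
            )
        return pd.DataFrame(rows)

    def test_same_protein_both_timepoints_merges(self):
        nt = "TGTGCAGCAGCAGCAGCATGG" * 3  # translates cleanly, len 63
        bl = self._frame([(nt, 0, 21)], "BL")
        f6 = self._frame([(nt, 0, 21)], "FUP6")
        db = build_patient_db(bl, f6)
        assert len(db) == 1
        assert db.entries[0].provenance == {"BL", "FUP6"}

    def test_empty_fup6(self):
        nt = "TGTGCAGCAGCAGCAGCATGG" * 3
        db = build_patient_db(self._frame([(nt, 0, 21)], "BL"), None)
        assert len(db) == 1 and db.entries[0].provenance == {"BL"}

    def test_entry_count_bounded_by_input(self, ref):
        from igrep.simulate import simulate_repertoire
        from igrep.annotate import annotate_table
        from conftest import small_config

        truth = simulate_repertoire(small_config(81))
        seqs = sorted({m.nt_sequence for m in truth.molecules})
        table = pd.DataFrame(
            {
                "sequence_id": [f"s{i}" for i in range(len(seqs))],
                "sequence": seqs,
                "duplicate_count": 1,
                "subject": "T1",
                "timepoint": "BL",
                "cell_subset": "N",
            }
        )
        annotated, _ = annotate_table(table, ref)
        db = build_patient_db(annotated, None)
        assert 0 < len(db) <= len(annotated)

    def test_stop_containing_input_skipped(self):
        nt = "TAA" + "TGTGCAGCATGG" * 3
        db = build_patient_db(self._frame([(nt, 0, 12)], "BL"), None)
        assert len(db) == 0 and db.n_skipped == 1


class TestRoundTripAndRollup:
    def test_digested_peptides_map_back_to_source(self, rng):
        entries = []
        for i in range(10):
            aa = "".join(rng.choice(list("ACDEFGHKLMNQSTVWY"), 50))
            entries.append(entry(f"e{i}", aa, (20, 32)))
        db = ProteinDatabase(entries)
        for e in entries:
            for pep in digest_tryptic(e.vh_aa):
                occs, _ = map_peptides(db, [pep.sequence])
                assert any(o.entry_id == e.entry_id for o in occs[pep.sequence])

    def test_match_report_and_rollups(self):
        e0 = entry("e0", "GGGGGCARDYWGQG", (6, 11),
                   provenance={"BL", "FUP6"}, isotypes={"IgG"}, subsets={"M"})
        e1 = entry("e1", "GGGGGCAKEFWGQG", (6, 11),
                   provenance={"BL"}, isotypes={"IgA"}, subsets={"N"})
        db = ProteinDatabase([e0, e1])
        obs = pd.DataFrame(
            {"peptide": ["GCARDYWGQG"], "q_value": [0.001], "mode": ["DIA"]}
        )
        report = match_report(db, obs, "DIA")
        per = report.per_entry.set_index("entry_id")
        assert bool(per.loc["e0", "matched"]) is True
        assert bool(per.loc["e1", "matched"]) is False
        tp = rollup_matches(report, "timepoint").set_index("timepoint")
        assert tp.loc["BL", "n_matched"] == 1 and tp.loc["FUP6", "n_matched"] == 1
        iso = rollup_matches(report, "isotype").set_index("isotype")
        assert iso.loc["IgG", "n_matched"] == 1 and "IgA" not in iso.index

    def test_no_matches_all_zero(self):
        db = ProteinDatabase([entry("e0", "GGGGGCARDYWGQG", (6, 11),
                                    provenance={"BL"})])
        obs = pd.DataFrame({"peptide": ["WWWWWW"], "q_value": [0.001], "mode": ["DIA"]})
        report = match_report(db, obs, "DIA")
        assert report.n_matched == 0
        assert rollup_matches(report, "timepoint").empty
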