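"""UMI consensus stage: quality filter, grouping, majority vote, collapsing."""

import numpy as np
import pytest

from igrep.consensus import (
    ConsensusRecord,
    ConsensusRejection,
    SequencingRead,
    build_consensus,
    collapse_duplicates,
    filter_quality,
    group_by_umi,
    run_consensus,
)
from igrep.simulate import SUBSET_TAGS, TAG_TO_SUBSET, simulate_reads, simulate_repertoire

from conftest import small_config


def make_read(rid, payload, q=30, umi="AAAAAAAA", tag="ACGTAC"):
    return SequencingRead(rid, tag, umi, payload, [q] * len(payload))


class TestFilterQuality:
    def test_q30_read_retained(self):
        assert filter_quality([make_read("r", "ACGT", q=30)]) != []

    def test_q10_read_dropped(self):
        assert filter_quality([make_read("r", "ACGT", q=10)]) == []

    def test_boundary_mean_q20_retained(self):
        read = SequencingRead("r", "ACGTAC", "A" * 8, "ACGT", [10, 30, 10, 30])
        assert filter_quality([read]) == [read]

    def test_mixed_set_matches_rescan_oracle(self, rng):
        reads = []
        for i in range(200):
            quals = rng.integers(2, 41, size=50).tolist()
            reads.append(SequencingRead(f"r{i}", "ACGTAC", "A" * 8, "A" * 50, quals))
        kept = filter_quality(reads, 20)
        oracle = [r for r in reads if sum(r.qualities) / len(r.qualities) >= 20]
        assert kept == oracle

    def test_missing_qualities_error(self):
        bad = SequencingRead("r", "ACGTAC", "A" * 8, "", [])
        with pytest.raises(ValueError):
            filter_quality([bad])


class TestGroupByUmi:
    def test_single_group(self):
        reads = [make_read(f"r{i}", "ACGT") for i in range(10)]
        groups = group_by_umi(reads)
        assert len(groups) == 1 and len(next(iter(groups.values()))) == 10

    def test_all_distinct_umis(self):
        reads = [
            SequencingRead(f"r{i}", "ACGTAC", np.base_repr(i, 4).zfill(8).translate(
                str.maketrans("0123", "ACGT")), "ACGT", [30] * 4)
            for i in range(10)
        ]
        groups = group_by_umi(reads)
        assert len(groups) == 10
        assert all(len(g) == 1 for g in groups.values())

    def test_partition_property(self, rng):
        reads = [
            make_read(f"r{i}", "ACGT", umi="".join(rng.choice(list("AC"), 8)))
            for i in range(100)
        ]
        groups = group_by_umi(reads)
        assert sum(len(g) for g in groups.values()) == 100


def brute_force_consensus(payloads, quals):
    """Independent per-position majority vote with summed-Phred weights."""
    L = len(payloads[0])
    consensus = []
    for pos in range(L):
        weights = {}
        for p, q in zip(payloads, quals):
            weights[p[pos]] = weights.get(p[pos], 0) + q[pos]
        best = max(weights.values())
        winners = [b for b, w in weights.items() if w == best]
        consensus.append(winners[0] if len(winners) == 1 else "N")
    cons = "".join(consensus)
    errs = []
    informative = [i for i, c in enumerate(cons) if c != "N"]
    for p in payloads:
        if informative:
            errs.append(sum(p[i] != cons[i] for i in informative) / len(informative))
        else:
            errs.append(0.0)
    return cons, sum(errs) / len(errs)


class TestBuildConsensus:
    def test_five_identical_reads(self):
        group = [make_read(f"r{i}", "ACGTACGT") for i in range(5)]
        rec = build_consensus(group)
        assert isinstance(rec, ConsensusRecord)
        assert rec.consensus_nt == "ACGTACGT"
        assert rec.mean_within_group_error == 0.0
        assert rec.read_support == 5

    def test_four_reads_rejected(self):
        group = [make_read(f"r{i}", "ACGTACGT") for i in range(4)]
        rej = build_consensus(group)
        assert isinstance(rej, ConsensusRejection)
        assert rej.reason == "too_few_reads"

    def test_high_scatter_rejected_matches_oracle(self, rng):
        base = "".join(rng.choice(list("ACGT"), 100))
        payloads = []
        for _ in range(6):
            arr = list(base)
            for pos in rng.choice(100, size=15, replace=False):
                arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
            payloads.append("".join(arr))
        group = [make_read(f"r{i}", p) for i, p in enumerate(payloads)]
        out = build_consensus(group)
        _, oracle_err = brute_force_consensus(payloads, [[30] * 100] * 6)
        assert oracle_err > 0.1
        assert isinstance(out, ConsensusRejection) and out.reason == "error_exceeded"

    def test_random_groups_match_brute_force(self, rng):
        for trial in range(20):
            base = "".join(rng.choice(list("ACGT"), 40))
            payloads, quals = [], []
            for _ in range(6):
                arr = list(base)
                for pos in rng.choice(40, size=2, replace=False):
                    arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
                payloads.append("".join(arr))
                quals.append(rng.integers(20, 41, size=40).tolist())
            group = [
                SequencingRead(f"r{i}", "ACGTAC", "A" * 8, p, q)
                for i, (p, q) in enumerate(zip(payloads, quals))
            ]
            out = build_consensus(group, max_error=1.0)
            cons, err = brute_force_consensus(payloads, quals)
            assert isinstance(out, ConsensusRecord)
            assert out.consensus_nt == cons
            assert out.mean_within_group_error == pytest.approx(err)

    def test_length_conflict(self):
        group = [make_read("r0", "ACGTACGT")] * 4 + [make_read("r4", "ACGTACG")]
        rej = build_consensus(group)
        assert rej.reason == "length_conflict"

    def test_error_boundaries(self):
        # 8 clean reads + 2 reads with the first k of 100 positions flipped:
        # consensus is the clean base, group error = 0.2 * k/100
        base = "A" * 100
        def group_with_k(k):
            payloads = [base] * 8 + ["C" * k + "A" * (100 - k)] * 2
            return [make_read(f"r{i}", p) for i, p in enumerate(payloads)]
        ok = build_consensus(group_with_k(45))   # group error 0.09
        bad = build_consensus(group_with_k(55))  # group error 0.11
        assert isinstance(ok, ConsensusRecord)
        assert ok.mean_within_group_error == pytest.approx(0.09)
        assert isinstance(bad, ConsensusRejection) and bad.reason == "error_exceeded"

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestCollapseDuplicates:
    def _rec(self, seq, umi):
        return ConsensusRecord(umi, "N", seq, 5, 0.0, "S1", "BL")

    def test_three_identical_merge(self):
        out = collapse_duplicates([self._rec("ACGT", f"U{i}") for i in range(3)])
        assert len(out) == 1 and out[0].duplicate_count == 3

    def test_all_distinct(self):
        out = collapse_duplicates([self._rec(s, "U") for s in ("AAAA", "CCCC", "GGGG")])
        assert sorted(u.duplicate_count for u in out) == [1, 1, 1]

    def test_mixed_matches_hashmap_oracle(self, rng):
        seqs = ["".join(rng.choice(list("AC"), 4)) for _ in range(100)]
        out = collapse_duplicates([self._rec(s, f"U{i}") for i, s in enumerate(seqs)])
        oracle = {}
        for s in seqs:
            oracle[s] = oracle.get(s, 0) + 1
        assert {u.nt_sequence: u.duplicate_count for u in out} == oracle
        assert sum(u.duplicate_count for u in out) == len(seqs)


class TestConservationAndRecovery:
    def test_every_read_group_accounted_for(self, rng):
        cfg = small_config(21, reads_per_molecule_law=("poisson", {"lam": 6.0}))
        truth = simulate_repertoire(cfg)
        reads = simulate_reads(truth, cfg, rng)
        uniques, rejections = run_consensus(reads, TAG_TO_SUBSET, "T1", "BL")
        n_groups_emitted = sum(u.duplicate_count for u in uniques)
        assert n_groups_emitted + len(rejections) == len(group_by_umi(reads))

    def test_noise_free_recovery_of_molecule_set(self, rng):
        cfg = small_config(22)
        truth = simulate_repertoire(cfg)
        reads = simulate_reads(truth, cfg, rng)
        uniques, rejections = run_consensus(reads, TAG_TO_SUBSET, "T1", "BL")
        assert rejections == []
        recovered = {(u.subset, u.nt_sequence) for u in uniques}
        assert recovered == truth.unique_sequences()
        # duplicate_count equals molecules per (subset, sequence)
        mol_counts = {}
        for m in truth.molecules:
            key = (m.subset, m.nt_sequence)
            mol_counts[key] = mol_counts.get(key, 0) + 1
        for u in uniques:
            assert u.duplicate_count == mol_counts[(u.subset, u.nt_sequence)]

    def test_min_reads_monotonicity(self, rng):
        cfg = small_config(23, reads_per_molecule_law=("poisson", {"lam": 6.0}))
        truth = simulate_repertoire(cfg)
        reads = simulate_reads(truth, cfg, rng)
        counts = []
        for min_reads in (3, 5, 8):
            uniques, _ = run_consensus(
                reads, TAG_TO_SUBSET, "T1", "BL", min_reads=min_reads
            )
            counts.append(sum(u.duplicate_count for u in uniques))
        assert counts[0] >= counts[1] >= counts[2]
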