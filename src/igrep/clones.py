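"""Clonal lineage assignment.

Productive sequences are partitioned into clones by the three-criterion rule:
identical CDR3 (junction) length, same IGHV and IGHJ gene (allele suffixes
stripped), and single-linkage clustering of the nucleotide junction at a
length-normalized Hamming distance threshold of 0.1.  Single linkage at a
fixed cut is realized as connected components of the thresholded distance
graph, which is equivalent to cutting the single-linkage dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


def strip_allele(call: str) -> str:
    """Gene-level segment name: 'IGHV3-23*01' -> 'IGHV3-23'."""
    return call.split("*")[0]


def partition_key(row) -> tuple[str, str, int]:
    """(v_gene, j_gene, junction length in nt) — criteria I and II."""
    return (strip_allele(row.v_call), strip_allele(row.j_call), len(row.junction))


def normalized_hamming(junction_a: str, junction_b: str) -> float:
    """Length-normalized Hamming distance between equal-length junctions."""
    if len(junction_a) != len(junction_b):
        raise ValueError("junctions must have equal length")
    if not junction_a:
        raise ValueError("empty junction")
    return sum(a != b for a, b in zip(junction_a, junction_b)) / len(junction_a)


def single_linkage_clones(
    members: list[tuple[str, str]], threshold: float = 0.1
) -> dict[str, int]:
    """Cluster (sequence_id, junction_nt) pairs sharing one partition key.

    Returns sequence_id -> local cluster index; clusters are connected
    components of the graph with an edge wherever the normalized Hamming
    distance is <= ``threshold``.
    """
    ids = [m[0] for m in members]
    if not ids:
        return {}
    arr = np.array(
        [np.frombuffer(j.encode(), dtype=np.uint8) for _, j in members]
    )
    n, L = arr.shape
    dist = (arr[:, None, :] != arr[None, :, :]).mean(axis=2)
    ii, jj = np.nonzero(dist <= threshold)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return dict(zip(ids, labels.tolist()))


@dataclass
class CloneTable:
    """Clone partition of one clustering stratum."""

    stratum: tuple
    clones: pd.DataFrame  # clone_id, size, v_gene, j_gene, junction_length, member ids

    def sizes(self) -> np.ndarray:
        return self.clones["size"].to_numpy()


def assign_clones(
    rearrangements: pd.DataFrame,
    threshold: float = 0.1,
    pool_timepoints: bool = False,
) -> pd.DataFrame:
    """Assign ``clone_id`` to every productive rearrangement.

    Clustering strata are (subject, timepoint, cell_subset), or with
    ``pool_timepoints`` (subject, cell_subset) so that clone identity is
    comparable between BL and FUP6 for overlap analyses.  Clone ids are
    deterministic: within a stratum, clusters are ordered by size descending
    then by their lexicographically smallest member sequence_id.
    """
    df = rearrangements.copy()
    df["clone_id"] = pd.Series([pd.NA] * len(df), dtype="object")
    prod = df[df["productive"].astype(bool)]
    if prod.empty:
        return df
    strat_cols = ["subject", "cell_subset"] if pool_timepoints else [
        "subject", "timepoint", "cell_subset"
    ]
    for stratum, idx in prod.groupby(strat_cols, sort=True).groups.items():
        stratum = stratum if isinstance(stratum, tuple) else (stratum,)
        sub = df.loc[idx]
        clusters: list[tuple[str, list]] = []  # (smallest member id, member index list)
        for key, kidx in sub.groupby(
            sub.apply(partition_key, axis=1), sort=True
        ).groups.items():
            part = df.loc[kidx]
            local = single_linkage_clones(
                list(zip(part["sequence_id"], part["junction"])), threshold
            )
            by_label: dict[int, list] = {}
            for sid, label in local.items():
                by_label.setdefault(label, []).append(sid)
            for label, sids in by_label.items():
                clusters.append((min(sids), sids))
        clusters.sort(key=lambda c: (-len(c[1]), c[0]))
        prefix = "_".join(str(s) for s in stratum)
        sid_to_clone = {}
        for rank, (_, sids) in enumerate(clusters):
            for sid in sids:
                sid_to_clone[sid] = f"{prefix}|clone{rank:05d}"
        mask = df["sequence_id"].isin(sid_to_clone)
        df.loc[mask, "clone_id"] = df.loc[mask, "sequence_id"].map(sid_to_clone)
    return df


def clone_table(rearrangements: pd.DataFrame) -> pd.DataFrame:
    """Summarize an assigned table into one row per clone (size = unique seqs)."""
    prod = rearrangements[rearrangements["clone_id"].notna()]
    rows = []
    for clone_id, grp in prod.groupby("clone_id", sort=True):
        first = grp.iloc[0]
        rows.append(
            {
                "clone_id": clone_id,
                "size": len(grp),
                "v_gene": strip_allele(first["v_call"]),
                "j_gene": strip_allele(first["j_call"]),
                "junction_length": len(first["junction"]),
                "subject": first["subject"],
                "cell_subset": first["cell_subset"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id", "size", "v_gene", "j_gene",
            "junction_length", "subject", "cell_subset",
        ],
    )
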