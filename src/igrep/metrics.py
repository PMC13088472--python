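"""Repertoire summary statistics.

Hill-number diversity under the fixed-depth bootstrap (n = 126 unique
sequences, 200 repetitions, admission floor n >= 100), percentage of expanded
clones (> 50 unique members), mean somatic-hypermutation frequency, IGHV
family and isotype usage vectors, and longitudinal clonal overlap estimated
under the same bootstrap.

The sampling unit everywhere is the unique sequence; clone abundances are
recomputed inside each bootstrap draw from the drawn members' clone ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

V_FAMILY_UNIVERSE = tuple(f"IGHV{i}" for i in range(1, 8))
ISOTYPE_UNIVERSE = ("IgD", "IgM", "IgG", "IgA")


def qc_filter_sample(n_unique: int, min_unique: int = 100) -> bool:
    """Sample admission rule: at least ``min_unique`` unique sequences."""
    return n_unique >= min_unique


def hill_diversity(sizes, q: float) -> float:
    """Hill number of order q for a clone-size abundance vector.

    q = 0 is clone richness; q = 1 is exp(Shannon entropy) — diversity
    weighted by clone size; other q use the general formula
    (sum p_i^q)^(1/(1-q)).
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0 or sizes.sum() <= 0:
        raise ValueError("empty abundance vector")
    if np.any(sizes < 1):
        raise ValueError("clone sizes must be >= 1")
    p = sizes / sizes.sum()
    if q == 0:
        return float(len(p))
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


@dataclass
class DiversityResult:
    q: float
    mean_hill: float
    sd_hill: float
    n_subsample: int
    n_reps: int
    seed: int


def bootstrap_diversity(
    clone_ids,
    qs=(0, 1),
    n: int = 126,
    reps: int = 200,
    seed: int = 0,
    min_unique: int = 100,
) -> dict[float, DiversityResult]:
    """Bootstrap Hill diversity of one sample.

    ``clone_ids`` lists the clone id of each unique sequence.  Per repetition,
    ``n`` unique sequences are drawn with replacement, clone abundances are
    rebuilt from the draw, and Hill numbers computed; the mean and sd over
    repetitions are reported.  Refuses samples below the admission floor.
    """
    clone_ids = np.asarray(clone_ids)
    if not qc_filter_sample(len(clone_ids), min_unique):
        raise ValueError(
            f"sample has {len(clone_ids)} unique sequences; "
            f"admission floor is {min_unique}"
        )
    rng = np.random.default_rng(seed)
    values = {q: np.empty(reps) for q in qs}
    for r in range(reps):
        draw = clone_ids[rng.integers(0, len(clone_ids), size=n)]
        _, counts = np.unique(draw, return_counts=True)
        for q in qs:
            values[q][r] = hill_diversity(counts, q)
    return {
        q: DiversityResult(
            q=q,
            mean_hill=float(values[q].mean()),
            sd_hill=float(values[q].std(ddof=1)),
            n_subsample=n,
            n_reps=reps,
            seed=seed,
        )
        for q in qs
    }


def pct_large_clones(clone_sizes, min_members: int = 50) -> float:
    """Percentage of clones with strictly more than ``min_members`` unique sequences."""
    sizes = np.asarray(clone_sizes)
    if sizes.size == 0:
        raise ValueError("empty clone table")
    return 100.0 * float((sizes > min_members).sum()) / sizes.size


def usage_fractions(sample: pd.DataFrame, key: str) -> pd.Series:
    """Per-category fraction of unique sequences over a fixed category universe.

    ``key`` is ``"v_family"`` (universe IGHV1-IGHV7) or ``"isotype"``
    (IgD/IgM/IgG/IgA); absent categories are reported as 0.
    """
    if key == "v_family":
        column, universe = "v_family", V_FAMILY_UNIVERSE
    elif key == "isotype":
        column, universe = "c_call", ISOTYPE_UNIVERSE
    else:
        raise ValueError(f"unknown usage key {key!r}")
    counts = sample[column].value_counts()
    total = len(sample)
    return pd.Series(
        {cat: counts.get(cat, 0) / total if total else 0.0 for cat in universe},
        name=key,
    )


def shm_summary(sample: pd.DataFrame) -> float:
    """Unweighted mean SHM frequency over unique sequences."""
    if sample.empty:
        raise ValueError("empty sample")
    return float(sample["shm_freq"].mean())


@dataclass
class OverlapResult:
    subject: str
    subset: str
    mean_overlap: float
    sd_overlap: float
    n_reps: int
    definition_tag: str


def clonal_overlap(
    clone_ids_bl,
    clone_ids_fup6,
    n: int = 126,
    reps: int = 200,
    seed: int = 0,
    min_unique: int = 100,
    denominator: str = "jaccard",
    subject: str = "",
    subset: str = "",
) -> OverlapResult:
    """Bootstrap clonal overlap between two timepoints of one subject/subset.

    Clone ids must come from pooled-timepoint clustering so identity is
    comparable.  Per repetition, ``n`` unique sequences are drawn with
    replacement independently from each timepoint; the overlap of one
    repetition is |shared clones| over a denominator selected by
    ``denominator``: "jaccard" (union of clones seen in either draw, default),
    "bl" (clones seen at baseline) or "mean" (mean of the two directional
    overlaps).
    """
    a = np.asarray(clone_ids_bl)
    b = np.asarray(clone_ids_fup6)
    for name, ids in (("BL", a), ("FUP6", b)):
        if not qc_filter_sample(len(ids), min_unique):
            raise ValueError(f"{name} sample below the n >= {min_unique} admission floor")
    if denominator not in ("jaccard", "bl", "mean"):
        raise ValueError(f"unknown overlap denominator {denominator!r}")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for r in range(reps):
        sa = set(a[rng.integers(0, len(a), size=n)])
        sb = set(b[rng.integers(0, len(b), size=n)])
        shared = len(sa & sb)
        if denominator == "jaccard":
            vals[r] = shared / len(sa | sb)
        elif denominator == "bl":
            vals[r] = shared / len(sa)
        else:
            vals[r] = 0.5 * (shared / len(sa) + shared / len(sb))
    return OverlapResult(
        subject=subject,
        subset=subset,
        mean_overlap=float(vals.mean()),
        sd_overlap=float(vals.std(ddof=1)),
        n_reps=reps,
        definition_tag=denominator,
    )


def sample_metrics(
    assigned: pd.DataFrame,
    n: int = 126,
    reps: int = 200,
    seed: int = 0,
    min_unique: int = 100,
    large_clone_min: int = 50,
) -> pd.DataFrame:
    """Tidy per-(subject, timepoint, subset) metric table for one assigned cohort.

    Samples below the admission floor (n >= 100 unique sequences) are excluded;
    excluded strata are reported with metric ``excluded`` and the unique count.
    """
    rows = []
    prod = assigned[assigned["clone_id"].notna()]
    for (subject, timepoint, subset), grp in prod.groupby(
        ["subject", "timepoint", "cell_subset"], sort=True
    ):
        base = {"subject": subject, "timepoint": timepoint, "cell_subset": subset,
                "n_reps": reps, "seed": seed, "definition_tag": ""}
        if not qc_filter_sample(len(grp), min_unique):
            rows.append({**base, "metric": "excluded", "value": float(len(grp)),
                         "sd": np.nan, "n_reps": 0})
            continue
        div = bootstrap_diversity(
            grp["clone_id"].to_numpy(), (0, 1), n, reps, seed, min_unique
        )
        for q in (0, 1):
            rows.append({**base, "metric": f"diversity_q{q}",
                         "value": div[q].mean_hill, "sd": div[q].sd_hill})
        sizes = grp.groupby("clone_id").size().to_numpy()
        rows.append({**base, "metric": "pct_clones_gt50",
                     "value": pct_large_clones(sizes, large_clone_min), "sd": np.nan})
        rows.append({**base, "metric": "mean_shm_freq",
                     "value": shm_summary(grp), "sd": np.nan})
        for key in ("v_family", "isotype"):
            for cat, frac in usage_fractions(grp, key).items():
                rows.append({**base, "metric": f"usage_{key}_{cat}",
                             "value": float(frac), "sd": np.nan})
    return pd.DataFrame(rows)
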