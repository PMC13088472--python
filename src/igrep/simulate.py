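"""Synthetic VH repertoire generator.

Produces ground-truth B-cell receptor heavy-chain repertoires with the
statistical structure the downstream analysis assumes: V(D)J recombination on
the packaged germline set, junction-sparing somatic hypermutation at
subset-specific rates, power-law clone sizes (expanded vs. diverse subsets),
isotype and IGHV-family usage vectors, longitudinal clone retention in the
low-overlap regime, UMI-tagged reads with sequencing error, and tryptic
peptide observations drawn from translated VH proteins.

Every operation takes an explicit ``numpy.random.Generator``; a whole
simulation flows from the single seed in :class:`SimulationConfig`, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .consensus import SequencingRead
from .germline import GermlineReference, load_toy_reference
from .proteome import digest_tryptic, translate_nt

ISOTYPES = ("IgD", "IgM", "IgG", "IgA")
SUBSETS = ("N", "DN", "M", "P")
#: fixed 6-nt index tags labelling the sorted cell subset
SUBSET_TAGS = {"N": "ACGTAC", "DN": "TGCATG", "M": "CATGCA", "P": "GTACGT"}
TAG_TO_SUBSET = {v: k for k, v in SUBSET_TAGS.items()}

_CODON_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SubsetConfig:
    """Per-subset generation parameters.

    ``clone_size_law`` is ``(name, params)`` with name ``"zeta"`` (power law
    with exponent ``a``, truncated at ``max_size``) or ``"constant"``
    (``size``); it governs the number of member molecules per clone.
    """

    n_clones: int
    clone_size_law: tuple = ("zeta", {"a": 2.0, "max_size": 200})
    shm_rate: float = 0.0
    isotype_probs: dict = field(
        default_factory=lambda: {"IgD": 0.25, "IgM": 0.25, "IgG": 0.25, "IgA": 0.25}
    )
    vfamily_probs: dict = field(
        default_factory=lambda: {f"IGHV{i}": 0.2 for i in range(1, 6)}
    )

    def validate(self) -> None:
        for name, probs in (("isotype_probs", self.isotype_probs),
                            ("vfamily_probs", self.vfamily_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not 0.0 <= self.shm_rate <= 1.0:
            raise ValueError("shm_rate must be in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    subject: str = "S1"
    subsets: dict = field(default_factory=dict)  # name -> SubsetConfig
    reads_per_molecule_law: tuple = ("poisson", {"lam": 12.0})
    per_base_read_error: float = 0.001
    umi_length: int = 12
    retention_fraction: float = 0.02
    fup6_diversity_scale: float = 1.0
    insert_len_range: tuple = (0, 30)
    mutate_junction: bool = False
    q_high: int = 30
    q_low: int = 15
    low_q_fraction: float = 0.02

    def validate(self) -> None:
        if self.umi_length not in (8, 12):
            raise ValueError("umi_length must be 8 or 12")
        for x in (self.per_base_read_error, self.retention_fraction, self.low_q_fraction):
            if not 0.0 <= x <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        lo, hi = self.insert_len_range
        if lo % 3 or hi % 3 or lo > hi:
            raise ValueError("insert_len_range must be multiples of 3 with lo <= hi")
        for sub in self.subsets.values():
            sub.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["subsets"] = {
            k: SubsetConfig(**{**v, "clone_size_law": tuple(v["clone_size_law"])})
            for k, v in raw.get("subsets", {}).items()
        }
        for key in ("reads_per_molecule_law", "insert_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def default_config(seed: int = 0, subject: str = "S1") -> SimulationConfig:
    """Study-like defaults: diverse unmutated naive cells, expanded mutated
    double-negative cells and plasmablasts, class-switched memory cells, and a
    low (<3%) longitudinal clone-retention regime."""
    subsets = {
        "N": SubsetConfig(
            n_clones=300,
            clone_size_law=("zeta", {"a": 3.0, "max_size": 20}),
            shm_rate=0.0,
            isotype_probs={"IgD": 0.45, "IgM": 0.50, "IgG": 0.03, "IgA": 0.02},
            vfamily_probs={"IGHV1": 0.20, "IGHV2": 0.10, "IGHV3": 0.35,
                           "IGHV4": 0.25, "IGHV5": 0.10},
        ),
        "DN": SubsetConfig(
            n_clones=150,
            clone_size_law=("zeta", {"a": 1.8, "max_size": 200}),
            shm_rate=0.04,
            isotype_probs={"IgD": 0.0, "IgM": 0.20, "IgG": 0.50, "IgA": 0.30},
            vfamily_probs={"IGHV1": 0.20, "IGHV2": 0.10, "IGHV3": 0.35,
                           "IGHV4": 0.25, "IGHV5": 0.10},
        ),
        "M": SubsetConfig(
            n_clones=200,
            clone_size_law=("zeta", {"a": 2.2, "max_size": 100}),
            shm_rate=0.06,
            isotype_probs={"IgD": 0.0, "IgM": 0.15, "IgG": 0.55, "IgA": 0.30},
            vfamily_probs={"IGHV1": 0.20, "IGHV2": 0.10, "IGHV3": 0.35,
                           "IGHV4": 0.25, "IGHV5": 0.10},
        ),
        "P": SubsetConfig(
            n_clones=80,
            clone_size_law=("zeta", {"a": 1.6, "max_size": 300}),
            shm_rate=0.07,
            isotype_probs={"IgD": 0.0, "IgM": 0.05, "IgG": 0.60, "IgA": 0.35},
            vfamily_probs={"IGHV1": 0.20, "IGHV2": 0.10, "IGHV3": 0.35,
                           "IGHV4": 0.25, "IGHV5": 0.10},
        ),
    }
    return SimulationConfig(seed=seed, subject=subject, subsets=subsets)


@dataclass
class Molecule:
    """One simulated mRNA molecule with full ground truth."""

    molecule_id: str
    subject: str
    timepoint: str
    subset: str
    true_clone_id: str
    nt_sequence: str
    isotype: str
    v_name: str
    j_name: str
    true_junction_nt: str
    junction_start: int
    n_mutations: int
    n_mutations_v: int  # mutations 5' of the junction (germline-alignable V region)


@dataclass
class SimulatedTruth:
    """All molecules of one (subject, timepoint) snapshot, with clone-level truth."""

    subject: str
    timepoint: str
    molecules: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.molecules])

    def clone_ids(self) -> set:
        return {m.true_clone_id for m in self.molecules}

    def unique_sequences(self) -> set:
        return {(m.subset, m.nt_sequence) for m in self.molecules}


def recombine_vdj(
    ref: GermlineReference,
    vfamily_probs: dict,
    rng: np.random.Generator,
    insert_len_range: tuple = (0, 30),
):
    """Recombine one naive in-frame VH molecule.

    The sequence is V prefix through its anchor codon + a random insert whose
    length is a multiple of 3 + the J segment from its anchor codon on; the
    junction runs from the V anchor codon through the J anchor codon
    inclusive, so its translation starts with C and ends with W or F.  Inserts
    introducing a stop codon are resampled.
    """
    v_segs = ref.by_class("V")
    j_segs = ref.by_class("J")
    families = sorted(vfamily_probs)
    fam = families[rng.choice(len(families), p=[vfamily_probs[f] for f in families])]
    fam_segs = [s for s in v_segs if s.family == fam]
    if not fam_segs:
        raise ValueError(f"no V segment for family {fam} in reference")
    v = fam_segs[rng.integers(len(fam_segs))]
    j = j_segs[rng.integers(len(j_segs))]

    v_part = v.nt_sequence[: v.anchor_offset + 3]
    j_part = j.nt_sequence[j.anchor_offset :]
    lo, hi = insert_len_range
    while True:
        ins_len = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        insert = "".join(rng.choice(list("ACGT"), size=ins_len))
        bad = any(insert[i : i + 3] in _CODON_STOPS for i in range(0, ins_len, 3))
        if not bad:
            break
    seq = v_part + insert + j_part
    junction_start = v.anchor_offset
    junction = seq[junction_start : junction_start + 3 + ins_len + 3]
    return seq, v.name, j.name, junction, junction_start


def apply_shm(
    nt_sequence: str,
    shm_rate: float,
    rng: np.random.Generator,
    junction_span: tuple | None = None,
) -> tuple[str, int]:
    """Mutate each site outside ``junction_span`` independently at ``shm_rate``.

    Substitutions go to a uniformly chosen different base; returns the mutated
    sequence and the realized substitution count.
    """
    if not 0.0 <= shm_rate <= 1.0:
        raise ValueError("shm_rate must be in [0, 1]")
    arr = np.frombuffer(nt_sequence.encode(), dtype=np.uint8).copy()
    eligible = np.ones(len(arr), dtype=bool)
    if junction_span is not None:
        eligible[junction_span[0] : junction_span[1]] = False
    hit = eligible & (rng.random(len(arr)) < shm_rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in np.flatnonzero(hit):
        options = bases[bases != arr[i]]
        arr[i] = options[rng.integers(3)]
    return arr.tobytes().decode(), int(hit.sum())


def _draw_clone_sizes(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name, params = law
    if name == "constant":
        return np.full(n, int(params["size"]))
    if name == "zeta":
        a, max_size = float(params["a"]), int(params.get("max_size", 10**9))
        out = np.empty(n, dtype=int)
        filled = 0
        while filled < n:
            draw = rng.zipf(a, size=n)
            draw = draw[draw <= max_size]
            take = min(len(draw), n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out
    raise ValueError(f"unknown clone_size_law {name!r}")


def _draw_reads_per_molecule(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name, params = law
    if name == "constant":
        return np.full(n, int(params["n"]))
    if name == "poisson":
        counts = rng.poisson(float(params["lam"]), size=n)
        if "min" in params:
            counts = np.maximum(counts, int(params["min"]))
        return counts
    raise ValueError(f"unknown reads_per_molecule_law {name!r}")


def _make_clone_members(
    founder_seq: str,
    junction_span: tuple,
    size: int,
    shm_rate: float,
    rng: np.random.Generator,
    mutate_junction: bool,
) -> list[tuple[str, int, int]]:
    """Independent SHM draws from one founder; member sequences kept distinct
    when the rate allows it (at rate 0 all members collapse onto the founder
    and turn into copies downstream).  Draws whose translation gains a stop
    codon are resampled: the simulated repertoire models the productive
    sequences that enter the analysis."""
    span = None if mutate_junction else junction_span
    members: list[tuple[str, int, int]] = []
    seen: set[str] = set()
    for _ in range(size):
        for _attempt in range(50):
            seq, n_mut = apply_shm(founder_seq, shm_rate, rng, span)
            if translate_nt(seq) is None:
                continue
            if seq not in seen or shm_rate == 0.0:
                break
        seen.add(seq)
        n_mut_v = sum(
            1 for i in range(junction_span[0]) if seq[i] != founder_seq[i]
        )
        members.append((seq, n_mut, n_mut_v))
    return members


@dataclass
class _CloneSpec:
    clone_id: str
    founder_seq: str
    v_name: str
    j_name: str
    junction_nt: str
    junction_start: int


def _new_clone_specs(
    ref, sub_cfg: SubsetConfig, cfg: SimulationConfig, n: int,
    prefix: str, rng: np.random.Generator, taken: set | None = None,
) -> list[_CloneSpec]:
    # distinct lineages carry distinct junctions within a subset snapshot, so
    # the true clone partition is recoverable by junction clustering
    taken = set() if taken is None else taken
    specs = []
    for i in range(n):
        for _attempt in range(100):
            seq, v_name, j_name, junction, jstart = recombine_vdj(
                ref, sub_cfg.vfamily_probs, rng, cfg.insert_len_range
            )
            if (v_name, j_name, junction) not in taken:
                break
        taken.add((v_name, j_name, junction))
        specs.append(_CloneSpec(f"{prefix}_c{i}", seq, v_name, j_name, junction, jstart))
    return specs


def _realize_subset(
    specs: list[_CloneSpec], sub_cfg: SubsetConfig, cfg: SimulationConfig,
    subset: str, timepoint: str, rng: np.random.Generator,
) -> list[Molecule]:
    sizes = _draw_clone_sizes(sub_cfg.clone_size_law, len(specs), rng)
    isos = sorted(sub_cfg.isotype_probs)
    iso_p = [sub_cfg.isotype_probs[i] for i in isos]
    molecules = []
    for spec, size in zip(specs, sizes):
        span = (spec.junction_start, spec.junction_start + len(spec.junction_nt))
        members = _make_clone_members(
            spec.founder_seq, span, int(size), sub_cfg.shm_rate, rng, cfg.mutate_junction
        )
        isotype = isos[rng.choice(len(isos), p=iso_p)]
        for k, (seq, n_mut, n_mut_v) in enumerate(members):
            junction = seq[span[0] : span[1]]
            molecules.append(
                Molecule(
                    molecule_id=f"{spec.clone_id}_{timepoint}_m{k}",
                    subject=cfg.subject,
                    timepoint=timepoint,
                    subset=subset,
                    true_clone_id=spec.clone_id,
                    nt_sequence=seq,
                    isotype=isotype,
                    v_name=spec.v_name,
                    j_name=spec.j_name,
                    true_junction_nt=junction,
                    junction_start=spec.junction_start,
                    n_mutations=n_mut,
                    n_mutations_v=n_mut_v,
                )
            )
    return molecules


def simulate_repertoire(
    config: SimulationConfig,
    ref: GermlineReference | None = None,
    timepoint: str = "BL",
    rng: np.random.Generator | None = None,
) -> SimulatedTruth:
    """Simulate one timepoint snapshot across all configured subsets."""
    config.validate()
    ref = ref or load_toy_reference()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    molecules = []
    for subset in SUBSETS:
        if subset not in config.subsets:
            continue
        sub_cfg = config.subsets[subset]
        specs = _new_clone_specs(
            ref, sub_cfg, config, sub_cfg.n_clones, f"{subset}_{timepoint}", rng
        )
        molecules.extend(_realize_subset(specs, sub_cfg, config, subset, timepoint, rng))
    return SimulatedTruth(config.subject, timepoint, molecules)


def simulate_longitudinal_pair(
    config: SimulationConfig, ref: GermlineReference | None = None
) -> tuple[SimulatedTruth, SimulatedTruth, dict]:
    """Simulate paired BL / FUP6 snapshots with tunable clone retention.

    Each BL clone lineage is retained at FUP6 independently with probability
    ``retention_fraction`` (same junction, V/J and founder; fresh clone-size
    and SHM draws), topped up with newly recombined clones to reach
    ``fup6_diversity_scale`` x n_clones.  Returns both truths plus the per-
    subset true retained-lineage counts.
    """
    config.validate()
    ref = ref or load_toy_reference()
    rng = np.random.default_rng(config.seed)
    bl_mols, fup_mols = [], []
    true_overlap = {}
    for subset in SUBSETS:
        if subset not in config.subsets:
            continue
        sub_cfg = config.subsets[subset]
        bl_specs = _new_clone_specs(
            ref, sub_cfg, config, sub_cfg.n_clones, f"{subset}_BL", rng
        )
        bl_mols.extend(_realize_subset(bl_specs, sub_cfg, config, subset, "BL", rng))

        retained = [s for s in bl_specs if rng.random() < config.retention_fraction]
        n_total = int(round(config.fup6_diversity_scale * sub_cfg.n_clones))
        n_new = max(n_total - len(retained), 0)
        new_specs = _new_clone_specs(
            ref, sub_cfg, config, n_new, f"{subset}_F6", rng,
            taken={(s.v_name, s.j_name, s.junction_nt) for s in retained},
        )
        fup_mols.extend(
            _realize_subset(retained + new_specs, sub_cfg, config, subset, "FUP6", rng)
        )
        true_overlap[subset] = {
            "n_bl_clones": len(bl_specs),
            "n_retained": len(retained),
            "retained_clone_ids": sorted(s.clone_id for s in retained),
        }
    return (
        SimulatedTruth(config.subject, "BL", bl_mols),
        SimulatedTruth(config.subject, "FUP6", fup_mols),
        true_overlap,
    )


def generate_reads(
    molecule: Molecule,
    reads_per_molecule: int,
    per_base_read_error: float,
    umi: str,
    index_tag: str,
    rng: np.random.Generator,
    q_high: int = 30,
    q_low: int = 15,
    low_q_fraction: float = 0.0,
) -> list[SequencingRead]:
    """Emit UMI-tagged reads of one molecule with i.i.d. substitution errors.

    Each read is index_tag + UMI + payload; a ``low_q_fraction`` of reads gets
    a flat low Phred so the quality filter is exercisable.
    """
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    template = np.frombuffer(molecule.nt_sequence.encode(), dtype=np.uint8)
    reads = []
    for r in range(int(reads_per_molecule)):
        payload = template.copy()
        errs = np.flatnonzero(rng.random(len(payload)) < per_base_read_error)
        for i in errs:
            options = bases[bases != payload[i]]
            payload[i] = options[rng.integers(3)]
        q = q_low if rng.random() < low_q_fraction else q_high
        reads.append(
            SequencingRead(
                read_id=f"{molecule.molecule_id}_r{r}",
                index_tag=index_tag,
                umi=umi,
                payload=payload.tobytes().decode(),
                qualities=[q] * len(payload),
            )
        )
    return reads


def _draw_unique_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        umi = "".join(rng.choice(list("ACGT"), size=length))
        if umi not in seen:
            seen.add(umi)
            out.append(umi)
    return out


def simulate_reads(
    truth: SimulatedTruth, config: SimulationConfig, rng: np.random.Generator
) -> list[SequencingRead]:
    """UMI-tagged read set for a whole snapshot (one distinct UMI per molecule)."""
    mols = truth.molecules
    umis = _draw_unique_umis(len(mols), config.umi_length, rng)
    counts = _draw_reads_per_molecule(config.reads_per_molecule_law, len(mols), rng)
    reads = []
    for mol, umi, n in zip(mols, umis, counts):
        reads.extend(
            generate_reads(
                mol, n, config.per_base_read_error, umi, SUBSET_TAGS[mol.subset],
                rng, config.q_high, config.q_low, config.low_q_fraction,
            )
        )
    return reads


def simulate_peptides(
    truth: SimulatedTruth,
    sampling_fraction: float,
    decoy_fraction: float,
    rng: np.random.Generator,
    mode: str = "DIA",
    peptide_emit_prob: float = 0.7,
) -> pd.DataFrame:
    """Tryptic peptide observations from translated VH molecules.

    A ``sampling_fraction`` of distinct molecule sequences is digested; each
    peptide is emitted with probability ``peptide_emit_prob`` and a q-value
    below the mode's FDR cutoff.  Decoys are shuffled true peptides with
    q-values spanning [0, 1] so FDR filtering is exercisable.
    """
    if not 0.0 <= sampling_fraction <= 1.0 or not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("fractions must be in [0, 1]")
    cutoff = 0.01 if mode == "DIA" else 0.1
    seqs = sorted({m.nt_sequence for m in truth.molecules})
    rows = []
    for seq in seqs:
        if rng.random() >= sampling_fraction:
            continue
        aa = translate_nt(seq)
        if aa is None:
            continue
        for pep in digest_tryptic(aa):
            if rng.random() < peptide_emit_prob:
                rows.append((pep.sequence, float(rng.uniform(0, cutoff)), mode))
    n_decoys = int(round(decoy_fraction * len(rows)))
    true_peps = [r[0] for r in rows]
    for _ in range(n_decoys):
        pep = list(true_peps[rng.integers(len(true_peps))])
        rng.shuffle(pep)
        rows.append(("".join(pep), float(rng.uniform(0, 1)), mode))
    return pd.DataFrame(rows, columns=["peptide", "q_value", "mode"])


def write_fastq(reads: list[SequencingRead], path) -> None:
    """Write inline-tagged reads as (gzipped if *.gz) 4-line FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            seq = r.index_tag + r.umi + r.payload
            qual = chr(33 + 30) * (len(r.index_tag) + len(r.umi)) + "".join(
                chr(33 + q) for q in r.qualities
            )
            fh.write(f"@{r.read_id}\n{seq}\n+\n{qual}\n")


def write_manifest(config: SimulationConfig, timepoint: str, path) -> None:
    """Sidecar manifest: read layout plus index-tag -> subset decoding."""
    with open(path, "w") as fh:
        fh.write(
            "# read layout: 6 nt index_tag | "
            f"{config.umi_length} nt UMI | VH payload\n"
        )
        fh.write("subject\ttimepoint\tumi_length\tindex_tag\tcell_subset\n")
        for subset, tag in SUBSET_TAGS.items():
            fh.write(
                f"{config.subject}\t{timepoint}\t{config.umi_length}\t{tag}\t{subset}\n"
            )


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
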