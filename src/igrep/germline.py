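"""Germline V/J segment reference.

A reference is a small set of heavy-chain V and J segments with the position of
the conserved junction anchor codon (Cys for V, Trp/Phe for J) annotated per
segment.  The packaged toy reference spans families IGHV1-IGHV5 (two segments
each) plus four J segments and is sufficient for simulation and for the
self-contained best-identity aligner in :mod:`igrep.annotate`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

_DNA = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class GermlineSegment:
    """One germline segment with its conserved junction anchor.

    ``anchor_offset`` is the 0-based nucleotide index of the codon encoding the
    conserved anchor residue (Cys for V segments, Trp/Phe for J segments) and
    must fall on a codon boundary of the segment's reading frame.
    """

    name: str
    segment_class: str  # "V", "D" or "J"
    family: str
    nt_sequence: str
    anchor_offset: int

    def __post_init__(self) -> None:
        if not _DNA.match(self.nt_sequence):
            raise ValueError(f"{self.name}: sequence must be nonempty A/C/G/T")
        if self.segment_class not in ("V", "D", "J"):
            raise ValueError(f"{self.name}: bad segment_class {self.segment_class}")
        if not 0 <= self.anchor_offset < len(self.nt_sequence):
            raise ValueError(f"{self.name}: anchor_offset out of bounds")
        if self.anchor_offset % 3 != 0:
            raise ValueError(f"{self.name}: anchor_offset not a codon boundary")

    @property
    def gene(self) -> str:
        """Gene-level name with the allele suffix (``*NN``) stripped."""
        return self.name.split("*")[0]


class GermlineReference:
    """Collection of germline segments, indexed by class and name."""

    def __init__(self, segments: list[GermlineSegment]):
        self.segments = list(segments)
        self._by_name = {s.name: s for s in self.segments}
        if len(self._by_name) != len(self.segments):
            raise ValueError("duplicate segment names in reference")
        if not self.by_class("V") or not self.by_class("J"):
            raise ValueError("reference needs at least one V and one J segment")

    def by_class(self, segment_class: str) -> list[GermlineSegment]:
        return [s for s in self.segments if s.segment_class == segment_class]

    def __getitem__(self, name: str) -> GermlineSegment:
        return self._by_name[name]

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def v_families(self) -> list[str]:
        return sorted({s.family for s in self.by_class("V")})

    @classmethod
    def from_fasta(cls, path) -> "GermlineReference":
        """Read segments from FASTA with key=value annotations in the header."""
        segments = []
        for rec in SeqIO.parse(str(path), "fasta"):
            attrs = dict(kv.split("=") for kv in rec.description.split()[1:])
            segments.append(
                GermlineSegment(
                    name=rec.id,
                    segment_class=attrs["segment_class"],
                    family=attrs["family"],
                    nt_sequence=str(rec.seq).upper(),
                    anchor_offset=int(attrs["anchor_offset"]),
                )
            )
        return cls(segments)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.segments:
                fh.write(
                    f">{s.name} segment_class={s.segment_class} "
                    f"family={s.family} anchor_offset={s.anchor_offset}\n"
                )
                for i in range(0, len(s.nt_sequence), 60):
                    fh.write(s.nt_sequence[i : i + 60] + "\n")


def load_toy_reference() -> GermlineReference:
    """Load the packaged toy germline set (IGHV1-IGHV5 families, 4 J segments)."""
    with resources.as_file(
        resources.files("igrep") / "data" / "toy_germline.fasta"
    ) as path:
        return GermlineReference.from_fasta(path)
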