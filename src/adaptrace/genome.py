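"""Reference genome container: named replicons plus annotated features.

A :class:`ReferenceGenome` holds one or more replicons (a main chromosome
and, typically, smaller plasmids) together with feature intervals used by
the acquisition analyses: hotspot-prone elements (transposases, rRNA genes,
proviruses), the self-targeting site, and the HEN (homing endonuclease)
cut site. Coordinates are 0-based half-open; circular replicons are
supported, with intervals allowed to wrap (stored unwrapped: ``end`` may
exceed the replicon length and is interpreted modulo length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import DNA_ALPHABET, revcomp

FEATURE_KINDS = {
    "transposase",
    "rRNA",
    "provirus",
    "target_site",
    "hen_site",
    "plasmid_marker",
}

HOTSPOT_KINDS = ("transposase", "rRNA", "provirus")


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a replicon (0-based half-open)."""

    replicon: str
    start: int
    end: int
    strand: str
    kind: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def name(self) -> str:
        return f"{self.kind}:{self.label}"


@dataclass
class Replicon:
    name: str
    sequence: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceGenome:
    replicons: list[Replicon]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_name = {}
        for rep in self.replicons:
            if rep.name in by_name:
                raise ValueError(f"duplicate replicon name {rep.name!r}")
            if not set(rep.sequence) <= DNA_ALPHABET:
                raise ValueError(f"replicon {rep.name!r}: non-ACGT symbols")
            by_name[rep.name] = rep
        for f in self.features:
            rep = by_name.get(f.replicon)
            if rep is None:
                raise ValueError(f"feature on unknown replicon {f.replicon!r}")
            if f.end > len(rep) and not rep.circular:
                raise ValueError(f"feature {f.name} exceeds linear replicon")

    # -- lookups ---------------------------------------------------------

    def replicon(self, name: str) -> Replicon:
        for rep in self.replicons:
            if rep.name == name:
                return rep
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.replicons)

    def features_of(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def target_cut_site(self) -> tuple[str, int, str]:
        """(replicon, coordinate, coding strand) of the self-target cut site.

        The cut site is modeled as the 5' boundary of the target_site
        feature on its declared coding strand.
        """
        sites = self.features_of("target_site")
        if len(sites) != 1:
            raise ValueError(
                f"expected exactly one target_site feature, found {len(sites)}"
            )
        f = sites[0]
        pos = f.start if f.strand == "+" else f.end
        return f.replicon, pos, f.strand

    # -- sequence access -------------------------------------------------

    def fetch(self, replicon: str, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end) on the given strand, wrapping if circular."""
        rep = self.replicon(replicon)
        n = len(rep)
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        if rep.circular:
            start %= n
            end = start + (end - start) if end - start <= n else None
            if end is None:
                raise ValueError("interval longer than circular replicon")
            seq = (rep.sequence * 2)[start:end] if end > n else rep.sequence[start:end]
        else:
            if start < 0 or end > n:
                raise ValueError(
                    f"interval [{start}, {end}) outside linear replicon {replicon}"
                )
            seq = rep.sequence[start:end]
        return seq if strand == "+" else revcomp(seq)

    def upstream_kmer(
        self, replicon: str, start: int, end: int, strand: str, k: int = 3
    ) -> str:
        """The k bases immediately 5' of [start, end) on the given strand.

        This is the PAM position for a protospacer at that placement. On a
        linear replicon too close to the edge, the missing bases are padded
        with ``N``.
        """
        rep = self.replicon(replicon)
        n = len(rep)
        if strand == "+":
            s, e = start - k, start
            if rep.circular:
                return self.fetch(replicon, s % n, s % n + k, "+")
            if s < 0:
                return "N" * (-s) + rep.sequence[0:e]
            return rep.sequence[s:e]
        s, e = end, end + k
        if rep.circular:
            return revcomp(self.fetch(replicon, s % n, s % n + k, "+"))
        if e > n:
            return revcomp(rep.sequence[s:n] + "N" * (e - n))
        return revcomp(rep.sequence[s:e])

    # -- I/O -------------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(
                Seq(rep.sequence),
                id=rep.name,
                description=f"circular={rep.circular}",
            )
            for rep in self.replicons
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def write_bed(self, path: str | Path) -> None:
        """Features as BED6 (name = kind:label, score = 0)."""
        with open(path, "w") as fh:
            for f in sorted(self.features, key=lambda f: (f.replicon, f.start)):
                fh.write(
                    f"{f.replicon}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n"
                )

    @classmethod
    def from_fasta(
        cls, fasta: str | Path, bed: str | Path | None = None
    ) -> "ReferenceGenome":
        replicons = []
        for rec in SeqIO.parse(str(fasta), "fasta"):
            circular = "circular=True" in rec.description
            replicons.append(Replicon(rec.id, str(rec.seq).upper(), circular))
        features: list[Feature] = []
        if bed is not None:
            with open(bed) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    chrom, start, end, name, _score, strand = line.split("\t")[:6]
                    kind, _, label = name.partition(":")
                    features.append(
                        Feature(chrom, int(start), int(end), strand.strip(), kind, label)
                    )
        return cls(replicons, features)
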