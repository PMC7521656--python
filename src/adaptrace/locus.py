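"""CRISPR locus and amplicon-design descriptions.

A :class:`CrisprLocus` is the array a read is parsed against: leader,
direct repeat, and the ordered endogenous spacers (leader-proximal first).
New repeat-spacer units are integrated at the leader end, so an amplicon
anchored in the leader 3' end and in endogenous spacer 1 spans every newly
acquired unit.

The crRNA handle lengths (8 nt 5' handle, 22 nt 3' handle in this type I-B
system) are carried as informational constants; parsing itself only uses
leader/repeat/spacer sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._seq import DNA_ALPHABET

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTC"


@dataclass
class CrisprLocus:
    locus_id: str
    leader: str
    repeat: str
    spacers: list[str]
    five_prime_handle_len: int = 8
    three_prime_handle_len: int = 22

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValueError("endogenous locus must carry at least one spacer")
        for s in [self.leader, self.repeat, *self.spacers]:
            if not set(s) <= DNA_ALPHABET:
                raise ValueError("locus sequences must be ACGT only")
        if len(self.repeat) < self.five_prime_handle_len:
            raise ValueError("repeat shorter than 5' handle")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "locus_id": self.locus_id,
            "leader": self.leader,
            "repeat": self.repeat,
            "spacers": list(self.spacers),
            "five_prime_handle_len": self.five_prime_handle_len,
            "three_prime_handle_len": self.three_prime_handle_len,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CrisprLocus":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class AmpliconDesign:
    """Primer scheme of the adaptation assay.

    The forward primer binds the leader 3' end (after the sequencing
    adapter and 0-3 random diversity bases); the reverse primer binds
    inside an endogenous spacer, so the sequenced fragment covers the
    leader-proximal end of the array where new units appear.
    """

    locus_id: str
    adapter: str
    forward_anchor: str  # leader 3' segment
    reverse_anchor: str  # 5' segment of endogenous spacer 1
    anchor_max_mismatches: int = 2
    repeat_max_mismatches: int = 3

    def __post_init__(self) -> None:
        if not self.forward_anchor or not self.reverse_anchor:
            raise ValueError("anchors must be nonempty")
        if self.anchor_max_mismatches < 0 or self.repeat_max_mismatches < 0:
            raise ValueError("mismatch allowances must be >= 0")

    @classmethod
    def from_locus(
        cls,
        locus: CrisprLocus,
        adapter: str = DEFAULT_ADAPTER,
        anchor_len: int = 20,
        anchor_max_mismatches: int = 2,
        repeat_max_mismatches: int = 3,
    ) -> "AmpliconDesign":
        if len(locus.leader) < anchor_len or len(locus.spacers[0]) < anchor_len:
            raise ValueError("locus too short for requested anchor length")
        return cls(
            locus_id=locus.locus_id,
            adapter=adapter,
            forward_anchor=locus.leader[-anchor_len:],
            reverse_anchor=locus.spacers[0][:anchor_len],
            anchor_max_mismatches=anchor_max_mismatches,
            repeat_max_mismatches=repeat_max_mismatches,
        )
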