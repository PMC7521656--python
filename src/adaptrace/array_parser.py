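"""Detection of newly inserted repeat-spacer units in amplicon reads.

The assay amplifies the leader-proximal end of a CRISPR array; an
unexpanded array yields ``leader-anchor + repeat + spacer1…`` while an
array that acquired new units yields one or two extra ``repeat + novel
spacer`` blocks before endogenous spacer 1. Parsing is purely
Hamming-based (no gaps): substitution-dominated short-read errors are the
model, and every matching decision has an exact brute-force oracle.

Rejected reads are data, not errors: each carries a reason code and the
reject tally is part of the run report's conservation identity
(total = expanded + unexpanded + rejected).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import hamming, revcomp
from .locus import AmpliconDesign, CrisprLocus

# reject reason codes
NO_ADAPTER = "no_adapter"
NO_ANCHOR = "no_anchor"
NO_REPEAT_AT_START = "no_repeat_at_start"
NO_REPEAT = "no_repeat"
SHORT_SEGMENT = "short_segment"
TOO_SHORT = "too_short"

MIN_TERMINAL_OVERLAP = 12  # nt of reverse anchor needed to call the array end


@dataclass
class ParsedRead:
    read_id: str
    status: str  # expanded | unexpanded | reject
    spacers: list[str] = field(default_factory=list)
    reason: str | None = None
    orientation: str | None = None  # forward | reverse

    @property
    def expanded(self) -> bool:
        return self.status == "expanded"


@dataclass
class SpacerCall:
    """A novel spacer aggregated over its supporting reads."""

    locus_id: str
    spacer_id: str
    seq: str
    insertion_index: int  # 1 = leader-proximal (modal over reads)
    support: int
    read_ids: list[str] = field(default_factory=list)


def orient_and_trim(
    read: str,
    design: AmpliconDesign,
    random_prefix_range: tuple[int, int] = (0, 3),
) -> tuple[str | None, str | None, str | None]:
    """Locate adapter + random bases + leader anchor; strip them.

    Tries the read and its reverse complement, so output is always
    oriented leader → array. Returns ``(remainder, orientation, reason)``
    where a ``None`` remainder means the read was rejected for ``reason``.
    """
    la = len(design.adapter)
    lanch = len(design.forward_anchor)
    mm = design.anchor_max_mismatches
    klo, khi = random_prefix_range
    adapter_seen = False
    for orientation, seq in (("forward", read), ("reverse", revcomp(read))):
        if la:
            if len(seq) < la:
                continue
            if hamming(seq[:la], design.adapter, mm) > mm:
                continue
        adapter_seen = True
        for k in range(klo, khi + 1):
            pos = la + k
            if pos + lanch > len(seq):
                break
            if hamming(seq[pos : pos + lanch], design.forward_anchor, mm) <= mm:
                return seq[pos + lanch :], orientation, None
    return None, None, (NO_ANCHOR if adapter_seen or not la else NO_ADAPTER)


def detect_expansion(
    trimmed: str,
    locus: CrisprLocus,
    design: AmpliconDesign,
    min_spacer_len: int = 20,
    max_spacer_len: int = 60,
) -> tuple[str, list[str], str | None]:
    """Walk repeat/spacer blocks from the leader end of a trimmed read.

    Greedy scan: a repeat must open the array; each inter-repeat segment
    is a spacer; the walk ends when the remainder matches the 5' of
    endogenous spacer 1 (the reverse primer anchor). Segments seen before
    that terminator are the novel spacers, leader-proximal first.

    Returns ``(status, spacers, reason)`` with status one of
    ``expanded`` / ``unexpanded`` / ``reject``.
    """
    rep = locus.repeat
    rlen = len(rep)
    mm_rep = design.repeat_max_mismatches
    mm_anchor = design.anchor_max_mismatches
    anchor = design.reverse_anchor

    if len(trimmed) < rlen:
        return "reject", [], TOO_SHORT
    if hamming(trimmed[:rlen], rep, mm_rep) > mm_rep:
        return "reject", [], NO_REPEAT_AT_START

    pos = rlen
    spacers: list[str] = []
    while True:
        rest = trimmed[pos:]
        cmp_len = min(len(rest), len(anchor))
        if cmp_len >= MIN_TERMINAL_OVERLAP and (
            hamming(rest[:cmp_len], anchor[:cmp_len], mm_anchor) <= mm_anchor
        ):
            return ("expanded" if spacers else "unexpanded"), spacers, None
        hi = min(max_spacer_len, len(rest) - rlen)
        found = None
        for o in range(min_spacer_len, hi + 1):
            if hamming(rest[o : o + rlen], rep, mm_rep) <= mm_rep:
                found = o
                break
        if found is None:
            reason = SHORT_SEGMENT if len(rest) < min_spacer_len + rlen else NO_REPEAT
            return "reject", spacers, reason
        spacers.append(rest[:found])
        pos += found + rlen


def parse_read(
    read_id: str,
    seq: str,
    locus: CrisprLocus,
    design: AmpliconDesign,
    random_prefix_range: tuple[int, int] = (0, 3),
    min_spacer_len: int = 20,
    max_spacer_len: int = 60,
) -> ParsedRead:
    trimmed, orientation, reason = orient_and_trim(seq, design, random_prefix_range)
    if trimmed is None:
        return ParsedRead(read_id, "reject", reason=reason)
    status, spacers, reason = detect_expansion(
        trimmed, locus, design, min_spacer_len, max_spacer_len
    )
    return ParsedRead(read_id, status, spacers, reason, orientation)


def parse_reads(
    reads: Iterable[tuple[str, str]],
    locus: CrisprLocus,
    design: AmpliconDesign,
    **kwargs,
) -> list[ParsedRead]:
    return [parse_read(rid, seq, locus, design, **kwargs) for rid, seq in reads]


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from a FASTQ file (gzip allowed)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper()


def reject_summary(parses: Iterable[ParsedRead]) -> Counter:
    return Counter(p.reason for p in parses if p.status == "reject")


def aggregate_calls(
    parses: Iterable[ParsedRead],
    locus_id: str,
    min_reads: int = 1,
    max_representatives: int = 5,
) -> list[SpacerCall]:
    """Group identical novel spacers into supported calls.

    Exact-sequence deduplication; support is the number of observations
    across expansion-bearing reads; the insertion index is the modal
    leader-proximal position (ties to the smaller index). Output is
    sorted by support descending, then lexicographically by sequence.
    """
    support: Counter[str] = Counter()
    indices: dict[str, Counter[int]] = {}
    rep_reads: dict[str, list[str]] = {}
    for p in parses:
        if not p.expanded:
            continue
        for idx, seq in enumerate(p.spacers, start=1):
            support[seq] += 1
            indices.setdefault(seq, Counter())[idx] += 1
            reps = rep_reads.setdefault(seq, [])
            if len(reps) < max_representatives:
                reps.append(p.read_id)
    ordered = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    calls: list[SpacerCall] = []
    num = 0
    for seq, n in ordered:
        if n < min_reads:
            continue
        num += 1
        idx_counts = indices[seq]
        modal_idx = min(
            idx_counts, key=lambda i: (-idx_counts[i], i)
        )  # modal, ties to leader-proximal
        calls.append(
            SpacerCall(
                locus_id=locus_id,
                spacer_id=f"nsp{num:05d}",
                seq=seq,
                insertion_index=modal_idx,
                support=n,
                read_ids=rep_reads[seq],
            )
        )
    return calls


def calls_to_frame(calls: Iterable[SpacerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": c.locus_id,
                "spacer_id": c.spacer_id,
                "seq": c.seq,
                "reads": c.support,
                "index": c.insertion_index,
            }
            for c in calls
        ],
        columns=["locus", "spacer_id", "seq", "reads", "index"],
    )


def write_calls(calls: Iterable[SpacerCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
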