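"""Genome-wide placement of novel spacers and feature-distance annotation.

The mapper is an internal seed-and-verify Hamming search (pigeonhole: a
pattern with at most ``max_mm`` mismatches over ``max_mm + 1`` segments
must match one segment exactly), run on both strands of every replicon
with circular replicons virtually extended so protospacers may span the
origin. It is deliberately gap-free and exhaustive — every position within
the mismatch budget is reported — so a naive all-positions scan is an
exact oracle for it.

The 3-nt PAM is attached at mapping time: the bases immediately 5' of the
protospacer on the protospacer strand (genomic reverse complement for
minus-strand hits).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._seq import DNA_ALPHABET, hamming, revcomp
from .array_parser import SpacerCall
from .genome import ReferenceGenome
from .simulate import TruthTable

DEFAULT_SEED_LEN = 12


@dataclass
class ProtospacerHit:
    spacer_id: str
    replicon: str
    start: int  # 0-based; for circular wrap, end = start + len may exceed L
    end: int
    strand: str
    mismatches: int
    unique: bool
    pam: str
    support: int = 1  # read support of the underlying spacer call
    distance_to_target: int | None = None
    distance_to_hen: int | None = None


def _segments(q: str, n_seg: int) -> list[tuple[int, str]]:
    """Split q into n_seg near-equal pigeonhole segments as (offset, seq)."""
    L = len(q)
    bounds = [round(i * L / n_seg) for i in range(n_seg + 1)]
    return [(bounds[i], q[bounds[i] : bounds[i + 1]]) for i in range(n_seg)]


def map_spacer(
    spacer: str,
    ref: ReferenceGenome,
    max_mm: int = 2,
    spacer_id: str = "spacer",
    support: int = 1,
) -> list[ProtospacerHit]:
    """All placements of a spacer within ``max_mm`` substitutions.

    Returns hits on both strands of all replicons, sorted by
    (mismatches, replicon, start, strand); ``unique`` is set on every hit
    and is true iff exactly one hit exists at the minimal mismatch count.
    """
    if not set(spacer) <= DNA_ALPHABET:
        raise ValueError(f"spacer {spacer_id}: non-ACGT symbols")
    if len(spacer) < DEFAULT_SEED_LEN:
        raise ValueError(
            f"spacer {spacer_id}: length {len(spacer)} below seed length "
            f"{DEFAULT_SEED_LEN}"
        )
    lq = len(spacer)
    hits: list[ProtospacerHit] = []
    for rep in ref.replicons:
        L = len(rep)
        if lq > L:
            continue
        text = rep.sequence + rep.sequence[: lq - 1] if rep.circular else rep.sequence
        for strand, q in (("+", spacer), ("-", revcomp(spacer))):
            starts: set[int] = set()
            for off, seg in _segments(q, max_mm + 1):
                i = text.find(seg)
                while i != -1:
                    s = i - off
                    if 0 <= s <= len(text) - lq and (not rep.circular or s < L):
                        starts.add(s)
                    i = text.find(seg, i + 1)
            for s in starts:
                d = hamming(text[s : s + lq], q, max_mm)
                if d <= max_mm:
                    hits.append(
                        ProtospacerHit(
                            spacer_id=spacer_id,
                            replicon=rep.name,
                            start=s,
                            end=s + lq,
                            strand=strand,
                            mismatches=d,
                            unique=False,
                            pam=ref.upstream_kmer(rep.name, s, s + lq, strand),
                            support=support,
                        )
                    )
    if hits:
        best = min(h.mismatches for h in hits)
        n_best = sum(h.mismatches == best for h in hits)
        for h in hits:
            h.unique = n_best == 1 and h.mismatches == best
    hits.sort(key=lambda h: (h.mismatches, h.replicon, h.start, h.strand))
    return hits


def map_calls(
    calls: Iterable[SpacerCall],
    ref: ReferenceGenome,
    max_mm: int = 2,
    best_only: bool = True,
) -> list[ProtospacerHit]:
    """Map aggregated spacer calls; by default keep only best-tier hits."""
    out: list[ProtospacerHit] = []
    for c in calls:
        hits = map_spacer(c.seq, ref, max_mm, spacer_id=c.spacer_id, support=c.support)
        if best_only and hits:
            best = hits[0].mismatches
            hits = [h for h in hits if h.mismatches == best]
        out.extend(hits)
    return out


def truth_to_hits(truth: TruthTable, ref: ReferenceGenome) -> list[ProtospacerHit]:
    """Perfect hits straight from the simulator's truth table.

    Used when scoring stages downstream of mapping in isolation.
    """
    return [
        ProtospacerHit(
            spacer_id=r.spacer_id,
            replicon=r.replicon,
            start=r.start,
            end=r.end,
            strand=r.strand,
            mismatches=0,
            unique=True,
            pam=r.pam,
            support=max(r.reads, 1),
        )
        for r in truth
    ]


# ---------------------------------------------------------------------------
# distances


def _interval_gap(a: int, b: int, c: int, d: int, L: int | None) -> int:
    """Minimal unsigned gap between [a,b) and [c,d); 0 if they overlap.

    ``L`` is the replicon length for circular replicons (both arcs are
    considered), None for linear ones.
    """
    gap = max(a, c) - min(b, d)
    if gap <= 0:
        return 0
    if L is None:
        return gap
    other = L - (b - a) - (d - c) - gap
    return min(gap, max(other, 0))


def annotate_distances(
    hits: Sequence[ProtospacerHit], ref: ReferenceGenome
) -> list[ProtospacerHit]:
    """Attach signed target-cut distances and unsigned HEN-site gaps.

    ``distance_to_target`` is the signed offset from the target cut-site
    coordinate to the hit's nearest edge, negative upstream on the target
    gene's coding strand, 0 when the hit spans the cut.
    ``distance_to_hen`` is the minimal gap between the hit interval and
    the HEN recognition site (0 if overlapping). Hits on replicons
    without the respective feature keep ``None``.
    """
    target = ref.features_of("target_site")
    hens = ref.features_of("hen_site")
    if target:
        t_rep, t_cut, t_coding = ref.target_cut_site()
    for h in hits:
        rep = ref.replicon(h.replicon)
        L = len(rep) if rep.circular else None
        if target and h.replicon == t_rep:
            if h.start <= t_cut <= h.end:
                d = 0
            elif h.end < t_cut:
                d = h.end - t_cut
            else:
                d = h.start - t_cut
            h.distance_to_target = -d if t_coding == "-" else d
        for f in hens:
            if f.replicon != h.replicon:
                continue
            h.distance_to_hen = _interval_gap(h.start, h.end, f.start, f.end, L)
    return list(hits)


def hen_distance_buckets(
    hits: Sequence[ProtospacerHit], upper: int = 214
) -> dict[str, int]:
    """Count hits overlapping the HEN site, proximal (0 < d <= upper), distal."""
    annotated = [h for h in hits if h.distance_to_hen is not None]
    overlap = sum(h.distance_to_hen == 0 for h in annotated)
    proximal = sum(0 < h.distance_to_hen <= upper for h in annotated)
    return {
        "overlap": overlap,
        "proximal": proximal,
        "within_upper": overlap + proximal,
        "distal": len(annotated) - overlap - proximal,
    }


# ---------------------------------------------------------------------------
# source accounting


def classify_source(
    hits: Sequence[ProtospacerHit],
    ref: ReferenceGenome,
    unique_only: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-replicon and per-feature-kind spacer accounting.

    Both unweighted (unique spacer calls) and read-weighted tallies are
    produced; per-replicon fractions sum to 1 over observed replicons.
    """
    pool = [h for h in hits if h.unique] if unique_only else list(hits)
    rows = []
    for h in pool:
        kinds = [
            f.kind
            for f in ref.features
            if f.replicon == h.replicon and max(h.start, f.start) < min(h.end, f.end)
        ]
        rows.append(
            {
                "replicon": h.replicon,
                "support": h.support,
                "feature_kind": kinds[0] if kinds else "none",
            }
        )
    df = pd.DataFrame(rows, columns=["replicon", "support", "feature_kind"])
    if df.empty:
        empty = pd.DataFrame(
            columns=["spacers", "reads", "frac_spacers", "frac_reads"]
        )
        return {"per_replicon": empty, "per_feature": empty.copy()}
    per_rep = df.groupby("replicon").agg(
        spacers=("replicon", "size"), reads=("support", "sum")
    )
    per_rep["frac_spacers"] = per_rep["spacers"] / per_rep["spacers"].sum()
    per_rep["frac_reads"] = per_rep["reads"] / per_rep["reads"].sum()
    per_feat = df.groupby("feature_kind").agg(
        spacers=("feature_kind", "size"), reads=("support", "sum")
    )
    per_feat["frac_spacers"] = per_feat["spacers"] / per_feat["spacers"].sum()
    per_feat["frac_reads"] = per_feat["reads"] / per_feat["reads"].sum()
    return {"per_replicon": per_rep, "per_feature": per_feat}


# ---------------------------------------------------------------------------
# I/O


def hits_to_frame(hits: Sequence[ProtospacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spacer_id": h.spacer_id,
                "replicon": h.replicon,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "mismatches": h.mismatches,
                "unique": h.unique,
                "pam": h.pam,
                "reads": h.support,
                "distance_to_target": h.distance_to_target,
                "distance_to_hen": h.distance_to_hen,
            }
            for h in hits
        ],
        columns=[
            "spacer_id",
            "replicon",
            "start",
            "end",
            "strand",
            "mismatches",
            "unique",
            "pam",
            "reads",
            "distance_to_target",
            "distance_to_hen",
        ],
    )


def write_hits(hits: Sequence[ProtospacerHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_hits_bed(hits: Sequence[ProtospacerHit], path: str | Path) -> None:
    """Hits as BED6: score = read support, name = spacer id."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.replicon, h.start)):
            fh.write(
                f"{h.replicon}\t{h.start}\t{h.end}\t{h.spacer_id}\t"
                f"{h.support}\t{h.strand}\n"
            )
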