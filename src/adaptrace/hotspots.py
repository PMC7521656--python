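"""Acquisition hotspots and the strand-resolved target-distance profile.

Hotspot calling is a declared statistic of this package, not a
reconstruction of any published threshold: replicons are tiled with
non-overlapping windows (default 1 kb), the null is a uniform Poisson
background over the whole genome, upper-tail p-values are corrected by
Benjamini-Hochberg across all windows, and runs of adjacent significant
windows are merged into single calls. Unique-spacer counts are the
primary statistic; read-weighted counts are carried alongside.

The target profile bins uniquely mapped hits by signed distance to the
self-target cut site (negative = upstream on the target's coding strand)
and source strand, and fits a per-side geometric decay scale by maximum
likelihood — the signature of processive degradation emanating from the
cut feeding spacer acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import ReferenceGenome
from .mapping import ProtospacerHit


@dataclass
class HotspotCall:
    replicon: str
    start: int
    end: int
    observed: int  # unique spacers
    observed_reads: int
    expected: float
    p_value: float
    q_value: float
    plus: int
    minus: int
    features: list[str] = field(default_factory=list)


def tile_windows(
    hits: Sequence[ProtospacerHit],
    ref: ReferenceGenome,
    window: int = 1000,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Per-window counts with uniform-background expectations and p/q.

    Hits are assigned to the window containing their start coordinate, so
    window counts on a replicon sum exactly to its hit count. The last
    window of a replicon may be shorter; its expectation is scaled.
    """
    pool = [h for h in hits if h.unique] if unique_only else list(hits)
    for rep in ref.replicons:
        if window > len(rep):
            raise ValueError(
                f"window {window} larger than replicon {rep.name} ({len(rep)} nt)"
            )
    total = len(pool)
    total_len = ref.total_length
    rows = []
    for rep in ref.replicons:
        n_win = -(-len(rep) // window)
        counts = np.zeros(n_win, dtype=int)
        reads = np.zeros(n_win, dtype=int)
        plus = np.zeros(n_win, dtype=int)
        for h in pool:
            if h.replicon != rep.name:
                continue
            w = (h.start % len(rep)) // window
            counts[w] += 1
            reads[w] += h.support
            if h.strand == "+":
                plus[w] += 1
        for w in range(n_win):
            start = w * window
            end = min(start + window, len(rep))
            rows.append(
                {
                    "replicon": rep.name,
                    "start": start,
                    "end": end,
                    "observed": int(counts[w]),
                    "observed_reads": int(reads[w]),
                    "plus": int(plus[w]),
                    "minus": int(counts[w] - plus[w]),
                    "expected": total * (end - start) / total_len,
                }
            )
    df = pd.DataFrame(rows)
    df["p_value"] = stats.poisson.sf(df["observed"] - 1, df["expected"])
    if len(df):
        _, q, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
        df["q_value"] = q
    else:
        df["q_value"] = []
    return df


def call_hotspots(
    hits: Sequence[ProtospacerHit],
    ref: ReferenceGenome,
    window: int = 1000,
    alpha: float = 0.05,
    unique_only: bool = True,
) -> list[HotspotCall]:
    """Merged maximal runs of significant windows, feature-annotated."""
    df = tile_windows(hits, ref, window, unique_only)
    sig = df[df["q_value"] <= alpha].sort_values(["replicon", "start"])
    calls: list[HotspotCall] = []
    current: HotspotCall | None = None
    for row in sig.itertuples():
        if (
            current is not None
            and row.replicon == current.replicon
            and row.start == current.end
        ):
            current.end = row.end
            current.observed += row.observed
            current.observed_reads += row.observed_reads
            current.expected += row.expected
            current.plus += row.plus
            current.minus += row.minus
            current.p_value = min(current.p_value, row.p_value)
            current.q_value = min(current.q_value, row.q_value)
        else:
            current = HotspotCall(
                replicon=row.replicon,
                start=row.start,
                end=row.end,
                observed=row.observed,
                observed_reads=row.observed_reads,
                expected=row.expected,
                p_value=row.p_value,
                q_value=row.q_value,
                plus=row.plus,
                minus=row.minus,
            )
            calls.append(current)
    for c in calls:
        c.features = [
            f.name
            for f in ref.features
            if f.replicon == c.replicon and max(c.start, f.start) < min(c.end, f.end)
        ]
    return calls


def hotspots_to_frame(calls: Sequence[HotspotCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon": c.replicon,
                "start": c.start,
                "end": c.end,
                "observed": c.observed,
                "observed_reads": c.observed_reads,
                "expected": c.expected,
                "p_value": c.p_value,
                "q_value": c.q_value,
                "plus": c.plus,
                "minus": c.minus,
                "features": ";".join(c.features) if c.features else ".",
            }
            for c in calls
        ],
        columns=[
            "replicon",
            "start",
            "end",
            "observed",
            "observed_reads",
            "expected",
            "p_value",
            "q_value",
            "plus",
            "minus",
            "features",
        ],
    )


def write_hotspots_bed(calls: Sequence[HotspotCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            name = c.features[0] if c.features else "hotspot"
            fh.write(f"{c.replicon}\t{c.start}\t{c.end}\t{name}\t{c.observed}\t.\n")


# ---------------------------------------------------------------------------
# target profile


@dataclass
class TargetProfile:
    radius: int
    bin_size: int
    bins: pd.DataFrame  # columns: bin_start, strand, count
    n: int  # hits within the profiling radius
    upstream_scale: float = float("nan")  # geometric decay scale, nt
    downstream_scale: float = float("nan")
    upstream_coding_fraction: float = float("nan")
    downstream_template_fraction: float = float("nan")

    @property
    def is_empty(self) -> bool:
        return self.n == 0


def _geometric_scale_mle(distances: np.ndarray) -> float:
    """MLE of the geometric decay scale (mean offset) from distances >= 1."""
    if distances.size == 0:
        return float("nan")
    return float(distances.mean())


def profile_target(
    hits: Sequence[ProtospacerHit],
    ref: ReferenceGenome,
    radius: int = 5000,
    bin_size: int = 100,
    unique_only: bool = True,
) -> TargetProfile:
    """Signed-distance x strand histogram around the target cut site.

    Uses ``distance_to_target`` (computed here if absent). Hits at
    distance 0 (spanning the cut) count in the histogram's 0 bin on their
    strand but are excluded from the per-side strand fractions and decay
    fits. The per-side scale is the maximum-likelihood geometric mean
    offset of the unbinned distances within the radius.
    """
    from .mapping import annotate_distances

    _, _, coding = ref.target_cut_site()
    pool = [h for h in hits if h.unique] if unique_only else list(hits)
    if any(h.distance_to_target is None for h in pool):
        annotate_distances(pool, ref)
    pool = [
        h
        for h in pool
        if h.distance_to_target is not None and abs(h.distance_to_target) <= radius
    ]
    edges = np.arange(-radius, radius + bin_size, bin_size)
    rows = []
    for strand in "+-":
        d = np.array(
            [h.distance_to_target for h in pool if h.strand == strand], dtype=float
        )
        counts, _ = np.histogram(d, bins=edges)
        for b, c in zip(edges[:-1], counts):
            rows.append({"bin_start": int(b), "strand": strand, "count": int(c)})
    bins = pd.DataFrame(rows, columns=["bin_start", "strand", "count"])
    if not pool:
        return TargetProfile(radius, bin_size, bins, n=0)

    template = "-" if coding == "+" else "+"
    up = [h for h in pool if h.distance_to_target < 0]
    down = [h for h in pool if h.distance_to_target > 0]
    up_d = np.array([-h.distance_to_target for h in up], dtype=float)
    down_d = np.array([h.distance_to_target for h in down], dtype=float)
    return TargetProfile(
        radius=radius,
        bin_size=bin_size,
        bins=bins,
        n=len(pool),
        upstream_scale=_geometric_scale_mle(up_d),
        downstream_scale=_geometric_scale_mle(down_d),
        upstream_coding_fraction=(
            sum(h.strand == coding for h in up) / len(up) if up else float("nan")
        ),
        downstream_template_fraction=(
            sum(h.strand == template for h in down) / len(down)
            if down
            else float("nan")
        ),
    )
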