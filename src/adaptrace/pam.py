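"""PAM consensus from mapped protospacers.

Tallies the k-mer (default trinucleotide) immediately 5' of each uniquely
mapped protospacer, for spacers passing the read-support filter, and
derives the position frequency matrix, per-position consensus, modal-motif
fraction, and per-position information content (2 - Shannon entropy in
bits, no small-sample correction).

Two weightings are supported: per unique spacer (default — read counts
conflate PCR amplification with acquisition frequency) and per read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import ProtospacerHit

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PamSummary:
    k: int
    n: int  # total weight of contributing hits
    counts: Counter = field(default_factory=Counter)
    pfm: np.ndarray | None = None  # 4 x k, rows A,C,G,T, columns sum to 1
    consensus: str = ""
    modal_kmer: str = ""
    modal_fraction: float = float("nan")
    modal_tie: bool = False
    info_bits: np.ndarray | None = None

    @property
    def is_empty(self) -> bool:
        return self.n == 0


def summarize_pams(
    hits: Sequence[ProtospacerHit],
    min_reads: int = 10,
    weighting: str = "per_spacer",
    k: int = 3,
) -> PamSummary:
    """PAM tallies and motif statistics for support-filtered unique hits.

    Hits with read support below ``min_reads``, non-unique hits, and hits
    whose upstream window runs off a linear replicon (contains N) are
    excluded. Zero surviving hits yield an empty-summary sentinel rather
    than an exception.
    """
    if weighting not in ("per_spacer", "per_read"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts: Counter = Counter()
    for h in hits:
        if not h.unique or h.support < min_reads:
            continue
        pam = h.pam
        if len(pam) != k or not set(pam) <= set(BASES):
            continue
        counts[pam] += h.support if weighting == "per_read" else 1
    n = sum(counts.values())
    if n == 0:
        return PamSummary(k=k, n=0)

    pfm = np.zeros((4, k))
    for kmer, c in counts.items():
        for j, base in enumerate(kmer):
            pfm[_BASE_IDX[base], j] += c
    pfm /= n

    # argmax over rows in A,C,G,T order gives the lexicographic tie-break
    consensus = "".join(BASES[int(np.argmax(pfm[:, j]))] for j in range(k))
    top = max(counts.values())
    modal_candidates = sorted(km for km, c in counts.items() if c == top)
    modal_kmer = modal_candidates[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    info_bits = 2.0 + plogp.sum(axis=0)

    return PamSummary(
        k=k,
        n=n,
        counts=counts,
        pfm=pfm,
        consensus=consensus,
        modal_kmer=modal_kmer,
        modal_fraction=top / n,
        modal_tie=len(modal_candidates) > 1,
        info_bits=info_bits,
    )


def counts_to_frame(summary: PamSummary) -> pd.DataFrame:
    rows = sorted(summary.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["pam", "count"])
    if summary.n:
        df["fraction"] = df["count"] / summary.n
    return df


def write_pam_counts(summary: PamSummary, path: str | Path) -> None:
    counts_to_frame(summary).to_csv(path, sep="\t", index=False)


def write_pfm(summary: PamSummary, path: str | Path) -> None:
    """PFM as TSV, rows A,C,G,T — directly loadable as a logo matrix."""
    if summary.pfm is None:
        pd.DataFrame(index=list(BASES)).to_csv(path, sep="\t")
        return
    df = pd.DataFrame(
        summary.pfm,
        index=list(BASES),
        columns=[f"pos{j + 1}" for j in range(summary.k)],
    )
    df.to_csv(path, sep="\t", float_format="%.6f")
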