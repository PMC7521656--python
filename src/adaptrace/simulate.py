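"""Synthetic acquisition-assay generator with known ground truth.

Emulates the statistical structure of a self-targeting adaptation
experiment in a GC-rich archaeon: a multi-replicon genome (one main
chromosome plus smaller plasmids) carrying hotspot-prone features and a
self-target site; prespacer origins drawn from a mixture of

* a **target-proximal** component — distance from the cut site decays
  geometrically, and source strand follows the degradation polarity rule
  (origins upstream of the cut come from the coding strand, downstream
  origins from the template strand),
* a **hotspot** component — uniform within a randomly chosen hotspot
  feature (transposase / rRNA / provirus intervals),
* a **background** component — uniform genome-wide, both strands.

A configurable fraction of prespacers is placed so that the 3 nt
immediately 5' of the protospacer equal a modal PAM motif (rejection
sampling against the fixed reference, so the genome itself is never
edited). Amplicon reads of the expanded locus are then synthesized with
the assay's primer scheme (adapter + 0-3 random bases + leader anchor),
one or two inserted repeat-spacer units per read, and i.i.d. substitution
errors.

Every planted event is recorded in a :class:`TruthTable` so downstream
stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import mutate, random_dna, revcomp
from .genome import HOTSPOT_KINDS, Feature, ReferenceGenome, Replicon
from .locus import DEFAULT_ADAPTER, AmpliconDesign, CrisprLocus


class ConfigurationError(ValueError):
    """A simulation request that cannot be satisfied as configured."""


class SamplingError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


@dataclass
class SimulationConfig:
    seed: int = 0

    # genome
    chromosome_length: int = 200_000
    plasmid_length: int = 20_000
    gc: float = 0.65
    n_transposase: int = 4
    n_rrna: int = 2
    n_provirus: int = 1
    feature_length: int = 1_200
    include_target: bool = True
    target_site_length: int = 36
    include_hen: bool = True
    hen_site_length: int = 22

    # prespacer sampling
    n_prespacers: int = 5_000
    w_target: float = 0.5
    w_hotspot: float = 0.2
    w_background: float = 0.3
    target_decay_scale: float = 500.0
    target_upstream_fraction: float = 0.5
    upstream_strand: str = "coding"  # coding | template | either
    downstream_strand: str = "template"
    pam_modal_motif: str = "TAC"
    pam_modal_fraction: float = 0.76
    spacer_len_range: tuple[int, int] = (34, 39)
    distinct_sequences: bool = False
    max_pam_attempts: int = 20_000

    # read simulation
    n_reads: int = 50_000
    error_rate: float = 0.0
    double_insertion_fraction: float = 0.0
    random_prefix_range: tuple[int, int] = (0, 3)
    read_assignment: str = "even"  # even | multinomial
    orientation: str = "mixed"  # forward | reverse | mixed
    read_length: int | None = None

    def validate(self) -> None:
        probs = {
            "w_target": self.w_target,
            "w_hotspot": self.w_hotspot,
            "w_background": self.w_background,
            "pam_modal_fraction": self.pam_modal_fraction,
            "double_insertion_fraction": self.double_insertion_fraction,
            "error_rate": self.error_rate,
            "gc": self.gc,
            "target_upstream_fraction": self.target_upstream_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if abs(self.w_target + self.w_hotspot + self.w_background - 1.0) > 1e-9:
            raise ConfigurationError("mixture weights must sum to 1")
        lo, hi = self.spacer_len_range
        if not 0 < lo <= hi:
            raise ConfigurationError("bad spacer length range")
        klo, khi = self.random_prefix_range
        if not 0 <= klo <= khi:
            raise ConfigurationError("bad random prefix range")
        if self.upstream_strand not in ("coding", "template", "either"):
            raise ConfigurationError("bad upstream_strand")
        if self.downstream_strand not in ("coding", "template", "either"):
            raise ConfigurationError("bad downstream_strand")
        if self.read_assignment not in ("even", "multinomial"):
            raise ConfigurationError("bad read_assignment")
        if self.orientation not in ("forward", "reverse", "mixed"):
            raise ConfigurationError("bad orientation")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one simulation stage.

        Streams keep each operation deterministic under the config seed
        regardless of call order.
        """
        return np.random.default_rng([int(self.seed), int(stream)])


_STREAM_GENOME = 0
_STREAM_PRESPACERS = 1
_STREAM_READS = 2
_STREAM_LOCUS = 3


@dataclass(frozen=True)
class PlantedSpacer:
    spacer_id: str
    seq: str
    replicon: str
    start: int
    end: int
    strand: str
    component: str  # target | hotspot | background
    pam: str
    reads: int = 0


@dataclass
class TruthTable:
    """Simulator record of planted prespacers, for recovery scoring."""

    rows: list[PlantedSpacer] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "spacer_id": r.spacer_id,
                    "seq": r.seq,
                    "replicon": r.replicon,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "component": r.component,
                    "pam": r.pam,
                    "reads": r.reads,
                }
                for r in self.rows
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype={"seq": str, "pam": str})
        return cls([PlantedSpacer(**rec) for rec in df.to_dict("records")])


# ---------------------------------------------------------------------------
# reference genome


def _place_features(
    rng: np.random.Generator,
    replicon: str,
    strand_choices: str,
    length: int,
    specs: list[tuple[str, str, int]],
    max_attempts: int = 10_000,
) -> list[Feature]:
    """Place non-overlapping intervals by rejection sampling."""
    placed: list[Feature] = []
    occupied: list[tuple[int, int]] = []
    for kind, label, flen in specs:
        if flen >= length:
            raise ConfigurationError(
                f"replicon {replicon} too small for feature {kind}:{label}"
            )
        for _ in range(max_attempts):
            start = int(rng.integers(0, length - flen))
            end = start + flen
            if all(end <= s or start >= e for s, e in occupied):
                break
        else:
            raise ConfigurationError(
                f"could not place feature {kind}:{label} without overlap"
            )
        strand = str(rng.choice(list(strand_choices)))
        placed.append(Feature(replicon, start, end, strand, kind, label))
        occupied.append((start, end))
    return placed


def make_reference(config: SimulationConfig) -> ReferenceGenome:
    """Generate a deterministic multi-replicon reference with features.

    One linear main chromosome (default 200 kb) carries the hotspot
    features and the self-target site; one circular plasmid (default
    20 kb) carries the HEN cut site. GC content defaults to 0.65.
    """
    config.validate()
    rng = config.rng(_STREAM_GENOME)
    chrom = Replicon("chromosome", random_dna(rng, config.chromosome_length, config.gc))
    plasmid = Replicon(
        "plasmid", random_dna(rng, config.plasmid_length, config.gc), circular=True
    )

    chrom_specs: list[tuple[str, str, int]] = []
    for i in range(config.n_transposase):
        chrom_specs.append(("transposase", f"tnp{i + 1}", config.feature_length))
    for i in range(config.n_rrna):
        chrom_specs.append(("rRNA", f"rrn{i + 1}", config.feature_length))
    for i in range(config.n_provirus):
        chrom_specs.append(("provirus", f"provirus{i + 1}", config.feature_length))
    if config.include_target:
        chrom_specs.append(("target_site", "crtI", config.target_site_length))
    features = _place_features(
        rng, chrom.name, "+-", config.chromosome_length, chrom_specs
    )
    if config.include_target:
        # fix the target's declared coding strand to "+" for a stable
        # signed-distance convention across seeds
        features = [
            replace(f, strand="+") if f.kind == "target_site" else f for f in features
        ]
    if config.include_hen:
        features += _place_features(
            rng,
            plasmid.name,
            "+",
            config.plasmid_length,
            [("hen_site", "polB_hen", config.hen_site_length)],
        )
    return ReferenceGenome([chrom, plasmid], features)


def make_locus(config: SimulationConfig, locus_id: str = "P1") -> CrisprLocus:
    """Random CRISPR locus: AT-rich 120-nt leader, 30-nt repeat, 4 spacers."""
    rng = config.rng(_STREAM_LOCUS)
    lo, hi = config.spacer_len_range
    leader = random_dna(rng, 120, gc=0.40)
    repeat = random_dna(rng, 30, gc=0.50)
    spacers = [
        random_dna(rng, int(rng.integers(lo, hi + 1)), gc=0.60) for _ in range(4)
    ]
    return CrisprLocus(locus_id, leader, repeat, spacers)


# ---------------------------------------------------------------------------
# prespacer sampling


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _resolve_strand(rule: str, coding: str, rng: np.random.Generator) -> str:
    if rule == "coding":
        return coding
    if rule == "template":
        return _flip(coding)
    return str(rng.choice(["+", "-"]))


def sample_prespacers(ref: ReferenceGenome, config: SimulationConfig) -> TruthTable:
    """Draw prespacer origins from the target/hotspot/background mixture.

    Each draw independently decides (a) its mixture component, (b) its
    spacer length, and (c) whether it must carry the modal upstream PAM;
    the placement is then rejection-sampled until the PAM requirement is
    met. The returned truth table stores placement, component, and the
    realized upstream trinucleotide for every planted spacer.
    """
    config.validate()
    if config.w_target > 0 and not ref.features_of("target_site"):
        raise ConfigurationError("w_target > 0 but reference has no target_site")
    hotspot_feats = [f for f in ref.features if f.kind in HOTSPOT_KINDS]
    if config.w_hotspot > 0 and not hotspot_feats:
        raise ConfigurationError("w_hotspot > 0 but reference has no hotspot features")

    rng = config.rng(_STREAM_PRESPACERS)
    lo, hi = config.spacer_len_range
    weights = np.array([config.w_target, config.w_hotspot, config.w_background])
    hs_weights = np.array([f.end - f.start for f in hotspot_feats], dtype=float)
    if hs_weights.size:
        hs_weights /= hs_weights.sum()
    rep_lengths = np.array([len(r) for r in ref.replicons], dtype=float)
    rep_weights = rep_lengths / rep_lengths.sum()

    if config.w_target > 0:
        t_rep, t_cut, t_coding = ref.target_cut_site()

    rows: list[PlantedSpacer] = []
    seen: set[str] = set()
    k = len(config.pam_modal_motif)

    for i in range(config.n_prespacers):
        comp = ("target", "hotspot", "background")[rng.choice(3, p=weights)]
        length = int(rng.integers(lo, hi + 1))
        want_modal = rng.random() < config.pam_modal_fraction

        for attempt in range(config.max_pam_attempts):
            if comp == "target":
                offset = int(rng.geometric(1.0 / config.target_decay_scale))
                upstream = rng.random() < config.target_upstream_fraction
                sign = 1 if t_coding == "+" else -1
                if upstream:
                    edge = t_cut - sign * offset
                    start = edge - length if sign == 1 else edge
                    strand = _resolve_strand(config.upstream_strand, t_coding, rng)
                else:
                    edge = t_cut + sign * offset
                    start = edge if sign == 1 else edge - length
                    strand = _resolve_strand(config.downstream_strand, t_coding, rng)
                replicon = t_rep
            elif comp == "hotspot":
                f = hotspot_feats[int(rng.choice(len(hotspot_feats), p=hs_weights))]
                start = int(rng.integers(f.start, f.end - length))
                strand = str(rng.choice(["+", "-"]))
                replicon = f.replicon
            else:
                rep = ref.replicons[int(rng.choice(len(ref.replicons), p=rep_weights))]
                hi_start = len(rep) if rep.circular else len(rep) - length
                start = int(rng.integers(0, hi_start))
                strand = str(rng.choice(["+", "-"]))
                replicon = rep.name

            end = start + length
            rep_obj = ref.replicon(replicon)
            if start < 0 or (not rep_obj.circular and end > len(rep_obj)):
                continue
            pam = ref.upstream_kmer(replicon, start, end, strand, k=k)
            if want_modal and pam != config.pam_modal_motif:
                continue
            seq = ref.fetch(replicon, start, end, strand)
            if config.distinct_sequences and seq in seen:
                continue
            break
        else:
            raise SamplingError(
                f"prespacer {i}: no placement satisfying component={comp}, "
                f"modal_pam={want_modal} after {config.max_pam_attempts} attempts"
            )

        seen.add(seq)
        rows.append(
            PlantedSpacer(
                spacer_id=f"sp{i:05d}",
                seq=seq,
                replicon=replicon,
                start=start,
                end=end,
                strand=strand,
                component=comp,
                pam=pam,
            )
        )
    return TruthTable(rows)


# ---------------------------------------------------------------------------
# amplicon reads


@dataclass
class SimulatedRead:
    read_id: str
    seq: str
    planted: list[str]  # planted spacer ids, leader-proximal first


def _assign_reads(
    rng: np.random.Generator, n_spacers: int, n_reads: int, mode: str
) -> np.ndarray:
    if mode == "multinomial":
        return rng.integers(0, n_spacers, size=n_reads)
    base, rem = divmod(n_reads, n_spacers)
    idx = np.repeat(np.arange(n_spacers), base)
    if rem:
        extra = rng.choice(n_spacers, size=rem, replace=False)
        idx = np.concatenate([idx, extra])
    rng.shuffle(idx)
    return idx


def simulate_amplicon_reads(
    locus: CrisprLocus,
    truth: TruthTable,
    design: AmpliconDesign,
    config: SimulationConfig,
) -> tuple[list[SimulatedRead], TruthTable]:
    """Synthesize amplicon reads of the expanded locus.

    Each read is
    ``adapter + k random bases + leader-anchor + (repeat + spacer) x m
    + repeat + spacer1-anchor`` with m = 2 at ``double_insertion_fraction``
    (the leader-proximal unit is the read's assigned spacer, the distal
    unit a second planted spacer), else m = 1. Substitution errors are
    applied i.i.d. at ``error_rate``; orientation follows
    ``config.orientation``. Returns the reads and a truth table whose
    per-spacer read counts reflect the realized assignment.
    """
    config.validate()
    if len(truth) == 0:
        raise ConfigurationError("truth table is empty")
    rng = config.rng(_STREAM_READS)
    n = len(truth)
    primary = _assign_reads(rng, n, config.n_reads, config.read_assignment)
    klo, khi = config.random_prefix_range

    counts = np.zeros(n, dtype=int)
    reads: list[SimulatedRead] = []
    max_construct = 0
    for ri in range(config.n_reads):
        i = int(primary[ri])
        unit_ids = [i]
        if rng.random() < config.double_insertion_fraction:
            unit_ids.append(int(rng.integers(0, n)))
        parts = [design.adapter]
        kpref = int(rng.integers(klo, khi + 1))
        if kpref:
            parts.append(random_dna(rng, kpref, gc=0.5))
        parts.append(design.forward_anchor)
        for j in unit_ids:
            parts.append(locus.repeat)
            parts.append(truth.rows[j].seq)
            counts[j] += 1
        parts.append(locus.repeat)
        parts.append(design.reverse_anchor)
        seq = "".join(parts)
        max_construct = max(max_construct, len(seq))
        if config.read_length is not None and config.read_length < len(seq):
            raise ConfigurationError(
                f"read_length={config.read_length} shorter than amplicon "
                f"construct ({len(seq)} nt)"
            )
        seq = mutate(rng, seq, config.error_rate)
        if config.orientation == "reverse" or (
            config.orientation == "mixed" and rng.random() < 0.5
        ):
            seq = revcomp(seq)
        reads.append(
            SimulatedRead(
                read_id=f"read{ri:06d}",
                seq=seq,
                planted=[truth.rows[j].spacer_id for j in unit_ids],
            )
        )
    updated = TruthTable(
        [replace(r, reads=int(c)) for r, c in zip(truth.rows, counts)]
    )
    return reads, updated


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    """Write reads as FASTQ with constant quality 'I' (Q40).

    The planted spacer ids travel in the description so scoring never
    needs a side channel.
    """
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"@{r.read_id} planted={','.join(r.planted)}\n"
                f"{r.seq}\n+\n{'I' * len(r.seq)}\n"
            )
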