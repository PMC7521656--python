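"""End-to-end orchestration: simulate → parse → map → PAM → hotspots → profile.

A :class:`RunConfig` fixes every stage parameter and the seed; re-running
the same config byte-reproduces all tabular outputs. The run report
(``summary.json``) echoes all parameters for provenance and satisfies the
read-conservation identity ``total = expanded + unexpanded + rejected``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import array_parser, hotspots as hotspot_mod, mapping, pam as pam_mod
from .genome import ReferenceGenome
from .locus import AmpliconDesign, CrisprLocus
from .simulate import (
    SimulationConfig,
    make_locus,
    make_reference,
    sample_prespacers,
    simulate_amplicon_reads,
    write_fastq,
)

log = logging.getLogger("adaptrace")


@dataclass
class RunConfig:
    outdir: str = "adaptrace_out"
    seed: int = 0
    # inputs (ignored when simulating)
    simulate: bool = True
    reads: str | None = None
    reference: str | None = None
    features: str | None = None
    locus: str | None = None
    # stage parameters
    simulation: dict = field(default_factory=dict)
    anchor_len: int = 20
    anchor_max_mismatches: int = 2
    repeat_max_mismatches: int = 3
    min_reads: int = 10
    max_mm: int = 2
    window: int = 1000
    alpha: float = 0.05
    radius: int = 5000
    bin_size: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute the configured stages and write the run report.

    Returns the summary dict (also written to ``<outdir>/summary.json``).
    Stages whose inputs are unavailable (e.g. mapping without a
    reference) are skipped with a logged notice.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=force or True)
    summary: dict = {"parameters": _echo_params(config)}

    ref: ReferenceGenome | None = None
    locus: CrisprLocus | None = None
    reads_path: Path | None = None

    if config.simulate:
        sim = config.simulation_config()
        ref = make_reference(sim)
        locus = make_locus(sim)
        design = AmpliconDesign.from_locus(
            locus,
            anchor_len=config.anchor_len,
            anchor_max_mismatches=config.anchor_max_mismatches,
            repeat_max_mismatches=config.repeat_max_mismatches,
        )
        truth = sample_prespacers(ref, sim)
        reads, truth = simulate_amplicon_reads(locus, truth, design, sim)
        ref.write_fasta(out / "reference.fasta")
        ref.write_bed(out / "features.bed")
        locus.to_yaml(out / "locus.yaml")
        truth.write_tsv(out / "truth.tsv")
        reads_path = out / "reads.fastq"
        write_fastq(reads, reads_path)
        summary["simulation"] = {
            "n_prespacers": len(truth),
            "n_reads": len(reads),
        }
    else:
        if config.reads is None:
            raise ValueError("no reads: set simulate=true or provide --reads")
        reads_path = Path(config.reads)
        if config.locus is None:
            raise ValueError("parsing requires a locus YAML")
        locus = CrisprLocus.from_yaml(config.locus)
        design = AmpliconDesign.from_locus(
            locus,
            anchor_len=config.anchor_len,
            anchor_max_mismatches=config.anchor_max_mismatches,
            repeat_max_mismatches=config.repeat_max_mismatches,
        )
        if config.reference is not None:
            ref = ReferenceGenome.from_fasta(config.reference, config.features)

    # ---- parse ----------------------------------------------------------
    parses = array_parser.parse_reads(
        array_parser.iter_fastq(reads_path), locus, design
    )
    n_total = len(parses)
    n_exp = sum(p.status == "expanded" for p in parses)
    n_unexp = sum(p.status == "unexpanded" for p in parses)
    n_rej = sum(p.status == "reject" for p in parses)
    assert n_total == n_exp + n_unexp + n_rej
    calls = array_parser.aggregate_calls(parses, locus_id=locus.locus_id)
    array_parser.write_calls(calls, out / "calls.tsv")
    rejects = array_parser.reject_summary(parses)
    summary["parse"] = {
        "total_reads": n_total,
        "expanded_reads": n_exp,
        "unexpanded_reads": n_unexp,
        "rejected_reads": n_rej,
        "rejects_by_reason": dict(sorted(rejects.items())),
        "unique_spacers": len(calls),
    }

    if ref is None:
        log.info("no reference genome: skipping map/PAM/hotspot/profile stages")
        summary["skipped"] = ["map", "pam", "hotspots", "profile"]
        _write_summary(summary, out)
        return summary

    # ---- map ------------------------------------------------------------
    hits = mapping.map_calls(calls, ref, max_mm=config.max_mm)
    mapping.annotate_distances(hits, ref)
    mapping.write_hits(hits, out / "hits.tsv")
    mapping.write_hits_bed(hits, out / "hits.bed")
    source = mapping.classify_source(hits, ref)
    summary["map"] = {
        "hits": len(hits),
        "unique_hits": sum(h.unique for h in hits),
        "per_replicon_fraction": {
            str(k): round(float(v), 6)
            for k, v in source["per_replicon"]["frac_spacers"].items()
        },
    }

    # ---- PAM ------------------------------------------------------------
    pam_stats = {}
    for weighting in ("per_spacer", "per_read"):
        s = pam_mod.summarize_pams(
            hits, min_reads=config.min_reads, weighting=weighting
        )
        pam_stats[weighting] = {
            "n": s.n,
            "modal_kmer": s.modal_kmer,
            "modal_fraction": None if s.is_empty else round(s.modal_fraction, 6),
            "consensus": s.consensus,
        }
        if weighting == "per_spacer":
            pam_mod.write_pam_counts(s, out / "pam_counts.tsv")
            pam_mod.write_pfm(s, out / "pam_pfm.tsv")
    summary["pam"] = pam_stats

    # ---- hotspots -------------------------------------------------------
    hs = hotspot_mod.call_hotspots(
        hits, ref, window=config.window, alpha=config.alpha
    )
    hotspot_mod.hotspots_to_frame(hs).to_csv(
        out / "hotspots.tsv", sep="\t", index=False
    )
    hotspot_mod.write_hotspots_bed(hs, out / "hotspots.bed")
    summary["hotspots"] = {
        "count": len(hs),
        "feature_labels": sorted({f for c in hs for f in c.features}),
    }

    # ---- target profile -------------------------------------------------
    if ref.features_of("target_site"):
        prof = hotspot_mod.profile_target(
            hits, ref, radius=config.radius, bin_size=config.bin_size
        )
        prof.bins.to_csv(out / "target_profile.tsv", sep="\t", index=False)
        summary["target_profile"] = {
            "n_within_radius": prof.n,
            "upstream_scale": _round(prof.upstream_scale),
            "downstream_scale": _round(prof.downstream_scale),
            "upstream_coding_fraction": _round(prof.upstream_coding_fraction),
            "downstream_template_fraction": _round(prof.downstream_template_fraction),
        }
    else:
        log.info("no target_site feature: skipping target profile")
        summary.setdefault("skipped", []).append("profile")

    _write_summary(summary, out)
    return summary


def _round(x: float, nd: int = 4) -> float | None:
    import math

    return None if x is None or math.isnan(x) else round(float(x), nd)


def _echo_params(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def _write_summary(summary: dict, out: Path) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
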