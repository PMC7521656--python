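# adaptrace

Analysis toolkit for **CRISPR adaptation (spacer acquisition) assays** read
out by amplicon sequencing, modeled on self-targeting experiments in a
haloarchaeal type I-B system. When a crRNA directs the interference
machinery (Cascade + Cas3) against the host's own genome, the cell acquires
new spacers at the leader end of its CRISPR arrays; sequencing the 5′ end
of each array reveals which genomic fragments were captured. `adaptrace`
turns those reads into the quantities such a study reports:

* **novel spacer calls** — detection of newly inserted repeat–spacer units
  (one or two per read) in primer-anchored amplicons, with exact-sequence
  aggregation and read support;
* **protospacer maps** — placement of each spacer on a multi-replicon
  reference (chromosome + plasmids) by an internal mismatch-tolerant
  search, with strand, uniqueness, and circular-origin handling;
* **PAM consensus** — the trinucleotide immediately 5′ of each protospacer,
  as counts, a position frequency matrix, consensus, modal-motif fraction,
  and per-position information content;
* **acquisition hotspots** — genome windows enriched over a uniform
  Poisson background (Benjamini–Hochberg corrected), annotated with
  overlapping features (transposases, rRNA operons, proviruses);
* **target-site profile** — strand-resolved distance histogram around the
  self-target cut site with a per-side geometric decay fit, capturing the
  signature of Cas3 degradation products feeding acquisition (upstream
  spacers from the coding strand, downstream spacers from the template
  strand).

A **synthetic-data generator** produces reference genomes, CRISPR loci,
planted prespacer origins (target-proximal / hotspot / background mixture
with configurable PAM bias), and error-bearing amplicon reads with a full
truth table, so every stage is testable against planted ground truth at
desk scale.

## The model in brief

Prespacer origins are drawn from a three-component mixture: with weight
*w*<sub>target</sub> an origin sits at geometric distance *d* ~ Geom(1/λ)
from the target cut site (default λ = 500 nt), strand-assigned by the
degradation polarity rule; with *w*<sub>hotspot</sub> uniformly inside a
hotspot feature; otherwise uniformly genome-wide. A fraction *p* of
origins (default 0.76) is constrained so the 3 nt upstream of the
protospacer equal the modal PAM (default `TAC`), by rejection sampling
against the fixed reference. Hotspot calling tiles each replicon with
1-kb windows, tests observed unique-spacer counts against
Poisson(*N·w/G*), and controls FDR at 0.05 by Benjamini–Hochberg.
Information content per PAM position is 2 − *H*(column) bits.

## Worked example

```bash
adaptrace run-all --seed 1 --out demo
# run complete: demo/summary.json
# reads=50000 expanded=50000 unique_spacers=3115
```

With the default simulation (5,000 planted prespacers, 50,000 error-free
reads), `demo/summary.json` reports, among other things:

```
"parse":  50,000 reads, all expansion-bearing, 3,115 unique spacers
"map":    replicon fractions chromosome 0.957 / plasmid 0.043
"pam":    per-read modal TAC at 0.758; per-spacer modal TAC at 0.618
"hotspots": 8 calls, labeled with all four transposases, both rRNA
            operons, the provirus, and the target site
"target_profile": upstream coding-strand fraction 0.95,
            downstream template-strand fraction 0.98
```

Read the numbers as follows. Every error-free read parses and carries its
planted unit, so detection is exactly conservative. The per-read modal-PAM
fraction (0.758) recovers the planted 0.76; the per-spacer figure is lower
because target-proximal prespacers frequently duplicate placements and
collapse into single calls, diluting the per-unique-spacer tally — the
package reports both weightings for precisely this reason. Hotspot calls
land on the planted enrichment features and the target site, and the
strand fractions around the cut reproduce the planted polarity rule.

Each stage is also available separately (`adaptrace simulate / parse /
map / pam / hotspots / profile`); see `adaptrace COMMAND --help`.

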