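# Methods

## Scope and coordinate conventions

`adaptrace` analyses amplicon sequencing of the leader-proximal end of
CRISPR arrays after adaptation, and ships a generator that plants known
acquisition events so each stage can be scored exactly. Throughout,
coordinates are 0-based half-open; strand `+` is the replicon sequence as
written; on circular replicons an interval may wrap, stored unwrapped
(`end = start + length`, interpreted modulo the replicon length). The
"coding strand" of the self-target gene is the strand declared on the
`target_site` feature; the cut site is that feature's 5′ boundary on the
coding strand. Signed distances to the cut are negative upstream on the
coding strand.

## Synthetic genome and locus

The generator emits one linear chromosome (default 200 kb) and one
circular plasmid (default 20 kb), i.i.d. bases at a configurable GC
fraction (default 0.65, matching a high-GC archaeal genome). Hotspot
features (default four transposases, two rRNA operons, one provirus, each
1.2 kb), the target site, and a HEN (homing endonuclease) recognition
site on the plasmid are placed uniformly without overlap by rejection
sampling. Because no public sequence of the assayed locus is bundled,
the CRISPR locus is synthesized per seed — a 120-nt AT-rich leader
(GC 0.40), a 30-nt repeat, and four endogenous spacers — typical type I-B
dimensions; every downstream algorithm is sequence-agnostic, and a real
locus can be supplied as YAML. Spacer lengths default to 34–39 nt. The
crRNA handle lengths (8 nt 5′, 22 nt 3′) are carried as locus constants
but play no role in parsing.

## Prespacer mixture

Each planted prespacer independently draws:

* **component** — target-proximal (*w*<sub>t</sub> = 0.5), hotspot
  (*w*<sub>h</sub> = 0.2), or background (*w*<sub>b</sub> = 0.3). The
  default weights are a qualitative rendering of the observed structure
  (strong concentration near the target, clear feature hotspots, a
  genome-wide floor); they are configuration, not estimates.
* **target geometry** — offset from the cut site ~ Geometric(1/λ),
  λ = 500 nt by default (the data show only a qualitative decay; λ is a
  declared scale). Side is chosen 50/50; strand follows the polarity rule
  (upstream → coding strand, downstream → template strand), each side's
  rule independently configurable.
* **PAM constraint** — with probability 0.76 the placement is rejected
  until the 3 nt 5′ of the protospacer equal the modal motif `TAC`
  (per-attempt redraw of the position within the same component, so the
  marginal distance distribution is unchanged); otherwise the upstream
  trinucleotide is unconstrained, so a small excess (~0.24/64) of
  non-constrained draws is modal by chance. Rejection sampling against
  the fixed reference keeps the genome internally consistent — reference
  bases are never rewritten.

An optional `distinct_sequences` flag re-draws any placement whose
spacer sequence was already planted, for scenarios that count unique
spacers exactly.

## Read model

Each read is `adapter + k random bases (k ~ U{0..3}) + leader 3′ anchor +
(repeat + spacer) × m + repeat + spacer1 5′ anchor`, with m = 2 at the
double-insertion fraction (the leader-proximal unit is the read's
assigned spacer; the distal unit is a second planted spacer). Reads span
the full amplicon: a fixed short read length cannot hold a two-unit
expansion (~200 nt of insert), so truncation is only available
explicitly, and a `read_length` below the construct size is a
configuration error. Errors are i.i.d. substitutions (no indels) —
substitution-dominated short-read chemistry is the model, and it keeps
the parser's acceptance analytically tractable. Orientation is mixed
(50/50 reverse-complement) by default. Reads are assigned to spacers
evenly by default (⌊n/N⌋ each, remainder random) so that "c reads per
spacer" scenarios are exact; a multinomial mode exists. Qualities are
constant `I`; quality-score realism and PCR bias are non-goals.

Each stage draws from its own seeded stream (`default_rng([seed, k])`),
so outputs are byte-reproducible and independent of call order.

## Array parsing

Trimming locates the adapter (Hamming ≤ anchor budget, default 2), then
the leader anchor at each admissible random-prefix offset, on the read
and its reverse complement; output is normalized leader → array.
Expansion detection then walks the array greedily: a repeat (Hamming ≤
repeat budget, default 3) must open the trimmed read; each inter-repeat
segment (20–60 nt scan window) is a spacer; the walk terminates when the
remainder matches the 5′ of endogenous spacer 1. Segments before the
terminator are the novel spacers, leader-proximal first; a read whose
first segment is endogenous spacer 1 is "unexpanded". Rejects carry
reason codes and enter the conservation identity
`total = expanded + unexpanded + rejected`, which the pipeline asserts.

Aggregation is exact-sequence deduplication (no error-tolerant
clustering — no published clustering rule exists to reconstruct), support
sorted descending with lexicographic tie-break, insertion index modal
over reads.

## Protospacer mapping

An internal seed-and-verify Hamming search replaces an external aligner:
the query is split into `max_mm + 1` near-equal segments (pigeonhole — at
most `max_mm` mismatches leave one segment exact), exact segment matches
nominate candidate starts, and full-length Hamming verification keeps
hits within budget (default 2). Circularity is honored by extending the
text by `len − 1` bases and deduplicating wrapped starts. The search is
exhaustive within budget, so a naive all-positions scan is an exact
oracle (tested for mm ∈ {0,1,2}). `unique` is true iff exactly one hit
exists at the minimal mismatch tier; downstream statistics use unique
hits by default to sidestep an unstated multimapper policy. The PAM is
attached at mapping time as the 3 nt genomically 5′ of the hit on the
hit's strand.

## PAM summary

Hits passing the read-support filter (default ≥ 10 reads) and uniqueness
are tallied per k-mer (k = 3). Both weightings are reported: per unique
spacer (default — read counts conflate PCR amplification with acquisition
frequency) and per read. Whether a published "76 %" style figure is per
spacer or per read is generally ambiguous, and the two can differ
materially when planted duplicates collapse (see the README example), so
the pipeline always emits both. The PFM normalizes each column to 1
(exact to 1e-9); consensus is the per-position argmax with lexicographic
tie-break (rows ordered A,C,G,T); information content is 2 − Shannon
entropy (log₂) per column with no small-sample correction; modal-k-mer
ties are flagged and broken lexicographically. Zero surviving hits yield
an empty-summary sentinel, not an exception.

## Hotspots and target profile

No statistical hotspot definition exists to reconstruct, so the statistic
is the package's own and fully logged: non-overlapping windows (default
1 kb; the trailing partial window is expectation-scaled), uniform
expectation `total · width / genome length`, upper-tail Poisson p-values,
BH (statsmodels `fdr_bh`) across all windows at α = 0.05, maximal runs of
adjacent significant windows merged, overlapping feature labels attached.
Hits are binned by start coordinate, making window counts exactly
conservative. Under a uniform background the empirical FDR is verified
≤ 0.05 + 3·MC error over 100 Monte-Carlo replicates.

The target profile bins uniquely mapped hits by signed cut distance ×
strand (default radius 5 kb, bin 100 nt) and reports the upstream
coding-strand and downstream template-strand fractions plus a per-side
decay scale. The scale is the maximum-likelihood estimate of the
geometric mean offset — the sample mean of the unbinned distances — with
no truncation correction: at λ = 500 and radius ≥ 5 kb the truncated mass
is < 10⁻⁴, far below the documented ±10 % recovery tolerance. Hits
spanning the cut (distance 0) are excluded from per-side statistics.

## What the simulations do and do not show

Passing recovery tests on this generator demonstrates algorithmic
correctness — conservation, oracle equivalence, estimator consistency,
FDR control — under the planted model: i.i.d. genome composition,
substitution-only errors, perfectly known locus, and mixture-form origin
structure. Real libraries add PCR duplicates and chimeras, indels,
quality heterogeneity, repeat polymorphism, and biological origin
structure richer than three components; none of these are modeled, and
results on real data depend on the configured mismatch budgets (defaults:
anchors 2, repeats 3, mapping 2) that the assay's original processing did
not document.

## Problem sizes

The test suite and the acceptance script run simulations at the scales
the analyses need for their stated tolerances: libraries of 11,000–50,000
error-free reads for exact conservation, 5,000 prespacers for the
modal-PAM estimate (binomial SE ≈ 0.6 pp), 2,600 distinct spacers for
unique-spacer accounting, 20,000 target-proximal draws for decay-scale
recovery, and a 30–50 kb genome for oracle-equivalence scans.
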