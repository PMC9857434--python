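# Methods

This note documents the models behind `sspcr`, the reasoning behind every
tunable default, what the synthetic-genome generator does and does not
emulate, and the numerical conventions the implementation relies on.

## Coordinate and strand conventions

Coordinates are 0-based, half-open throughout; conversion to 1-based happens
only at formatting boundaries (BED output is native).  Primers are written
5′→3′.  A site on strand `+` means the primer sequence itself appears on the
plus strand over the footprint (the primer anneals to the minus strand and
extends toward increasing coordinates); strand `−` means the footprint's
plus-strand slice is the primer's reverse complement.  Only strict `ACGT`
is accepted: every downstream rule counts base matches, and silently
matching IUPAC ambiguity codes would change those counts.

## Melting temperatures

Two estimators serve two length scales:

* **Wallace rule** (2 °C per A/T, 4 °C per G/C) for the 10-nt 3′ overlap
  shared by an outer primer and its semi-site-specific partner, screened
  against a 20–40 °C window.  A 10-mer spans exactly 20–40 °C under the
  rule, so the window is a consistency statement rather than a filter; the
  nine bundled overlaps measure 26–34 °C.
* **Nearest-neighbor model** (Biopython's SantaLucia tables, one monovalent
  salt correction) for full 20–30-nt primers against a 60–65 °C window.
  Default conditions: 50 mM monovalent salt, 250 nM primer, echoed into
  every report.  The Wallace rule badly overestimates Tm at these lengths.

The source protocol names neither method; both choices and all conditions
are configurable (`ThermoConfig`).

## Secondary-structure screens

"Severe" hairpins and dimers are quantified as complementary run lengths:

* hairpin: an antiparallel self-complementary stem of ≥ 4 bp closing a loop
  of ≥ 3 nt fails;
* cross-dimer: a duplex run of ≥ 8 bp between two oligos fails, with a
  stricter ceiling of 6 bp for runs that include either 3′ terminus (where
  the polymerase extends).  The 3′ ceiling was fixed so that every published
  secondary-round pair passes (the largest observed 3′-terminal run among
  them is 5 bp);
* base evenness of the semi primer's heterologous 5′ part: no base above
  0.50 (the largest published fraction is 7/15 ≈ 0.467), with the
  all-four-bases-present requirement enforced during de-novo design only —
  one published 5′ part contains no G at all.

## The partial-annealing model

Annealing at mismatched sites is ungapped and 3′-anchored: the primer's 3′
terminus pairs a template base and matches are counted positionwise over the
full footprint; footprints overhanging a template end are discarded.  A site
qualifies in a relaxed-stringency cycle when

1. the consecutive 3′-terminal match run is ≥ 2 (functional priming needs a
   paired 3′ end),
2. total matches are ≥ 8 **and** the mismatch fraction is ≤ 0.60, **or**
3. the perfect 3′-terminal run alone reaches ≥ 10 nt (`strong_3prime_run`).

Clause 3 is this package's mechanical reading of the scheme's keystone
event: the semi primer's designed 10-nt overlap is a perfect 3′-anchored
decamer with Wallace Tm ≥ 20 °C, which primes at a 25–40 °C annealing step
no matter how mismatched the heterologous tail is.  A bare mismatch-fraction
ceiling would veto that event for primers longer than 25 nt (10 guaranteed
matches out of 27 is already 63 % mismatch), including several published
semi primers at their own target loci — so the 60 % figure is treated as a
tolerance observation, not a hard admission rule.  Setting
`strong_3prime_run=None` restores the bare three-threshold model.  The
8-match floor is likewise a floor, not a ceiling; observed productive sites
ranged from 8 to 17 matches and the scanner reports full statistics
(`site_statistics`) so users can compare.

## Two-round product classification

The analytic predictor (`run_primary`, `run_secondary`) classifies every
candidate product:

* **target** — both termini carry perfect binding sites for that round's
  primers.  In the primary round this means a perfect outer site converging
  with a qualifying partial site on the strand synthesised from it, with
  extension running back through the complete perfect footprint; the product
  is flanked by the primer and its reverse complement.  In the secondary
  round it means an inner-primed strand converted by a semi partial event,
  giving inner/semi-flanked products whose length is
  (partial-site anchor − inner-primer start) + semi length.
* **suppressed-short** — primary-round targets shorter than 200 bp
  (configurable): their terminal inverted repeats favour intra-strand
  hairpin formation over primer annealing.  This is a hard length threshold,
  not a thermodynamic competition model, because the mechanism is
  qualitative.  Secondary products are flanked by two different primers and
  are not subject to it.
* **nontarget-unamplifiable** — everything else the relaxed cycle primes:
  converging partial-partial pairs (enumerable for inspection via
  `enumerate_background`) and semi events away from product termini.  These
  strands never gain a perfect terminus and stay linear.

Copy-number bookkeeping is qualitative (exponential vs linear); annealing
temperatures in `ThermalProgram` are reporting metadata and the stringency
class alone drives behaviour.  Exactly one relaxed-stringency stage is
allowed per program; removing it (ablation) leaves only products flanked by
two perfect sites, i.e. no walking.  In the relaxed cycle only the round's
walking primer partially anneals (the outer primer in the primary round, the
semi primer in the secondary round); partial annealing by the inner primer
at 40 °C is neglected.  The extension ceiling defaults to 10 kb,
approximating what a 3-min extension step can synthesise.

Two corner cases found by oracle comparison are modelled explicitly: when a
partial footprint overlaps the perfect footprint and the primer suffix
across the overlap is its own reverse complement, the short product is a
genuine self-priming palindromic amplicon (classed by the normal rules,
which makes it suppressed-short at default thresholds); the analogous
coincidence exists for semi events landing on the inner primer's terminus.

## The string-synthesis oracle

`string_synthesis_oracle` is an independent verifier that shares no
classification logic with the predictor: it plays every cycle out literally
on raw strings (denature → anneal → extend to the template 5′ end or the
ceiling, primer incorporated at the new strand's 5′ terminus), tracks exact
integer copy numbers, and calls a duplex exponential when both strands at
least doubled over the final two cycles.  Guards keep it tractable
(templates ≤ 50 kb, ≤ 12 cycles), so tests run it with a scaled stage
structure (3 stringent / 1 relaxed / 6 stringent) that preserves the
scheme's qualitative behaviour.  The acceptance suite asserts exact
agreement — oracle exponential set = analytic target ∪ suppressed-short
(suppression is a classification overlay the literal simulation does not
model) — across 50 seeded fixtures up to 50 kb, in both rounds.

## Primer-set design

Candidate windows (20–30 nt) from the extension strand of the known region
are filtered on nearest-neighbor Tm, hairpin and self-dimer screens, and for
outer candidates a compliant 3′ overlap; candidates are ranked by Tm
centrality, then junction proximity, then leftmost coordinate (the ranking
is this package's choice; the protocol only says primers were "selected").
The inner primer is chosen first, then three outer tiers strictly 5′ of it
with a configurable start-to-start spacing (default 5 bp).  Combinations
whose fixed overlap already forms a disqualifying duplex with the inner
primer are rejected up front: no sampled semi tail could ever repair that.

Semi primers copy their partner's 3′ overlap verbatim and draw the 5′ tail
by seeded rejection sampling (budget 10 000), stratified by G+C count so
skewed overlaps still reach the Tm window.  Accepted tails keep the common
3′ suffix at exactly the overlap length, satisfy evenness and heterology
(no shared k-mer ≥ 5 with the outer's 5′ remainder — published pairs satisfy
this, while strict positionwise non-identity they do not), and pass all
screens including cross-dimer against the inner primer.  The semi primer
inherits its partner's total length, as in the published sets, so its
footprint at a product terminus never overhangs the incorporated outer
primer.  Everything is deterministic given the seed.

## The synthetic-genome generator

`generate_walk_fixture` emulates the one thing the walk needs from a real
genome: a known region abutting an unknown flank that contains qualifying
partial-annealing sites.  It draws a seeded random genome (default 12 kb,
junction at 1.5 kb), designs a primer set on the known region, and plants
minus-strand partial sites at configured distances (defaults 1.5 and 8.0 kb,
the span of the longest reported walks; the acceptance run sweeps
0.4–8.0 kb) with exact match counts and 3′-run lengths.  Optional decoys
plant a perfect duplicate site (a legitimate extra product) or an
out-of-reach converging partial-partial pair (which must stay nontarget).

A ~25-nt primer allowed 60 % mismatches finds chance qualifying sites on
random sequence at roughly 1 % of positions, so by default the generator
*scrubs* the template: chance sites that would add unplanted exponential
products are disabled by point mutations placed outside every protected
footprint (primer anchors, planted sites), iterating to a fixed point; if a
chance site is buried in protected bases the fixture is regenerated from a
derived seed.  Scrubbing makes the planted truth an exact prediction of the
simulator's target set — the honest basis for recovery tests — and can be
switched off to study realistic background.  What the generator does **not**
emulate: real genomes' repeat structure, GC skew and compositional
autocorrelation, which make both perfect-site uniqueness and chance-site
statistics less benign than uniform random sequence; passing tests therefore
demonstrate the scheme's internal logic, not wet-lab success rates.

## Problem sizes in the shipped checks

The acceptance suite runs 50 fixture/oracle comparisons on genomes of
8–50 kb, planted-site recovery on 12-kb genomes across 0.4–8.0-kb distances,
a 100-primer brute-force scanner comparison on a 10-kb template, and 100
seeded design runs on 1-kb regions.  `scripts/acceptance.py` regenerates
eight 5-site fixtures per run from the supplied seed.  These sizes were
chosen as the smallest that exercise every regime (suppression threshold,
extension ceiling, nested multi-site walks) with comfortable margins.

## Known limitations

* Priming admission is combinatorial (match counts and runs), not
  thermodynamic: no ΔG model, no polymerase-specific 3′-mismatch extension
  table, no gapped/bulged annealing (alignments are shown gapless in the
  source data).
* Amplification is presence/absence; no cycle-by-cycle yields, no
  efficiency differences between long and short targets beyond the hairpin
  suppression threshold.
* The reagent mixture, polymerase choice and product sequencing are out of
  scope; thermal-program temperatures are carried as metadata only.
* Imported primer tables that violate length/Tm windows produce warnings,
  not errors, so published sets load under stricter user configurations.
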