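"""Seeded synthetic-genome fixtures for walking simulations.

A fixture emulates the situation the walking protocol faces on a real genome:
a known region (from which a compliant primer set is designed) abutting an
unknown flank into which qualifying partial-annealing sites for the tier-I
outer primer are planted at configured distances.  Default distances span the
regime reported for walking experiments (products roughly 0.4-8.0 kb from the
known/unknown junction).

Because a ~25-nt primer allowed up to 60% mismatches finds chance qualifying
sites on random sequence at an appreciable rate, the generator by default
*scrubs* the template: chance sites that would add unplanted exponential
products (for the outer primer within converging reach of a perfect site, or
for the semi primer on the strands the secondary round copies) are disabled
by point mutations outside every planted footprint.  This makes the planted
truth an exact prediction of the simulator's target set.  Scrubbing can be
switched off for background-realism studies.

Optional adversarial decoys:

* ``perfect-duplicate`` — a full perfect binding site on the opposite strand;
  it legitimately yields an extra exponential product (both termini perfect).
* ``partial-partial`` — a converging pair of qualifying partial sites placed
  beyond converging reach of any perfect site; candidates between them must
  be classed nontarget.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field, replace

from .annealing import PartialAnnealingModel, scan_partial_sites, scan_strand
from .design import (
    DesignConfig,
    DesignError,
    PrimerSet,
    build_primer_set,
    write_primer_tsv,
)
from .seqcore import GenomicInterval, NucleotideSequence, revcomp, write_bed, write_fasta
from .thermo import ThermoConfig

__all__ = [
    "PlantedSite",
    "Decoy",
    "SyntheticGenomeSpec",
    "TruthFeature",
    "WalkFixture",
    "generate_walk_fixture",
    "FixtureError",
]

_BASES = "ACGT"


class FixtureError(RuntimeError):
    """Raised when planted features cannot be reconciled on the template."""


@dataclass(frozen=True)
class PlantedSite:
    """One qualifying partial-annealing site for the tier-I outer primer.

    ``distance`` is measured from the known/unknown junction to the 5'-most
    base of the site's footprint in plus-strand coordinates; the site sits on
    the minus strand so that extension converges back toward the known
    region.  ``total_matches`` excludes no column but must leave the base
    just past the 3' run mismatched, so the run length is exact; ``None``
    resolves to two matches above the model's floor for the primer's length.
    """

    distance: int
    total_matches: int | None = None
    three_prime_run: int = 4


@dataclass(frozen=True)
class Decoy:
    kind: str  # perfect-duplicate | partial-partial
    distance: int
    total_matches: int = 12
    three_prime_run: int = 3
    gap: int = 300  # partial-partial only: distance between the paired sites

    def __post_init__(self) -> None:
        if self.kind not in ("perfect-duplicate", "partial-partial"):
            raise ValueError(f"unknown decoy kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    genome_length: int = 12_000
    seed: int = 0
    junction: int = 1_500
    sites: tuple[PlantedSite, ...] = (PlantedSite(1_500, None, 4), PlantedSite(8_000, None, 3))
    decoys: tuple[Decoy, ...] = ()
    suppression_threshold: int = 200
    extension_ceiling: int = 10_000
    scrub: bool = True
    contig_name: str = "synth"

    def __post_init__(self) -> None:
        if self.junction >= self.genome_length:
            raise ValueError("junction must lie inside the genome")
        for s in self.sites:
            if self.junction + s.distance >= self.genome_length:
                raise ValueError(
                    f"planted site at distance {s.distance} falls off the genome"
                )


@dataclass(frozen=True)
class TruthFeature:
    kind: str  # planted-site | outer-anchor | inner-anchor | decoy-*
    interval: GenomicInterval
    amplicon_class: str = "nontarget-unamplifiable"
    expected_primary_length: int | None = None
    expected_secondary_length: int | None = None
    total_matches: int | None = None
    three_prime_run: int | None = None

    @property
    def name(self) -> str:
        return self.kind


@dataclass
class WalkFixture:
    template: NucleotideSequence
    known_region: NucleotideSequence
    primer_set: PrimerSet
    truth: list[TruthFeature]
    spec: SyntheticGenomeSpec
    model: PartialAnnealingModel

    def planted_truth(self) -> list[TruthFeature]:
        return [t for t in self.truth if t.kind == "planted-site"]

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "template": os.path.join(out_dir, "template.fasta"),
            "truth": os.path.join(out_dir, "truth.bed"),
            "primers": os.path.join(out_dir, "primers.tsv"),
        }
        write_fasta([self.template], paths["template"])
        write_bed(self.truth, paths["truth"])
        write_primer_tsv(self.primer_set.all_records(), paths["primers"])
        return paths


def _plant(
    genome: list[str],
    primer: str,
    start: int,
    orientation: str,
    matches: int | None,
    run3: int,
    rng: random.Random,
    model: PartialAnnealingModel,
) -> int:
    """Write a partial site footprint into the genome.

    Orientation '-' anchors the primer 3' end at ``start`` (column 0 of the
    footprint); orientation '+' anchors it at ``start + L - 1``.
    """
    L = len(primer)
    if not model.min_3prime_run <= run3 < L:
        raise ValueError(f"3' run {run3} invalid for a {L}-nt primer")
    if matches is None:
        matches = min(max(run3, model.min_matches_for(L)) + 2, L - 1)
    if not max(run3, model.min_matches_for(L)) <= matches <= L - 1:
        raise ValueError(
            f"planted matches {matches} cannot satisfy the annealing model "
            f"(floor {model.min_matches_for(L)}) while keeping the site imperfect"
        )
    target = revcomp(primer) if orientation == "-" else primer
    # column c pairs the primer 3' terminus at c=0 ('-') or c=L-1 ('+')
    cols = list(range(L)) if orientation == "-" else list(range(L - 1, -1, -1))
    match_cols = set(cols[:run3])
    pool = cols[run3 + 1 :]  # skip the run-terminating column
    match_cols.update(rng.sample(pool, matches - run3))
    for c in range(L):
        want = target[c]
        if c in match_cols:
            genome[start + c] = want
        else:
            choices = [b for b in _BASES if b != want]
            genome[start + c] = rng.choice(choices)
    return matches


def _reserve(occupied: list[tuple[int, int]], start: int, end: int, what: str) -> None:
    for a, b in occupied:
        if start < b and a < end:
            raise FixtureError(
                f"planted features overlap irreconcilably: {what} at [{start}, {end}) "
                f"collides with [{a}, {b})"
            )
    occupied.append((start, end))


def generate_walk_fixture(
    spec: SyntheticGenomeSpec,
    model: PartialAnnealingModel | None = None,
    design_cfg: DesignConfig | None = None,
    thermo_cfg: ThermoConfig | None = None,
) -> WalkFixture:
    """Seeded random genome + designed primer set + planted ground truth.

    Deterministic: the same spec yields a byte-identical template.  When
    scrubbing cannot reconcile a chance site buried inside protected primer
    anchors, the whole fixture is regenerated from a derived seed (bounded
    retries) before giving up.
    """
    model = model or PartialAnnealingModel()
    thermo_cfg = thermo_cfg or ThermoConfig()
    last: FixtureError | None = None
    for attempt in range(6):
        rng = random.Random(f"{spec.seed}:{attempt}")
        try:
            return _generate_once(spec, model, design_cfg, thermo_cfg, rng, attempt)
        except _ScrubFailure as exc:
            last = exc
    raise FixtureError(f"fixture generation failed after retries: {last}")


class _ScrubFailure(FixtureError):
    """Internal: a chance site could not be reconciled; retry with a new seed."""


def _generate_once(
    spec: SyntheticGenomeSpec,
    model: PartialAnnealingModel,
    design_cfg: DesignConfig | None,
    thermo_cfg: ThermoConfig,
    rng: random.Random,
    base_attempt: int,
) -> WalkFixture:
    design_cfg = replace(design_cfg or DesignConfig(), seed=spec.seed + 31 * base_attempt)
    genome = [rng.choice(_BASES) for _ in range(spec.genome_length)]

    # --- design a compliant primer set on the known region -----------------
    primer_set = None
    for attempt in range(10):
        known = NucleotideSequence("".join(genome[: spec.junction]), "known")
        try:
            primer_set = build_primer_set(
                known, "downstream",
                replace(design_cfg, seed=design_cfg.seed + attempt),
                thermo_cfg, gene="walk",
            )
            break
        except DesignError:
            genome[: spec.junction] = [rng.choice(_BASES) for _ in range(spec.junction)]
    if primer_set is None:
        raise FixtureError("could not design a compliant primer set on the known region")

    outer, semi = primer_set.pair("I")
    inner = primer_set.inner
    P = outer.bases
    L = len(P)
    s = outer.anchor.start
    i_start = inner.anchor.start
    contig = spec.contig_name

    # protect only the primer anchor footprints: the rest of the known region
    # may be point-mutated by the scrubber without touching any design rule
    occupied: list[tuple[int, int]] = []
    planted_partials: dict[int, tuple[str, int, int]] = {}
    for rec in (*primer_set.outers, inner):
        # alternative outer tiers may overlap one another; no collision check
        occupied.append((rec.anchor.start, rec.anchor.end))
    truth: list[TruthFeature] = [
        TruthFeature("outer-anchor", GenomicInterval(contig, s, s + L, "+")),
        TruthFeature(
            "inner-anchor",
            GenomicInterval(contig, i_start, i_start + len(inner), "+"),
        ),
    ]

    # --- plant the qualifying sites ----------------------------------------
    for site in spec.sites:
        q = spec.junction + site.distance
        _reserve(occupied, q, q + L, "planted site")
        matches = _plant(
            genome, P, q, "-", site.total_matches, site.three_prime_run, rng, model
        )
        planted_partials[q] = ("-", matches, site.three_prime_run)
        span = (q + L) - s
        reachable = span <= spec.extension_ceiling
        klass = (
            "nontarget-unamplifiable"
            if not reachable
            else ("suppressed-short" if span < spec.suppression_threshold else "target")
        )
        truth.append(
            TruthFeature(
                "planted-site",
                GenomicInterval(contig, q, q + L, "-"),
                amplicon_class=klass,
                expected_primary_length=span if reachable else None,
                expected_secondary_length=(q - i_start) + len(semi) if reachable else None,
                total_matches=matches,
                three_prime_run=site.three_prime_run,
            )
        )

    for decoy in spec.decoys:
        q = spec.junction + decoy.distance
        if decoy.kind == "perfect-duplicate":
            _reserve(occupied, q, q + L, "perfect duplicate")
            rc = revcomp(P)
            for c in range(L):
                genome[q + c] = rc[c]
            truth.append(
                TruthFeature(
                    "decoy-perfect-duplicate",
                    GenomicInterval(contig, q, q + L, "-"),
                    amplicon_class="target",
                    expected_primary_length=(q + L) - s,
                )
            )
        else:  # partial-partial converging pair, out of reach of perfect sites
            if (q + decoy.gap + 2 * L) - s <= spec.extension_ceiling:
                raise FixtureError(
                    "partial-partial decoy lies within converging reach of the "
                    "perfect site and would form a genuine product; place it "
                    "beyond the extension ceiling"
                )
            q2 = q + L + decoy.gap
            _reserve(occupied, q, q + L, "decoy partial (+)")
            _reserve(occupied, q2, q2 + L, "decoy partial (-)")
            _plant(genome, P, q, "+", decoy.total_matches, decoy.three_prime_run, rng, model)
            _plant(genome, P, q2, "-", decoy.total_matches, decoy.three_prime_run, rng, model)
            planted_partials[q] = ("+", decoy.total_matches, decoy.three_prime_run)
            planted_partials[q2] = ("-", decoy.total_matches, decoy.three_prime_run)
            truth.append(
                TruthFeature(
                    "decoy-partial-pair",
                    GenomicInterval(contig, q, q2 + L, "+"),
                    amplicon_class="nontarget-unamplifiable",
                )
            )

    protected = {p for a, b in occupied for p in range(a, b)}

    if spec.scrub:
        _scrub(genome, primer_set, spec, model, protected, rng, planted_partials)

    template = NucleotideSequence("".join(genome), contig)
    return WalkFixture(template, NucleotideSequence(template.bases[: spec.junction], "known"),
                       primer_set, truth, spec, model)


def _scrub(
    genome: list[str],
    primer_set: PrimerSet,
    spec: SyntheticGenomeSpec,
    model: PartialAnnealingModel,
    protected: set[int],
    rng: random.Random,
    planted_partials: dict[int, tuple[str, int, int]] | None = None,
) -> None:
    """Point-mutate chance sites that would add unplanted exponential products.

    A chance site that overlaps a planted partial footprint so heavily that it
    cannot be broken outside the protected bases is resolved by re-planting
    that site with a fresh random match pattern (same statistics)."""
    planted_partials = planted_partials or {}
    outer, semi = primer_set.pair("I")
    inner = primer_set.inner
    P, S, I = outer.bases, semi.bases, inner.bases
    L, LI = len(P), len(I)
    s = outer.anchor.start
    i_start = inner.anchor.start
    contig = spec.contig_name

    planted_minus = {
        spec.junction + st.distance for st in spec.sites
    } | {
        spec.junction + d.distance
        for d in spec.decoys
        if d.kind == "perfect-duplicate"
    }

    def break_site(start: int, anchor_cols: list[int], target: str) -> bool:
        """Mutate the first unprotected anchored column so the site no longer
        qualifies; fall back to eroding matched columns below the floor."""
        for c in anchor_cols[: model.min_3prime_run]:
            pos = start + c
            if pos not in protected:
                want = target[c]
                genome[pos] = rng.choice([b for b in _BASES if b != want])
                return True
        # anchor protected: erode unprotected matched columns until the site
        # no longer satisfies the annealing model (run and totals re-checked)
        def still_qualifies() -> bool:
            cols = [genome[start + c] == target[c] for c in range(len(target))]
            run = 0
            for ok in cols:
                if not ok:
                    break
                run += 1
            return model.qualifies(sum(cols), run, len(target))

        matched = [c for c in range(len(target)) if genome[start + c] == target[c]]
        for c in matched:
            pos = start + c
            if pos in protected:
                continue
            genome[pos] = rng.choice([b for b in _BASES if b != target[c]])
            if not still_qualifies():
                return True
        # stubborn overlap with a planted partial footprint: re-plant it
        P_len = len(P)
        for pstart, (orient, m, r3) in planted_partials.items():
            if start < pstart + P_len and pstart < start + len(target):
                _plant(genome, P, pstart, orient, m, r3, rng, model)
                return True
        return False

    rc_p = revcomp(P)
    for _round in range(30):
        dirty = False
        template = NucleotideSequence("".join(genome), contig)
        sites = scan_partial_sites(outer, template, model)
        perfect_plus = [x for x in sites if x.perfect and x.interval.strand == "+"]
        perfect_minus = [x for x in sites if x.perfect and x.interval.strand == "-"]
        # chance '-' sites within converging reach of a perfect '+' site
        for x in sites:
            if x.interval.strand != "-" or x.interval.start in planted_minus or x.perfect:
                continue
            if any(
                pp.interval.end <= x.interval.start
                and x.interval.end - pp.interval.start <= spec.extension_ceiling
                for pp in perfect_plus
            ):
                if not break_site(x.interval.start, [0, 1], rc_p):
                    raise _ScrubFailure("cannot scrub a chance site overlapping planted features")
                dirty = True
        # chance '+' sites feeding a planted perfect duplicate
        for x in sites:
            if x.interval.strand != "+" or x.perfect:
                continue
            if any(
                x.interval.end <= pm.interval.start
                and pm.interval.end - x.interval.start <= spec.extension_ceiling
                for pm in perfect_minus
            ):
                if not break_site(x.interval.start, [L - 1, L - 2], P):
                    raise _ScrubFailure("cannot scrub a chance site overlapping planted features")
                dirty = True
        # chance semi-primer sites on the strands the secondary round copies
        tmpl = template.bases
        for q in sorted(planted_minus):
            span = (q + L) - s
            if span > spec.extension_ceiling:
                continue
            ssdna_i = tmpl[i_start:q] + rc_p
            terminus = q - i_start
            for hit in scan_strand(S, ssdna_i, model):
                if hit.start == terminus:
                    continue
                if hit.start < LI:
                    # mirror the simulator: only the palindromic-coincidence
                    # case keeps a perfect inner terminus on the short copy
                    cand = S + revcomp(ssdna_i[: hit.start])
                    if not cand.endswith(revcomp(I)):
                        continue
                start = i_start + hit.start  # genomic anchor of the semi footprint
                if start in planted_minus:
                    # anchored exactly at another planted site: the product it
                    # primes is that walk's own product (same sequence)
                    continue
                if not break_site(start, [0, 1], revcomp(S)):
                    raise _ScrubFailure("cannot scrub a chance semi site")
                dirty = True
        if not dirty:
            return
    raise _ScrubFailure("scrubbing did not converge; planted features too dense")
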