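"""Two-round walking-PCR logic: classify candidate products on a template.

The scheme's specificity argument, which this module encodes analytically:

* **Primary round** (single outer site-specific primer).  Stringent cycles
  only let the primer prime at perfect sites, accumulating single-stranded
  copies of the region downstream of each such site.  In the single
  low-stringency cycle the primer may partially anneal anywhere the
  :class:`~sspcr.annealing.PartialAnnealingModel` allows — on genomic strands
  and on those nascent strands.  A candidate amplicon is *target* only when it
  runs from a perfect site through a qualifying partial site on the strand
  synthesized from that perfect site: extension back through the complete
  perfect footprint is what stamps a perfect primer-binding site onto the new
  strand's 3' end and makes the duplex exponentially amplifiable.  Both
  termini of such a product carry the primer (as a terminal inverted repeat),
  which lets short products fold into hairpins; products below the
  suppression threshold are therefore reclassified ``suppressed-short``.
  Partial-partial site pairs never gain a perfect terminus and are classed
  ``nontarget-unamplifiable``.

* **Secondary round** (inner site-specific primer + semi-site-specific
  primer).  Stringent cycles extend from perfect inner-primer sites on
  primary products.  In the single reduced-stringency cycle the semi primer —
  whose 3' terminal bases equal the outer primer's — partially anneals on the
  inner-primed strand, by construction at the outer-primer terminus of
  genuine products.  Extension back through the inner primer stamps a perfect
  inner site onto the new strand, giving a product flanked by perfect inner
  and semi sites: exponential.  Everything else stays single-stranded.

Copy-number bookkeeping is qualitative (exponential vs linear); annealing
temperatures on the thermal program are reporting metadata, the stringency
class alone drives behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annealing import (
    AnnealingSite,
    PartialAnnealingModel,
    StrandHit,
    scan_partial_sites,
    scan_perfect_sites,
    scan_strand,
)
from .design import PrimerRecord, longest_common_3prime_suffix
from .seqcore import GenomicInterval, NucleotideSequence, revcomp

__all__ = [
    "Stage",
    "ThermalProgram",
    "ProgramError",
    "OverlapMismatchError",
    "default_primary_program",
    "default_secondary_program",
    "SsDnaRecord",
    "AmpliconPrediction",
    "PrimaryResult",
    "run_primary",
    "run_secondary",
    "band_report",
    "BandReport",
    "TARGET",
    "SUPPRESSED",
    "NONTARGET",
    "canonical_duplex",
]

TARGET = "target"
SUPPRESSED = "suppressed-short"
NONTARGET = "nontarget-unamplifiable"

_RELAXED = ("low", "reduced")
_STRINGENT = ("high", "moderate-high")


class ProgramError(RuntimeError):
    """Raised when a thermal program violates the scheme's invariants."""


class OverlapMismatchError(RuntimeError):
    """Raised when the semi primer does not overlap the outer primer used in
    the primary round — the scheme's keystone constraint."""


@dataclass(frozen=True)
class Stage:
    stringency: str
    cycles: int
    anneal_c: float  # reporting metadata only

    def __post_init__(self) -> None:
        if self.stringency not in _RELAXED + _STRINGENT:
            raise ProgramError(f"unknown stringency class {self.stringency!r}")
        if self.cycles <= 0:
            raise ProgramError("cycle counts must be positive")


@dataclass(frozen=True)
class ThermalProgram:
    """Ordered stages of (stringency class, cycle count) plus the extension
    ceiling (maximum synthesisable product length, default 10 kb)."""

    stages: tuple[Stage, ...]
    extension_ceiling: int = 10_000

    def __post_init__(self) -> None:
        relaxed = [s for s in self.stages if s.stringency in _RELAXED]
        if len(relaxed) > 1:
            raise ProgramError("at most one relaxed-stringency stage per program")
        if any(s.cycles != 1 for s in relaxed):
            raise ProgramError("the relaxed-stringency stage must run exactly one cycle")
        if self.extension_ceiling <= 0:
            raise ProgramError("extension ceiling must be positive")

    @property
    def relaxed_stage(self) -> Stage | None:
        for s in self.stages:
            if s.stringency in _RELAXED:
                return s
        return None

    def as_dict(self) -> dict:
        return {
            "stages": [
                {"stringency": s.stringency, "cycles": s.cycles, "anneal_c": s.anneal_c}
                for s in self.stages
            ],
            "extension_ceiling": self.extension_ceiling,
        }


def default_primary_program(extension_ceiling: int = 10_000) -> ThermalProgram:
    """Five moderate-high-stringency cycles, one low-stringency cycle, then
    twenty-five moderate-high-stringency cycles (annealing 60/25/60 degC)."""
    return ThermalProgram(
        (
            Stage("moderate-high", 5, 60.0),
            Stage("low", 1, 25.0),
            Stage("moderate-high", 25, 60.0),
        ),
        extension_ceiling,
    )


def default_secondary_program(extension_ceiling: int = 10_000) -> ThermalProgram:
    """Five high-stringency cycles, one reduced-stringency cycle, then
    twenty-five high-stringency cycles (annealing 65/40/65 degC)."""
    return ThermalProgram(
        (
            Stage("high", 5, 65.0),
            Stage("reduced", 1, 40.0),
            Stage("high", 25, 65.0),
        ),
        extension_ceiling,
    )


@dataclass(frozen=True)
class SsDnaRecord:
    """A single-stranded extension product; its 5' end is the priming primer."""

    origin: GenomicInterval
    site: AnnealingSite
    stage: str
    primer: PrimerRecord
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and not self.sequence.startswith(self.primer.bases):
            raise ValueError("ssDNA 5' terminus must equal the priming primer")


@dataclass(frozen=True)
class AmpliconPrediction:
    """One predicted product with coordinates and amplifiability class.

    ``sequence`` is the strand written 5'->3' starting with the left terminal
    primer; ``length`` equals ``len(sequence)`` for products with sequences
    and may exceed the genomic interval span when an incorporated primer tail
    (the semi primer's heterologous 5' part) overhangs the template.
    """

    interval: GenomicInterval
    length: int
    left_primer: PrimerRecord
    right_primer: PrimerRecord
    round: str  # primary | secondary
    amplicon_class: str
    tir_length: int = 0
    sequence: str | None = None
    site: AnnealingSite | None = None

    @property
    def name(self) -> str:
        return f"{self.round}:{self.amplicon_class}:{self.length}bp"


def canonical_duplex(seq: str) -> str:
    """Orientation-independent key for a double-stranded product."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def terminal_inverted_repeat(seq: str) -> int:
    """Longest t with seq[:t] reverse-complementary to seq[-t:]."""
    rc = revcomp(seq)
    t = 0
    limit = len(seq) // 2
    while t < limit and seq[t] == rc[t]:
        t += 1
    return t


@dataclass
class PrimaryResult:
    products: list[AmpliconPrediction]
    ssdna: list[SsDnaRecord]
    sites: list[AnnealingSite]
    warning: str | None = None

    @property
    def targets(self) -> list[AmpliconPrediction]:
        return [p for p in self.products if p.amplicon_class == TARGET]

    def amplifiable(self) -> list[AmpliconPrediction]:
        """Products that amplify exponentially regardless of the hairpin
        suppression overlay (target plus suppressed-short)."""
        return [p for p in self.products if p.amplicon_class in (TARGET, SUPPRESSED)]


def _require_relaxed(program: ThermalProgram, expected: str, round_name: str) -> bool:
    st = program.relaxed_stage
    if st is None:
        return False  # stringent-only ablation run: perfect sites only
    if st.stringency != expected:
        raise ProgramError(
            f"{round_name} round expects a {expected!r} relaxed stage, got {st.stringency!r}"
        )
    return True


def run_primary(
    template: NucleotideSequence,
    outer: PrimerRecord,
    program: ThermalProgram | None = None,
    model: PartialAnnealingModel | None = None,
    suppression_threshold: int = 200,
    enumerate_background: bool = True,
) -> PrimaryResult:
    """Predict the outcome of the single-primer primary round on a template."""
    program = program or default_primary_program()
    model = model or PartialAnnealingModel()
    relaxed = _require_relaxed(program, "low", "primary")
    if outer.role != "outer":
        raise ValueError(f"primary round is driven by an outer primer, got {outer.role!r}")

    P = outer.bases
    L = len(P)
    T = template.bases
    N = len(T)
    ceiling = program.extension_ceiling
    contig = template.name or "template"

    perfect = scan_perfect_sites(outer, template)
    sites = scan_partial_sites(outer, template, model) if relaxed else perfect

    ssdna: list[SsDnaRecord] = []
    for ps in perfect:
        if ps.interval.strand == "+":
            s = ps.interval.start
            ext_end = min(N, s + ceiling)
            origin = GenomicInterval(contig, s, ext_end, "+")
        else:
            e = ps.interval.end
            ext_start = max(0, e - ceiling)
            origin = GenomicInterval(contig, ext_start, e, "-")
        ssdna.append(SsDnaRecord(origin, ps, "stringent-pre", outer))

    if not perfect:
        return PrimaryResult(
            [], ssdna, sites,
            warning=f"primer {outer.name!r} has no perfect site on {contig!r}: walking fails",
        )

    plus = [s for s in sites if s.interval.strand == "+"]
    minus = [s for s in sites if s.interval.strand == "-"]

    products: list[AmpliconPrediction] = []
    seen: set[str] = set()

    def classify(length: int) -> str:
        return SUPPRESSED if length < suppression_threshold else TARGET

    def suffix_self_rc(j: int) -> bool:
        """Extension through a partial footprint that overlaps the perfect
        footprint regenerates a perfect terminus only when the primer suffix
        across the overlap is its own reverse complement (the self-priming
        palindromic short-product artifact)."""
        tail = P[j:]
        return tail == revcomp(tail)

    def add_target(a: AnnealingSite, b: AnnealingSite, anchor: AnnealingSite) -> None:
        # a on '+', b on '-', extension converging, span <= ceiling
        span = b.interval.end - a.interval.start
        if a.perfect:
            seq = T[a.interval.start : b.interval.start] + revcomp(P)
            strand = "+"
        else:
            seq = revcomp(T[a.interval.end : b.interval.end]) + revcomp(P)
            strand = "-"
        key = canonical_duplex(seq)
        if key in seen:
            return
        seen.add(key)
        products.append(
            AmpliconPrediction(
                interval=GenomicInterval(contig, a.interval.start, b.interval.end, strand),
                length=span,
                left_primer=outer,
                right_primer=outer,
                round="primary",
                amplicon_class=classify(span),
                tir_length=terminal_inverted_repeat(seq),
                sequence=seq,
                site=anchor,
            )
        )

    for a in plus:
        for b in minus:
            if b.interval.end - a.interval.start > ceiling:
                continue
            if a.perfect and b.interval.start >= a.interval.start:
                j = b.interval.start - a.interval.start
                if j >= L or suffix_self_rc(j):
                    add_target(a, b, b)
                continue
            if b.perfect and b.interval.end >= a.interval.end:
                j = b.interval.end - a.interval.end
                if j >= L or suffix_self_rc(j):
                    add_target(a, b, a)
                continue
            if b.interval.start < a.interval.end:
                continue  # overlapping partial-partial pairs cannot converge
            if not a.perfect and not b.perfect and enumerate_background:
                products.append(
                    AmpliconPrediction(
                        interval=GenomicInterval(
                            contig, a.interval.start, b.interval.end, "+"
                        ),
                        length=b.interval.end - a.interval.start,
                        left_primer=outer,
                        right_primer=outer,
                        round="primary",
                        amplicon_class=NONTARGET,
                    )
                )

    warning = None
    if not any(p.amplicon_class in (TARGET, SUPPRESSED) for p in products):
        warning = "no qualifying partial site converges with a perfect site: walking fails"
    return PrimaryResult(products, ssdna, sites, warning)


def run_secondary(
    primary_products: Sequence[AmpliconPrediction],
    inner: PrimerRecord,
    semi: PrimerRecord,
    program: ThermalProgram | None = None,
    model: PartialAnnealingModel | None = None,
    overlap_length: int = 10,
    enumerate_background: bool = True,
) -> list[AmpliconPrediction]:
    """Predict the nested secondary round on the primary product pool.

    Only exponentially amplified primary products (class target) carry enough
    template into the secondary reaction to matter; suppressed and non-target
    ones are ignored.  Raises :class:`OverlapMismatchError` when the semi
    primer's 3' part does not overlap the outer primer that generated a
    product, and ``ValueError`` for an empty primary input.
    """
    program = program or default_secondary_program()
    model = model or PartialAnnealingModel()
    relaxed = _require_relaxed(program, "reduced", "secondary")
    if inner.role != "inner" or semi.role != "semi":
        raise ValueError("secondary round needs an inner and a semi primer")
    if not primary_products:
        raise ValueError("empty primary input: nothing to re-amplify")

    I, S = inner.bases, semi.bases
    LI, LS = len(I), len(S)
    ceiling = program.extension_ceiling

    out: list[AmpliconPrediction] = []
    seen: set[str] = set()
    for prod in primary_products:
        if prod.amplicon_class != TARGET or prod.sequence is None:
            continue
        ov = longest_common_3prime_suffix(S, prod.left_primer.bases)
        if ov != overlap_length:
            raise OverlapMismatchError(
                f"semi primer {semi.name!r} shares a {ov}-nt 3' overlap with outer "
                f"{prod.left_primer.name!r}; the scheme requires exactly {overlap_length}"
            )
        U = prod.sequence
        for strand_seq, forward in ((revcomp(U), True), (U, False)):
            # perfect inner sites: inner anneals to this strand, extension
            # copies the strand 5' of the footprint
            for hit in scan_strand(I, strand_seq, None):
                ssdna_i = I + revcomp(strand_seq[: hit.start])
                semi_hits = scan_strand(S, ssdna_i, model if relaxed else None)
                for sh in semi_hits:
                    if sh.start < LI:
                        # extension normally must run through the inner primer;
                        # a shorter copy keeps a perfect inner terminus only in
                        # the palindromic-coincidence case
                        cand = S + revcomp(ssdna_i[: sh.start])
                        if not cand.endswith(revcomp(I)):
                            continue
                    if LS + sh.start > ceiling:
                        continue
                    seq = ssdna_i[: sh.start] + revcomp(S)  # inner-first orientation
                    key = canonical_duplex(seq)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        AmpliconPrediction(
                            interval=_secondary_interval(
                                prod, hit, sh, forward, len(U), LI, LS
                            ),
                            length=LS + sh.start,
                            left_primer=inner,
                            right_primer=semi,
                            round="secondary",
                            amplicon_class=TARGET,
                            tir_length=terminal_inverted_repeat(seq),
                            sequence=seq,
                        )
                    )
            if enumerate_background and relaxed:
                # semi partial events on the duplex strands themselves: the new
                # strand's 3' end copies the template's 5' terminus, which no
                # secondary-round primer matches perfectly -> never converted
                for sh in scan_strand(S, strand_seq, model):
                    out.append(
                        AmpliconPrediction(
                            interval=prod.interval,
                            length=min(LS + sh.start, ceiling),
                            left_primer=semi,
                            right_primer=prod.left_primer,
                            round="secondary",
                            amplicon_class=NONTARGET,
                        )
                    )
    return out


def _secondary_interval(
    prod: AmpliconPrediction,
    inner_hit: StrandHit,
    semi_hit: StrandHit,
    forward: bool,
    ulen: int,
    LI: int,
    LS: int,
) -> GenomicInterval:
    """Genomic footprint of a secondary product (tails clipped to the primary
    product's interval)."""
    iv = prod.interval
    if forward and iv.strand == "+":
        d = ulen - inner_hit.start - LI  # offset of the inner primer on U
        start = iv.start + d
        end = min(iv.start + d + semi_hit.start + LS, iv.end)
        if start < end:
            return GenomicInterval(iv.contig, start, end, "+")
    if forward and iv.strand == "-":
        d = ulen - inner_hit.start - LI
        end = iv.end - d
        start = max(iv.end - d - semi_hit.start - LS, iv.start)
        if start < end:
            return GenomicInterval(iv.contig, start, end, "-")
    return iv  # chance orientations: report the primary footprint


@dataclass(frozen=True)
class BandReport:
    rows: tuple[dict, ...]
    n_target: int
    n_suppressed: int
    n_nontarget: int

    def sketch(self) -> str:
        """Text-art gel sketch: exponential bands ordered by length."""
        lines = ["lane: predicted products (top = largest)"]
        bands = [r for r in self.rows if r["class"] == TARGET]
        if not bands:
            lines.append("  (no exponentially amplified band)")
        for r in bands:
            lines.append(f"  {'=' * 12}  {r['length']} bp")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "bands": list(self.rows),
            "n_target": self.n_target,
            "n_suppressed": self.n_suppressed,
            "n_nontarget": self.n_nontarget,
        }


def band_report(products: Iterable[AmpliconPrediction]) -> BandReport:
    """Tabulate predicted products by length (descending); classes are
    preserved verbatim — no reclassification happens at reporting time."""
    prods = sorted(products, key=lambda p: -p.length)
    rows = tuple(
        {
            "length": p.length,
            "class": p.amplicon_class,
            "round": p.round,
            "left_primer": p.left_primer.name,
            "right_primer": p.right_primer.name,
            "contig": p.interval.contig,
            "start": p.interval.start,
            "end": p.interval.end,
        }
        for p in prods
    )
    return BandReport(
        rows,
        sum(p.amplicon_class == TARGET for p in prods),
        sum(p.amplicon_class == SUPPRESSED for p in prods),
        sum(p.amplicon_class == NONTARGET for p in prods),
    )


# re-exported here because fixtures are part of the simulation surface
from .fixture import SyntheticGenomeSpec, WalkFixture, generate_walk_fixture  # noqa: E402,F401

__all__ += ["SyntheticGenomeSpec", "WalkFixture", "generate_walk_fixture"]
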