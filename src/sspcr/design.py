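"""Construction and validation of semi-site-specific primer sets.

A walking set for one gene comprises:

* three *outer* site-specific primers (tiers I-III) selected from the known
  region, each oriented so extension proceeds toward the unknown flank;
* one *inner* site-specific primer nested between every outer primer and the
  known/unknown junction;
* one *semi-site-specific* primer per outer primer, whose 3' terminal
  ``overlap_length`` bases (default 10) are identical to its partner outer
  primer's 3' terminus while the 5' remainders of the two are heterologous
  (operationalised as sharing no k-mer of length >= ``heterology_kmer``).

The outer primer drives the single-primer primary PCR; the semi primer pairs
with the inner primer in the secondary PCR, where its short 3' overlap lets
it prime at the outer-primer terminus of genuine primary products only.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

from .seqcore import GenomicInterval, NucleotideSequence, revcomp
from . import thermo as _thermo
from .thermo import ThermoConfig, _longest_common_substring, _longest_suffix_in

__all__ = [
    "PrimerRecord",
    "PrimerSet",
    "DesignConfig",
    "DesignError",
    "TableFormatError",
    "longest_common_3prime_suffix",
    "select_site_specific_primers",
    "design_semi_primer",
    "build_primer_set",
    "validate_primer_table",
    "ValidationReport",
    "CheckResult",
    "load_primer_tsv",
    "write_primer_tsv",
    "bundled_primers",
]


class DesignError(RuntimeError):
    """Raised when a design constraint cannot be satisfied."""


class TableFormatError(ValueError):
    """Raised for malformed primer tables (missing role/tier/columns)."""


@dataclass(frozen=True)
class PrimerRecord:
    """One oligo with its role in the walking scheme.

    ``anchor`` is the binding interval within the known region; it is absent
    for imported primers and covers only the 3' overlap's source window
    conceptually for semi primers (whose 5' part is heterologous).
    """

    name: str
    gene: str
    role: str  # outer | inner | semi
    tier: str  # I | II | III | ""
    sequence: NucleotideSequence
    anchor: GenomicInterval | None = None
    partner: str | None = None  # designated partner outer primer (semi only)
    imported: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("outer", "inner", "semi"):
            raise TableFormatError(f"primer {self.name!r}: unknown role {self.role!r}")
        if self.role == "semi" and self.tier not in ("I", "II", "III"):
            raise TableFormatError(
                f"semi primer {self.name!r} must carry a tier (I/II/III)"
            )
        if self.role == "outer" and self.tier not in ("I", "II", "III"):
            raise TableFormatError(
                f"outer primer {self.name!r} must carry a tier (I/II/III)"
            )
        if not self.imported and not 20 <= len(self.sequence) <= 30:
            raise ValueError(
                f"primer {self.name!r} length {len(self.sequence)} outside [20, 30]"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def bases(self) -> str:
        return self.sequence.bases


@dataclass(frozen=True)
class PrimerSet:
    gene: str
    outers: tuple[PrimerRecord, PrimerRecord, PrimerRecord]
    inner: PrimerRecord
    semis: tuple[PrimerRecord, PrimerRecord, PrimerRecord]
    direction: str  # upstream | downstream

    def __post_init__(self) -> None:
        if self.direction not in ("upstream", "downstream"):
            raise ValueError(f"direction must be upstream/downstream, got {self.direction!r}")

    def all_records(self) -> list[PrimerRecord]:
        return [*self.outers, self.inner, *self.semis]

    def pair(self, tier: str) -> tuple[PrimerRecord, PrimerRecord]:
        """(outer, semi) pair for a tier."""
        o = next(p for p in self.outers if p.tier == tier)
        s = next(p for p in self.semis if p.tier == tier)
        return o, s


@dataclass(frozen=True)
class DesignConfig:
    """Every numeric design constraint, with the published defaults."""

    overlap_length: int = 10
    overlap_tm_window: tuple[float, float] = (20.0, 40.0)
    primer_tm_window: tuple[float, float] = (60.0, 65.0)
    primer_length_window: tuple[int, int] = (20, 30)
    heterology_kmer: int = 5
    seed: int = 0
    retry_budget: int = 10_000
    tier_spacing: int = 5  # minimum start-to-start spacing between outer tiers
    junction_margin: int = 0  # bases the inner primer must keep clear of the junction

    def __post_init__(self) -> None:
        lo, hi = self.overlap_tm_window
        plo, phi = self.primer_tm_window
        llo, lhi = self.primer_length_window
        if not (lo < hi and plo < phi and llo < lhi):
            raise ValueError("config windows must be well-ordered")
        if self.overlap_length >= llo:
            raise ValueError("overlap_length must be below the primer length window")

    def as_dict(self) -> dict:
        return {
            "overlap_length": self.overlap_length,
            "overlap_tm_window": list(self.overlap_tm_window),
            "primer_tm_window": list(self.primer_tm_window),
            "primer_length_window": list(self.primer_length_window),
            "heterology_kmer": self.heterology_kmer,
            "seed": self.seed,
            "retry_budget": self.retry_budget,
            "tier_spacing": self.tier_spacing,
            "junction_margin": self.junction_margin,
        }


def longest_common_3prime_suffix(
    a: NucleotideSequence | str, b: NucleotideSequence | str
) -> int:
    """Maximal L such that the last L bases of a equal the last L bases of b."""
    sa = a.bases if isinstance(a, NucleotideSequence) else str(a)
    sb = b.bases if isinstance(b, NucleotideSequence) else str(b)
    n = 0
    limit = min(len(sa), len(sb))
    while n < limit and sa[-1 - n] == sb[-1 - n]:
        n += 1
    return n


def _shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[j : j + k] in kmers for j in range(len(b) - k + 1))


# ---------------------------------------------------------------------------
# site-specific primer selection
# ---------------------------------------------------------------------------


def _passes_self_checks(bases: str, cfg: DesignConfig, th: ThermoConfig) -> tuple[bool, str]:
    tm = _thermo.tm_nearest_neighbor(bases, th)
    lo, hi = cfg.primer_tm_window
    if not lo <= tm <= hi:
        return False, f"Tm {tm:.2f} outside [{lo}, {hi}]"
    if not _thermo.hairpin_check(bases, th).passed:
        return False, "hairpin"
    if not _thermo.dimer_check(bases, bases, th).passed:
        return False, "self-dimer"
    return True, ""


def select_site_specific_primers(
    known_region: NucleotideSequence,
    direction: str,
    cfg: DesignConfig | None = None,
    th: ThermoConfig | None = None,
    gene: str = "gene",
):
    """Select three outer (tiers I-III) and one inner site-specific primer.

    All primers are taken from the strand whose 5'->3' reading extends toward
    the unknown flank: the plus strand of the known region for a downstream
    walk, its reverse complement for an upstream walk.  Candidates are ranked
    by closeness of their nearest-neighbor Tm to the window centre, ties
    broken by proximity to the junction, then by leftmost coordinate.  Outer
    primers must additionally carry a 3' terminal overlap window whose Wallace
    Tm lies in the configured overlap window, since the semi primer inherits
    that exact 10-mer.

    Returns ``(outers, inner)``; raises :class:`DesignError` when the region
    is too short or no window passes the filters.
    """
    cfg = cfg or DesignConfig()
    th = th or ThermoConfig()
    llo, lhi = cfg.primer_length_window
    region = known_region.bases
    n = len(region)
    if direction not in ("upstream", "downstream"):
        raise ValueError(f"direction must be upstream/downstream, got {direction!r}")
    if n < 4 * llo + cfg.junction_margin + 3 * cfg.tier_spacing:
        raise DesignError(
            f"region too short: {n} bp cannot host three outer primers and a nested "
            f"inner primer of >= {llo} nt each"
        )
    # Work on the extension strand; the junction sits at its right end.
    work = region if direction == "downstream" else revcomp(region)

    tm_lo, tm_hi = cfg.primer_tm_window
    tm_mid = 0.5 * (tm_lo + tm_hi)
    ov_lo, ov_hi = cfg.overlap_tm_window

    candidates: list[tuple[float, int, int, int, str]] = []
    rejects: dict[str, int] = {}

    def reject(reason: str) -> None:
        rejects[reason] = rejects.get(reason, 0) + 1

    for length in range(llo, lhi + 1):
        for start in range(0, n - length + 1):
            w = work[start : start + length]
            try:
                tm = _thermo.tm_nearest_neighbor(w, th)
            except ValueError:
                continue
            if not tm_lo <= tm <= tm_hi:
                reject("tm-window")
                continue
            if not _thermo.hairpin_check(w, th).passed:
                reject("hairpin")
                continue
            if not _thermo.dimer_check(w, w, th).passed:
                reject("self-dimer")
                continue
            end = start + length
            # rank: Tm centrality, then junction proximity (end near n), then leftmost
            candidates.append((abs(tm - tm_mid), n - end, start, length, w))
    if not candidates:
        raise DesignError(
            f"no window of {llo}-{lhi} nt passes the design filters; rejections: {rejects}"
        )
    candidates.sort()

    def interval(start: int, length: int) -> GenomicInterval:
        if direction == "downstream":
            return GenomicInterval(known_region.name or "known", start, start + length, "+")
        return GenomicInterval(
            known_region.name or "known", n - (start + length), n - start, "-"
        )

    overlap_ok = [
        c
        for c in candidates
        if ov_lo <= _thermo.tm_wallace(c[4][-cfg.overlap_length :]) <= ov_hi
    ]
    if not overlap_ok:
        raise DesignError("no candidate window has a compliant 3' overlap Tm")

    # Choose the inner primer first (best-ranked candidate that leaves room for
    # three spaced outer primers strictly 5' of it), then the outer tiers.
    for _, _, i_start, i_len, i_seq in candidates:
        i_end_limit = n - cfg.junction_margin
        if i_start + i_len > i_end_limit:
            continue
        rc_inner = revcomp(i_seq)
        outers: list[tuple[int, int, str]] = []
        for _, _, o_start, o_len, o_seq in overlap_ok:
            if o_start + o_len > i_start:
                continue  # nesting: outer anchors must lie 5' of the inner anchor
            # the semi primer inherits this outer's 3' overlap verbatim, so a
            # complementary run between that overlap and the inner primer can
            # never be sampled away; reject the combination up front
            overlap = o_seq[-cfg.overlap_length :]
            if _longest_suffix_in(overlap, rc_inner) >= th.max_3prime_complement_run:
                continue
            if _longest_common_substring(overlap, rc_inner) >= th.max_cross_complement_run:
                continue
            if any(abs(o_start - prev[0]) < cfg.tier_spacing for prev in outers):
                continue
            outers.append((o_start, o_len, o_seq))
            if len(outers) == 3:
                break
        if len(outers) < 3:
            continue
        # tiers ordered I (closest to junction) -> III (farthest)
        outers.sort(key=lambda o: -(o[0] + o[1]))
        outer_recs = tuple(
            PrimerRecord(
                name=f"{gene}_oSSP_{tier}",
                gene=gene,
                role="outer",
                tier=tier,
                sequence=NucleotideSequence(seq, f"{gene}_oSSP_{tier}"),
                anchor=interval(start, length),
            )
            for tier, (start, length, seq) in zip(("I", "II", "III"), outers)
        )
        inner_rec = PrimerRecord(
            name=f"{gene}_iSSP",
            gene=gene,
            role="inner",
            tier="",
            sequence=NucleotideSequence(i_seq, f"{gene}_iSSP"),
            anchor=interval(i_start, i_len),
        )
        return outer_recs, inner_rec
    raise DesignError(
        "could not nest an inner primer 3' of three spaced outer primers; "
        f"candidate windows: {len(candidates)}, rejections: {rejects}"
    )


# ---------------------------------------------------------------------------
# semi-site-specific primer design
# ---------------------------------------------------------------------------


def design_semi_primer(
    outer: PrimerRecord,
    inner: PrimerRecord,
    cfg: DesignConfig | None = None,
    th: ThermoConfig | None = None,
    seed: int | None = None,
) -> PrimerRecord:
    """Design the semi-site-specific partner of an outer primer.

    The semi primer's 3' terminal ``overlap_length`` bases are copied from the
    outer primer; the 5' remainder is drawn by seeded rejection sampling until
    it satisfies base evenness (all four bases present, none above the
    configured ceiling), heterology against the outer primer's 5' remainder,
    the hairpin and dimer screens (against itself and against the inner
    primer) and the full-primer Tm window.  The semi primer is given the same
    total length as its partner, as in the published sets, so its footprint at
    a product terminus never overhangs the incorporated outer primer.

    Deterministic for a fixed seed.  Raises :class:`DesignError` with the
    most-frequent failing constraint when the retry budget is exhausted.
    """
    cfg = cfg or DesignConfig()
    th = th or ThermoConfig()
    k = cfg.overlap_length
    overlap = outer.bases[-k:]
    ov_tm = _thermo.tm_wallace(overlap)
    ov_lo, ov_hi = cfg.overlap_tm_window
    if not ov_lo <= ov_tm <= ov_hi:
        raise DesignError(
            f"outer primer {outer.name!r} 3' {k}-mer has Wallace Tm {ov_tm:.0f} degC, "
            f"outside [{ov_lo:.0f}, {ov_hi:.0f}]; the walking scheme requires a "
            "compliant overlap"
        )
    tail_len = len(outer) - k
    outer_tail = outer.bases[:-k]
    rng = random.Random(cfg.seed if seed is None else seed)
    # evenness of the heterologous part is enforced strictly during design
    th_design = replace(th, evenness_require_all_bases=True)
    tm_lo, tm_hi = cfg.primer_tm_window
    fails: dict[str, int] = {}
    for _ in range(cfg.retry_budget):
        # stratified composition sampling: drawing the tail's G+C count
        # uniformly first keeps extreme-but-required compositions reachable
        # when the inherited overlap is strongly AT- or GC-skewed
        gc = rng.randint(1, tail_len - 1)
        letters = [rng.choice("GC") for _ in range(gc)]
        letters += [rng.choice("AT") for _ in range(tail_len - gc)]
        rng.shuffle(letters)
        tail = "".join(letters)
        candidate = tail + overlap
        if tail[-1] == outer.bases[-k - 1]:
            fails["overlap-exact"] = fails.get("overlap-exact", 0) + 1
            continue  # would extend the common 3' suffix beyond overlap_length
        if not _thermo.base_evenness(tail, th_design).passed:
            fails["evenness"] = fails.get("evenness", 0) + 1
            continue
        if _shares_kmer(tail, outer_tail, cfg.heterology_kmer):
            fails["heterology"] = fails.get("heterology", 0) + 1
            continue
        tm = _thermo.tm_nearest_neighbor(candidate, th)
        if not tm_lo <= tm <= tm_hi:
            fails["tm-window"] = fails.get("tm-window", 0) + 1
            continue
        if not _thermo.hairpin_check(candidate, th).passed:
            fails["hairpin"] = fails.get("hairpin", 0) + 1
            continue
        if not _thermo.dimer_check(candidate, candidate, th).passed:
            fails["self-dimer"] = fails.get("self-dimer", 0) + 1
            continue
        if not _thermo.dimer_check(candidate, inner.bases, th).passed:
            fails["dimer-vs-inner"] = fails.get("dimer-vs-inner", 0) + 1
            continue
        name = f"{outer.gene}_semi_oSSP_{outer.tier}"
        return PrimerRecord(
            name=name,
            gene=outer.gene,
            role="semi",
            tier=outer.tier,
            sequence=NucleotideSequence(candidate, name),
            anchor=None,
            partner=outer.name,
        )
    worst = max(fails, key=fails.get) if fails else "none"
    raise DesignError(
        f"retry budget ({cfg.retry_budget}) exhausted designing semi primer for "
        f"{outer.name!r}; most frequent failure: {worst} ({fails})"
    )


def build_primer_set(
    known_region: NucleotideSequence,
    direction: str,
    cfg: DesignConfig | None = None,
    th: ThermoConfig | None = None,
    gene: str = "gene",
) -> PrimerSet:
    """Full design pipeline: three outers + inner + three semi primers."""
    cfg = cfg or DesignConfig()
    th = th or ThermoConfig()
    outers, inner = select_site_specific_primers(known_region, direction, cfg, th, gene)
    semis = tuple(
        design_semi_primer(o, inner, cfg, th, seed=cfg.seed + 1000 + i)
        for i, o in enumerate(outers)
    )
    return PrimerSet(gene=gene, outers=outers, inner=inner, semis=semis, direction=direction)


# ---------------------------------------------------------------------------
# table validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CheckResult:
    subject: str  # primer name or "name1+name2" for pair rules
    rule: str
    passed: bool
    severity: str  # "fail" | "warning" | "info"
    detail: str = ""


@dataclass
class ValidationReport:
    entries: list[CheckResult] = field(default_factory=list)

    def add(self, subject: str, rule: str, passed: bool, severity: str = "fail",
            detail: str = "") -> None:
        self.entries.append(
            CheckResult(subject, rule, passed, severity if not passed else "info", detail)
        )

    @property
    def failures(self) -> list[CheckResult]:
        return [e for e in self.entries if not e.passed and e.severity == "fail"]

    @property
    def warnings(self) -> list[CheckResult]:
        return [e for e in self.entries if not e.passed and e.severity == "warning"]

    @property
    def n_failures(self) -> int:
        return len(self.failures)

    def summary(self) -> dict:
        return {
            "checks": len(self.entries),
            "passed": sum(e.passed for e in self.entries),
            "failures": self.n_failures,
            "warnings": len(self.warnings),
        }

    def as_dict(self) -> dict:
        return {
            "summary": self.summary(),
            "entries": [
                {
                    "subject": e.subject,
                    "rule": e.rule,
                    "passed": e.passed,
                    "severity": e.severity,
                    "detail": e.detail,
                }
                for e in self.entries
            ],
        }


def validate_primer_table(
    records: Sequence[PrimerRecord],
    cfg: DesignConfig | None = None,
    th: ThermoConfig | None = None,
    strict: bool = False,
) -> ValidationReport:
    """Check every design rule on a primer table grouped by gene.

    Per primer: length window, full-primer Tm window, hairpin, self-dimer.
    Per (outer, semi) pair: 3'-overlap length, overlap Wallace Tm window,
    heterology of the 5' remainders, evenness of the semi 5' part.  Per
    secondary pair (semi, inner): cross-dimer.  Never mutates its input.

    Window violations on imported tables are reported as warnings so that
    published sets can be loaded under stricter user configs; ``strict=True``
    (used for freshly designed sets) turns them into failures.
    """
    cfg = cfg or DesignConfig()
    th = th or ThermoConfig()
    window_severity = "fail" if strict else "warning"
    rep = ValidationReport()
    by_gene: dict[str, list[PrimerRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)

    llo, lhi = cfg.primer_length_window
    tm_lo, tm_hi = cfg.primer_tm_window
    ov_lo, ov_hi = cfg.overlap_tm_window

    for gene, recs in by_gene.items():
        for r in recs:
            L = len(r)
            rep.add(r.name, "length-window", llo <= L <= lhi, window_severity,
                    f"length {L}, window [{llo}, {lhi}]")
            try:
                tm = _thermo.tm_nearest_neighbor(r.bases, th)
                rep.add(r.name, "tm-window", tm_lo <= tm <= tm_hi, window_severity,
                        f"Tm {tm:.2f}, window [{tm_lo}, {tm_hi}]")
            except ValueError as exc:
                rep.add(r.name, "tm-window", False, window_severity, str(exc))
            hp = _thermo.hairpin_check(r.bases, th)
            rep.add(r.name, "hairpin", hp.passed, "fail",
                    f"longest stem {hp.longest_run}, threshold {hp.threshold}")
            sd = _thermo.dimer_check(r.bases, r.bases, th)
            rep.add(r.name, "self-dimer", sd.passed, "fail",
                    f"run {sd.longest_run}, 3' run {sd.longest_3prime_run}")

        outers = {r.tier: r for r in recs if r.role == "outer"}
        semis = {r.tier: r for r in recs if r.role == "semi"}
        inners = [r for r in recs if r.role == "inner"]
        for tier, semi in semis.items():
            outer = outers.get(tier)
            if outer is None:
                rep.add(semi.name, "partner-outer-exists", False, "fail",
                        f"no tier-{tier} outer primer for gene {gene}")
                continue
            pair = f"{outer.name}+{semi.name}"
            ov = longest_common_3prime_suffix(outer.bases, semi.bases)
            rep.add(pair, "overlap-suffix", ov == cfg.overlap_length, "fail",
                    f"longest common 3' suffix {ov}, required {cfg.overlap_length}")
            ov_tm = _thermo.tm_wallace(semi.bases[-cfg.overlap_length:])
            rep.add(pair, "overlap-tm-window", ov_lo <= ov_tm <= ov_hi, window_severity,
                    f"overlap Wallace Tm {ov_tm:.0f}, window [{ov_lo}, {ov_hi}]")
            o_tail = outer.bases[: -cfg.overlap_length]
            s_tail = semi.bases[: -cfg.overlap_length]
            rep.add(pair, "heterology",
                    not _shares_kmer(o_tail, s_tail, cfg.heterology_kmer), "fail",
                    f"5' remainders share a >= {cfg.heterology_kmer}-mer")
            ev = _thermo.base_evenness(s_tail, th) if s_tail else None
            if ev is not None:
                rep.add(semi.name, "evenness-5prime", ev.passed, window_severity,
                        f"max fraction {ev.max_fraction:.3f}, "
                        f"missing {list(ev.missing_bases)}")
            for inner in inners:
                pd = _thermo.dimer_check(semi.bases, inner.bases, th)
                rep.add(f"{semi.name}+{inner.name}", "pair-dimer", pd.passed, "fail",
                        f"run {pd.longest_run}, 3' run {pd.longest_3prime_run}")
    return rep


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["gene", "role", "tier", "name", "sequence"]


def load_primer_tsv(path, imported: bool = True) -> list[PrimerRecord]:
    """Load a primer table (columns: gene, role, tier, name, sequence)."""
    out: list[PrimerRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _TSV_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise TableFormatError(f"primer table missing columns: {missing}")
        for row in reader:
            if not row.get("role"):
                raise TableFormatError(f"primer {row.get('name')!r}: missing role")
            out.append(
                PrimerRecord(
                    name=row["name"],
                    gene=row["gene"],
                    role=row["role"],
                    tier=row.get("tier") or "",
                    sequence=NucleotideSequence(row["sequence"], row["name"]),
                    imported=imported,
                )
            )
    if not out:
        raise TableFormatError(f"primer table {path} is empty")
    return out


def write_primer_tsv(records: Iterable[PrimerRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLUMNS)
        for r in records:
            writer.writerow([r.gene, r.role, r.tier, r.name, r.bases])


def bundled_primers() -> list[PrimerRecord]:
    """The published gadA/gadR/hyg walking primer sets shipped with the
    package (9 outer, 9 semi, 3 inner primers)."""
    ref = resources.files("sspcr").joinpath("data/published_primers.tsv")
    with resources.as_file(ref) as path:
        return load_primer_tsv(path, imported=True)
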