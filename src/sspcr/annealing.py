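"""Perfect and partial primer-annealing site discovery.

The annealing model is ungapped and 3'-anchored: the primer's 3' terminus is
placed against a template base and matches are counted positionwise over the
full footprint.  A footprint that would overhang a template end is discarded
(no virtual padding).  A site qualifies during a relaxed-stringency cycle when

* the run of consecutive matches at the primer's 3' terminus is at least
  ``min_3prime_run`` (default 2 — functional priming needs a paired 3' end),
* the total number of matched bases is at least ``min_total_matches``
  (default 8, the lower bound observed for productive partial annealing), and
* the mismatch fraction over the footprint does not exceed
  ``max_mismatch_fraction`` (default 0.60 — primers are reported to tolerate
  mismatch rates up to 60%).

Perfect (full-length) sites always qualify and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqcore import GenomicInterval, NucleotideSequence, revcomp

__all__ = [
    "PartialAnnealingModel",
    "AnnealingSite",
    "StrandHit",
    "scan_perfect_sites",
    "scan_partial_sites",
    "scan_strand",
    "site_statistics",
    "SiteStatistics",
]

_ENCODE = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def encode(bases: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PartialAnnealingModel:
    """Thresholds governing priming at mismatched sites in a relaxed cycle.

    A site qualifies when its 3'-terminal run reaches ``min_3prime_run`` and
    either the total match count clears both the absolute floor and the
    mismatch-fraction ceiling, or the 3'-terminal perfect run alone reaches
    ``strong_3prime_run`` (default 10).  The strong-run clause reflects the
    walking scheme's keystone event: a perfect 3'-anchored decamer — the
    designed overlap, Wallace Tm 20-40 degC — primes at relaxed-cycle
    temperatures no matter how mismatched the 5' tail is, which a bare
    mismatch-fraction cap would wrongly veto for primers longer than 25 nt.
    Set ``strong_3prime_run=None`` to disable the clause.
    """

    min_3prime_run: int = 2
    min_total_matches: int = 8
    max_mismatch_fraction: float = 0.60
    strong_3prime_run: int | None = 10

    def __post_init__(self) -> None:
        if self.min_3prime_run < 1:
            raise ValueError("min_3prime_run must be >= 1")
        if self.min_total_matches < self.min_3prime_run:
            raise ValueError("min_total_matches must be >= min_3prime_run")
        if not 0 < self.max_mismatch_fraction < 1:
            raise ValueError("max_mismatch_fraction must be in (0, 1)")
        if self.strong_3prime_run is not None and (
            self.strong_3prime_run < self.min_3prime_run
        ):
            raise ValueError("strong_3prime_run must be >= min_3prime_run")

    def min_matches_for(self, primer_length: int) -> int:
        """Effective match floor combining the absolute and fractional rules."""
        frac_floor = int(np.ceil((1.0 - self.max_mismatch_fraction) * primer_length))
        return max(self.min_total_matches, frac_floor)

    def qualifies(self, total_matches: int, three_prime_run: int, primer_length: int) -> bool:
        if three_prime_run < self.min_3prime_run:
            return False
        if self.strong_3prime_run is not None and three_prime_run >= self.strong_3prime_run:
            return True
        return total_matches >= self.min_matches_for(primer_length)

    def as_dict(self) -> dict:
        return {
            "min_3prime_run": self.min_3prime_run,
            "min_total_matches": self.min_total_matches,
            "max_mismatch_fraction": self.max_mismatch_fraction,
            "strong_3prime_run": self.strong_3prime_run,
        }


@dataclass(frozen=True)
class AnnealingSite:
    """One candidate priming event on a double-stranded template."""

    interval: GenomicInterval
    primer_name: str
    total_matches: int
    three_prime_run: int
    mismatch_fraction: float
    perfect: bool

    def __post_init__(self) -> None:
        if self.perfect and self.mismatch_fraction != 0.0:
            raise ValueError("perfect site must have zero mismatches")
        if self.three_prime_run > self.total_matches:
            raise ValueError("3' run cannot exceed total matches")


@dataclass(frozen=True)
class StrandHit:
    """A priming event of a primer on one single strand (5'->3' string).

    ``start`` is the 0-based index of the base paired with the primer's
    3'-terminal base; the footprint occupies ``[start, start + len(primer))``
    of the strand and extension copies ``strand[:start]``.
    """

    start: int
    total_matches: int
    three_prime_run: int
    perfect: bool


def _match_stats(windows_eq: np.ndarray, anchored_left: bool):
    """Row-wise total matches and 3'-anchored run length for a boolean
    (n_windows, L) match matrix.  ``anchored_left`` selects whether the
    primer's 3' terminus corresponds to column 0 (annealing to the given
    strand) or to the last column (site on the '+' strand of a duplex)."""
    total = windows_eq.sum(axis=1)
    mat = windows_eq if anchored_left else windows_eq[:, ::-1]
    # run of leading True per row: index of first False (or L if none)
    inv = ~mat
    first_false = np.where(inv.any(axis=1), inv.argmax(axis=1), mat.shape[1])
    return total.astype(np.int64), first_false.astype(np.int64)


def scan_strand(
    primer: str | NucleotideSequence,
    strand: str | NucleotideSequence,
    model: PartialAnnealingModel | None = None,
) -> list[StrandHit]:
    """All positions where ``primer`` anneals to the given single strand.

    With ``model=None`` only perfect (full-length) hits are returned.  The
    primer anneals antiparallel, so hits are windows equal (or near-equal) to
    the primer's reverse complement; the window start pairs the primer 3' end.
    """
    p = primer.bases if isinstance(primer, NucleotideSequence) else str(primer)
    s = strand.bases if isinstance(strand, NucleotideSequence) else str(strand)
    L = len(p)
    if L > len(s):
        return []
    target = encode(revcomp(p))
    arr = encode(s)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)
    eq = windows == target
    total, run3 = _match_stats(eq, anchored_left=True)
    if model is None:
        idx = np.nonzero(total == L)[0]
    else:
        keep = total >= model.min_matches_for(L)
        if model.strong_3prime_run is not None:
            keep |= run3 >= model.strong_3prime_run
        idx = np.nonzero(keep & (run3 >= model.min_3prime_run))[0]
    return [
        StrandHit(int(i), int(total[i]), int(run3[i]), bool(total[i] == L)) for i in idx
    ]


def _scan_duplex(
    primer: str,
    template: NucleotideSequence,
    model: PartialAnnealingModel | None,
    primer_name: str,
) -> list[AnnealingSite]:
    p = primer
    t = template.bases
    L = len(p)
    if L > len(t):
        return []
    arr = encode(t)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)
    sites: list[AnnealingSite] = []
    for strand, target, anchored_left in (
        ("+", encode(p), False),
        ("-", encode(revcomp(p)), True),
    ):
        eq = windows == target
        total, run3 = _match_stats(eq, anchored_left=anchored_left)
        if model is None:
            idx = np.nonzero(total == L)[0]
        else:
            keep = total >= model.min_matches_for(L)
            if model.strong_3prime_run is not None:
                keep |= run3 >= model.strong_3prime_run
            idx = np.nonzero(keep & (run3 >= model.min_3prime_run))[0]
        for i in idx:
            tm = int(total[i])
            sites.append(
                AnnealingSite(
                    GenomicInterval(template.name or "template", int(i), int(i) + L, strand),
                    primer_name,
                    tm,
                    int(run3[i]),
                    (L - tm) / L,
                    tm == L,
                )
            )
    sites.sort(key=lambda s: (s.interval.start, s.interval.strand))
    return sites


def scan_perfect_sites(primer, template: NucleotideSequence) -> list[AnnealingSite]:
    """Every position, on both strands, where the primer matches full-length.

    Footprint intervals are reported in plus-strand coordinates.
    """
    p, name = _primer_str(primer)
    return _scan_duplex(p, template, None, name)


def scan_partial_sites(
    primer, template: NucleotideSequence, model: PartialAnnealingModel
) -> list[AnnealingSite]:
    """All sites on both strands whose 3'-anchored ungapped alignment passes
    the partial-annealing model; perfect sites are included and flagged."""
    p, name = _primer_str(primer)
    return _scan_duplex(p, template, model, name)


def _primer_str(primer) -> tuple[str, str]:
    if isinstance(primer, NucleotideSequence):
        return primer.bases, primer.name
    if hasattr(primer, "sequence"):  # PrimerRecord
        return primer.sequence.bases, primer.name
    return str(primer), "primer"


@dataclass(frozen=True)
class SiteStatistics:
    count: int
    match_range: tuple[int, int] | None
    three_prime_run_range: tuple[int, int] | None
    match_histogram: dict[int, int]
    three_prime_run_histogram: dict[int, int]


def site_statistics(sites: Iterable[AnnealingSite]) -> SiteStatistics:
    """Summary (count, match-count range, 3'-run range, histograms) of a site
    collection; invariant under input order."""
    matches = sorted(s.total_matches for s in sites)
    runs = sorted(s.three_prime_run for s in sites)
    if not matches:
        return SiteStatistics(0, None, None, {}, {})
    hist_m: dict[int, int] = {}
    for m in matches:
        hist_m[m] = hist_m.get(m, 0) + 1
    hist_r: dict[int, int] = {}
    for r in runs:
        hist_r[r] = hist_r.get(r, 0) + 1
    return SiteStatistics(
        len(matches), (matches[0], matches[-1]), (runs[0], runs[-1]), hist_m, hist_r
    )
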