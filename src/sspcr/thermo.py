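"""Oligo thermodynamic and composition filters used by the primer designer.

Two melting-temperature estimators are exposed, matching common practice for
the two very different length scales the walking scheme cares about:

* :func:`tm_wallace` — the Wallace rule (2 degC per A/T, 4 degC per G/C), used
  for the short (10 nt) 3'-overlap shared between an outer primer and its
  semi-site-specific partner.  For a 10-mer the rule spans exactly
  20-40 degC, the window the overlap is required to sit in.
* :func:`tm_nearest_neighbor` — a nearest-neighbor model (via Biopython's
  SantaLucia tables) with a single monovalent-salt correction, used for full
  20-30 nt primers against the 60-65 degC design window.  The Wallace rule
  grossly overestimates Tm at these lengths.

Secondary-structure screens are run-length based: a hairpin is called when two
substrings of one oligo can form an antiparallel stem of at least
``max_self_complement_run`` base pairs closing a loop of >= 3 nt; a dimer when
two oligos share a complementary run of at least ``max_cross_complement_run``
base pairs, with a stricter ceiling (``max_3prime_complement_run``) for runs
that involve either 3' terminus, where extension by the polymerase starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.SeqUtils import MeltingTemp as _mt

from .seqcore import NucleotideSequence, revcomp

__all__ = [
    "ThermoConfig",
    "tm_wallace",
    "tm_nearest_neighbor",
    "hairpin_check",
    "dimer_check",
    "base_evenness",
    "HairpinResult",
    "DimerResult",
    "EvennessResult",
]

_MIN_LOOP = 3  # smallest loop (nt) that lets a stem fold back


@dataclass(frozen=True)
class ThermoConfig:
    """Numeric thresholds for all thermodynamic/composition filters.

    Defaults were fixed once against the shipped gadA/gadR/hyg primer table:
    every published primer passes the hairpin screen and every secondary-round
    pair (semi + inner) passes the dimer screen at these settings.
    """

    tm_method_short: str = "wallace"
    tm_method_full: str = "nearest-neighbor"
    monovalent_mM: float = 50.0
    primer_nM: float = 250.0
    max_self_complement_run: int = 4
    max_cross_complement_run: int = 8
    max_3prime_complement_run: int = 6
    evenness_max_fraction: float = 0.50
    evenness_require_all_bases: bool = False

    def __post_init__(self) -> None:
        if self.monovalent_mM <= 0 or self.primer_nM <= 0:
            raise ValueError("concentrations must be positive")
        for name in ("max_self_complement_run", "max_cross_complement_run",
                     "max_3prime_complement_run"):
            if getattr(self, name) < 3:
                raise ValueError(f"{name} must be >= 3")
        if not 0.25 <= self.evenness_max_fraction <= 1.0:
            raise ValueError("evenness_max_fraction must be in [0.25, 1]")

    def as_dict(self) -> dict:
        return {
            "tm_method_short": self.tm_method_short,
            "tm_method_full": self.tm_method_full,
            "monovalent_mM": self.monovalent_mM,
            "primer_nM": self.primer_nM,
            "max_self_complement_run": self.max_self_complement_run,
            "max_cross_complement_run": self.max_cross_complement_run,
            "max_3prime_complement_run": self.max_3prime_complement_run,
            "evenness_max_fraction": self.evenness_max_fraction,
            "evenness_require_all_bases": self.evenness_require_all_bases,
        }


def _bases(s: NucleotideSequence | str) -> str:
    return s.bases if isinstance(s, NucleotideSequence) else str(s)


def tm_wallace(s: NucleotideSequence | str) -> float:
    """Wallace-rule Tm for short (<= 14 nt) segments: 2(A+T) + 4(G+C)."""
    b = _bases(s)
    if len(b) > 14:
        raise ValueError(
            f"Wallace rule is only meaningful for <= 14 nt segments, got {len(b)} nt; "
            "use tm_nearest_neighbor for full primers"
        )
    at = b.count("A") + b.count("T")
    gc = b.count("G") + b.count("C")
    return float(2 * at + 4 * gc)


def tm_nearest_neighbor(s: NucleotideSequence | str, cfg: ThermoConfig | None = None) -> float:
    """Nearest-neighbor Tm (degC) with a monovalent-salt correction.

    Deterministic for a fixed config; defaults are 50 mM monovalent salt and
    250 nM primer.
    """
    cfg = cfg or ThermoConfig()
    b = _bases(s)
    if not 8 <= len(b) <= 60:
        raise ValueError(f"nearest-neighbor Tm expects 8-60 nt, got {len(b)}")
    return float(
        _mt.Tm_NN(b, Na=cfg.monovalent_mM, dnac1=cfg.primer_nM, dnac2=0, saltcorr=5)
    )


@dataclass(frozen=True)
class HairpinResult:
    passed: bool
    longest_run: int
    threshold: int


def longest_hairpin_stem(bases: str, min_loop: int = _MIN_LOOP) -> int:
    """Longest antiparallel self-complementary stem closing a loop >= min_loop.

    A stem of length k means ``s[i:i+k] == revcomp(s[j:j+k])`` for some
    ``j >= i + k + min_loop``.
    """
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    n = len(bases)
    best = 0
    for p in range(n):
        cp = comp[bases[p]]
        for q in range(p + min_loop + 1, n):  # loop for k=1 is q - p - 1
            if bases[q] != cp:
                continue
            k = 1
            # extend inward while bases pair and the remaining loop stays >= min_loop
            while (
                p + k < q - k
                and (q - k) - (p + k) - 1 >= min_loop
                and bases[p + k] == comp[bases[q - k]]
            ):
                k += 1
            if k > best:
                best = k
    return best


def hairpin_check(s: NucleotideSequence | str, cfg: ThermoConfig | None = None) -> HairpinResult:
    """Pass/fail hairpin screen; fails iff the longest stem reaches the threshold."""
    cfg = cfg or ThermoConfig()
    run = longest_hairpin_stem(_bases(s))
    return HairpinResult(run < cfg.max_self_complement_run, run, cfg.max_self_complement_run)


@dataclass(frozen=True)
class DimerResult:
    passed: bool
    longest_run: int
    longest_3prime_run: int
    threshold: int
    threshold_3prime: int


def _longest_common_substring(a: str, b: str) -> int:
    best = 0
    la, lb = len(a), len(b)
    for i in range(la):
        if la - i <= best:
            break
        for j in range(lb):
            k = 0
            while i + k < la and j + k < lb and a[i + k] == b[j + k]:
                k += 1
            if k > best:
                best = k
    return best


def _longest_suffix_in(a: str, b: str) -> int:
    """Longest suffix of `a` occurring as a substring of `b`."""
    for k in range(min(len(a), len(b)), 0, -1):
        if a[-k:] in b:
            return k
    return 0


def dimer_check(
    a: NucleotideSequence | str, b: NucleotideSequence | str, cfg: ThermoConfig | None = None
) -> DimerResult:
    """Screen a pair of oligos (a may equal b for a self-dimer) for
    complementary runs.  Symmetric in its arguments.

    The overall run is the longest antiparallel duplex the two can form
    (longest common substring of ``a`` and ``revcomp(b)``); a stricter
    threshold applies to runs that include either oligo's 3'-terminal base.
    """
    cfg = cfg or ThermoConfig()
    sa, sb = _bases(a), _bases(b)
    run = _longest_common_substring(sa, revcomp(sb))
    run3 = max(_longest_suffix_in(sa, revcomp(sb)), _longest_suffix_in(sb, revcomp(sa)))
    passed = run < cfg.max_cross_complement_run and run3 < cfg.max_3prime_complement_run
    return DimerResult(passed, run, run3, cfg.max_cross_complement_run,
                       cfg.max_3prime_complement_run)


@dataclass(frozen=True)
class EvennessResult:
    fractions: Mapping[str, float]
    passed: bool
    missing_bases: tuple[str, ...]
    max_fraction: float


def base_evenness(s: NucleotideSequence | str, cfg: ThermoConfig | None = None) -> EvennessResult:
    """Per-base composition of an oligo (or oligo part) and a pass/fail verdict.

    Passes iff no base exceeds ``evenness_max_fraction`` and, when
    ``evenness_require_all_bases`` is set, all four bases are present.  The
    all-bases requirement is enforced during de-novo design but is off by
    default so published primer sets whose 5' parts happen to lack one base
    still validate.
    """
    cfg = cfg or ThermoConfig()
    b = _bases(s)
    fr = {base: b.count(base) / len(b) for base in "ACGT"}
    missing = tuple(base for base in "ACGT" if fr[base] == 0.0)
    mx = max(fr.values())
    passed = mx <= cfg.evenness_max_fraction and (
        not cfg.evenness_require_all_bases or not missing
    )
    return EvennessResult(fr, passed, missing, mx)
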