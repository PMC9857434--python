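"""Literal strand-level PCR simulation — the brute-force verifier.

This module deliberately shares no product-classification logic with
:mod:`sspcr.simulate`.  It plays the reaction out cycle by cycle on raw
strings: every cycle each strand in the pool is denatured and serves as a
template; primers anneal (perfect full-length hits always; model-governed
partial hits for the round's walking primer in the single relaxed cycle) and
are extended to the template's 5' end or the extension ceiling, creating new
strands with the priming primer incorporated at their 5' terminus.  Strand
copy numbers are tracked as exact integers, and a duplex is called
*exponential* when both of its strands kept (at least) doubling over the
final stringent cycles — the behaviour the analytic predictor calls a target
product.  Everything else accumulates at most linearly.

Combinatorial guards keep the literal simulation tractable: templates up to
50 kb and at most 12 cycles.  Scaled-down stage structures (e.g. 3 stringent
/ 1 relaxed / 6 stringent) preserve the scheme's qualitative behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annealing import PartialAnnealingModel, scan_strand
from .design import PrimerRecord
from .seqcore import NucleotideSequence, revcomp
from .simulate import ThermalProgram

__all__ = ["OracleGuardError", "OracleResult", "string_synthesis_oracle"]

_MAX_TEMPLATE = 50_000
_MAX_CYCLES = 12

#: which primer roles may partially anneal in each relaxed-stringency class
_WALKING_ROLES = {"low": ("outer",), "reduced": ("semi",)}


class OracleGuardError(RuntimeError):
    """Raised when an input exceeds the combinatorial guard."""


@dataclass
class OracleResult:
    exponential: set[str]  # canonical duplex sequences
    linear: set[str]  # strands that never amplified exponentially
    counts: Mapping[str, int]  # final copy number per distinct strand

    def exponential_lengths(self) -> list[int]:
        return sorted(len(s) for s in self.exponential)


def _canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def string_synthesis_oracle(
    templates: NucleotideSequence | Sequence[NucleotideSequence],
    primers: Sequence[PrimerRecord],
    program: ThermalProgram,
    model: PartialAnnealingModel | None = None,
    cycle_cap: int = _MAX_CYCLES,
) -> OracleResult:
    """Simulate every cycle literally and classify duplex products.

    ``templates`` may be one double-stranded molecule or a pool of them; both
    strands of each enter the pool at copy number 1.
    """
    model = model or PartialAnnealingModel()
    if isinstance(templates, NucleotideSequence):
        templates = [templates]
    total_cycles = sum(st.cycles for st in program.stages)
    if total_cycles > cycle_cap:
        raise OracleGuardError(
            f"{total_cycles} cycles exceed the cap ({cycle_cap}); scale the program down"
        )
    for t in templates:
        if len(t) > _MAX_TEMPLATE:
            raise OracleGuardError(f"template {t.name!r} exceeds {_MAX_TEMPLATE} bases")

    ceiling = program.extension_ceiling
    counts: dict[str, int] = {}
    genomic: set[str] = set()
    for t in templates:
        for strand in (t.bases, revcomp(t.bases)):
            counts[strand] = counts.get(strand, 0) + 1
            genomic.add(strand)

    history: list[dict[str, int]] = [dict(counts)]
    primer_seqs = [(p.bases, p.role) for p in primers]

    for stage in program.stages:
        walking = _WALKING_ROLES.get(stage.stringency, ())
        for _cycle in range(stage.cycles):
            new: dict[str, int] = {}
            for strand, copy in counts.items():
                for pbases, role in primer_seqs:
                    if len(pbases) > len(strand):
                        continue
                    relaxed_here = role in walking
                    hits = scan_strand(pbases, strand, model if relaxed_here else None)
                    for hit in hits:
                        room = ceiling - len(pbases)
                        lo = max(0, hit.start - room)
                        product = pbases + revcomp(strand[lo : hit.start])
                        new[product] = new.get(product, 0) + copy
            for seq, n in new.items():
                counts[seq] = counts.get(seq, 0) + n
            history.append(dict(counts))

    return _classify(counts, history, genomic)


def _classify(
    counts: dict[str, int], history: list[dict[str, int]], genomic: set[str]
) -> OracleResult:
    """Exponential = both strands of a duplex at least doubled over the last
    two cycles; genomic input strands are template, not product."""
    final = history[-1]
    two_back = history[-3] if len(history) >= 3 else history[0]

    def grows(seq: str) -> bool:
        now = final.get(seq, 0)
        then = two_back.get(seq, 0)
        return then >= 1 and now >= 2 * then and now > then

    exponential: set[str] = set()
    linear: set[str] = set()
    for seq in counts:
        if seq in genomic:
            continue
        partner = revcomp(seq)
        if grows(seq) and grows(partner):
            exponential.add(_canonical(seq))
        else:
            linear.add(seq)
    linear -= {s for c in exponential for s in (c, revcomp(c))}
    return OracleResult(exponential, linear, counts)
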