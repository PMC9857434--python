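import pytest

from sspcr.annealing import PartialAnnealingModel
from sspcr.design import DesignConfig, bundled_primers
from sspcr.fixture import SyntheticGenomeSpec, generate_walk_fixture
from sspcr.oracle import string_synthesis_oracle
from sspcr.seqcore import NucleotideSequence
from sspcr.simulate import (
    SUPPRESSED,
    TARGET,
    Stage,
    ThermalProgram,
    canonical_duplex,
    run_primary,
    run_secondary,
)
from sspcr.thermo import ThermoConfig


@pytest.fixture(scope="session")
def published():
    """The shipped gadA/gadR/hyg primer table (9 outer, 9 semi, 3 inner)."""
    return bundled_primers()


@pytest.fixture(scope="session")
def published_pairs(published):
    """(outer, semi) records per gene and tier."""
    by = {}
    for r in published:
        by.setdefault(r.gene, {}).setdefault(r.role, {})[r.tier] = r
    return [
        (by[g]["outer"][t], by[g]["semi"][t])
        for g in sorted(by)
        for t in ("I", "II", "III")
    ]


@pytest.fixture(scope="session")
def thermo_cfg():
    return ThermoConfig()


@pytest.fixture(scope="session")
def design_cfg():
    return DesignConfig()


@pytest.fixture(scope="session")
def model():
    return PartialAnnealingModel()


@pytest.fixture(scope="session")
def walk_fixture():
    """Default two-site synthetic walking fixture (deterministic, seed 1)."""
    return generate_walk_fixture(SyntheticGenomeSpec(seed=1))


def scaled_primary_program(ceiling: int = 10_000) -> ThermalProgram:
    """Oracle-sized stage structure preserving the primary round's shape."""
    return ThermalProgram(
        (Stage("moderate-high", 3, 60), Stage("low", 1, 25), Stage("moderate-high", 6, 60)),
        ceiling,
    )


def scaled_secondary_program(ceiling: int = 10_000) -> ThermalProgram:
    return ThermalProgram(
        (Stage("high", 3, 65), Stage("reduced", 1, 40), Stage("high", 6, 65)), ceiling
    )


def run_both_rounds(fx, tier="I"):
    """Analytic primary + secondary on a fixture's tier-I primer trio."""
    outer, semi = fx.primer_set.pair(tier)
    inner = fx.primer_set.inner
    primary = run_primary(
        fx.template, outer, model=fx.model,
        suppression_threshold=fx.spec.suppression_threshold,
    )
    secondary = (
        run_secondary(primary.products, inner, semi, model=fx.model)
        if primary.products
        else []
    )
    return primary, secondary


def assert_oracle_agreement(fx, primary, secondary):
    """Analytic exponential set must equal the literal string-synthesis
    oracle's, in both rounds (suppression is a classification overlay the
    oracle does not model, hence target + suppressed-short)."""
    outer, semi = fx.primer_set.pair("I")
    inner = fx.primer_set.inner
    ceiling = fx.spec.extension_ceiling
    orc = string_synthesis_oracle(
        fx.template, [outer], scaled_primary_program(ceiling), fx.model
    )
    analytic = {
        canonical_duplex(p.sequence)
        for p in primary.products
        if p.amplicon_class in (TARGET, SUPPRESSED)
    }
    assert analytic == orc.exponential, "primary round disagrees with the oracle"
    targets = [p for p in primary.products if p.amplicon_class == TARGET]
    sec_targets = {
        canonical_duplex(p.sequence) for p in secondary if p.amplicon_class == TARGET
    }
    if targets:
        duplexes = [NucleotideSequence(p.sequence, f"p{i}") for i, p in enumerate(targets)]
        orc2 = string_synthesis_oracle(
            duplexes, [inner, semi], scaled_secondary_program(ceiling), fx.model
        )
        assert sec_targets == orc2.exponential, "secondary round disagrees with the oracle"
    else:
        assert not sec_targets
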