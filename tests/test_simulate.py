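import random

import pytest

from conftest import (
    assert_oracle_agreement,
    run_both_rounds,
    scaled_primary_program,
    scaled_secondary_program,
)
from sspcr.annealing import PartialAnnealingModel
from sspcr.design import PrimerRecord
from sspcr.fixture import (
    Decoy,
    FixtureError,
    PlantedSite,
    SyntheticGenomeSpec,
    generate_walk_fixture,
)
from sspcr.oracle import OracleGuardError, string_synthesis_oracle
from sspcr.seqcore import NucleotideSequence, revcomp
from sspcr.simulate import (
    NONTARGET,
    SUPPRESSED,
    TARGET,
    OverlapMismatchError,
    ProgramError,
    Stage,
    ThermalProgram,
    band_report,
    default_primary_program,
    default_secondary_program,
    run_primary,
    run_secondary,
)


def make_primer(bases, role="outer", tier="I", gene="g", name=None):
    name = name or f"{gene}_{role}_{tier}"
    return PrimerRecord(name, gene, role, tier, NucleotideSequence(bases, name))


def rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def planted_template(rng, primer, site_offset, junction=400, length=4000):
    """Template with a perfect '+' site at 100 and one qualifying '-' partial
    site ``site_offset`` bases past the perfect site."""
    genome = list(rand_dna(rng, length))
    L = len(primer)
    genome[100 : 100 + L] = primer
    q = 100 + site_offset
    target = revcomp(primer)
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    cols = set(range(4)) | set(rng.sample(range(5, L), 10))
    genome[q : q + L] = [
        target[c] if c in cols else flip[target[c]] for c in range(L)
    ]
    return NucleotideSequence("".join(genome), "t"), q


#: strict model for hand-built templates: chance sites on random sequence
#: essentially cannot reach 14 matches with a 4-base 3' run
STRICT = PartialAnnealingModel(min_3prime_run=4, min_total_matches=14,
                               max_mismatch_fraction=0.5)


class TestThermalProgram:
    def test_two_relaxed_stages_rejected(self):
        with pytest.raises(ProgramError):
            ThermalProgram((Stage("low", 1, 25), Stage("reduced", 1, 40)))

    def test_relaxed_stage_must_be_single_cycle(self):
        with pytest.raises(ProgramError):
            ThermalProgram((Stage("low", 2, 25),))

    def test_wrong_relaxed_class_for_round(self):
        rng = random.Random(0)
        outer = make_primer(rand_dna(rng, 25))
        bad = ThermalProgram((Stage("reduced", 1, 40),))
        with pytest.raises(ProgramError, match="primary"):
            run_primary(NucleotideSequence(rand_dna(rng, 500), "t"), outer, bad)


class TestPrimaryRound:
    def test_single_planted_site_gives_one_target_with_oracle_length(self):
        rng = random.Random(21)
        primer = rand_dna(rng, 25)
        template, q = planted_template(rng, primer, 1500)
        outer = make_primer(primer)
        res = run_primary(template, outer, model=STRICT, enumerate_background=False)
        targets = res.targets
        assert len(targets) == 1
        assert targets[0].length == (q + 25) - 100
        orc = string_synthesis_oracle(template, [outer], scaled_primary_program(), STRICT)
        assert {len(s) for s in orc.exponential} == {targets[0].length}

    def test_close_site_is_suppressed_short(self):
        rng = random.Random(22)
        primer = rand_dna(rng, 25)
        template, q = planted_template(rng, primer, 80)
        res = run_primary(template, make_primer(primer), model=STRICT,
                          suppression_threshold=200, enumerate_background=False)
        assert [p.amplicon_class for p in res.products] == [SUPPRESSED]
        assert not res.targets

    def test_no_partial_site_means_walking_fails(self):
        rng = random.Random(23)
        primer = rand_dna(rng, 25)
        genome = list(rand_dna(rng, 800))
        genome[50:75] = primer
        # restrict with a near-perfect model so chance sites cannot qualify
        strict = PartialAnnealingModel(2, 24, 0.05)
        res = run_primary(
            NucleotideSequence("".join(genome), "t"), make_primer(primer), model=strict
        )
        assert res.targets == [] and "fail" in res.warning

    def test_absent_primer_warns_with_empty_result(self):
        rng = random.Random(24)
        res = run_primary(
            NucleotideSequence(rand_dna(rng, 600), "t"),
            make_primer(rand_dna(rng, 25)),
        )
        assert res.products == [] and "no perfect site" in res.warning

    def test_target_products_carry_terminal_inverted_repeat(self, walk_fixture):
        primary, _ = run_both_rounds(walk_fixture)
        outer, _ = walk_fixture.primer_set.pair("I")
        for p in primary.targets:
            assert p.tir_length >= len(outer)
            assert p.sequence.startswith(outer.bases)
            assert p.sequence.endswith(revcomp(outer.bases))


class TestSecondaryRound:
    def test_fixture_yields_one_secondary_target_per_planted_site(self, walk_fixture):
        primary, secondary = run_both_rounds(walk_fixture)
        targets = [p for p in secondary if p.amplicon_class == TARGET]
        expected = sorted(
            t.expected_secondary_length
            for t in walk_fixture.planted_truth()
            if t.amplicon_class == TARGET
        )
        assert sorted(p.length for p in targets) == expected

    def test_secondary_length_equals_oracle_product(self, walk_fixture):
        primary, secondary = run_both_rounds(walk_fixture)
        assert_oracle_agreement(walk_fixture, primary, secondary)

    def test_unrelated_semi_primer_is_a_hard_error(self, walk_fixture):
        primary, _ = run_both_rounds(walk_fixture)
        rng = random.Random(31)
        stranger = make_primer(rand_dna(rng, 25), role="semi", tier="I", name="stranger")
        with pytest.raises(OverlapMismatchError):
            run_secondary(primary.products, walk_fixture.primer_set.inner, stranger)

    def test_empty_primary_input_rejected(self, walk_fixture):
        _, semi = walk_fixture.primer_set.pair("I")
        with pytest.raises(ValueError, match="empty"):
            run_secondary([], walk_fixture.primer_set.inner, semi)

    def test_tail_arithmetic_secondary_minus_primary_span(self):
        """Secondary target length = inner->site span + semi length; the semi
        tail adds exactly (semi length - overlap) over the genomic span."""
        for seed in range(40, 45):
            fx = generate_walk_fixture(SyntheticGenomeSpec(seed=seed))
            outer, semi = fx.primer_set.pair("I")
            inner = fx.primer_set.inner
            primary, secondary = run_both_rounds(fx)
            targets = {p.length for p in secondary if p.amplicon_class == TARGET}
            for t in fx.planted_truth():
                if t.amplicon_class != TARGET:
                    continue
                q = t.interval.start
                closed_form = (q - inner.anchor.start) + len(semi)
                assert closed_form in targets
                # equivalent decomposition through the junction
                d_site = q - fx.spec.junction
                d_inner = fx.spec.junction - inner.anchor.start
                assert closed_form == d_site + d_inner + len(semi)


class TestOracle:
    def test_zero_primers_no_products(self, walk_fixture):
        orc = string_synthesis_oracle(
            walk_fixture.template, [], scaled_primary_program(), walk_fixture.model
        )
        assert orc.exponential == set()

    def test_stringent_only_program_leaves_linear_ssdna_only(self, walk_fixture):
        outer, _ = walk_fixture.primer_set.pair("I")
        program = ThermalProgram((Stage("moderate-high", 8, 60),))
        orc = string_synthesis_oracle(
            walk_fixture.template, [outer], program, walk_fixture.model
        )
        assert orc.exponential == set()
        assert any(s.startswith(outer.bases) for s in orc.linear)

    def test_cycle_guard(self, walk_fixture):
        outer, _ = walk_fixture.primer_set.pair("I")
        program = ThermalProgram((Stage("moderate-high", 30, 60),))
        with pytest.raises(OracleGuardError):
            string_synthesis_oracle(walk_fixture.template, [outer], program)


class TestRelaxedCycleAblation:
    def test_no_relaxed_stage_yields_zero_targets(self):
        stringent_primary = ThermalProgram((Stage("moderate-high", 30, 60),))
        for seed in (50, 51):
            fx = generate_walk_fixture(SyntheticGenomeSpec(seed=seed))
            outer, _ = fx.primer_set.pair("I")
            res = run_primary(fx.template, outer, stringent_primary, fx.model)
            assert res.targets == []


class TestBandReport:
    def test_empty(self):
        rep = band_report([])
        assert rep.rows == () and "no exponentially amplified band" in rep.sketch()

    def test_sorted_descending_and_classes_preserved(self, walk_fixture):
        primary, secondary = run_both_rounds(walk_fixture)
        rep = band_report(secondary)
        lengths = [r["length"] for r in rep.rows]
        assert lengths == sorted(lengths, reverse=True)
        assert rep.n_target == sum(p.amplicon_class == TARGET for p in secondary)
        assert rep.n_nontarget == sum(p.amplicon_class == NONTARGET for p in secondary)


class TestFixtureGenerator:
    def test_same_seed_byte_identical_template(self):
        a = generate_walk_fixture(SyntheticGenomeSpec(seed=9))
        b = generate_walk_fixture(SyntheticGenomeSpec(seed=9))
        assert a.template.bases == b.template.bases
        assert [p.bases for p in a.primer_set.all_records()] == [
            p.bases for p in b.primer_set.all_records()
        ]

    def test_zero_planted_sites_walking_fails(self):
        fx = generate_walk_fixture(SyntheticGenomeSpec(seed=9, sites=()))
        outer, _ = fx.primer_set.pair("I")
        res = run_primary(fx.template, outer, model=fx.model,
                          enumerate_background=False)
        assert res.targets == [] and res.warning is not None

    def test_overlapping_planted_sites_rejected(self):
        with pytest.raises(FixtureError, match="irreconcilably"):
            generate_walk_fixture(
                SyntheticGenomeSpec(seed=9, sites=(PlantedSite(1000), PlantedSite(1010)))
            )

    def test_truth_bed_roundtrip(self, tmp_path, walk_fixture):
        from sspcr.seqcore import read_bed

        paths = walk_fixture.write(tmp_path / "fx")
        back = read_bed(paths["truth"])
        planted = [b for b in back if b.name == "planted-site"]
        assert [b.interval for b in planted] == [
            t.interval for t in walk_fixture.planted_truth()
        ]

    def test_decoy_within_reach_is_rejected(self):
        with pytest.raises(FixtureError, match="ceiling"):
            generate_walk_fixture(
                SyntheticGenomeSpec(
                    seed=9, decoys=(Decoy("partial-partial", 3000),)
                )
            )
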