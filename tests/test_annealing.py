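import random

import pytest

from sspcr.annealing import (
    PartialAnnealingModel,
    scan_partial_sites,
    scan_perfect_sites,
    scan_strand,
    site_statistics,
)
from sspcr.seqcore import NucleotideSequence, revcomp


def brute_scan(primer: str, template: str, model: PartialAnnealingModel):
    """Per-position, per-strand match counter — the independent oracle."""
    L = len(primer)
    out = []
    for strand, target in (("+", primer), ("-", revcomp(primer))):
        for i in range(len(template) - L + 1):
            win = template[i : i + L]
            matches = sum(1 for x, y in zip(win, target) if x == y)
            if strand == "+":
                run = 0
                for x, y in zip(reversed(win), reversed(target)):
                    if x != y:
                        break
                    run += 1
            else:
                run = 0
                for x, y in zip(win, target):
                    if x != y:
                        break
                    run += 1
            strong = (
                model.strong_3prime_run is not None
                and run >= model.strong_3prime_run
            )
            weak = (
                matches >= model.min_total_matches
                and (L - matches) / L <= model.max_mismatch_fraction
            )
            if run >= model.min_3prime_run and (weak or strong):
                out.append((i, strand, matches, run))
    return sorted(out)


def sites_as_tuples(sites):
    return sorted(
        (s.interval.start, s.interval.strand, s.total_matches, s.three_prime_run)
        for s in sites
    )


def rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestPerfectScan:
    def test_planted_window_found_once(self):
        rng = random.Random(0)
        primer = rand_dna(rng, 25)
        template = NucleotideSequence(rand_dna(rng, 500) + primer + rand_dna(rng, 500), "t")
        sites = scan_perfect_sites(NucleotideSequence(primer, "p"), template)
        assert len(sites) == 1 and sites[0].interval.start == 500
        assert sites[0].perfect and sites[0].mismatch_fraction == 0.0

    def test_planted_twice_found_twice(self):
        rng = random.Random(1)
        primer = rand_dna(rng, 25)
        template = NucleotideSequence(
            primer + rand_dna(rng, 100) + primer + rand_dna(rng, 50), "t"
        )
        assert len(scan_perfect_sites(NucleotideSequence(primer, "p"), template)) == 2

    def test_strand_symmetry(self):
        rng = random.Random(2)
        primer = rand_dna(rng, 25)
        fwd = NucleotideSequence(rand_dna(rng, 300) + primer + rand_dna(rng, 300), "t")
        rev = NucleotideSequence(revcomp(fwd.bases), "trc")
        (a,) = scan_perfect_sites(NucleotideSequence(primer, "p"), fwd)
        (b,) = scan_perfect_sites(NucleotideSequence(primer, "p"), rev)
        assert a.interval.strand == "+" and b.interval.strand == "-"
        assert len(fwd) - a.interval.end == b.interval.start


class TestPartialScan:
    def test_threshold_arithmetic_at_60_percent_mismatch(self):
        # exact 3' 10-mer, everything else mismatched: 15/25 = 0.60 exactly
        rng = random.Random(3)
        primer = rand_dna(rng, 25)
        target = revcomp(primer)  # '-' orientation window
        window = "".join(
            target[c] if c < 10 else {"A": "C", "C": "A", "G": "T", "T": "G"}[target[c]]
            for c in range(25)
        )
        template = NucleotideSequence(rand_dna(rng, 200) + window + rand_dna(rng, 200), "t")
        model = PartialAnnealingModel()
        hits = [
            s
            for s in scan_partial_sites(NucleotideSequence(primer, "p"), template, model)
            if s.interval.start == 200
        ]
        assert len(hits) == 1
        assert hits[0].total_matches == 10
        assert hits[0].mismatch_fraction == pytest.approx(0.60)

    def test_3prime_terminal_mismatch_rejected(self):
        rng = random.Random(4)
        primer = rand_dna(rng, 25)
        target = revcomp(primer)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        # same construct but the 3'-anchoring base (column 0) mismatched
        window = flip[target[0]] + "".join(
            target[c] if c < 11 else flip[target[c]] for c in range(1, 25)
        )
        template = NucleotideSequence(rand_dna(rng, 200) + window + rand_dna(rng, 200), "t")
        hits = [
            s
            for s in scan_partial_sites(
                NucleotideSequence(primer, "p"), template, PartialAnnealingModel()
            )
            if s.interval.start == 200 and s.interval.strand == "-"
        ]
        assert hits == []

    def test_matches_bruteforce_oracle(self):
        rng = random.Random(5)
        model = PartialAnnealingModel()
        template = NucleotideSequence(rand_dna(rng, 2000), "t")
        for _ in range(20):
            primer = NucleotideSequence(rand_dna(rng, 25), "p")
            assert sites_as_tuples(
                scan_partial_sites(primer, template, model)
            ) == brute_scan(primer.bases, template.bases, model)

    def test_limit_equivalence_with_perfect_scan(self):
        rng = random.Random(6)
        template = NucleotideSequence(rand_dna(rng, 3000), "t")
        primer = NucleotideSequence(rand_dna(rng, 20), "p")
        strict = PartialAnnealingModel(
            min_3prime_run=1, min_total_matches=20, max_mismatch_fraction=1e-9,
            strong_3prime_run=20,
        )
        assert sites_as_tuples(scan_partial_sites(primer, template, strict)) == (
            sites_as_tuples(scan_perfect_sites(primer, template))
        )

    def test_monotonicity_in_each_threshold(self):
        rng = random.Random(7)
        template = NucleotideSequence(rand_dna(rng, 3000), "t")
        primer = NucleotideSequence(rand_dna(rng, 25), "p")
        base = PartialAnnealingModel(2, 10, 0.5)
        base_sites = set(sites_as_tuples(scan_partial_sites(primer, template, base)))
        for relaxed in (
            PartialAnnealingModel(1, 10, 0.5),
            PartialAnnealingModel(2, 8, 0.5),
            PartialAnnealingModel(2, 10, 0.6),
            PartialAnnealingModel(2, 10, 0.5, strong_3prime_run=8),
        ):
            relaxed_sites = set(sites_as_tuples(scan_partial_sites(primer, template, relaxed)))
            assert base_sites <= relaxed_sites

    def test_self_consistency_of_reported_statistics(self):
        rng = random.Random(8)
        template = NucleotideSequence(rand_dna(rng, 4000), "t")
        primer = NucleotideSequence(rand_dna(rng, 25), "p")
        for s in scan_partial_sites(primer, template, PartialAnnealingModel()):
            win = template.bases[s.interval.start : s.interval.end]
            target = primer.bases if s.interval.strand == "+" else revcomp(primer.bases)
            matches = sum(1 for x, y in zip(win, target) if x == y)
            assert matches == s.total_matches
            assert s.mismatch_fraction == (len(primer) - matches) / len(primer)

    def test_overhanging_footprints_discarded(self):
        primer = NucleotideSequence("ACGTACGTACGTACGTACGT", "p")
        template = NucleotideSequence(primer.bases[5:], "t")  # shorter than the primer
        assert scan_partial_sites(primer, template, PartialAnnealingModel()) == []

    def test_scan_strand_matches_minus_orientation(self):
        rng = random.Random(9)
        template = NucleotideSequence(rand_dna(rng, 2000), "t")
        primer = NucleotideSequence(rand_dna(rng, 25), "p")
        model = PartialAnnealingModel()
        minus = [
            (s.interval.start, s.total_matches, s.three_prime_run)
            for s in scan_partial_sites(primer, template, model)
            if s.interval.strand == "-"
        ]
        hits = [
            (h.start, h.total_matches, h.three_prime_run)
            for h in scan_strand(primer, template, model)
        ]
        assert sorted(minus) == sorted(hits)


class TestSiteStatistics:
    def test_empty(self):
        st = site_statistics([])
        assert st.count == 0 and st.match_range is None

    def test_planted_range_mirrors_observed_span(self):
        rng = random.Random(10)
        primer = rand_dna(rng, 25)
        target = revcomp(primer)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}

        def window(m):
            cols = set(range(2)) | set(rng.sample(range(3, 25), m - 2))
            return "".join(target[c] if c in cols else flip[target[c]] for c in range(25))

        template = NucleotideSequence(
            rand_dna(rng, 100) + window(8) + rand_dna(rng, 100) + window(17) + rand_dna(rng, 100),
            "t",
        )
        # a 25-mer with 8 matches exceeds the default 60% mismatch ceiling, so
        # widen the fraction to probe the full observed 8-17 match span
        loose = PartialAnnealingModel(2, 8, 0.70)
        sites = [
            s
            for s in scan_partial_sites(NucleotideSequence(primer, "p"), template, loose)
            if s.interval.start in (100, 225)
        ]
        st = site_statistics(sites)
        assert st.count == 2 and st.match_range == (8, 17)

    def test_order_invariance(self):
        rng = random.Random(11)
        template = NucleotideSequence(rand_dna(rng, 3000), "t")
        primer = NucleotideSequence(rand_dna(rng, 25), "p")
        sites = scan_partial_sites(primer, template, PartialAnnealingModel())
        a = site_statistics(sites)
        b = site_statistics(list(reversed(sites)))
        assert a == b
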