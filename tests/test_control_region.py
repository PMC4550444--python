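"""Control-region scanners: motifs, poly-tracts, microsatellites, repeats."""

import numpy as np
import pytest

from mitochar.control_region import (
    control_region_report,
    find_microsatellites,
    find_motifs,
    find_poly_tracts,
    find_tandem_repeats,
)
from mitochar.errors import MitocharError
from mitochar.mito_io import FeatureClass, extract_gene_sequence, reverse_complement
from mitochar.synthetic_data import (
    ControlRegionPlan,
    SimParams,
    generate_mitogenome,
)


def _random_at_rich(rng, n, at=0.94):
    p = [at * 0.5, (1 - at) * 0.5, (1 - at) * 0.5, at * 0.5]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


class TestFindMotifs:
    def test_direct_match(self):
        hits = find_motifs("TTATACTAATT", "ATACTAA")
        assert [h.start for h in hits] == [3]

    def test_no_match_is_empty(self):
        assert find_motifs("AAAA", "ATAGA") == []

    def test_overlapping_occurrences_all_reported(self):
        assert [h.start for h in find_motifs("ATATATA", "ATA")] == [1, 3, 5]

    def test_both_strands(self):
        hits = find_motifs("AAATCTATAA", "ATAGA", both_strands=True)
        assert [(h.start, h.strand) for h in hits] == [(4, "reverse-complement")]

    def test_non_acgt_motif_rejected(self):
        with pytest.raises(MitocharError):
            find_motifs("ACGT", "ANGA")

    def test_planted_motif_recovered(self, synthetic):
        genome, table, gt = synthetic
        region = extract_gene_sequence(genome, table["control_region"])
        hits = find_motifs(region, "ATAGA")
        assert [h.start for h in hits] == [gt.cr_features["ATAGA"][0]]


class TestFindPolyTracts:
    def test_isolated_run(self):
        (tract,) = find_poly_tracts("C" + "T" * 18 + "C", "T", 10)
        assert (tract.base, tract.start, tract.length) == ("T", 2, 18)

    def test_below_threshold_is_empty(self):
        assert find_poly_tracts("T" * 9, "T", 10) == []

    def test_runs_are_maximal(self):
        tracts = find_poly_tracts("TTTTT", "T", 3)
        assert len(tracts) == 1
        assert tracts[0].length == 5

    def test_planted_tracts_recovered_exactly(self, synthetic):
        genome, table, gt = synthetic
        region = extract_gene_sequence(genome, table["control_region"])
        t = find_poly_tracts(region, "T", 10)
        assert [(x.start, x.length) for x in t] == [gt.cr_features["poly_T"]]
        a = find_poly_tracts(region, "A", 10)
        assert [(x.start, x.length) for x in a] == [gt.cr_features["poly_A"]]


def _brute_microsatellites(region, max_unit=6, min_copies=5):
    """Quadratic oracle: test every (start, unit length) pair directly."""
    n = len(region)
    found = set()
    for u in range(1, max_unit + 1):
        for i in range(n - u * min_copies + 1):
            unit = region[i : i + u]
            # primitive unit only
            if any(u % d == 0 and unit == unit[:d] * (u // d) for d in range(1, u)):
                continue
            copies = 1
            while region[i + copies * u : i + (copies + 1) * u] == unit:
                copies += 1
            if copies < min_copies:
                continue
            # maximality: not extendable by a full copy on the left
            if i >= u and region[i - u : i] == unit:
                continue
            found.add((i + 1, unit, copies))
    return found


def _canonical_subset(hits):
    return {(h.start, h.unit, h.copies) for h in hits}


class TestFindMicrosatellites:
    def test_at8_repeat(self):
        hits = find_microsatellites("G" + "AT" * 8 + "G")
        assert _canonical_subset(hits) == {(2, "AT", 8)}

    def test_below_copy_threshold_is_empty(self):
        assert find_microsatellites("ATATAT", min_copies=5) == []

    def test_canonical_phase_prefers_at_over_ta(self):
        hits = find_microsatellites("G" + "TA" * 8 + "TG")
        # run is TATA...TAT; the AT phase keeps 8 copies and is preferred
        (h,) = [x for x in hits if len(x.unit) == 2]
        assert h.unit == "AT"
        assert h.copies == 8

    def test_every_hit_revalidates_by_substring_check(self, synthetic):
        genome, table, _ = synthetic
        region = extract_gene_sequence(genome, table["control_region"])
        for h in find_microsatellites(region):
            assert region[h.start - 1 : h.start - 1 + h.span] == h.unit * h.copies

    def test_matches_brute_force_on_random_regions(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            region = _random_at_rich(rng, int(rng.integers(80, 500)))
            hits = find_microsatellites(region)
            # every reported hit revalidates and is maximal
            for h in hits:
                u = len(h.unit)
                s0 = h.start - 1
                assert region[s0 : s0 + h.span] == h.unit * h.copies
                assert region[s0 - u : s0] != h.unit  # cannot extend left
                assert region[s0 + h.span : s0 + h.span + u] != h.unit
            # every brute-force locus is covered by a reported hit of the
            # same period with at least as many copies (phase may differ
            # by less than one unit)
            for start, unit, copies in _brute_microsatellites(region):
                u = len(unit)
                span = copies * u
                covered = any(
                    len(h.unit) == u
                    and h.copies >= copies
                    and min(h.start + h.span, start + span)
                    - max(h.start, start)
                    >= (copies - 1) * u
                    for h in hits
                )
                assert covered, (region, start, unit, copies)


def _brute_tandem_repeats(region, min_period=10, min_identity=0.9):
    """Quadratic oracle: does ANY window repeat with the given identity?"""
    n = len(region)
    best = []
    for p in range(min_period, n // 2 + 1):
        for i in range(n - 2 * p + 1):
            matches = sum(
                region[i + k] == region[i + p + k] for k in range(p)
            )
            if matches / p >= min_identity:
                best.append((i + 1, p))
    return best


class TestFindTandemRepeats:
    def test_planted_exact_duplication(self):
        rng = np.random.default_rng(3)
        unit = _random_at_rich(rng, 51)
        region = _random_at_rich(rng, 120) + unit + unit + _random_at_rich(rng, 120)
        hits = find_tandem_repeats(region)
        assert any(
            h.period == 51 and h.copies >= 2.0 and h.identity == 1.0 for h in hits
        )

    def test_two_planted_duplications_both_reported(self):
        genome, table, gt = generate_mitogenome(
            SimParams(seed=5, control_region=ControlRegionPlan(duplications=(31, 25)))
        )
        region = extract_gene_sequence(genome, table["control_region"])
        hits = find_tandem_repeats(region)
        periods = {h.period for h in hits}
        for want in (31, 25):
            start, span = gt.cr_features[f"duplication_{want}bp"]
            assert any(
                abs(h.period - want) <= 1 and h.start >= start - 1 and h.identity >= 0.9
                for h in hits
            ), (want, hits)

    def test_uniform_random_region_has_no_hits(self):
        rng = np.random.default_rng(17)
        region = "".join(rng.choice(list("ACGT"), size=372))
        assert find_tandem_repeats(region) == []
        assert _brute_tandem_repeats(region) == []

    def test_short_region_returns_empty(self):
        assert find_tandem_repeats("ACGT" * 4) == []

    def test_agreement_with_brute_force_on_random_regions(self):
        rng = np.random.default_rng(29)
        for _ in range(15):
            region = _random_at_rich(rng, int(rng.integers(60, 300)), at=0.7)
            ours = find_tandem_repeats(region)
            oracle = _brute_tandem_repeats(region)
            # hit sets agree on existence (merging may change counts)
            assert bool(ours) == bool(oracle)


class TestControlRegionReport:
    def test_all_planted_features_reported(self, synthetic):
        genome, table, gt = synthetic
        region = extract_gene_sequence(genome, table["control_region"])
        rep = control_region_report(region)
        assert [h.start for h in rep.motif_hits] == [gt.cr_features["ATAGA"][0]]
        assert [(t.start, t.length) for t in rep.poly_t] == [gt.cr_features["poly_T"]]
        assert [(t.start, t.length) for t in rep.poly_a] == [gt.cr_features["poly_A"]]
        at_start, at_len = gt.cr_features["AT_repeat"]
        assert any(
            h.unit == "AT" and h.start == at_start and h.copies == at_len // 2
            for h in rep.microsatellites
        )

    def test_empty_region_gives_empty_report(self):
        rep = control_region_report("")
        assert rep.motif_hits == () and rep.microsatellites == ()

    def test_revcomp_report_mirrors_coordinates(self, synthetic):
        genome, table, gt = synthetic
        region = extract_gene_sequence(genome, table["control_region"])
        n = len(region)
        fwd = control_region_report(region)
        # scanning the reverse complement of the already-reversed region
        # must mirror every feature: a tract at s with length L maps to
        # n - (s + L - 1) + 1 on the other strand
        rev = control_region_report(reverse_complement(region), revcomp=True)
        assert rev.orientation == "reverse-complement"
        fwd_t = [(t.start, t.length) for t in fwd.poly_t]
        rev_t = [(t.start, t.length) for t in rev.poly_t]
        assert fwd_t == rev_t  # double reversal restores the original frame
        assert [h.start for h in rev.motif_hits] == [h.start for h in fwd.motif_hits]

    def test_scanner_outputs_shift_under_flanking_concatenation(self):
        rng = np.random.default_rng(31)
        core = "G" + "AT" * 8 + "G" + "T" * 12 + "G"
        flank = "".join(rng.choice(list("GC"), size=25))
        plain = find_microsatellites(core)
        shifted = find_microsatellites(flank + core + flank)
        assert {(h.start + len(flank), h.unit, h.copies) for h in plain} == {
            (h.start, h.unit, h.copies) for h in shifted
        }
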