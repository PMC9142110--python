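"""Control-region scanners: poly-N runs, microsatellites, tandem repeats,
stem-loops, and the five-part partition."""

import numpy as np
import pytest

from mitoprofile.control_region import (
    CrElement,
    find_microsatellites,
    find_poly_runs,
    find_stem_loops,
    find_tandem_repeats,
    partition_cr,
)
from mitoprofile.model import MitoError, revcomp
from mitoprofile.validation import recover_cr_elements
from mitoprofile.synthetic import GenomeConfig, generate_mitogenome


def _random_seq(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), size=n, p=list(p)))


class TestPolyRuns:
    def test_planted_run_recovered(self):
        rng = np.random.default_rng(0)
        seq = "ACGC" * 25 + "T" * 9 + "ACGC" * 25
        (e,) = find_poly_runs(seq)
        assert (e.start, e.end, e.details) == (101, 109, {"base": "T", "run_length": 9})

    def test_alternating_sequence_empty(self):
        assert find_poly_runs("ACACAC") == []

    def test_abutting_runs_stay_maximal_and_separate(self):
        es = find_poly_runs("TTTTTTTAAAAAAA")
        assert [(e.details["base"], e.details["run_length"]) for e in es] == [("T", 7), ("A", 7)]

    def test_min_len_validation(self):
        with pytest.raises(MitoError):
            find_poly_runs("AAAA", min_len=1)


class TestMicrosatellites:
    def test_at8_recovered(self):
        seq = "GGCC" + "AT" * 8 + "CCGG"
        (e,) = find_microsatellites(seq)
        assert (e.start, e.end) == (5, 20)
        assert e.details == {"unit": "AT", "copies": 8}

    def test_homopolymer_left_to_poly_run_scanner(self):
        assert find_microsatellites("AAAAAAAAAA") == []
        assert find_microsatellites("AAAAAAAAAA", include_homopolymers=True)

    def test_cag5_recovered(self):
        (e,) = find_microsatellites("TT" + "CAG" * 5 + "TT")
        assert e.details == {"unit": "CAG", "copies": 5}

    def test_output_irredundant_under_period_doubling(self):
        es = find_microsatellites("GGCC" + "AT" * 8 + "CCGG")
        assert len(es) == 1 and es[0].details["unit"] == "AT"


class TestTandemRepeats:
    def test_exact_triple_copy_recovered(self):
        rng = np.random.default_rng(5)
        unit = _random_seq(rng, 25)
        seq = _random_seq(rng, 80) + unit * 3 + _random_seq(rng, 80)
        hits = [e for e in find_tandem_repeats(seq) if e.details["unit_length"] == 25]
        assert hits and hits[0].details["copies"] == pytest.approx(3.0)
        assert (hits[0].start, hits[0].end) == (81, 155)

    def test_partial_copy_counted_fractionally(self):
        rng = np.random.default_rng(8)
        unit = _random_seq(rng, 19)

        def guard(b):  # any base that breaks the repeat continuation
            return "A" if b != "A" else "C"

        prefix = "GC" + "".join(guard(unit[-j]) for j in (3, 2, 1))
        suffix = "".join(guard(unit[(14 + i) % 19]) for i in range(5)) + "G"
        seq = prefix + unit * 3 + unit[:14] + suffix
        hits = [e for e in find_tandem_repeats(seq) if e.details["unit_length"] == 19]
        assert hits and hits[0].details["copies"] == pytest.approx((3 * 19 + 14) / 19, abs=1e-4)
        assert (hits[0].start, hits[0].end) == (6, 76)

    def test_random_sequence_mostly_empty_at_defaults(self):
        # detector specificity on unstructured uniform sequence
        hits = 0
        for seed in range(200):
            seq = _random_seq(np.random.default_rng(seed), 300)
            if find_tandem_repeats(seq):
                hits += 1
        assert hits <= 10  # >= 95% of seeds empty

    def test_short_period_arrays_left_to_microsat_scanner(self):
        assert find_tandem_repeats("GG" + "AT" * 20 + "GG") == []


class TestStemLoops:
    def _hairpin(self, rng, stem=18, loop=8, flank="GTA"):
        left = _random_seq(rng, stem)
        mid = ("AAGGAAGG" * 4)[:loop]  # loop ends can never pair inward
        # "CCA" guards cannot pair with any of the flank's first three bases
        return "CCA" + left + mid + revcomp(left) + flank + "CCC", 4, 3 + 2 * stem + loop

    def test_planted_perfect_hairpin_recovered(self):
        rng = np.random.default_rng(2)
        seq, start, end = self._hairpin(rng)
        hits = [e for e in find_stem_loops(seq) if e.start == start]
        assert hits
        d = hits[0].details
        assert (d["stem_length"], d["loop_length"], d["mismatches"]) == (18, 8, 0)

    def test_gta_flank_classified_modified(self):
        rng = np.random.default_rng(2)
        seq, start, _ = self._hairpin(rng, flank="GTA")
        (hit,) = [e for e in find_stem_loops(seq) if e.start == start]
        assert hit.details["flank_motif"] == "modified"

    def test_gat_flank_classified_exact(self):
        rng = np.random.default_rng(2)
        seq, start, _ = self._hairpin(rng, flank="GAAAT")
        (hit,) = [e for e in find_stem_loops(seq) if e.start == start]
        assert hit.details["flank_motif"] == "exact"

    def test_homopolymer_has_no_hairpin(self):
        assert find_stem_loops("A" * 200) == []


class TestShiftEquivariance:
    @pytest.mark.parametrize("scanner", [find_poly_runs, find_microsatellites,
                                         find_tandem_repeats, find_stem_loops])
    def test_origin_shifts_coordinates_only(self, scanner, synthetic_genome):
        g, t, _ = synthetic_genome
        seq = t["CR"].coding_sequence(g)
        base = scanner(seq, origin=1)
        shifted = scanner(seq, origin=1001)
        assert [(e.start + 1000, e.end + 1000, e.kind) for e in base] == [
            (e.start, e.end, e.kind) for e in shifted
        ]


class TestPartition:
    def test_generator_cr_partitions_into_five_parts(self, synthetic_genome):
        g, t, truth = synthetic_genome
        f = t["CR"]
        seq = f.coding_sequence(g)
        local = [
            CrElement(e["kind"], e["local_start"], e["local_end"], dict(e))
            for e in truth["cr_elements"]
        ]
        part = partition_cr(seq, local)
        assert [s[0] for s in part.segments] == [
            "lead", "repeat_block_1", "spacer_1", "repeat_block_2", "tail"
        ]
        assert part.lengths == [360, 75, 23, 44, 233]
        assert sum(part.lengths) == len(seq)

    def test_no_elements_gives_single_segment(self):
        part = partition_cr("ACGT" * 10, [])
        assert part.segments == [("whole", 1, 40)]

    def test_zero_length_cr_rejected(self):
        with pytest.raises(MitoError):
            partition_cr("", [])

    def test_segment_lengths_always_conserve_cr_length(self):
        for seed in (3, 4, 5):
            g, t, truth = generate_mitogenome(GenomeConfig(seed=seed))
            seq = t["CR"].coding_sequence(g)
            local = [CrElement(e["kind"], e["local_start"], e["local_end"], dict(e))
                     for e in truth["cr_elements"]]
            assert sum(partition_cr(seq, local).lengths) == len(seq)


class TestPlantAndRecover:
    def test_all_planted_elements_recovered_exactly(self):
        for seed in (0, 7, 13):
            genome, table, truth = generate_mitogenome(GenomeConfig(seed=seed))
            assert recover_cr_elements(genome, table, truth) == []
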