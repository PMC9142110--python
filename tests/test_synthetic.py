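"""The synthetic-mitogenome generator and tree-evolved alignments."""

import pytest

from mitoprofile.model import MitoError
from mitoprofile.organization import junction_gaps
from mitoprofile.phylogeny import jc_distance
from mitoprofile.synthetic import (
    CrPlan,
    GenomeConfig,
    RepeatBlockPlan,
    SimConfig,
    evolve_alignment,
    generate_mitogenome,
)
from mitoprofile.tree import from_newick


class TestGenerateMitogenome:
    def test_default_layout_has_37_genes_plus_cr(self, synthetic_genome):
        _, table, _ = synthetic_genome
        assert len(table) == 38
        assert len(table.by_class("PCG")) == 13
        assert len(table.by_class("tRNA")) == 22
        assert len(table.by_class("rRNA")) == 2
        assert len(table.by_class("CR")) == 1

    def test_same_seed_is_byte_identical(self):
        g1, _, _ = generate_mitogenome(GenomeConfig(seed=5))
        g2, _, _ = generate_mitogenome(GenomeConfig(seed=5))
        assert g1.sequence == g2.sequence

    def test_seed_changes_sequence_not_skeleton(self):
        g1, t1, _ = generate_mitogenome(GenomeConfig(seed=5))
        g2, t2, _ = generate_mitogenome(GenomeConfig(seed=6))
        assert g1.sequence != g2.sequence
        assert [(f.name, f.start, f.end, f.strand) for f in t1] == [
            (f.name, f.start, f.end, f.strand) for f in t2
        ]

    def test_planted_motif_overlaps_report_minus_seven(self, synthetic_genome):
        _, table, truth = synthetic_genome
        report = junction_gaps(table)
        assert report.ign_of("ATP6") == -7
        assert report.ign_of("ND4L") == -7
        assert all(m["matches_ATGNTAA"] for m in truth["motif_junctions"])

    def test_cr_plan_mismatch_is_config_error(self):
        bad = CrPlan(tail_len=100)  # no longer tiles the 735 bp CR
        with pytest.raises(MitoError, match="CR plan"):
            generate_mitogenome(GenomeConfig(seed=0, cr_plan=bad))

    def test_non_seven_motif_junction_is_config_error(self):
        cfg = GenomeConfig(seed=0, motif_junctions=(("ND2", "COI"),))
        with pytest.raises(MitoError, match="overlap 7"):
            generate_mitogenome(cfg)

    def test_repeat_block_plan_arithmetic(self):
        b = RepeatBlockPlan(19, 3, 18)
        assert b.length == 75 and b.copies == pytest.approx(75 / 19)

    def test_pcg_start_and_stop_codons_honored(self, synthetic_genome):
        g, table, truth = synthetic_genome
        for rec in truth["features"]:
            if rec["class"] != "PCG":
                continue
            cds = table[rec["name"]].coding_sequence(g)
            assert cds.startswith(rec["start_codon"])
            tail = {"TAA": "TAA", "TAG": "TAG", "T-": "T", "TA-": "TA"}[rec["stop_codon"]]
            assert cds.endswith(tail)

    def test_anticodon_positions_recomputed_clean(self, synthetic_genome):
        _, table, _ = synthetic_genome
        for f in table.by_class("tRNA"):
            assert f.anticodon_flag is None


class TestEvolveAlignment:
    def test_thirteen_genes_with_partition_truth(self):
        alns, truth = evolve_alignment(SimConfig(seed=3))
        assert len(alns) == 13
        total = sum(a.length for a in alns.values())
        assert max(e for _, e in truth["partitions"].values()) == total

    def test_deterministic_for_seed(self):
        a1, _ = evolve_alignment(SimConfig(seed=3))
        a2, _ = evolve_alignment(SimConfig(seed=3))
        assert all(a1[g].sequences == a2[g].sequences for g in a1)

    def test_zero_branch_lengths_everywhere_identical(self):
        taxa = from_newick(SimConfig().tree_newick).taxa()
        nwk = "(" + ",".join(f"{t}:0" for t in taxa) + ");"
        cfg = SimConfig(tree_newick=nwk, seed=1, gene_lengths={"ND2": 200})
        alns, _ = evolve_alignment(cfg)
        assert len(set(alns["ND2"].sequences.values())) == 1

    def test_jc_corrected_distance_matches_truth_under_jc(self):
        from mitoprofile.phylogeny import PhyloModel

        cfg = SimConfig(
            tree_newick="(X:0.05,Y:0.05);",
            model=PhyloModel(),  # JC truth
            gene_lengths={"g": 50_000},
            seed=2,
        )
        alns, _ = evolve_alignment(cfg)
        a = alns["g"]
        assert abs(jc_distance(a["X"], a["Y"]) - 0.1) < 0.01

    def test_invalid_gene_length_rejected(self):
        with pytest.raises(MitoError):
            evolve_alignment(SimConfig(gene_lengths={"g": 0}))


class TestYamlConfig:
    def test_yaml_config_round_trips_into_generator(self, tmp_path):
        from mitoprofile.synthetic import config_from_yaml

        cfg_yaml = tmp_path / "cfg.yaml"
        cfg_yaml.write_text(
            "seed: 9\n"
            "cr_plan:\n"
            "  lead_len: 360\n"
            "  spacer_len: 23\n"
            "  tail_len: 233\n"
            "  blocks:\n"
            "    - {unit_length: 19, full_copies: 3, partial_len: 18}\n"
            "    - {unit_length: 16, full_copies: 2, partial_len: 12}\n"
            "  hairpin: {stem: 15, loop: 8, offset: 150, flank: GTA}\n"
            "  microsat: {unit: AT, copies: 8, offset: 100}\n"
            "  poly_runs:\n"
            "    - {base: A, length: 9, offset: 62}\n"
            "    - {base: T, length: 9, offset: 156}\n"
        )
        cfg = config_from_yaml(cfg_yaml, seed=4)
        assert cfg.seed == 4  # explicit seed wins over the file's
        assert cfg.cr_plan.hairpin.stem == 15
        _, _, truth = generate_mitogenome(cfg)
        hp = [e for e in truth["cr_elements"] if e["kind"] == "stem_loop"]
        assert hp[0]["stem_length"] == 15
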