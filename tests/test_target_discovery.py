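import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet.target_discovery import (
    InteractionSite,
    MirnaFamily,
    MirnaRecord,
    PredictedSite,
    classify_biotype,
    collapse_families,
    filter_interactions,
    load_program_predictions,
    merge_evidence,
    read_interaction_table,
    scan_seed_sites,
    write_interaction_table,
)
from _oracles import regex_seed_scan


class TestCollapseFamilies:
    def test_groups_by_family(self):
        fams = collapse_families(
            [
                MirnaRecord("miR-A", "UAGCUUAUCAGACUGAUGUUGA", "F1"),
                MirnaRecord("miR-B", "CAGCUUAUCAGACUGAUGUUGA", "F1"),
            ]
        )
        assert len(fams) == 1
        assert fams[0].member_ids == {"miR-A", "miR-B"}
        assert fams[0].seed7 == "AGCUUAU"

    def test_unassigned_becomes_singleton(self):
        (fam,) = collapse_families([MirnaRecord("miR-C", "UAGCUUAUCAGACUGAUGUUGA", "")])
        assert fam.family_id == "miR-C"
        assert fam.member_ids == {"miR-C"}

    def test_empty_input(self):
        assert collapse_families([]) == []

    def test_seed_mismatch_names_family(self):
        with pytest.raises(ValueError, match="F1"):
            collapse_families(
                [
                    MirnaRecord("miR-A", "UAGCUUAUCAGACUGAUGUUGA", "F1"),
                    MirnaRecord("miR-B", "UUUUUUUUCAGACUGAUGUUGA", "F1"),
                ]
            )

    def test_invalid_mature_sequence(self):
        with pytest.raises(ValueError):
            MirnaRecord("miR-X", "ACGTACGT", "F")  # DNA alphabet
        with pytest.raises(ValueError):
            MirnaRecord("miR-Y", "ACGUACG", "F")  # too short


def _tx(seq, tid="T1", gene="G1"):
    from cernet.target_discovery import TranscriptRecord

    return TranscriptRecord(tid, gene, gene, "protein_coding", seq)


class TestScanSeedSites:
    def test_mir21_8mer(self, mir21_family):
        # rc of miR-21 positions 2-8 (AGCUUAU) is ATAAGCT; trailing A -> 8mer
        (site,) = scan_seed_sites(_tx("GGGATAAGCTAGGG"), mir21_family)
        assert (site.start, site.end, site.site_type) == (3, 11, "8mer")

    def test_mir21_7mer_m8_without_a1(self, mir21_family):
        (site,) = scan_seed_sites(_tx("GGGATAAGCTGGGG"), mir21_family)
        assert (site.start, site.end, site.site_type) == (3, 10, "7mer-m8")

    def test_poly_a_has_no_sites(self, mir21_family):
        assert scan_seed_sites(_tx("A" * 200), mir21_family) == []

    def test_7mer_a1_without_m8(self, mir21_family):
        # core match TAAGCT + A, preceded by G (not the m8-pairing A)
        (site,) = scan_seed_sites(_tx("GGGTAAGCTAGGG"), mir21_family)
        assert (site.start, site.end, site.site_type) == (3, 10, "7mer-A1")

    def test_6mer_disabled_by_default(self, mir21_family):
        assert scan_seed_sites(_tx("GGGTAAGCTGGGG"), mir21_family) == []
        (site,) = scan_seed_sites(
            _tx("GGGTAAGCTGGGG"),
            mir21_family,
            frozenset({"8mer", "7mer-m8", "7mer-A1", "6mer"}),
        )
        assert (site.start, site.end, site.site_type) == (3, 9, "6mer")

    def test_unknown_site_type_rejected(self, mir21_family):
        with pytest.raises(ValueError, match="site types"):
            scan_seed_sites(_tx("ACGT" * 10), mir21_family, frozenset({"9mer"}))

    @pytest.mark.parametrize("seed_idx", range(5))
    def test_agrees_with_regex_oracle(self, seed_idx):
        rng = np.random.default_rng(100 + seed_idx)
        seed7 = "".join(rng.choice(list("ACGU"), size=7))
        family = MirnaFamily(f"F{seed_idx}", frozenset({"m"}), seed7)
        all_types = frozenset({"8mer", "7mer-m8", "7mer-A1", "6mer"})
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(500, 3000))))
            got = {
                (s.start, s.end, s.site_type)
                for s in scan_seed_sites(_tx(seq), family, all_types)
            }
            assert got == regex_seed_scan(seq, seed7, include_6mer=True)


class TestClassifyBiotype:
    @pytest.mark.parametrize(
        "biotype, expected",
        [("protein_coding", "protein_coding")]
        + [
            (b, "lncRNA")
            for b in (
                "processed_transcript",
                "lincRNA",
                "3prime_overlapping_ncrna",
                "antisense",
                "non_coding",
                "sense_intronic",
                "sense_overlapping",
            )
        ]
        + [
            (b, "sncRNA")
            for b in ("snRNA", "snoRNA", "rRNA", "Mt_tRNA", "Mt_rRNA", "misc_RNA", "miRNA")
        ]
        + [
            (b, "pseudogene")
            for b in (
                "polymorphic_pseudogene",
                "pseudogene",
                "IG_C_pseudogene",
                "IG_J_pseudogene",
                "IG_V_pseudogene",
                "TR_V_pseudogene",
                "TR_J_pseudogene",
            )
        ],
    )
    def test_all_listed_biotypes(self, biotype, expected):
        assert classify_biotype(biotype) == expected

    def test_unknown_is_other(self):
        assert classify_biotype("made_up_biotype") == "other"


def _pred(fam, gene, start, end, program):
    return PredictedSite(fam, gene, start, end, "external", program)


class TestMergeEvidence:
    def test_overlapping_programs_merge(self):
        merged = merge_evidence(
            [_pred("F1", "G", 10, 17, "TargetScan"), _pred("F1", "G", 12, 19, "PITA")]
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (10, 19)
        assert merged[0].program_count == 2

    def test_disjoint_sites_stay_separate(self):
        merged = merge_evidence(
            [_pred("F1", "G", 10, 17, "TargetScan"), _pred("F1", "G", 30, 37, "PITA")]
        )
        assert len(merged) == 2

    def test_adjacency_does_not_merge(self):
        merged = merge_evidence(
            [_pred("F1", "G", 10, 17, "TargetScan"), _pred("F1", "G", 17, 24, "PITA")]
        )
        assert len(merged) == 2

    def test_five_programs_one_locus(self):
        programs = ["TargetScan", "miRanda", "PITA", "PicTar2", "RNA22"]
        merged = merge_evidence(
            [_pred("F1", "G", 10 + i, 17 + i, p) for i, p in enumerate(programs)]
        )
        assert len(merged) == 1
        assert merged[0].program_count == 5

    def test_different_families_never_merge(self):
        merged = merge_evidence(
            [_pred("F1", "G", 10, 17, "PITA"), _pred("F2", "G", 10, 17, "PITA")]
        )
        assert len(merged) == 2

    site_lists = st.lists(
        st.builds(
            lambda fam, gene, start, length, program: _pred(
                fam, gene, start, start + length, program
            ),
            fam=st.sampled_from(["F1", "F2"]),
            gene=st.sampled_from(["G1", "G2"]),
            start=st.integers(0, 120),
            length=st.integers(6, 25),
            program=st.sampled_from(["TargetScan", "miRanda", "PITA"]),
        ),
        min_size=1,
        max_size=25,
    )

    @given(site_lists, st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_order_independent(self, sites, rand):
        def key(ms):
            return sorted(
                (m.family_id, m.gene_id, m.start, m.end, tuple(sorted(m.programs)))
                for m in ms
            )

        merged = merge_evidence(sites)
        shuffled = sites[:]
        rand.shuffle(shuffled)
        assert key(merge_evidence(shuffled)) == key(merged)
        remerged = merge_evidence(
            [
                PredictedSite(m.family_id, m.gene_id, m.start, m.end, "external", p)
                for m in merged
                for p in m.programs
            ]
        )
        assert key(remerged) == key(merged)


class TestLoadProgramPredictions:
    HEADER = "program\tmirna_id\tgene_id\tchrom\tstart\tend\tstrand\n"

    def _families(self):
        return collapse_families(
            [MirnaRecord("miR-A", "UAGCUUAUCAGACUGAUGUUGA", "F1")]
        )

    def test_known_program_mapped_to_family(self):
        tsv = self.HEADER + "TargetScan\tmiR-A\tG\tchrG\t10\t17\t+\n"
        load = load_program_predictions(io.StringIO(tsv), self._families())
        assert load.n_dropped == 0
        (site,) = load.sites
        assert (site.family_id, site.program) == ("F1", "TargetScan")

    def test_same_site_two_programs_kept_separate(self):
        tsv = (
            self.HEADER
            + "TargetScan\tmiR-A\tG\tchrG\t10\t17\t+\n"
            + "PITA\tmiR-A\tG\tchrG\t10\t17\t+\n"
        )
        load = load_program_predictions(io.StringIO(tsv), self._families())
        assert len(load.sites) == 2

    def test_unmappable_mirna_dropped_and_counted(self):
        tsv = self.HEADER + "PITA\tmiR-unknown\tG\tchrG\t10\t17\t+\n"
        with pytest.warns(UserWarning, match="dropped 1"):
            load = load_program_predictions(io.StringIO(tsv), self._families())
        assert load.sites == [] and load.n_dropped == 1

    def test_unknown_program_warned_but_kept(self):
        tsv = self.HEADER + "NovelTool\tmiR-A\tG\tchrG\t10\t17\t+\n"
        with pytest.warns(UserWarning, match="NovelTool"):
            load = load_program_predictions(io.StringIO(tsv), self._families())
        assert load.sites[0].program == "NovelTool"


class TestFilterInteractions:
    def _site(self, support, programs):
        return InteractionSite(
            "F1", "G", "T1", 0, 8, "+",
            frozenset(list("abcdef")[:programs]),
            supporting_experiments=support,
        )

    @pytest.mark.parametrize(
        "support, programs, thresholds, kept",
        [
            (2, 3, (1, 3), True),
            (0, 5, (1, 1), False),
            (0, 1, (0, 0), True),  # vacuous thresholds keep everything
            (1, 2, (1, 3), False),
        ],
    )
    def test_threshold_logic(self, support, programs, thresholds, kept):
        out = filter_interactions([self._site(support, programs)], *thresholds)
        assert (len(out) == 1) is kept

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_interactions([], min_experiments=-1)


def test_interaction_table_roundtrip(tmp_path):
    sites = [
        InteractionSite("F1", "G1", "T1", 5, 13, "+", frozenset({"builtin"}), 2, 37),
        InteractionSite("F2", "G2", "T2", 0, 7, "+", frozenset({"PITA", "RNA22"}), 0, 0),
    ]
    path = tmp_path / "sites.tsv"
    write_interaction_table(sites, path)
    assert read_interaction_table(path) == sites
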