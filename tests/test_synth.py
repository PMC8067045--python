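"""Synthetic generators: determinism, planted structure, truth consistency."""

import hashlib
from pathlib import Path

import pandas as pd
import pytest

from budmir import synth
from budmir.catalog import parse_mirna_id
from budmir.config import SynthConfig
from budmir.targets import mismatch_vector, _revcomp


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestConfig:
    def test_planted_fold_below_two_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(planted_fold=1.5)

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(mirna_len=10)


class TestReference:
    def test_counts_forced_by_config(self):
        cfg = SynthConfig(seed=0, n_families=2, members_per_family=2,
                          n_diff_families=1)
        ref = synth.gen_mirna_reference(cfg)
        families = {parse_mirna_id(m)[1] for m in ref}
        assert len(families) == 2
        focal = [m for m in ref if m.startswith("vvi-")]
        assert len(focal) == 2  # first family only; second is conserved-only

    def test_sequence_length(self, synth_cfg, synth_ref):
        assert all(len(s) == synth_cfg.mirna_len for s in synth_ref.values())

    def test_some_family_spans_two_species(self, synth_ref):
        by_family: dict[str, set] = {}
        for m in synth_ref:
            sp, fam = parse_mirna_id(m)
            by_family.setdefault(fam, set()).add(sp)
        assert any(len(sp) >= 2 for sp in by_family.values())

    def test_deterministic(self, synth_cfg):
        assert synth.gen_mirna_reference(synth_cfg) == \
            synth.gen_mirna_reference(synth_cfg)


class TestLibraries:
    def test_manifest_marks_planted_families(self, synth_cfg, synth_libs):
        _, _, fam_truth = synth_libs
        diff = synth_cfg.differential_families()
        marked = fam_truth[fam_truth["is_differential"]]
        assert set(marked["family"]) == set(diff)
        assert (marked["true_fold"] == synth_cfg.planted_fold).all()
        assert dict(zip(marked["family"], marked["direction"])) == diff

    def test_near_miss_reads_flagged_unannotatable(self, synth_libs):
        _, seq_truth, _ = synth_libs
        nearmiss = seq_truth[seq_truth["origin"].str.contains("nearmiss")]
        assert len(nearmiss) > 0
        assert (~nearmiss["annotatable"]).all()
        assert (nearmiss["mm_to_nearest_ref"] == 3).all()

    def test_contains_variant_tiers(self, synth_libs):
        _, seq_truth, _ = synth_libs
        assert set(seq_truth["mm_to_nearest_ref"]) >= {0, 1, 2, 3}

    def test_depth_validation(self, synth_ref):
        cfg = SynthConfig(seed=0)
        cfg.library_depth = 0
        with pytest.raises(ValueError):
            synth.gen_smallrna_libraries(cfg, synth_ref)

    def test_deterministic(self, synth_cfg, synth_ref):
        a = synth.gen_smallrna_libraries(synth_cfg, synth_ref)[0]
        b = synth.gen_smallrna_libraries(synth_cfg, synth_ref)[0]
        pd.testing.assert_frame_equal(a, b)


class TestTranscriptome:
    def test_site_truth_consistent_with_fasta(self, synth_ref,
                                              synth_transcriptome):
        """Re-deriving each planted site's mismatch vector from the FASTA
        must reproduce the truth table exactly."""
        transcriptome, truth = synth_transcriptome
        for row in truth.itertuples(index=False):
            window = transcriptome[row.transcript_id][row.start - 1:row.end]
            vec = mismatch_vector(synth_ref[row.mirna_id], window)
            derived = {i + 1 for i, v in enumerate(vec) if v}
            stated = ({int(p) for p in str(row.mismatch_positions).split(",")}
                      if row.mismatch_positions else set())
            assert derived == stated

    def test_rule_outcomes_recorded(self, synth_transcriptome):
        _, truth = synth_transcriptome
        by_pattern = {str(r.mismatch_positions): bool(r.passes_positional)
                      for r in truth.itertuples(index=False)}
        assert by_pattern.get("", True) is True       # perfect site passes
        if "10" in by_pattern:
            assert by_pattern["10"] is False           # central window
        if "3,5" in by_pattern:
            assert by_pattern["3,5"] is False          # two in the 2-9 window
        if "13,14,15" in by_pattern:
            assert by_pattern["13,14,15"] is False     # three consecutive

    def test_out_of_range_mismatch_position_rejected(self, synth_ref):
        mid = sorted(synth_ref)[0]
        cfg = SynthConfig(seed=0, site_plan=[(mid, "TX0000", (22,))])
        with pytest.raises(ValueError, match="outside"):
            synth.gen_transcriptome_with_sites(cfg, synth_ref)

    def test_unknown_mirna_rejected(self, synth_ref):
        cfg = SynthConfig(seed=0, site_plan=[("vvi-miR9999x", "TX0000", ())])
        with pytest.raises(ValueError, match="unknown miRNA"):
            synth.gen_transcriptome_with_sites(cfg, synth_ref)


class TestDegTable:
    def test_planted_de_genes_pass_thresholds(self, synth_cfg):
        deg, truth = synth.gen_deg_table(synth_cfg)
        merged = deg.merge(truth, on="gene_id")
        de = merged[merged["true_status"].isin(["up_in_SD", "down_in_SD"])]
        assert (de["adjusted_p"] <= 0.05).all()
        assert (de["log2fc_sd_vs_ld"].abs() >= 1).all()
        non_de = merged[merged["true_status"] == "not_DE"]
        assert (non_de["adjusted_p"] > 0.05).all()

    def test_not_expressed_genes_below_fpkm_floor(self, synth_cfg):
        deg, truth = synth.gen_deg_table(synth_cfg)
        merged = deg.merge(truth, on="gene_id")
        ne = merged[merged["true_status"] == "not_expressed"]
        assert len(ne) > 0
        assert ((ne["fpkm_ld"] < 1) & (ne["fpkm_sd"] < 1)).all()

    def test_inverse_pair_directions_oppose_mirna(self, synth_cfg):
        _, truth = synth.gen_deg_table(synth_cfg)
        diff = synth_cfg.differential_families()
        planted = truth[truth["planted_inverse"]]
        assert len(planted) == synth_cfg.n_inverse_pairs
        for row in planted.itertuples(index=False):
            fam = parse_mirna_id(row.mirna_id)[1]
            expected = "down_in_SD" if diff[fam] == "SD" else "up_in_SD"
            assert row.true_status == expected

    def test_too_many_inverse_pairs_rejected(self):
        cfg = SynthConfig(seed=0, n_inverse_pairs=3)
        cfg.n_inverse_pairs = 10**6
        with pytest.raises(ValueError, match="exceeds"):
            synth.gen_deg_table(cfg)


class TestGenesetsAndPpi:
    def test_planted_set_is_downregulated_and_large_enough(self, synth_cfg):
        pathways, _, _, truth = synth.gen_genesets_and_ppi(synth_cfg)
        _, deg_truth = synth.gen_deg_table(synth_cfg)
        planted = pathways[truth["enriched_set"]]["members"]
        assert len(planted) >= 7
        down = set(deg_truth.loc[deg_truth["true_status"] == "down_in_SD",
                                 "gene_id"])
        assert planted <= down

    def test_ppi_scores_span_the_threshold(self, synth_cfg):
        _, _, ppi, _ = synth.gen_genesets_and_ppi(synth_cfg)
        assert 700 in set(ppi["score"]) and 701 in set(ppi["score"])

    def test_hub_has_targets_and_interactors(self, synth_cfg):
        _, tf_sets, ppi, truth = synth.gen_genesets_and_ppi(synth_cfg)
        hub = truth["hub"]
        assert hub in tf_sets and len(tf_sets[hub]["members"]) > 0
        touching = ppi[(ppi["protein_a"] == hub) | (ppi["protein_b"] == hub)]
        assert (touching["score"] > 700).any()


class TestGenerateAll:
    def test_byte_identical_across_runs(self, tmp_path, synth_cfg):
        p1 = synth.generate_all(synth_cfg, tmp_path / "a")
        p2 = synth.generate_all(synth_cfg, tmp_path / "b")
        for key in p1:
            assert _sha(p1[key]) == _sha(p2[key]), key

    def test_different_seed_changes_outputs(self, tmp_path):
        p1 = synth.generate_all(SynthConfig(seed=1), tmp_path / "a")
        p2 = synth.generate_all(SynthConfig(seed=2), tmp_path / "b")
        assert _sha(p1["counts_tsv"]) != _sha(p2["counts_tsv"])
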