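import numpy as np
import pytest

from pregbs.io import read_bed, read_fasta, read_maf
from pregbs.motif import GR_MOTIF_PATTERN, PRE_GBS_PATTERN, compile_motif, scan_genome
from pregbs.simulate import (
    SimulationConfig,
    analyze_dataset,
    compose_alignment,
    emit_dataset,
    evolve_lineage,
    make_ancestor,
    simulate_dataset,
)

SMALL = dict(length=40_000, n_cpg_sites=20, n_tpg_sites=60)


class TestConfig:
    def test_rejects_bad_probabilities(self):
        with pytest.raises(ValueError):
            SimulationConfig(mu=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(lam=0.5)

    def test_rejects_infeasible_placement(self):
        with pytest.raises(ValueError, match="too small"):
            SimulationConfig(length=1000, n_cpg_sites=50, n_tpg_sites=50)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("length: 40000\nn_cpg_sites: 20\nn_tpg_sites: 60\nlambda: 30\n")
        config = SimulationConfig.from_yaml(path)
        assert config.lam == 30 and config.length == 40_000


class TestAncestor:
    def test_planted_sites_recoverable(self):
        config = SimulationConfig(**SMALL)
        ancestor, sites = make_ancestor(config, seed=2)
        assert len(sites) == 80
        pre = compile_motif(PRE_GBS_PATTERN)
        consensus = compile_motif(GR_MOTIF_PATTERN)
        for site in sites:
            window = ancestor.sequence[site.anc_start : site.anc_start + 13]
            assert window == site.planted_seq
            motif = pre if site.planted_class == "cpg" else consensus
            assert motif.matches(window)

    def test_sites_non_overlapping(self):
        _, sites = make_ancestor(SimulationConfig(**SMALL), seed=2)
        starts = sorted(site.anc_start for site in sites)
        assert all(b - a >= 13 for a, b in zip(starts, starts[1:]))

    def test_deterministic_under_seed(self):
        config = SimulationConfig(**SMALL)
        a1, _ = make_ancestor(config, seed=5)
        a2, _ = make_ancestor(config, seed=5)
        a3, _ = make_ancestor(config, seed=6)
        assert a1.sequence == a2.sequence != a3.sequence

    def test_gc_content_honoured(self):
        config = SimulationConfig(length=200_000, n_cpg_sites=0, n_tpg_sites=0,
                                  gc_content=0.6)
        ancestor, _ = make_ancestor(config, seed=1)
        gc = sum(ancestor.sequence.count(b) for b in "GC") / len(ancestor.sequence)
        assert gc == pytest.approx(0.6, abs=0.01)


class TestEvolution:
    def test_mu_zero_identity(self):
        config = SimulationConfig(**SMALL, mu=0.0, delta=0.0)
        ancestor, _ = make_ancestor(config, seed=3)
        lineage = evolve_lineage(ancestor, config, lineage_seed=4)
        assert lineage.derived.sequence == ancestor.sequence
        block = compose_alignment(lineage, evolve_lineage(ancestor, config, 5))
        assert "-" not in block.ref_text and block.ref_text == block.tgt_text

    def test_delta_zero_no_gap_columns(self):
        config = SimulationConfig(**SMALL, delta=0.0)
        ancestor, _ = make_ancestor(config, seed=3)
        block = compose_alignment(
            evolve_lineage(ancestor, config, 4), evolve_lineage(ancestor, config, 5)
        )
        assert "-" not in block.ref_text and "-" not in block.tgt_text

    def test_substitution_rate_matches_mu(self):
        config = SimulationConfig(length=200_000, n_cpg_sites=0, n_tpg_sites=0,
                                  mu=0.02, lam=1.0, delta=0.0, gc_content=0.4)
        ancestor, _ = make_ancestor(config, seed=8)
        lineage = evolve_lineage(ancestor, config, 9)
        diff = sum(a != b for a, b in zip(ancestor.sequence, lineage.derived.sequence))
        assert diff / len(ancestor.sequence) == pytest.approx(0.02, rel=0.1)

    def test_high_lambda_destroys_planted_cpg(self):
        # lambda*mu/3 = 1: the elevated deamination channel fires at every
        # CpG, so nearly every planted CpG loses its dinucleotide
        config = SimulationConfig(length=100_000, n_cpg_sites=100, n_tpg_sites=0,
                                  mu=0.06, lam=50.0, delta=0.0)
        ancestor, sites = make_ancestor(config, seed=10)
        lineage = evolve_lineage(ancestor, config, 11)
        destroyed = 0
        for site in sites:
            got = lineage.derived.sequence[site.anc_start + 3 : site.anc_start + 5]
            destroyed += got != "CG"
        assert destroyed >= 99

    def test_lambda_one_cpg_behaves_like_background(self):
        # at lambda=1 the CpG channel reduces exactly to the uniform model:
        # C->T at CpG sites happens at ~mu/3, not faster
        config = SimulationConfig(length=400_000, n_cpg_sites=0, n_tpg_sites=0,
                                  mu=0.03, lam=1.0, delta=0.0, gc_content=0.5)
        ancestor, _ = make_ancestor(config, seed=12)
        lineage = evolve_lineage(ancestor, config, 13)
        anc, der = ancestor.sequence, lineage.derived.sequence
        cpg_c = [i for i in range(len(anc) - 1) if anc[i : i + 2] == "CG"]
        to_t = sum(der[i] == "T" for i in cpg_c) / len(cpg_c)
        assert to_t == pytest.approx(0.01, rel=0.2)

    def test_indel_alignment_is_exact_record(self):
        config = SimulationConfig(**SMALL, delta=0.01)
        ancestor, _ = make_ancestor(config, seed=3)
        lin1 = evolve_lineage(ancestor, config, 4)
        lin2 = evolve_lineage(ancestor, config, 5)
        block = compose_alignment(lin1, lin2)
        assert block.ref_text.replace("-", "") == lin1.derived.sequence
        assert block.tgt_text.replace("-", "") == lin2.derived.sequence


class TestDataset:
    def test_emitted_files_consistent(self, tmp_path):
        config = SimulationConfig(**SMALL)
        paths = emit_dataset(config, tmp_path / "d", seed=6)
        (ref,) = read_fasta(paths["ref_fasta"])
        (tgt,) = read_fasta(paths["tgt_fasta"])
        (block,) = read_maf(paths["maf"])
        assert block.ref_text.replace("-", "") == ref.sequence
        assert block.tgt_text.replace("-", "") == tgt.sequence
        for iv in read_bed(paths["regulatory_bed"]):
            assert 0 <= iv.start < iv.end <= len(ref.sequence) + config.track_padding

    def test_byte_identical_reruns(self, tmp_path):
        config = SimulationConfig(**SMALL)
        p1 = emit_dataset(config, tmp_path / "a", seed=6)
        p2 = emit_dataset(config, tmp_path / "b", seed=6)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_zero_planted_sites_valid(self, tmp_path):
        config = SimulationConfig(length=10_000, n_cpg_sites=0, n_tpg_sites=0)
        paths = emit_dataset(config, tmp_path / "z", seed=1)
        assert read_bed(paths["regulatory_bed"]) == []

    def test_extreme_track_rates_match_truth(self):
        config = SimulationConfig(**SMALL, rho=1.0, rho0=0.0)
        ds = simulate_dataset(config, seed=14)
        regulatory_truth = {t.ref_start for t in ds.truth if t.regulatory}
        derived_truth = {
            t.ref_start for t in ds.truth if t.deamination_derived and t.ref_start >= 0
        }
        assert regulatory_truth == derived_truth

    def test_truth_coordinates_match_genomes(self):
        config = SimulationConfig(**SMALL)
        ds = simulate_dataset(config, seed=15)
        pre = compile_motif(PRE_GBS_PATTERN)
        consensus = compile_motif(GR_MOTIF_PATTERN)
        checked = 0
        for t in ds.truth:
            if t.ref_start < 0:
                continue
            seq = ds.ref.sequence[t.ref_start : t.ref_end]
            expected = {"consensus": consensus, "pre": pre}.get(t.ref_class)
            if expected is not None:
                assert expected.matches(seq)
                checked += 1
        assert checked > 50


class TestPipelineOnSimulation:
    def test_mu_zero_full_stack_null(self):
        config = SimulationConfig(**SMALL, mu=0.0, delta=0.0)
        result = analyze_dataset(simulate_dataset(config, seed=16))
        assert result.spectrum.n_variants == 0
        assert result.pre_gbs_total == result.pre_gbs_unique == 0

    def test_pre_gbs_recall_against_truth(self):
        # strong deamination, no indels: every planted CpG site that became
        # a consensus match in the human lineage while the sister kept its
        # CpG must be recovered as a pre-GBS
        config = SimulationConfig(length=100_000, n_cpg_sites=150, n_tpg_sites=0,
                                  mu=0.02, lam=40.0, delta=0.0)
        ds = simulate_dataset(config, seed=17)
        result = analyze_dataset(ds)
        expected = {
            t.ref_start
            for t in ds.truth
            if t.deamination_derived and t.tgt_class == "pre"
        }
        got = {r.occurrence.interval.start for r in result.homologs
               if r.status == "ok"}
        from pregbs.variants import classify_homolog

        motif = compile_motif(GR_MOTIF_PATTERN)
        got_pre = {
            r.occurrence.interval.start
            for r in result.homologs
            if r.status == "ok" and classify_homolog(r.homolog_seq, motif).pooled_nt == "G"
        }
        assert expected, "scenario should produce deamination-derived sites"
        assert expected <= got_pre
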