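"""Synthetic-data generators: determinism, planted truth, calibration."""

import filecmp

import numpy as np
import pytest

from methdriver.annotation import (
    join_probes_to_promoters,
    promoter_windows,
    read_gtf_lnc,
    read_manifest,
)
from methdriver.bsp import call_clone, sample_summary
from methdriver.diffexpr import rank_test_de
from methdriver.diffmeth import probe_dm
from methdriver.integrate import spearman_pair
from methdriver.simulate import (
    SimConfig,
    gen_annotation,
    gen_bsp,
    gen_counts,
    gen_methylation,
    gen_survival,
    simulate_all,
)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path, small_cfg):
        simulate_all(small_cfg, tmp_path / "a")
        simulate_all(small_cfg, tmp_path / "b")
        names = [p.name for p in (tmp_path / "a").iterdir() if p.is_file()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert not mismatch and not errors
        clones_a = sorted(p.name for p in (tmp_path / "a" / "bsp_clones").iterdir())
        m2, mm2, e2 = filecmp.cmpfiles(
            tmp_path / "a" / "bsp_clones", tmp_path / "b" / "bsp_clones",
            clones_a, shallow=False,
        )
        assert not mm2 and not e2

    def test_different_seeds_differ(self, small_cfg):
        import dataclasses

        ann1 = gen_annotation(small_cfg)
        ann2 = gen_annotation(dataclasses.replace(small_cfg, seed=small_cfg.seed + 1))
        b1 = gen_methylation(small_cfg, ann1)
        b2 = gen_methylation(
            dataclasses.replace(small_cfg, seed=small_cfg.seed + 1), ann2
        )
        assert not np.array_equal(b1.beta, b2.beta)


class TestAnnotationFixture:
    def test_truth_join_reproduced_by_annotation_module(self, tmp_path, small_cfg):
        simulate_all(small_cfg, tmp_path)
        probes = read_manifest(tmp_path / "manifest.tsv")
        tx = read_gtf_lnc(tmp_path / "lnc.gtf", {"lincRNA", "antisense"})
        windows = promoter_windows(tx)
        got = join_probes_to_promoters(probes, windows)
        import json

        truth = json.loads((tmp_path / "truth.json").read_text())
        assert got == [tuple(p) for p in truth["join"]]

    def test_both_strands_present(self, small_cfg):
        ann = gen_annotation(small_cfg)
        strands = {t.strand for t in ann.transcripts}
        assert strands == {"+", "-"}

    def test_driver_probes_inside_their_promoter(self, small_cfg):
        ann = gen_annotation(small_cfg)
        windows = {w.gene_id: w for w in promoter_windows(ann.transcripts)}
        pos = {p.probe_id: (p.chrom, p.pos) for p in ann.probes}
        for gid, info in ann.truth.driver_genes.items():
            w = windows[gid]
            for pid in info["probe_ids"]:
                chrom, p = pos[pid]
                assert chrom == w.chrom and w.start <= p < w.end


class TestMethylation:
    def test_beta_values_in_unit_interval(self, small_cfg):
        ann = gen_annotation(small_cfg)
        b = gen_methylation(small_cfg, ann)
        assert np.nanmin(b.beta) >= 0 and np.nanmax(b.beta) <= 1

    def test_null_config_within_type_one_expectation(self):
        cfg = SimConfig(seed=3, n_tumor=12, n_normal=12, n_genes=20,
                        n_probes=300, delta_beta_planted=0.0)
        ann = gen_annotation(cfg)
        b = gen_methylation(cfg, ann)
        res = probe_dm(b)
        n_sig = sum(r.fdr < 0.05 for r in res)
        # BH under the global null rejects anything at all with prob <= alpha
        assert n_sig / len(res) < 0.05

    def test_planted_probes_recovered(self):
        cfg = SimConfig(seed=9, n_tumor=15, n_normal=15, n_genes=40, n_probes=300,
                        frac_driver=0.15, delta_beta_planted=0.5)
        ann = gen_annotation(cfg)
        res = {r.probe_id: r for r in probe_dm(gen_methylation(cfg, ann))}
        planted = [p for i in ann.truth.driver_genes.values() for p in i["probe_ids"]]
        assert np.mean([res[p].direction != "ns" for p in planted]) >= 0.9


class TestCounts:
    def test_near_poisson_at_tiny_dispersion(self):
        cfg = SimConfig(seed=4, n_tumor=50, n_normal=50, n_genes=40,
                        nb_dispersion=0.0, frac_driver=0.05, linkage=False)
        ann = gen_annotation(cfg)
        m = gen_counts(cfg, ann)
        null_genes = [i for i, g in enumerate(m.genes)
                      if g not in ann.truth.driver_genes]
        ratios = [m.counts[i].var() / m.counts[i].mean() for i in null_genes[:20]]
        assert np.median(ratios) == pytest.approx(1.0, rel=0.35)

    def test_planted_drivers_recovered_by_de(self):
        cfg = SimConfig(seed=6, n_tumor=20, n_normal=20, n_genes=60,
                        frac_driver=0.2, linkage=False)
        ann = gen_annotation(cfg)
        res = {r.gene_id: r for r in rank_test_de(gen_counts(cfg, ann))}
        drivers = ann.truth.driver_genes
        assert np.mean([res[g].direction != "ns" for g in drivers]) >= 0.9

    def test_linkage_mode_induces_negative_correlation(self):
        cfg = SimConfig(seed=8, n_tumor=20, n_normal=20, n_genes=40,
                        frac_driver=0.25, linkage=True)
        ann = gen_annotation(cfg)
        beta = gen_methylation(cfg, ann)
        m = gen_counts(cfg, ann, beta)
        probe_ix = {p: i for i, p in enumerate(beta.probes)}
        gene_ix = {g: i for i, g in enumerate(m.genes)}
        rhos = []
        for gid, info in ann.truth.driver_genes.items():
            rows = [probe_ix[p] for p in info["probe_ids"]]
            mean_beta = beta.beta[rows].mean(axis=0)
            rho, _ = spearman_pair(mean_beta, m.counts[gene_ix[gid]].astype(float))
            rhos.append(rho)
        assert np.median(rhos) < -0.3


class TestBsp:
    def test_full_methylation_perfect_conversion(self):
        cfg = SimConfig(seed=2, n_bsp_pairs=1, clones_per_sample=3,
                        clone_meth_p_tumor=1.0, conversion_eff=1.0)
        fix = gen_bsp(cfg)
        ref = fix.amplicon
        for clone in fix.clones["BT01"]:
            for i in ref.cpg_positions:
                assert clone[i] == "C"
            for i in ref.non_cpg_c_positions:
                assert clone[i] == "T"

    def test_poor_conversion_fails_qc_half_the_time(self):
        cfg = SimConfig(seed=13, n_bsp_pairs=2, clones_per_sample=50,
                        conversion_eff=0.5)
        fix = gen_bsp(cfg)
        all_calls = [
            call_clone(fix.amplicon, s)
            for clones in fix.clones.values() for s in clones
        ]
        frac_fail = np.mean([not c.passed_qc for c in all_calls])
        assert frac_fail > 0.95  # conversion 0.5 almost never reaches 0.95

    def test_amplicon_has_planted_cpg_count(self, small_cfg):
        fix = gen_bsp(small_cfg)
        assert len(fix.amplicon.cpg_positions) == small_cfg.amplicon_n_cpg


class TestSurvival:
    def test_no_censoring_all_events(self):
        cfg = SimConfig(seed=5, censor_rate=0.0)
        recs = gen_survival(cfg, {f"s{i}": "low" for i in range(30)})
        assert all(r.event == 1 for r in recs)

    def test_censor_rate_matches_expectation(self):
        cfg = SimConfig(seed=5, censor_rate=0.4)
        recs = gen_survival(cfg, {f"s{i}": "low" for i in range(500)})
        frac = np.mean([r.event == 0 for r in recs])
        assert frac == pytest.approx(0.4, abs=0.07)

    def test_null_hazard_ratio_gives_uniformish_p(self):
        from scipy.stats import kstest

        from methdriver.survival import logrank

        ps = []
        for rep in range(60):
            cfg = SimConfig(seed=3000 + rep, hazard_ratio=1.0, censor_rate=0.2)
            groups = {f"h{i}": "high" for i in range(30)}
            groups.update({f"l{i}": "low" for i in range(30)})
            _, p = logrank(gen_survival(cfg, groups))
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01
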