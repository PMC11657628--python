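import hashlib

import numpy as np
import pytest

from divomics.genomic_io import IntervalSet
from divomics.popgen import wc_fst
from divomics.synthetic_data import (
    SimulationConfig,
    TruthManifest,
    coupling_function,
    plant_cnv_segments,
    plant_dmrs,
    simulate_all,
    simulate_genome,
    simulate_genotypes,
    simulate_input_depth,
    simulate_medip,
    write_dataset,
)


def md5_of(path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(fraction_fixed=0.6, fraction_high_fst=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(gc_fraction=1.5)

    def test_yaml_round_trip(self, tmp_path, small_config):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        back = SimulationConfig.from_yaml(p)
        assert back == small_config


class TestGenome:
    def test_determinism_byte_identical(self, tmp_path, small_config):
        for d in ("run1", "run2"):
            data = simulate_all(small_config)
            write_dataset(data, tmp_path / d)
        for f in sorted((tmp_path / "run1").iterdir()):
            assert md5_of(f) == md5_of(tmp_path / "run2" / f.name), f.name

    def test_gc_fraction_realized(self, small_dataset, small_config):
        g = small_dataset["genome"]
        gc = sum(s.count("G") + s.count("C") for s in g.contigs.values())
        assert abs(gc / g.total_length - small_config.gc_fraction) < 0.02

    def test_promoter_cpg_enrichment(self, small_config):
        genome, genes, *_ = simulate_genome(small_config)
        flank = small_config.promoter_flank
        prom_cpg = prom_bp = 0
        for g in genes:
            lo = max(0, g.tss - flank)
            hi = min(genome.contig_length(g.contig), g.tss + flank)
            prom_cpg += genome.cpg_count(g.contig, lo, hi)
            prom_bp += hi - lo
        genome_rate = genome.cpg_count_total() / genome.total_length
        assert prom_cpg / prom_bp >= 2 * genome_rate

    def test_too_many_genes_error(self):
        with pytest.raises((ValueError, RuntimeError)):
            simulate_genome(SimulationConfig(n_contigs=1, contig_length=50_000, n_genes=40))

    def test_repeats_and_qtls_nondegenerate(self, small_dataset):
        assert len(small_dataset["repeats"]) > 0
        assert len(small_dataset["qtls"]) > 0
        assert (small_dataset["qtls"].df["end"] > small_dataset["qtls"].df["start"]).all()


class TestGenotypes:
    def test_planted_counts_match_config(self, small_dataset, small_config):
        truth = small_dataset["truth"]
        assert truth.locus_class.count("fixed") == round(
            small_config.fraction_fixed * small_config.n_loci
        )
        assert truth.locus_class.count("high_fst") == round(
            small_config.fraction_high_fst * small_config.n_loci
        )

    def test_default_config_ten_fixed_loci(self):
        # fraction 0.002 of 5000 loci
        assert round(SimulationConfig().fraction_fixed * SimulationConfig().n_loci) == 10

    def test_fixed_loci_opposite_homozygotes_without_missingness(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, missing_rate=0.0)
        genome, *_ = simulate_genome(cfg)
        table, truth = simulate_genotypes(cfg, genome)
        fixed = [i for i, c in enumerate(truth["locus_class"]) if c == "fixed"]
        assert fixed
        ma = table.group_mask("A")
        for j in fixed:
            a = set(table.dosage[ma, j].tolist())
            b = set(table.dosage[~ma, j].tolist())
            assert (a, b) in (({0}, {2}), ({2}, {0}))

    def test_neutral_mean_fst_recovers_background(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config,
            fraction_fixed=0.0,
            fraction_high_fst=0.0,
            fraction_cpg_loss=0.0,
            fraction_novel_cpg=0.0,
            n_loci=800,
        )
        genome, *_ = simulate_genome(cfg)
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table, _ = simulate_genotypes(cfg, genome, rng=rng)
            _, global_fst = wc_fst(table)
            vals.append(global_fst)
        assert abs(np.mean(vals) - cfg.fst_background) < 0.02

    def test_planted_context_flags(self, small_dataset):
        table = small_dataset["genotypes"]
        truth = small_dataset["truth"]
        genome = small_dataset["genome"]
        for j, flag in enumerate(truth.cpg_loss_flags):
            if flag:
                contig, pos = str(table.contig[j]), int(table.pos[j])
                base = genome.base(contig, pos)
                assert (base == "C" and genome.base(contig, pos + 1) == "G") or (
                    base == "G" and genome.base(contig, pos - 1) == "C"
                )
        for j, flag in enumerate(truth.novel_cpg_flags):
            if flag:
                contig, pos = str(table.contig[j]), int(table.pos[j])
                assert str(table.alt[j]) == "C"
                assert genome.base(contig, pos) != "C"
                assert genome.base(contig, pos + 1) == "G"


class TestMedip:
    def test_poisson_limit_at_tiny_dispersion(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, medip_dispersion=1e-6)
        genome, *_ = simulate_genome(cfg)
        dmrs, tiles, cf = plant_dmrs(cfg, genome)
        reads, groups = simulate_medip(cfg, genome, [])
        # variance/mean over windows of identical CpG coupling ~ 1
        from divomics.medip_dmr import window_counts

        mat = window_counts({"A01": reads["A01"]}, genome, cfg.window_bp)
        ratios = []
        for level, sub in mat.groupby("cpg_count"):
            if len(sub) >= 30 and sub["A01"].mean() > 5:
                ratios.append(sub["A01"].var() / sub["A01"].mean())
        assert ratios and 0.7 < np.median(ratios) < 1.4

    def test_planted_dmr_group_separation(self, default_dataset):
        # hyper-in-A windows: line-A mean count above line-B in >=95% of windows
        data = default_dataset
        genome = data["genome"]
        from divomics.medip_dmr import sample_columns, window_counts

        mat = window_counts(data["medip_reads"], genome, 300)
        samples = sample_columns(mat)
        a_cols = [s for s in samples if s.startswith("A")]
        b_cols = [s for s in samples if s.startswith("B")]
        wins = 0
        total = 0
        for d in data["truth"].dmrs:
            for w in d["window_indices"]:
                a_mean = mat.iloc[w][a_cols].mean()
                b_mean = mat.iloc[w][b_cols].mean()
                hi, lo = (a_mean, b_mean) if d["direction"] == "hyper_in_A" else (b_mean, a_mean)
                wins += hi > lo
                total += 1
        assert total > 0
        assert wins / total >= 0.95

    def test_null_centred_at_zero(self, small_config):
        genome, *_ = simulate_genome(small_config)
        reads, groups = simulate_medip(small_config, genome, [])  # no planted DMRs
        from divomics.medip_dmr import sample_columns, window_counts

        mat = window_counts(reads, genome, small_config.window_bp)
        samples = sample_columns(mat)
        a_cols = [s for s in samples if groups[s] == "A"]
        b_cols = [s for s in samples if groups[s] == "B"]
        cpm_a = mat[a_cols].div(mat[a_cols].sum()).mean(axis=1)
        cpm_b = mat[b_cols].div(mat[b_cols].sum()).mean(axis=1)
        informative = mat[samples].sum(axis=1) >= 10
        diff = (cpm_a - cpm_b)[informative]
        assert abs(diff.mean()) < 0.2 * diff.std()

    def test_coupling_function_saturating(self):
        f = coupling_function(np.array([0, 1, 10, 100]), 10.0)
        assert f[0] == 0
        assert np.all(np.diff(f) > 0)
        assert f[-1] < 1


class TestInputDepth:
    def test_flat_genome_median_log2_near_zero(self, small_config):
        genome, *_ = simulate_genome(small_config)
        depth = simulate_input_depth(small_config, genome, [])  # ratio 1 everywhere
        from divomics.cnv_calling import window_counts_from_reads

        counts = window_counts_from_reads(depth["A"], depth["B"], genome, 500)
        a = counts["count_a"].to_numpy(dtype=float)
        b = counts["count_b"].to_numpy(dtype=float)
        na, nb = len(depth["A"]), len(depth["B"])
        ok = (a > 0) & (b > 0)
        log2 = np.log2((a[ok] / na) / (b[ok] / nb))
        assert abs(np.median(log2)) < 0.05

    def test_planted_ratio2_segment_log2(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, n_input_reads=250_000)
        genome, *_ = simulate_genome(cfg)
        seg = [{"contig": "chr1", "start": 20_000, "end": 24_000, "ratio": 2.0}]
        rng = np.random.default_rng(11)
        depth = simulate_input_depth(cfg, genome, seg, rng=rng)
        from divomics.cnv_calling import window_counts_from_reads

        counts = window_counts_from_reads(depth["A"], depth["B"], genome, 500)
        na, nb = len(depth["A"]), len(depth["B"])
        inseg = (
            (counts["contig"] == "chr1")
            & (counts["start"] >= 20_000)
            & (counts["end"] <= 24_000)
        )
        a = counts.loc[inseg, "count_a"].to_numpy(dtype=float)
        b = counts.loc[inseg, "count_b"].to_numpy(dtype=float)
        mean_log2 = np.log2((a / na) / (b / nb)).mean()
        assert abs(mean_log2 - 1.0) < 0.1

    def test_overlapping_segments_error(self, small_config):
        genome, *_ = simulate_genome(small_config)
        segs = [
            {"contig": "chr1", "start": 1_000, "end": 5_000, "ratio": 2.0},
            {"contig": "chr1", "start": 4_000, "end": 8_000, "ratio": 3.0},
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_input_depth(small_config, genome, segs)

    def test_planted_segments_disjoint(self, small_config):
        genome, *_ = simulate_genome(small_config)
        segs = plant_cnv_segments(small_config, genome)
        ivs = IntervalSet.from_records([(s["contig"], s["start"], s["end"]) for s in segs])
        df = ivs.df
        for (_, r1), (_, r2) in zip(df.iterrows(), df.iloc[1:].iterrows()):
            if r1["contig"] == r2["contig"]:
                assert r1["end"] <= r2["start"]


class TestTruthManifest:
    def test_json_round_trip(self, tmp_path, small_dataset):
        truth = small_dataset["truth"]
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = TruthManifest.from_json(p)
        assert back == truth

    def test_planted_features_within_bounds(self, small_dataset, small_config):
        genome = small_dataset["genome"]
        truth = small_dataset["truth"]
        for d in truth.dmrs + truth.cnv_segments:
            assert 0 <= d["start"] < d["end"] <= genome.contig_length(d["contig"])

    def test_locus_classes_mutually_exclusive(self, small_dataset):
        assert all(
            c in ("fixed", "high_fst", "neutral")
            for c in small_dataset["truth"].locus_class
        )
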