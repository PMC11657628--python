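import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divomics.genomic_io import IntervalSet, ReferenceGenome
from divomics.medip_dmr import (
    coupling_normalize,
    cpg_enrichment_score,
    differential_windows,
    direction_summary,
    extend_reads,
    merge_dmrs,
    stacked_read_cap,
    stacked_read_filter,
    window_counts,
)


@pytest.fixture
def flat_genome():
    return ReferenceGenome({"c1": "ACGT" * 2500})  # 10 kb


class TestStackedReads:
    def test_cap_lambda_point_one(self):
        # P(X>=2 | 0.1) ~ 4.7e-3 >= 1e-3 but P(X>=3) ~ 1.5e-4 < 1e-3
        assert stacked_read_cap(0.1, p=0.001) == 2

    def test_cap_by_hand_poisson_tail(self):
        lam, p = 0.5, 0.001
        cap = stacked_read_cap(lam, p)
        assert stats.poisson.sf(cap - 1, lam) >= p
        assert stats.poisson.sf(cap, lam) < p

    def test_cap_monotone_in_lambda(self):
        caps = [stacked_read_cap(lam) for lam in (0.01, 0.1, 1.0, 5.0, 20.0)]
        assert caps == sorted(caps)

    def test_unique_starts_untouched(self, flat_genome):
        reads = IntervalSet.from_records(
            [("c1", i * 100, i * 100 + 50, ".", "+", "s") for i in range(20)], kind="reads"
        )
        out, removed = stacked_read_filter(reads, flat_genome)
        assert removed == 0
        assert len(out) == 20

    def test_tall_stack_truncated(self, flat_genome):
        rows = [("c1", 500, 550, ".", "+", "s")] * 50
        rows += [("c1", i * 7, i * 7 + 50, ".", "+", "s") for i in range(100)]
        reads = IntervalSet.from_records(rows, kind="reads")
        lam = len(reads) / flat_genome.total_length
        cap = stacked_read_cap(lam)
        out, removed = stacked_read_filter(reads, flat_genome)
        assert removed == 50 - cap
        stack = out.df[(out.df["start"] == 500) & (out.df["strand"] == "+")]
        assert len(stack) == cap

    def test_strands_counted_separately(self, flat_genome):
        rows = [("c1", 500, 550, ".", "+", "s"), ("c1", 500, 550, ".", "-", "s")]
        reads = IntervalSet.from_records(rows, kind="reads")
        out, removed = stacked_read_filter(reads, flat_genome)
        assert removed == 0


class TestExtendReads:
    def test_plus_strand(self, flat_genome):
        reads = IntervalSet.from_records([("c1", 100, 150, ".", "+", "s")], kind="reads")
        out = extend_reads(reads, flat_genome, target=100)
        assert out.df.iloc[0]["start"] == 100 and out.df.iloc[0]["end"] == 200

    def test_minus_strand(self, flat_genome):
        reads = IntervalSet.from_records([("c1", 100, 150, ".", "-", "s")], kind="reads")
        out = extend_reads(reads, flat_genome, target=100)
        assert out.df.iloc[0]["start"] == 50 and out.df.iloc[0]["end"] == 150

    def test_long_read_untouched(self, flat_genome):
        reads = IntervalSet.from_records([("c1", 100, 220, ".", "+", "s")], kind="reads")
        out = extend_reads(reads, flat_genome, target=100)
        assert out.df.iloc[0]["end"] == 220

    def test_clipped_at_contig_bounds(self, flat_genome):
        reads = IntervalSet.from_records(
            [("c1", 9_980, 9_999, ".", "+", "s"), ("c1", 10, 60, ".", "-", "s")],
            kind="reads",
        )
        out = extend_reads(reads, flat_genome, target=100)
        assert out.df["end"].max() <= 10_000
        assert out.df["start"].min() == 0


class TestWindowCounts:
    def test_read_within_one_window(self, flat_genome):
        reads = {"s1": IntervalSet.from_records([("c1", 300, 600, ".", "+", "s1")], kind="reads")}
        mat = window_counts(reads, flat_genome, 300)
        assert mat["s1"].tolist()[:3] == [0, 1, 0]

    def test_straddling_read_counted_in_both(self, flat_genome):
        reads = {"s1": IntervalSet.from_records([("c1", 250, 350, ".", "+", "s1")], kind="reads")}
        mat = window_counts(reads, flat_genome, 300)
        assert mat["s1"].tolist()[:2] == [1, 1]

    def test_total_increments_at_least_reads(self, flat_genome):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 9_800, 200)
        reads = {
            "s1": IntervalSet.from_records(
                [("c1", int(s), int(s) + 100, ".", "+", "s1") for s in starts], kind="reads"
            )
        }
        mat = window_counts(reads, flat_genome, 300)
        assert mat["s1"].sum() >= 200

    def test_cpg_count_column(self):
        g = ReferenceGenome({"c1": "CGCGCG" + "A" * 294 + "T" * 300})
        mat = window_counts({}, g, 300)
        assert mat["cpg_count"].tolist() == [3, 0]


class TestCouplingNormalize:
    def make_matrix(self, counts, cf):
        n = len(cf)
        df = pd.DataFrame(
            {
                "contig": "c1",
                "start": np.arange(n) * 300,
                "end": np.arange(1, n + 1) * 300,
                "cpg_count": cf,
            }
        )
        for name, col in counts.items():
            df[name] = col
        return df

    def test_uniform_matrix_rms_one(self):
        mat = self.make_matrix({"s1": [7] * 50}, [3] * 50)
        rms = coupling_normalize(mat)
        np.testing.assert_allclose(rms["s1"], 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        cf = rng.integers(0, 20, 400)
        counts = rng.poisson(5 + 2 * cf)
        m1 = self.make_matrix({"s1": counts}, cf)
        m2 = self.make_matrix({"s1": counts * 2}, cf)
        r1 = coupling_normalize(m1)
        r2 = coupling_normalize(m2)
        np.testing.assert_allclose(r1["s1"], r2["s1"], rtol=1e-9)

    def test_decorrelates_rms_from_cf(self):
        rng = np.random.default_rng(2)
        n = 4000
        cf = rng.integers(1, 30, n).astype(float)  # covered windows only
        mean = 150 * cf / (cf + 10)
        counts = rng.poisson(mean)
        mat = self.make_matrix({"s1": counts}, cf.astype(int))
        rms = coupling_normalize(mat)
        rho_before = stats.spearmanr(counts, cf).statistic
        rho_after = stats.spearmanr(rms["s1"], cf).statistic
        assert abs(rho_before) >= 0.5
        assert abs(rho_after) < 0.1


class TestDifferential:
    def setup_matrix(self, rng, n=600, depth=30.0, shifted=None):
        """NB matrix; ``shifted`` windows get +-log2fc/2 between groups."""
        cf = rng.integers(2, 25, n)
        f = cf / (cf + 10)
        samples = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(7)]
        groups = {s: s[0] for s in samples}
        mat = pd.DataFrame(
            {"contig": "c1", "start": np.arange(n) * 300, "end": np.arange(1, n + 1) * 300, "cpg_count": cf}
        )
        shift_vec = np.zeros(n)
        if shifted is not None:
            shift_vec[shifted] = 0.5
        for s in samples:
            sign = 1.0 if groups[s] == "A" else -1.0
            mean = depth * f * 2.0 ** (sign * shift_vec)
            npar = 1 / 0.2
            mat[s] = rng.negative_binomial(npar, npar / (npar + mean))
        return mat, groups

    def test_min_row_sum_drops_window(self):
        samples = {"A1": [5], "A2": [2], "B1": [1], "B2": [1]}
        mat = pd.DataFrame({"contig": ["c1"], "start": [0], "end": [300], "cpg_count": [5]})
        for s, v in samples.items():
            mat[s] = v
        rms = coupling_normalize(mat)
        out = differential_windows(mat, rms, {s: s[0] for s in samples}, min_row_sum=10)
        assert len(out) == 0  # total count 9 < 10

    def test_total_ten_kept(self):
        samples = {"A1": [5], "A2": [3], "B1": [1], "B2": [1]}
        mat = pd.DataFrame({"contig": ["c1"], "start": [0], "end": [300], "cpg_count": [5]})
        for s, v in samples.items():
            mat[s] = v
        rms = coupling_normalize(mat)
        out = differential_windows(mat, rms, {s: s[0] for s in samples}, min_row_sum=10)
        assert len(out) == 1

    def test_zero_variance_equal_means_p_one(self):
        mat = pd.DataFrame({"contig": ["c1"], "start": [0], "end": [300], "cpg_count": [5]})
        for s in ("A1", "A2", "B1", "B2"):
            mat[s] = [6]
        rms = coupling_normalize(mat)
        out = differential_windows(mat, rms, {s: s[0] for s in mat.columns[4:]}, min_row_sum=1)
        assert out["p"].iloc[0] == 1.0

    def test_power_on_planted_shift(self):
        rng = np.random.default_rng(3)
        planted = np.arange(0, 60)
        mat, groups = self.setup_matrix(rng, depth=40.0, shifted=planted)
        rms = coupling_normalize(mat)
        out = differential_windows(mat, rms, groups)
        in_planted = out["start"] < 60 * 300
        assert (out.loc[in_planted, "p"] <= 0.05).mean() >= 0.6
        assert (out.loc[in_planted, "log2fc"] < 0).mean() > 0.9  # B below A
        assert (out.loc[~in_planted, "p"] <= 0.05).mean() < 0.15


class TestMergeDmrs:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["contig", "start", "end", "cpg_count", "log2fc", "p"])

    def test_adjacent_same_direction_merged(self):
        diff = self.frame(
            [("c1", 0, 300, 4, 1.0, 0.01), ("c1", 300, 600, 5, 0.8, 0.02)]
        )
        dmrs = merge_dmrs(diff, alpha=0.05)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end, d.n_windows) == (0, 600, 2)
        assert d.direction == "hyper_in_B"
        assert d.n_cpgs == 9

    def test_opposite_directions_not_merged(self):
        diff = self.frame(
            [("c1", 0, 300, 4, 1.0, 0.01), ("c1", 300, 600, 5, -0.8, 0.02)]
        )
        assert len(merge_dmrs(diff, alpha=0.05)) == 2

    def test_gap_not_merged(self):
        diff = self.frame(
            [("c1", 0, 300, 4, 1.0, 0.01), ("c1", 600, 900, 5, 1.0, 0.02)]
        )
        assert len(merge_dmrs(diff, alpha=0.05)) == 2

    def test_one_bp_gap_merged(self):
        diff = self.frame(
            [("c1", 0, 300, 4, 1.0, 0.01), ("c1", 301, 600, 5, 1.0, 0.02)]
        )
        assert len(merge_dmrs(diff, alpha=0.05)) == 1

    def test_insignificant_excluded(self):
        diff = self.frame([("c1", 0, 300, 4, 1.0, 0.2)])
        assert merge_dmrs(diff, alpha=0.05) == []

    def test_n_cpgs_recomputed_with_genome(self):
        g = ReferenceGenome({"c1": "CG" * 300})
        diff = self.frame([("c1", 0, 300, 999, 1.0, 0.01)])
        dmrs = merge_dmrs(diff, alpha=0.05, genome=g)
        assert dmrs[0].n_cpgs == 150


class TestDirectionSummary:
    def test_percentages(self):
        dmrs = [{"direction": "hypo_in_B"}] * 107 + [{"direction": "hyper_in_B"}] * 125
        s = direction_summary(dmrs)
        assert s["n_total"] == 232
        assert s["pct_hypo_in_B"] == pytest.approx(100 * 107 / 232)
        assert s["n_hypo_in_B"] + s["n_hyper_in_B"] == s["n_total"]


class TestCpgEnrichmentScore:
    def test_whole_genome_is_one(self, small_genome):
        regions = IntervalSet.from_records(
            [(name, 0, small_genome.contig_length(name)) for name in small_genome.contigs]
        )
        s = cpg_enrichment_score(regions, small_genome)
        assert s["relh_score"] == pytest.approx(1.0)
        assert s["goge_score"] == pytest.approx(1.0, rel=0.05)

    def test_islands_enriched(self, small_dataset):
        genome = small_dataset["genome"]
        regions = IntervalSet.from_records(
            [(i["contig"], i["start"], i["end"]) for i in small_dataset["truth"].islands]
        )
        assert cpg_enrichment_score(regions, genome)["relh_score"] > 1.0

    def test_split_invariance(self, small_genome):
        whole = IntervalSet.from_records([("chr1", 1_000, 3_000)])
        halves = IntervalSet.from_records([("chr1", 1_000, 2_000), ("chr1", 2_000, 3_000)])
        s1 = cpg_enrichment_score(whole, small_genome)
        s2 = cpg_enrichment_score(halves, small_genome)
        # CpGs straddling the cut are the only permissible difference
        assert abs(s1["cpg_in_regions"] - s2["cpg_in_regions"]) <= 1
        assert s1["relh_score"] == pytest.approx(s2["relh_score"], rel=0.05)

    def test_empty_regions_error(self, small_genome):
        with pytest.raises(ValueError):
            cpg_enrichment_score(IntervalSet(pd.DataFrame(columns=["contig", "start", "end"])), small_genome)
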