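"""Synthetic-data generator: determinism, conservation, distributional
structure of the simulated reads and tag tables."""

import numpy as np
import pytest
from scipy import stats

from mesmark import (EnrichmentModel, SimulationConfig, annotate_genes,
                     build_toy_genome, simulate_expression_tags,
                     simulate_reads)
from mesmark.errors import ConfigurationError, PlacementError
from mesmark.simulate import default_control_model, default_mes4_model


@pytest.mark.parametrize("n_auto, length, with_x, n_chrom, x_count", [
    (1, 100_000, True, 2, 1),
    (5, 1_000_000, True, 6, 1),
    (2, 50_000, False, 2, 0),
])
def test_build_toy_genome_shapes(n_auto, length, with_x, n_chrom, x_count):
    g = build_toy_genome(n_auto, length, with_x)
    assert len(g.chromosomes) == n_chrom
    assert sum(c.is_x for c in g.chromosomes) == x_count
    assert g.total_length == n_chrom * length
    assert g.names[0] == "chrI"
    if with_x:
        assert g.x_name == "chrX"


def test_build_toy_genome_rejects_bad_args():
    with pytest.raises(ConfigurationError):
        build_toy_genome(0, 100_000)
    with pytest.raises(ConfigurationError):
        build_toy_genome(1, 500)


class TestAnnotateGenes:
    def test_degenerate_mixture_labels_all_soma(self, small_genome):
        genes = annotate_genes(small_genome, 5, (500, 1000), {"soma": 1.0},
                               seed=0)
        assert (genes.df["gene_class"] == "soma").all()

    def test_same_seed_identical(self, small_genome):
        a = annotate_genes(small_genome, 10, (500, 1000),
                           {"germline": 0.5, "soma": 0.5}, seed=3)
        b = annotate_genes(small_genome, 10, (500, 1000),
                           {"germline": 0.5, "soma": 0.5}, seed=3)
        assert a.df.equals(b.df)

    def test_class_counts_within_binomial_interval(self):
        # 100 genes at 50/50 should land inside the central 99% binomial
        # interval, computed independently from the binomial CDF
        g = build_toy_genome(1, 400_000, include_x=False)
        genes = annotate_genes(g, 100, (500, 1000),
                               {"germline": 0.5, "soma": 0.5}, seed=1)
        lo, hi = stats.binom.interval(0.99, 100, 0.5)
        n_germ = int((genes.df["gene_class"] == "germline").sum())
        assert lo <= n_germ <= hi

    def test_spaced_placement_never_overlaps(self, small_genome):
        genes = annotate_genes(small_genome, 8, (500, 2000), {"soma": 1.0},
                               seed=5)
        for _, sub in genes.df.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].shift(-1).dropna().to_numpy()
                    >= sub["end"].to_numpy()[:-1]).all()

    def test_oversized_gene_raises(self, small_genome):
        with pytest.raises(PlacementError):
            annotate_genes(small_genome, 2, (15_000, 25_000), {"soma": 1.0},
                           seed=0)

    def test_bad_proportions_raise(self, small_genome):
        with pytest.raises(ConfigurationError):
            annotate_genes(small_genome, 2, (500, 1000),
                           {"soma": 0.5, "germline": 0.4}, seed=0)

    def test_strand_aware_tss_tes(self, small_genome):
        genes = annotate_genes(small_genome, 10, (500, 1000), {"soma": 1.0},
                               seed=2)
        fwd = genes.df["strand"] == "+"
        assert (genes.tss()[fwd] == genes.df.loc[fwd, "start"]).all()
        assert (genes.tss()[~fwd] == genes.df.loc[~fwd, "end"] - 1).all()


class TestSimulateReads:
    def test_determinism_and_count_conservation(self, small_genome):
        genes = annotate_genes(small_genome, 5, (500, 1000),
                               {"germline": 1.0}, seed=0)
        cfg = SimulationConfig(n_reads=5_000, seed=42)
        a = simulate_reads(small_genome, genes, default_mes4_model(), cfg)
        b = simulate_reads(small_genome, genes, default_mes4_model(), cfg)
        assert len(a) == 5_000
        assert a == b

    def test_replicates_differ_but_are_reproducible(self, small_genome):
        genes = annotate_genes(small_genome, 5, (500, 1000),
                               {"germline": 1.0}, seed=0)
        cfg = SimulationConfig(n_reads=2_000, seed=7)
        r0 = simulate_reads(small_genome, genes, default_mes4_model(), cfg,
                            replicate=0)
        r1 = simulate_reads(small_genome, genes, default_mes4_model(), cfg,
                            replicate=1)
        assert r0 != r1
        r0_again = simulate_reads(small_genome, genes, default_mes4_model(),
                                  cfg, replicate=0)
        assert r0 == r0_again

    def test_sorted_by_chrom_start(self, small_genome):
        genes = annotate_genes(small_genome, 5, (500, 1000),
                               {"germline": 1.0}, seed=0)
        cfg = SimulationConfig(n_reads=2_000, seed=1)
        r = simulate_reads(small_genome, genes, default_control_model(), cfg)
        order = np.lexsort((r.start, r.chrom.astype(str)))
        assert (order == np.arange(len(r))).all()

    def test_input_mode_chromosome_shares_match_lengths(self):
        # per-chromosome read counts of a flat control are multinomial on
        # length shares; each marginal checked against its 99% interval
        g = build_toy_genome(3, 50_000, include_x=True)
        genes = annotate_genes(g, 5, (500, 1000), {"germline": 1.0}, seed=0)
        n = 10_000
        cfg = SimulationConfig(n_reads=n, seed=3)
        r = simulate_reads(g, genes, default_control_model("input"), cfg)
        for c in g.chromosomes:
            share = c.length / g.total_length
            lo, hi = stats.binom.interval(0.99, n, share)
            count = int((r.chrom == c.name).sum())
            assert lo <= count <= hi

    def test_zero_weight_class_gets_no_reads(self, small_genome):
        genes = annotate_genes(small_genome, 10, (500, 1000),
                               {"germline": 0.5, "soma": 0.5}, seed=4)
        model = EnrichmentModel(mode="mes4_maintenance",
                                background_fraction=0.0,
                                class_weights={"germline": 1.0, "soma": 0.0})
        cfg = SimulationConfig(n_reads=5_000, seed=9)
        r = simulate_reads(small_genome, genes, model, cfg)
        soma = genes.df[genes.df["gene_class"] == "soma"]
        for rec in soma.itertuples(index=False):
            sel = r.chrom == rec.chrom
            starts = r.start[sel]
            assert not ((starts >= rec.start) & (starts < rec.end)).any()

    def test_five_prime_bias_shifts_reads_toward_tss(self):
        # mean strand-oriented relative position under a 5' bias must sit
        # below the uniform-bias run's mean (one-sided, same n and seed)
        g = build_toy_genome(1, 200_000, include_x=False)
        genes = annotate_genes(g, 20, (3_000, 5_000), {"germline": 1.0},
                               seed=1)
        cfg = SimulationConfig(n_reads=20_000, seed=2)

        def mean_rel_pos(bias, strength):
            model = EnrichmentModel(mode="mes4_maintenance",
                                    background_fraction=0.0,
                                    positional_bias=bias,
                                    bias_strength=strength,
                                    class_weights={"germline": 1.0})
            r = simulate_reads(g, genes, model, cfg)
            rels = []
            for rec in genes.df.itertuples(index=False):
                sel = ((r.chrom == rec.chrom) & (r.start >= rec.start)
                       & (r.start < rec.end))
                u = (r.start[sel] - rec.start) / (rec.end - rec.start)
                if rec.strand == "-":
                    u = 1.0 - u
                rels.append(u)
            return float(np.concatenate(rels).mean())

        biased = mean_rel_pos("five_prime", 1.0)
        flat = mean_rel_pos("uniform", 0.0)
        assert biased < 0.5
        assert biased < flat

    def test_input_mode_flat_coverage_chi_square(self):
        # read starts of a 1e5-read input split over 10 equal windows
        # should not reject uniformity at alpha=0.001
        g = build_toy_genome(1, 100_000, include_x=False)
        genes = annotate_genes(g, 5, (500, 1000), {"germline": 1.0}, seed=0)
        cfg = SimulationConfig(n_reads=100_000, seed=6)
        r = simulate_reads(g, genes, default_control_model("input"), cfg)
        counts, _ = np.histogram(r.start, bins=10, range=(0, 100_000))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            EnrichmentModel(mode="mes4_maintenance",
                            class_weights={"germline": 0.0})

    def test_reads_clamped_to_chromosome(self, small_genome):
        genes = annotate_genes(small_genome, 5, (500, 1000),
                               {"germline": 1.0}, seed=0)
        cfg = SimulationConfig(n_reads=20_000, seed=8)
        r = simulate_reads(small_genome, genes, default_control_model(), cfg)
        for c in small_genome.chromosomes:
            sel = r.chrom == c.name
            assert (r.end[sel] <= c.length).all()
            assert (r.start[sel] >= 0).all()


class TestExpressionTags:
    TISSUES = ["germline", "muscle", "nerve", "gut"]

    @pytest.fixture
    def genes(self, small_genome):
        return annotate_genes(small_genome, 30, (400, 600),
                              {"germline": 0.3, "soma": 0.3,
                               "ubiquitous": 0.4}, seed=12)

    def test_soma_genes_have_zero_germline_tags(self, genes):
        tags = simulate_expression_tags(genes, self.TISSUES, depth=10,
                                        seed=1)
        soma = genes.genes_by_class("soma")
        assert (tags.loc[soma, "germline"] == 0).all()

    def test_germline_genes_silent_in_soma(self, genes):
        tags = simulate_expression_tags(genes, self.TISSUES, depth=10,
                                        seed=1)
        germ = genes.genes_by_class("germline")
        assert (tags.loc[germ, ["muscle", "nerve", "gut"]] == 0).all().all()

    def test_ubiquitous_genes_expressed_everywhere_at_depth_10(self, genes):
        # P(Poisson(10) = 0) = e^-10 ~ 4.5e-5 per tissue; at this seed and
        # gene count every ubiquitous gene clears >= 1 tag in all tissues
        tags = simulate_expression_tags(genes, self.TISSUES, depth=10,
                                        seed=1)
        ubiq = genes.genes_by_class("ubiquitous")
        assert (tags.loc[ubiq] >= 1).all().all()

    def test_determinism(self, genes):
        a = simulate_expression_tags(genes, self.TISSUES, depth=10, seed=2)
        b = simulate_expression_tags(genes, self.TISSUES, depth=10, seed=2)
        assert a.equals(b)

    def test_unknown_tissue_rejected(self, genes):
        with pytest.raises(ConfigurationError):
            simulate_expression_tags(genes, self.TISSUES + ["liver"],
                                     depth=10, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_expression_tags(genes, ["germline", "muscle"],
                                     depth=10, seed=0)
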