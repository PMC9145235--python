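"""Marker QC, association scans, intersections, annotation, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from shankvb.assoc import (
    GeneAnnotation,
    GenotypeMatrix,
    HitSet,
    annotate_genes,
    assoc_scan,
    filter_markers,
    genomewide_threshold,
    hits_from_scan,
    hypergeom_enrichment,
    intersect_hits,
    run_association,
    shared_gene_summary,
)
from shankvb.exceptions import ValidationError
from shankvb.synthetic import GenoSimSpec, generate_genotypes


def matrix_from(dosages):
    d = np.asarray(dosages, float)
    n, m = d.shape
    return GenotypeMatrix(
        dosages=d,
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        chrom=np.array(["1"] * m),
        pos=np.arange(1, m + 1) * 100,
        ref=np.full(m, "A"),
        alt=np.full(m, "G"),
        line_ids=np.array([f"L{i}" for i in range(n)]),
    )


class TestFilterMarkers:
    def test_low_call_rate_removed(self):
        # 4 of 5 lines called: call rate 0.8 < 0.9
        G = matrix_from(np.array([[0, 0, 1, 2, np.nan]]).T)
        with pytest.warns(UserWarning):  # the sole SNP is removed
            out = filter_markers(G)
        assert out.n_snps == 0

    def test_maf_boundary_retained(self):
        # MAF 1/8 = 0.125 >= 0.05, full call rate
        G = matrix_from(np.array([[0, 0, 0, 1]]).T)
        out = filter_markers(G)
        assert out.n_snps == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        d = rng.integers(0, 3, size=(20, 50)).astype(float)
        d[rng.random((20, 50)) < 0.1] = np.nan
        G = matrix_from(d)
        out = filter_markers(G, maf_min=0.05, callrate_min=0.9)
        kept = set(out.snp_ids)
        for j in range(50):
            col = d[:, j]
            obs = col[~np.isnan(col)]
            call = len(obs) / 20
            p = obs.sum() / (2 * len(obs)) if len(obs) else 0.0
            maf = min(p, 1 - p)
            assert ((call >= 0.9) and (maf >= 0.05)) == (f"s{j}" in kept)

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(30, 40)).astype(float)
        d[rng.random((30, 40)) < 0.2] = np.nan
        G = matrix_from(d)
        once = filter_markers(G)
        twice = filter_markers(once)
        assert list(once.snp_ids) == list(twice.snp_ids)

    def test_all_removed_warns_not_raises(self):
        G = matrix_from(np.zeros((10, 3)))  # monomorphic: MAF 0
        with pytest.warns(UserWarning):
            out = filter_markers(G)
        assert out.n_snps == 0


class TestThreshold:
    def test_published_snp_count_gives_1_25e6(self):
        thr = genomewide_threshold(797_058)
        assert float(f"{thr:.3g}") == 1.25e-06

    @pytest.mark.parametrize("n,expect", [(1, 1.0), (10**6, 1e-6)])
    def test_reciprocal(self, n, expect):
        assert genomewide_threshold(n) == pytest.approx(expect)

    def test_zero_snps_invalid(self):
        with pytest.raises(ValidationError):
            genomewide_threshold(0)


class TestAssocScan:
    def test_null_type_one_error_within_binomial_band(self):
        G, y, _ = generate_genotypes(
            GenoSimSpec(n_lines=202, m_snps=2000, seed=21))
        y = np.random.default_rng(22).permutation(y)
        for method in ("marginal", "pc_adjusted"):
            scan = assoc_scan(G, y, method)
            rate = (scan["p"] <= 0.01).mean()
            se = math.sqrt(0.01 * 0.99 / 2000)
            assert abs(rate - 0.01) <= 1.96 * se + 1e-12

    def test_planted_qtl_detected(self):
        hits = 0
        for rep in range(20):
            spec = GenoSimSpec(n_lines=202, m_snps=1000, qtl=((500, 1.0),),
                               h2_marker=0.2, seed=300 + rep)
            G, y, _ = generate_genotypes(spec)
            _, _, consensus = run_association(G, y, threshold=1 / 1000)
            hits += int("snp000500" in consensus)
        assert hits >= 16  # >= 80 % power

    def test_pc_adjustment_deflates_stratified_nulls(self):
        rng = np.random.default_rng(30)
        n, m = 200, 600
        pop = np.repeat([0, 1], n // 2)
        # half the SNPs have strongly divergent frequencies between pops
        p0 = rng.uniform(0.1, 0.5, m)
        p1 = p0.copy()
        p1[: m // 2] = np.clip(p0[: m // 2] + rng.choice([-0.3, 0.3], m // 2),
                               0.05, 0.95)
        freqs = np.where(pop[:, None] == 0, p0[None, :], p1[None, :])
        d = rng.binomial(2, freqs).astype(float)
        y = pop * 1.0 + rng.normal(0, 1, n)  # trait shifted by population
        G = matrix_from(d)
        med = {}
        for method in ("marginal", "pc_adjusted"):
            scan = assoc_scan(G, y, method)
            med[method] = np.median(-np.log10(scan["p"]))
        assert med["pc_adjusted"] < med["marginal"]

    def test_invariant_to_joint_line_reordering(self):
        G, y, _ = generate_genotypes(
            GenoSimSpec(n_lines=60, m_snps=100, qtl=((5, 1.0),),
                        h2_marker=0.3, seed=31))
        perm = np.random.default_rng(32).permutation(60)
        G2 = GenotypeMatrix(G.dosages[perm], G.snp_ids, G.chrom, G.pos,
                            G.ref, G.alt, G.line_ids[perm])
        p1 = assoc_scan(G, y, "marginal")["p"]
        p2 = assoc_scan(G2, y[perm], "marginal")["p"]
        assert np.allclose(p1, p2, rtol=1e-10)

    def test_monomorphic_snp_flagged_p1(self):
        d = np.column_stack([np.ones(20) * 2, np.arange(20) % 3])
        G = matrix_from(d)
        scan = assoc_scan(G, np.random.default_rng(33).normal(size=20))
        assert scan.loc[0, "monomorphic"]
        assert scan.loc[0, "p"] == 1.0
        assert not scan.loc[1, "monomorphic"]

    def test_matches_scalar_regression_oracle(self):
        from scipy import stats as ss

        G, y, _ = generate_genotypes(GenoSimSpec(n_lines=50, m_snps=20, seed=34))
        scan = assoc_scan(G, y, "marginal")
        for j in (0, 7, 19):
            res = ss.linregress(G.dosages[:, j], y)
            assert scan.loc[j, "p"] == pytest.approx(res.pvalue, rel=1e-9)
            assert scan.loc[j, "beta"] == pytest.approx(res.slope, rel=1e-9)


class TestIntersectHits:
    def test_basic_intersection(self):
        h1 = HitSet("m1", frozenset({"a", "b"}), 0.01)
        h2 = HitSet("m2", frozenset({"b", "c"}), 0.01)
        assert intersect_hits([h1, h2]) == {"b"}

    def test_identical_and_disjoint(self):
        h1 = HitSet("m1", frozenset({"a", "b"}), 0.01)
        assert intersect_hits([h1, h1]) == {"a", "b"}
        h3 = HitSet("m3", frozenset({"x"}), 0.01)
        assert intersect_hits([h1, h3]) == frozenset()

    def test_commutative_and_contained(self):
        h1 = HitSet("m1", frozenset({"a", "b", "c"}), 0.01)
        h2 = HitSet("m2", frozenset({"b", "c", "d"}), 0.01)
        h3 = HitSet("m3", frozenset({"c", "d", "e"}), 0.01)
        out = intersect_hits([h1, h2, h3])
        assert out == intersect_hits([h3, h1, h2])
        for h in (h1, h2, h3):
            assert out <= h.snps


class TestAnnotateGenes:
    GENES = [
        GeneAnnotation("g1", "1", 100, 200),
        GeneAnnotation("g2", "1", 300, 400),
        GeneAnnotation("g3", "2", 50, 80),
    ]

    def test_boundary_positions_inclusive(self):
        snps = pd.DataFrame({"snp_id": ["a", "b", "c"], "chrom": ["1"] * 3,
                             "pos": [100, 200, 250]})
        out = annotate_genes(snps, self.GENES, flank=0)
        assert set(zip(out["snp_id"], out["gene_id"])) == {("a", "g1"),
                                                           ("b", "g1")}

    def test_flank_monotone_nesting(self):
        snps = pd.DataFrame({"snp_id": ["a"], "chrom": ["1"], "pos": [250]})
        none = annotate_genes(snps, self.GENES, flank=0)
        near = annotate_genes(snps, self.GENES, flank=50)
        assert len(none) == 0
        assert set(near["gene_id"]) == {"g1", "g2"}

    def test_unknown_chromosome_skipped_with_warning(self):
        snps = pd.DataFrame({"snp_id": ["a"], "chrom": ["9"], "pos": [100]})
        with pytest.warns(UserWarning):
            out = annotate_genes(snps, self.GENES)
        assert len(out) == 0

    def test_matches_bruteforce_interval_oracle(self):
        rng = np.random.default_rng(40)
        genes = []
        for i in range(20):
            start = int(rng.integers(1, 5000))
            genes.append(GeneAnnotation(f"g{i}", str(rng.integers(1, 3)),
                                        start, start + int(rng.integers(10, 400))))
        snps = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(200)],
            "chrom": rng.integers(1, 3, 200).astype(str),
            "pos": rng.integers(1, 5500, 200),
        })
        flank = 25
        out = annotate_genes(snps, genes, flank=flank)
        got = set(zip(out["snp_id"], out["gene_id"]))
        expect = {
            (s, g.gene_id)
            for _, (s, c, p) in snps.iterrows()
            for g in genes
            if str(c) == g.chrom and g.start - flank <= p <= g.end + flank
        }
        assert got == expect


class TestSharedGeneSummary:
    def test_worked_example(self):
        out = shared_gene_summary({"T1": {"g1", "g2"}, "T2": {"g2"}})
        assert out.n_unique == 1
        assert out.n_shared == 1
        assert out.unique_per_trait == {"T1": 1, "T2": 0}

    def test_single_trait_all_unique(self):
        out = shared_gene_summary({"T1": {"g1", "g2", "g3"}})
        assert out.n_unique == 3
        assert out.n_shared == 0

    def test_unique_plus_shared_is_total(self):
        rng = np.random.default_rng(41)
        genes = [f"g{i}" for i in range(30)]
        mapping = {
            f"T{t}": set(rng.choice(genes, size=rng.integers(1, 10),
                                    replace=False))
            for t in range(6)
        }
        out = shared_gene_summary(mapping)
        total = len(set().union(*mapping.values()))
        assert out.n_unique + out.n_shared == total
        assert (out.gene_degree >= 1).all()


class TestHypergeomEnrichment:
    def test_term_equals_universe_p_one(self):
        uni = {f"g{i}" for i in range(10)}
        out = hypergeom_enrichment({"g1", "g2"}, {"t": set(uni)}, uni)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_disjoint_selection_p_one(self):
        uni = {f"g{i}" for i in range(10)}
        out = hypergeom_enrichment({"g5", "g6"}, {"t": {"g1", "g2"}}, uni)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        # universe 10, term 4, selected 5, overlap 4
        uni = [f"g{i}" for i in range(10)]
        term = set(uni[:4])
        selected = set(uni[:4]) | {uni[9]}
        out = hypergeom_enrichment(selected, {"t": term}, uni)
        count = sum(
            1 for draw in itertools.combinations(uni, 5)
            if len(set(draw) & term) >= 4
        )
        exact = count / math.comb(10, 5)
        assert out.loc[0, "p"] == pytest.approx(exact, rel=1e-12)

    def test_empty_universe_raises(self):
        with pytest.raises(ValidationError):
            hypergeom_enrichment(set(), {"t": set()}, set())
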