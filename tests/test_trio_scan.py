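"""Tests of the genome-scale scan: stratification, gene ranking,
enrichment, SNP ranking and TPR summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from fedchow import (
    ScanConfig,
    SimulationSpec,
    adjust_by_icv,
    enrich_selection,
    rank_snps,
    records_to_frame,
    scan_genes,
    select_genes,
    simulate_trio_dataset,
    stratify_by_genotype,
    stratify_by_labels,
    tpr_at_m,
)
from fedchow.data_io import GenotypeMatrix, SnpRecord
from fedchow.trio_scan import TrioRecord


def _record(gene_id, p, stratifier="rs1"):
    return TrioRecord(
        stratifier_id=stratifier,
        gene_id=gene_id,
        biomarker_id="vol",
        f_value=1.0,
        p_value=p,
        q_value=p,
        group_sizes=(5, 5, 5),
        per_group_pearson=((0.1, 0.5, 5),) * 3,
    )


CENTRAL = ScanConfig(solver="centralized")


class TestStratify:
    def test_direct_mapping_with_missing(self):
        gm = GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(6)],
            snps=[SnpRecord(snp_id="rs1")],
            calls=np.array([[0, 0, 1, 1, 2, np.nan]]).T,
        )
        strat = stratify_by_genotype(gm, "rs1")
        sizes = {g: sum(1 for v in strat.groups.values() if v == g)
                 for g in (0, 1, 2)}
        assert sizes == {0: 2, 1: 2, 2: 1}
        assert strat.dropped_samples == ("S5",)

    def test_absent_snp_is_lookup_failure(self):
        gm = GenotypeMatrix(
            sample_ids=["S0"], snps=[SnpRecord(snp_id="rs1")],
            calls=np.array([[0.0]]),
        )
        with pytest.raises(KeyError):
            stratify_by_genotype(gm, "rs999")

    def test_hwe_group_proportions(self):
        spec = SimulationSpec(n_samples=600, allele_freq=0.3, n_snps=1,
                              n_causal_snps=1, seed=13)
        from fedchow import simulate_genotypes

        gm = simulate_genotypes(spec)
        strat = stratify_by_genotype(gm, gm.snp_ids[0])
        labels = np.array(list(strat.groups.values()))
        for g, expected in [(0, 0.49), (1, 0.42), (2, 0.09)]:
            se = math.sqrt(expected * (1 - expected) / 600)
            assert abs((labels == g).mean() - expected) < 3 * se

    def test_label_column_stratifier(self):
        labels = pd.Series(
            ["e3/e3", "e3/e4", "e4/e4", None, "e3/e3"],
            index=[f"S{i}" for i in range(5)], name="apoe",
        )
        strat = stratify_by_labels(labels)
        assert strat.source == "apoe"
        assert strat.dropped_samples == ("S3",)
        assert strat.distinct_labels == ["e3/e3", "e3/e4", "e4/e4"]
        with pytest.raises(ValueError, match="levels"):
            stratify_by_labels(
                pd.Series(list("abcd"), index=list("wxyz"), name="bad")
            )


class TestScanGenes:
    def test_planted_gene_has_smallest_p(self, small_trio_dataset):
        spec, (genotypes, expression, biomarker, truth) = small_trio_dataset
        strat = stratify_by_genotype(genotypes, truth["snp_id"][0])
        records = scan_genes(strat, biomarker, expression, CENTRAL)
        assert len(records) == spec.n_genes
        best = min(records, key=lambda r: (r.p_value, r.gene_id))
        assert best.gene_id == truth["gene_id"][0]
        # q-values exist wherever p does, in [0, 1]
        assert all(
            0 <= r.q_value <= 1 for r in records if not r.is_missing
        )

    def test_null_scan_calibrated(self):
        spec = SimulationSpec(
            n_samples=150, group_slopes=(0.5, 0.5, 0.5), noise_sd=0.3,
            n_genes=400, n_causal_genes=1, n_snps=1, n_causal_snps=1,
            balanced_groups=True, seed=23,
        )
        genotypes, expression, biomarker, _ = simulate_trio_dataset(spec)
        strat = stratify_by_genotype(genotypes, genotypes.snp_ids[0])
        records = scan_genes(strat, biomarker, expression, CENTRAL)
        rate = np.mean([r.p_value < 0.05 for r in records])
        se = math.sqrt(0.05 * 0.95 / len(records))
        assert abs(rate - 0.05) < 3 * se

    def test_constant_biomarker_yields_missing_p(self, small_trio_dataset):
        _, (genotypes, expression, biomarker, truth) = small_trio_dataset
        constant = pd.Series(1.0, index=biomarker.index)
        strat = stratify_by_genotype(genotypes, truth["snp_id"][0])
        records = scan_genes(strat, constant, expression, CENTRAL)
        assert all(r.is_missing for r in records)
        assert all(math.isnan(r.q_value) for r in records)

    def test_invariant_to_gene_and_sample_order(self, small_trio_dataset):
        _, (genotypes, expression, biomarker, truth) = small_trio_dataset
        strat = stratify_by_genotype(genotypes, truth["snp_id"][0])
        base = scan_genes(strat, biomarker, expression, CENTRAL)

        rng = np.random.default_rng(1)
        shuffled_genes = expression.values.sample(frac=1, random_state=5)
        shuffled_samples = shuffled_genes[
            list(rng.permutation(expression.sample_ids))
        ]
        from fedchow import ExpressionMatrix

        again = scan_genes(
            strat, biomarker, ExpressionMatrix(values=shuffled_samples),
            CENTRAL,
        )
        by_gene = {r.gene_id: r for r in again}
        for r in base:
            assert by_gene[r.gene_id].p_value == pytest.approx(
                r.p_value, rel=1e-12, nan_ok=True
            )

    def test_federated_scan_deterministic_and_matches_centralized(
        self, small_trio_dataset
    ):
        _, (genotypes, expression, biomarker, truth) = small_trio_dataset
        sub = expression.values.iloc[:8]
        from fedchow import ExpressionMatrix

        expr = ExpressionMatrix(values=sub)
        strat = stratify_by_genotype(genotypes, truth["snp_id"][0])
        fed_cfg = ScanConfig(solver="federated", n_sites=3, seed=99)
        run1 = records_to_frame(scan_genes(strat, biomarker, expr, fed_cfg))
        run2 = records_to_frame(scan_genes(strat, biomarker, expr, fed_cfg))
        assert run1.to_csv() == run2.to_csv()  # byte-identical rerun
        central = records_to_frame(scan_genes(strat, biomarker, expr, CENTRAL))
        np.testing.assert_allclose(
            run1["p"].to_numpy(), central["p"].to_numpy(), rtol=1e-6
        )


class TestSelectGenes:
    def test_threshold_with_no_significant_genes(self):
        records = [_record(f"G{i}", 0.5) for i in range(4)]
        assert select_genes(records, alpha=0.05) == []

    def test_top_n_takes_smallest(self):
        records = [
            _record("G1", 0.001), _record("G2", 0.2),
            _record("G3", 0.01), _record("G4", 0.05),
        ]
        assert select_genes(records, top_n=3) == ["G1", "G3", "G4"]

    def test_ties_broken_lexicographically(self):
        records = [_record(g, 0.01) for g in ("GB", "GA", "GC")]
        assert select_genes(records, top_n=2) == ["GA", "GB"]
        assert select_genes(records, top_n=2) == select_genes(records, top_n=2)

    def test_oversized_top_n_warns_and_returns_all(self):
        records = [_record("G1", 0.1), _record("G2", float("nan"))]
        with pytest.warns(UserWarning, match="exceeds"):
            assert select_genes(records, top_n=5) == ["G1"]

    def test_exactly_one_mode_required(self):
        records = [_record("G1", 0.1)]
        with pytest.raises(ValueError):
            select_genes(records)
        with pytest.raises(ValueError):
            select_genes(records, alpha=0.05, top_n=3)


class TestEnrichSelection:
    def test_total_overlap_is_certain(self):
        genes = [f"G{i}" for i in range(10)]
        res = enrich_selection(genes, genes, genes)
        assert res.overlap == 10
        assert res.p_value == 0.0  # no more-extreme outcome exists

    def test_disjoint_sets(self):
        res = enrich_selection(["G1"], ["G2"], ["G1", "G2", "G3"])
        assert res.overlap == 0

    def test_case_insensitive_matching(self):
        res = enrich_selection(
            ["brca1"], ["BRCA1"], ["BRCA1", "TP53", "APOE"]
        )
        assert res.overlap == 1

    def test_out_of_universe_entries_dropped(self):
        res = enrich_selection(
            ["G1", "NOT_THERE"], ["G1", "ALSO_NOT"], [f"G{i}" for i in range(5)]
        )
        assert res.draw_size == 1 and res.reference_size == 1

    def test_monotone_in_overlap(self):
        from fedchow import hypergeom_enrichment

        previous = 1.0
        for k in range(0, 11):
            p = hypergeom_enrichment(100, 20, 10, k).p_value
            assert p <= previous + 1e-12
            previous = p

    def test_empty_universe_fatal(self):
        with pytest.raises(ValueError):
            enrich_selection(["G1"], ["G1"], [])


class TestRankSnps:
    @pytest.fixture(scope="class")
    def planted_ranking(self):
        # moderate planted slopes: with very divergent slopes the causal
        # genes' slope-mixture variance makes them detectable under *every*
        # stratifier and the overlap counts saturate, so the ranking can
        # only discriminate when the per-group slopes are moderate
        spec = SimulationSpec(
            n_samples=300, n_genes=150, n_causal_genes=16, n_snps=12,
            n_causal_snps=4, group_slopes=(0.5, 0.5, 1.0), noise_sd=0.5,
            balanced_groups=True, seed=31,
        )
        genotypes, expression, biomarker, truth = simulate_trio_dataset(spec)
        reference = sorted(set(truth["gene_id"]))
        # top_n matches each causal SNP's own gene dosage (16 genes over 4
        # SNPs): a causal SNP fills its selection with its own genes while
        # a null SNP's top-4 rarely reaches the reference
        ranked = rank_snps(
            genotypes.snp_ids, genotypes, biomarker, expression,
            reference, top_n=4, config=CENTRAL,
        )
        return spec, truth, ranked

    def test_causal_snps_occupy_top_ranks(self, planted_ranking):
        spec, truth, ranked = planted_ranking
        causal = set(truth["snp_id"])
        top = {r.snp_id for r in ranked[: len(causal)]}
        assert top == causal
        # the ranking must be signal-driven, not a tie broken by SNP name
        causal_overlaps = {r.overlap for r in ranked if r.snp_id in causal}
        null_overlaps = {r.overlap for r in ranked if r.snp_id not in causal}
        assert min(causal_overlaps) > max(null_overlaps)

    def test_tpr_at_number_planted(self, planted_ranking):
        spec, truth, ranked = planted_ranking
        causal = set(truth["snp_id"])
        assert tpr_at_m(ranked, causal, len(causal)) == 1.0

    def test_equal_overlap_gives_equal_p(self, planted_ranking):
        _, _, ranked = planted_ranking
        by_overlap = {}
        for r in ranked:
            if math.isfinite(r.enrichment_p):
                by_overlap.setdefault(r.overlap, set()).add(r.enrichment_p)
        for overlap, ps in by_overlap.items():
            assert len(ps) == 1, f"overlap {overlap} maps to {ps}"

    def test_monomorphic_snp_ranked_last_with_missing_p(self):
        spec = SimulationSpec(n_samples=60, n_genes=5, n_causal_genes=1,
                              n_snps=2, n_causal_snps=1, balanced_groups=True,
                              seed=8)
        genotypes, expression, biomarker, _ = simulate_trio_dataset(spec)
        genotypes.calls[:, 1] = 0.0  # second SNP monomorphic
        ranked = rank_snps(
            genotypes.snp_ids, genotypes, biomarker, expression,
            expression.gene_ids[:2], top_n=2, config=CENTRAL,
        )
        assert ranked[-1].snp_id == genotypes.snp_ids[1]
        assert math.isnan(ranked[-1].enrichment_p)
        assert [r.rank for r in ranked] == [1, 2]


class TestTprAtM:
    def _ranking(self, snp_ids):
        from fedchow import SnpRankRecord

        return [
            SnpRankRecord(snp_id=s, enrichment_p=0.01 * i, overlap=1, rank=i + 1)
            for i, s in enumerate(snp_ids)
        ]

    def test_all_positives_first(self):
        ranked = self._ranking([f"P{i}" for i in range(5)] + ["N1", "N2"])
        assert tpr_at_m(ranked, {f"P{i}" for i in range(5)}, 5) == 1.0

    def test_full_depth_equals_prevalence(self):
        ranked = self._ranking(["P1", "N1", "P2", "N2"])
        assert tpr_at_m(ranked, {"P1", "P2"}, 4) == 0.5

    def test_random_ranking_matches_prevalence_on_average(self, rng):
        snps = [f"S{i}" for i in range(20)]
        positives = set(snps[:10])
        m = 5
        tprs = []
        for _ in range(1000):
            order = list(rng.permutation(snps))
            tprs.append(tpr_at_m(self._ranking(order), positives, m))
        # mean TPR of a random ranking is the prevalence
        prevalence = 0.5
        se = np.std(tprs, ddof=1) / math.sqrt(len(tprs))
        assert abs(np.mean(tprs) - prevalence) < 3 * se

    def test_m_out_of_range(self):
        ranked = self._ranking(["A", "B"])
        with pytest.raises(ValueError):
            tpr_at_m(ranked, {"A"}, 0)
        with pytest.raises(ValueError):
            tpr_at_m(ranked, {"A"}, 3)


class TestAdjustByIcv:
    def test_elementwise_division(self):
        np.testing.assert_allclose(
            adjust_by_icv([2.0, 4.0], [2.0, 2.0]), [1.0, 2.0]
        )

    def test_rank_preserving_for_common_icv(self, rng):
        volume = rng.uniform(1, 10, 30)
        adjusted = adjust_by_icv(volume, np.full(30, 3.7))
        assert (np.argsort(adjusted) == np.argsort(volume)).all()

    def test_matches_division_oracle_and_keeps_index(self, rng):
        volume = pd.Series(rng.uniform(1, 5, 10), index=[f"S{i}" for i in range(10)])
        icv = pd.Series(rng.uniform(8, 12, 10), index=volume.index)
        adjusted = adjust_by_icv(volume, icv)
        np.testing.assert_allclose(adjusted.to_numpy(),
                                   volume.to_numpy() / icv.to_numpy())
        assert list(adjusted.index) == list(volume.index)

    def test_nonpositive_icv_rejected(self):
        with pytest.raises(ValueError):
            adjust_by_icv([1.0, 2.0], [1.0, 0.0])


class TestRecordsToFrame:
    def test_layout(self):
        frame = records_to_frame([_record("G1", 0.01)])
        assert list(frame.columns) == [
            "stratifier_id", "gene_id", "biomarker_id", "F", "p", "q",
            "n_g1", "n_g2", "n_g3",
            "r_g1", "p_g1", "r_g2", "p_g2", "r_g3", "p_g3",
        ]
        assert frame.loc[0, "gene_id"] == "G1"
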