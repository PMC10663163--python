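import numpy as np
import pandas as pd
import pytest

from ctscore.annotation import build_annotation, read_gtf, select_longest_transcript
from ctscore.chip import gene_body_fraction, meta_gene_matrix, split_by_expression
from ctscore.enrichment import reprogramming_score
from ctscore.quant import gene_rpkm, score_dataset
from ctscore.simulate import (
    SimConfig,
    expected_ct_ratio,
    simulate_annotation,
    simulate_chip_coverage,
    simulate_counts,
    simulate_metadata,
    simulate_signature_expression,
    write_gtf,
)
from ctscore.stats import summarize_medians


class TestSimulateAnnotation:
    def test_same_seed_same_gtf_bytes(self, tmp_path):
        for run in ("a", "b"):
            cfg = SimConfig(seed=123, n_genes=30)
            annotation, _ = simulate_annotation(cfg)
            write_gtf(annotation, tmp_path / f"{run}.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_gtf_round_trip_recovers_models(self, tmp_path):
        cfg = SimConfig(seed=5, n_genes=20)
        annotation, _ = simulate_annotation(cfg)
        path = tmp_path / "sim.gtf"
        write_gtf(annotation, path)
        back = build_annotation(read_gtf(path))
        assert back.genes() == annotation.genes()
        for g in annotation.genes():
            a, b = annotation[g], back[g]
            assert [(e.start, e.end) for e in a.exons] == [(e.start, e.end) for e in b.exons]

    def test_decoy_isoforms_never_win_selection(self):
        cfg = SimConfig(seed=9, n_genes=40, decoy_isoforms=True)
        annotation, _ = simulate_annotation(cfg)
        # the annotation already holds the longest per gene; verify directly
        for g in annotation.genes():
            assert annotation[g].transcript_id.endswith(".t1")

    def test_gene_loci_do_not_overlap(self):
        cfg = SimConfig(seed=2, n_genes=50)
        annotation, sizes = simulate_annotation(cfg)
        spans = sorted(
            (annotation[g].span.start, annotation[g].span.end) for g in annotation.genes()
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert spans[-1][1] <= sizes[cfg.chrom]

    def test_fixed_exon_count_makes_all_genes_scoreable(self):
        cfg = SimConfig(seed=4, n_genes=25, exon_count_range=(5, 5))
        annotation, _ = simulate_annotation(cfg)
        meta = simulate_metadata(cfg)
        table, _ = simulate_counts(cfg, annotation, meta)
        scores, _, filters = score_dataset(table, annotation)
        assert filters["passed"].all()
        assert (annotation.n_exons() == 5).all()


class TestSimulateCounts:
    def test_same_seed_identical_tables(self):
        cfg = SimConfig(seed=77, n_genes=15)
        annotation, _ = simulate_annotation(cfg)
        meta = simulate_metadata(cfg)
        t1, _ = simulate_counts(cfg, annotation, meta)
        t2, _ = simulate_counts(cfg, annotation, meta)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_poisson_means_match_truth_at_high_expression(self):
        # theta = 0, alpha -> 0: empirical exon means within 3 s.e. of lambda*L*s
        cfg = SimConfig(
            seed=8, n_genes=30, dispersion=0.0, theta={"only": 0.0},
            samples_per_condition=12, expr_log_mean=np.log(1.0), expr_log_sd=0.3,
        )
        annotation, _ = simulate_annotation(cfg)
        meta = simulate_metadata(cfg)
        table, truth = simulate_counts(cfg, annotation, meta)
        within = 0
        total = 0
        for (gene, _tid, rank), row in table.counts.iterrows():
            L = annotation[gene].exon(rank).length
            mu = truth.lam[gene] * L
            se = np.sqrt(mu / len(row))
            total += 1
            within += abs(row.mean() - mu) <= 3 * se
        assert within / total > 0.95

    def test_null_pipeline_centres_at_unit_ratio(self):
        cfg = SimConfig(seed=21, theta={"only": 0.0})
        annotation, _ = simulate_annotation(cfg)
        meta = simulate_metadata(cfg)
        table, _ = simulate_counts(cfg, annotation, meta)
        scores, _, _ = score_dataset(table, annotation)
        medians = summarize_medians(scores)["median_log2_ratio"]
        assert abs(medians.mean()) < 0.05

    def test_planted_genes_follow_their_own_rates(self):
        cfg = SimConfig(
            seed=13, n_genes=80, exon_count_range=(6, 6), dispersion=0.0,
            theta={"a": 0.0}, n_planted=20, theta_planted={"a": 1.0},
            expr_log_mean=np.log(1.0), expr_log_sd=0.2,
        )
        annotation, _ = simulate_annotation(cfg)
        meta = simulate_metadata(cfg)
        table, truth = simulate_counts(cfg, annotation, meta)
        scores, _, _ = score_dataset(table, annotation)
        ratios = scores.ratio_matrix().mean(axis=1)
        planted = ratios.index.intersection(truth.planted)
        background = ratios.index.difference(truth.planted)
        assert ratios[planted].median() > 1.5
        assert abs(ratios[background].median() - 1.0) < 0.1


class TestExpectedCtRatio:
    def test_zero_rate_is_unity(self):
        assert expected_ct_ratio(0.0, ("fixed", 4), 8) == 1.0

    def test_fixed_start_closed_form(self):
        assert expected_ct_ratio(0.5, ("fixed", 4), 6) == pytest.approx(1.5)
        assert expected_ct_ratio(0.5, ("fixed", 4), 9) == pytest.approx(1.5)

    def test_uniform_start_worked_case(self):
        # n = 6, equal lengths: 1 + 0.5 * ((3/5) + (4/5)) / 2 = 1.35
        assert expected_ct_ratio(0.5, ("uniform",), 6) == pytest.approx(1.35)

    def test_uniform_start_with_unequal_lengths(self):
        # manual length weighting over intermediate exons {4, 5}
        lengths = [100, 100, 100, 300, 100, 100]
        expect = 1 + 0.5 * (300 * 3 / 5 + 100 * 4 / 5) / 400
        assert expected_ct_ratio(0.5, ("uniform",), 6, lengths) == pytest.approx(expect)

    def test_too_few_exons_rejected(self):
        with pytest.raises(ValueError):
            expected_ct_ratio(0.5, ("fixed", 4), 4)

    def test_late_fixed_start_dilutes_ratio(self):
        # start rank 6 of 8: intermediates {4..7}, only {6, 7} carry cryptic reads
        assert expected_ct_ratio(0.8, ("fixed", 6), 8) == pytest.approx(1 + 0.8 * 0.5)


class TestSimulateMetadata:
    def test_sample_count_and_columns(self):
        cfg = SimConfig(seed=1, theta={"a": 0, "b": 0.1, "c": 0.2}, samples_per_condition=4)
        meta = simulate_metadata(cfg)
        assert len(meta) == 12
        assert set(meta.columns) >= {"sample", "condition", "cage", "sex", "day"}

    def test_no_confounding_balances_cages_exactly(self):
        cfg = SimConfig(seed=1, theta={"a": 0, "b": 0}, samples_per_condition=6)
        meta = simulate_metadata(cfg)
        tab = meta.groupby(["condition", "cage"]).size().unstack()
        assert (tab["A"] == tab["B"]).all()

    def test_confounding_weight_skews_cage_counts(self):
        cfg = SimConfig(
            seed=1, theta={"ref": 0, "trt": 0.3}, samples_per_condition=6,
            confounding_weight=2 / 3,
        )
        meta = simulate_metadata(cfg)
        counts = meta.groupby(["condition", "cage"]).size()
        assert counts[("ref", "B")] == 1
        assert counts[("trt", "B")] == 5

    def test_day_parsed_from_condition_names(self):
        cfg = SimConfig(seed=1, theta={"D0": 0, "D6": 0.4}, samples_per_condition=2)
        meta = simulate_metadata(cfg)
        assert set(meta.loc[meta["condition"] == "D6", "day"]) == {6}

    def test_seed_determinism(self):
        cfg = SimConfig(seed=42, theta={"a": 0, "b": 0.1})
        pd.testing.assert_frame_equal(simulate_metadata(cfg), simulate_metadata(cfg))


class TestSimulateChip:
    @pytest.fixture
    def setup(self):
        cfg = SimConfig(seed=6, n_genes=30)
        annotation, sizes = simulate_annotation(cfg)
        meta = simulate_metadata(cfg)
        table, truth = simulate_counts(cfg, annotation, meta)
        return cfg, annotation, sizes, table, truth

    def test_flat_enrichment_gives_genomic_body_fraction(self, setup):
        _, annotation, sizes, _, truth = setup
        track = simulate_chip_coverage(annotation, truth.lam, sizes, enrichment=0.0)
        genomic = sum(
            annotation[g].span.end - annotation[g].span.start for g in annotation.genes()
        ) / sizes["chr1"]
        assert gene_body_fraction(track, annotation) == pytest.approx(genomic, rel=1e-12)

    def test_enrichment_raises_body_over_flank_in_top_tercile(self, setup):
        _, annotation, sizes, table, truth = setup
        track = simulate_chip_coverage(annotation, truth.lam, sizes, enrichment=2.0)
        matrix = meta_gene_matrix(track, annotation)
        _, means = gene_rpkm(table, annotation)
        top = split_by_expression(matrix, means, K=3)[3]
        body_cols = [c for c in matrix.columns if c.startswith("b")]
        flank_cols = [c for c in matrix.columns if c.startswith(("u", "d"))]
        assert top[body_cols].mean().mean() > top[flank_cols].mean().mean()

    def test_deterministic_given_inputs(self, setup):
        _, annotation, sizes, _, truth = setup
        t1 = simulate_chip_coverage(annotation, truth.lam, sizes)
        t2 = simulate_chip_coverage(annotation, truth.lam, sizes)
        assert all(np.array_equal(t1.runs[c], t2.runs[c]) for c in t1.runs)


class TestSignatureExpression:
    def test_poised_samples_separate_at_large_effect(self):
        cfg = SimConfig(seed=3)
        sig = [f"SIG{i}" for i in range(20)]
        mat, groups = simulate_signature_expression(sig, cfg, delta=3.0)
        scores = reprogramming_score(mat, sig, transform=None)
        assert scores[groups == "poised"].mean() > scores[groups == "control"].mean()

    def test_null_effect_keeps_groups_close(self):
        cfg = SimConfig(seed=3)
        sig = [f"SIG{i}" for i in range(20)]
        mat, groups = simulate_signature_expression(sig, cfg, delta=0.0)
        scores = reprogramming_score(mat, sig, transform=None)
        gap = scores[groups == "poised"].mean() - scores[groups == "control"].mean()
        assert abs(gap) < 0.5

    def test_seed_determinism(self):
        cfg = SimConfig(seed=10)
        m1, _ = simulate_signature_expression(["g"], cfg)
        m2, _ = simulate_signature_expression(["g"], cfg)
        pd.testing.assert_frame_equal(m1, m2)


class TestEndToEndRecovery:
    def test_median_ratio_tracks_cryptic_rate(self):
        cfg = SimConfig(
            seed=19, n_genes=150, exon_count_range=(5, 10),
            theta={"t0": 0.0, "t1": 0.25, "t2": 0.5},
        )
        annotation, _ = simulate_annotation(cfg)
        meta = simulate_metadata(cfg)
        table, _ = simulate_counts(cfg, annotation, meta)
        scores, _, _ = score_dataset(table, annotation)
        data = summarize_medians(scores).merge(meta, on="sample")
        by_cond = data.groupby("condition")["median_log2_ratio"].mean()
        assert by_cond["t0"] < by_cond["t1"] < by_cond["t2"]

    def test_empirical_mean_ratio_near_closed_form(self):
        cfg = SimConfig(
            seed=23, n_genes=120, exon_count_range=(6, 6), dispersion=0.01,
            theta={"c": 0.4}, expr_log_mean=np.log(2.0), expr_log_sd=0.2,
            samples_per_condition=4,
        )
        annotation, _ = simulate_annotation(cfg)
        meta = simulate_metadata(cfg)
        table, _ = simulate_counts(cfg, annotation, meta)
        scores, _, _ = score_dataset(table, annotation)
        ratios = scores.ratio_matrix().mean(axis=1)
        se = ratios.std() / np.sqrt(len(ratios))
        assert abs(ratios.mean() - expected_ct_ratio(0.4, ("fixed", 4), 6)) < 3 * se + 0.02
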