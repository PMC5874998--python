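"""Synthetic gene/cohort generator: determinism, truth bookkeeping, SAM emission."""

from __future__ import annotations

import re

import numpy as np
import pytest

from titinsplice.ase_classify import classify_all
from titinsplice.exon_usage import usage_table
from titinsplice.filtering import qc_filter
from titinsplice.junction_io import extract_junctions
from titinsplice.synthetic_data import (
    AltSiteSpec,
    SimConfig,
    emit_cohort_sam,
    emit_spliced_sam,
    make_titin_like_model,
    make_toy_gene,
    simulate_junction_counts,
)


def two_isoform_config(p: float = 0.5, **kwargs) -> SimConfig:
    defaults = dict(
        n_exons=3,
        seed=42,
        n_samples=8,
        depth=1000.0,
        isoforms={"full": (1, 2, 3), "skip": (1, 3)},
        proportions={"full": p, "skip": 1 - p},
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestMakeToyGene:
    def test_meta_only_and_repeat_flags(self):
        config = SimConfig(
            n_exons=12,
            seed=1,
            meta_only_ids=frozenset({4, 5}),
            repeat_blocks=("B1", "B2", "B3"),
            repeat_copies=2,
            repeat_start=6,
        )
        model = make_toy_gene(config)
        assert model.exon(4).exon_class == "meta_only"
        assert model.exon(5).exon_class == "meta_only"
        blocks = [model.exon(i).repeat_block for i in range(6, 12)]
        assert blocks == ["B1", "B2", "B3", "B1", "B2", "B3"]
        assert model.exon(12).repeat_block is None

    def test_repeat_spec_exceeding_gene_rejected(self):
        config = SimConfig(
            n_exons=6, seed=1, repeat_blocks=("B1", "B2"), repeat_copies=2, repeat_start=5
        )
        with pytest.raises(ValueError, match="exceeds"):
            make_toy_gene(config)

    def test_same_seed_same_model(self):
        a = make_toy_gene(SimConfig(n_exons=12, seed=9))
        b = make_toy_gene(SimConfig(n_exons=12, seed=9))
        assert a.exons == b.exons

    def test_frameshift_exons_break_multiple_of_three(self):
        config = SimConfig(n_exons=5, seed=3, frameshift_exons=frozenset({2}))
        model = make_toy_gene(config)
        assert model.exon(2).coding_length % 3 == 1
        for other in (1, 3, 4, 5):
            assert model.exon(other).coding_length % 3 == 0

    def test_minus_strand_toggle_reverses_orientation(self):
        plus = make_toy_gene(SimConfig(n_exons=4, seed=2, strand="+"))
        minus = make_toy_gene(SimConfig(n_exons=4, seed=2, strand="-"))
        assert plus.exon(1).genomic_start < plus.exon(4).genomic_start
        assert minus.exon(1).genomic_start > minus.exon(4).genomic_start
        assert [e.length for e in plus.exons] == [e.length for e in minus.exons]

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            two_isoform_config(proportions={"full": 0.6, "skip": 0.6})


class TestTitinLikeModel:
    def test_structure_matches_the_metatranscript_layout(self):
        model = make_titin_like_model()
        assert len(model.exons) == 364
        assert [e.exon_id for e in model.exons] == list(range(1, 365))
        assert model.exon(1).exon_class == "noncoding"
        assert sum(e.coding_length > 0 for e in model.exons) == 363
        assert model.strand == "-"
        meta = {e.exon_id for e in model.exons if e.exon_class == "meta_only"}
        assert meta == {148, 150, *range(159, 172), *range(213, 218)}
        repeat = {e.exon_id for e in model.exons if e.repeat_block is not None}
        assert repeat == set(range(172, 206))

    def test_n2a_isoform_carries_the_47_50_junction(self):
        model = make_titin_like_model()
        n2a = model.isoform("N2A")
        assert (47, 50) in n2a.junctions()
        assert 49 not in n2a.exon_ids


class TestSimulateCounts:
    def test_single_isoform_all_exons_fully_included(self):
        config = SimConfig(
            n_exons=4, seed=5, n_samples=4, depth=500.0,
            isoforms={"only": (1, 2, 3, 4)}, proportions={"only": 1.0},
        )
        model = make_toy_gene(config)
        matrix, truth = simulate_junction_counts(model, config)
        assert matrix.n_junctions == 3
        assert all(truth.mean_inclusion(i) == 1.0 for i in range(1, 5))

    def test_truth_records_mixture_inclusion(self):
        config = two_isoform_config(p=0.26)
        model = make_toy_gene(config)
        _, truth = simulate_junction_counts(model, config)
        assert truth.mean_inclusion(2) == pytest.approx(0.26)
        assert truth.mean_inclusion(1) == 1.0

    def test_expected_counts_scale_with_proportion_and_depth(self):
        config = two_isoform_config(p=0.25, n_samples=10, depth=100.0)
        model = make_toy_gene(config)
        _, truth = simulate_junction_counts(model, config)
        by_mean = sorted(truth.expected_counts.values())
        # pooled means: 2 junctions at 0.25*100*10=250, 1 at 0.75*100*10=750
        assert by_mean == pytest.approx([250.0, 250.0, 750.0])

    def test_determinism_same_seed_identical_counts(self):
        config = two_isoform_config()
        model = make_toy_gene(config)
        a, _ = simulate_junction_counts(model, config)
        b, _ = simulate_junction_counts(model, config)
        assert a.counts.equals(b.counts)
        assert a.junctions == b.junctions

    def test_negative_binomial_noise_is_overdispersed(self):
        base = two_isoform_config(n_samples=200, depth=200.0)
        nb = two_isoform_config(
            n_samples=200, depth=200.0, count_noise="negative_binomial", nb_dispersion=0.5
        )
        model = make_toy_gene(base)
        poisson_counts, _ = simulate_junction_counts(model, base)
        nb_counts, _ = simulate_junction_counts(model, nb)
        var_p = poisson_counts.counts.iloc[0].var()
        var_nb = nb_counts.counts.iloc[0].var()
        assert var_nb > 2 * var_p

    def test_alt_site_offsets_recovered_exactly(self):
        for offset, side in [(4, "acceptor"), (-3, "acceptor"), (6, "donor"), (-9, "donor")]:
            config = SimConfig(
                n_exons=3, seed=8, n_samples=3, depth=300.0,
                isoforms={"full": (1, 2, 3)}, proportions={"full": 1.0},
                alt_site_spec=(AltSiteSpec(exon=2, side=side, offset=offset, usage_fraction=0.3),),
            )
            model = make_toy_gene(config)
            matrix, _ = simulate_junction_counts(model, config)
            events = classify_all(matrix.junctions, model)
            alt = [e for e in events if e.category.startswith("alt_")]
            assert len(alt) == 1
            observed = (
                alt[0].acceptor_offset_nt if side == "acceptor" else alt[0].donor_offset_nt
            )
            assert observed == offset
            assert alt[0].category == f"alt_{side}"


class TestEmitSam:
    def test_one_read_per_junction_count(self):
        config = two_isoform_config(n_samples=1, depth=50.0)
        model = make_toy_gene(config)
        matrix, _ = simulate_junction_counts(model, config)
        counts = matrix.sample_counts("sample01")
        sam = emit_spliced_sam(model, counts, seed=3)
        body = [ln for ln in sam.splitlines() if not ln.startswith("@")]
        assert len(body) == sum(counts.values())
        assert all(ln.split("\t")[5].count("N") == 1 for ln in body)

    def test_round_trip_reproduces_matrix_exactly(self, tmp_path):
        config = two_isoform_config(n_samples=3, depth=100.0)
        model = make_toy_gene(config)
        matrix, _ = simulate_junction_counts(model, config)
        for sample, text in emit_cohort_sam(model, matrix, seed=17).items():
            path = tmp_path / f"{sample}.sam"
            path.write_text(text)
            assert extract_junctions(path) == matrix.sample_counts(sample)

    def test_anchor_bounds_at_default_read_length(self):
        config = two_isoform_config(n_samples=1, depth=200.0)
        model = make_toy_gene(config)
        matrix, _ = simulate_junction_counts(model, config)
        sam = emit_spliced_sam(model, matrix.sample_counts("sample01"), read_length=86, seed=5)
        for line in sam.splitlines():
            if line.startswith("@"):
                continue
            left, _, right = map(int, re.match(r"(\d+)M(\d+)N(\d+)M", line.split("\t")[5]).groups())
            assert 8 <= left <= 78
            assert 8 <= right <= 78
            assert left + right == 86

    def test_too_short_reads_rejected(self):
        config = two_isoform_config()
        model = make_toy_gene(config)
        with pytest.raises(ValueError, match="too short"):
            emit_spliced_sam(model, {}, read_length=16, min_anchor=8)

    def test_fixed_seed_byte_identical(self):
        config = two_isoform_config(n_samples=1)
        model = make_toy_gene(config)
        counts = simulate_junction_counts(model, config)[0].sample_counts("sample01")
        assert emit_spliced_sam(model, counts, seed=9) == emit_spliced_sam(model, counts, seed=9)


class TestFullPipelineRecovery:
    def test_simulate_extract_classify_filter_usage_recovers_truth(self, tmp_path):
        """End-to-end through SAM text at moderate depth, single replicate."""
        config = SimConfig(
            n_exons=5, seed=123, n_samples=20, depth=500.0,
            isoforms={"full": (1, 2, 3, 4, 5), "skip3": (1, 2, 4, 5)},
            proportions={"full": 0.68, "skip3": 0.32},
        )
        model = make_toy_gene(config)
        matrix, truth = simulate_junction_counts(model, config)
        per_sample = {}
        for sample, text in emit_cohort_sam(model, matrix, seed=99).items():
            path = tmp_path / f"{sample}.sam"
            path.write_text(text)
            per_sample[sample] = extract_junctions(path)
        from titinsplice.junction_io import merge_samples

        recovered = merge_samples(per_sample)
        qc = qc_filter(recovered)
        counts = recovered.subset(qc.passing).totals()
        events = classify_all(list(counts), model)
        rows = {r.exon_id: r for r in usage_table(model, events, counts)}
        p_true = truth.mean_inclusion(3)
        # pooled reads ~ depth*n_samples: sampling error << 0.02
        assert rows[3].inclusion_rate == pytest.approx(p_true, abs=0.02)
        for steady in (2, 4):
            assert rows[steady].category == "constitutively_expressed"
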