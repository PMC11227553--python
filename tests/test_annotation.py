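"""Promoter construction, probe and CNV-segment mapping."""

import numpy as np
import pandas as pd
import pytest

from miromics.annotation import (
    MirnaAnnotation,
    ProbeAnnotation,
    build_promoters,
    category_frequency_test,
    map_cnv_to_mirnas,
    map_probes_to_promoters,
    summarize_promoter_methylation,
    tss_category,
)


def _ann_table(rows):
    return pd.DataFrame(
        rows, columns=["mirna_id", "chrom", "tss", "strand", "locus_start", "locus_end"]
    )


class TestBuildPromoters:
    @pytest.mark.parametrize(
        "strand,tss,expected",
        [
            ("+", 10000, (8000, 10500)),
            ("-", 10000, (9500, 12000)),
            ("+", 100, (1, 600)),  # clipped at chromosome start
        ],
    )
    def test_window_definition(self, strand, tss, expected):
        table = _ann_table([("m1", "chr1", tss, strand, tss + 30, tss + 51)])
        (promoter,) = build_promoters(table)
        assert promoter.promoter == expected

    def test_unclipped_length_is_window_plus_one(self):
        table = _ann_table([("m1", "chr1", 50000, "+", 50030, 50051)])
        (p,) = build_promoters(table, upstream=2000, downstream=500)
        assert p.promoter[1] - p.promoter[0] + 1 == 2501

    def test_bad_strand_rejected_and_missing_tss_excluded(self, caplog):
        table = _ann_table(
            [
                ("ok", "chr1", 5000, "+", 5030, 5051),
                ("bad", "chr1", 6000, "*", 6030, 6051),
                ("gone", "chr1", np.nan, "+", 7030, 7051),
            ]
        )
        with caplog.at_level("WARNING", logger="miromics.annotation"):
            out = build_promoters(table)
        assert [p.mirna_id for p in out] == ["ok"]
        assert "unknown strand" in caplog.text
        assert "missing TSS" in caplog.text

    def test_duplicate_tss_keeps_first_by_position(self):
        table = _ann_table(
            [
                ("m1", "chr1", 9000, "+", 9030, 9051),
                ("m1", "chr1", 5000, "+", 5030, 5051),
            ]
        )
        (p,) = build_promoters(table)
        assert p.tss == 5000


class TestProbeMapping:
    @staticmethod
    def _promoter(strand="+", tss=10000):
        table = _ann_table([("m1", "chr1", tss, strand, tss + 30, tss + 51)])
        return build_promoters(table)

    @pytest.mark.parametrize(
        "offset,expected",
        [(-100, "TSS200"), (-1500, "TSS2000"), (40, "Body"), (10, "Outside")],
    )
    def test_categories_plus_strand(self, offset, expected):
        (m,) = self._promoter("+")
        probes = [ProbeAnnotation("cg1", "chr1", 10000 + offset, "I", "Island")]
        (a,) = map_probes_to_promoters(probes, [m])
        assert a.tss_category == expected

    def test_probe_outside_promoter_not_assigned(self):
        (m,) = self._promoter("+")
        probes = [ProbeAnnotation("cg1", "chr1", 10600, "I", "Island")]
        assert map_probes_to_promoters(probes, [m]) == []

    def test_probe_on_tss_counts_downstream(self):
        # distance 0 is the downstream side: Body only if inside the locus
        (m,) = self._promoter("+")
        assert tss_category(10000, m) == "Outside"
        inside = MirnaAnnotation("m2", "chr1", 10000, "+", 9990, 10011, (8000, 10500))
        assert tss_category(10000, inside) == "Body"

    def test_strand_equivariance(self):
        """Mirroring strand and reflecting probe positions about the TSS gives
        identical category assignments."""
        rng = np.random.default_rng(42)
        tss = 100000
        plus = build_promoters(_ann_table([("m", "chr1", tss, "+", tss + 30, tss + 51)]))
        minus = build_promoters(_ann_table([("m", "chr1", tss, "-", tss - 51, tss - 30)]))
        offsets = rng.integers(-2200, 2200, size=200)
        for d in offsets:
            p_plus = [ProbeAnnotation("cg", "chr1", int(tss + d), "I", "Island")]
            p_minus = [ProbeAnnotation("cg", "chr1", int(tss - d), "I", "Island")]
            a_plus = map_probes_to_promoters(p_plus, plus)
            a_minus = map_probes_to_promoters(p_minus, minus)
            assert [x.tss_category for x in a_plus] == [x.tss_category for x in a_minus]

    def test_order_independent_and_idempotent(self, small_cohort):
        ann = small_cohort.annotation
        promoters = build_promoters(ann.mirnas)
        probes = ann.probes
        a1 = map_probes_to_promoters(probes, promoters)
        a2 = map_probes_to_promoters(
            probes.sample(frac=1, random_state=0), list(reversed(promoters))
        )
        assert a1 == a2

    def test_shared_probe_contributes_to_both_promoters(self):
        table = _ann_table(
            [
                ("m1", "chr1", 10000, "+", 10030, 10051),
                ("m2", "chr1", 10400, "+", 10430, 10451),
            ]
        )
        promoters = build_promoters(table)
        probes = [ProbeAnnotation("cg1", "chr1", 9900, "I", "Island")]
        assigned = map_probes_to_promoters(probes, promoters)
        assert {a.mirna_id for a in assigned} == {"m1", "m2"}

    def test_chromosome_style_mismatch_is_hard_error(self):
        (m,) = self._promoter()
        probes = [ProbeAnnotation("cg1", "1", 10000, "I", "Island")]
        with pytest.raises(ValueError, match="harmonize"):
            map_probes_to_promoters(probes, [m])


class TestPromoterMethylation:
    @staticmethod
    def _assign(probe_ids, mirna="m1"):
        from miromics.annotation import ProbeAssignment

        return [ProbeAssignment(p, mirna, "TSS200") for p in probe_ids]

    def test_mean_single_and_missing(self):
        beta = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.8, 0.2], "s2": [0.1, np.nan, 0.5, np.nan]},
            index=["p1", "p2", "p3", "p4"],
        )
        out = summarize_promoter_methylation(beta, self._assign(["p1", "p2"]))
        assert out.loc["m1", "s1"] == pytest.approx(0.3)
        assert out.loc["m1", "s2"] == pytest.approx(0.1)  # missing ignored
        out_single = summarize_promoter_methylation(beta, self._assign(["p3"]))
        assert out_single.loc["m1", "s1"] == pytest.approx(0.8)

    def test_all_probes_missing_gives_missing_cell(self):
        beta = pd.DataFrame({"s1": [np.nan, np.nan], "s2": [0.3, 0.5]}, index=["p1", "p2"])
        out = summarize_promoter_methylation(beta, self._assign(["p1", "p2"]))
        assert np.isnan(out.loc["m1", "s1"])
        assert out.loc["m1", "s2"] == pytest.approx(0.4)

    def test_empty_assignment_errors(self):
        beta = pd.DataFrame({"s1": [0.2]}, index=["p1"])
        with pytest.raises(ValueError, match="no probes mapped"):
            summarize_promoter_methylation(beta, [])

    def test_output_bounded_by_contributing_probes(self, small_cohort):
        ann = small_cohort.annotation
        promoters = build_promoters(ann.mirnas)
        assignments = map_probes_to_promoters(ann.probes, promoters)
        beta = small_cohort.beta
        out = summarize_promoter_methylation(beta, assignments)
        table = pd.DataFrame(
            [(a.probe_id, a.mirna_id) for a in assignments], columns=["probe_id", "mirna_id"]
        )
        for mid, grp in table.groupby("mirna_id"):
            probes = [p for p in grp["probe_id"] if p in beta.index]
            if not probes:
                continue
            sub = beta.loc[probes]
            assert (out.loc[mid] >= sub.min(axis=0) - 1e-12).all()
            assert (out.loc[mid] <= sub.max(axis=0) + 1e-12).all()


def _brute_force_cnv(segments, annotations):
    """Quadratic all-pairs containment oracle for segment lookup."""
    samples = sorted(segments["sample"].unique())
    out = pd.DataFrame(
        np.nan, index=[m.mirna_id for m in annotations], columns=samples
    )
    for m in annotations:
        mid = (m.locus_start + m.locus_end) // 2
        for seg in segments.itertuples(index=False):
            if (
                seg.chrom == m.chrom
                and seg.start <= mid <= seg.end
            ):
                out.loc[m.mirna_id, seg.sample] = seg.segment_mean
    return out


class TestCnvMapping:
    def test_containment_and_gap(self):
        ann = [MirnaAnnotation("m1", "chr1", 1000, "+", 1100, 1121, (0, 0)),
               MirnaAnnotation("m2", "chr1", 9000, "+", 9100, 9121, (0, 0))]
        segs = pd.DataFrame(
            [("s1", "chr1", 1, 5000, 0.5)],
            columns=["sample", "chrom", "start", "end", "segment_mean"],
        )
        out = map_cnv_to_mirnas(segs, ann)
        assert out.loc["m1", "s1"] == pytest.approx(0.5)
        assert np.isnan(out.loc["m2", "s1"])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        ann = [
            MirnaAnnotation(f"m{i}", "chr1", 1, "+", int(p), int(p) + 21, (0, 0))
            for i, p in enumerate(rng.integers(1, 100000, size=20))
        ]
        rows = []
        for s in ("s1", "s2"):
            bounds = np.sort(rng.choice(np.arange(1, 100000), size=10, replace=False))
            for a, b in zip(bounds[:-1:2], bounds[1::2]):
                rows.append((s, "chr1", int(a), int(b), float(rng.normal())))
        segs = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "segment_mean"])
        fast = map_cnv_to_mirnas(segs, ann)
        slow = _brute_force_cnv(segs, ann)
        pd.testing.assert_frame_equal(fast, slow, check_names=False)

    def test_overlapping_segments_error_names_sample(self):
        ann = [MirnaAnnotation("m1", "chr1", 1000, "+", 1100, 1121, (0, 0))]
        segs = pd.DataFrame(
            [("sX", "chr1", 1, 5000, 0.5), ("sX", "chr1", 4000, 9000, -0.2)],
            columns=["sample", "chrom", "start", "end", "segment_mean"],
        )
        with pytest.raises(ValueError, match="sX.*chr1"):
            map_cnv_to_mirnas(segs, ann)


class TestCategoryFrequency:
    def test_perfect_fit_gives_zero_statistic(self):
        background = ["A"] * 50 + ["B"] * 50
        assigned = ["A"] * 10 + ["B"] * 10
        _, stat, p = category_frequency_test(assigned, background)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # counts [10, 20] against proportions [0.5, 0.5]: sum (O-E)^2/E = 10/3
        background = ["A", "B"] * 100
        assigned = ["A"] * 10 + ["B"] * 20
        _, stat, _ = category_frequency_test(assigned, background)
        assert stat == pytest.approx(10 / 3)

    def test_degenerate_single_category_errors(self):
        with pytest.raises(ValueError, match="2 non-empty"):
            category_frequency_test(["A"] * 5, ["A"] * 50)

    def test_assigned_count_in_empty_background_category_errors(self):
        with pytest.raises(ValueError, match="absent from background"):
            category_frequency_test(
                ["A", "B"], ["A"] * 10 + ["C"] * 10, categories=("A", "B", "C")
            )
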