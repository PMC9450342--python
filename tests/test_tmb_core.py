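"""Subset counting, per-Mb conversion, threshold classification, cohort summary."""

import json
import random

import pytest

from tmbcount import (CountingScope, IntervalSet, NormalizedVariant, PanelConfig,
                      TMBReport, classify_threshold, compute_tmb, count_genome,
                      count_in_footprint, count_panel, count_protein_modifying,
                      render_report, summarize_cohort)
from tmbcount.consensus import ConsensusSet
from tmbcount.tmb_core import TMBEstimate


def make_variant(pos, ref="A", alt="G", contig="1", impact=None, gene=None, effect=None):
    vclass = "SNV" if len(ref) == len(alt) == 1 else ("INS" if len(alt) > len(ref) else "DEL")
    return NormalizedVariant(contig=contig, pos=pos, ref=ref, alt=alt, vclass=vclass,
                             impact=impact, gene=gene, effect=effect)


def make_consensus(variants):
    return ConsensusSet(variants=tuple(variants), policy="strelka2+mutect2",
                        input_tallies={})


SCOPE = CountingScope(allowed_contigs=("1", "2"), alignable_bases=10_000)


class TestGenomeCount:
    def test_off_scope_contigs_are_dropped(self):
        vs = [make_variant(100 * i) for i in range(1, 6)] + [make_variant(50, contig="MT")]
        assert count_genome(make_consensus(vs), SCOPE) == (5, 0)

    def test_empty_consensus(self):
        assert count_genome(make_consensus([]), SCOPE) == (0, 0)

    def test_snv_and_indel_tallied_separately(self):
        vs = [make_variant(10), make_variant(20, ref="AT", alt="A"),
              make_variant(30, ref="A", alt="AGG"), make_variant(40)]
        assert count_genome(make_consensus(vs), SCOPE) == (2, 2)


class TestFootprintCount:
    FP = IntervalSet.from_iter([("1", 100, 200)])

    def test_snv_inside_footprint_counted(self):
        assert count_in_footprint([make_variant(150)], self.FP) == (1, 0)

    def test_snv_outside_footprint_not_counted(self):
        # footprint is 0-based [100, 200) == 1-based 101..200
        assert count_in_footprint([make_variant(100)], self.FP) == (0, 0)
        assert count_in_footprint([make_variant(101)], self.FP) == (1, 0)

    def test_deletion_partially_overlapping_end_counted(self):
        # ref span 1-based 199..206 overlaps footprint bases up to 0-based 199
        v = make_variant(199, ref="ACGTACGT", alt="A")
        assert count_in_footprint([v], self.FP) == (0, 1)

    def test_deletion_starting_after_footprint_end_not_counted(self):
        v = make_variant(201, ref="ACG", alt="A")
        assert count_in_footprint([v], self.FP) == (0, 0)

    def test_insertion_intersects_via_anchor_base_only(self):
        inside = make_variant(150, ref="A", alt="ATT")
        at_end = make_variant(201, ref="A", alt="ATT")  # anchor outside [100,200)
        assert count_in_footprint([inside], self.FP) == (0, 1)
        assert count_in_footprint([at_end], self.FP) == (0, 0)

    def test_counts_match_position_mask_scan(self):
        rng = random.Random(13)
        fp = IntervalSet.from_iter([("1", rng.randrange(0, 900), rng.randrange(900, 1000))
                                    for _ in range(5)])
        mask = set()
        for _, s, e in fp:
            mask.update(range(s, e))
        variants = []
        for _ in range(200):
            pos = rng.randint(1, 990)
            kind = rng.choice(["SNV", "INS", "DEL"])
            if kind == "SNV":
                variants.append(make_variant(pos))
            elif kind == "INS":
                variants.append(make_variant(pos, ref="A", alt="A" + "T" * rng.randint(1, 3)))
            else:
                variants.append(make_variant(pos, ref="A" * (1 + rng.randint(1, 4)), alt="A"))
        expected_snv = expected_indel = 0
        for v in variants:
            span = range(v.pos - 1, v.pos - 1 + len(v.ref))
            if any(p in mask for p in span):
                if v.vclass == "SNV":
                    expected_snv += 1
                else:
                    expected_indel += 1
        assert count_in_footprint(variants, fp) == (expected_snv, expected_indel)


class TestProteinCount:
    def test_only_high_and_moderate_count(self):
        vs = [make_variant(10 * i, impact=imp)
              for i, imp in enumerate(["HIGH", "MODERATE", "LOW", "MODIFIER", None], 1)]
        assert count_protein_modifying(vs) == (2, 0)

    def test_all_modifier_counts_zero(self):
        vs = [make_variant(10 * i, impact="MODIFIER") for i in range(1, 5)]
        assert count_protein_modifying(vs) == (0, 0)


PANEL_FP = IntervalSet.from_iter([("1", 0, 1000)])


def panel_config(cosmic=(), tsg=(), match_mode="allele"):
    return PanelConfig(panel_genes=frozenset({"PG1", "PG2"}),
                       tumor_suppressor_genes=frozenset(tsg),
                       cosmic_sites=frozenset(cosmic), match_mode=match_mode)


class TestPanelCount:
    def test_exclusion_rules_each_remove_their_variant(self):
        cosmic_v = make_variant(100, gene="PG1")
        nonsense = make_variant(200, gene="PG1", impact="HIGH", effect="stop_gained")
        tsg_low = make_variant(300, gene="TSG1", impact="LOW", effect="synonymous_variant")
        keep1 = make_variant(400, gene="PG2", impact="MODERATE", effect="missense_variant")
        keep2 = make_variant(500, gene="PG1")
        cfg = panel_config(cosmic={cosmic_v.key}, tsg={"TSG1"})
        pc = count_panel([cosmic_v, nonsense, tsg_low, keep1, keep2], PANEL_FP, cfg)
        assert (pc.snv_count, pc.indel_count) == (2, 0)
        assert (pc.n_excluded_cosmic, pc.n_excluded_nonsense, pc.n_excluded_tsg) == (1, 1, 1)

    def test_no_footprint_overlap_counts_zero(self):
        cfg = panel_config()
        assert tuple(count_panel([make_variant(5000)], PANEL_FP, cfg)) == (0, 0)

    def test_variant_matching_two_rules_removed_once(self):
        v = make_variant(100, gene="TSG1", impact="HIGH", effect="stop_gained")
        cfg = panel_config(cosmic={v.key}, tsg={"TSG1"})
        pc = count_panel([v], PANEL_FP, cfg)
        assert (pc.snv_count, pc.indel_count) == (0, 0)
        assert pc.n_excluded_cosmic + pc.n_excluded_nonsense + pc.n_excluded_tsg == 1

    def test_nonsense_removed_even_outside_tsg(self):
        v = make_variant(100, gene="PG1", impact="HIGH", effect="stop_gained")
        pc = count_panel([v], PANEL_FP, panel_config())
        assert pc.n_excluded_nonsense == 1

    def test_frameshift_in_tsg_removed_but_not_outside(self):
        in_tsg = make_variant(100, ref="AT", alt="A", gene="TSG1", impact="HIGH",
                              effect="frameshift_variant")
        outside = make_variant(200, ref="AT", alt="A", gene="PG1", impact="HIGH",
                               effect="frameshift_variant")
        pc = count_panel([in_tsg, outside], PANEL_FP, panel_config(tsg={"TSG1"}))
        assert (pc.snv_count, pc.indel_count) == (0, 1)
        assert pc.n_excluded_tsg == 1

    def test_position_match_mode_ignores_alleles(self):
        v = make_variant(100, alt="T", gene="PG1")
        cfg = panel_config(cosmic={("1", 100)}, match_mode="position")
        assert count_panel([v], PANEL_FP, cfg).n_excluded_cosmic == 1

    def test_exclusions_only_decrease_the_count(self):
        rng = random.Random(5)
        variants = [make_variant(10 * i, gene=rng.choice(["PG1", "TSG1"]),
                                 impact=rng.choice(["HIGH", "LOW", None]),
                                 effect=rng.choice(["stop_gained", "missense_variant", None]))
                    for i in range(1, 60)]
        bare = count_panel(variants, PANEL_FP, panel_config())
        cosmic = {variants[i].key for i in rng.sample(range(len(variants)), 10)}
        strict = count_panel(variants, PANEL_FP, panel_config(cosmic=cosmic, tsg={"TSG1"}))
        assert strict.snv_count + strict.indel_count <= bare.snv_count + bare.indel_count

    def test_empty_panel_gene_list_is_an_error(self):
        with pytest.raises(ValueError, match="panel"):
            PanelConfig(panel_genes=frozenset())


class TestTmbArithmetic:
    def test_zero_count_is_zero_tmb(self):
        assert compute_tmb(0, 123456) == 0.0

    def test_genome_scale_division(self):
        # 38014 SNVs over the 1-22,X,Y alignable space
        assert format(compute_tmb(38014, 2667837836), ".4f") == "14.2490"

    def test_rounding_boundary_does_not_leak_into_classification(self):
        tmb = compute_tmb(9_999_999, 10**12)  # 9.999999/Mb
        assert format(tmb, ".4f") == "10.0000"
        assert classify_threshold(tmb) == "low"  # classification uses unrounded value

    def test_count_just_under_threshold_rate_stays_low(self):
        # largest integer count below 10/Mb of the 1-22,X,Y alignable space
        tmb = compute_tmb(26678, 2667837836)
        assert format(tmb, ".4f") == "9.9999"
        assert classify_threshold(tmb) == "low"

    def test_non_positive_denominator_rejected(self):
        with pytest.raises(ValueError):
            compute_tmb(5, 0)
        with pytest.raises(ValueError):
            compute_tmb(5, -10)


class TestThreshold:
    @pytest.mark.parametrize("tmb,expected", [
        (10.0, "high"), (9.9999, "low"), (17.12, "high"), (0.0, "low"),
        (10.0001, "high"), (9.999999999, "low")])
    def test_boundary_inclusive_classification(self, tmb, expected):
        assert classify_threshold(tmb) == expected

    def test_custom_threshold(self):
        assert classify_threshold(5.0, threshold=5.0) == "high"
        assert classify_threshold(4.9999, threshold=5.0) == "low"

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_threshold(1.0, threshold=-1.0)


def make_report(sample_id, classes, threshold=10.0):
    estimates = {}
    for key, cls in zip(TMBReport.estimate_keys(), classes):
        tmb = 20.0 if cls == "high" else 1.0
        estimates[key] = TMBEstimate(count=1, denominator_bases=1_000_000,
                                     tmb_per_mb=tmb, classification=cls)
    return TMBReport(sample_id=sample_id, threshold=threshold, estimates=estimates)


class TestCohortSummary:
    def test_consistent_and_discordant_tallies(self):
        reports = [make_report("s1", ["high"] * 8),
                   make_report("s2", ["low"] * 8),
                   make_report("s3", ["high"] + ["low"] * 7)]
        summary = summarize_cohort(reports)
        assert summary.n_consistently_high == 1
        assert summary.n_consistently_low == 1
        assert summary.discordant_by_k == {1: 1}
        assert summary.n_consistent + sum(summary.discordant_by_k.values()) == 3

    def test_single_sample_is_trivially_consistent(self):
        summary = summarize_cohort([make_report("s1", ["low"] * 8)])
        assert summary.n_consistently_low == 1

    def test_mixed_thresholds_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            summarize_cohort([make_report("s1", ["low"] * 8),
                              make_report("s2", ["low"] * 8, threshold=20.0)])

    def test_randomized_cohort_matches_agreement_scan(self):
        rng = random.Random(99)
        reports = [make_report(f"s{i}", [rng.choice(["high", "low"]) for _ in range(8)])
                   for i in range(60)]
        summary = summarize_cohort(reports)
        n_high = n_low = 0
        by_k = {}
        for r in reports:
            vec = [r.estimates[k].classification for k in TMBReport.estimate_keys()]
            k = min(vec.count("high"), vec.count("low"))
            if k == 0:
                if vec[0] == "high":
                    n_high += 1
                else:
                    n_low += 1
            else:
                by_k[k] = by_k.get(k, 0) + 1
        assert (summary.n_consistently_high, summary.n_consistently_low) == (n_high, n_low)
        assert dict(summary.discordant_by_k) == by_k

    def test_selection_restricts_the_estimates_considered(self):
        r = make_report("s1", ["high"] + ["low"] * 7)  # discordant over all 8
        summary = summarize_cohort([r], selection=[("genome", "snv")])
        assert summary.n_consistently_high == 1


class TestRendering:
    def test_identical_reports_render_identically(self):
        a, b = make_report("s1", ["high"] * 8), make_report("s1", ["high"] * 8)
        for fmt in ("tsv", "json"):
            assert render_report(a, fmt) == render_report(b, fmt)

    def test_json_round_trip_preserves_values(self):
        r = make_report("s1", ["high", "low"] * 4)
        data = json.loads(render_report(r, "json"))
        assert data["sample_id"] == "s1"
        assert data["estimates"]["genome_snv"]["classification"] == "high"
        assert data["estimates"]["genome_total"]["classification"] == "low"

    def test_tsv_has_one_row_per_estimate(self):
        lines = render_report(make_report("s1", ["high"] * 8), "tsv").strip().splitlines()
        assert len(lines) == 1 + 8

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            render_report(make_report("s1", ["high"] * 8), "xml")

    def test_cohort_summary_renders_deterministically(self):
        reports = [make_report("s1", ["high"] * 8), make_report("s2", ["low"] * 8)]
        a = render_report(summarize_cohort(reports), "tsv")
        b = render_report(summarize_cohort(reports), "tsv")
        assert a == b and "s1" in a
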