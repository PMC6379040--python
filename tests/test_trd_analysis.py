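"""tr-d roles, HGS detection, event classes, shuffling null, 4d rates."""

import math

import numpy as np
import pytest

from clonnet.trd_analysis import (
    HGS,
    categorize_shared_trd,
    classify_tr_orf,
    classify_trd,
    collect_trd_events,
    detect_hgs,
    events_to_frame,
    fourfold_degenerate_rate,
    identify_trd_roles,
    shuffle_expected_occurrence,
)
from clonnet.simulate import SimConfig, evolve_genomes, synth_sequences_for_trd
from clonnet.onfinder import build_orthnets

from test_orthnet_search import GENOMES, build_net, polygon, trd_net


class TestRoles:
    def test_single_extra_uni_tr_node_is_the_tr_copy(self):
        net = trd_net("N", GENOMES, "Spa", n_tr=1)
        roles = identify_trd_roles(net)
        assert roles["Spa"].cl_copies == ["Spa|nSpa"]
        assert roles["Spa"].tr_copies == ["Spa|tr0"]
        assert roles["Spa"].excluded == []

    def test_tandem_donors_representative_is_longest_orf(self):
        net = trd_net("N", GENOMES, "Spa", n_tr=1)
        g = net.graph
        g.add_node("Spa|don2", genome="Spa", gene="don2", orf_length=1200,
                   scaffold="s", rank=1, truncation="none")
        g.add_edge("Spa|nSpa", "Spa|don2", property="td", reciprocity="und",
                   candidate_rank=0)
        g.nodes["Spa|nSpa"]["orf_length"] = 900
        roles = identify_trd_roles(net)
        assert set(roles["Spa"].cl_copies) == {"Spa|nSpa", "Spa|don2"}
        assert roles["Spa"].representative == "Spa|don2"

    def test_extra_node_with_reciprocal_cl_edge_is_excluded(self):
        net = trd_net("N", GENOMES, "Spa", n_tr=1)
        g = net.graph
        g.add_node("Spa|odd", genome="Spa", gene="odd", orf_length=900,
                   scaffold="s", rank=2, truncation="none")
        g.add_edge("Spa|odd", "Aly|nAly", property="cl", reciprocity="rc",
                   candidate_rank=1)
        g.add_edge("Aly|nAly", "Spa|odd", property="cl", reciprocity="rc",
                   candidate_rank=1)
        roles = identify_trd_roles(net)
        assert "Spa|odd" in roles["Spa"].excluded
        assert roles["Spa"].tr_copies == ["Spa|tr0"]


class TestDetectHgs:
    def test_exact_copy_spans_full_window(self):
        cl, tr, truth = synth_sequences_for_trd(
            gene_length=600, flank=800, identity=1.0, seed=3,
            duplicated_span=(0, 2200),
        )
        hgs = detect_hgs(cl, tr)
        assert hgs, "no HGS found for an exact full-window copy"
        primary = hgs[0]
        assert primary.cl_start == 0 and primary.cl_end == len(cl)
        assert primary.identity > 0.99

    def test_planted_gene_body_recovered_within_seed_length(self):
        cl, tr, truth = synth_sequences_for_trd(
            gene_length=600, flank=800, identity=0.95, seed=4,
        )
        hgs = detect_hgs(cl, tr)
        assert hgs
        primary = hgs[0]
        gs, ge = truth["cl_segment"]
        assert abs(primary.cl_start - gs) <= 16
        assert abs(primary.cl_end - ge) <= 16

    def test_unrelated_sequences_give_no_long_hgs(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, 2000))
        b = "".join(rng.choice(bases, 2000))
        hgs = detect_hgs(a, b)
        assert all(h.length <= 100 for h in hgs)

    def test_low_identity_copy_rejected(self):
        cl, tr, _ = synth_sequences_for_trd(
            gene_length=600, flank=800, identity=0.5, seed=5,
        )
        assert detect_hgs(cl, tr) == []

    def test_reverse_strand_copy_found(self):
        cl, tr, truth = synth_sequences_for_trd(
            gene_length=600, flank=800, identity=1.0, seed=6,
        )
        comp = str.maketrans("ACGT", "TGCA")
        tr_rc = tr.translate(comp)[::-1]
        hgs = detect_hgs(cl, tr_rc)
        assert hgs and hgs[0].strand == "-"
        assert hgs[0].length >= 600 - 16

    def test_symmetry_under_window_swap(self):
        cl, tr, _ = synth_sequences_for_trd(
            gene_length=400, flank=500, identity=0.92, seed=7,
        )
        fwd = detect_hgs(cl, tr)[0]
        rev = detect_hgs(tr, cl)[0]
        assert (rev.cl_start, rev.cl_end) == (fwd.tr_start, fwd.tr_end)
        assert (rev.tr_start, rev.tr_end) == (fwd.cl_start, fwd.cl_end)
        assert rev.length == fwd.tr_end - fwd.tr_start


def _hgs(cl_start, cl_end):
    return HGS(cl_start=cl_start, cl_end=cl_end, tr_start=0,
               tr_end=cl_end - cl_start, strand="+", identity=1.0, score=1.0)


class TestClassifyTrd:
    def test_wide_hgs_is_complete_not_gene_only(self):
        # HGS = gene +/- 2 kb around a 1 kb gene
        assert classify_trd(_hgs(0, 5000), (2000, 3000)) == "complete"

    def test_exact_gene_hgs_is_gene_only(self):
        assert classify_trd(_hgs(2000, 3000), (2000, 3000)) == "gene_only"

    def test_partial_coverage_is_incomplete(self):
        assert classify_trd(_hgs(2000, 2600), (2000, 3000)) == "incomplete"

    def test_gene_only_bound_is_exclusive(self):
        # HGS of exactly 1.2 x coding length is complete, not gene_only
        assert classify_trd(_hgs(1900, 3100), (2000, 3000)) == "complete"
        assert classify_trd(_hgs(1901, 3100), (2000, 3000)) == "gene_only"

    def test_pipeline_on_synthetic_windows(self):
        for span, want in [
            (None, "gene_only"),  # span = exact gene body
            ((700, 1000), "incomplete"),  # half the gene
            ((100, 2100), "complete"),  # gene plus most of both flanks
        ]:
            cl, tr, truth = synth_sequences_for_trd(
                gene_length=600, flank=800, identity=1.0, seed=8,
                duplicated_span=span,
            )
            primary = detect_hgs(cl, tr)[0]
            got = classify_trd(primary, truth["gene"])
            assert got == want, f"span={span}"


class TestClassifyTrOrf:
    @pytest.mark.parametrize(
        "ratio,want",
        [(1.0, "complete"), (0.79, "truncated"), (0.8, "complete"),
         (1.2, "complete"), (1.21, "truncated")],
    )
    def test_inclusive_20pc_bounds(self, ratio, want):
        assert classify_tr_orf(int(ratio * 1000), 1000) == want


class TestShuffleNull:
    def test_fixed_seed_reproducible(self):
        kwargs = dict(
            hgs_lengths=[200, 400, 800],
            cl_genes=[(300, 1500), (500, 2000)],
            n_iter=200,
            seed=42,
        )
        a = shuffle_expected_occurrence(**kwargs)
        b = shuffle_expected_occurrence(**kwargs)
        assert a["complete"].expected_mean == b["complete"].expected_mean
        assert a["gene_only"].expected_sd == b["gene_only"].expected_sd

    def test_impossible_event_gives_p_near_zero(self):
        # every HGS shorter than the gene: a complete placement cannot occur
        res = shuffle_expected_occurrence(
            hgs_lengths=[100, 150],
            cl_genes=[(300, 1500)],
            n_iter=500,
            seed=1,
            observed={"complete": 3, "gene_only": 3},
        )
        assert res["complete"].expected_mean == 0.0
        assert res["complete"].p_value == pytest.approx(0.0, abs=1e-12)

    def test_mean_matches_exact_enumeration(self):
        # one gene of 100 bp centred in a 300 bp window, all HGS length 100:
        # valid starts 60..140 (81 of them), complete only at start 100.
        res = shuffle_expected_occurrence(
            hgs_lengths=[100],
            cl_genes=[(100, 300)],
            n_iter=4000,
            min_overlap=60,
            seed=11,
        )
        p_exact = 1.0 / 81.0
        se = math.sqrt(p_exact * (1 - p_exact) / 4000)
        assert res["complete"].expected_mean == pytest.approx(p_exact, abs=3 * se)
        # length 100 < 1.2 x 100, so every complete placement is gene-only
        assert res["gene_only"].expected_mean == res["complete"].expected_mean

    def test_two_length_mixture_enumeration(self):
        # lengths 100 and 260 over the same gene; exact P(complete) is the
        # average of the two per-length enumerations
        def p_complete(L, gene=100, window=300, ov=60):
            gs, ge = (window - gene) // 2, (window + gene) // 2
            starts = [
                s for s in range(0, window - L + 1)
                if min(s + L, ge) - max(s, gs) >= ov
            ]
            hits = [s for s in starts if s <= gs and s + L >= ge]
            return len(hits) / len(starts)

        res = shuffle_expected_occurrence(
            hgs_lengths=[100, 260],
            cl_genes=[(100, 300)],
            n_iter=4000,
            seed=13,
        )
        p_exact = 0.5 * (p_complete(100) + p_complete(260))
        se = math.sqrt(p_exact * (1 - p_exact) / 4000)
        assert res["complete"].expected_mean == pytest.approx(p_exact, abs=3 * se)

    def test_p_value_in_unit_interval(self):
        res = shuffle_expected_occurrence(
            hgs_lengths=[100, 200, 300],
            cl_genes=[(150, 1000)] * 5,
            n_iter=300,
            seed=3,
            observed={"complete": 1, "gene_only": 0},
        )
        for r in res.values():
            assert 0.0 <= r.p_value <= 1.0

    def test_too_short_gene_rejected(self):
        with pytest.raises(ValueError, match="min_overlap"):
            shuffle_expected_occurrence([100], [(40, 300)], n_iter=10, seed=0)


class TestFourDRate:
    def test_identical_orfs_rate_zero(self):
        orf = "ATGGGTCCTGCAACC" * 4 + "TAA"
        res = fourfold_degenerate_rate(orf, orf)
        assert res.raw_p == 0.0 and res.jc_rate == 0.0

    def test_one_difference_over_ten_sites_closed_form(self):
        # ten 4d sites (GGx glycine codons), one third-position difference
        cl = "ATG" + "GGT" * 10 + "TAA"
        tr = "ATG" + "GGT" * 9 + "GGC" + "TAA"
        res = fourfold_degenerate_rate(cl, tr)
        assert res.n_4d_sites == 10 and res.n_diff == 1
        assert res.raw_p == pytest.approx(0.1)
        assert res.jc_rate == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3), abs=1e-12)
        assert res.jc_rate == pytest.approx(0.1073, abs=1e-4)

    def test_all_third_positions_differ_is_saturated(self):
        cl = "ATG" + "GGT" * 10 + "TAA"
        tr = "ATG" + "GGA" * 10 + "TAA"
        res = fourfold_degenerate_rate(cl, tr)
        assert res.saturated and math.isnan(res.jc_rate)

    def test_few_sites_flagged_low_confidence(self):
        cl = "ATG" + "GGT" * 3 + "TAA"
        res = fourfold_degenerate_rate(cl, cl)
        assert res.low_confidence

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            fourfold_degenerate_rate("ATGTAAGGT", "ATGTAAGGT")

    def test_non_codon_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            fourfold_degenerate_rate("ATGG", "ATGG")

    def test_zero_rate_iff_no_third_position_difference(self):
        cl = "ATG" + "GCT" * 5 + "GCA" * 5 + "TAA"
        tr = "ATG" + "GCT" * 5 + "GCG" * 5 + "TAA"
        res = fourfold_degenerate_rate(cl, tr)
        assert (res.raw_p == 0.0) == (res.n_diff == 0)
        assert res.n_diff == 5


class TestSharedTrd:
    def test_cl_linked_tr_copies_are_tr_cl(self):
        net = trd_net("N", GENOMES, "Spa", n_tr=1)
        g = net.graph
        g.add_node("Esa|tr0", genome="Esa", gene="tr0", orf_length=500,
                   scaffold="s", rank=0, truncation="none")
        for gg in GENOMES:
            if gg not in ("Esa", "Spa"):
                g.add_edge("Esa|tr0", f"{gg}|n{gg}", property="tr",
                           reciprocity="uni", candidate_rank=1)
        g.add_edge("Esa|tr0", "Spa|tr0", property="cl", reciprocity="rc",
                   candidate_rank=1)
        g.add_edge("Spa|tr0", "Esa|tr0", property="cl", reciprocity="rc",
                   candidate_rank=1)
        got = categorize_shared_trd([net], ("Esa", "Spa"))
        assert got == {"N": "tr_cl"}

    def test_unlinked_tr_copies_are_ind_parallel(self):
        net = trd_net("N", GENOMES, "Spa", n_tr=1)
        g = net.graph
        g.add_node("Esa|tr0", genome="Esa", gene="tr0", orf_length=500,
                   scaffold="s", rank=0, truncation="none")
        for gg in GENOMES:
            if gg != "Esa":
                g.add_edge("Esa|tr0", f"{gg}|n{gg}", property="tr",
                           reciprocity="uni", candidate_rank=1)
        got = categorize_shared_trd([net], ("Esa", "Spa"))
        assert got == {"N": "ind_parallel"}

    def test_planted_pre_divergence_duplication_recovered_as_tr_cl(self):
        # a trd planted on an internal branch leaves co-linear Tr copies in
        # both daughter genomes
        cfg = SimConfig(n_loci=600, p_td=0.0, p_tr=0.0, p_trd=0.02,
                        p_del=0.0, seed=21)
        genomes, besthits, clusters, truth = evolve_genomes(cfg, "((A,B),C);")
        shared = [
            e for e in truth.events
            if e.event_type == "trd" and e.genomes == frozenset({"A", "B"})
        ]
        assert shared, "no trd planted on the internal branch with this seed"
        orthnets, _, _ = build_orthnets(genomes, besthits, clusters)
        net_of = {}
        for net in orthnets:
            for n in net.graph.nodes:
                net_of[n] = net
        got = categorize_shared_trd(orthnets, ("A", "B"))
        confirmed = 0
        for e in shared:
            nodes = truth.orthnet_nodes[e.ancestral_locus]
            net = net_of[next(iter(nodes))]
            if len([x for x in truth.events
                    if x.ancestral_locus == e.ancestral_locus]) > 1:
                continue  # collisions can change the expected category
            assert got.get(net.orthnet_id) == "tr_cl", net.orthnet_id
            confirmed += 1
        assert confirmed >= 1


class TestEventTable:
    def test_one_row_per_tr_copy_with_expression_join(self):
        net = trd_net("N", GENOMES, "Spa", n_tr=2)
        net.graph.nodes["Spa|tr0"]["orf_length"] = 880  # near the CL copy's 900
        events = collect_trd_events([net])
        assert len(events) == 2
        assert all(e.sharing == "lineage_specific" for e in events)
        by_copy = {e.tr_copy: e for e in events}
        assert by_copy["Spa|tr0"].tr_orf_status == "complete"
        assert by_copy["Spa|tr1"].tr_orf_status == "truncated"  # 500 vs 900
        frame = events_to_frame(events, expression={"tr0": True})
        assert list(frame["expressed"]) == [True, False]
        assert set(frame.columns) >= {
            "orthnet_id", "genome_id", "cl_copy", "tr_copy", "sharing",
        }

    def test_shared_event_categories_in_table(self):
        net = trd_net("N", GENOMES, "Spa", n_tr=1)
        g = net.graph
        g.add_node("Esa|tr0", genome="Esa", gene="tr0", orf_length=500,
                   scaffold="s", rank=0, truncation="none")
        for gg in GENOMES:
            if gg != "Esa":
                g.add_edge("Esa|tr0", f"{gg}|n{gg}", property="tr",
                           reciprocity="uni", candidate_rank=1)
        events = collect_trd_events([net])
        assert {e.sharing for e in events} == {"ind_parallel"}
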