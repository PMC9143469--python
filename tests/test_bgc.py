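import pytest

from cypminer.bgc import (
    BgcCluster,
    ClusterSignature,
    aggregate_by_type,
    aggregates_from_fixture,
    assign_p450s_to_clusters,
    bgc_family_breakdown,
    breakdown_from_aggregates,
    label_family,
    max_p450s_from_aggregates,
    max_p450s_per_cluster,
)
from cypminer.identification import MotifEvidence, P450Call
from cypminer.sequence_io import ProteinRecord


def _gene(pid, start, end, genome="g1", contig="c1"):
    return ProteinRecord(pid, genome, contig, start, end, "+", "M" * 10)


def _call(pid, family="CYP105", subfamily="AB", status="P450", genome="g1"):
    call = P450Call(pid, genome, status, MotifEvidence(True, 0, True, 5, 420))
    call.family, call.subfamily = family, subfamily
    return call


def _cluster(cid, start, end, bgc_type="NRPS", genome="g1", contig="c1"):
    return BgcCluster(genome, contig, cid, bgc_type, start, end)


class TestContainment:
    def test_contained_gene_is_member(self):
        sigs, residual = assign_p450s_to_clusters(
            [_gene("p1", 100, 1300)], [_call("p1")], [_cluster("b1", 50, 20000)]
        )
        assert sigs[0].member_ids == ["p1"] and residual == []

    def test_boundary_spanning_gene_is_not_member(self):
        sigs, residual = assign_p450s_to_clusters(
            [_gene("p1", 19900, 21100)], [_call("p1")], [_cluster("b1", 50, 20000)]
        )
        assert sigs[0].member_ids == [] and residual == ["p1"]

    def test_overlap_mode_admits_spanning_gene(self):
        sigs, _ = assign_p450s_to_clusters(
            [_gene("p1", 19900, 21100)],
            [_call("p1")],
            [_cluster("b1", 50, 20000)],
            mode="overlap",
        )
        assert sigs[0].member_ids == ["p1"]

    def test_members_ordered_by_start(self):
        genes = [_gene("p2", 5000, 6000), _gene("p1", 1000, 2000)]
        calls = [_call("p2", subfamily="G"), _call("p1", subfamily="AB")]
        sigs, _ = assign_p450s_to_clusters(genes, calls, [_cluster("b1", 1, 10000)])
        assert sigs[0].signature == "CYP105AB,CYP105G"

    def test_overlapping_clusters_assign_to_both_with_warning(self):
        clusters = [_cluster("b1", 1, 5000), _cluster("b2", 500, 6000)]
        with pytest.warns(UserWarning, match="multiple overlapping clusters"):
            sigs, _ = assign_p450s_to_clusters(
                [_gene("p1", 1000, 2000)], [_call("p1")], clusters
            )
        assert sigs[0].member_ids == ["p1"] and sigs[1].member_ids == ["p1"]

    def test_fragments_excluded_unless_requested(self):
        genes = [_gene("p1", 100, 200), _gene("f1", 300, 400)]
        calls = [_call("p1"), _call("f1", status="fragment")]
        clusters = [_cluster("b1", 1, 1000)]
        sigs, _ = assign_p450s_to_clusters(genes, calls, clusters)
        assert sigs[0].member_ids == ["p1"]
        sigs, _ = assign_p450s_to_clusters(genes, calls, clusters, include_fragments=True)
        assert sigs[0].member_ids == ["p1", "f1"]

    def test_membership_invariant_under_coordinate_mirroring(self):
        genes = [_gene("p1", 100, 1300), _gene("p2", 1500, 2600), _gene("p3", 9000, 9900)]
        calls = [_call(p) for p in ("p1", "p2", "p3")]
        clusters = [_cluster("b1", 50, 3000)]
        fwd, _ = assign_p450s_to_clusters(genes, calls, clusters)
        m = 100_000  # mirror: pos -> m - pos + 1, strand-agnostic containment
        mirrored_genes = [
            _gene(g.id, m - g.end + 1, m - g.start + 1) for g in genes
        ]
        mirrored_clusters = [
            _cluster(c.cluster_id, m - c.end + 1, m - c.start + 1) for c in clusters
        ]
        rev, _ = assign_p450s_to_clusters(mirrored_genes, calls, mirrored_clusters)
        assert set(fwd[0].member_ids) == set(rev[0].member_ids)
        assert rev[0].member_ids == list(reversed(fwd[0].member_ids))


class TestAggregation:
    def test_variety_grouping(self):
        sigs = [
            ClusterSignature("b1", "Indole", ["CYP244A", "CYP245A"]),
            ClusterSignature("b2", "Indole", ["CYP244A", "CYP245A"]),
            ClusterSignature("b3", "Indole", ["CYP244A"]),
            ClusterSignature("b4", "T1PKS", []),
        ]
        aggs = aggregate_by_type(sigs)
        assert len(aggs) == 1  # empty clusters excluded
        agg = aggs[0]
        assert agg.varieties == {"CYP244A,CYP245A": 2, "CYP244A": 1}
        assert agg.n_clusters == 3 and agg.n_p450_total == 5

    def test_indole_fixture_reproduces_published_total(self, fixtures):
        aggs = aggregates_from_fixture(fixtures.table4)
        indole = next(a for a in aggs if a.bgc_type == "Indole")
        assert indole.n_p450_total == 105
        assert indole.varieties["CYP244A,CYP245A"] == 51

    def test_t1pks_fixture_cluster_count(self, fixtures):
        aggs = aggregates_from_fixture(fixtures.table4)
        t1pks = next(a for a in aggs if a.bgc_type == "T1PKS")
        assert t1pks.n_clusters == 223

    def test_empty_signature_list(self):
        assert aggregate_by_type([]) == []


class TestMaxAndBreakdown:
    def test_fixture_maximum_is_six(self, fixtures):
        assert max_p450s_from_aggregates(aggregates_from_fixture(fixtures.table4)) == 6

    def test_singleton_clusters(self):
        sigs = [ClusterSignature(f"b{i}", "NRPS", ["CYP105AB"]) for i in range(3)]
        assert max_p450s_per_cluster(sigs) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_p450s_per_cluster([])

    def test_breakdown_counts_and_percentages(self):
        sigs = [
            ClusterSignature("b1", "NRPS", ["CYP107AW", "CYP107AW", "CYP107AW", "CYP105G"])
        ]
        bd = bgc_family_breakdown(sigs)
        assert bd["CYP107"] == (3, 75.0) and bd["CYP105"] == (1, 25.0)

    def test_label_grammar_tolerates_fixture_dialects(self):
        assert label_family("CYP105W2/3") == "CYP105"
        assert label_family("CYP107AX-fragment") == "CYP107"
        assert label_family("CYP113 × 1") == "CYP113"
        with pytest.raises(ValueError, match="grammar"):
            label_family("P450-x")

    def test_fixture_breakdown_totals(self, fixtures):
        bd = breakdown_from_aggregates(aggregates_from_fixture(fixtures.table4))
        assert sum(n for n, _ in bd.values()) == 1236
        assert len(bd) == 35  # distinct families among cluster members

    def test_synthetic_breakdown_matches_planted_mix(self, default_sim, default_results):
        truth = default_sim["truth"]
        planted: dict[str, int] = {}
        for cid, t in truth["clusters"].items():
            for pid in t["members"]:
                prot = truth["proteins"][pid]
                fam = prot["source_family"]
                if prot["expected_basis"] == "new-family":
                    continue
                planted[fam] = planted.get(fam, 0) + 1
        bd = bgc_family_breakdown(default_results["signatures"])
        for fam, n in planted.items():
            assert bd[fam][0] == n
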