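"""Mating statistics, intersterility-group delimitation, gene flow."""

import math
import random

import networkx as nx
import numpy as np
import pytest

from gcpsr.datasets import gene_flow_fixture, gene_flow_percentages
from gcpsr.errors import MatingDataError
from gcpsr.mating import (
    MatingMatrix,
    PairingRecord,
    assign_unknown,
    delimit_isgs,
    gene_flow_report,
    summarize_pair,
)
from gcpsr.simulate import simulate_mating


def matrix_from_outcomes(outcomes, a="g1_t1", b="g2_t1",
                         groups=("g1", "g2")):
    records = [PairingRecord(a, b, o, r + 1) for r, o in enumerate(outcomes)]
    return MatingMatrix(records, groups={a: groups[0], b: groups[1]})


class TestSummarizePair:
    def test_all_interfertile(self):
        m = matrix_from_outcomes(["CRUSTOSE_DIPLOID"] * 10)
        s = summarize_pair(m, "g1", "g2")
        assert (s.if_pct, s.is_pct, s.n) == (100.0, 0.0, 10)

    def test_all_intersterile(self):
        m = matrix_from_outcomes(["BLACK_LINE"] * 8 + ["WHITE_FLUFFY"] * 2)
        s = summarize_pair(m, "g1", "g2")
        assert (s.if_pct, s.is_pct, s.n) == (0.0, 100.0, 10)

    def test_unscored_counts_in_denominator(self):
        m = matrix_from_outcomes(
            ["CRUSTOSE_DIPLOID"] * 5 + ["BLACK_LINE"] * 3
            + ["WHITE_FLUFFY"] + ["UNSCORED"])
        s = summarize_pair(m, "g1", "g2")
        assert (s.if_pct, s.is_pct, s.n) == (50.0, 40.0, 10)
        assert s.if_pct + s.is_pct < 100.0  # unscored remainder

    def test_if_plus_is_is_100_without_unscored(self):
        rng = random.Random(3)
        outcomes = [rng.choice(["CRUSTOSE_DIPLOID", "BLACK_LINE",
                                "WHITE_FLUFFY"]) for _ in range(50)]
        s = summarize_pair(matrix_from_outcomes(outcomes), "g1", "g2")
        assert s.if_pct + s.is_pct == pytest.approx(100.0)

    def test_unknown_group_rejected(self):
        m = matrix_from_outcomes(["CRUSTOSE_DIPLOID"])
        with pytest.raises(MatingDataError, match="unknown group"):
            summarize_pair(m, "g1", "nope")

    def test_empty_pair_flagged_undefined(self):
        m = matrix_from_outcomes(["CRUSTOSE_DIPLOID"])
        records = m.records
        m2 = MatingMatrix(records, groups={"g1_t1": "g1", "g2_t1": "g2",
                                           "x": "g3"})
        s = summarize_pair(m2, "g1", "g3")
        assert s.undefined and s.n == 0

    def test_outcome_token_validated(self):
        with pytest.raises(MatingDataError, match="unknown outcome"):
            PairingRecord("a", "b", "FUSED")

    def test_self_pairing_rejected(self):
        with pytest.raises(MatingDataError):
            PairingRecord("a", "a", "CRUSTOSE_DIPLOID")


class TestDelimit:
    def two_cliques(self):
        records = []
        groups = {}
        for g, members in (("P", ["p1", "p2", "p3"]),
                           ("Q", ["q1", "q2", "q3"])):
            for iso in members:
                groups[iso] = g
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    records.append(PairingRecord(a, b, "CRUSTOSE_DIPLOID"))
        for a in ["p1", "p2", "p3"]:
            for b in ["q1", "q2", "q3"]:
                records.append(PairingRecord(a, b, "BLACK_LINE"))
        return MatingMatrix(records, groups=groups)

    def test_two_cliques_two_groups(self):
        part = delimit_isgs(self.two_cliques())
        assert part.n_groups() == 2
        groups = set(part.groups().values())
        assert frozenset({"p1", "p2", "p3"}) in groups

    def test_planted_sixteen_groups_recovered(self):
        m, truth = simulate_mating(n_groups=16, testers_per_group=5,
                                   pairings_per_pair=40, seed=42)
        part = delimit_isgs(m)
        assert part.n_groups() == 16
        assert set(part.groups().values()) == {
            frozenset(v) for v in truth.true_partition.values()}

    def test_record_order_and_relabeling_invariance(self):
        m = self.two_cliques()
        shuffled = m.records.sample(frac=1.0, random_state=5)
        m2 = MatingMatrix(shuffled, groups=m.groups)
        assert delimit_isgs(m).groups() == delimit_isgs(m2).groups()
        # swap a/b columns
        flipped = m.records.rename(columns={"isolate_a": "isolate_b",
                                            "isolate_b": "isolate_a"})
        m3 = MatingMatrix(flipped, groups=m.groups)
        assert delimit_isgs(m).groups() == delimit_isgs(m3).groups()

    def test_agrees_with_component_oracle(self):
        rng = np.random.default_rng(9)
        isolates = [f"i{k}" for k in range(20)]
        records = []
        for i, a in enumerate(isolates):
            for b in isolates[i + 1:]:
                if rng.random() < 0.15:
                    fert = rng.random() < 0.5
                    records.append(PairingRecord(
                        a, b, "CRUSTOSE_DIPLOID" if fert else "BLACK_LINE"))
        m = MatingMatrix(records)
        part = delimit_isgs(m)
        g = nx.Graph()
        scored = {r.isolate_a for r in records} | {
            r.isolate_b for r in records}
        g.add_nodes_from(scored)
        for r in records:
            if r.outcome == "CRUSTOSE_DIPLOID":
                g.add_edge(r.isolate_a, r.isolate_b)
        oracle = {frozenset(c) for c in nx.connected_components(g)}
        assert set(part.groups().values()) == oracle

    def test_raising_threshold_never_merges(self):
        m, _ = simulate_mating(n_groups=6, testers_per_group=4,
                               pairings_per_pair=10, p_between=0.3, seed=2)
        lo = delimit_isgs(m, edge_threshold=0.3).n_groups()
        hi = delimit_isgs(m, edge_threshold=0.8).n_groups()
        assert hi >= lo

    def test_no_scored_records_rejected(self):
        m = matrix_from_outcomes(["UNSCORED"] * 3)
        with pytest.raises(MatingDataError, match="scored"):
            delimit_isgs(m)


class TestGeneFlow:
    def test_published_flow_pairs_in_order(self):
        m = gene_flow_fixture()
        part = delimit_isgs(m)
        report = gene_flow_report(m, part, report_min_pct=10)
        got = [(s.group_a, s.group_b, round(s.if_pct, 1)) for s in report]
        expected = [(a, b, p) if a < b else (b, a, p)
                    for a, b, p in gene_flow_percentages()]
        assert got == expected
        assert [s.if_pct for s in report] == sorted(
            (s.if_pct for s in report), reverse=True)

    def test_groups_stay_separate_despite_flow(self):
        m = gene_flow_fixture()
        assert delimit_isgs(m).n_groups() == 4

    def test_isolated_groups_empty_report(self):
        records = [PairingRecord("a1", "a2", "CRUSTOSE_DIPLOID"),
                   PairingRecord("a1", "b1", "BLACK_LINE"),
                   PairingRecord("b1", "b2", "CRUSTOSE_DIPLOID")]
        m = MatingMatrix(records, groups={"a1": "A", "a2": "A",
                                          "b1": "B", "b2": "B"})
        assert gene_flow_report(m, delimit_isgs(m)) == []

    def test_high_threshold_empties_report(self):
        m = gene_flow_fixture()
        assert gene_flow_report(m, delimit_isgs(m), report_min_pct=50) == []


class TestAssignUnknown:
    def panel_matrix(self, rates, n=48, partial_is=None):
        """Unknown isolate u0 vs three panels with given IF rates."""
        records = []
        panels = {}
        for gi, rate in enumerate(rates):
            g = f"G{gi}"
            testers = [f"{g}_t1", f"{g}_t2"]
            panels[g] = testers
            k = round(rate * n / 100)
            for t in testers:
                for r in range(n):
                    outcome = ("CRUSTOSE_DIPLOID" if r < k
                               else "BLACK_LINE")
                    records.append(PairingRecord("u0", t, outcome, r + 1))
        return MatingMatrix(records), panels

    def test_clean_assignment_unambiguous(self):
        m, panels = self.panel_matrix([100, 0, 0])
        res = assign_unknown(m, ["u0"], panels)
        assert res.best_group == "G0" and not res.ambiguous

    def test_divergent_lineage_flagged(self):
        # closest panel only 65% interfertile, with substantial residual
        # intersterility: tentative assignment
        m, panels = self.panel_matrix([65.3, 20, 5])
        res = assign_unknown(m, ["u0"], panels)
        assert res.best_group == "G0"
        assert res.ambiguous
        assert res.partial_intersterility_pct > 25

    def test_close_top_two_flagged(self):
        m, panels = self.panel_matrix([55, 52])
        res = assign_unknown(m, ["u0"], panels)
        assert res.best_group == "G0" and res.ambiguous

    def test_no_scored_pairings_rejected(self):
        m, panels = self.panel_matrix([100])
        with pytest.raises(MatingDataError):
            assign_unknown(m, ["zz"], panels)


class TestSimulatedCalibration:
    def test_override_reproduces_target_rate(self):
        m, _ = simulate_mating(
            n_groups=4, testers_per_group=5, pairings_per_pair=40,
            gene_flow_overrides=[("BS01", "BS02", 0.411)], seed=8)
        s = summarize_pair(m, "BS01", "BS02")
        # binomial error at n = 25 pairs x 40 reps = 1000 pairings
        assert s.n == 1000
        assert abs(s.if_pct - 41.1) < 5.0

    def test_perfect_blocks_recover_planted_groups(self):
        m, truth = simulate_mating(n_groups=5, testers_per_group=3,
                                   pairings_per_pair=4, p_within=1.0,
                                   p_between=0.0, seed=1)
        part = delimit_isgs(m)
        assert set(part.groups().values()) == {
            frozenset(v) for v in truth.true_partition.values()}
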