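"""Grouping logic: consensus, conflict, presence fractions, IEL calls."""

from fractions import Fraction

import pytest

from gcpsr.concordance import (
    GroupingConfig,
    LocusGenealogySet,
    calls_from_support_cells,
    clade_presence_fraction,
    conflicts,
    iel_resolution_table,
    is_nondiscordant,
    is_well_supported,
    majority_rule_consensus,
    recognize_iels,
)
from gcpsr.datasets import LOCI, SPECIES, iel_support_cells
from gcpsr.errors import TaxonSetError
from gcpsr.phylo_io import Bipartition, SupportRecord, SupportTree, \
    read_support_tree

from conftest import conflicts_oracle


def genealogy_from_clades(locus_clades, universe, loci=None):
    """Build a LocusGenealogySet where each locus's MP and Bayesian trees
    display the given clades with (mpbp, bpp) supports."""
    loci = loci or sorted(locus_clades)
    mp, bayes = {}, {}
    for locus in loci:
        clades = locus_clades[locus]
        mp[locus] = SupportTree.from_clades(
            {c: SupportRecord(mpbp=s[0]) for c, s in clades.items()},
            universe, locus=locus, analysis_tag="MP_CONSENSUS")
        bayes[locus] = SupportTree.from_clades(
            {c: SupportRecord(bpp=s[1]) for c, s in clades.items()},
            universe, locus=locus, analysis_tag="BAYES_CONSENSUS")
    return LocusGenealogySet(loci=tuple(loci), mp_trees=mp, bayes_trees=bayes)


class TestConflicts:
    U = frozenset("ABCDE")

    def bip(self, side, universe=None):
        return Bipartition(frozenset(side), universe or self.U)

    def test_nested_clades_compatible(self):
        assert not conflicts(self.bip("AB"), self.bip("ABC"))

    def test_disjoint_clades_compatible(self):
        assert not conflicts(self.bip("AB"), self.bip("CD"))

    def test_overlapping_clades_conflict(self):
        u = frozenset("ABCD")
        assert conflicts(self.bip("AB", u), self.bip("BC", u))

    def test_symmetric_and_irreflexive(self, quartet_conflicts):
        bips, verdicts = quartet_conflicts
        for a in bips:
            assert not conflicts(a, a)
        for (a, b), expected in verdicts.items():
            assert conflicts(a, b) == conflicts(b, a)

    @pytest.mark.parametrize("taxa", ["ABCD", "ABCDE"])
    def test_agrees_with_enumeration_oracle(self, taxa):
        bips, verdicts = conflicts_oracle(taxa)
        for (a, b), expected in verdicts.items():
            if a == b:
                continue
            assert conflicts(a, b) == expected, (a, b)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(TaxonSetError):
            conflicts(self.bip("AB"), self.bip("AB", frozenset("ABCDEF")))


class TestConsensus:
    def tree(self, newick):
        return read_support_tree(newick, dialect="mpbp")

    def test_identical_trees_full_frequency(self):
        trees = [self.tree("((A,B),(C,D),E);")] * 3
        cons = majority_rule_consensus(trees)
        sup = cons.bipartition_supports()
        assert len(sup) == 2
        assert all(rec.mpbp == 100 for rec in sup.values())
        assert sup.keys() == trees[0].bipartition_supports().keys()

    def test_no_shared_splits_gives_star(self):
        trees = [self.tree("((A,B),(C,D),E);"),
                 self.tree("((A,C),(B,E),D);")]
        cons = majority_rule_consensus(trees, 0.5)
        assert cons.bipartition_supports() == {}

    def test_three_quarters_retained_half_dropped(self):
        # clade AB in 3/4 trees, clade DE in 2/4: strict > 0.5 keeps only AB
        trees = [self.tree("((A,B),C,(D,E));"),
                 self.tree("((A,B),C,D,E);"),
                 self.tree("((A,B),(C,D),E);"),
                 self.tree("(A,B,C,(D,E));")]
        cons = majority_rule_consensus(trees, 0.5)
        sup = {tuple(sorted(min(k, key=len))): rec.mpbp
               for k, rec in cons.bipartition_supports().items()}
        assert sup == {("A", "B"): 75.0}

    def test_output_is_mutually_compatible(self):
        trees = [self.tree("((A,B),(C,(D,E)));"),
                 self.tree("(((A,B),C),(D,E));"),
                 self.tree("((A,(B,C)),(D,E));")]
        cons = majority_rule_consensus(trees, 0.5)
        bips = [Bipartition(min(k, key=lambda s: (len(s), sorted(s))),
                            cons.taxa)
                for k in cons.bipartition_supports()]
        for i, a in enumerate(bips):
            for b in bips[i + 1:]:
                assert not conflicts(a, b)

    def test_taxon_mismatch_reported(self):
        with pytest.raises(TaxonSetError) as err:
            majority_rule_consensus(
                [self.tree("((A,B),(C,D));"), self.tree("((A,B),(C,E));")])
        assert err.value.symmetric_difference == {"D", "E"}

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            majority_rule_consensus([self.tree("(A,B,C,D);")], 0.3)


def six_locus_fixture():
    """Six loci over 3 species x 3 individuals; clade SP1 present in 5 of 6
    loci, clade SP2 in all, clade SP3 never."""
    sp = {f"SP{k}": frozenset(f"SP{k}_{i}" for i in "abc") for k in "123"}
    universe = frozenset().union(*sp.values())
    locus_clades = {}
    for j in range(6):
        clades = {sp["SP2"]: (90, 99)}
        if j != 0:
            clades[sp["SP1"]] = (96, 100)
        locus_clades[f"L{j}"] = clades
    gen = genealogy_from_clades(locus_clades, universe,
                                loci=[f"L{j}" for j in range(6)])
    return gen, sp, universe


class TestPresenceFraction:
    def test_present_everywhere(self):
        gen, sp, u = six_locus_fixture()
        assert clade_presence_fraction(Bipartition(sp["SP2"], u), gen) == 1.0

    def test_five_of_six_passes_three_quarters(self):
        gen, sp, u = six_locus_fixture()
        frac = clade_presence_fraction(Bipartition(sp["SP1"], u), gen)
        assert frac == pytest.approx(5 / 6)
        assert frac >= float(Fraction(3, 4))

    def test_degenerate_restriction_counts_absent(self):
        gen, sp, u = six_locus_fixture()
        # a clade with a single member restricted into every locus
        one = Bipartition(frozenset({"SP1_a", "ZZZ"}),
                          u | {"ZZZ"})
        restricted = one.restrict(u)
        assert clade_presence_fraction(
            Bipartition(restricted.clade_side, u), gen) == 0.0

    def test_excluded_locus_shrinks_denominator(self):
        gen, sp, u = six_locus_fixture()
        cfg = GroupingConfig(exclude_loci=("L0",))
        assert clade_presence_fraction(
            Bipartition(sp["SP1"], u), gen, cfg) == 1.0


class TestWellSupported:
    def test_passing_supports(self):
        gen, sp, u = six_locus_fixture()
        assert is_well_supported(Bipartition(sp["SP1"], u), "L1", gen)

    def test_tie_at_threshold_passes(self):
        sp = {"X": frozenset({"x1", "x2"}), "Y": frozenset({"y1", "y2"})}
        u = sp["X"] | sp["Y"]
        gen = genealogy_from_clades({"L0": {sp["X"]: (70, 95)}}, u)
        assert is_well_supported(Bipartition(sp["X"], u), "L0", gen)

    def test_just_below_threshold_fails(self):
        sp = {"X": frozenset({"x1", "x2"}), "Y": frozenset({"y1", "y2"})}
        u = sp["X"] | sp["Y"]
        gen = genealogy_from_clades({"L0": {sp["X"]: (69, 100)}}, u)
        assert not is_well_supported(Bipartition(sp["X"], u), "L0", gen)

    def test_absent_from_mp_tree_fails_despite_bpp(self):
        sp = frozenset({"x1", "x2"})
        u = sp | {"y1", "y2"}
        mp = SupportTree.from_clades({}, u, analysis_tag="MP_CONSENSUS")
        bayes = SupportTree.from_clades(
            {sp: SupportRecord(bpp=100)}, u, analysis_tag="BAYES_CONSENSUS")
        gen = LocusGenealogySet(("L0",), {"L0": mp}, {"L0": bayes})
        assert not is_well_supported(Bipartition(sp, u), "L0", gen)


class TestNondiscordance:
    def fixture(self, conflict_supports):
        a = frozenset({"s1", "s2", "s3"})
        u = a | {"t1", "t2", "t3"}
        crossing = frozenset({"s1", "s2", "t1"})  # conflicts with a
        gen = genealogy_from_clades(
            {"L0": {a: (90, 99)},
             "L1": {crossing: conflict_supports}}, u)
        return Bipartition(a, u), gen

    def test_supported_and_uncontradicted(self):
        clade, gen = self.fixture((40, 80))  # conflict not well supported
        assert is_nondiscordant(clade, gen)

    def test_well_supported_conflict_blocks(self):
        clade, gen = self.fixture((95, 100))
        assert not is_nondiscordant(clade, gen)

    def test_never_well_supported_fails(self):
        a = frozenset({"s1", "s2"})
        u = a | {"t1", "t2"}
        gen = genealogy_from_clades({"L0": {a: (69, 100)}}, u)
        assert not is_nondiscordant(Bipartition(a, u), gen)


class TestRecognizeIels:
    def test_modified_mode_emits_per_locus_calls(self):
        gen, sp, u = six_locus_fixture()
        calls = recognize_iels(gen, [Bipartition(sp["SP1"], u)])
        assert {c.locus for c in calls} == {f"L{j}" for j in range(1, 6)}
        assert all(c.is_iel for c in calls)

    def test_never_supported_clade_yields_no_iel(self):
        gen, sp, u = six_locus_fixture()
        calls = recognize_iels(gen, [Bipartition(sp["SP3"], u)])
        assert not any(c.is_iel for c in calls)

    def test_perfect_concordance_all_loci(self):
        sp = {f"S{k}": frozenset({f"S{k}_1", f"S{k}_2"}) for k in "1234"}
        u = frozenset().union(*sp.values())
        clades = {c: (100, 100) for c in sp.values()}
        gen = genealogy_from_clades(
            {f"L{j}": clades for j in range(6)}, u)
        calls = recognize_iels(gen, [Bipartition(c, u) for c in sp.values()])
        assert sum(c.is_iel for c in calls) == 4 * 6

    def test_threshold_monotonicity(self):
        gen, sp, u = six_locus_fixture()
        cands = [Bipartition(sp["SP1"], u), Bipartition(sp["SP2"], u)]
        base = {(c.species, c.locus) for c in recognize_iels(
            gen, cands, GroupingConfig()) if c.is_iel}
        stricter = {(c.species, c.locus) for c in recognize_iels(
            gen, cands, GroupingConfig(mpbp_min=95, bpp_min=99.5))
            if c.is_iel}
        assert stricter <= base

    def test_concordance_mode_majority_rule(self):
        gen, sp, u = six_locus_fixture()
        cfg = GroupingConfig(mode="CONCORDANCE")
        calls = recognize_iels(
            gen, [Bipartition(sp["SP1"], u), Bipartition(sp["SP3"], u)], cfg)
        verdicts = {c.clade: c.is_iel for c in calls}
        assert verdicts[Bipartition(sp["SP1"], u)] is True  # 5/6 >= 3/4
        assert verdicts[Bipartition(sp["SP3"], u)] is False

    def test_empty_candidates_empty_result(self):
        gen, _, _ = six_locus_fixture()
        assert recognize_iels(gen, []) == []


class TestResolutionTable:
    def test_published_cells_lenient_counts(self):
        cfg = GroupingConfig(strict_thresholds=False)
        calls = calls_from_support_cells(iel_support_cells(), LOCI, cfg)
        table = iel_resolution_table(calls, 15, LOCI)
        assert table["actin"] == "12/15"
        assert table["hisps"] == "13/15"
        assert table["h3h"] == "7/15"
        assert table["lsu_rdna"] == "2/15"

    def test_strict_mode_is_subset_of_lenient(self):
        cells = iel_support_cells()
        strict = calls_from_support_cells(cells, LOCI, GroupingConfig())
        lenient = calls_from_support_cells(
            cells, LOCI, GroupingConfig(strict_thresholds=False))
        s = {(c.species, c.locus) for c in strict if c.is_iel}
        l = {(c.species, c.locus) for c in lenient if c.is_iel}
        assert s <= l
        # the lenient-only cells are exactly the published sub-threshold ones
        assert ("A_gallica", "hisps") in l - s

    def test_no_calls_zero_over_n(self):
        assert iel_resolution_table([], 15, ["actin"]) == {"actin": "0/15"}
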