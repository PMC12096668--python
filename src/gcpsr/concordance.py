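"""Genealogical-concordance grouping: consensus trees, clade conflict and
independent-evolutionary-lineage (IEL) recognition.

The grouping step of genealogical concordance phylogenetic species
recognition (GCPSR) asks, clade by clade, whether multi-locus genealogies
agree.  Three rules are implemented, selectable via
:class:`GroupingConfig.mode`:

``CONCORDANCE``
    a clade is an IEL when it is present in at least a majority fraction
    (default 3/4) of the single-locus genealogies;
``NONDISCORDANCE``
    a clade is an IEL when it is well supported (MPBP and BPP above
    thresholds) in at least one locus and no locus displays a conflicting
    clade that is itself well supported at the same level;
``MODIFIED``
    the conservative-locus variant used when all loci evolve slowly: a clade
    is an IEL *at a locus* when it appears in both that locus's maximum
    parsimony and Bayesian majority-rule consensus trees with MPBP >= 70 and
    BPP >= 95 (defaults; ties pass).

``strict_thresholds=False`` additionally admits a sub-threshold cell as an
IEL when the same clade passes the thresholds at one or more other loci —
the lenient reading needed to reproduce published support tables that list
such cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import TaxonSetError
from .phylo_io import Bipartition, SupportRecord, SupportTree

__all__ = [
    "GroupingConfig",
    "LocusGenealogySet",
    "IELCall",
    "majority_rule_consensus",
    "conflicts",
    "clade_presence_fraction",
    "is_well_supported",
    "is_nondiscordant",
    "recognize_iels",
    "iel_resolution_table",
    "calls_from_support_cells",
]

MODES = ("CONCORDANCE", "NONDISCORDANCE", "MODIFIED")


@dataclass(frozen=True)
class GroupingConfig:
    """Thresholds and mode switches for IEL recognition.

    majority_fraction
        fraction of loci a clade must appear in under the concordance rule;
        with L loci "majority" is presence in >= ceil(fraction * L) loci.
    mpbp_min, bpp_min
        support thresholds (0-100 scale); comparisons use ``>=``.
    require_both_trees
        count a clade as present at a locus only when both the MP and the
        Bayesian consensus display it (the conservative reading); when
        False, either tree suffices.
    exclude_loci
        loci dropped from the majority denominator (e.g. a conserved rDNA
        backbone); they still participate in the per-locus modified rule.
    """

    majority_fraction: Fraction = Fraction(3, 4)
    mpbp_min: float = 70.0
    bpp_min: float = 95.0
    mode: str = "MODIFIED"
    strict_thresholds: bool = True
    require_both_trees: bool = True
    exclude_loci: Tuple[str, ...] = ()

    def __post_init__(self):
        if not 0 < self.majority_fraction <= 1:
            raise ValueError("majority_fraction must be in (0, 1]")
        for t in (self.mpbp_min, self.bpp_min):
            if not 0 <= t <= 100:
                raise ValueError("support thresholds must be in [0, 100]")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class LocusGenealogySet:
    """Per-locus MP and Bayesian consensus trees over one taxon universe.

    Trees may cover unequal taxon subsets (loci rarely have identical
    specimen coverage); the shared universe is the union of all leaves.
    """

    loci: Tuple[str, ...]
    mp_trees: Mapping[str, SupportTree]
    bayes_trees: Mapping[str, SupportTree]

    def __post_init__(self):
        self.loci = tuple(self.loci)
        if len(self.loci) != len(set(self.loci)):
            raise ValueError("locus names must be unique")
        for locus in self.loci:
            if locus not in self.mp_trees or locus not in self.bayes_trees:
                raise KeyError(f"missing trees for locus {locus!r}")

    @property
    def universe(self) -> frozenset:
        out: frozenset = frozenset()
        for locus in self.loci:
            out |= self.mp_trees[locus].taxa | self.bayes_trees[locus].taxa
        return out

    def pair(self, locus: str) -> Tuple[SupportTree, SupportTree]:
        return self.mp_trees[locus], self.bayes_trees[locus]


@dataclass(frozen=True)
class IELCall:
    """Outcome of testing one candidate clade at one locus (or overall).

    ``mpbp``/``bpp`` are the supports observed for the clade at the locus
    (None when absent); ``rule_fired`` names the grouping rule applied and
    ``is_iel`` the verdict.  Calls are emitted per (clade, locus) in
    MODIFIED mode and per clade otherwise (``locus=""``).
    """

    clade: Bipartition
    locus: str
    mpbp: Optional[float] = None
    bpp: Optional[float] = None
    rule_fired: str = "MODIFIED"
    is_iel: bool = False
    species: str = ""  # optional display name for the candidate clade

    def __post_init__(self):
        for v in (self.mpbp, self.bpp):
            if v is not None and not 0 <= v <= 100:
                raise ValueError("supports must lie in [0, 100]")


# ---------------------------------------------------------------------------
# consensus

def majority_rule_consensus(trees: Sequence[SupportTree],
                            threshold: float = 0.5,
                            support_field: str = "mpbp",
                            locus: str = "",
                            analysis_tag: str = "OTHER") -> SupportTree:
    """Majority-rule consensus of trees over one taxon set.

    Retains exactly the non-trivial bipartitions whose frequency across the
    input trees strictly exceeds ``threshold`` (0.5 <= threshold <= 1, which
    guarantees the retained set is mutually compatible), each annotated with
    its frequency x 100 in ``support_field``.
    """
    if not trees:
        raise ValueError("no input trees")
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0.5, 1.0]")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise TaxonSetError("input trees span different taxon sets",
                                t.taxa ^ taxa)
    counts: Dict[frozenset, int] = {}
    for t in trees:
        for key in t.bipartition_supports():
            counts[key] = counts.get(key, 0) + 1
    ref = min(taxa)
    clades: Dict[frozenset, SupportRecord] = {}
    for key, n in counts.items():
        freq = n / len(trees)
        if freq > threshold:
            side = next(s for s in key if ref not in s)
            clades[side] = SupportRecord(**{support_field: round(freq * 100, 6)})
    return SupportTree.from_clades(clades, taxa, locus=locus,
                                   analysis_tag=analysis_tag)


# ---------------------------------------------------------------------------
# clade logic

def conflicts(a: Bipartition, b: Bipartition) -> bool:
    """True when no single tree can display both bipartitions.

    Two splits of the same universe are compatible iff one of the four
    conditions holds: A subset B, B subset A, A and B disjoint, or A union B
    is the whole universe.  Trivial bipartitions conflict with nothing.
    """
    if a.universe != b.universe:
        raise TaxonSetError("bipartitions over different universes",
                            a.universe ^ b.universe)
    A, B, U = a.clade_side, b.clade_side, a.universe
    compatible = (A <= B or B <= A or not (A & B) or (A | B) == U)
    return not compatible


def _present_at_locus(clade: Bipartition, genealogies: LocusGenealogySet,
                      locus: str, config: GroupingConfig) -> bool:
    mp, bayes = genealogies.pair(locus)
    if config.require_both_trees:
        return mp.displays(clade) and bayes.displays(clade)
    return mp.displays(clade) or bayes.displays(clade)


def clade_presence_fraction(clade: Bipartition,
                            genealogies: LocusGenealogySet,
                            config: GroupingConfig = GroupingConfig()
                            ) -> float:
    """Fraction of loci whose consensus trees display the clade.

    The clade is restricted to each locus's taxon subset before comparison;
    restrictions with fewer than 2 members count as absent.  The denominator
    is the number of loci after ``config.exclude_loci``; zero informative
    loci yield 0.0.
    """
    loci = [l for l in genealogies.loci if l not in config.exclude_loci]
    if not loci:
        return 0.0
    hits = sum(
        1 for l in loci if _present_at_locus(clade, genealogies, l, config))
    return hits / len(loci)


def _supports_at(clade: Bipartition, genealogies: LocusGenealogySet,
                 locus: str) -> Tuple[Optional[float], Optional[float]]:
    mp, bayes = genealogies.pair(locus)
    mp_rec = mp.support_for(clade)
    by_rec = bayes.support_for(clade)
    return (mp_rec.mpbp if mp_rec else None,
            by_rec.bpp if by_rec else None)


def is_well_supported(clade: Bipartition, locus: str,
                      genealogies: LocusGenealogySet,
                      config: GroupingConfig = GroupingConfig()) -> bool:
    """Clade occurs in both of the locus's consensus trees with
    MPBP >= mpbp_min and BPP >= bpp_min (ties pass)."""
    mp, bayes = genealogies.pair(locus)
    if not (mp.displays(clade) and bayes.displays(clade)):
        return False
    mpbp, bpp = _supports_at(clade, genealogies, locus)
    return (mpbp is not None and bpp is not None
            and mpbp >= config.mpbp_min and bpp >= config.bpp_min)


def is_nondiscordant(clade: Bipartition,
                     genealogies: LocusGenealogySet,
                     config: GroupingConfig = GroupingConfig()) -> bool:
    """Well supported somewhere, contradicted nowhere at the same level.

    "Contradicted at the same level of support" means some locus displays a
    bipartition that conflicts with the clade and itself passes
    :func:`is_well_supported` under the same thresholds.
    """
    if not any(is_well_supported(clade, l, genealogies, config)
               for l in genealogies.loci):
        return False
    for locus in genealogies.loci:
        mp, bayes = genealogies.pair(locus)
        taxa = mp.taxa | bayes.taxa
        r = clade.restrict(taxa)
        if len(r.clade_side) < 2 or len(r.complement) < 2:
            continue
        seen = set()
        for tree in (mp, bayes):
            for key in tree.bipartition_supports():
                if key in seen:
                    continue
                seen.add(key)
                side = min(key, key=lambda s: (len(s), sorted(s)))
                other = Bipartition(side, tree.taxa)
                rr = r.restrict(tree.taxa)
                if len(rr.clade_side) < 2 or len(rr.complement) < 2:
                    continue
                if conflicts(rr, other) and is_well_supported(
                        other, locus, genealogies, config):
                    return False
    return True


def recognize_iels(genealogies: LocusGenealogySet,
                   candidates: Iterable[Bipartition],
                   config: GroupingConfig = GroupingConfig(),
                   names: Optional[Mapping[Bipartition, str]] = None
                   ) -> List[IELCall]:
    """Apply the configured grouping rule to every candidate clade.

    Returns one :class:`IELCall` per (candidate, locus) in MODIFIED mode —
    including loci where the clade is present but under-supported, so the
    published-style support table can be rendered — and one call per
    candidate in the other modes.  Candidates are typically the putative
    species clades, or every bipartition of a concatenated tree.
    """
    names = names or {}
    calls: List[IELCall] = []
    for clade in candidates:
        label = names.get(clade, "")
        if config.mode == "CONCORDANCE":
            frac = clade_presence_fraction(clade, genealogies, config)
            calls.append(IELCall(
                clade=clade, locus="", rule_fired="CONCORDANCE",
                is_iel=frac >= float(config.majority_fraction),
                species=label))
            continue
        if config.mode == "NONDISCORDANCE":
            calls.append(IELCall(
                clade=clade, locus="", rule_fired="NONDISCORDANCE",
                is_iel=is_nondiscordant(clade, genealogies, config),
                species=label))
            continue
        # MODIFIED: per-locus presence + thresholds
        per_locus = []
        for locus in genealogies.loci:
            present = _present_at_locus(clade, genealogies, locus, config)
            mpbp, bpp = (_supports_at(clade, genealogies, locus)
                         if present else (None, None))
            passes = (present and mpbp is not None and bpp is not None
                      and mpbp >= config.mpbp_min and bpp >= config.bpp_min)
            per_locus.append((locus, present, mpbp, bpp, passes))
        passes_somewhere = any(p[4] for p in per_locus)
        for locus, present, mpbp, bpp, passes in per_locus:
            if not present:
                continue
            is_iel = passes if config.strict_thresholds else (
                mpbp is not None and bpp is not None and passes_somewhere)
            calls.append(IELCall(
                clade=clade, locus=locus, mpbp=mpbp, bpp=bpp,
                rule_fired="MODIFIED", is_iel=is_iel, species=label))
    return calls


def iel_resolution_table(calls: Iterable[IELCall],
                         species_count: int,
                         loci: Optional[Sequence[str]] = None
                         ) -> Dict[str, str]:
    """Per-locus "x/n" resolution summary.

    ``x`` counts distinct candidate clades called IEL at that locus and
    ``n`` is the number of putative species.  Loci without any call are
    reported as "0/n" when listed explicitly in ``loci``.
    """
    if species_count < 1:
        raise ValueError("species_count must be >= 1")
    per_locus: Dict[str, set] = {}
    for call in calls:
        if not call.locus:
            continue
        per_locus.setdefault(call.locus, set())
        if call.is_iel:
            per_locus[call.locus].add(call.clade)
    if loci is None:
        loci = sorted(per_locus)
    return {l: f"{len(per_locus.get(l, set()))}/{species_count}"
            for l in loci}


def calls_from_support_cells(
        cells: Mapping[Tuple[str, str], Optional[Tuple[float, float]]],
        loci: Sequence[str],
        config: GroupingConfig = GroupingConfig()) -> List[IELCall]:
    """Build IEL calls from an encoded support table.

    ``cells`` maps (species, locus) to an observed (MPBP, BPP) pair, or None
    where the species clade is absent from that locus's consensus trees.
    Each species is represented by a two-member placeholder clade so the
    calls compose with :func:`iel_resolution_table` and report renderers.
    The strict/lenient threshold logic matches :func:`recognize_iels`.
    """
    species = sorted({sp for sp, _ in cells})
    universe = frozenset(f"{sp}#{i}" for sp in species for i in (1, 2))
    clade_of = {sp: Bipartition(frozenset({f"{sp}#1", f"{sp}#2"}), universe)
                for sp in species}
    calls: List[IELCall] = []
    for sp in species:
        observed = [(l, cells.get((sp, l))) for l in loci]
        passes = {l: (v is not None and v[0] >= config.mpbp_min
                      and v[1] >= config.bpp_min) for l, v in observed}
        anywhere = any(passes.values())
        for locus, value in observed:
            if value is None:
                continue
            mpbp, bpp = value
            is_iel = passes[locus] if config.strict_thresholds else anywhere
            calls.append(IELCall(
                clade=clade_of[sp], locus=locus, mpbp=mpbp, bpp=bpp,
                rule_fired="MODIFIED", is_iel=is_iel, species=sp))
    return calls
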