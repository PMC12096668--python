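"""Species ranking: from candidate clades to an exhaustive species partition.

The ranking step of GCPSR takes the concatenated (multi-gene) species tree,
together with the per-locus IEL calls, and applies two criteria:

* *genetic differentiation* — only clades backed by evidence become species:
  either route (a), the clade is an IEL at one or more loci, or route (b),
  its species-tree supports reach BPP >= 95 and MPBP or MLBS >= 70; and a
  most-inclusive-first traversal absorbs minor tip clades nested inside an
  accepted species instead of ranking them;
* *exhaustive subdivision* — every individual ends up in exactly one
  species; leaves not covered by any accepted clade are handled by the
  residual policy (their maximal unassigned subtrees become flagged species,
  or are attached to the adjacent accepted species).

Also provides a partition diff (mergers / splits / identical groups) used to
compare phylogenetic species against biological species from mating tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .concordance import IELCall
from .errors import RankingError, TaxonSetError
from .phylo_io import Bipartition, SupportRecord, SupportTree

__all__ = [
    "RankingConfig",
    "CandidateClade",
    "SpeciesPartition",
    "PartitionDiff",
    "candidate_species_clades",
    "rank_species",
    "compare_partitions",
]


@dataclass(frozen=True)
class RankingConfig:
    bpp_min: float = 95.0
    mp_or_ml_min: float = 70.0  # satisfied by MPBP or MLBS
    require_iel_or_support: bool = True
    residual_policy: str = "OWN_SPECIES"  # or "ATTACH_SISTER"
    outgroup: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.residual_policy not in ("OWN_SPECIES", "ATTACH_SISTER"):
            raise ValueError("residual_policy must be OWN_SPECIES or "
                             "ATTACH_SISTER")
        for t in (self.bpp_min, self.mp_or_ml_min):
            if not 0 <= t <= 100:
                raise ValueError("thresholds must lie in [0, 100]")


@dataclass(frozen=True)
class CandidateClade:
    """A species-tree clade with the evidence routes that admitted it."""

    clade: Bipartition
    routes: Tuple[str, ...]  # subset of ("IEL", "SUPPORT")
    supports: SupportRecord
    iel_loci: Tuple[str, ...] = ()


@dataclass
class SpeciesRecord:
    members: frozenset
    supports: SupportRecord = field(default_factory=SupportRecord)
    iel_loci: Tuple[str, ...] = ()
    routes: Tuple[str, ...] = ()
    residual: bool = False
    absorbed: Tuple[frozenset, ...] = ()  # nested candidate substructures


@dataclass
class SpeciesPartition:
    """Exhaustive, disjoint assignment of taxa to species."""

    assignment: Dict[str, str]
    species: Dict[str, SpeciesRecord]

    def __post_init__(self):
        covered: set = set()
        for sid, rec in self.species.items():
            if covered & rec.members:
                raise RankingError("species member sets overlap")
            covered |= rec.members
            for m in rec.members:
                if self.assignment.get(m) != sid:
                    raise RankingError(
                        f"assignment and species records disagree for {m!r}")
        if covered != set(self.assignment):
            raise RankingError("partition is not an exhaustive subdivision")

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.assignment)

    def n_species(self) -> int:
        return len(self.species)

    def groups(self) -> Dict[str, frozenset]:
        return {sid: rec.members for sid, rec in self.species.items()}

    @classmethod
    def from_assignment(cls, assignment: Mapping[str, str]
                        ) -> "SpeciesPartition":
        species: Dict[str, SpeciesRecord] = {}
        for taxon, sid in assignment.items():
            species.setdefault(sid, SpeciesRecord(members=frozenset()))
        members: Dict[str, set] = {sid: set() for sid in species}
        for taxon, sid in assignment.items():
            members[sid].add(taxon)
        for sid in species:
            species[sid] = SpeciesRecord(members=frozenset(members[sid]))
        return cls(assignment=dict(assignment), species=species)


@dataclass
class PartitionDiff:
    """Mergers, splits and identical groups between two partitions.

    A merger is k >= 2 groups of partition A whose union is exactly one
    group of B; a split is the converse.  Components of the intersection
    graph that are neither are listed under ``complex``.
    """

    identical_pairs: int = 0
    mergers: List[Tuple[Tuple[str, ...], str]] = field(default_factory=list)
    splits: List[Tuple[str, Tuple[str, ...]]] = field(default_factory=list)
    complex: List[Tuple[Tuple[str, ...], Tuple[str, ...]]] = field(
        default_factory=list)

    def is_empty(self) -> bool:
        return not (self.mergers or self.splits or self.complex)


# ---------------------------------------------------------------------------

def _species_tree_clades(species_tree: SupportTree, config: RankingConfig):
    """Rooted clades eligible as candidates: outgroup-free, below the full
    ingroup."""
    out = frozenset(config.outgroup)
    ingroup = species_tree.taxa - out
    for leafset, rec in species_tree.clades():
        clade = leafset - out
        if clade != leafset:  # clade contains outgroup taxa
            continue
        if len(clade) < 2 or clade == ingroup:
            continue
        yield leafset, rec


def candidate_species_clades(species_tree: SupportTree,
                             iels: Iterable[IELCall],
                             config: RankingConfig = RankingConfig()
                             ) -> List[CandidateClade]:
    """Clades of the species tree admissible as phylogenetic species.

    Route (a): the clade is an IEL at >= 1 locus.  Route (b): on the species
    tree, BPP >= bpp_min and (MPBP or MLBS) >= mp_or_ml_min.  The full
    ingroup and any clade containing outgroup taxa are never candidates.
    """
    iel_loci: Dict[frozenset, List[str]] = {}
    for call in iels:
        if call.is_iel:
            members = frozenset(call.clade.clade_side)
            iel_loci.setdefault(members, [])
            if call.locus and call.locus not in iel_loci[members]:
                iel_loci[members].append(call.locus)
    out: List[CandidateClade] = []
    for leafset, rec in _species_tree_clades(species_tree, config):
        routes = []
        loci = tuple(iel_loci.get(leafset, ()))
        if leafset in iel_loci:
            routes.append("IEL")
        bpp_ok = rec.bpp is not None and rec.bpp >= config.bpp_min
        mpml_ok = ((rec.mpbp is not None and rec.mpbp >= config.mp_or_ml_min)
                   or (rec.mlbs is not None and rec.mlbs >= config.mp_or_ml_min))
        if bpp_ok and mpml_ok:
            routes.append("SUPPORT")
        if routes or not config.require_iel_or_support:
            out.append(CandidateClade(
                clade=Bipartition(leafset, species_tree.taxa),
                routes=tuple(routes), supports=rec, iel_loci=loci))
    out.sort(key=lambda c: (-len(c.clade.clade_side),
                            sorted(c.clade.clade_side)))
    return out


def _sorted_children(node):
    def key(child):
        return min(lf.taxon.label for lf in child.leaf_iter())
    return sorted(node.child_nodes(), key=key)


def rank_species(species_tree: SupportTree,
                 candidates: Sequence[CandidateClade],
                 config: RankingConfig = RankingConfig()
                 ) -> SpeciesPartition:
    """Accept candidates most-inclusive-first; enforce exhaustive subdivision.

    A deterministic preorder traversal (children ordered by smallest member
    label) accepts a candidate clade as a species iff no already-accepted
    species contains it; candidates nested inside an accepted species are
    recorded as absorbed substructure, not ranked.  Unassigned leaves are
    then handled by ``config.residual_policy``.  Outgroup taxa are excluded
    from the partition.
    """
    out = frozenset(config.outgroup)
    ingroup = species_tree.taxa - out
    cand_by_clade = {frozenset(c.clade.clade_side) - out: c
                     for c in candidates}
    tree_clades = {ls - out for ls in _rooted_leafsets(species_tree)}
    for members in cand_by_clade:
        if members not in tree_clades:
            raise RankingError(
                f"candidate {sorted(members)[:4]}... is not a clade of the "
                "species tree")

    accepted: List[Tuple[frozenset, CandidateClade]] = []
    absorbed: Dict[frozenset, List[frozenset]] = {}

    def visit(node, covering: Optional[frozenset]):
        leafset = frozenset(lf.taxon.label for lf in node.leaf_iter()) - out
        cand = cand_by_clade.get(leafset)
        if cand is not None and len(leafset) >= 2 and leafset != ingroup:
            if covering is None:
                accepted.append((leafset, cand))
                covering = leafset
            else:
                absorbed.setdefault(covering, []).append(leafset)
        for child in _sorted_children(node):
            if not child.is_leaf():
                visit(child, covering)

    visit(species_tree.tree.seed_node, None)

    assignment: Dict[str, str] = {}
    species: Dict[str, SpeciesRecord] = {}
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"PS{counter:02d}"

    for members, cand in accepted:
        sid = new_id()
        species[sid] = SpeciesRecord(
            members=members, supports=cand.supports,
            iel_loci=cand.iel_loci, routes=cand.routes,
            absorbed=tuple(absorbed.get(members, ())))
        for m in members:
            assignment[m] = sid

    # exhaustive subdivision: deal with leaves in no accepted clade
    unassigned = ingroup - set(assignment)
    if unassigned:
        residual_groups = _maximal_unassigned_subtrees(
            species_tree, set(assignment), out)
        for group in residual_groups:
            if config.residual_policy == "OWN_SPECIES":
                sid = new_id()
                species[sid] = SpeciesRecord(members=group, residual=True)
                for m in group:
                    assignment[m] = sid
            else:  # ATTACH_SISTER
                sid = _nearest_assigned_species(
                    species_tree, group, assignment)
                if sid is None:
                    sid = new_id()
                    species[sid] = SpeciesRecord(members=group, residual=True)
                else:
                    rec = species[sid]
                    species[sid] = SpeciesRecord(
                        members=rec.members | group, supports=rec.supports,
                        iel_loci=rec.iel_loci, routes=rec.routes,
                        residual=rec.residual, absorbed=rec.absorbed)
                for m in group:
                    assignment[m] = sid
    return SpeciesPartition(assignment=assignment, species=species)


def _rooted_leafsets(species_tree: SupportTree) -> set:
    out = set()
    for node in species_tree.tree.preorder_node_iter():
        out.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def _maximal_unassigned_subtrees(species_tree: SupportTree,
                                 assigned: set, outgroup: frozenset
                                 ) -> List[frozenset]:
    groups: List[frozenset] = []

    def visit(node):
        leafset = frozenset(
            lf.taxon.label for lf in node.leaf_iter()) - outgroup
        if not leafset:
            return
        if not (leafset & assigned):
            groups.append(leafset)
            return
        for child in _sorted_children(node):
            visit(child)

    visit(species_tree.tree.seed_node)
    return groups


def _nearest_assigned_species(species_tree: SupportTree, group: frozenset,
                              assignment: Mapping[str, str]) -> Optional[str]:
    """Species id of the closest assigned leaves, walking rootward from the
    residual group; ties broken by smallest species id."""
    best = None
    for n in species_tree.tree.preorder_node_iter():
        leafset = frozenset(lf.taxon.label for lf in n.leaf_iter())
        if group <= leafset and (best is None or len(leafset) < best[0]):
            best = (len(leafset), n)
    node = best[1] if best else None
    while node is not None:
        labels = [lf.taxon.label for lf in node.leaf_iter()]
        sids = sorted({assignment[l] for l in labels if l in assignment})
        if sids:
            return sids[0]
        node = node.parent_node
    return None


# ---------------------------------------------------------------------------

def compare_partitions(a: SpeciesPartition, b: SpeciesPartition
                       ) -> PartitionDiff:
    """Diff two partitions of the same taxa via their intersection graph."""
    if a.taxa != b.taxa:
        raise TaxonSetError("partitions cover different taxa",
                            a.taxa ^ b.taxa)
    ga, gb = a.groups(), b.groups()
    graph = nx.Graph()
    graph.add_nodes_from(("A", k) for k in ga)
    graph.add_nodes_from(("B", k) for k in gb)
    for ka, ma in ga.items():
        for kb, mb in gb.items():
            if ma & mb:
                graph.add_edge(("A", ka), ("B", kb))
    diff = PartitionDiff()
    for comp in nx.connected_components(graph):
        akeys = tuple(sorted(k for side, k in comp if side == "A"))
        bkeys = tuple(sorted(k for side, k in comp if side == "B"))
        if len(akeys) == 1 and len(bkeys) == 1:
            diff.identical_pairs += 1
        elif len(bkeys) == 1:
            diff.mergers.append((akeys, bkeys[0]))
        elif len(akeys) == 1:
            diff.splits.append((akeys[0], bkeys))
        else:
            diff.complex.append((akeys, bkeys))
    diff.mergers.sort()
    diff.splits.sort()
    diff.complex.sort()
    return diff
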