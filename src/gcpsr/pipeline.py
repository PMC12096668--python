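"""End-to-end GCPSR: genealogies + species tree -> species partition."""

from __future__ import annotations

from typing import Iterable, List, Optional, Tuple

from .concordance import (
    GroupingConfig,
    IELCall,
    LocusGenealogySet,
    recognize_iels,
)
from .phylo_io import Bipartition, SupportTree
from .ranking import (
    CandidateClade,
    RankingConfig,
    SpeciesPartition,
    candidate_species_clades,
    rank_species,
)

__all__ = ["delimit_phylogenetic_species", "species_tree_candidates"]


def species_tree_candidates(species_tree: SupportTree,
                            config: RankingConfig = RankingConfig()
                            ) -> List[Bipartition]:
    """Every outgroup-free clade of the species tree below the full ingroup
    — the default candidate pool when no species hypotheses are supplied."""
    out = frozenset(config.outgroup)
    ingroup = species_tree.taxa - out
    pool = []
    for leafset, _rec in species_tree.clades():
        if leafset & out or len(leafset) < 2 or leafset == ingroup:
            continue
        pool.append(Bipartition(leafset, species_tree.taxa))
    pool.sort(key=lambda b: (-len(b.clade_side), sorted(b.clade_side)))
    return pool


def delimit_phylogenetic_species(
        genealogies: LocusGenealogySet,
        species_tree: SupportTree,
        grouping: GroupingConfig = GroupingConfig(),
        ranking: RankingConfig = RankingConfig(),
        candidates: Optional[Iterable[Bipartition]] = None,
) -> Tuple[SpeciesPartition, List[IELCall], List[CandidateClade]]:
    """Run grouping then ranking; returns (partition, IEL calls, candidates).

    Candidate clades default to every clade of the species tree.  IEL
    recognition runs on those candidates over the per-locus genealogies;
    the ranking step then accepts clades that are IELs at >= 1 locus or
    well supported on the species tree, most-inclusive-first, and enforces
    exhaustive subdivision.
    """
    if candidates is None:
        candidates = species_tree_candidates(species_tree, ranking)
    candidates = list(candidates)
    calls = recognize_iels(genealogies, candidates, grouping)
    cands = candidate_species_clades(species_tree, calls, ranking)
    partition = rank_species(species_tree, cands, ranking)
    return partition, calls, cands
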