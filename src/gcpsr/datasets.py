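"""Bundled example data: the published Chinese *Armillaria* summary tables.

These are the printed summary values of a 16-biological-species /
15-phylogenetic-species *Armillaria* study (six loci, ~600 specimens,
30,340 mate pairings): the per-locus IEL support table, the concatenated
species-tree support triples, the per-species spore statistics
(mean ± 95% error limit and n) and the reported between-species gene-flow
percentages.  The underlying raw data (alignments, pairing records, spore
measurements) are not published, so these tables are the finest-grained
inputs available; tests and worked examples use them as fixtures, and the
synthetic generator is calibrated against them.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .mating import MatingMatrix, PairingRecord
from .morphometry import SporeSampleSummary, summary_from_published

__all__ = [
    "LOCI",
    "SPECIES",
    "ALIGNED_LENGTHS",
    "iel_support_cells",
    "species_tree_triples",
    "published_resolution_row",
    "spore_summaries",
    "gene_flow_percentages",
    "gene_flow_fixture",
    "kg_scenario",
]

#: The six loci, in published column order.
LOCI: Tuple[str, ...] = ("actin", "h3h", "hisps", "lsu_rdna", "rpb1", "tef1a")

#: The 15 phylogenetic species (14 *Armillaria* + 1 *Desarmillaria*).
SPECIES: Tuple[str, ...] = (
    "A_algida", "A_amygdalispora", "A_borealis", "A_bruneocystidia",
    "A_gallica", "A_korhonenii", "A_luteopileata", "A_mellea",
    "A_ostoyae", "A_pungentisquamosa", "A_sinapina", "A_sinensis",
    "A_tibetica", "A_violacea", "D_tabescens",
)

#: Per-locus aligned lengths (bp) of the trimmed datasets.
ALIGNED_LENGTHS: Dict[str, int] = {
    "actin": 755, "h3h": 1283, "hisps": 1452,
    "lsu_rdna": 1338, "rpb1": 1160, "tef1a": 893,
}

# (MPBP, BPP) observed for each species clade at each locus's consensus
# trees; absent cells mean the clade is not displayed there.
_IEL_CELLS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "A_algida": {"actin": (96, 100), "rpb1": (90, 100), "tef1a": (95, 100)},
    "A_amygdalispora": {"actin": (71, 100), "hisps": (99, 100),
                        "rpb1": (33, 100), "tef1a": (76, 100)},
    "A_borealis": {"actin": (98, 100), "hisps": (95, 100),
                   "tef1a": (73, 100)},
    "A_bruneocystidia": {},
    "A_gallica": {"actin": (99, 100), "h3h": (97, 100), "hisps": (50, 100),
                  "rpb1": (99, 100)},
    "A_korhonenii": {"actin": (99, 100), "h3h": (99, 100),
                     "hisps": (99, 100), "rpb1": (100, 100),
                     "tef1a": (100, 100)},
    "A_luteopileata": {"h3h": (91, 100), "hisps": (99, 100),
                       "tef1a": (77, 100)},
    "A_mellea": {"actin": (84, 100), "h3h": (99, 100), "hisps": (99, 100),
                 "lsu_rdna": (99, 100), "rpb1": (100, 100),
                 "tef1a": (100, 100)},
    "A_ostoyae": {"actin": (86, 97), "hisps": (93, 100), "tef1a": (97, 100)},
    "A_pungentisquamosa": {"actin": (89, 100), "h3h": (99, 100),
                           "hisps": (99, 100), "rpb1": (100, 100),
                           "tef1a": (100, 100)},
    "A_sinapina": {"actin": (97, 100), "hisps": (93, 100),
                   "rpb1": (51, 93), "tef1a": (100, 100)},
    "A_sinensis": {"actin": (90, 100), "hisps": (83, 92)},
    "A_tibetica": {"hisps": (73, 99), "rpb1": (89, 100)},
    "A_violacea": {"actin": (74, 100), "h3h": (92, 100), "hisps": (92, 100),
                   "rpb1": (63, 100)},
    "D_tabescens": {"actin": (100, 100), "h3h": (99, 100),
                    "hisps": (93, 100), "lsu_rdna": (90, 96),
                    "rpb1": (100, 100), "tef1a": (100, 100)},
}

#: Concatenated-tree support triples (MPBP, MLBS, BPP) per species clade.
_PS_TRIPLES: Dict[str, Tuple[float, float, float]] = {
    "A_algida": (94, 100, 100), "A_amygdalispora": (99, 100, 100),
    "A_borealis": (51, 30, 95), "A_bruneocystidia": (89, 100, 100),
    "A_gallica": (99, 100, 100), "A_korhonenii": (99, 100, 100),
    "A_luteopileata": (99, 100, 100), "A_mellea": (99, 100, 100),
    "A_ostoyae": (99, 100, 81), "A_pungentisquamosa": (99, 100, 100),
    "A_sinapina": (99, 100, 100), "A_sinensis": (87, 100, 100),
    "A_tibetica": (95, 100, 100), "A_violacea": (99, 100, 100),
    "D_tabescens": (99, 100, 100),
}

#: The resolution row as printed ("x/15" per locus).  The rpb1 and tef1a
#: entries disagree with a direct count of the printed cells (10 each);
#: both are kept so callers can see the discrepancy.
_PRINTED_RESOLUTION: Dict[str, str] = {
    "actin": "12/15", "h3h": "7/15", "hisps": "13/15",
    "lsu_rdna": "2/15", "rpb1": "11/15", "tef1a": "9/15",
}

# Spore statistics: species -> (mean length, EL length, mean Q, EL Q, n).
# "A_mellea_nipponica" is the secondarily homothallic subspecies scored as
# its own biological species.
_SPORE_TABLE: Dict[str, Tuple[float, float, float, float, int]] = {
    "A_algida": (8.34, 0.09, 1.52, 0.02, 331),
    "A_amygdalispora": (8.96, 0.13, 1.70, 0.03, 120),
    "A_borealis": (8.78, 0.07, 1.55, 0.02, 390),
    "A_bruneocystidia": (8.05, 0.09, 1.50, 0.02, 235),
    "A_gallica": (8.48, 0.09, 1.63, 0.02, 285),
    "A_korhonenii": (8.74, 0.07, 1.61, 0.02, 490),
    "A_luteopileata": (8.23, 0.10, 1.59, 0.02, 314),
    "A_mellea": (9.11, 0.12, 1.61, 0.02, 287),
    "A_mellea_nipponica": (9.53, 0.11, 1.65, 0.02, 429),
    "A_ostoyae": (8.56, 0.08, 1.57, 0.02, 365),
    "A_pungentisquamosa": (7.59, 0.08, 1.47, 0.02, 300),
    "A_sinapina": (7.78, 0.09, 1.57, 0.02, 243),
    "A_sinensis": (8.10, 0.21, 1.55, 0.02, 332),
    "A_tibetica": (8.41, 0.05, 1.45, 0.01, 657),
    "A_violacea": (8.52, 0.08, 1.64, 0.02, 210),
    "D_tabescens": (7.93, 0.10, 1.40, 0.02, 218),
}

#: Reported cross-species interfertility percentages (residual gene flow).
_GENE_FLOW: Tuple[Tuple[str, str, float], ...] = (
    ("A_algida", "A_luteopileata", 41.1),
    ("A_bruneocystidia", "A_algida", 16.6),
    ("A_bruneocystidia", "A_luteopileata", 16.0),
    ("A_bruneocystidia", "A_korhonenii", 13.1),
)


def iel_support_cells() -> Dict[Tuple[str, str], Optional[Tuple[float, float]]]:
    """(species, locus) -> (MPBP, BPP) or None where the clade is absent."""
    return {(sp, locus): _IEL_CELLS[sp].get(locus)
            for sp in SPECIES for locus in LOCI}


def species_tree_triples() -> Dict[str, Tuple[float, float, float]]:
    return dict(_PS_TRIPLES)


def published_resolution_row() -> Dict[str, str]:
    return dict(_PRINTED_RESOLUTION)


def spore_summaries() -> List[SporeSampleSummary]:
    """Published per-species spore summaries (SDs back-derivable from EL)."""
    return [summary_from_published(sp, l_m, el_l, q_m, el_q, n)
            for sp, (l_m, el_l, q_m, el_q, n) in sorted(_SPORE_TABLE.items())]


def gene_flow_percentages() -> Tuple[Tuple[str, str, float], ...]:
    return _GENE_FLOW


def gene_flow_fixture(n_per_pair: int = 1000) -> MatingMatrix:
    """Pairing records reproducing the published gene-flow percentages.

    Each involved species gets two testers; within-species pairings are
    fully interfertile, and each reported species pair gets ``n_per_pair``
    cross pairings on a single tester pair with exactly the reported
    interfertility percentage (the rest scored as black lines).  Because
    the cross rate stays below 50%, component-based delimitation keeps the
    species separate while the gene-flow report lists all four pairs.
    """
    species = sorted({s for a, b, _ in _GENE_FLOW for s in (a, b)})
    records: List[PairingRecord] = []
    groups: Dict[str, str] = {}
    for sp in species:
        t1, t2 = f"{sp}_t1", f"{sp}_t2"
        groups[t1] = groups[t2] = sp
        records.extend(PairingRecord(t1, t2, "CRUSTOSE_DIPLOID", r + 1)
                       for r in range(40))
    for a, b, pct in _GENE_FLOW:
        k = round(pct * n_per_pair / 100.0)
        for r in range(n_per_pair):
            outcome = "CRUSTOSE_DIPLOID" if r < k else "BLACK_LINE"
            records.append(PairingRecord(f"{a}_t1", f"{b}_t1", outcome, r + 1))
    return MatingMatrix(records, groups=groups)


def kg_scenario():
    """Miniature of the one mating/phylogeny disagreement: two biological
    species with no differentiating clade.

    Returns ``(genealogies, species_tree, mating_matrix)`` for three true
    phylogenetic lineages A, B and KG, where KG's individuals split into
    two fully intersterile mating groups K and G (a heterothallic /
    secondarily homothallic pair).  Every locus displays the clades A, B
    and K+G with full support and nothing subdividing K+G, so GCPSR finds
    3 species while the mating matrix yields 4 intersterility groups.
    """
    from .concordance import LocusGenealogySet
    from .phylo_io import SupportRecord, SupportTree

    members = {
        "A": tuple(f"A_i{i}" for i in range(1, 5)),
        "B": tuple(f"B_i{i}" for i in range(1, 5)),
        "K": tuple(f"K_i{i}" for i in range(1, 4)),
        "G": tuple(f"G_i{i}" for i in range(1, 4)),
    }
    universe = [m for sp in sorted(members) for m in members[sp]]
    clades = {
        frozenset(members["A"]): None,
        frozenset(members["B"]): None,
        frozenset(members["K"] + members["G"]): None,
    }
    loci = ("actin", "h3h", "hisps", "rpb1")
    mp_trees, bayes_trees = {}, {}
    for locus in loci:
        mp_trees[locus] = SupportTree.from_clades(
            {c: SupportRecord(mpbp=100) for c in clades}, universe,
            locus=locus, analysis_tag="MP_CONSENSUS")
        bayes_trees[locus] = SupportTree.from_clades(
            {c: SupportRecord(bpp=100) for c in clades}, universe,
            locus=locus, analysis_tag="BAYES_CONSENSUS")
    genealogies = LocusGenealogySet(loci=loci, mp_trees=mp_trees,
                                    bayes_trees=bayes_trees)
    species_tree = SupportTree.from_clades(
        {c: SupportRecord(mpbp=99, mlbs=100, bpp=100) for c in clades},
        universe, locus="concatenated", analysis_tag="SPECIES_TREE")

    records: List[PairingRecord] = []
    groups: Dict[str, str] = {}
    for bs, isos in (("A", members["A"]), ("B", members["B"]),
                     ("K", members["K"]), ("G", members["G"])):
        for iso in isos:
            groups[iso] = bs
    isolates = sorted(groups)
    for i, a in enumerate(isolates):
        for b in isolates[i + 1:]:
            outcome = ("CRUSTOSE_DIPLOID" if groups[a] == groups[b]
                       else "BLACK_LINE")
            records.append(PairingRecord(a, b, outcome))
    matrix = MatingMatrix(records, groups=groups)
    return genealogies, species_tree, matrix
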