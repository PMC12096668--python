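"""Synthetic data with planted ground truth for every analysis stage.

The generator emulates the statistical structure a multi-locus species
delimitation study rests on, without simulating sequences:

* per-locus gene trees copy a species-guide topology; each true species
  clade survives at a locus with probability ``concordance_prob`` (the
  between-species concordance the method exploits) or is perturbed by
  regrafting one member outside the clade (the within-species discordance
  that breaks it), with clade supports drawn from separate concordant /
  discordant laws;
* a concatenated species tree carries MPBP/MLBS/BPP triples per species
  clade, with selected clades forcible to fixed triples;
* mating matrices score replicate pairings of every tester pair, each
  pairing independently interfertile with the pair's probability
  (within-group 0.85, between-group 0.02 by default, with group-pair
  overrides for planted gene flow);
* spore tables draw (length, width) from per-species bivariate normals.

Default scale mirrors the motivating study: 15 species x 12 individuals,
six loci, 16 intersterility groups x 5 testers.  Everything is driven by an
integer seed through :class:`numpy.random.Generator`; the same seed and
configuration reproduce identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .concordance import LocusGenealogySet
from .phylo_io import Bipartition, SupportRecord, SupportTree

__all__ = [
    "SimulationTruth",
    "default_partition",
    "simulate_locus_trees",
    "simulate_species_tree",
    "simulate_mating",
    "simulate_spores",
    "DEFAULT_LOCI",
    "DEFAULT_SPORE_PARAMS",
]

#: Locus names of the six-gene design the generator emulates.
DEFAULT_LOCI = ("actin", "h3h", "hisps", "lsu_rdna", "rpb1", "tef1a")

CONCORDANT_LAW = {"mpbp": (85.0, 100.0), "bpp": (96.0, 100.0)}
DISCORDANT_LAW = {"mpbp": (10.0, 69.0), "bpp": (50.0, 94.0)}
SPECIES_TREE_LAW = {"mpbp": (85.0, 100.0), "mlbs": (85.0, 100.0),
                    "bpp": (96.0, 100.0)}


@dataclass
class SimulationTruth:
    """Planted ground truth recorded alongside each simulated dataset."""

    seed: int
    true_partition: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    concordance_events: Dict[Tuple[str, str], bool] = field(
        default_factory=dict)  # (species, locus) -> clade retained?
    pair_probabilities: Dict[Tuple[str, str], float] = field(
        default_factory=dict)
    spore_params: Dict[str, Tuple[float, float, float, float, float]] = field(
        default_factory=dict)


def default_partition(n_species: int = 15, n_individuals: int = 12,
                      species_prefix: str = "SP") -> Dict[str, Tuple[str, ...]]:
    """Planted species map: SP01 -> (SP01_i01, ..., SP01_i12), etc."""
    return {
        f"{species_prefix}{s + 1:02d}": tuple(
            f"{species_prefix}{s + 1:02d}_i{i + 1:02d}"
            for i in range(n_individuals))
        for s in range(n_species)
    }


def _draw(rng: np.random.Generator, law: Mapping[str, Tuple[float, float]]
          ) -> SupportRecord:
    values = {f: round(float(rng.uniform(lo, hi)), 1)
              for f, (lo, hi) in law.items()}
    return SupportRecord(**values)


def _guide_universe(true_partition: Mapping[str, Sequence[str]]) -> List[str]:
    out: List[str] = []
    for sp in sorted(true_partition):
        out.extend(true_partition[sp])
    return out


def simulate_locus_trees(
        true_partition: Mapping[str, Sequence[str]],
        loci: Sequence[str] = DEFAULT_LOCI,
        concordance_prob: float = 5.0 / 6.0,
        concordant_law: Mapping[str, Tuple[float, float]] = None,
        discordant_law: Mapping[str, Tuple[float, float]] = None,
        seed: int = 0) -> Tuple[LocusGenealogySet, SimulationTruth]:
    """Per-locus MP + Bayesian consensus trees with planted concordance.

    For every locus the species-guide topology (a polytomy of species
    clades) is copied.  Each species clade is retained with probability
    ``concordance_prob`` and annotated with supports from the concordant
    law; otherwise one randomly chosen member is regrafted outside the
    clade (attached at the root), the reduced clade gets supports from the
    discordant law, and the true clade is absent at that locus.  MP and
    Bayesian trees share each locus's topology; the MP tree carries the
    MPBP values, the Bayesian tree the BPP values.
    """
    if not 0 <= concordance_prob <= 1:
        raise ValueError("concordance_prob must be in [0, 1]")
    if len(true_partition) < 2:
        raise ValueError("need at least 2 species")
    for sp, members in true_partition.items():
        if len(members) < 2:
            raise ValueError(f"species {sp!r} needs >= 2 individuals to be "
                             "a clade (and to be perturbable)")
    concordant_law = concordant_law or CONCORDANT_LAW
    discordant_law = discordant_law or DISCORDANT_LAW
    rng = np.random.default_rng(seed)
    universe = _guide_universe(true_partition)
    truth = SimulationTruth(
        seed=seed,
        true_partition={sp: tuple(m) for sp, m in true_partition.items()})

    mp_trees: Dict[str, SupportTree] = {}
    bayes_trees: Dict[str, SupportTree] = {}
    for locus in loci:
        mp_clades: Dict[frozenset, SupportRecord] = {}
        by_clades: Dict[frozenset, SupportRecord] = {}
        for sp in sorted(true_partition):
            members = frozenset(true_partition[sp])
            retained = bool(rng.random() < concordance_prob)
            truth.concordance_events[(sp, locus)] = retained
            if retained:
                rec = _draw(rng, concordant_law)
                clade = members
            else:
                stray = sorted(members)[int(rng.integers(len(members)))]
                clade = members - {stray}  # stray sits at the root
                rec = _draw(rng, discordant_law)
                if len(clade) < 2:
                    continue
            mp_clades[clade] = SupportRecord(mpbp=rec.mpbp)
            by_clades[clade] = SupportRecord(bpp=rec.bpp)
        mp_trees[locus] = SupportTree.from_clades(
            mp_clades, universe, locus=locus, analysis_tag="MP_CONSENSUS")
        bayes_trees[locus] = SupportTree.from_clades(
            by_clades, universe, locus=locus, analysis_tag="BAYES_CONSENSUS")
    genealogies = LocusGenealogySet(
        loci=tuple(loci), mp_trees=mp_trees, bayes_trees=bayes_trees)
    return genealogies, truth


def simulate_species_tree(
        true_partition: Mapping[str, Sequence[str]],
        supports_law: Mapping[str, Tuple[float, float]] = None,
        forced_supports: Mapping[str, Tuple[float, float, float]] = None,
        backbone: str = "star",
        seed: int = 0) -> SupportTree:
    """Concatenated species tree with MPBP/MLBS/BPP triples per clade.

    ``forced_supports`` pins named species' clades to exact
    (MPBP, MLBS, BPP) triples, e.g. to plant a weakly supported species
    that only the IEL route can rescue.  ``backbone="star"`` (default)
    leaves the between-species backbone unresolved, so the species clades
    are the deepest resolved units; ``backbone="random"`` adds a random
    resolved backbone whose internal clades draw from the same law.
    """
    supports_law = supports_law or SPECIES_TREE_LAW
    forced_supports = forced_supports or {}
    rng = np.random.default_rng(seed)
    universe = _guide_universe(true_partition)
    clades: Dict[frozenset, SupportRecord] = {}
    for sp in sorted(true_partition):
        members = frozenset(true_partition[sp])
        if sp in forced_supports:
            mpbp, mlbs, bpp = forced_supports[sp]
            clades[members] = SupportRecord(mpbp=mpbp, mlbs=mlbs, bpp=bpp)
        else:
            clades[members] = _draw(rng, supports_law)
    if backbone == "random":
        blocks = [frozenset(true_partition[sp])
                  for sp in sorted(true_partition)]
        while len(blocks) > 2:
            i, j = sorted(rng.choice(len(blocks), size=2, replace=False))
            merged = blocks[i] | blocks[j]
            blocks = [b for k, b in enumerate(blocks) if k not in (i, j)]
            blocks.append(merged)
            if len(merged) < len(universe):
                clades[merged] = _draw(rng, supports_law)
    elif backbone != "star":
        raise ValueError("backbone must be 'star' or 'random'")
    return SupportTree.from_clades(clades, universe, locus="concatenated",
                                   analysis_tag="SPECIES_TREE")


def simulate_mating(true_isgs: Mapping[str, Sequence[str]] = None,
                    n_groups: int = 16, testers_per_group: int = 5,
                    pairings_per_pair: int = 40,
                    p_within: float = 0.85, p_between: float = 0.02,
                    p_black_line: float = 0.9,
                    gene_flow_overrides: Sequence[Tuple[str, str, float]] = (),
                    seed: int = 0):
    """Pairing records over planted intersterility groups.

    Each tester pair receives ``pairings_per_pair`` replicate pairings;
    every pairing independently scores CRUSTOSE_DIPLOID with the pair's
    interfertility probability (within-group ``p_within``, between-group
    ``p_between``, or an override for named group pairs), else BLACK_LINE
    with probability ``p_black_line`` of the remainder and WHITE_FLUFFY
    otherwise.  Replication is per tester pair, so group-pair totals are
    ``pairings_per_pair`` x (number of tester pairs), matching the
    hundreds-to-thousands of pairings per group pair in real designs, and
    each pair's interfertile proportion concentrates at its true
    probability.

    Returns ``(MatingMatrix, SimulationTruth)``.
    """
    from .mating import MatingMatrix  # local import to avoid cycle

    if true_isgs is None:
        true_isgs = {
            f"BS{g + 1:02d}": tuple(
                f"BS{g + 1:02d}_t{t + 1}" for t in range(testers_per_group))
            for g in range(n_groups)}
    rng = np.random.default_rng(seed)
    overrides = {}
    for ga, gb, p in gene_flow_overrides:
        overrides[tuple(sorted((ga, gb)))] = p
    groups = {iso: g for g, isos in true_isgs.items() for iso in isos}
    isolates = sorted(groups)
    truth = SimulationTruth(seed=seed, true_partition={
        g: tuple(isos) for g, isos in true_isgs.items()})

    rows_a: List[str] = []
    rows_b: List[str] = []
    outcomes: List[str] = []
    replicates: List[int] = []
    for i, a in enumerate(isolates):
        for b in isolates[i + 1:]:
            ga, gb = groups[a], groups[b]
            if ga == gb:
                p = p_within
            else:
                p = overrides.get(tuple(sorted((ga, gb))), p_between)
            truth.pair_probabilities[(a, b)] = p
            fertile = rng.random(pairings_per_pair) < p
            black = rng.random(pairings_per_pair) < p_black_line
            for r in range(pairings_per_pair):
                rows_a.append(a)
                rows_b.append(b)
                if fertile[r]:
                    outcomes.append("CRUSTOSE_DIPLOID")
                else:
                    outcomes.append("BLACK_LINE" if black[r]
                                    else "WHITE_FLUFFY")
                replicates.append(r + 1)
    df = pd.DataFrame({"isolate_a": rows_a, "isolate_b": rows_b,
                       "outcome": outcomes, "replicate": replicates})
    return MatingMatrix(df, groups=groups), truth


#: Per-species (mean length, sd length, mean width, sd width, corr) in um,
#: spanning the 7.6-9.5 um length range typical of the group.
DEFAULT_SPORE_PARAMS: Dict[str, Tuple[float, float, float, float, float]] = {
    "SPORE_A": (8.41, 0.65, 5.80, 0.45, 0.55),
    "SPORE_B": (8.96, 0.70, 5.27, 0.48, 0.55),
    "SPORE_C": (7.59, 0.60, 5.16, 0.42, 0.55),
    "SPORE_D": (9.53, 0.72, 5.78, 0.50, 0.55),
}


def simulate_spores(per_species: Mapping[
                        str, Tuple[float, float, float, float, float]] = None,
                    n_specimens: int = 10,
                    spores_per_specimen: int = 33,
                    seed: int = 0) -> Tuple[pd.DataFrame, SimulationTruth]:
    """Bivariate-normal (length, width) spore tables with provenance ids.

    Each specimen contributes one basidioma with ``spores_per_specimen``
    spores (>= 30, the conventional minimum per specimen).  Draws are
    truncated at zero by redrawing.  Returns a tidy DataFrame with columns
    species, specimen_id, basidioma_id, length_um, width_um.
    """
    per_species = per_species or DEFAULT_SPORE_PARAMS
    if spores_per_specimen < 30:
        raise ValueError("measure at least 30 spores per specimen")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed, spore_params=dict(per_species))
    rows = []
    for sp in sorted(per_species):
        mu_l, sd_l, mu_w, sd_w, rho = per_species[sp]
        if sd_l <= 0 or sd_w <= 0 or not -1 < rho < 1:
            raise ValueError(f"invalid spore parameters for {sp!r}")
        cov = [[sd_l ** 2, rho * sd_l * sd_w],
               [rho * sd_l * sd_w, sd_w ** 2]]
        for spec in range(n_specimens):
            spec_id = f"{sp}_s{spec + 1:02d}"
            bas_id = f"{spec_id}_b1"
            draws = rng.multivariate_normal(
                [mu_l, mu_w], cov, size=spores_per_specimen,
                method="cholesky")
            while (draws <= 0).any():  # truncate at zero by redraw
                bad = (draws <= 0).any(axis=1)
                draws[bad] = rng.multivariate_normal(
                    [mu_l, mu_w], cov, size=int(bad.sum()),
                    method="cholesky")
            for l, w in draws:
                rows.append((sp, spec_id, bas_id, float(l), float(w)))
    df = pd.DataFrame(rows, columns=[
        "species", "specimen_id", "basidioma_id", "length_um", "width_um"])
    return df, truth
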