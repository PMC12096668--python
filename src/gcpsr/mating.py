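"""Mating-test analysis: interfertility statistics and intersterility groups.

Haploid tester isolates are paired on agar; each pairing is scored as an
interfertile reaction (the colonies fuse into a brown crustose diploid), an
intersterile reaction (an antagonistic black demarcation line forms, or both
sides stay white and fluffy), or left unscored.  For a pair of groups the
interfertility percentage IF is the share of crustose-diploid pairings and
the intersterility percentage IS the share of black-line plus white-fluffy
pairings; the denominator N counts *all* pairing attempts including
unscored ones, which is why IF + IS can fall short of 100.

Intersterility groups (ISGs, biological species) are delimited on a graph
over isolates: two isolates are joined when the proportion of their
replicate pairings scored crustose-diploid reaches ``edge_threshold``
(default 0.5), and ISGs are the connected components.  Interfertile isolate
pairs that end up in different components are retained as evidence of
residual gene flow between reproductively isolated groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .errors import MatingDataError

__all__ = [
    "OUTCOMES",
    "PairingRecord",
    "MatingMatrix",
    "GroupPairSummary",
    "ISGPartition",
    "summarize_pair",
    "pair_table",
    "delimit_isgs",
    "gene_flow_report",
    "assign_unknown",
]

OUTCOMES = ("CRUSTOSE_DIPLOID", "BLACK_LINE", "WHITE_FLUFFY", "UNSCORED")
STERILE = ("BLACK_LINE", "WHITE_FLUFFY")


@dataclass(frozen=True)
class PairingRecord:
    isolate_a: str
    isolate_b: str
    outcome: str
    replicate: int = 1

    def __post_init__(self):
        if self.isolate_a == self.isolate_b:
            raise MatingDataError(
                f"self-pairing of {self.isolate_a!r} is not a mating test")
        if self.outcome not in OUTCOMES:
            raise MatingDataError(
                f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}")


class MatingMatrix:
    """Pairing records plus optional group/population labels per isolate.

    Internally a pandas DataFrame (isolate_a, isolate_b, outcome, replicate)
    with isolate pairs stored in sorted order, so all derived statistics are
    invariant to record order and to which isolate was listed first.
    """

    def __init__(self, records: Iterable[PairingRecord] | pd.DataFrame,
                 groups: Optional[Mapping[str, str]] = None,
                 populations: Optional[Mapping[str, str]] = None):
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame(
                [(r.isolate_a, r.isolate_b, r.outcome, r.replicate)
                 for r in records],
                columns=["isolate_a", "isolate_b", "outcome", "replicate"])
        if len(df):
            bad = set(df["outcome"]) - set(OUTCOMES)
            if bad:
                raise MatingDataError(f"unknown outcome token(s) {sorted(bad)}")
            if (df["isolate_a"] == df["isolate_b"]).any():
                raise MatingDataError("self-pairings present")
            swap = df["isolate_a"] > df["isolate_b"]
            a = df["isolate_a"].where(~swap, df["isolate_b"])
            b = df["isolate_b"].where(~swap, df["isolate_a"])
            df = df.assign(isolate_a=a, isolate_b=b)
        self.records = df.reset_index(drop=True)
        self.groups = dict(groups or {})
        self.populations = dict(populations or {})
        known = set(self.records["isolate_a"]) | set(self.records["isolate_b"])
        missing = known - set(self.groups) if self.groups else set()
        if self.groups and missing:
            raise MatingDataError(
                f"isolates without a group label: {sorted(missing)[:6]}")

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, records_path, groups_path=None) -> "MatingMatrix":
        df = pd.read_csv(records_path)
        need = {"isolate_a", "isolate_b", "outcome"}
        if not need <= set(df.columns):
            raise MatingDataError(
                f"records CSV must have columns {sorted(need)}")
        if "replicate" not in df.columns:
            df["replicate"] = 1
        groups = populations = None
        if groups_path is not None:
            gdf = pd.read_csv(groups_path)
            groups = dict(zip(gdf["isolate"], gdf["group"]))
            if "population" in gdf.columns:
                populations = dict(zip(gdf["isolate"],
                                       gdf["population"].fillna("")))
        return cls(df, groups=groups, populations=populations)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    # -- helpers -----------------------------------------------------------

    @property
    def isolates(self) -> List[str]:
        return sorted(set(self.records["isolate_a"])
                      | set(self.records["isolate_b"]))

    def group_of(self, isolate: str) -> str:
        return self.groups.get(isolate, isolate)

    def _with_groups(self) -> pd.DataFrame:
        df = self.records
        return df.assign(
            group_a=df["isolate_a"].map(self.group_of),
            group_b=df["isolate_b"].map(self.group_of))

    def pair_weights(self) -> pd.DataFrame:
        """Per isolate pair: n pairings and interfertile proportion."""
        df = self.records.assign(
            fert=(self.records["outcome"] == "CRUSTOSE_DIPLOID"))
        g = df.groupby(["isolate_a", "isolate_b"], sort=True).agg(
            n=("fert", "size"), weight=("fert", "mean"),
            scored=("outcome", lambda s: (s != "UNSCORED").sum()))
        return g.reset_index()


@dataclass(frozen=True)
class GroupPairSummary:
    """IF%/IS%/N for one pair of groups (full precision; round on display)."""

    group_a: str
    group_b: str
    if_pct: float
    is_pct: float
    n: int

    def __post_init__(self):
        if self.n > 0 and self.if_pct + self.is_pct > 100.0 + 1e-9:
            raise MatingDataError("IF + IS exceeds 100%")

    @property
    def undefined(self) -> bool:
        return self.n == 0

    def display(self) -> Tuple[float, float, int]:
        return (round(self.if_pct, 1), round(self.is_pct, 1), self.n)


def summarize_pair(matrix: MatingMatrix, group_a: str, group_b: str
                   ) -> GroupPairSummary:
    """IF/IS/N between two groups (or within one group when equal).

    N counts every pairing attempt including UNSCORED ones; percentages are
    over N, matching published tables where IF + IS < 100 implies an
    unclassified remainder.
    """
    known = set(matrix.groups.values()) if matrix.groups else set(
        matrix.isolates)
    for g in (group_a, group_b):
        if g not in known:
            raise MatingDataError(f"unknown group {g!r}")
    df = matrix._with_groups()
    lo, hi = sorted((group_a, group_b))
    sel = df[((df["group_a"] == lo) & (df["group_b"] == hi))
             | ((df["group_a"] == hi) & (df["group_b"] == lo))]
    n = len(sel)
    if n == 0:
        return GroupPairSummary(group_a, group_b, float("nan"),
                                float("nan"), 0)
    n_if = int((sel["outcome"] == "CRUSTOSE_DIPLOID").sum())
    n_is = int(sel["outcome"].isin(STERILE).sum())
    return GroupPairSummary(group_a, group_b,
                            100.0 * n_if / n, 100.0 * n_is / n, n)


def pair_table(matrix: MatingMatrix) -> pd.DataFrame:
    """IF/IS/N for every observed group pair (published-matrix analog)."""
    df = matrix._with_groups()
    swap = df["group_a"] > df["group_b"]
    lo = df["group_a"].where(~swap, df["group_b"])
    hi = df["group_b"].where(~swap, df["group_a"])
    df = df.assign(group_a=lo, group_b=hi,
                   fert=df["outcome"] == "CRUSTOSE_DIPLOID",
                   ster=df["outcome"].isin(STERILE))
    g = df.groupby(["group_a", "group_b"], sort=True).agg(
        n=("outcome", "size"), n_if=("fert", "sum"), n_is=("ster", "sum"))
    g["if_pct"] = 100.0 * g["n_if"] / g["n"]
    g["is_pct"] = 100.0 * g["n_is"] / g["n"]
    return g.reset_index()[["group_a", "group_b", "if_pct", "is_pct", "n"]]


@dataclass
class ISGPartition:
    """Intersterility groups with the isolate graph's edge table."""

    assignment: Dict[str, str]  # isolate -> ISG id
    edges: pd.DataFrame  # isolate_a, isolate_b, n, weight, within
    gene_flow_pairs: pd.DataFrame  # cross-component interfertile pairs

    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> Dict[str, frozenset]:
        out: Dict[str, set] = {}
        for isolate, isg in self.assignment.items():
            out.setdefault(isg, set()).add(isolate)
        return {k: frozenset(v) for k, v in out.items()}


def delimit_isgs(matrix: MatingMatrix, edge_threshold: float = 0.5,
                 linkage: str = "components") -> ISGPartition:
    """Partition isolates into intersterility groups.

    A graph is built over every isolate entering at least one scored
    pairing, with an edge where the pairwise interfertile proportion is
    >= ``edge_threshold``; ISGs are the connected components, named
    ``ISG01``... by smallest member isolate.  ``linkage="average"`` instead
    merges components by average-linkage agglomeration of pair weights,
    useful for dense designs; the default tolerates sparse ones.
    """
    if not 0 < edge_threshold <= 1:
        raise MatingDataError("edge_threshold must be in (0, 1]")
    weights = matrix.pair_weights()
    scored = weights[weights["scored"] > 0]
    if not len(scored):
        raise MatingDataError("matrix has no scored pairing")
    isolates = sorted(set(scored["isolate_a"]) | set(scored["isolate_b"]))
    graph = nx.Graph()
    graph.add_nodes_from(isolates)
    for row in scored.itertuples():
        if row.weight >= edge_threshold:
            graph.add_edge(row.isolate_a, row.isolate_b)
    if linkage == "average":
        comps = _average_linkage_components(scored, isolates, edge_threshold)
    elif linkage == "components":
        comps = [sorted(c) for c in nx.connected_components(graph)]
    else:
        raise MatingDataError(f"unknown linkage {linkage!r}")
    comps.sort(key=lambda c: c[0])
    assignment = {iso: f"ISG{i + 1:02d}"
                  for i, comp in enumerate(comps) for iso in comp}
    edges = scored.assign(
        within=[assignment[a] == assignment[b]
                for a, b in zip(scored["isolate_a"], scored["isolate_b"])])
    flow = edges[(~edges["within"]) & (edges["weight"] > 0)]
    return ISGPartition(assignment=assignment,
                        edges=edges.reset_index(drop=True),
                        gene_flow_pairs=flow.reset_index(drop=True))


def _average_linkage_components(scored: pd.DataFrame, isolates: List[str],
                                threshold: float) -> List[List[str]]:
    """Agglomerate isolates while the average pairwise weight between two
    clusters (over observed pairs) is >= threshold."""
    clusters: List[set] = [{i} for i in isolates]
    w = {(r.isolate_a, r.isolate_b): (r.weight, r.n)
         for r in scored.itertuples()}

    def avg(c1: set, c2: set) -> float:
        tot = cnt = 0.0
        for a in c1:
            for b in c2:
                key = (a, b) if a < b else (b, a)
                if key in w:
                    weight, n = w[key]
                    tot += weight * n
                    cnt += n
        return tot / cnt if cnt else 0.0

    merged = True
    while merged and len(clusters) > 1:
        merged = False
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a = avg(clusters[i], clusters[j])
                if a >= threshold and (best is None or a > best[0]):
                    best = (a, i, j)
        if best:
            _, i, j = best
            clusters[i] |= clusters[j]
            del clusters[j]
            merged = True
    return [sorted(c) for c in clusters]


def gene_flow_report(matrix: MatingMatrix, partition: ISGPartition,
                     report_min_pct: float = 10.0) -> List[GroupPairSummary]:
    """Distinct group pairs with IF% >= ``report_min_pct``, sorted by
    descending interfertility: the residual gene-flow table.

    Groups are the user-supplied labels (species), so population-restricted
    flow stays visible via ``matrix.populations`` in downstream reports.
    """
    table = pair_table(matrix)
    out = []
    for row in table.itertuples():
        if row.group_a == row.group_b:
            continue
        if row.if_pct >= report_min_pct:
            out.append(GroupPairSummary(row.group_a, row.group_b,
                                        row.if_pct, row.is_pct, int(row.n)))
    out.sort(key=lambda s: (-s.if_pct, s.group_a, s.group_b))
    return out


@dataclass(frozen=True)
class AssignmentResult:
    best_group: str
    if_by_group: Dict[str, float]
    ambiguous: bool
    partial_intersterility_pct: float  # IS% against the best group


def assign_unknown(matrix: MatingMatrix, unknown: Iterable[str],
                   panels: Mapping[str, Sequence[str]],
                   edge_threshold: float = 0.5,
                   partial_is_min: float = 25.0) -> AssignmentResult:
    """Assign an unknown isolate set against tester panels by interfertility.

    Returns the panel group with maximal IF%, flagged ambiguous when (i)
    two or more groups exceed ``edge_threshold`` x 100, (ii) the top two
    groups differ by under 10 percentage points, or (iii) the unknown shows
    substantial residual intersterility (IS% >= ``partial_is_min``) with
    even its best-matching panel — the situation of a divergent lineage
    only tentatively assignable to its closest group.
    """
    unknown = set(unknown)
    df = matrix.records
    if_by_group: Dict[str, float] = {}
    is_by_group: Dict[str, float] = {}
    for group, testers in panels.items():
        testers = set(testers)
        sel = df[(df["isolate_a"].isin(unknown) & df["isolate_b"].isin(testers))
                 | (df["isolate_b"].isin(unknown)
                    & df["isolate_a"].isin(testers))]
        if len(sel) == 0:
            continue
        if_by_group[group] = float(
            100.0 * (sel["outcome"] == "CRUSTOSE_DIPLOID").mean())
        is_by_group[group] = float(100.0 * sel["outcome"].isin(STERILE).mean())
    if not if_by_group:
        raise MatingDataError("unknown isolates have no scored pairing "
                              "against any panel")
    ranked = sorted(if_by_group.items(), key=lambda kv: (-kv[1], kv[0]))
    best = ranked[0][0]
    above = [g for g, pct in ranked if pct >= edge_threshold * 100.0]
    close = (len(ranked) > 1 and ranked[0][1] - ranked[1][1] < 10.0)
    partial_is = is_by_group.get(best, 0.0)
    return AssignmentResult(
        best_group=best, if_by_group=dict(ranked),
        ambiguous=len(above) >= 2 or close or partial_is >= partial_is_min,
        partial_intersterility_pct=partial_is)
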