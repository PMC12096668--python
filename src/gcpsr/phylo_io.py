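"""Reading, writing and basic manipulation of support-annotated trees and
aligned sequence blocks.

Trees are the raw material of genealogical-concordance species delimitation:
per-locus maximum-parsimony and Bayesian consensus trees whose internal nodes
carry bootstrap proportions (MPBP), likelihood bootstrap supports (MLBS)
and/or posterior probabilities (BPP), plus a concatenated multi-gene species
tree annotated with all three.  This module parses those trees (via dendropy)
into :class:`SupportTree` objects, extracts their unrooted bipartitions with
the attached support records, and provides supermatrix concatenation of
per-locus alignment blocks with partition bookkeeping.

Support scale is always 0-100 internally; posterior probabilities given as
values in [0, 1] can be rescaled on read (``bpp_as_probability=True``).
Partition coordinates are 0-based half-open internally and exported 1-based
inclusive (the convention of common partition files).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
from Bio import SeqIO

from .errors import (
    AlignmentError,
    SupportValueError,
    TaxonSetError,
    TreeParseError,
)

__all__ = [
    "SupportRecord",
    "Bipartition",
    "SupportTree",
    "AlignmentBlock",
    "Supermatrix",
    "read_support_tree",
    "write_support_tree",
    "extract_bipartitions",
    "read_alignment_fasta",
    "concatenate_alignments",
    "write_partition_definitions",
]

ANALYSIS_TAGS = ("MP_CONSENSUS", "BAYES_CONSENSUS", "SPECIES_TREE", "OTHER")

#: Named support-label dialects.  A dialect maps the "/"-separated tokens of
#: an internal-node label to support fields.  ``triple`` is adaptive the way
#: concatenated-tree figures are usually annotated: three tokens are
#: MPBP/MLBS/BPP, two tokens are MLBS/BPP.
DIALECTS: Dict[str, Tuple[Tuple[str, ...], ...]] = {
    "mpbp": (("mpbp",),),
    "mlbs": (("mlbs",),),
    "bpp": (("bpp",),),
    "mpbp/bpp": (("mpbp", "bpp"),),
    "mlbs/bpp": (("mlbs", "bpp"),),
    "mpbp/mlbs/bpp": (("mpbp", "mlbs", "bpp"), ("mlbs", "bpp")),
}


@dataclass(frozen=True)
class SupportRecord:
    """Per-node support values on the 0-100 scale; absent values are None."""

    mpbp: Optional[float] = None
    mlbs: Optional[float] = None
    bpp: Optional[float] = None

    def __post_init__(self):
        for name in ("mpbp", "mlbs", "bpp"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise SupportValueError(
                    f"{name} support {v!r} outside [0, 100]"
                )

    def is_empty(self) -> bool:
        return self.mpbp is None and self.mlbs is None and self.bpp is None

    def merged_with(self, other: "SupportRecord") -> "SupportRecord":
        """Field-wise merge, preferring values from ``self``."""
        return SupportRecord(
            mpbp=self.mpbp if self.mpbp is not None else other.mpbp,
            mlbs=self.mlbs if self.mlbs is not None else other.mlbs,
            bpp=self.bpp if self.bpp is not None else other.bpp,
        )


def _fmt_support(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of a taxon universe, stored as one side.

    Equality and hashing are *unrooted*: a bipartition equals another when
    they cut the same universe into the same two parts, whichever side was
    used to construct them.  ``clade_side`` keeps the rooted reading (the
    leaf set below a node) for uses that care, e.g. species membership.
    """

    clade_side: frozenset
    universe: frozenset

    def __post_init__(self):
        if not self.clade_side <= self.universe:
            raise TaxonSetError(
                "clade side is not a subset of the universe",
                self.clade_side - self.universe,
            )

    @property
    def complement(self) -> frozenset:
        return self.universe - self.clade_side

    @property
    def is_trivial(self) -> bool:
        return len(self.clade_side) < 2 or len(self.complement) < 2

    def key(self) -> frozenset:
        """Canonical unrooted identity: the frozenset of both sides."""
        return frozenset((self.clade_side, self.complement))

    def restrict(self, taxa: frozenset) -> "Bipartition":
        """Induced bipartition on a taxon subset (e.g. one locus's taxa)."""
        taxa = frozenset(taxa)
        return Bipartition(self.clade_side & taxa, taxa)

    def __eq__(self, other):
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.universe == other.universe and self.key() == other.key()

    def __hash__(self):
        return hash((self.universe, self.key()))

    def __repr__(self):
        side = ",".join(sorted(self.clade_side))
        return f"Bipartition({{{side}}} | rest of {len(self.universe)})"


class SupportTree:
    """A rooted tree whose internal nodes carry optional support records.

    Thin wrapper over a :class:`dendropy.Tree`; every non-leaf node gets a
    ``supports`` attribute (a :class:`SupportRecord`).  Instances also carry
    the locus name (or ``"concatenated"``) and an analysis tag used to pick
    a default support-label dialect.
    """

    def __init__(self, tree: dendropy.Tree, locus: str = "",
                 analysis_tag: str = "OTHER"):
        if analysis_tag not in ANALYSIS_TAGS:
            raise ValueError(f"unknown analysis_tag {analysis_tag!r}")
        self.tree = tree
        self.locus = locus
        self.analysis_tag = analysis_tag
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = {x for x in labels if labels.count(x) > 1}
            raise TaxonSetError("duplicate leaf labels", dupes)
        self._taxa = frozenset(labels)
        for node in tree.preorder_node_iter():
            if not hasattr(node, "supports"):
                node.supports = SupportRecord()

    # -- basic accessors --------------------------------------------------

    @property
    def taxa(self) -> frozenset:
        return self._taxa

    def n_leaves(self) -> int:
        return len(self._taxa)

    @staticmethod
    def _leafset(node) -> frozenset:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def clades(self, include_root: bool = False):
        """Yield ``(leafset, SupportRecord)`` for internal nodes (rooted)."""
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node is self.tree.seed_node and not include_root:
                continue
            yield self._leafset(node), node.supports

    def clade_supports(self) -> Dict[frozenset, SupportRecord]:
        """Rooted clade -> support record (root excluded)."""
        out: Dict[frozenset, SupportRecord] = {}
        for leafset, rec in self.clades():
            out[leafset] = rec.merged_with(out.get(leafset, SupportRecord()))
        return out

    def bipartition_supports(self) -> Dict[frozenset, SupportRecord]:
        """Canonical unrooted bipartition key -> support record.

        One entry per internal edge; the two root-adjacent edges of a rooted
        binary tree induce the same split and are merged.  The result is
        cached: trees are treated as immutable once constructed.
        """
        cached = getattr(self, "_bip_cache", None)
        if cached is not None:
            return cached
        out: Dict[frozenset, SupportRecord] = {}
        for leafset, rec in self.clades():
            bip = Bipartition(leafset, self._taxa)
            if bip.is_trivial:
                continue
            key = bip.key()
            out[key] = out.get(key, SupportRecord()).merged_with(rec)
        self._bip_cache = out
        return out

    def displays(self, bip: Bipartition) -> bool:
        """True if this tree contains ``bip`` restricted to its own taxa.

        The restriction rule of clade comparison across loci with unequal
        specimen coverage: a restriction with fewer than 2 members, or an
        empty complement, counts as absent; a restriction whose complement
        is a single taxon is a trivial split displayed by every tree.
        """
        r = bip.restrict(self._taxa)
        if len(r.clade_side) < 2 or len(r.complement) < 1:
            return False
        if len(r.complement) == 1:
            return True
        return r.key() in self.bipartition_supports()

    def support_for(self, bip: Bipartition) -> Optional[SupportRecord]:
        r = bip.restrict(self._taxa)
        if len(r.clade_side) < 2 or len(r.complement) < 2:
            return None
        return self.bipartition_supports().get(r.key())

    # -- construction -----------------------------------------------------

    @classmethod
    def from_clades(cls, clades: Mapping[frozenset, SupportRecord],
                    universe: Iterable[str], locus: str = "",
                    analysis_tag: str = "OTHER") -> "SupportTree":
        """Build a rooted tree displaying exactly a laminar family of clades.

        ``clades`` must be pairwise nested-or-disjoint subsets of
        ``universe`` with 2 <= |clade| < |universe|.  Taxa contained in no
        clade attach directly to the root.
        """
        universe = sorted(set(universe))
        uset = frozenset(universe)
        for c in clades:
            if not 2 <= len(c) < len(uset) or not c <= uset:
                raise TaxonSetError(f"invalid clade of size {len(c)}", c - uset)
        ordered = sorted(clades, key=lambda c: (-len(c), sorted(c)))
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                if a & b and not b <= a:
                    raise TaxonSetError(
                        "clades are not laminar (nested-or-disjoint)", a & b)

        tns = dendropy.TaxonNamespace(universe)
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node.supports = SupportRecord()
        node_for: Dict[frozenset, dendropy.Node] = {uset: tree.seed_node}
        parents: List[frozenset] = [uset]
        for c in ordered:
            parent = min((p for p in parents if c <= p), key=len)
            node = dendropy.Node()
            node.supports = clades[c]
            node_for[parent].add_child(node)
            node_for[c] = node
            parents.append(c)
        for label in universe:
            parent = min((p for p in parents if label in p), key=len)
            leaf = dendropy.Node()
            leaf.taxon = tns.get_taxon(label)
            leaf.supports = SupportRecord()
            node_for[parent].add_child(leaf)
        return cls(tree, locus=locus, analysis_tag=analysis_tag)


# ---------------------------------------------------------------------------
# reading / writing

def _resolve_dialect(dialect: Optional[str], analysis_tag: str):
    if dialect is None or dialect == "auto":
        dialect = {"MP_CONSENSUS": "mpbp",
                   "BAYES_CONSENSUS": "bpp",
                   "SPECIES_TREE": "mpbp/mlbs/bpp"}.get(analysis_tag)
        if dialect is None:
            raise TreeParseError(
                "no support dialect given and analysis_tag does not imply one")
    if dialect not in DIALECTS:
        raise TreeParseError(
            f"unknown support dialect {dialect!r}; known: {sorted(DIALECTS)}")
    return DIALECTS[dialect]


def _parse_support_label(label: str, layouts, bpp_as_probability: bool
                         ) -> SupportRecord:
    tokens = label.split("/")
    layout = next((lay for lay in layouts if len(lay) == len(tokens)), None)
    if layout is None:
        raise TreeParseError(
            f"support label {label!r} has {len(tokens)} field(s); dialect "
            f"expects {sorted({len(l) for l in layouts})}")
    values: Dict[str, float] = {}
    for name, tok in zip(layout, tokens):
        tok = tok.strip()
        if tok in ("", "-", "*"):
            continue
        try:
            v = float(tok)
        except ValueError as exc:
            raise TreeParseError(
                f"support token {tok!r} is not numeric") from exc
        if name == "bpp" and bpp_as_probability:
            v *= 100.0
        values[name] = v
    return SupportRecord(**values)


def read_support_tree(text: str, dialect: Optional[str] = None,
                      schema: str = "newick", locus: str = "",
                      analysis_tag: str = "OTHER",
                      bpp_as_probability: bool = False) -> SupportTree:
    """Parse a Newick/NEXUS tree whose internal-node labels encode supports.

    Parameters
    ----------
    dialect:
        Key of :data:`DIALECTS` describing how "/"-separated label tokens map
        to MPBP/MLBS/BPP, or ``None``/``"auto"`` to infer from
        ``analysis_tag`` (MP consensus -> single MPBP value, Bayesian
        consensus -> single BPP value, species tree -> adaptive triple).
    bpp_as_probability:
        Rescale BPP tokens from [0, 1] to the internal 0-100 scale.
    """
    layouts = _resolve_dialect(dialect, analysis_tag)
    try:
        tree = dendropy.Tree.get(
            data=text, schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeParseError(f"could not parse {schema} tree: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.supports = SupportRecord()
            continue
        label = (node.label or "").strip()
        node.supports = (
            SupportRecord() if not label
            else _parse_support_label(label, layouts, bpp_as_probability)
        )
    return SupportTree(tree, locus=locus, analysis_tag=analysis_tag)


def _support_label(rec: SupportRecord, layout: Sequence[str],
                   pad_full: bool = False) -> str:
    present = [f for f in layout if getattr(rec, f) is not None]
    if not present:
        return ""
    # keep positional meaning: emit fields up to the last present one with
    # "-" for gaps (re-read as absent); adaptive dialects always write the
    # full layout so the token count stays unambiguous.
    last = len(layout) - 1 if pad_full else max(
        layout.index(f) for f in present)
    toks = []
    for f in layout[: last + 1]:
        v = getattr(rec, f)
        toks.append("-" if v is None else _fmt_support(v))
    return "/".join(toks)


def write_support_tree(st: SupportTree, dialect: Optional[str] = None,
                       schema: str = "newick") -> str:
    """Serialize deterministically, supports re-encoded as node labels.

    Children are emitted in input order; branch lengths are written when
    present.  Round-tripping through :func:`read_support_tree` with the same
    dialect preserves the bipartition set and every support value exactly.
    """
    layouts = _resolve_dialect(dialect, st.analysis_tag)
    layout = layouts[0]
    pad_full = len(layouts) > 1

    def render(node) -> str:
        if node.is_leaf():
            s = node.taxon.label
        else:
            inner = ",".join(render(ch) for ch in node.child_nodes())
            s = f"({inner}){_support_label(node.supports, layout, pad_full)}"
        if node.edge.length is not None:
            s += f":{node.edge.length:g}"
        return s

    newick = render(st.tree.seed_node) + ";"
    if schema == "newick":
        return newick + "\n"
    if schema == "nexus":
        return ("#NEXUS\nbegin trees;\n"
                f"    tree {st.locus or 'tree1'} = [&R] {newick}\n"
                "end;\n")
    raise TreeParseError(f"unsupported output schema {schema!r}")


def extract_bipartitions(st: SupportTree
                         ) -> List[Tuple[Bipartition, SupportRecord]]:
    """All non-trivial unrooted bipartitions with their support records.

    One entry per internal edge; the duplicate split at the root of a
    bifurcating rooted tree is merged.  A star tree yields an empty list.
    """
    out = []
    for key, rec in st.bipartition_supports().items():
        sides = sorted(key, key=lambda s: (len(s), sorted(s)))
        out.append((Bipartition(sides[0], st.taxa), rec))
    out.sort(key=lambda br: (len(br[0].clade_side), sorted(br[0].clade_side)))
    return out


# ---------------------------------------------------------------------------
# alignments and supermatrix

_IUPAC = set("ACGTURYSWKMBDHVN")
_GAPLIKE = set("-?.")


@dataclass(frozen=True)
class AlignmentBlock:
    """One locus's aligned sequences: taxon label -> aligned string."""

    locus: str
    rows: Mapping[str, str]
    aligned_length: int = field(default=0)

    def __post_init__(self):
        if not self.rows:
            raise AlignmentError(f"alignment block {self.locus!r} is empty")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"block {self.locus!r}: unequal row lengths {sorted(lengths)}")
        (length,) = lengths
        if self.aligned_length == 0:
            object.__setattr__(self, "aligned_length", length)
        elif self.aligned_length != length:
            raise AlignmentError(
                f"block {self.locus!r}: declared length {self.aligned_length} "
                f"!= actual {length}")
        for taxon, seq in self.rows.items():
            bad = set(seq.upper()) - _IUPAC - _GAPLIKE
            if bad:
                raise AlignmentError(
                    f"block {self.locus!r}, row {taxon!r}: non-IUPAC "
                    f"symbol(s) {sorted(bad)}")


def read_alignment_fasta(source, locus: str) -> AlignmentBlock:
    """Read one locus from a FASTA file/handle/string into a block."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    rows: Dict[str, str] = {}
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in rows:
            raise AlignmentError(f"duplicate FASTA record {rec.id!r}")
        rows[rec.id] = str(rec.seq)
    return AlignmentBlock(locus=locus, rows=rows)


@dataclass(frozen=True)
class Supermatrix:
    """Concatenated alignment with 0-based half-open partition coordinates."""

    rows: Mapping[str, str]
    partitions: Mapping[str, Tuple[int, int]]

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.partitions.values())


def concatenate_alignments(blocks: Sequence[AlignmentBlock],
                           taxa: Iterable[str],
                           missing_symbol: str = "?") -> Supermatrix:
    """Concatenate per-locus blocks over a common taxon set.

    Every taxon gets a row; a taxon unsequenced at a locus is padded with
    ``missing_symbol`` (default ``"?"``, deliberately distinct from the
    alignment gap ``"-"``) across that partition.  A taxon present in a
    block but absent from ``taxa`` is an error listing the offenders.
    """
    taxa = list(dict.fromkeys(taxa))
    if not taxa:
        raise AlignmentError("empty taxon set")
    loci = [b.locus for b in blocks]
    if len(loci) != len(set(loci)):
        dupes = sorted({x for x in loci if loci.count(x) > 1})
        raise AlignmentError(f"duplicate locus names: {dupes}")
    taxon_set = set(taxa)
    for b in blocks:
        extra = set(b.rows) - taxon_set
        if extra:
            raise AlignmentError(
                f"block {b.locus!r} contains taxa absent from the taxon set: "
                f"{sorted(extra)}")
    parts: Dict[str, Tuple[int, int]] = {}
    pieces: Dict[str, List[str]] = {t: [] for t in taxa}
    pos = 0
    for b in blocks:
        parts[b.locus] = (pos, pos + b.aligned_length)
        pos += b.aligned_length
        pad = missing_symbol * b.aligned_length
        for t in taxa:
            pieces[t].append(b.rows.get(t, pad))
    rows = {t: "".join(ps) for t, ps in pieces.items()}
    return Supermatrix(rows=rows, partitions=parts)


def write_partition_definitions(sm: Supermatrix) -> str:
    """Partition file text: one ``locus = start-end`` line, 1-based inclusive,
    in supermatrix order."""
    lines = []
    for locus, (s, e) in sorted(sm.partitions.items(), key=lambda kv: kv[1][0]):
        lines.append(f"{locus} = {s + 1}-{e}")
    return "\n".join(lines) + "\n"
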