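"""Time trees, alignments, trait tables and their I/O.

The central object is :class:`TimeTree`: a rooted, strictly bifurcating
phylogeny whose node *heights* measure time before the most recent sampled
tip.  Calendar dates (decimal years) exist only at the I/O boundary; inside
the package every time is a height.  The module also provides alignment
containers with site-pattern compression, tab-delimited trait/date tables,
posterior tree logs in the NEXUS trees-block dialect, and maximum clade
credibility (MCC) summarization of a posterior tree sample.

Newick/NEXUS parsing is delegated to dendropy; FASTA to Biopython.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "TimeTree",
    "Alignment",
    "PatternSet",
    "TraitTable",
    "parse_newick",
    "write_newick",
    "read_fasta",
    "write_fasta",
    "read_nexus_alignment",
    "read_tree_log",
    "write_tree_log",
    "read_table",
    "parse_tip_dates",
    "compress_patterns",
    "mcc_tree",
    "NUCLEOTIDE_STATES",
    "IUPAC_PARTIALS",
]

# --------------------------------------------------------------------------
# Character state conventions
# --------------------------------------------------------------------------

NUCLEOTIDE_STATES = "ACGT"

#: IUPAC code -> tuple of compatible nucleotide indices (A,C,G,T).
#: Gaps and unknowns are fully ambiguous, the standard pruning convention.
IUPAC_PARTIALS: Dict[str, Tuple[int, ...]] = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,), "U": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3), "-": (0, 1, 2, 3), "?": (0, 1, 2, 3), "X": (0, 1, 2, 3),
}


# --------------------------------------------------------------------------
# TimeTree
# --------------------------------------------------------------------------

class TimeTree:
    """Rooted binary tree with node heights (time before the latest tip).

    Nodes are integers ``0 .. 2n-2``; tips are ``0 .. n-1`` in the order of
    ``taxa``, internal nodes follow.  ``parent[v]`` is ``-1`` for the root;
    ``children[v]`` is empty for tips and has exactly two entries for
    internal nodes.  Heights are nonnegative, with ``heights[parent] >
    heights[child]`` strictly on every edge.
    """

    __slots__ = ("taxa", "parent", "children", "heights", "annotations")

    def __init__(
        self,
        taxa: Sequence[str],
        parent: Sequence[int],
        children: Sequence[Sequence[int]],
        heights: Sequence[float],
        annotations: Optional[Dict[int, Dict[str, object]]] = None,
        validate: bool = True,
    ):
        self.taxa: List[str] = list(taxa)
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.children: List[List[int]] = [list(c) for c in children]
        self.heights = np.asarray(heights, dtype=float).copy()
        self.annotations: Dict[int, Dict[str, object]] = {
            int(k): dict(v) for k, v in (annotations or {}).items()
        }
        if validate:
            self.validate()

    # -- basic structure ----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.heights)

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValidationError(f"tree has {len(roots)} roots, expected 1")
        return int(roots[0])

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def branch_length(self, v: int) -> float:
        """Duration of the edge above node ``v`` (0.0 for the root)."""
        p = self.parent[v]
        if p < 0:
            return 0.0
        return float(self.heights[p] - self.heights[v])

    def postorder(self) -> List[int]:
        """Children-before-parents node ordering (iterative)."""
        order: List[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> List[int]:
        return list(reversed(self.postorder()))

    def tip_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise ValidationError(f"taxon {label!r} not in tree") from None

    def copy(self) -> "TimeTree":
        return TimeTree(
            self.taxa, self.parent, self.children, self.heights,
            self.annotations, validate=False,
        )

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        n, m = self.n_tips, self.n_nodes
        if n < 2:
            raise ValidationError("tree needs at least 2 tips")
        if m != 2 * n - 1:
            raise ValidationError(f"{m} nodes inconsistent with {n} tips")
        if len(set(self.taxa)) != n:
            raise ValidationError("duplicate taxon labels")
        _ = self.root  # exactly one root
        for v in range(m):
            kids = self.children[v]
            if v < n:
                if kids:
                    raise ValidationError(f"tip {v} has children")
            elif len(kids) != 2:
                raise ValidationError(f"internal node {v} has {len(kids)} children")
            for c in kids:
                if self.parent[c] != v:
                    raise ValidationError("parent/child links disagree")
                if not self.heights[v] > self.heights[c]:
                    raise ValidationError(
                        f"non-positive branch: h[{v}]={self.heights[v]} "
                        f"<= h[{c}]={self.heights[c]}"
                    )
        if np.any(self.heights < -1e-12):
            raise ValidationError("negative node height")
        if len(self.postorder()) != m:
            raise ValidationError("tree is not connected")

    # -- clade bitsets -------------------------------------------------------

    def clades(self) -> Dict[int, int]:
        """Map internal node -> clade bitmask over the tip ordering of ``taxa``.

        Bit ``i`` corresponds to ``sorted(self.taxa)[i]`` so that masks are
        comparable across trees sharing a taxon set.
        """
        rank = {t: i for i, t in enumerate(sorted(self.taxa))}
        masks: Dict[int, int] = {}
        for v in self.postorder():
            if self.is_tip(v):
                masks[v] = 1 << rank[self.taxa[v]]
            else:
                c1, c2 = self.children[v]
                masks[v] = masks[c1] | masks[c2]
        return masks

    # -- text representation --------------------------------------------------

    def newick(self, precision: int = 12, annotations: bool = False) -> str:
        return write_newick(self, precision=precision, annotations=annotations)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TimeTree n_tips={self.n_tips} root_height={self.heights[self.root]:.4g}>"


# --------------------------------------------------------------------------
# Newick parsing / writing
# --------------------------------------------------------------------------

def parse_newick(
    text: str,
    date_map: Optional[Mapping[str, float]] = None,
    date_tol: float = 1e-6,
) -> TimeTree:
    """Parse a Newick string with branch lengths into a :class:`TimeTree`.

    Heights are computed from root-to-tip path lengths: the deepest tip sits
    at height 0.  When ``date_map`` (taxon -> decimal year) is given, the
    implied tip heights ``latest date - tip date`` must agree with the
    path-derived heights to within ``date_tol`` — the dates anchor the
    calendar, the branch lengths fix the geometry.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"Newick parse failure: {exc}") from exc

    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(lb is None for lb in labels):
        raise ParseError("unlabeled tip")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate taxon labels in Newick")

    # Collapse a unary root (dendropy keeps a root edge seed node).
    seed = dtree.seed_node
    while len(seed.child_nodes()) == 1:
        seed = seed.child_nodes()[0]

    # depth from (effective) root
    depth: Dict[dendropy.Node, float] = {seed: 0.0}
    nodes_pre: List[dendropy.Node] = []
    stack = [seed]
    while stack:
        nd = stack.pop()
        nodes_pre.append(nd)
        for ch in nd.child_nodes():
            bl = ch.edge.length
            if bl is None:
                raise ParseError("missing branch length")
            if bl < 0:
                raise ValidationError(f"negative branch length {bl}")
            depth[ch] = depth[nd] + float(bl)
            stack.append(ch)

    for nd in nodes_pre:
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            raise ValidationError(
                f"non-bifurcating node with {len(kids)} children (polytomies unsupported)"
            )

    max_depth = max(depth[lf] for lf in leaves)
    taxa = [lf.taxon.label for lf in leaves]
    index: Dict[dendropy.Node, int] = {lf: i for i, lf in enumerate(leaves)}
    internals = [nd for nd in nodes_pre if nd.child_nodes()]
    for j, nd in enumerate(internals):
        index[nd] = len(taxa) + j

    m = 2 * len(taxa) - 1
    parent = np.full(m, -1, dtype=np.int64)
    children: List[List[int]] = [[] for _ in range(m)]
    heights = np.zeros(m)
    for nd in nodes_pre:
        v = index[nd]
        heights[v] = max_depth - depth[nd]
        for ch in nd.child_nodes():
            parent[index[ch]] = v
            children[v].append(index[ch])

    tree = TimeTree(taxa, parent, children, heights)

    if date_map is not None:
        missing = [t for t in taxa if t not in date_map]
        if missing:
            raise ValidationError(f"tips missing from date map: {missing}")
        latest = max(date_map[t] for t in taxa)
        for i, t in enumerate(taxa):
            implied = latest - float(date_map[t])
            if abs(implied - heights[i]) > date_tol:
                raise ValidationError(
                    f"tip {t!r}: date-implied height {implied:.6g} disagrees "
                    f"with path-derived height {heights[i]:.6g}"
                )
    return tree


def _annot_string(ann: Dict[str, object]) -> str:
    if not ann:
        return ""
    parts = []
    for k, v in ann.items():
        if isinstance(v, float):
            parts.append(f"{k}={v:.6g}")
        else:
            parts.append(f"{k}={v}")
    return "[&" + ",".join(parts) + "]"


def write_newick(tree: TimeTree, precision: int = 12, annotations: bool = False) -> str:
    """Serialize a :class:`TimeTree` to Newick with branch lengths."""

    def rec(v: int) -> str:
        ann = _annot_string(tree.annotations.get(v, {})) if annotations else ""
        if tree.is_tip(v):
            core = tree.taxa[v] + ann
        else:
            c1, c2 = tree.children[v]
            core = f"({rec(c1)},{rec(c2)})" + ann
        p = tree.parent[v]
        if p < 0:
            return core
        bl = tree.heights[p] - tree.heights[v]
        return f"{core}:{bl:.{precision}g}"

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        return rec(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


# --------------------------------------------------------------------------
# Tip dates
# --------------------------------------------------------------------------

_DATE_SUFFIX = re.compile(r"_(\d{3,4}(?:\.\d+)?)$")


def parse_tip_dates(
    taxa: Iterable[str],
    date_table: Optional[Mapping[str, float]] = None,
) -> Dict[str, float]:
    """Extract decimal-year tip dates.

    A trailing ``_<decimal year>`` in the taxon label supplies the date; an
    explicit ``date_table`` entry overrides the label.  Taxa with neither are
    omitted from the result.
    """
    out: Dict[str, float] = {}
    for t in taxa:
        if date_table is not None and t in date_table:
            out[t] = float(date_table[t])
            continue
        m = _DATE_SUFFIX.search(t)
        if m:
            out[t] = float(m.group(1))
    return out


# --------------------------------------------------------------------------
# Alignment / PatternSet
# --------------------------------------------------------------------------

@dataclass
class Alignment:
    """Taxa-by-sites character matrix over the nucleotide alphabet.

    ``partitions`` maps a partition name to a half-open site range
    ``(start, stop)``; the default is one partition covering everything.
    """

    taxa: List[str]
    sequences: List[str]
    partitions: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValidationError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels in alignment")
        if not self.sequences:
            raise ValidationError("empty alignment")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValidationError("unequal sequence lengths")
        self.sequences = [s.upper() for s in self.sequences]
        for ch in set("".join(self.sequences)):
            if ch not in IUPAC_PARTIALS:
                raise ValidationError(f"unknown character {ch!r}")
        if not self.partitions:
            self.partitions = {"all": (0, L)}

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def row(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def check_matches_tree(self, tree: TimeTree) -> None:
        if set(self.taxa) != set(tree.taxa):
            raise ValidationError("alignment and tree taxon sets differ")


@dataclass
class PatternSet:
    """Unique weighted site patterns of one alignment partition.

    ``patterns`` is an ``(n_taxa, n_patterns)`` array of characters; weights
    sum to the partition length.  Taxon order matches ``taxa``.
    """

    taxa: List[str]
    patterns: np.ndarray  # dtype '<U1'
    weights: np.ndarray   # int

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def tip_partials(self, states: str = NUCLEOTIDE_STATES) -> np.ndarray:
        """(n_taxa, K, n_patterns) array of tip partial likelihoods."""
        K = len(states)
        out = np.zeros((len(self.taxa), K, self.n_patterns))
        for i in range(len(self.taxa)):
            for p in range(self.n_patterns):
                ch = self.patterns[i, p]
                idx = IUPAC_PARTIALS.get(ch)
                if idx is None:
                    raise ValidationError(f"unknown character {ch!r}")
                out[i, list(idx), p] = 1.0
        return out


def compress_patterns(aln: Alignment, site_range: Optional[Tuple[int, int]] = None) -> PatternSet:
    """Collapse identical alignment columns into weighted unique patterns."""
    if site_range is None:
        site_range = (0, aln.n_sites)
    start, stop = site_range
    if not (0 <= start < stop <= aln.n_sites):
        raise ValidationError(f"bad site range {site_range}")
    cols = np.array([list(s[start:stop]) for s in aln.sequences])  # taxa x sites
    uniq, inv, counts = np.unique(cols, axis=1, return_inverse=True, return_counts=True)
    return PatternSet(list(aln.taxa), uniq, counts.astype(np.int64))


# --------------------------------------------------------------------------
# Trait tables
# --------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Per-taxon discrete state labels or continuous vectors.

    ``values`` maps taxon -> state label (str) for discrete traits, or
    taxon -> 1-D float array for continuous traits.  ``missing`` flags taxa
    with no observation (treated as fully ambiguous downstream).
    """

    values: Dict[str, object]
    missing: set = field(default_factory=set)

    @property
    def is_discrete(self) -> bool:
        return all(isinstance(v, str) for v in self.values.values())

    def states(self) -> List[str]:
        if not self.is_discrete:
            raise ValidationError("continuous trait table has no state set")
        st = sorted({v for v in self.values.values()})
        if len(st) < 2:
            raise ValidationError("discrete trait needs at least 2 observed states")
        return st

    def check_complete(self, tree: TimeTree) -> None:
        absent = [t for t in tree.taxa if t not in self.values and t not in self.missing]
        if absent:
            raise ValidationError(f"taxa without trait values: {absent}")

    def vector_matrix(self, taxa: Sequence[str]) -> np.ndarray:
        """Stack continuous trait vectors in the given taxon order."""
        rows = []
        for t in taxa:
            v = self.values.get(t)
            if v is None:
                raise ValidationError(f"no continuous trait for {t!r}")
            rows.append(np.atleast_1d(np.asarray(v, dtype=float)))
        return np.vstack(rows)


def read_table(path_or_buf) -> "pd.DataFrame":
    """Read a tab-delimited table with a header row (taxon<TAB>value...)."""
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ParseError("table needs >= 2 tab-delimited columns")
    return df


def read_trait_table(path_or_buf, missing_token: str = "?") -> TraitTable:
    df = read_table(path_or_buf)
    values: Dict[str, object] = {}
    missing: set = set()
    for _, row in df.iterrows():
        taxon = str(row.iloc[0])
        rest = row.iloc[1:]
        if len(rest) == 1:
            v = rest.iloc[0]
            if isinstance(v, str) and v != missing_token:
                values[taxon] = v
            elif isinstance(v, str):
                missing.add(taxon)
            else:
                values[taxon] = np.array([float(v)])
        else:
            values[taxon] = rest.to_numpy(dtype=float)
    return TraitTable(values, missing)


# --------------------------------------------------------------------------
# FASTA / NEXUS I/O
# --------------------------------------------------------------------------

def read_fasta(path_or_buf) -> Alignment:
    from Bio import SeqIO

    handle = io.StringIO(path_or_buf) if "\n" in str(path_or_buf) else path_or_buf
    taxa, seqs = [], []
    for rec in SeqIO.parse(handle, "fasta"):
        taxa.append(rec.id)
        seqs.append(str(rec.seq))
    if not taxa:
        raise ParseError("no FASTA records found")
    return Alignment(taxa, seqs)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for t, s in zip(aln.taxa, aln.sequences):
            fh.write(f">{t}\n{s}\n")


def read_nexus_alignment(path_or_buf) -> Alignment:
    data = dendropy.DnaCharacterMatrix.get(
        path=str(path_or_buf), schema="nexus", preserve_underscores=True,
    )
    taxa = [tx.label for tx in data.taxon_namespace]
    seqs = [str(data[tx]).replace(" ", "") for tx in data.taxon_namespace]
    return Alignment(taxa, seqs)


def read_tree_log(path_or_buf, schema: str = "nexus") -> List[TimeTree]:
    """Read a posterior tree log (NEXUS trees block, translate table honored)."""
    kwargs = dict(schema=schema, preserve_underscores=True)
    if hasattr(path_or_buf, "read") or "\n" in str(path_or_buf):
        tl = dendropy.TreeList.get(data=str(path_or_buf), **kwargs)
    else:
        tl = dendropy.TreeList.get(path=str(path_or_buf), **kwargs)
    return [parse_newick(t.as_string(schema="newick").strip()) for t in tl]


def write_tree_log(trees: Sequence[TimeTree], path, labels: Optional[Sequence[str]] = None) -> None:
    """Write trees as a NEXUS trees block with a translate table."""
    if not trees:
        raise ValidationError("no trees to write")
    taxa = trees[0].taxa
    number = {t: i + 1 for i, t in enumerate(sorted(taxa))}
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin trees;\n\ttranslate\n")
        items = sorted(number.items(), key=lambda kv: kv[1])
        fh.write(",\n".join(f"\t\t{i} {t}" for t, i in items))
        fh.write(";\n")
        for k, tr in enumerate(trees):
            renamed = tr.copy()
            renamed.taxa = [str(number[t]) for t in tr.taxa]
            name = labels[k] if labels is not None else f"STATE_{k}"
            fh.write(f"tree {name} = [&R] {renamed.newick()}\n")
        fh.write("end;\n")


# --------------------------------------------------------------------------
# MCC summarization
# --------------------------------------------------------------------------

def mcc_tree(trees: Sequence[TimeTree], burnin_fraction: float) -> TimeTree:
    """Maximum clade credibility tree of a posterior sample.

    Discards the first ``burnin_fraction`` of the sample, tallies clade
    frequencies over the rest, and returns (a copy of) the sampled tree that
    maximizes the product of its clades' posterior frequencies.  Internal
    nodes are annotated with ``posterior`` (clade frequency) and
    ``height_mean`` (mean height over trees containing the clade).
    """
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValidationError("burnin_fraction must be in [0, 1)")
    start = int(len(trees) * burnin_fraction)
    kept = list(trees[start:])
    if len(kept) < 2:
        raise ValidationError("need >= 2 post-burnin trees")
    taxon_set = set(kept[0].taxa)
    for tr in kept:
        if set(tr.taxa) != taxon_set:
            raise ValidationError("inconsistent taxon sets in tree sample")

    counts: Dict[int, int] = {}
    height_sums: Dict[int, float] = {}
    per_tree_masks = []
    for tr in kept:
        masks = tr.clades()
        per_tree_masks.append(masks)
        seen = {}
        for v, mk in masks.items():
            if not tr.is_tip(v):
                seen[mk] = tr.heights[v]
        for mk, h in seen.items():
            counts[mk] = counts.get(mk, 0) + 1
            height_sums[mk] = height_sums.get(mk, 0.0) + h

    n = len(kept)
    best_idx, best_score = 0, -np.inf
    for k, (tr, masks) in enumerate(zip(kept, per_tree_masks)):
        score = sum(
            np.log(counts[mk] / n)
            for v, mk in masks.items() if not tr.is_tip(v)
        )
        if score > best_score:
            best_idx, best_score = k, score

    best = kept[best_idx].copy()
    masks = per_tree_masks[best_idx]
    for v, mk in masks.items():
        if best.is_tip(v):
            continue
        ann = best.annotations.setdefault(v, {})
        ann["posterior"] = counts[mk] / n
        ann["height_mean"] = height_sums[mk] / counts[mk]
    return best
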