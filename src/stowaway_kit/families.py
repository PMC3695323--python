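"""Family classification of mined elements.

Elements are grouped with the 80-80-80 rule (>= 80 % identity over >= 80 %
of the shorter sequence, elements >= 80 bp), families are single-linkage
connected components of that relation, per-family consensi come from a star
alignment to the longest member, and between-element distances use the
Kimura two-parameter model feeding a Saitou-Nei Neighbor-Joining tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._align import nw_align
from .sequences import iupac_consensus_code, IUPAC_EXPAND

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class SaturationError(ValueError):
    """K2P distance undefined: substitution proportions at/over saturation."""


@dataclass
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float      # matches / non-gap-pair columns
    coverage: float      # non-gap-pair columns / shorter raw length
    P: float             # transition proportion (over non-gap-pair columns)
    Q: float             # transversion proportion


def global_align(a: str, b: str, scoring: AlignmentScoring | None = None
                 ) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch alignment with affine gaps, end gaps
    penalized.  Identity, coverage and the K2P proportions P (transitions)
    and Q (transversions) are tallied over columns where both rows carry a
    base (pairwise deletion)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    sc = scoring or AlignmentScoring()
    a, b = a.upper(), b.upper()
    score, ai, bi = nw_align(a, b, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
    rows_a, rows_b = [], []
    matches = cols = transitions = transversions = 0
    for x, y in zip(ai, bi):
        ca = a[x] if x >= 0 else "-"
        cb = b[y] if y >= 0 else "-"
        rows_a.append(ca)
        rows_b.append(cb)
        if ca != "-" and cb != "-" and ca != "N" and cb != "N":
            cols += 1
            if ca == cb:
                matches += 1
            elif frozenset((ca, cb)) in _TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    identity = matches / cols if cols else 0.0
    coverage = cols / min(len(a), len(b))
    P = transitions / cols if cols else 0.0
    Q = transversions / cols if cols else 0.0
    return PairwiseAlignment("".join(rows_a), "".join(rows_b), float(score),
                             identity, coverage, P, Q)


def k2p_distance(aln: PairwiseAlignment | tuple[float, float]) -> float:
    """Kimura two-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    Raises :class:`SaturationError` outside the valid domain instead of
    returning NaN.
    """
    if isinstance(aln, PairwiseAlignment):
        P, Q = aln.P, aln.Q
    else:
        P, Q = aln
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"substitution proportions saturated (P={P:.4g}, Q={Q:.4g})")
    return -0.5 * math.log(w1 * math.sqrt(w2))


# ---------------------------------------------------------------------------
# 80-80-80 clustering


@dataclass
class ClusterParams:
    min_identity: float = 0.80
    min_coverage: float = 0.80
    min_length: int = 80


@dataclass
class Family:
    family_id: str
    member_ids: list[str]
    consensus: str
    mean_identity: float


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def related_8080(a: str, b: str, params: ClusterParams | None = None
                 ) -> tuple[bool, PairwiseAlignment]:
    """The 80-80 relation between two sequences (length filter excluded)."""
    params = params or ClusterParams()
    aln = global_align(a, b)
    ok = aln.identity >= params.min_identity and aln.coverage >= params.min_coverage
    return ok, aln


def cluster_families(elements: list[tuple[str, str]],
                     params: ClusterParams | None = None) -> list[Family]:
    """Partition (id, sequence) elements into 80-80-80 families.

    Families are single-linkage connected components of the pairwise
    relation; numbering is deterministic: descending size, then smallest
    member id.  Elements shorter than ``min_length`` are dropped.
    """
    if not elements:
        raise ValueError("empty element set")
    params = params or ClusterParams()
    kept = [(eid, seq) for eid, seq in elements if len(seq) >= params.min_length]
    if not kept:
        return []
    ids = [eid for eid, _ in kept]
    seqs = dict(kept)
    uf = _UnionFind(ids)
    identities: dict[frozenset, float] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ok, aln = related_8080(seqs[ids[i]], seqs[ids[j]], params)
            identities[frozenset((ids[i], ids[j]))] = aln.identity
            if ok:
                uf.union(ids[i], ids[j])
    groups: dict[str, list[str]] = {}
    for eid in ids:
        groups.setdefault(uf.find(eid), []).append(eid)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    families = []
    for k, members in enumerate(ordered, start=1):
        members = sorted(members)
        if len(members) > 1:
            pair_ids = [identities[frozenset((a, b))]
                        for i, a in enumerate(members) for b in members[i + 1:]]
            mean_ident = float(np.mean(pair_ids))
        else:
            mean_ident = 1.0
        consensus = build_consensus([seqs[m] for m in members])
        families.append(Family(f"F{k}", members, consensus, mean_ident))
    return families


def build_consensus(members: list[str]) -> str:
    """Star-alignment consensus: align every member to the longest one,
    take the per-column majority base on the reference coordinates, encode
    ties as IUPAC degenerate codes, and drop majority-gap columns."""
    if not members:
        raise ValueError("family has no members")
    if len(members) == 1:
        return members[0]
    ref_idx = max(range(len(members)), key=lambda i: len(members[i]))
    ref = members[ref_idx]
    columns: list[list[str]] = [[c] for c in ref]
    for idx, m in enumerate(members):
        if idx == ref_idx:
            continue
        aln = global_align(ref, m)
        ri = -1
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca != "-":
                ri += 1
                columns[ri].append(cb)  # cb may be '-'
    out = []
    for col in columns:
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        winners = {c for c, n in counts.items() if n == best}
        if "-" in winners:
            if len(winners) == 1 or counts.get("-", 0) > len(col) / 2:
                continue  # majority-gap column removed
            winners.discard("-")
        winners.discard("N")
        if not winners:
            continue
        out.append(next(iter(winners)) if len(winners) == 1
                   else iupac_consensus_code(winners))
    return "".join(out)


def mean_pairwise_identity(members: list[str]) -> float:
    """Average pairwise global-alignment identity over all member pairs."""
    if len(members) < 2:
        return 1.0
    vals = [global_align(a, b).identity
            for i, a in enumerate(members) for b in members[i + 1:]]
    return float(np.mean(vals))


def msa_column_identity(members: list[str]) -> float:
    """Star-MSA column identity: fraction of non-gap characters agreeing
    with the column majority, averaged over reference columns."""
    if len(members) < 2:
        return 1.0
    ref_idx = max(range(len(members)), key=lambda i: len(members[i]))
    ref = members[ref_idx]
    columns: list[list[str]] = [[c] for c in ref]
    for idx, m in enumerate(members):
        if idx == ref_idx:
            continue
        aln = global_align(ref, m)
        ri = -1
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca != "-":
                ri += 1
                if cb != "-":
                    columns[ri].append(cb)
    fracs = []
    for col in columns:
        if len(col) < 2:
            continue
        counts = {c: col.count(c) for c in set(col)}
        fracs.append(max(counts.values()) / len(col))
    return float(np.mean(fracs)) if fracs else 1.0


# ---------------------------------------------------------------------------
# distance matrices and Neighbor-Joining


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if (m < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        np.fill_diagonal(m, 0.0)
        self.matrix = m


def k2p_matrix(elements: list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise K2P distances from global alignments of all element pairs."""
    labels = [eid for eid, _ in elements]
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(global_align(elements[i][1], elements[j][1]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0          # branch to parent
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def _min_leaf(self) -> str:
        return min(l.name for l in self.leaves())

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        kids = sorted(self.children, key=lambda c: c._min_leaf())
        inner = ",".join(c._newick_inner() for c in kids)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"

    def leaf_distances(self) -> dict[frozenset, float]:
        """Path lengths between all leaf pairs."""
        dists: dict[frozenset, float] = {}

        def walk(node) -> list[tuple[str, float]]:
            if node.is_leaf():
                return [(node.name, node.length)]
            below: list[list[tuple[str, float]]] = [walk(c) for c in node.children]
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for na, da in below[i]:
                        for nb, db in below[j]:
                            dists[frozenset((na, nb))] = da + db
            merged = [(n, d + node.length) for sub in below for n, d in sub]
            return merged

        walk_result = walk(self)
        del walk_result
        return dists


def parse_newick(text: str) -> TreeNode:
    """Parse a newick string into a :class:`TreeNode` (via scikit-bio)."""
    import io
    from skbio import TreeNode as SkbioNode

    sk = SkbioNode.read(io.StringIO(text))

    def conv(n) -> TreeNode:
        node = TreeNode(name=n.name,
                        length=float(n.length) if n.length is not None else 0.0)
        node.children = [conv(c) for c in n.children]
        return node

    return conv(sk)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei Neighbor-Joining with deterministic tie-breaking.

    Ties in the Q criterion go to the lexicographically smallest label pair
    (internal nodes inherit the smallest leaf label beneath them).  Negative
    branch lengths are clamped to zero with the deficit moved to the sibling
    branch, preserving the pair's summed length.  Two taxa yield a single
    edge of length d (split evenly across the two child branches).
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in dm.labels}
    labels = list(dm.labels)
    d: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((labels[i], labels[j]))] = dm.matrix[i, j]

    def dist(a, b):
        return d[frozenset((a, b))]

    while len(labels) > 2:
        r = len(labels)
        R = {a: sum(dist(a, b) for b in labels if b != a) for a in labels}
        best = None
        best_pair = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = labels[i], labels[j]
                q = (r - 2) * dist(a, b) - R[a] - R[b]
                pair = tuple(sorted((a, b)))
                if best is None or q < best - 1e-12 or \
                        (abs(q - best) <= 1e-12 and pair < best_pair):
                    best, best_pair = q, pair
        a, b = best_pair
        dab = dist(a, b)
        la = 0.5 * dab + (R[a] - R[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        parent = TreeNode(children=[na, nb])
        new_label = min(a, b)
        for c in labels:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[frozenset((new_label, c))] = max(duc, 0.0)
        labels = [l for l in labels if l not in (a, b)]
        labels.append(new_label)
        labels.sort()
        nodes[new_label] = parent
    a, b = sorted(labels)
    dab = dist(a, b)
    na, nb = nodes[a], nodes[b]
    # the final edge of length d(a,b) is split across the two child branches;
    # every leaf-pair path length is preserved
    na.length = nb.length = dab / 2
    return TreeNode(children=[na, nb])


# ---------------------------------------------------------------------------
# TIR consensus table


@dataclass
class TIRConsensus:
    family_ids: list[str]
    tirs: list[str]             # flush-left, right-padded with '.'
    consensus: str              # per-column IUPAC consensus
    conserved_terminal_run: int  # longest run of non-degenerate columns from col 0


def tir_consensus(entries: list[tuple[str, str]]) -> TIRConsensus:
    """Align family left-TIRs flush at the terminus and build the IUPAC
    consensus row (e.g. a {T, C} column becomes 'Y'); reports the longest
    terminal run of non-degenerate consensus columns."""
    if not entries:
        raise ValueError("no TIR entries")
    for fid, tir in entries:
        if not tir:
            raise ValueError(f"family {fid} lacks a detected TIR")
    width = max(len(t) for _, t in entries)
    padded = [t.upper().ljust(width, ".") for _, t in entries]
    consensus = []
    for col in range(width):
        bases = {p[col] for p in padded if p[col] != "."}
        bases = {b for b in bases if b in "ACGT"} or {"N"}
        consensus.append(iupac_consensus_code(frozenset(bases))
                         if bases != {"N"} else "N")
    cons = "".join(consensus)
    run = 0
    for c in cons:
        if c in "ACGT":
            run += 1
        else:
            break
    return TIRConsensus([fid for fid, _ in entries], padded, cons, run)
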