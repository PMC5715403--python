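"""Alignment, conserved-block trimming and neighbor-joining trees.

The domain-split trees are built from a multiple alignment (progressive
aligner here, or an externally computed MSA read with
:func:`nifbkit.core_io.read_alignment_fasta`), trimmed to well-conserved
blocks, converted to Poisson-corrected p-distances and joined with the
standard rate-corrected neighbor-joining criterion.  Rooting places the root
at the midpoint of a designated outgroup leaf's branch.

NJ is exact on additive distance matrices: given leaf-to-leaf path distances
measured on any tree it reconstructs that tree's topology, which is the main
correctness oracle used by the test suite.  Determinism is guaranteed by a
lexicographic tie-break on the smallest leaf label of each cluster and by
clamping negative branch-length estimates to zero.

Trees are ``skbio.TreeNode`` objects; Newick is the exchange format.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .architecture import ArchitectureCall

# Distance corrections.
NONE = "NONE"
POISSON = "POISSON"

GAP = "-"


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """An ordered, equal-length set of gapped rows."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        length = len(self.rows[0][1])
        if any(len(seq) != length for _, seq in self.rows):
            raise ValueError("not an alignment: rows differ in length")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row identifiers in alignment")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def sequence(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.sequence(rid).replace(GAP, "")


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringConfig:
    """Scoring for the progressive aligner.

    ``gap_col`` is the linear per-column cost of inserting an all-gap column
    into a profile, and the score of pairing a gap with a residue; two gaps
    paired score zero.
    """

    matrix: str = "BLOSUM62"
    gap_col: float = -4.0


def _pair_distance(a: str, b: str, matrix) -> float:
    """1 - identity of the global pairwise alignment (guide-tree distance)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    n_cols = counts.identities + counts.mismatches + counts.gaps
    return 1.0 - (counts.identities / n_cols if n_cols else 0.0)


def _profile_merge(
    prof_a: list[str], prof_b: list[str], matrix, gap_col: float
) -> tuple[list[str], list[str]]:
    """Needleman-Wunsch on two profiles with average-of-pairs column scores."""

    def col_score(ca: str, cb: str) -> float:
        total = 0.0
        for x in ca:
            for y in cb:
                if x == GAP and y == GAP:
                    total += 0.0
                elif x == GAP or y == GAP:
                    total += gap_col
                else:
                    total += float(matrix[x, y])
        return total / (len(ca) * len(cb))

    la, lb = len(prof_a[0]), len(prof_b[0])
    cols_a = ["".join(s[j] for s in prof_a) for j in range(la)]
    cols_b = ["".join(s[j] for s in prof_b) for j in range(lb)]

    score = np.zeros((la + 1, lb + 1))
    move = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, la + 1):
        score[i, 0] = score[i - 1, 0] + gap_col
        move[i, 0] = 1
    for j in range(1, lb + 1):
        score[0, j] = score[0, j - 1] + gap_col
        move[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = score[i - 1, j - 1] + col_score(cols_a[i - 1], cols_b[j - 1])
            up = score[i - 1, j] + gap_col
            left = score[i, j - 1] + gap_col
            # deterministic preference: diagonal, then up, then left
            best, m = diag, 0
            if up > best:
                best, m = up, 1
            if left > best:
                best, m = left, 2
            score[i, j], move[i, j] = best, m

    out_a: list[list[str]] = [[] for _ in prof_a]
    out_b: list[list[str]] = [[] for _ in prof_b]
    i, j = la, lb
    while i > 0 or j > 0:
        m = move[i, j]
        if i > 0 and j > 0 and m == 0:
            for k, s in enumerate(prof_a):
                out_a[k].append(s[i - 1])
            for k, s in enumerate(prof_b):
                out_b[k].append(s[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and (m == 1 or j == 0):
            for k, s in enumerate(prof_a):
                out_a[k].append(s[i - 1])
            for k in range(len(prof_b)):
                out_b[k].append(GAP)
            i -= 1
        else:
            for k in range(len(prof_a)):
                out_a[k].append(GAP)
            for k, s in enumerate(prof_b):
                out_b[k].append(s[j - 1])
            j -= 1
    return (["".join(reversed(s)) for s in out_a],
            ["".join(reversed(s)) for s in out_b])


def align_progressive(
    records: Sequence, scoring: ScoringConfig = ScoringConfig()
) -> Alignment:
    """Progressive multiple alignment.

    Guide tree from average-linkage clustering of pairwise alignment
    distances; clusters are merged by profile-profile dynamic programming.
    Deterministic for a fixed input order and scoring configuration.
    """
    if len(records) < 2:
        raise ValueError("nothing to align: need at least 2 records")
    matrix = substitution_matrices.load(scoring.matrix)
    ids = [r.id for r in records]
    seqs = [r.sequence for r in records]
    n = len(records)

    if n == 2:
        merged_a, merged_b = _profile_merge([seqs[0]], [seqs[1]], matrix,
                                            scoring.gap_col)
        return Alignment(((ids[0], merged_a[0]), (ids[1], merged_b[0])))

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_distance(seqs[i], seqs[j], matrix)
            dist[i, j] = dist[j, i] = d
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")

    # cluster id -> (member indices, profile rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(linkage):
        ca, cb = clusters.pop(int(a)), clusters.pop(int(b))
        merged_a, merged_b = _profile_merge(ca[1], cb[1], matrix,
                                            scoring.gap_col)
        clusters[n + step] = (ca[0] + cb[0], merged_a + merged_b)

    members, profile = clusters.popitem()[1]
    by_index = dict(zip(members, profile))
    return Alignment(tuple((ids[i], by_index[i]) for i in range(n)))


# ---------------------------------------------------------------------------
# Conserved-block selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockParams:
    """Column-conservation thresholds for block selection.

    Defaults mirror the canonical conserved-block trimming settings:
    a column is conserved when its modal residue reaches half the rows,
    highly conserved at 85%; runs of 8 or more consecutive non-conserved
    columns split blocks; blocks shorter than 10 columns are discarded; and
    gap-containing columns are excluded outright unless ``allow_gaps``.
    """

    conserved_fraction: float = 0.5
    flank_fraction: float = 0.85
    max_noncons_run: int = 8
    min_block_len: int = 10
    allow_gaps: bool = False


@dataclass(frozen=True)
class BlockSet:
    """Retained column intervals (1-based, inclusive, sorted, disjoint)."""

    intervals: tuple[tuple[int, int], ...]

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


# column statuses
_HIGH, _CONS, _NONCONS, _GAP = "HIGH", "CONS", "NONCONS", "GAPCOL"


def _classify_columns(alignment: Alignment, params: BlockParams) -> list[str]:
    n = alignment.n_rows
    statuses: list[str] = []
    for j in range(alignment.length):
        column = [seq[j] for _, seq in alignment.rows]
        n_gaps = column.count(GAP)
        if n_gaps and not params.allow_gaps:
            statuses.append(_GAP)
            continue
        residues = [c for c in column if c != GAP]
        if not residues:
            statuses.append(_GAP)
            continue
        modal = max(residues.count(r) for r in set(residues))
        freq = modal / n
        if freq >= params.flank_fraction:
            statuses.append(_HIGH)
        elif freq >= params.conserved_fraction:
            statuses.append(_CONS)
        else:
            statuses.append(_NONCONS)
    return statuses


def select_blocks(alignment: Alignment,
                  params: BlockParams = BlockParams()) -> BlockSet:
    """Select well-conserved column blocks.

    Candidate blocks are maximal gap-free runs containing fewer than
    ``max_noncons_run`` consecutive non-conserved columns, trimmed so that
    both flanks are highly conserved; blocks shorter than ``min_block_len``
    are discarded.  Row order does not affect the result.
    """
    statuses = _classify_columns(alignment, params)
    length = len(statuses)

    # split at gap columns and at long non-conserved runs
    segments: list[tuple[int, int]] = []
    start = None
    run = 0
    for j in range(length + 1):
        st = statuses[j] if j < length else _GAP
        if st == _GAP or (st == _NONCONS and run + 1 >= params.max_noncons_run):
            if start is not None:
                # drop the trailing non-conserved run from the segment
                end = j - 1
                if st == _NONCONS:
                    end = j - 1 - run
                if end >= start:
                    segments.append((start, end))
                start = None
            run = params.max_noncons_run if st == _NONCONS else 0
        else:
            run = run + 1 if st == _NONCONS else 0
            if start is None and st != _NONCONS:
                start = j
            elif start is None and st == _NONCONS and run < params.max_noncons_run:
                # non-conserved columns before the first conserved one are
                # trimmed later; still open the segment so runs are counted
                start = j

    intervals: list[tuple[int, int]] = []
    for s, e in segments:
        while s <= e and statuses[s] != _HIGH:
            s += 1
        while e >= s and statuses[e] != _HIGH:
            e -= 1
        if s > e:
            continue
        if e - s + 1 < params.min_block_len:
            continue
        intervals.append((s + 1, e + 1))
    return BlockSet(tuple(intervals))


def extract_blocks(alignment: Alignment, blocks: BlockSet) -> Alignment:
    """Concatenate the retained columns, preserving row order."""
    for s, e in blocks.intervals:
        if not (1 <= s <= e <= alignment.length):
            raise ValueError(f"block out of range: ({s}, {e})")
    new_rows = []
    for rid, seq in alignment.rows:
        parts = [seq[s - 1 : e] for s, e in blocks.intervals]
        new_rows.append((rid, "".join(parts)))
    return Alignment(tuple(new_rows))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def pdistance(alignment: Alignment, correction: str = POISSON) -> DistanceMatrix:
    """Pairwise-deletion p-distances, optionally Poisson corrected.

    p = mismatches / gap-free shared columns; the Poisson correction is
    d = -ln(1 - p).  Raises on a pair with no comparable columns and on a
    saturated (p = 1) pair under the Poisson correction.
    """
    if correction not in (NONE, POISSON):
        raise ValueError(f"unknown correction {correction!r}")
    if alignment.n_rows < 2:
        raise ValueError("need at least 2 rows")
    ids = alignment.ids
    seqs = [seq for _, seq in alignment.rows]
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = 0
            mismatch = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a == GAP or b == GAP:
                    continue
                shared += 1
                if a != b:
                    mismatch += 1
            if shared == 0:
                raise ValueError(
                    f"incomparable pair: {ids[i]!r} and {ids[j]!r} share no "
                    "gap-free columns"
                )
            p = mismatch / shared
            if correction == POISSON:
                if p >= 1.0:
                    raise ValueError(
                        f"saturated distance between {ids[i]!r} and {ids[j]!r}"
                    )
                d = -math.log(1.0 - p)
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Standard agglomerative NJ with the rate-corrected join criterion
    Q(i,j) = (n-2) d(i,j) - r_i - r_j.  Ties are broken toward the
    lexicographically smallest pair of cluster labels (a cluster is labelled
    by its smallest leaf label), negative branch-length estimates are clamped
    to zero, and the result is an unrooted tree (trifurcating root for three
    or more taxa).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("invalid distance matrix: need at least 2 taxa")
    data = np.asarray(dm.data, dtype=float)
    if not np.allclose(data, data.T):
        raise ValueError("invalid distance matrix: not symmetric")

    if n == 2:
        d = float(data[0, 1])
        a = TreeNode(name=ids[0], length=d / 2)
        b = TreeNode(name=ids[1], length=d / 2)
        return TreeNode(children=[a, b])

    # active clusters: label -> (representative label, node)
    nodes: dict[str, TreeNode] = {rid: TreeNode(name=rid) for rid in ids}
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((ids[i], ids[j]))] = float(data[i, j])
    active = sorted(ids)

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best_pair: tuple[str, str] | None = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                pair = (min(a, b), max(a, b))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and (best_pair is None or pair < best_pair)
                ):
                    best_q = q
                    best_pair = pair
        a, b = best_pair  # type: ignore[misc]
        dab = d(a, b)
        va = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        vb = dab - va
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length = max(va, 0.0)
        nb.length = max(vb, 0.0)
        new = TreeNode(children=[na, nb])
        rep = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            duc = (d(a, c) + d(b, c) - dab) / 2
            dist[frozenset((rep, c))] = duc
        active = sorted([c for c in active if c not in (a, b)] + [rep])
        nodes[rep] = new

    a, b, c = active
    va = (d(a, b) + d(a, c) - d(b, c)) / 2
    vb = (d(a, b) + d(b, c) - d(a, c)) / 2
    vc = (d(a, c) + d(b, c) - d(a, b)) / 2
    na, nb, nc = nodes[a], nodes[b], nodes[c]
    na.length = max(va, 0.0)
    nb.length = max(vb, 0.0)
    nc.length = max(vc, 0.0)
    return TreeNode(children=[na, nb, nc])


# ---------------------------------------------------------------------------
# Rooting and Newick I/O
# ---------------------------------------------------------------------------

def root_tree(tree: TreeNode, outgroup_label: str) -> TreeNode:
    """Root on the branch to ``outgroup_label``, split at its midpoint.

    A previously rooted tree is unrooted first, so re-rooting on the same
    outgroup is idempotent.
    """
    labels = {t.name for t in tree.tips()}
    if outgroup_label not in labels:
        raise ValueError(f"outgroup not found: {outgroup_label!r}")
    work = tree.copy()
    if len(work.children) == 2:
        work.unroot()  # in place; merges the two root edges
    return work.root_by_outgroup([outgroup_label])


def write_newick(tree: TreeNode) -> str:
    """Serialize to a Newick string."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string; duplicate leaf labels are rejected."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [t.name for t in tree.tips()]
    if len(set(labels)) != len(labels):
        raise ValueError("malformed newick: duplicate leaf labels")
    return tree


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance (unrooted bipartition symmetric difference)."""
    import dendropy
    from dendropy.calculate import treecompare

    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError(
            f"leaf set mismatch: {sorted(l1 ^ l2)} not shared by both trees"
        )
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                           taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                           taxon_namespace=tns)
    return int(treecompare.symmetric_difference(d1, d2))


def annotate_tree(
    tree: TreeNode, calls: Iterable[ArchitectureCall]
) -> tuple[str, pd.DataFrame]:
    """Pair each leaf with its architecture call.

    Returns the (unchanged) Newick string and a sidecar table with one row
    per leaf.  Raises when any leaf lacks a call.
    """
    by_id = {c.record_id: c for c in calls}
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in by_id]
    if missing:
        raise ValueError(f"unannotated leaf: {missing}")
    sidecar = pd.DataFrame(
        {"leaf": leaves, "architecture": [by_id[l].label for l in leaves]}
    )
    return write_newick(tree), sidecar
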