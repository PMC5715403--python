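"""Progressive alignment, block selection (vs rule oracle), distances,
neighbor joining (vs additive oracle), rooting, Newick and RF."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from nifbkit import ProteinRecord
from nifbkit.architecture import SINGLE, ArchitectureCall
from nifbkit.phylo import (
    Alignment,
    BlockParams,
    BlockSet,
    align_progressive,
    annotate_tree,
    extract_blocks,
    nj_tree,
    parse_newick,
    pdistance,
    rf_distance,
    root_tree,
    select_blocks,
    write_newick,
)

# ---------------------------------------------------------------------------
# Oracles / generators
# ---------------------------------------------------------------------------

def random_binary_tree(rng, n):
    """Random unrooted topology with uniform(0.1, 1) branch lengths."""
    labels = [f"T{i}" for i in range(n)]
    nodes = [TreeNode(name=l) for l in labels]
    while len(nodes) > 3:
        j = int(rng.integers(1, len(nodes)))
        i = int(rng.integers(0, j))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        nodes.append(TreeNode(children=[a, b]))
    for nd in nodes:
        nd.length = float(rng.uniform(0.1, 1.0))
    return TreeNode(children=nodes), labels


def additive_matrix(tree, labels):
    n = len(labels)
    tips = {l: tree.find(l) for l in labels}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tips[labels[i]].distance(tips[labels[j]])
    return DistanceMatrix(d, labels)


def oracle_blocks(rows, params):
    """Independent column-by-column application of the block rules."""
    n = len(rows)
    length = len(rows[0])
    status = []
    for j in range(length):
        col = [s[j] for s in rows]
        if "-" in col and not params.allow_gaps:
            status.append("gap")
            continue
        residues = [c for c in col if c != "-"]
        if not residues:
            status.append("gap")
            continue
        modal = max(residues.count(r) for r in set(residues))
        f = modal / n
        status.append("high" if f >= params.flank_fraction
                      else "cons" if f >= params.conserved_fraction
                      else "non")
    # candidate runs: split on gap columns and on runs of >= max_noncons_run
    # consecutive non-conserved columns
    runs = []
    cur = []
    j = 0
    while j <= length:
        st = status[j] if j < length else "gap"
        if st == "gap":
            if cur:
                runs.append(cur)
                cur = []
            j += 1
            continue
        if st == "non":
            k = j
            while k < length and status[k] == "non":
                k += 1
            if k - j >= params.max_noncons_run:
                if cur:
                    runs.append(cur)
                    cur = []
            else:
                cur.extend(range(j, k))
            j = k
            continue
        cur.append(j)
        j += 1
    if cur:
        runs.append(cur)
    out = []
    for run in runs:
        while run and status[run[0]] != "high":
            run.pop(0)
        while run and status[run[-1]] != "high":
            run.pop()
        if run and run[-1] - run[0] + 1 >= params.min_block_len:
            out.append((run[0] + 1, run[-1] + 1))
    return tuple(out)


class R:
    def __init__(self, i, s):
        self.id, self.sequence = i, s


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

class TestAlignProgressive:
    def test_identical_pair_gap_free(self):
        aln = align_progressive([R("a", "MKVLHPC"), R("b", "MKVLHPC")])
        assert aln.length == 7
        assert all("-" not in s for _, s in aln.rows)

    def test_single_gap_placement(self):
        aln = align_progressive([R("a", "HPC"), R("b", "HAPC")])
        assert aln.length == 4
        assert aln.sequence("a").count("-") == 1
        assert aln.sequence("b") == "HAPC"

    def test_pairwise_matches_dp_oracle(self):
        """Pairwise path equals plain Needleman-Wunsch on the same scoring."""
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(aas), size=int(rng.integers(3, 15))))
            b = "".join(rng.choice(list(aas), size=int(rng.integers(3, 15))))
            aln = align_progressive([R("a", a), R("b", b)])

            # NW oracle with linear gap cost -4 (the profile-merge scoring)
            la, lb = len(a), len(b)
            S = np.zeros((la + 1, lb + 1))
            for i in range(1, la + 1):
                S[i, 0] = S[i - 1, 0] - 4
            for j in range(1, lb + 1):
                S[0, j] = S[0, j - 1] - 4
            for i in range(1, la + 1):
                for j in range(1, lb + 1):
                    S[i, j] = max(S[i - 1, j - 1] + mat[a[i - 1], b[j - 1]],
                                  S[i - 1, j] - 4, S[i, j - 1] - 4)

            def score_of(rows):
                total = 0.0
                ra, rb = rows
                for x, y in zip(ra, rb):
                    if x == "-" or y == "-":
                        total += -4
                    else:
                        total += mat[x, y]
                return total

            got = score_of((aln.sequence("a"), aln.sequence("b")))
            assert got == pytest.approx(S[la, lb])
            # and the rows ungap back to the inputs
            assert aln.ungapped("a") == a and aln.ungapped("b") == b

    def test_three_identical(self):
        aln = align_progressive([R(x, "MKVLHPCAA") for x in "abc"])
        assert {s for _, s in aln.rows} == {"MKVLHPCAA"}

    def test_single_record_error(self):
        with pytest.raises(ValueError, match="nothing to align"):
            align_progressive([R("a", "MKV")])


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class TestSelectBlocks:
    def test_fully_conserved(self):
        aln = Alignment(tuple((f"s{i}", "A" * 50) for i in range(4)))
        blocks = select_blocks(aln)
        assert blocks.intervals == ((1, 50),)
        assert blocks.total_length == 50

    def test_gap_column_excluded(self):
        aln = Alignment(tuple((f"s{i}", "A" * 24 + "-" + "A" * 25)
                              for i in range(4)))
        assert select_blocks(aln).intervals == ((1, 24), (26, 50))

    def test_short_alignment_empty(self):
        aln = Alignment(tuple((f"s{i}", "AAAAA") for i in range(3)))
        blocks = select_blocks(aln)  # shorter than min_block_len
        assert blocks.intervals == ()
        assert blocks.total_length == 0

    def test_row_order_invariant(self):
        rng = np.random.default_rng(10)
        rows = ["".join(rng.choice(list("ACDG"), size=60,
                                   p=[0.7, 0.15, 0.1, 0.05]))
                for _ in range(5)]
        aln1 = Alignment(tuple((f"s{i}", s) for i, s in enumerate(rows)))
        aln2 = Alignment(tuple((f"s{i}", s)
                               for i, s in enumerate(reversed(rows))))
        assert select_blocks(aln1).intervals == select_blocks(aln2).intervals

    def test_agrees_with_rule_oracle(self):
        """200 seeded random alignments against the rule-application oracle."""
        rng = np.random.default_rng(99)
        alphabet = list("ACDEG-")
        for rep in range(200):
            n = int(rng.integers(2, 8))
            length = int(rng.integers(5, 120))
            conserved_bias = rng.uniform(0.3, 0.9)
            rows = []
            base = rng.choice(alphabet[:-1], size=length)
            for _ in range(n):
                row = [
                    base[j] if rng.random() < conserved_bias
                    else alphabet[int(rng.integers(0, len(alphabet)))]
                    for j in range(length)
                ]
                rows.append("".join(row))
            params = BlockParams()
            aln = Alignment(tuple((f"s{i}", s) for i, s in enumerate(rows)))
            assert select_blocks(aln, params).intervals == \
                oracle_blocks(rows, params), f"rep {rep}"


class TestExtractBlocks:
    aln = Alignment((("a", "ABCDEFGHIJKL"), ("b", "ABCDEFGHIJKL")))

    def test_identity(self):
        full = BlockSet(((1, 12),))
        assert extract_blocks(self.aln, full).rows == self.aln.rows

    def test_empty(self):
        out = extract_blocks(self.aln, BlockSet(()))
        assert [s for _, s in out.rows] == ["", ""]

    def test_concatenation(self):
        out = extract_blocks(self.aln, BlockSet(((1, 3), (10, 12))))
        assert out.sequence("a") == "ABCJKL"
        assert out.length == 6

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="block out of range"):
            extract_blocks(self.aln, BlockSet(((1, 13),)))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

class TestPdistance:
    def test_identical_rows(self):
        aln = Alignment((("a", "MKVL"), ("b", "MKVL")))
        assert pdistance(aln, "NONE")["a", "b"] == 0.0

    def test_count(self):
        aln = Alignment((("a", "AAAA"), ("b", "AAAT")))
        assert pdistance(aln, "NONE")["a", "b"] == pytest.approx(0.25)

    def test_poisson_closed_form(self):
        aln = Alignment((("a", "AAAA"), ("b", "AAAT")))
        assert pdistance(aln, "POISSON")["a", "b"] == \
            pytest.approx(-math.log(0.75))

    def test_pairwise_deletion(self):
        aln = Alignment((("a", "A-AA"), ("b", "AAAT")))
        # 3 comparable columns, 1 mismatch
        assert pdistance(aln, "NONE")["a", "b"] == pytest.approx(1 / 3)

    def test_incomparable_pair(self):
        aln = Alignment((("a", "A--"), ("b", "-AA")))
        with pytest.raises(ValueError, match="incomparable pair"):
            pdistance(aln, "NONE")

    def test_saturated(self):
        aln = Alignment((("a", "AAAA"), ("b", "TTTT")))
        with pytest.raises(ValueError, match="saturated distance"):
            pdistance(aln, "POISSON")

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(4)
        rows = [(f"s{i}", "".join(rng.choice(list("ACDG"), size=30)))
                for i in range(5)]
        dm1 = pdistance(Alignment(tuple(rows)), "NONE")
        dm2 = pdistance(Alignment(tuple(reversed(rows))), "NONE")
        for i in range(5):
            for j in range(5):
                a, b = f"s{i}", f"s{j}"
                assert dm1[a, b] == dm2[a, b]


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class TestNJ:
    def test_two_taxa(self):
        tree = nj_tree(DistanceMatrix(np.array([[0, 2.0], [2.0, 0]]),
                                      ["a", "b"]))
        a, b = tree.find("a"), tree.find("b")
        assert a.distance(b) == pytest.approx(2.0)

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3.0, 4.0], [3.0, 0, 5.0],
                                      [4.0, 5.0, 0]]), ["a", "b", "c"])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0},
                                        abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        # the container itself enforces symmetry before nj_tree ever runs
        from skbio.stats.distance import DistanceMatrixError

        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])

    def test_additive_recovery(self):
        """100 seeded random additive matrices, 4-10 leaves -> RF = 0."""
        rng = np.random.default_rng(7)
        for rep in range(100):
            n = int(rng.integers(4, 11))
            true_tree, labels = random_binary_tree(rng, n)
            nj = nj_tree(additive_matrix(true_tree, labels))
            assert rf_distance(nj, true_tree) == 0, f"rep {rep} (n={n})"

    def test_agrees_with_skbio_nj(self):
        """Independent cross-check against scikit-bio's NJ implementation."""
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            true_tree, labels = random_binary_tree(rng, n)
            dm = additive_matrix(true_tree, labels)
            ours = nj_tree(dm)
            theirs = skbio_nj(dm)
            assert rf_distance(ours, theirs) == 0

    def test_deterministic(self):
        rng = np.random.default_rng(21)
        true_tree, labels = random_binary_tree(rng, 8)
        dm = additive_matrix(true_tree, labels)
        assert write_newick(nj_tree(dm)) == write_newick(nj_tree(dm))


# ---------------------------------------------------------------------------
# Rooting, Newick, RF, annotation
# ---------------------------------------------------------------------------

class TestRooting:
    def test_outgroup_sister_to_rest(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_tree(tree, "A")
        kids = sorted(len(list(c.tips())) or 1 for c in rooted.children)
        assert kids == [1, 3]
        assert rooted.find("A").parent is rooted

    def test_midpoint_split(self):
        tree = parse_newick("(A:1,B:2,C:3);")
        rooted = root_tree(tree, "A")
        assert rooted.find("A").length == pytest.approx(0.5)

    def test_missing_outgroup(self):
        tree = parse_newick("(A:1,B:2,C:3);")
        with pytest.raises(ValueError, match="outgroup not found"):
            root_tree(tree, "Z")

    def test_reroot_idempotent(self):
        tree = parse_newick("((A:1,B:2):0.5,(C:1,D:1):0.5);")
        r1 = root_tree(tree, "A")
        r2 = root_tree(r1, "A")
        assert write_newick(r1) == write_newick(r2)


class TestNewick:
    def test_parse_two_leaf(self):
        tree = parse_newick("(A:1,B:2);")
        assert {t.name: t.length for t in tree.tips()} == {"A": 1.0, "B": 2.0}

    def test_round_trip_random_trees(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            tree, _ = random_binary_tree(rng, 10)
            back = parse_newick(write_newick(tree))
            assert rf_distance(tree, back) == 0
            for tip in tree.tips():
                assert back.find(tip.name).length == pytest.approx(
                    tip.length, abs=1e-9)

    def test_malformed(self):
        with pytest.raises(ValueError, match="malformed newick"):
            parse_newick("((A,B);")

    def test_duplicate_leaves(self):
        with pytest.raises(ValueError, match="malformed newick"):
            parse_newick("(A:1,A:2);")


class TestRF:
    def test_identical(self):
        t = parse_newick("((A,B),(C,D));")
        assert rf_distance(t, parse_newick("((A,B),(C,D));")) == 0

    def test_distinct_quartets(self):
        assert rf_distance(parse_newick("((A,B),(C,D));"),
                           parse_newick("((A,C),(B,D));")) == 2

    def test_star_vs_quartet(self):
        assert rf_distance(parse_newick("(A,B,C,D);"),
                           parse_newick("((A,B),(C,D));")) == 1

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValueError, match="leaf set mismatch"):
            rf_distance(parse_newick("(A,B,C);"), parse_newick("(A,B,D);"))


class TestAnnotateTree:
    def calls(self, labels):
        return [ArchitectureCall(l, SINGLE, ()) for l in labels]

    def test_full_annotation(self):
        tree = parse_newick("((A,B),(C,D));")
        nwk, sidecar = annotate_tree(tree, self.calls("ABCD"))
        assert len(sidecar) == 4
        assert set(sidecar["leaf"]) == set("ABCD")
        assert parse_newick(nwk)  # labels unchanged, still parseable

    def test_missing_call(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="unannotated leaf.*D"):
            annotate_tree(tree, self.calls("ABC"))

    def test_empty_calls(self):
        tree = parse_newick("(A,B,C);")
        with pytest.raises(ValueError, match="unannotated leaf"):
            annotate_tree(tree, [])
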