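import itertools
import math

import numpy as np
import pytest

from haplokit import selection
from haplokit.errors import DomainError
from haplokit.io_core import MsaAlignment

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}

# independent codon table (indexed TCAG order), used only by the oracle
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    b1 + b2 + b3: aa
    for (b1, b2, b3), aa in zip(itertools.product("TCAG", repeat=3), _AAS)
}


def oracle_sites(codon):
    """Potential synonymous sites: fraction of the 9 single changes that are
    synonymous; stop-creating changes count as nonsynonymous."""
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOPS and CODON_TABLE[mut] == CODON_TABLE[codon]:
                s += 1 / 3
    return s


def oracle_pathways(ci, cj):
    """Exhaustive enumeration of substitution orderings (the oracle)."""
    diffs = [p for p in range(3) if ci[p] != cj[p]]
    if not diffs:
        return 0.0, 0.0
    results, valid = [], []
    for order in itertools.permutations(diffs):
        cur, syn, non, ok = ci, 0, 0, True
        for p in order:
            nxt = cur[:p] + cj[p] + cur[p + 1 :]
            if nxt in STOPS:
                ok = False
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        results.append((syn, non))
        if ok:
            valid.append((syn, non))
    use = valid or results
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


def oracle_pair(ci_list, cj_list):
    Nd = Sd = N = S = 0.0
    for ci, cj in zip(ci_list, cj_list):
        if set(ci + cj) - set(BASES) or ci in STOPS or cj in STOPS:
            continue
        si, sj = oracle_sites(ci), oracle_sites(cj)
        S += (si + sj) / 2
        N += 3 - (si + sj) / 2
        sd, nd = oracle_pathways(ci, cj)
        Sd += sd
        Nd += nd
    return Nd, Sd, N, S


def random_codon(rng, no_stop=True):
    while True:
        c = "".join(rng.choice(list(BASES), 3))
        if not no_stop or c not in STOPS:
            return c


class TestNg86Pair:
    def test_identical_sequences(self):
        e = selection.ng86_pair("ATGGGTACC", "ATGGGTACC")
        assert e.Nd == e.Sd == 0
        assert e.ratio == 0.0 and e.status == selection.STATUS_ZERO_DN

    def test_synonymous_single_codon(self):
        e = selection.ng86_pair("GGG", "GGA")
        assert e.Sd == 1.0 and e.Nd == 0.0
        assert e.dN == 0.0
        assert e.ratio == 0.0

    def test_nonsynonymous_single_codon(self):
        e = selection.ng86_pair("TTT", "TTA")  # Phe -> Leu
        assert e.Nd == 1.0 and e.Sd == 0.0
        assert e.dS == 0.0
        assert e.status == selection.STATUS_UNDEFINED_DS
        # dN agrees with the pathway-enumeration oracle + JC
        Nd, Sd, N, S = oracle_pair(["TTT"], ["TTA"])
        assert e.dN == pytest.approx(-0.75 * math.log(1 - 4 * (Nd / N) / 3))

    def test_site_conservation_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            a = [random_codon(rng) for _ in range(n)]
            b = [random_codon(rng) for _ in range(n)]
            e = selection.ng86_pair(a, b)
            assert e.N_sites + e.S_sites == pytest.approx(3 * e.n_codons)

    def test_agrees_with_oracle_random_pairs(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 20))
            a = [random_codon(rng) for _ in range(n)]
            b = [random_codon(rng) for _ in range(n)]
            e = selection.ng86_pair(a, b)
            Nd, Sd, N, S = oracle_pair(a, b)
            assert e.Nd == pytest.approx(Nd)
            assert e.Sd == pytest.approx(Sd)
            assert e.N_sites == pytest.approx(N)
            assert e.S_sites == pytest.approx(S)

    def test_gap_and_stop_codons_skipped(self):
        e = selection.ng86_pair(["ATG", "---", "TAA", "GGT"],
                                ["ATG", "GGG", "GGG", "GGA"])
        assert e.n_codons == 2
        assert e.n_skipped == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            selection.ng86_pair("ATGATG", "ATG")

    def test_string_input_frame_checked(self):
        with pytest.raises(DomainError):
            selection.ng86_pair("ATGA", "ATGA")

    def test_segment_mask(self):
        a, b = ["AAA", "GGG", "TTT"], ["AAA", "GGA", "TTT"]
        e = selection.ng86_pair(a, b, segment_mask=[0, 2])
        assert e.Sd == 0 and e.n_codons == 2
        e2 = selection.ng86_pair(a, b, segment_mask=[1])
        assert e2.Sd == 1.0


class TestSegmentPartition:
    def test_overlap_rejected(self):
        with pytest.raises(DomainError):
            selection.SegmentPartition({"a": [(1, 10)], "b": [(10, 20)]})

    def test_remainder_fills_gaps(self):
        p = selection.SegmentPartition.with_remainder({"a": [(3, 5)]}, 10)
        assert p.segments["remainder"] == [(1, 2), (6, 10)]
        assert p.mask("a", 10) == [2, 3, 4]

    def test_mask_clipped_to_alignment(self):
        p = selection.SegmentPartition({"a": [(1, 100)]})
        assert p.mask("a", 5) == [0, 1, 2, 3, 4]


def _neutral_alignment(seed, n_codons=800, n_seqs=6, p=0.06):
    rng = np.random.default_rng(seed)
    anc = [random_codon(rng) for _ in range(n_codons)]

    def mutate(codon):
        while True:
            out = "".join(
                b if rng.random() > p else [x for x in BASES if x != b][rng.integers(3)]
                for b in codon
            )
            if out not in STOPS:
                return out

    rows = ["".join(mutate(c) for c in anc) for _ in range(n_seqs)]
    return MsaAlignment(ids=[f"s{i}" for i in range(n_seqs)], rows=rows, mode="codon")


def _synonymous_only_alignment(seed, n_codons=200, n_seqs=5):
    """Sequences differing from the ancestor only by synonymous changes."""
    rng = np.random.default_rng(seed)
    anc = [random_codon(rng) for _ in range(n_codons)]

    def syn_mutate(codon):
        if rng.random() > 0.3:
            return codon
        alts = []
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut not in STOPS and CODON_TABLE[mut] == CODON_TABLE[codon]:
                    alts.append(mut)
        return alts[rng.integers(len(alts))] if alts else codon

    rows = ["".join(syn_mutate(c) for c in anc) for _ in range(n_seqs)]
    return MsaAlignment(ids=[f"s{i}" for i in range(n_seqs)], rows=rows, mode="codon")


class TestSegmentMedians:
    def test_synonymous_only_segment_median_zero(self):
        aln = _synonymous_only_alignment(seed=4)
        part = selection.SegmentPartition({"seg": [(1, 200)]})
        summary = selection.segment_medians(aln, part)
        assert summary.median("seg") == 0.0
        assert summary.per_segment["seg"]["n_pairs_used"] == 10

    def test_neutral_simulation_near_one(self):
        aln = _neutral_alignment(seed=1)
        part = selection.SegmentPartition({"all": [(1, 800)]})
        summary = selection.segment_medians(aln, part)
        assert 0.8 <= summary.median("all") <= 1.25

    def test_single_pair_median_is_ratio(self):
        aln = MsaAlignment(ids=["a", "b"], rows=["ATGTTTGGG", "ATGTTAGGA"],
                           mode="codon")
        part = selection.SegmentPartition({"all": [(1, 3)]})
        summary = selection.segment_medians(aln, part)
        est = selection.ng86_pair("ATGTTTGGG", "ATGTTAGGA")
        assert summary.median("all") == est.ratio

    def test_requires_codon_mode(self):
        aln = MsaAlignment(ids=["a", "b"], rows=["MK", "MK"])
        with pytest.raises(DomainError):
            selection.segment_medians(
                aln, selection.SegmentPartition({"a": [(1, 2)]})
            )


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = MsaAlignment(ids=["a", "b"], rows=["MKVA", "MKVA"])
        _, mat = selection.p_distance_matrix(msa)
        assert mat[0, 1] == 0.0

    def test_counted_fraction(self):
        row_a = "A" * 30
        row_b = "C" * 3 + "A" * 27
        msa = MsaAlignment(ids=["a", "b"], rows=[row_a, row_b])
        _, mat = selection.p_distance_matrix(msa)
        assert mat[0, 1] == pytest.approx(0.1)

    def test_gaps_excluded(self):
        msa = MsaAlignment(ids=["a", "b"], rows=["AC-G", "ACC-"])
        _, mat = selection.p_distance_matrix(msa)
        assert mat[0, 1] == 0.0  # only 2 mutually non-gap, both equal

    def test_symmetric_zero_diagonal(self, rng):
        rows = ["".join(rng.choice(list("ACDEF-"), size=20)) for _ in range(5)]
        try:
            _, mat = selection.p_distance_matrix(
                MsaAlignment(ids=list("abcde"), rows=rows)
            )
        except DomainError:
            return
        assert np.allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)

    def test_no_comparable_columns_rejected(self):
        msa = MsaAlignment(ids=["a", "b"], rows=["A-", "-A"])
        with pytest.raises(DomainError):
            selection.p_distance_matrix(msa)


def random_additive_tree(rng, n_taxa):
    """Random binary tree; returns (labels, path-length distance matrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = {lab: None for lab in labels}
    adj: dict[str, list[tuple[str, float]]] = {lab: [] for lab in labels}
    pool = list(labels)
    counter = 0
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[j], pool[i]
        parent = f"n{counter}"
        counter += 1
        adj[parent] = []
        for child in (a, b):
            w = float(rng.uniform(0.1, 2.0))
            adj[parent].append((child, w))
            adj[child].append((parent, w))
        pool = [p for p in pool if p not in (a, b)] + [parent]
    mat = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nbr, w in adj[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + w
                    stack.append(nbr)
        for j, dst in enumerate(labels):
            mat[i, j] = dist[dst]
    return labels, mat


class TestNJ:
    def test_three_taxa_unique_topology(self):
        labels = ["a", "b", "c"]
        mat = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = selection.nj_tree(labels, mat)
        assert tree.leaves() == labels
        labs, d = tree.leaf_distances()
        assert d[labs.index("a"), labs.index("b")] == pytest.approx(2)
        assert d[labs.index("a"), labs.index("c")] == pytest.approx(3)

    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):0.5,(C:3,D:1));
        labels = ["A", "B", "C", "D"]
        mat = np.array(
            [
                [0, 3, 4.5, 2.5],
                [3, 0, 5.5, 3.5],
                [4.5, 5.5, 0, 4],
                [2.5, 3.5, 4, 0],
            ]
        )
        tree = selection.nj_tree(labels, mat)
        labs, d = tree.leaf_distances()
        idx = {l: i for i, l in enumerate(labs)}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert d[idx[a], idx[b]] == pytest.approx(mat[i, j])

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 9))
            labels, mat = random_additive_tree(rng, n)
            tree = selection.nj_tree(labels, mat)
            labs, d = tree.leaf_distances()
            idx = {l: i for i, l in enumerate(labs)}
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    assert d[idx[a], idx[b]] == pytest.approx(mat[i, j], abs=1e-9)
            assert not tree.clamped

    def test_taxon_permutation_invariance(self, rng):
        labels, mat = random_additive_tree(rng, 6)
        tree1 = selection.nj_tree(labels, mat)
        perm = list(rng.permutation(len(labels)))
        labels2 = [labels[i] for i in perm]
        mat2 = mat[np.ix_(perm, perm)]
        tree2 = selection.nj_tree(labels2, mat2)
        labs1, d1 = tree1.leaf_distances()
        labs2, d2 = tree2.leaf_distances()
        assert labs1 == labs2
        assert np.allclose(d1, d2)

    def test_newick_parses_with_dendropy(self, rng):
        import dendropy

        labels, mat = random_additive_tree(rng, 6)
        tree = selection.nj_tree(labels, mat)
        dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dtree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        mat[i, j], abs=1e-6
                    )

    def test_asymmetric_rejected(self):
        with pytest.raises(DomainError):
            selection.nj_tree(["a", "b", "c"],
                              np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]]))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(DomainError):
            selection.nj_tree(["a", "b"], np.zeros((2, 2)))

    def test_edge_count(self, rng):
        labels, mat = random_additive_tree(rng, 7)
        tree = selection.nj_tree(labels, mat)
        edges = []

        def walk(node):
            for child, w in node.children:
                edges.append(w)
                walk(child)

        walk(tree.root)
        assert len(edges) == 2 * 7 - 3
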