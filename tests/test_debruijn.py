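"""Extension cascade, fork resolution and single-iteration assembly."""

import pytest

from debra import kmer_engine as ke
from debra.debruijn_assembler import (
    BREAK, FORK_RESOLVED, KmerGraph, assemble_iteration, candidate_bases,
    filter_by_count, filter_by_strand, resolve_fork, verify_bidirectional,
)
from debra.kmer_engine import count_kmers, revcomp

from conftest import make_store, random_dna

K = 11


def graph_from_seqs(k, weighted_seqs, valley=0):
    """Toy graph from (sequence, (plus, minus)) pairs; counts accumulate."""
    table = {}
    for seq, (p, m) in weighted_seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            op, om = table.get(w, (0, 0))
            table[w] = (op + p, om + m)
    return KmerGraph.from_strings(k, table, valley)


def cand(base, plus, minus):
    b = "ACGT".index(base)
    return (b, 0, 0, plus, minus)


def bases(cands):
    return sorted("ACGT"[c[0]] for c in cands)


class TestCountFilter:
    def test_noise_below_fraction_of_best_is_dropped(self):
        assert bases(filter_by_count([cand("A", 60, 40), cand("C", 5, 3)])) == ["A"]

    def test_boundary_count_is_kept(self):
        surv = filter_by_count([cand("A", 60, 40), cand("C", 6, 4)])
        assert bases(surv) == ["A", "C"]

    def test_single_candidate_always_survives(self):
        assert bases(filter_by_count([cand("A", 4, 3)])) == ["A"]


class TestStrandFilter:
    def test_one_sided_candidates_lose_to_a_balanced_one(self):
        surv = filter_by_strand([cand("A", 30, 28), cand("C", 40, 0)])
        assert bases(surv) == ["A"]

    def test_all_kept_when_no_candidate_is_balanced(self):
        surv = filter_by_strand([cand("A", 40, 0), cand("C", 0, 35)])
        assert bases(surv) == ["A", "C"]

    def test_multiple_balanced_candidates_all_kept(self):
        surv = filter_by_strand([cand("A", 30, 28), cand("C", 31, 29)])
        assert bases(surv) == ["A", "C"]


def unique_kmers(seq, k):
    ws = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        c = min(w, revcomp(w))
        if c in ws:
            return False
        ws.add(c)
    return True


@pytest.fixture(scope="module")
def segments():
    """Kmer-disjoint random segments for toy graph construction."""
    segs = {name: random_dna(n, seed) for name, n, seed in [
        ("X", 150, 31), ("Y", 150, 32), ("Z", 150, 33), ("R", 60, 34),
    ]}
    assert unique_kmers("".join(segs.values()), K)
    return segs


class TestAdjacency:
    def test_linear_graph_has_one_successor(self, segments):
        g = graph_from_seqs(K, [(segments["X"], (5, 5))])
        res = candidate_bases(g, segments["X"][10:10 + K])
        assert sum(1 for v in res.values() if v != (0, 0)) == 1
        assert res[segments["X"][10 + K]] != (0, 0)

    def test_terminal_kmer_is_a_dead_end(self, segments):
        g = graph_from_seqs(K, [(segments["X"], (5, 5))])
        res = candidate_bases(g, segments["X"][-K:])
        assert all(v == (0, 0) for v in res.values())

    def test_repeat_exit_offers_two_branches(self, segments):
        s = segments
        genome = s["X"] + s["R"] + s["Y"] + s["R"] + s["Z"]
        g = graph_from_seqs(K, [(genome, (5, 5))])
        res = candidate_bases(g, s["R"][-K:])
        assert sum(1 for v in res.values() if v != (0, 0)) == 2


class TestForkResolution:
    def _fork(self, g, kmer):
        f = ke.encode_kmer(kmer)
        r = ke.revcomp_int(f, g.k)
        from debra.debruijn_assembler import _cands
        surv = filter_by_strand(filter_by_count(_cands(g, f, r)))
        assert len(surv) == 2
        return surv

    def test_short_error_tip_is_pruned(self, segments):
        s = segments
        main = s["X"] + s["Y"]
        junction = len(s["X"])
        tip_base = next(b for b in "ACGT" if b != s["Y"][0])
        tip = s["X"][-(K - 1):] + tip_base + random_dna(30, 35)
        g = graph_from_seqs(K, [(main, (10, 10)), (tip, (1, 1))])
        surv = self._fork(g, s["X"][-K:])
        dec = resolve_fork(g, surv)
        assert dec.outcome == FORK_RESOLVED
        assert dec.chosen == s["Y"][0]

    def test_two_genuine_long_branches_break_the_contig(self, segments):
        s = segments
        genome = s["X"] + s["R"] + s["Y"] + s["R"] + s["Z"]
        g = graph_from_seqs(K, [(genome, (10, 10))])
        surv = self._fork(g, s["R"][-K:])
        dec = resolve_fork(g, surv)
        assert dec.outcome == BREAK

    def test_both_branches_dying_early_breaks(self, segments):
        s = segments
        stem = s["X"][:50]
        b1 = stem[-(K - 1):] + "A" + random_dna(20, 36)
        b2 = stem[-(K - 1):] + "C" + random_dna(20, 37)
        assert b1[K - 1] != b2[K - 1]
        g = graph_from_seqs(K, [(stem, (10, 10)), (b1, (5, 5)), (b2, (5, 5))])
        surv = self._fork(g, stem[-K:])
        assert resolve_fork(g, surv).outcome == BREAK

    @pytest.mark.parametrize("len_a,len_b,expect", [
        (130, 30, FORK_RESOLVED),   # only the long branch survives its walk
        (130, 130, BREAK),          # both reach the step cap
        (30, 40, BREAK),            # both die early
    ])
    def test_walk_survival_matches_branch_length_oracle(self, segments, len_a, len_b, expect):
        # survival is exactly "the branch supports max(100, k) = 100 further
        # steps"; with k=11 a branch of 130 extra bases gives >=100 steps and
        # one of <=40 bases cannot
        s = segments
        stem = s["X"]
        a = stem[-(K - 1):] + "A" + random_dna(len_a, 38)
        c = stem[-(K - 1):] + "C" + random_dna(len_b, 39)
        g = graph_from_seqs(K, [(stem, (10, 10)), (a, (10, 10)), (c, (10, 10))])
        surv = self._fork(g, stem[-K:])
        assert resolve_fork(g, surv).outcome == expect


class TestBidirectionalVerification:
    def test_clean_linear_graph_verifies_everywhere(self, segments):
        x = segments["X"]
        g = graph_from_seqs(K, [(x, (5, 5))])
        for i in range(0, len(x) - K - 1, 7):
            assert verify_bidirectional(g, x[i : i + K], x[i + 1 : i + 1 + K])

    def test_balanced_convergence_point_fails_verification(self, segments):
        # two long paths converge into Z: the first k-mer fully inside Z has
        # two balanced predecessors, so the backward check is ambiguous
        s = segments
        assert s["X"][-1] != s["Y"][-1]
        p1 = s["X"] + s["Z"]
        p2 = s["Y"] + s["Z"]
        g = graph_from_seqs(K, [(p1, (10, 10)), (p2, (10, 10))])
        prev = s["X"][-1] + s["Z"][: K - 1]
        nxt = s["Z"][:K]
        assert not verify_bidirectional(g, prev, nxt)

    def test_short_erroneous_in_edge_is_resolved(self, segments):
        s = segments
        p1 = s["X"] + s["Z"]
        bad = next(b for b in "ACGT" if b != s["X"][-1])
        p2 = random_dna(24, 41) + bad + s["Z"][:40]  # short spurious in-edge
        g = graph_from_seqs(K, [(p1, (10, 10)), (p2, (1, 1))])
        prev = s["X"][-1] + s["Z"][: K - 1]
        nxt = s["Z"][:K]
        assert verify_bidirectional(g, prev, nxt)


def graph_of_genome(genome, k, circular=False, counts=(2, 2)):
    seq = genome + genome[: k - 1] if circular else genome
    return graph_from_seqs(k, [(seq, counts)])


class TestIterationAssembly:
    def test_linear_unique_genome_reassembles_minus_trimmed_ends(self):
        genome = random_dna(2000, 50)
        assert unique_kmers(genome, 21)
        g = graph_of_genome(genome, 21)
        contigs = assemble_iteration(g, [])
        assert len(contigs) == 1
        seq = contigs[0].seq
        expect = genome[21:-21]
        assert seq in (expect, revcomp(expect))

    def test_circular_unique_genome_gives_one_circular_rotation(self):
        genome = random_dna(2000, 51)
        assert unique_kmers(genome, 21)
        g = graph_of_genome(genome, 21, circular=True)
        contigs = assemble_iteration(g, [])
        assert len(contigs) == 1
        c = contigs[0]
        assert c.circular and len(c.seq) == 2000
        doubled = genome + genome
        assert c.seq in doubled or revcomp(c.seq) in doubled

    def test_no_kmer_appears_in_two_contigs(self, segments):
        s = segments
        genome = s["X"] + s["R"] + s["Y"] + s["R"] + s["Z"]
        g = graph_of_genome(genome, K)
        contigs = assemble_iteration(g, [])
        seen = set()
        for c in contigs:
            for i in range(len(c.seq) - K + 1):
                w = c.seq[i : i + K]
                key = min(w, revcomp(w))
                assert key not in seen
                seen.add(key)

    def test_reverse_complemented_input_gives_identical_assembly(self):
        from debra.iteration_controller import canonicalize_assembly
        genome = random_dna(3000, 52)
        seqs = [genome[i : i + 150] for i in range(0, 2900, 50)]
        fwd = count_kmers(make_store(seqs), 21, 1)
        rev = count_kmers(make_store([revcomp(x) for x in seqs]), 21, 1)
        a = canonicalize_assembly(assemble_iteration(KmerGraph.from_counts(fwd), []), 21)
        b = canonicalize_assembly(assemble_iteration(KmerGraph.from_counts(rev), []), 21)
        assert [c.seq for c in a] == [c.seq for c in b]

    def test_raising_extension_threshold_never_adds_length(self):
        genome = random_dna(3000, 53)
        noisy = []
        for i, p in enumerate(range(200, 2800, 400)):
            w = genome[p : p + 40]
            bad = next(b for b in "ACGT" if b != w[20])
            noisy.append((w[:20] + bad + w[21:], (1, 1)))
        total = None
        for ext_frac in (0.02, 0.1, 0.4):
            g = graph_from_seqs(21, [(genome, (10, 10))] + noisy)
            contigs = assemble_iteration(g, [], ext_frac=ext_frac)
            t = sum(len(c.seq) for c in contigs)
            assert total is None or t <= total
            total = t

    def test_isolated_seed_kmer_is_dropped(self):
        g = graph_from_seqs(21, [(random_dna(21, 54), (5, 5))])
        assert assemble_iteration(g, []) == []

    def test_prior_contigs_extend_at_larger_k(self):
        genome = random_dna(2000, 55)
        g1 = graph_of_genome(genome, 21)
        first = assemble_iteration(g1, [])
        g2 = graph_of_genome(genome, 33)
        second = assemble_iteration(g2, first)
        assert len(second) == 1
        # the larger-k pass may extend into the previously trimmed ends but
        # must never lose verified sequence
        assert len(second[0].seq) >= len(first[0].seq)
        assert second[0].seq in genome or revcomp(second[0].seq) in genome
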