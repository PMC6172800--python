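"""Pipeline stages: read retirement, pair connection, canonical output,
and whole-pipeline determinism."""

import io

import pytest

from debra import kmer_engine as ke
from debra.debruijn_assembler import KmerGraph
from debra.iteration_controller import (
    canonicalize_assembly, connect_pair, harvest_long_kmers, mark_used,
    run_assembly,
)
from debra.kmer_engine import count_kmers, revcomp
from debra.param_detector import AssemblyParams
from debra.reads_io import Contig, write_contigs
from debra.sim_eval import gen_contamination, random_genome

from conftest import make_store, random_dna


class TestMarkUsed:
    M = 100
    K = 21

    def setup_method(self):
        self.contig = Contig(random_dna(1200, 61))

    def retire(self, seqs, circular=False):
        self.contig.circular = circular
        store = make_store(seqs)
        mark_used(store, [self.contig], self.K, self.M)
        return [r.used for r in store.reads]

    def test_read_deep_inside_contig_is_retired(self):
        assert self.retire([self.contig.seq[500:600]]) == [True]

    def test_read_overlapping_a_contig_end_is_kept(self):
        assert self.retire([self.contig.seq[0:100]]) == [False]
        assert self.retire([self.contig.seq[1100:1200]]) == [False]

    def test_read_with_no_matching_kmer_is_kept(self):
        assert self.retire([random_dna(100, 62)]) == [False]

    def test_reverse_complement_reads_match_too(self):
        assert self.retire([revcomp(self.contig.seq[500:600])]) == [True]

    def test_any_match_in_a_circular_contig_retires(self):
        assert self.retire([self.contig.seq[0:100]], circular=True) == [True]


def seg(n, seed):
    return random_dna(n, seed)


@pytest.fixture(scope="module")
def repeat_genome():
    """X - R - Y - R - Z with a 200 bp exact repeat."""
    X, R, Y, Z = seg(900, 71), seg(200, 72), seg(900, 73), seg(900, 74)
    return {"genome": X + R + Y + R + Z, "X": X, "R": R, "Y": Y, "Z": Z}


class TestConnectPair:
    K = 21

    def graph_of(self, genome):
        return KmerGraph.from_counts(count_kmers(make_store([genome]), self.K, 1))

    def test_unique_path_recovers_the_genomic_fragment(self):
        genome = random_dna(4000, 63)
        g = self.graph_of(genome)
        frag = genome[1000:1300]
        m1, m2 = frag[:150], revcomp(frag[-150:])
        assert connect_pair(m1, m2, g, 900) == frag

    def test_fully_overlapping_mates(self):
        genome = random_dna(4000, 64)
        g = self.graph_of(genome)
        frag = genome[2000:2150]
        assert connect_pair(frag, revcomp(frag), g, 900) == frag

    def test_missing_anchor_is_a_failure_not_an_error(self):
        genome = random_dna(4000, 65)
        g = self.graph_of(genome)
        assert connect_pair(random_dna(150, 66), random_dna(150, 67), g, 900) is None

    def test_short_loop_around_a_repeat_is_ambiguous(self):
        # X - R - y - R - Z with y short enough that the path looping through
        # the second repeat copy also fits under the maximal insert
        X, R, y, Z = seg(900, 75), seg(200, 76), seg(100, 77), seg(900, 78)
        genome = X + R + y + R + Z
        g = self.graph_of(genome)
        frag = genome[850:1150]  # straddles the first repeat copy
        m1, m2 = frag[:150], revcomp(frag[-150:])
        assert connect_pair(m1, m2, g, 900) is None

    def test_long_spacer_restores_uniqueness(self, repeat_genome):
        genome = repeat_genome["genome"]
        g = self.graph_of(genome)
        frag = genome[850:1150]
        m1, m2 = frag[:150], revcomp(frag[-150:])
        assert connect_pair(m1, m2, g, 900) == frag


class TestHarvest:
    def test_in_buffer_pairs_are_replaced_by_contig_windows(self):
        genome = random_dna(3000, 68)
        contig = Contig(genome)
        frag = genome[100:400]
        store, _ = gen_contamination(genome, coverage=0.1, insert=300, seed=1, circular=False)
        params = AssemblyParams(I=300, max_insert=900)
        g = KmerGraph.from_counts(count_kmers(make_store([genome]), 21, 1))
        frags = harvest_long_kmers(store, [contig], g, params)
        assert frags  # every available pair yields one fragment
        for f in frags:
            assert f in genome

    def test_fragments_on_below_valley_kmers_are_rejected(self):
        # a gap-filling path supported only by low-count (contaminant-like)
        # k-mers must not become a fragment
        genome = random_dna(3000, 70)
        store, _ = gen_contamination(genome, coverage=0.4, insert=300, seed=3, circular=False)
        g = KmerGraph.from_counts(count_kmers(make_store([genome]), 21, 1))
        params = AssemblyParams(I=300, max_insert=900)
        # every genome k-mer has count 1; with a valley above that, all
        # connected fragments are unsupported (no contig mapping here)
        none = harvest_long_kmers(store, [], g, params, valley=1)
        some = harvest_long_kmers(store, [], g, params, valley=0)
        assert none == [] and len(some) > 0

    def test_used_pairs_yield_nothing(self):
        genome = random_dna(3000, 69)
        store, _ = gen_contamination(genome, coverage=0.1, insert=300, seed=2, circular=False)
        for r in store.reads:
            r.used = True
        params = AssemblyParams(I=300, max_insert=900)
        g = KmerGraph.from_counts(count_kmers(make_store([genome]), 21, 1))
        assert harvest_long_kmers(store, [Contig(genome)], g, params) == []


class TestCanonicalOutput:
    def test_strand_with_smaller_first_kmer_is_kept(self):
        seq = "TTGA" + random_dna(100, 80)
        out = canonicalize_assembly([Contig(seq)], 21)
        assert out[0].seq == min(seq, revcomp(seq))

    def test_circular_rotation_is_idempotent_across_strands(self):
        seq = random_dna(500, 81)
        first = canonicalize_assembly([Contig(seq, circular=True)], 21)[0].seq
        for rot in (100, 250, 499):
            r = seq[rot:] + seq[:rot]
            for s in (r, revcomp(r)):
                again = canonicalize_assembly([Contig(s, circular=True)], 21)[0].seq
                assert again == first

    def test_contigs_sorted_by_sequence_with_ordinals(self):
        a, b = sorted([random_dna(60, 82), random_dna(60, 83)])
        # feed in reverse order; canonicalization must sort and number
        out = canonicalize_assembly(
            [Contig(max(a, b)), Contig(min(a, b))], 5
        )
        assert [c.ordinal for c in out] == [1, 2]
        assert out[0].seq <= out[1].seq


class TestPipeline:
    def fasta_bytes(self, state):
        buf = io.StringIO()
        write_contigs(state.contigs, buf)
        return buf.getvalue()

    def test_empty_store_is_an_error(self):
        with pytest.raises(ValueError):
            run_assembly(make_store([]))

    def test_unpaired_run_skips_pair_stages(self):
        genome = random_genome(3000, 84)
        from debra.sim_eval import gen_substrings
        state = run_assembly(gen_substrings(genome, 60))
        assert state.params.I == 0
        assert state.params.long_k_ladder == []
        assert len(state.contigs) == 1

    def test_repeated_runs_and_worker_counts_are_byte_identical(self):
        genome = random_genome(10_000, 85)
        outs = []
        for cores in (1, 1, 4):
            store, _ = gen_contamination(genome, coverage=60, seed=9)
            state = run_assembly(store, cores=cores)
            outs.append(self.fasta_bytes(state))
        assert outs[0] == outs[1] == outs[2]
        assert outs[0].startswith(">Contig_1_")
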