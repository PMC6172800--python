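import random

import numpy as np
import pytest

from debra.kmer_engine import revcomp
from debra.reads_io import Read, ReadStore, UNPAIRED


def make_store(seqs, paired=False):
    return ReadStore(
        [Read(f"r{i}", s, UNPAIRED, None) for i, s in enumerate(seqs)],
        paired_mode=paired,
    )


def naive_kmer_counts(seqs, k):
    """Dictionary-of-strings oracle for strand-aware canonical counting."""
    d = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            c = min(w, revcomp(w))
            p, m = d.get(c, (0, 0))
            if w == c:
                p += 1
            else:
                m += 1
            d[c] = (p, m)
    return d


def random_dna(n, seed):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def shotgun_reads(genome, coverage, read_len, seed, circular=False):
    """Error-free uniformly placed single reads."""
    rng = np.random.default_rng(seed)
    n = int(round(coverage * len(genome) / read_len))
    src = genome + genome[:read_len] if circular else genome
    hi = len(genome) if circular else len(genome) - read_len + 1
    out = []
    for i, s in enumerate(rng.integers(0, hi, n).tolist()):
        seq = src[s : s + read_len]
        if i % 2:
            seq = revcomp(seq)
        out.append(seq)
    return out


@pytest.fixture(scope="session")
def genome_10k():
    return random_dna(10_000, 123)
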