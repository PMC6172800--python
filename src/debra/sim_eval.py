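"""Synthetic test sets and a QUAST-style assembly evaluator.

Two generators emulate the study designs the assembler is validated on:

* substrings set — one error-free read per base of a (usually circular)
  genome, every window of length K, with reads at even 0-based start
  positions reverse complemented; coverage equals K and both strand counts
  are exercised.
* contamination set — clean 2x150 bp pairs with exact 300 bp inserts
  randomly covering the genome at 60x, plus *carryover contamination*:
  pairs from a copy of the same genome mutated at 0.1% of positions, added
  at 0-15x.  A sweep helper generates the contaminant pool once so the
  levels are nested (per-site contaminant depth is monotone in level).

The evaluator aligns each contig to the reference with edlib (end-gap-free
on the reference, both strands, circular references doubled) and reports
N50, total and aligned length, substitutions per 100 kb, misassemblies (a
contig whose alignment splits into blocks with inconsistent order/strand or
a reference gap above 1 kb) and the length deviation L_R + L_A - 2*C_RA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .kmer_engine import BASES, revcomp
from .reads_io import Read, ReadStore, FIRST, SECOND, UNPAIRED

log = logging.getLogger(__name__)


@dataclass
class SimSpec:
    """Parameters of one synthetic read set."""

    genome_len: int
    circular: bool = True
    rng_seed: int = 0
    mode: str = "paired_shotgun"  # or "substrings"
    substring_len: int = 0
    mate_len: int = 150
    insert: int = 300
    coverage: float = 60.0
    contaminant_coverage: float = 0.0
    mutation_rate: float = 0.0


@dataclass
class EvalReport:
    """QUAST-style assembly quality summary."""

    n50: int = 0
    total_len: int = 0          # L_A
    aligned_len: int = 0        # C_RA
    mismatches_per_100kb: float = 0.0
    mismatches: int = 0
    misassemblies: int = 0
    deviation: int = 0          # L_R + L_A - 2*C_RA

    def to_dict(self) -> dict:
        return {
            "n50": self.n50, "total_len": self.total_len,
            "aligned_len": self.aligned_len,
            "mismatches": self.mismatches,
            "mismatches_per_100kb": round(self.mismatches_per_100kb, 3),
            "misassemblies": self.misassemblies, "deviation": self.deviation,
        }

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_tsv(self, path) -> None:
        d = self.to_dict()
        with open(path, "w") as fh:
            fh.write("\t".join(d) + "\n")
            fh.write("\t".join(str(v) for v in d.values()) + "\n")


def random_genome(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


# ---------------------------------------------------------------------------
# generators


def gen_substrings(genome: str, K: int, circular: bool = True) -> ReadStore:
    """All length-K windows of the genome, alternating strand.

    Circular genomes yield one read per position (with wraparound), linear
    genomes L-K+1 reads.  Reads starting at even 0-based positions are
    reverse complemented.  Error-free; per-base coverage of the circular
    output is exactly K.
    """
    L = len(genome)
    if K > L:
        raise ValueError("K exceeds genome length")
    src = genome + genome[: K - 1] if circular else genome
    n = L if circular else L - K + 1
    reads = []
    for p in range(n):
        s = src[p : p + K]
        if p % 2 == 0:
            s = revcomp(s)
        reads.append(Read(f"sub_{p}", s, UNPAIRED, None))
    return ReadStore(reads, paired_mode=False)


def mutate_genome(genome: str, rate: float, rng) -> tuple[str, list[int]]:
    """Substitute each position with probability ``rate`` (to a uniformly
    chosen different base); returns (mutant, mutated positions)."""
    arr = np.frombuffer(genome.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    lut = {ord(b): [ord(c) for c in BASES if c != b] for b in BASES}
    for p in hit.tolist():
        arr[p] = rng.choice(lut[arr[p]])
    return arr.tobytes().decode(), hit.tolist()


def _pairs_from(genome: str, n_pairs: int, mate_len: int, insert: int,
                rng, circular: bool = True) -> list[tuple[str, str]]:
    L = len(genome)
    src = genome + genome[:insert] if circular else genome
    hi = L if circular else L - insert + 1
    starts = rng.integers(0, hi, n_pairs)
    out = []
    for s in starts.tolist():
        frag = src[s : s + insert]
        out.append((frag[:mate_len], revcomp(frag[-mate_len:])))
    return out


def gen_contamination(genome: str, coverage: float = 60.0,
                      contaminant_coverage: float = 0.0,
                      mutation_rate: float = 0.001, mate_len: int = 150,
                      insert: int = 300, seed: int = 0,
                      circular: bool = True):
    """Clean pairs at ``coverage`` plus pairs from a mutated genome copy.

    Returns (ReadStore, truth) where truth records the mutated positions and
    the pair counts.  Mates are 150 bp on opposite strands, exactly
    ``insert`` apart outer-to-outer.
    """
    stores = gen_contamination_sweep(
        genome, [contaminant_coverage], coverage=coverage,
        mutation_rate=mutation_rate, mate_len=mate_len, insert=insert,
        seed=seed, circular=circular,
    )
    return stores[0]


def gen_contamination_sweep(genome: str, levels, coverage: float = 60.0,
                            mutation_rate: float = 0.001, mate_len: int = 150,
                            insert: int = 300, seed: int = 0,
                            circular: bool = True):
    """One (store, truth) per contaminant level, with nested contaminant
    read pools: the pairs at a lower level are a prefix of those at any
    higher level, so per-site contaminant depth grows monotonically."""
    if len(genome) < insert:
        raise ValueError("genome shorter than the insert size")
    L = len(genome)
    rng_clean = np.random.default_rng(seed)
    rng_mut = np.random.default_rng(seed + 1)
    rng_cont = np.random.default_rng(seed + 2)
    n_clean = int(round(coverage * L / (2 * mate_len)))
    clean = _pairs_from(genome, n_clean, mate_len, insert, rng_clean, circular)
    mutant, positions = mutate_genome(genome, mutation_rate, rng_mut)
    max_level = max(levels) if levels else 0.0
    n_cont_max = int(round(max_level * L / (2 * mate_len)))
    cont_pool = _pairs_from(mutant, n_cont_max, mate_len, insert, rng_cont, circular)

    out = []
    for level in levels:
        n_cont = int(round(level * L / (2 * mate_len)))
        reads = []
        idx = 0
        for tag, pairs in (("c", clean), ("x", cont_pool[:n_cont])):
            for s1, s2 in pairs:
                reads.append(Read(f"{tag}_{idx}/1", s1, FIRST, idx))
                reads.append(Read(f"{tag}_{idx}/2", s2, SECOND, idx))
                idx += 1
        truth = {
            "mutated_positions": positions,
            "n_clean_pairs": n_clean,
            "n_contaminant_pairs": n_cont,
            "coverage": coverage,
            "contaminant_coverage": level,
            "mate_len": mate_len,
            "insert": insert,
        }
        out.append((ReadStore(reads, paired_mode=True), truth))
    return out


def write_truth(truth: dict, path) -> None:
    """Serialize a generator truth record as JSON alongside the reads."""
    import json
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


# ---------------------------------------------------------------------------
# evaluation

_CIG = re.compile(r"(\d+)([=XIDM])")
_CHUNK = 500
_MAX_CHUNK_ERR = 0.3
_WHOLE_ERR = 0.05


def _cigar_stats(cigar: str) -> dict:
    d = {"=": 0, "X": 0, "I": 0, "D": 0, "M": 0}
    for n, op in _CIG.findall(cigar):
        d[op] += int(n)
    return d


def _best_alignment(query: str, target: str):
    """(strand, result) with the smaller edit distance (ties: + strand)."""
    fw = edlib.align(query, target, mode="HW", task="path")
    rv = edlib.align(revcomp(query), target, mode="HW", task="path")
    if rv["editDistance"] < fw["editDistance"]:
        return "-", rv
    return "+", fw


def evaluate(contigs, reference: str, circular_reference: bool = False,
             misassembly_gap: int = 1000) -> EvalReport:
    """Score an assembly against a single reference sequence.

    Contigs align end-gap-free on the reference (both strands; circular
    references are doubled so rotations and wraparound alignments score
    cleanly).  A contig aligning as one high-identity block contributes its
    substitution count; otherwise it is split into 500 bp chunks whose best
    placements are grouped into collinear same-strand blocks — every extra
    block (order/strand inconsistency or reference gap > ``misassembly_gap``)
    counts as one misassembly.  Chunks (or whole contigs) without a
    placement at <=30% error count into L_A but not C_RA.
    """
    seqs = [c.seq if hasattr(c, "seq") else str(c) for c in contigs]
    if not reference:
        raise ValueError("empty reference")
    L_R = len(reference)
    target = reference + reference if circular_reference else reference

    rep = EvalReport()
    lengths = []
    for seq in seqs:
        lengths.append(len(seq))
        rep.total_len += len(seq)
        if not seq:
            continue
        strand, res = _best_alignment(seq, target)
        if res["editDistance"] >= 0 and res["editDistance"] <= _WHOLE_ERR * len(seq):
            st = _cigar_stats(res["cigar"])
            rep.mismatches += st["X"]
            rep.aligned_len += len(seq)
            continue
        # fragmented placement
        chunks = []
        for off in range(0, len(seq), _CHUNK):
            piece = seq[off : off + _CHUNK]
            if len(piece) < 50 and chunks:
                break
            strand, res = _best_alignment(piece, target)
            d = res["editDistance"]
            if d < 0 or d > _MAX_CHUNK_ERR * len(piece):
                chunks.append(None)
                continue
            st = _cigar_stats(res["cigar"])
            rep.mismatches += st["X"]
            rep.aligned_len += len(piece)
            chunks.append((strand, res["locations"][0][0], off, len(piece)))
        placed = [c for c in chunks if c is not None]
        blocks = 1 if placed else 0
        for prev, cur in zip(placed, placed[1:]):
            (s1, t1, q1, l1), (s2, t2, q2, l2) = prev, cur
            if s1 != s2:
                blocks += 1
                continue
            dq = q2 - q1
            dt = (t2 - t1) if s1 == "+" else (t1 - t2)
            if dt < 0 or abs(dt - dq) > misassembly_gap:
                blocks += 1
        if blocks > 1:
            rep.misassemblies += blocks - 1

    total = sum(lengths)
    half = total / 2
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc >= half:
            rep.n50 = ln
            break
    rep.deviation = L_R + rep.total_len - 2 * rep.aligned_len
    rep.mismatches_per_100kb = (
        100_000 * rep.mismatches / rep.aligned_len if rep.aligned_len else 0.0
    )
    return rep
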