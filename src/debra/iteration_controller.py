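"""The multi-k assembly pipeline.

Order of operations: trim reads; detect parameters from the K_min k-mer
spectrum; iterate the k ladder ascending (build the graph from non-used
reads, assemble, retire reads whose information is already deep inside a
contig); for paired input, connect still-available pairs into fragments up
to the insert size and run the three longer-than-mate k iterations over the
fragment store; finally canonicalize (orientation, circular rotation,
alphabetical sort) and emit.  Every stage is deterministic: store order,
canonical k-mer order and a fixed sampling seed are the only orderings used,
so repeated runs and different worker counts produce byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import kmer_engine as ke
from . import param_detector as pd
from .debruijn_assembler import KmerGraph, assemble_iteration
from .kmer_engine import revcomp
from .param_detector import AssemblyParams, buffer_zone
from .read_trimmer import trim_store
from .reads_io import Contig, ReadStore, Read

log = logging.getLogger(__name__)

PATH_CAP = 1000  # live-path bound during pair connection


@dataclass
class AssemblyState:
    params: AssemblyParams
    contigs: list[Contig] = field(default_factory=list)
    store: ReadStore | None = None
    iteration_log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# marking reads as used


def mark_used(store: ReadStore, contigs, k: int, M: int) -> int:
    """Retire reads whose every contig-matching k-mer is deeper than M.

    A read is marked used iff at least one of its k-mers occurs in a contig
    and every matching k-mer lies more than M bases from both contig ends
    (any match inside a circular contig retires the read).  Returns the
    number of newly retired reads.
    """
    keys_parts, deep_parts = [], []
    for c in contigs:
        seq = c.seq + (c.seq[: k - 1] if c.circular else "")
        if len(seq) < k:
            continue
        kb, _, _ = ke.sequence_kmers(seq, k)
        if c.circular:
            deep = np.ones(len(kb), dtype=bool)
        else:
            p = np.arange(len(kb))
            deep = (p > M) & ((len(c.seq) - (p + k)) > M)
        keys_parts.append(kb)
        deep_parts.append(deep)
    if not keys_parts:
        return 0
    ck = np.concatenate(keys_parts)
    cd = np.concatenate(deep_parts)
    order = np.argsort(ck, kind="stable")
    ck, cd = ck[order], cd[order]
    # duplicate keys (sequence repeated across contigs): a shallow copy wins
    if len(ck) > 1:
        diff = np.concatenate(([True], ck[1:] != ck[:-1]))
        starts = np.flatnonzero(diff)
        cd = np.logical_and.reduceat(cd, starts)
        ck = ck[starts]

    rkeys, rid, _ = ke.window_scan(store, k)
    if len(rkeys) == 0:
        return 0
    pos = np.searchsorted(ck, rkeys)
    pos_c = np.minimum(pos, len(ck) - 1)
    matched = ck[pos_c] == rkeys
    ok = np.where(matched, cd[pos_c], True)
    bounds = np.flatnonzero(np.concatenate(([True], rid[1:] != rid[:-1])))
    reads_of_group = rid[bounds]
    any_match = np.logical_or.reduceat(matched, bounds)
    all_deep = np.logical_and.reduceat(ok, bounds)
    n = 0
    for i in reads_of_group[any_match & all_deep].tolist():
        r = store.reads[i]
        if not r.used:
            r.used = True
            n += 1
    return n


# ---------------------------------------------------------------------------
# connecting paired reads


def _successors(graph: KmerGraph, f: int, r: int):
    out = []
    entries = graph.entries
    mask, shift = graph.mask, graph.shift
    for b in range(4):
        nf = ((f << 2) | b) & mask
        nr = (r >> 2) | ((3 - b) << shift)
        if (nf if nf <= nr else nr) in entries:
            out.append((b, nf, nr))
    return out


def _one_way(a: str, b: str, graph: KmerGraph, max_insert: int, path_cap: int):
    """All assemblies of ``a`` ... ``b`` (mates as contig ends) up to
    max_insert total length; returns the fragment iff exactly one exists."""
    k = graph.k
    if len(a) < k or len(b) < k:
        return None
    try:
        tf = ke.encode_kmer(b[:k])
        sf = ke.encode_kmer(a[-k:])
    except ValueError:  # N in an anchor k-mer
        return None
    tr = ke.revcomp_int(tf, k)
    sr = ke.revcomp_int(sf, k)
    if min(tf, tr) not in graph.entries or min(sf, sr) not in graph.entries:
        return None

    completions = []
    # mates may overlap: occurrences of b's first k-mer inside a
    for p in range(len(a) - k + 1):
        if a[p : p + k] == b[:k]:
            ov = len(a) - p
            if ov <= len(b) and a[p:] == b[:ov] and p + len(b) >= len(a):
                completions.append(a[:p] + b)

    budget = max_insert - len(a) - len(b) + k
    if budget > 0:
        # paths share structure through a parent-pointer arena so a step is O(1)
        entries = graph.entries
        mask, shift = graph.mask, graph.shift
        arena: list[tuple[int, int]] = [(-1, -1)]
        live = [(sf, sr, 0)]
        for _ in range(budget):
            nxt = []
            for f, r, node in live:
                f2 = (f << 2) & mask
                r2 = r >> 2
                for bb in range(4):
                    nf = f2 | bb
                    nr = r2 | ((3 - bb) << shift)
                    if (nf if nf <= nr else nr) not in entries:
                        continue
                    arena.append((node, bb))
                    n2 = len(arena) - 1
                    if nf == tf:
                        rev = []
                        cur = n2
                        while cur > 0:
                            parent, base = arena[cur]
                            rev.append(ke.BASES[base])
                            cur = parent
                        completions.append(a + "".join(reversed(rev)) + b[k:])
                        if len(completions) > 1:
                            return None
                    nxt.append((nf, nr, n2))
            if len(nxt) > path_cap:
                return None  # repeat sea; conservative failure
            if not nxt:
                break
            live = nxt
    if len(completions) != 1:
        return None
    return completions[0]


def connect_pair(seq1: str, seq2: str, graph: KmerGraph, max_insert: int,
                 path_cap: int = PATH_CAP) -> str | None:
    """Unambiguous assembly of a pair with the mates as contig ends.

    Both directions are assembled (mate1 forward to mate2, and the reverse
    complement of mate2 to the reverse complement of mate1); the pair
    connects only if each yields exactly one path and the two sequences are
    reverse complements of each other.  Returns the fragment (full mate1 +
    gap fill + full mate2) or None.
    """
    fwd = _one_way(seq1, revcomp(seq2), graph, max_insert, path_cap)
    if fwd is None:
        return None
    rev = _one_way(seq2, revcomp(seq1), graph, max_insert, path_cap)
    if rev is None or rev != revcomp(fwd):
        return None
    return fwd


def harvest_long_kmers(store: ReadStore, contigs, graph_kmin: KmerGraph,
                       params: AssemblyParams, valley: int = 0) -> list[str]:
    """Fragment store for the longer-than-mate k iterations.

    Every available pair is turned into one fragment: pairs whose mates both
    map inside one contig (they sit in the buffer zone) are replaced by the
    contig sequence spanning them; the rest are connected by exhaustive path
    search between the anchor k-mers, kept only when unambiguous in both
    directions.  A connected fragment must not introduce K_min k-mers with
    counts at or below the spectrum valley: below-valley k-mers are untrusted
    for starting new sequence, and a "unique" gap-filling path supported only
    by them is how carryover-contaminant pairs would smuggle variant bases
    into a junction.
    """
    k = graph_kmin.k
    index: dict[bytes, tuple[int, int]] = {}
    for ci, c in enumerate(contigs):
        if len(c.seq) < k:
            continue
        kb, _, _ = ke.sequence_kmers(c.seq, k)
        for p, key in enumerate(kb.tolist()):
            if key not in index:
                index[key] = (ci, p)

    fragments: list[str] = []
    n_sub = n_conn = 0
    for r1, r2 in store.pairs():
        if r1.used or r2.used:
            continue
        s1, s2 = r1.trimmed_seq, r2.trimmed_seq
        if len(s1) < k or len(s2) < k:
            continue
        frag = _contig_substitute(s1, s2, contigs, index, k, params.max_insert)
        if frag is not None:
            fragments.append(frag)
            n_sub += 1
            continue
        frag = connect_pair(s1, s2, graph_kmin, params.max_insert)
        if frag is not None and _well_supported(frag, graph_kmin, valley):
            fragments.append(frag)
            n_conn += 1
    log.info(
        "harvested %d fragments (%d from contigs, %d connected)",
        len(fragments), n_sub, n_conn,
    )
    return fragments


def _well_supported(frag: str, graph_kmin: KmerGraph, valley: int) -> bool:
    k = graph_kmin.k
    entries = graph_kmin.entries
    if len(frag) < k:
        return False
    f = ke.encode_kmer(frag[:k])
    r = ke.revcomp_int(f, k)
    mask, shift = graph_kmin.mask, graph_kmin.shift
    codes = [("ACGT".index(c) if c in "ACGT" else -1) for c in frag[k:]]
    key = f if f <= r else r
    e = entries.get(key)
    if e is None or e[0] + e[1] <= valley:
        return False
    for b in codes:
        if b < 0:
            return False
        f = ((f << 2) | b) & mask
        r = (r >> 2) | ((3 - b) << shift)
        e = entries.get(f if f <= r else r)
        if e is None or e[0] + e[1] <= valley:
            return False
    return True


def _contig_substitute(s1, s2, contigs, index, k, max_insert):
    """Contig window standing in for an in-buffer pair, or None."""
    spans = []
    for s in (s1, s2):
        kb, _, valid = ke.sequence_kmers(s, k)
        hits = [index.get(key) for i, key in enumerate(kb.tolist()) if valid[i]]
        hits = [h for h in hits if h is not None]
        if not hits:
            return None
        cids = {h[0] for h in hits}
        if len(cids) != 1:
            return None
        spans.append((cids.pop(), min(h[1] for h in hits), max(h[1] for h in hits)))
    (c1, lo1, hi1), (c2, lo2, hi2) = spans
    if c1 != c2:
        return None
    lo, hi = min(lo1, lo2), max(hi1, hi2) + k
    if hi - lo > max_insert:
        return None
    return contigs[c1].seq[lo:hi]


# ---------------------------------------------------------------------------
# canonical output form


def _forward_keys(seq: str, k: int) -> np.ndarray:
    words = ke._pack_words(ke.encode_codes(seq), k)
    return ke.words_to_bytes(words)


def _canonical_rotation(seq: str, k: int) -> str:
    """Rotation of a circular contig starting at the globally smallest k-mer
    over both strands; ties resolved by the smallest full rotation string."""
    k = min(k, len(seq))
    best_key = None
    cands = []
    for s in (seq, revcomp(seq)):
        doubled = s + s[: k - 1]
        keys = _forward_keys(doubled, k)[: len(s)]
        mn = keys[np.argsort(keys, kind="stable")[0]]  # S dtype has no .min()
        if best_key is None or mn < best_key:
            best_key = mn
            cands = [(s, keys, mn)]
        elif mn == best_key:
            cands.append((s, keys, mn))
    rotations = []
    for s, keys, mn in cands:
        for p in np.flatnonzero(keys == mn).tolist():
            rotations.append(s[p:] + s[:p])
    return min(rotations)


def canonicalize_assembly(contigs, k_min: int, kmin_counts: ke.KmerCounts | None = None) -> list[Contig]:
    """Deterministic output form: strand by smaller first K_min-mer, circular
    rotation by globally smallest k-mer, contigs sorted by sequence, ordinals
    assigned, mean K_min-mer count attached when a count table is given."""
    out = []
    for c in contigs:
        if c.circular:
            seq = _canonical_rotation(c.seq, k_min)
        else:
            rc = revcomp(c.seq)
            kk = min(k_min, len(c.seq))
            if c.seq[:kk] == rc[:kk]:
                seq = min(c.seq, rc)
            else:
                seq = c.seq if c.seq[:kk] < rc[:kk] else rc
        out.append(Contig(seq, c.circular))
    out.sort(key=lambda c: c.seq)
    for i, c in enumerate(out, 1):
        c.ordinal = i
    if kmin_counts is not None:
        table = kmin_counts.key_bytes()
        totals = kmin_counts.totals
        for c in out:
            seq = c.seq + (c.seq[: k_min - 1] if c.circular else "")
            if len(seq) < k_min:
                c.mean_kmin_count = 0.0
                continue
            kb, _, _ = ke.sequence_kmers(seq, k_min)
            pos = np.searchsorted(table, kb)
            pos_c = np.minimum(pos, len(table) - 1)
            found = table[pos_c] == kb
            vals = np.where(found, totals[pos_c], 0)
            c.mean_kmin_count = float(vals.mean()) if len(vals) else 0.0
    return out


# ---------------------------------------------------------------------------
# the full pipeline


def run_assembly(store: ReadStore, *, kmin: int = pd.DEFAULT_KMIN,
                 steps: int = pd.DEFAULT_STEPS, v_f: float = pd.DEFAULT_VF,
                 ext_frac: float = pd.DEFAULT_EXT_FRAC,
                 balance_frac: float = pd.DEFAULT_BALANCE_FRAC,
                 insert_size: int | None = None, seed: int = pd.DEFAULT_SEED,
                 cores: int = 1, use_long_kmers: bool = True,
                 min_contig: int = 200) -> AssemblyState:
    """Trim, detect parameters, iterate the k ladder, connect pairs, run the
    long-k iterations, canonicalize.  Returns the assembly state; the contig
    list is ``state.contigs``."""
    if len(store) == 0:
        raise ValueError("empty read store")
    trim_report = trim_store(store, v_f)
    if store.total_trimmed_bases == 0:
        raise ValueError("all reads trimmed away; check the input for vector content")

    counts_kmin = ke.count_kmers(store, kmin, c_min=1, batches=cores)
    if len(counts_kmin) == 0:
        raise ValueError(f"no {kmin}-mers in the trimmed reads")
    hist = ke.build_histogram(counts_kmin)
    G = hist.genome_size_G
    T = store.total_trimmed_bases
    a_read = store.average_mate_length

    params = AssemblyParams(K_min=kmin, S=steps, V_f=v_f, ext_frac=ext_frac,
                            balance_frac=balance_frac, G=G, T=T, A_read=a_read,
                            seed=seed)
    params.C_min = pd.compute_cmin(T, G)
    params.C_max = pd.compute_cmax(T, G)
    params.K_max = pd.tune_kmax(store, kmin, params.C_min, params.C_max, a_read,
                                batches=cores)
    params.k_ladder = pd.choose_ladder(kmin, params.K_max, steps)

    counts_kmin_floor = counts_kmin.filtered(params.C_min)
    graph_kmin = KmerGraph.from_counts(counts_kmin_floor)
    if store.paired_mode:
        if insert_size is not None:
            params.I = int(insert_size)
        else:
            params.I = pd.estimate_insert(store, graph_kmin, rng_seed=seed)
        params.max_insert = 3 * params.I
        params.long_k_ladder = pd.long_k_ladder(params.K_max, params.I)
    log.info("parameters: %s", params.to_json())

    state = AssemblyState(params=params, store=store)
    M_reads = buffer_zone(params.I, params.K_max)
    contigs: list[Contig] = []

    for it, k in enumerate(params.k_ladder):
        if not any(not r.used and r.trimmed_len >= k for r in store.reads):
            state.iteration_log.append({"k": k, "skipped": True})
            continue
        if it == 0 and k == kmin:
            kc = counts_kmin_floor
        else:
            kc = ke.count_kmers(store, k, c_min=params.C_min, batches=cores)
        if len(kc) == 0:
            state.iteration_log.append({"k": k, "skipped": True})
            continue
        _, valley, _ = ke.detect_peak(kc.bins())
        graph = KmerGraph.from_counts(kc, valley)
        contigs = assemble_iteration(graph, contigs, ext_frac, balance_frac)
        contigs = canonicalize_assembly(contigs, kmin)
        retired = mark_used(store, contigs, k, M_reads)
        state.iteration_log.append({
            "k": k, "valley": valley, "kmers": len(graph),
            "contigs": len(contigs),
            "total_len": sum(len(c) for c in contigs),
            "reads_retired": retired,
        })
        log.info("k=%d: %s", k, state.iteration_log[-1])

    if store.paired_mode and params.long_k_ladder and use_long_kmers:
        fragments = harvest_long_kmers(store, contigs, graph_kmin, params,
                                       valley=hist.valley)
        if fragments:
            frag_store = ReadStore(
                [Read(f"frag_{i}", s) for i, s in enumerate(fragments)],
                paired_mode=False,
            )
            M_frag = buffer_zone(params.I, 0)
            for k in params.long_k_ladder:
                kc = ke.count_kmers(frag_store, k, c_min=1, batches=cores)
                if len(kc) == 0:
                    state.iteration_log.append({"k": k, "skipped": True})
                    continue
                graph = KmerGraph.from_counts(kc, 0)
                contigs = assemble_iteration(graph, contigs, ext_frac, balance_frac,
                                             join_only=True)
                contigs = canonicalize_assembly(contigs, kmin)
                mark_used(frag_store, contigs, k, M_frag)
                state.iteration_log.append({
                    "k": k, "long": True, "kmers": len(graph),
                    "contigs": len(contigs),
                    "total_len": sum(len(c) for c in contigs),
                })
                log.info("long k=%d: %s", k, state.iteration_log[-1])

    # output filter: sub-minimum contigs are mostly unverifiable stubs
    # (e.g. chains seeded on clustered contaminant variants); drop them
    contigs = [c for c in contigs if len(c.seq) >= min_contig or c.circular]
    state.contigs = canonicalize_assembly(contigs, kmin, counts_kmin)
    state.iteration_log.append({"trim_report_reads_trimmed": trim_report.reads_trimmed})
    return state


def assemble(store: ReadStore, **opts) -> list[Contig]:
    """Convenience wrapper: run the pipeline, return the final contigs."""
    return run_assembly(store, **opts).contigs
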