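"""One DeBruijn-graph assembly iteration at a fixed k.

Contigs are seeded from unused k-mers with count above the valley and
extended one base at a time.  An extension step has three outcomes: no
candidate k-mer (dead end), exactly one candidate, or alternate choices.
Alternates pass a three-filter cascade:

1. count filter — candidates with total count below ``ext_frac`` (default
   0.1) of the best candidate's count are noise and are dropped;
2. strand filter — if any surviving candidate has counts balanced on both
   strands, candidates seen predominately on one strand (an Illumina
   strand-specific error signature) are dropped;
3. bounded path exploration — each remaining choice is walked forward up to
   max(100, k) steps under the same filters; if exactly one walk survives
   its base is chosen, otherwise the contig breaks.

A surviving single choice is accepted only if extending backwards from the
new k-mer reproduces the previous k-mer under the same cascade (bidirectional
verification).  Every k-mer joins at most one contig per iteration; running
into another contig's terminal k-mer merges the two, running into its
interior stops extension.  A contig that runs into its own first k-mer is
circular.  When extension of an end is no longer possible the last k bases
of that end are removed: the final k-mer of a stopped end (and in the worst
case the seed k-mer itself) was never confirmed by assembling from the other
direction, so the full k-mer is discarded.  For contigs carrying
prior-iteration sequence the trim never eats into the previously verified
core.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import kmer_engine as ke
from .kmer_engine import BASES, revcomp
from .reads_io import Contig

log = logging.getLogger(__name__)

DEAD_END = "dead_end"
UNIQUE = "unique"
FORK_RESOLVED = "fork_resolved"
BREAK = "break"
CIRCULAR = "circular"


@dataclass
class ExtensionDecision:
    surviving_bases: list[str]
    outcome: str
    chosen: str | None = None


class KmerGraph:
    """Searchable canonical-k-mer table with per-k-mer used flags.

    ``entries`` maps the packed canonical k-mer (Python int) to
    (plus_count, minus_count); insertion order is ascending packed value,
    the deterministic seeding order.  ``used`` maps a k-mer to the id of the
    contig that owns it (set once per iteration, never cleared).
    """

    def __init__(self, k: int, entries: dict[int, tuple[int, int]], valley: int = 0):
        self.k = k
        self.entries = entries
        self.valley = valley
        self.used: dict[int, int] = {}
        self.mask = (1 << (2 * k)) - 1
        self.shift = 2 * (k - 1)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_counts(cls, counts: ke.KmerCounts, valley: int = 0) -> "KmerGraph":
        keys = counts.int_keys()
        plus = counts.plus.tolist()
        minus = counts.minus.tolist()
        return cls(counts.k, dict(zip(keys, zip(plus, minus))), valley)

    @classmethod
    def from_strings(cls, k: int, table: dict[str, tuple[int, int]], valley: int = 0) -> "KmerGraph":
        """Build from {k-mer string: (plus, minus)}; counts are re-attributed
        to the canonical orientation.  Intended for tests and toy graphs."""
        entries: dict[int, tuple[int, int]] = {}
        for s, (p, m) in table.items():
            f = ke.encode_kmer(s)
            r = ke.revcomp_int(f, k)
            key = min(f, r)
            if f > r:
                p, m = m, p
            op, om = entries.get(key, (0, 0))
            entries[key] = (op + p, om + m)
        return cls(k, dict(sorted(entries.items())), valley)

    def counts(self, kmer: str) -> tuple[int, int] | None:
        f = ke.encode_kmer(kmer)
        r = ke.revcomp_int(f, self.k)
        e = self.entries.get(min(f, r))
        if e is None:
            return None
        return e if f <= r else (e[1], e[0])


def _cands(graph: KmerGraph, f: int, r: int, include_used: bool = True,
           cid: int | None = None):
    """Successor candidates of the k-mer (f, r) as (base, nf, nr, plus, minus).

    Counts are oriented to the extension strand.  With ``include_used``
    False, k-mers owned by a contig other than ``cid`` are dropped.
    """
    k = graph.k
    out = []
    for b in range(4):
        nf = ((f << 2) | b) & graph.mask
        nr = (r >> 2) | ((3 - b) << graph.shift)
        key = nf if nf <= nr else nr
        e = graph.entries.get(key)
        if e is None:
            continue
        if not include_used:
            owner = graph.used.get(key)
            if owner is not None and owner != cid:
                continue
        p, m = e if nf <= nr else (e[1], e[0])
        out.append((b, nf, nr, p, m))
    return out


def candidate_bases(graph: KmerGraph, kmer: str) -> dict[str, tuple[int, int]]:
    """Per-base (plus, minus) counts of unused successors of ``kmer``."""
    f = ke.encode_kmer(kmer)
    r = ke.revcomp_int(f, graph.k)
    res = {b: (0, 0) for b in BASES}
    for b, _nf, _nr, p, m in _cands(graph, f, r, include_used=False, cid=None):
        res[BASES[b]] = (p, m)
    return res


def filter_by_count(cands, ext_frac: float = 0.1):
    """Drop candidates whose total count is below ext_frac of the maximum."""
    if not cands:
        return []
    best = max(c[3] + c[4] for c in cands)
    thr = ext_frac * best
    return [c for c in cands if c[3] + c[4] >= thr]


_STRAND_P = 1e-3


def _one_sided(p: int, m: int, balance_frac: float) -> bool:
    """True iff the counts are predominately on one strand.

    Requires both a minor-strand fraction below ``balance_frac`` and a skew
    that is statistically significant under fair strand sampling (binomial
    tail <= 1e-3): a 1:10 split of eleven observations is thin-coverage
    noise, not a systematic error signature, and must not disqualify a
    candidate.
    """
    t = p + m
    lo = min(p, m)
    if t == 0 or lo >= balance_frac * t:
        return False
    if t > 40:  # any sub-25% minor strand is already far beyond 3 sigma
        return True
    tail = sum(math.comb(t, i) for i in range(lo + 1)) / (2.0 ** t)
    return tail <= _STRAND_P


def _balanced(p: int, m: int, balance_frac: float) -> bool:
    return not _one_sided(p, m, balance_frac)


def filter_by_strand(cands, balance_frac: float = 0.25):
    """If any candidate is strand-balanced, drop the one-sided ones."""
    bal = [c for c in cands if _balanced(c[3], c[4], balance_frac)]
    return bal if bal else list(cands)


def _walk_survives(graph: KmerGraph, nf: int, nr: int,
                   ext_frac: float, balance_frac: float) -> bool:
    """Greedy forward walk from a candidate k-mer.

    The walk survives if it reaches max(100, k) steps or forks again under
    the filters (ambiguity is conservative: the original fork breaks); it
    dies only at a dead end.  Ownership is ignored during exploration —
    k-mers already inside contigs are evidence like any others; counting a
    claimed path as dead would steer forks toward unclaimed (typically
    erroneous) branches near contig seams.
    """
    k = graph.k
    max_steps = max(100, k)
    f, r = nf, nr
    for _ in range(max_steps):
        nxt = filter_by_count(_cands(graph, f, r), ext_frac)
        if len(nxt) > 1:
            nxt = filter_by_strand(nxt, balance_frac)
        if not nxt:
            return False
        if len(nxt) > 1:
            return True
        f, r = nxt[0][1], nxt[0][2]
    return True


def resolve_fork(graph: KmerGraph, survivors,
                 ext_frac: float = 0.1, balance_frac: float = 0.25) -> ExtensionDecision:
    """Bounded path exploration over >= 2 filter-surviving candidates."""
    alive = []
    for c in survivors:
        if _walk_survives(graph, c[1], c[2], ext_frac, balance_frac):
            alive.append(c)
    if len(alive) == 1:
        return ExtensionDecision([BASES[alive[0][0]]], FORK_RESOLVED, BASES[alive[0][0]])
    return ExtensionDecision([BASES[c[0]] for c in alive], BREAK)


def _cascade(graph: KmerGraph, f: int, r: int, cid: int | None,
             ext_frac: float, balance_frac: float, strict: bool = False):
    """Full extension cascade; returns (outcome, candidate or None).

    ``strict`` disables walk-based fork resolution (any surviving fork
    breaks): in the longer-than-mate-k phase the graph is thin fragment
    evidence, where "whose chain is longer" says nothing about which branch
    is real, so joins must be unambiguous outright.
    """
    cands = _cands(graph, f, r)
    if not cands:
        return DEAD_END, None
    surv = filter_by_count(cands, ext_frac)
    if len(surv) > 1:
        surv = filter_by_strand(surv, balance_frac)
    if len(surv) == 1:
        return UNIQUE, surv[0]
    if strict:
        return BREAK, None
    dec = resolve_fork(graph, surv, ext_frac, balance_frac)
    if dec.outcome == FORK_RESOLVED:
        chosen = next(c for c in surv if BASES[c[0]] == dec.chosen)
        return FORK_RESOLVED, chosen
    return BREAK, None


def verify_bidirectional(graph: KmerGraph, prev_kmer, next_kmer,
                         cid: int | None = None,
                         ext_frac: float = 0.1, balance_frac: float = 0.25,
                         strict: bool = False) -> bool:
    """True iff extending backwards from next_kmer uniquely yields prev_kmer.

    ``prev_kmer``/``next_kmer`` may be strings or (forward, rc) int pairs.
    The backward direction is evaluated as a forward extension of the
    reverse complement, through the full filter cascade.
    """
    k = graph.k
    if isinstance(prev_kmer, str):
        pf = ke.encode_kmer(prev_kmer)
        pr = ke.revcomp_int(pf, k)
    else:
        pf, pr = prev_kmer
    if isinstance(next_kmer, str):
        nf = ke.encode_kmer(next_kmer)
        nr = ke.revcomp_int(nf, k)
    else:
        nf, nr = next_kmer
    outcome, chosen = _cascade(graph, nr, nf, cid, ext_frac, balance_frac, strict)
    if chosen is None:
        return False
    required = 3 - ((pf >> graph.shift) & 3)
    return chosen[0] == required


# ---------------------------------------------------------------------------
# per-iteration contig state


class _Ctg:
    __slots__ = (
        "id", "seq", "keys", "left_stop", "right_stop", "left_cap", "right_cap",
        "circular", "absorbed", "first_f", "right_f", "right_r", "from_prior",
    )

    def __init__(self, cid: int, seq: str, k: int):
        self.id = cid
        self.seq = seq
        self.keys: list[int] = []
        self.left_stop = None
        self.right_stop = None
        self.left_cap = 0
        self.right_cap = 0
        self.circular = False
        self.absorbed = False
        self.from_prior = False
        self._sync_ends(k)

    def _sync_ends(self, k: int) -> None:
        self.first_f = ke.encode_kmer(self.seq[:k])
        self.right_f = ke.encode_kmer(self.seq[-k:])
        self.right_r = ke.revcomp_int(self.right_f, k)

    def flip(self, k: int) -> None:
        self.seq = revcomp(self.seq)
        self.left_stop, self.right_stop = self.right_stop, self.left_stop
        self.left_cap, self.right_cap = self.right_cap, self.left_cap
        self._sync_ends(k)


def _claim(graph: KmerGraph, ctg: _Ctg) -> None:
    """Mark every graph k-mer of the contig as owned by it."""
    k = graph.k
    seq = ctg.seq + (ctg.seq[: k - 1] if ctg.circular else "")
    if len(seq) < k:
        return
    keys = ke.words_to_ints(ke.pack_sequence_windows(ke.encode_codes(seq), k)[0], k)
    used = graph.used
    entries = graph.entries
    for key in keys:
        if key in entries and key not in used:
            used[key] = ctg.id
            ctg.keys.append(key)


def _absorb(graph: KmerGraph, ctg: _Ctg, other: _Ctg, reversed_: bool) -> None:
    """Merge ``other`` onto the right end of ``ctg``."""
    k = graph.k
    dseq = revcomp(other.seq) if reversed_ else other.seq
    ctg.seq = ctg.seq + dseq[k - 1 :]
    used = graph.used
    for key in other.keys:
        used[key] = ctg.id
    ctg.keys.extend(other.keys)
    if reversed_:
        ctg.right_stop = other.left_stop
        ctg.right_cap = other.left_cap
    else:
        ctg.right_stop = other.right_stop
        ctg.right_cap = other.right_cap
    ctg.from_prior = ctg.from_prior or other.from_prior
    other.absorbed = True
    ctg.right_f = ke.encode_kmer(ctg.seq[-k:])
    ctg.right_r = ke.revcomp_int(ctg.right_f, k)


def _extend_right(graph: KmerGraph, ctg: _Ctg, by_id: dict[int, _Ctg],
                  ext_frac: float, balance_frac: float,
                  strict: bool = False) -> None:
    k = graph.k
    f, r = ctg.right_f, ctg.right_r
    buf: list[str] = []

    def commit():
        if buf:
            ctg.seq += "".join(buf)
            buf.clear()

    while True:
        outcome, chosen = _cascade(graph, f, r, ctg.id, ext_frac, balance_frac, strict)
        if chosen is None:
            ctg.right_stop = outcome if outcome in (DEAD_END, BREAK) else BREAK
            break
        b, nf, nr, _, _ = chosen
        # the base is accepted only if extension from the new k-mer back to
        # the previous one passes the same cascade; this also guards merge
        # junctions and circular self-joins
        if not verify_bidirectional(graph, (f, r), (nf, nr), ctg.id,
                                    ext_frac, balance_frac, strict):
            ctg.right_stop = BREAK
            break
        key = nf if nf <= nr else nr
        owner = graph.used.get(key)
        if owner is not None:
            if owner == ctg.id:
                if nf == ctg.first_f:
                    # self-join: drop the wrapped duplicate of the first k-1
                    ctg.circular = True
                    ctg.right_stop = CIRCULAR
                    commit()
                    ctg.seq = ctg.seq[: len(ctg.seq) - (k - 1)]
                else:
                    ctg.right_stop = BREAK
                break
            other = by_id[owner]
            commit()
            if other.circular or other.absorbed:
                ctg.right_stop = BREAK
                break
            of = ke.encode_kmer(other.seq[:k])
            if nf == of:
                _absorb(graph, ctg, other, reversed_=False)
            else:
                orc = ke.revcomp_int(ke.encode_kmer(other.seq[-k:]), k)
                if nf == orc:
                    _absorb(graph, ctg, other, reversed_=True)
                else:
                    ctg.right_stop = BREAK
                    break
            if ctg.right_stop is not None:
                break  # absorbed contig's far end had already stopped
            f, r = ctg.right_f, ctg.right_r
            continue
        buf.append(BASES[b])
        graph.used[key] = ctg.id
        ctg.keys.append(key)
        ctg.right_cap += 1
        f, r = nf, nr
    commit()
    ctg.right_f, ctg.right_r = f, r


def _extend_both(graph: KmerGraph, ctg: _Ctg, by_id: dict[int, _Ctg],
                 ext_frac: float, balance_frac: float,
                 strict: bool = False) -> None:
    _extend_right(graph, ctg, by_id, ext_frac, balance_frac, strict)
    if ctg.circular or ctg.absorbed:
        return
    k = graph.k
    ctg.flip(k)
    ctg.right_stop = None
    _extend_right(graph, ctg, by_id, ext_frac, balance_frac, strict)
    if not ctg.circular:
        ctg.flip(k)


def assemble_iteration(graph: KmerGraph, prior_contigs, ext_frac: float = 0.1,
                       balance_frac: float = 0.25,
                       join_only: bool = False) -> list[Contig]:
    """One assembly iteration at the graph's k.

    Prior contigs are re-threaded through the current graph (their k-mers
    claimed first, so seeding and merging are order-independent) and
    extended at both ends; new contigs are then seeded from every unused
    k-mer with total count above the valley, in ascending canonical order.
    Terminally stopped ends are trimmed by the unverified last k bases
    (never eating into a prior-iteration core); new contigs shorter than k
    after trimming are dropped.
    """
    k = graph.k
    by_id: dict[int, _Ctg] = {}
    passthrough: list[Contig] = []
    work: list[_Ctg] = []

    cid = 0
    for pc in prior_contigs:
        if len(pc.seq) < k:
            passthrough.append(Contig(pc.seq, pc.circular))
            continue
        ctg = _Ctg(cid, pc.seq, k)
        ctg.circular = pc.circular
        ctg.from_prior = True
        by_id[cid] = ctg
        work.append(ctg)
        cid += 1
    for ctg in work:
        _claim(graph, ctg)

    # phase 1: extend prior contigs (circular ones are complete)
    for ctg in work:
        if not ctg.circular and not ctg.absorbed:
            _extend_both(graph, ctg, by_id, ext_frac, balance_frac, join_only)

    # phase 2: seed from unused above-valley k-mers in canonical order
    valley = graph.valley
    used = graph.used
    for key, (p, m) in graph.entries.items():
        if p + m <= valley or key in used:
            continue
        seq = ke.decode_kmer(key, k)
        ctg = _Ctg(cid, seq, k)
        ctg.left_cap = k
        ctg.right_cap = k
        by_id[cid] = ctg
        used[key] = cid
        ctg.keys.append(key)
        cid += 1
        _extend_both(graph, ctg, by_id, ext_frac, balance_frac, join_only)
        # a fresh seed always trims the full k at terminal stops
        ctg.left_cap = max(ctg.left_cap, k)
        ctg.right_cap = max(ctg.right_cap, k)

    out = list(passthrough)
    for ctg in by_id.values():
        if ctg.absorbed:
            continue
        if ctg.circular:
            out.append(Contig(ctg.seq, True))
            continue
        # join_only (the longer-than-mate-k phase): terminally stopped
        # extensions are rolled back wholesale — fragment evidence is there
        # to connect contigs across repeats, and a dangling extension that
        # joined nothing is unconfirmable duplication
        lt = ctg.left_cap if join_only else min(k, ctg.left_cap)
        rt = ctg.right_cap if join_only else min(k, ctg.right_cap)
        seq = ctg.seq[lt : max(0, len(ctg.seq) - rt)]
        if len(seq) < k:
            if ctg.from_prior:
                out.append(Contig(ctg.seq, False))  # never erode a prior core
            continue
        out.append(Contig(seq, False))
    return out
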