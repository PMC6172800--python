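"""Integer k-mer encoding, strand-aware counting and k-mer spectrum analysis.

K-mers are packed two bits per base (A=0, C=1, G=2, T=3) with the first base
most significant, so numeric order of the packed value equals lexicographic
order of the string.  A k-mer and its reverse complement are collapsed onto
the *canonical* form, the lexicographically smaller of the two; a window
observed in canonical orientation increments the plus-strand count, otherwise
the minus-strand count, and a self-reverse-complementary window counts as
plus.  K-mers up to 32 bases fit one 64-bit word; longer k-mers use several
words compared most-significant-first, preserving the order equivalence.

Counting is the sorted-array method: every window of every available read is
packed, canonicalized and sorted, and runs of equal values are reduced to
(plus, minus) counts.  Windows containing any non-ACGT base are skipped.
The counter can partition k-mers into hash batches (each k-mer lives in
exactly one batch, so the minimum-count filter is applied per batch) and the
merged result is identical for any number of batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

BASES = "ACGT"

# ASCII -> 2-bit code; anything not ACGT (incl. N and the read separator)
# maps to the invalid code 4.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_RC_CODE = np.full(256, 4, dtype=np.uint8)
_RC_CODE[:4] = [3, 2, 1, 0]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def encode_codes(seq: str) -> np.ndarray:
    """ASCII sequence -> uint8 code array (4 marks non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def encode_kmer(kmer: str) -> int:
    """Pack a k-mer string into an arbitrary-precision integer."""
    x = 0
    for ch in kmer:
        c = _CODE[ord(ch)]
        if c > 3:
            raise ValueError(f"non-ACGT base in k-mer: {kmer!r}")
        x = (x << 2) | int(c)
    return x


def decode_kmer(x: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(x >> shift) & 3])
    return "".join(out)


def revcomp_int(x: int, k: int) -> int:
    """Reverse complement of a packed k-mer."""
    y = 0
    for _ in range(k):
        y = (y << 2) | (3 - (x & 3))
        x >>= 2
    return y


def canonical_int(x: int, k: int) -> int:
    return min(x, revcomp_int(x, k))


def n_words(k: int) -> int:
    return (k + 31) // 32


# ---------------------------------------------------------------------------
# vectorized window packing


def _hier_packs(codes64: np.ndarray) -> dict[int, np.ndarray]:
    """Hierarchical doubling packs: P[p][i] = bases i..i+p-1 packed (2p bits)."""
    P = {1: codes64}
    for p in (2, 4, 8, 16, 32):
        h = P[p // 2]
        half = p // 2
        if len(h) <= half:
            break
        P[p] = (h[: len(h) - half] << np.uint64(p)) | h[half:]
    return P


def _span_slice(P: dict[int, np.ndarray], off: int, span: int, nwin: int) -> np.ndarray:
    """Packed value of bases [i+off, i+off+span) for every window start i."""
    val = None
    rem = span
    pos = off
    for p in (32, 16, 8, 4, 2, 1):
        if rem >= p:
            seg = P[p][pos : pos + nwin]
            val = seg if val is None else ((val << np.uint64(2 * p)) | seg)
            pos += p
            rem -= p
    return val


def _pack_words(codes: np.ndarray, k: int) -> np.ndarray:
    """(nwin, w) uint64 array of packed windows (invalid windows contain junk)."""
    n = len(codes)
    nwin = n - k + 1
    w = n_words(k)
    c64 = codes.astype(np.uint64)
    P = _hier_packs(c64)
    words = np.empty((nwin, w), dtype=np.uint64)
    for j in range(w):
        off = 32 * j
        span = min(32, k - off)
        words[:, j] = _span_slice(P, off, span, nwin)
    return words


def _valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of windows free of non-ACGT codes."""
    bad = (codes > 3).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    return (cs[k:] - cs[:-k]) == 0


def _lex_less(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise a < b for multi-word packed arrays (most-significant first)."""
    w = a.shape[1]
    less = np.zeros(len(a), dtype=bool)
    decided = np.zeros(len(a), dtype=bool)
    for j in range(w):
        aj, bj = a[:, j], b[:, j]
        newly = ~decided & (aj != bj)
        less[newly] = aj[newly] < bj[newly]
        decided |= newly
        if decided.all():
            break
    return less


def pack_sequence_windows(codes: np.ndarray, k: int):
    """Canonical packed windows of a code array.

    Returns (canon_words, is_minus, valid): canon_words is (nwin, w) uint64,
    is_minus marks windows whose forward form is not canonical, valid marks
    windows free of non-ACGT codes.  Rows of invalid windows are junk.
    """
    n = len(codes)
    if n < k:
        w = n_words(k)
        return (
            np.empty((0, w), dtype=np.uint64),
            np.empty(0, dtype=bool),
            np.empty(0, dtype=bool),
        )
    fwd = _pack_words(codes, k)
    rc_codes = _RC_CODE[codes][::-1]
    rcw = _pack_words(rc_codes, k)[::-1]
    valid = _valid_windows(codes, k)
    is_minus = _lex_less(rcw, fwd)
    canon = np.where(is_minus[:, None], rcw, fwd)
    return canon, is_minus, valid


def words_to_bytes(words: np.ndarray) -> np.ndarray:
    """(n, w) uint64 -> length-n 'S' array of big-endian fixed-width keys."""
    w = words.shape[1] if words.ndim == 2 else 1
    be = np.ascontiguousarray(words.reshape(len(words), w).astype(">u8"))
    return be.view(f"S{8 * w}").ravel()


def _word_spans(k: int) -> list[int]:
    """Bases covered by each word: 32, 32, ..., remainder (last word)."""
    w = n_words(k)
    return [32] * (w - 1) + [k - 32 * (w - 1)]


def words_to_ints(words: np.ndarray, k: int) -> list:
    """(n, w) uint64 -> Python ints in the true 2k-bit packing."""
    w = words.shape[1]
    if w == 1:
        return words[:, 0].tolist()
    spans = _word_spans(k)
    cols = [words[:, j].tolist() for j in range(w)]
    out = cols[0]
    for j in range(1, w):
        shift = 2 * spans[j]
        cj = cols[j]
        out = [(a << shift) | b for a, b in zip(out, cj)]
    return out


def int_to_words(x: int, k: int) -> tuple:
    spans = _word_spans(k)
    out = []
    for span in reversed(spans):
        out.append(x & ((1 << (2 * span)) - 1))
        x >>= 2 * span
    return tuple(reversed(out))


# ---------------------------------------------------------------------------
# counting


@dataclass
class KmerCounts:
    """Sorted strand-aware canonical k-mer counts (the sorted-array table)."""

    k: int
    words: np.ndarray  # (m, w) uint64, sorted ascending (lexicographic)
    plus: np.ndarray  # occurrences observed in canonical orientation
    minus: np.ndarray  # occurrences observed as the reverse complement
    aux: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.words)

    @property
    def totals(self) -> np.ndarray:
        return self.plus + self.minus

    def key_bytes(self) -> np.ndarray:
        return words_to_bytes(self.words)

    def int_keys(self) -> list:
        return words_to_ints(self.words, self.k)

    def bins(self) -> dict[int, int]:
        """count -> number of distinct k-mers with that total count."""
        tot = self.totals
        if len(tot) == 0:
            return {}
        bc = np.bincount(tot)
        return {int(c): int(m) for c, m in enumerate(bc) if m > 0}

    def filtered(self, c_min: int) -> "KmerCounts":
        keep = self.totals >= c_min
        return KmerCounts(self.k, self.words[keep], self.plus[keep], self.minus[keep], dict(self.aux))

    def kmer_strings(self) -> list[str]:
        return [decode_kmer(x, self.k) for x in self.int_keys()]


def _group_sorted(canon: np.ndarray, is_minus: np.ndarray, c_min: int):
    """Sort canonical windows and reduce runs to (words, plus, minus)."""
    w = canon.shape[1]
    order = np.lexsort(tuple(canon[:, j] for j in range(w - 1, -1, -1)))
    sw = canon[order]
    sm = is_minus[order]
    if len(sw) == 0:
        return sw, np.zeros(0, np.int64), np.zeros(0, np.int64), 0
    diff = np.zeros(len(sw), dtype=bool)
    diff[0] = True
    for j in range(w):
        diff[1:] |= sw[1:, j] != sw[:-1, j]
    starts = np.flatnonzero(diff)
    tot = np.diff(np.append(starts, len(sw)))
    minus = np.add.reduceat(sm.astype(np.int64), starts)
    plus = tot - minus
    keep = tot >= c_min
    dropped = int(tot[~keep].sum())
    return sw[starts[keep]], plus[keep], minus[keep], dropped


def count_kmers(store, k: int, c_min: int = 1, batches: int = 1) -> KmerCounts:
    """Count canonical k-mers over the store's available (non-used) reads.

    Returns one entry per distinct canonical k-mer with total count >= c_min,
    sorted by packed value.  Windows containing N are skipped.  ``batches``
    partitions k-mers by a hash for bounded-memory counting; the result is
    independent of the partitioning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if c_min < 1:
        raise ValueError("c_min must be >= 1")
    w = n_words(k)
    empty = KmerCounts(
        k,
        np.empty((0, w), np.uint64),
        np.zeros(0, np.int64),
        np.zeros(0, np.int64),
        {"total_windows": 0, "n_windows_with_n": 0, "n_dropped_below_cmin": 0},
    )
    codes = store.concat_codes()
    if len(codes) < k:
        log.warning("k=%d longer than every read; empty k-mer table", k)
        return empty
    avail = store.available_window_mask(k)
    total_windows = int(avail.sum())
    if total_windows == 0:
        log.warning("k=%d longer than every available read; empty k-mer table", k)
        return empty
    canon, is_minus, ok = pack_sequence_windows(codes, k)
    with_n = int((avail & ~ok).sum())
    sel = avail & ok
    canon = canon[sel]
    is_minus = is_minus[sel]

    if batches <= 1:
        words, plus, minus, dropped = _group_sorted(canon, is_minus, c_min)
    else:
        # hash-partition: every k-mer lands wholly in one batch, so the
        # c_min filter is valid per batch and the merge is a plain resort
        h = canon[:, 0].copy()
        for j in range(1, canon.shape[1]):
            h ^= canon[:, j]
        part = (h * np.uint64(0x9E3779B97F4A7C15)) >> np.uint64(64 - 16)
        part = part % np.uint64(batches)
        pieces = []
        dropped = 0
        for b in range(batches):
            m = part == b
            bw, bp, bm, bd = _group_sorted(canon[m], is_minus[m], c_min)
            pieces.append((bw, bp, bm))
            dropped += bd
        words = np.concatenate([p[0] for p in pieces])
        plus = np.concatenate([p[1] for p in pieces])
        minus = np.concatenate([p[2] for p in pieces])
        order = np.lexsort(tuple(words[:, j] for j in range(w - 1, -1, -1)))
        words, plus, minus = words[order], plus[order], minus[order]

    aux = {
        "total_windows": total_windows,
        "n_windows_with_n": with_n,
        "n_dropped_below_cmin": dropped,
    }
    return KmerCounts(k, np.ascontiguousarray(words), plus, minus, aux)


def sequence_kmers(seq: str, k: int):
    """Canonical keys of every window of one sequence.

    Returns (key_bytes, is_minus, valid) aligned to window offsets.
    """
    codes = encode_codes(seq)
    canon, is_minus, valid = pack_sequence_windows(codes, k)
    return words_to_bytes(canon), is_minus, valid


def window_scan(store, k: int):
    """Canonical key, read id and in-read offset of every available window.

    Windows are emitted in store order (the determinism anchor), skipping
    used reads and windows containing N.
    """
    codes = store.concat_codes()
    if len(codes) < k:
        z = np.empty(0, dtype=np.int64)
        return np.empty(0, dtype="S8"), z, z
    avail = store.available_window_mask(k)
    canon, is_minus, ok = pack_sequence_windows(codes, k)
    sel = np.flatnonzero(avail & ok)
    keys = words_to_bytes(canon[sel])
    starts = store.concat_starts()
    rid = np.searchsorted(starts, sel, side="right") - 1
    offs = sel - starts[rid]
    return keys, rid.astype(np.int64), offs.astype(np.int64)


# ---------------------------------------------------------------------------
# k-mer spectrum


@dataclass
class KmerHistogram:
    """count -> multiplicity table with detected main peak, valley and G."""

    k: int
    bins: dict[int, int]
    main_peak: int | None
    valley: int
    genome_size_G: int

    @property
    def n_distinct(self) -> int:
        return sum(self.bins.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("count\tmultiplicity\n")
            for c in sorted(self.bins):
                fh.write(f"{c}\t{self.bins[c]}\n")


_SMOOTH_WINDOW = 5


def _smoothed(bins: dict[int, int]) -> np.ndarray:
    """Centered moving average over counts 1..cmax with a shrinking window
    at the edges (a zero-padded edge would fake a rise at count 1)."""
    cmax = max(bins)
    m = np.zeros(cmax + 2, dtype=np.float64)
    for c, mult in bins.items():
        m[c] = mult
    kern = np.ones(_SMOOTH_WINDOW)
    num = np.convolve(m, kern, mode="same")
    valid = np.zeros_like(m)
    valid[1:] = 1.0
    den = np.convolve(valid, kern, mode="same")
    s = num / np.maximum(den, 1.0)
    s[0] = 0.0
    return s


def detect_peak(bins: dict[int, int]) -> tuple[int | None, int, int]:
    """Locate the genomic coverage peak of a k-mer spectrum.

    The multiplicity curve is smoothed with a centered moving average
    (window 5).  The first rise of the smoothed curve past its running
    minimum marks the end of the initial descent (the low-count noise mode,
    if any); the main peak is the largest smoothed multiplicity beyond that
    point.  The valley — the left low end of the distribution around the
    main peak — is found by walking left from the peak while the smoothed
    curve is non-increasing.  The genome size G is the number of distinct
    k-mers with count above the valley.  If no peak is found (monotone
    spectrum), 80% of the whole distribution is used as the estimate of G
    and the valley is zero.

    Returns (main_peak | None, valley, G).
    """
    if not bins:
        return None, 0, 0
    total_distinct = sum(bins.values())
    s = _smoothed(bins)
    cmax = len(s) - 2

    # end of the initial descent: first strict rise from the running minimum
    d0 = None
    running_min = np.inf
    for c in range(1, cmax + 1):
        running_min = min(running_min, s[c])
        if s[c + 1] > s[c] and s[c] <= running_min:
            d0 = c
            break
    if d0 is None or d0 >= cmax:
        return None, 0, int(round(0.8 * total_distinct))

    rest = s[d0 + 1 : cmax + 1]
    main_peak = int(d0 + 1 + np.argmax(rest))

    # left low end of the distribution around the main peak: the smoothed
    # minimum between the initial descent and the peak, taken at the largest
    # count achieving it (robust to jitter on the peak's flank and to a
    # secondary low-count mode left of the dip)
    seg = s[d0 : main_peak + 1]
    valley = int(d0 + np.flatnonzero(seg == seg.min())[-1])

    G = sum(mult for cnt, mult in bins.items() if cnt > valley)
    if G == 0:
        return None, 0, int(round(0.8 * total_distinct))
    return main_peak, valley, G


def build_histogram(counts: KmerCounts) -> KmerHistogram:
    """K-mer spectrum of a count table, with peak/valley/G detection."""
    bins = counts.bins()
    main_peak, valley, G = detect_peak(bins)
    return KmerHistogram(counts.k, bins, main_peak, valley, G)
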