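"""Read input, the in-memory read store, and contig FASTA output.

FASTA/FASTQ is auto-detected from the first record character, gzip from the
magic bytes.  Paired data may come as two files (mates matched by record
index) or one interleaved file.  Reads are stored in input-file order — the
order is a determinism anchor for everything downstream.  Base qualities are
parsed but ignored.  Non-ACGT characters are kept as N; k-mer generation
skips any window containing one.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .kmer_engine import encode_codes

log = logging.getLogger(__name__)

FIRST = "first"
SECOND = "second"
UNPAIRED = "unpaired"

def _sanitize(seq: str) -> str:
    s = seq.upper()
    if any(ch not in "ACGTN" for ch in s):
        s = "".join(ch if ch in "ACGT" else "N" for ch in s)
    return s


@dataclass
class Read:
    """One mate: original identity plus trim state and availability."""

    id: str
    seq: str
    pair_slot: str = UNPAIRED
    mate_index: int | None = None
    trimmed_len: int = -1
    used: bool = False

    def __post_init__(self):
        if self.trimmed_len < 0:
            self.trimmed_len = len(self.seq)

    @property
    def trimmed_seq(self) -> str:
        return self.seq[: self.trimmed_len]


@dataclass
class Contig:
    """Assembled sequence with circular flag and canonical-order metadata."""

    seq: str
    circular: bool = False
    mean_kmin_count: float = 0.0
    ordinal: int | None = None

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def name(self) -> str:
        base = f"Contig_{self.ordinal}_{self.mean_kmin_count:.1f}"
        return base + ("_Circ" if self.circular else "")


class ReadStore:
    """Ordered collection of reads with cached packed-window machinery.

    The store keeps reads columnar (ids, sequences, trim lengths, used
    flags) and lazily maintains a single concatenated 2-bit code array with
    separator sentinels between reads, from which all vectorized k-mer
    operations work.  Trimming invalidates the cache; marking reads used
    only changes the per-window availability mask.
    """

    def __init__(self, reads: list[Read], paired_mode: bool):
        self.reads = reads
        self.paired_mode = paired_mode
        self._codes = None
        self._starts = None

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    # -- aggregate statistics ------------------------------------------------

    @property
    def total_trimmed_bases(self) -> int:
        """T: total trimmed bases over non-used reads."""
        return sum(r.trimmed_len for r in self.reads if not r.used)

    T = total_trimmed_bases

    @property
    def average_mate_length(self) -> float:
        """A_read: mean trimmed mate length over non-empty, non-used reads."""
        lens = [r.trimmed_len for r in self.reads if not r.used and r.trimmed_len > 0]
        return float(np.mean(lens)) if lens else 0.0

    @property
    def n_pairs(self) -> int:
        return sum(1 for r in self.reads if r.pair_slot == FIRST)

    def pairs(self):
        """(first, second) Read tuples in store order."""
        by_mate: dict[int, list[Read]] = {}
        out = []
        for r in self.reads:
            if r.pair_slot == UNPAIRED:
                continue
            pair = by_mate.setdefault(r.mate_index, [None, None])
            pair[0 if r.pair_slot == FIRST else 1] = r
            if pair[0] is not None and pair[1] is not None:
                out.append(tuple(pair))
        return out

    # -- cached concatenation ------------------------------------------------

    def invalidate_cache(self) -> None:
        self._codes = None
        self._starts = None

    def _build_cache(self) -> None:
        seqs = [r.trimmed_seq for r in self.reads]
        joined = "#".join(seqs)
        self._codes = encode_codes(joined) if joined else np.empty(0, np.uint8)
        lens = np.array([len(s) for s in seqs], dtype=np.int64)
        starts = np.zeros(len(seqs), dtype=np.int64)
        if len(seqs) > 1:
            starts[1:] = np.cumsum(lens[:-1] + 1)
        self._starts = starts
        self._lens = lens

    def concat_codes(self) -> np.ndarray:
        if self._codes is None:
            self._build_cache()
        return self._codes

    def concat_starts(self) -> np.ndarray:
        if self._starts is None:
            self._build_cache()
        return self._starts

    def available_window_mask(self, k: int) -> np.ndarray:
        """Boolean over all concat window positions: True where the window
        lies inside a non-used read of trimmed length >= k."""
        codes = self.concat_codes()
        nwin = len(codes) - k + 1
        if nwin <= 0:
            return np.empty(0, dtype=bool)
        used = np.array([r.used for r in self.reads], dtype=bool)
        sel = (~used) & (self._lens >= k)
        diff = np.zeros(nwin + 1, dtype=np.int32)
        ws = self._starts[sel]
        wn = self._lens[sel] - k + 1
        np.add.at(diff, ws, 1)
        np.add.at(diff, ws + wn, -1)
        return np.cumsum(diff[:-1]) > 0


# ---------------------------------------------------------------------------
# input


def _open_text(path):
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


def _parse_records(path):
    with _open_text(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        if head == ">":
            fmt = "fasta"
        elif head == "@":
            fmt = "fastq"
        elif head == "":
            return
        else:
            raise ValueError(f"{path}: cannot detect FASTA/FASTQ (first char {head!r})")
        try:
            for rec in SeqIO.parse(fh, fmt):
                yield rec.id, _sanitize(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record ({exc})") from exc


def load_reads(paths, paired: bool = False, interleaved: bool = False) -> ReadStore:
    """Load reads into a store.

    ``paired`` with two paths matches mates by record index; ``paired`` with
    ``interleaved`` reads consecutive record pairs from each file.  Mates of
    a pair are stored adjacently (first, second) so the store order is fully
    determined by the input files.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no input files")
    reads: list[Read] = []
    if paired and not interleaved:
        if len(paths) != 2:
            raise ValueError("paired non-interleaved input requires exactly two files")
        it1, it2 = _parse_records(paths[0]), _parse_records(paths[1])
        idx = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None:
                raise ValueError(
                    f"mismatched mate counts between {paths[0]} and {paths[1]}"
                )
            reads.append(Read(r1[0], r1[1], FIRST, idx))
            reads.append(Read(r2[0], r2[1], SECOND, idx))
            idx += 1
    elif paired and interleaved:
        idx = 0
        for path in paths:
            pending = None
            for rec in _parse_records(path):
                if pending is None:
                    pending = rec
                else:
                    reads.append(Read(pending[0], pending[1], FIRST, idx))
                    reads.append(Read(rec[0], rec[1], SECOND, idx))
                    idx += 1
                    pending = None
            if pending is not None:
                raise ValueError(f"{path}: odd record count in interleaved paired file")
    else:
        for path in paths:
            for rid, seq in _parse_records(path):
                reads.append(Read(rid, seq, UNPAIRED, None))
    log.info("loaded %d reads from %d file(s)", len(reads), len(paths))
    return ReadStore(reads, paired_mode=paired)


# ---------------------------------------------------------------------------
# output

_WRAP = 80


def _wrapped(seq: str):
    for i in range(0, len(seq), _WRAP):
        yield seq[i : i + _WRAP]


def write_contigs(contigs, out) -> None:
    """Write canonicalized, sorted contigs as 80-column FASTA.

    Records are named ``Contig_N_C`` (N: 1-based ordinal after sorting, C:
    mean K_min-mer count, one decimal place), circular contigs suffixed
    ``_Circ``.
    """
    close = False
    if not hasattr(out, "write"):
        out = open(out, "w")
        close = True
    try:
        if not contigs:
            log.warning("no contigs to write; emitting empty FASTA")
        for c in contigs:
            out.write(f">{c.name}\n")
            for line in _wrapped(c.seq):
                out.write(line + "\n")
    finally:
        if close:
            out.close()


def store_to_fasta(store: ReadStore, path) -> None:
    with open(path, "w") as fh:
        for r in store.reads:
            fh.write(f">{r.id}\n{r.seq}\n")


def store_to_fastq(store: ReadStore, path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in store.reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{quality_char * len(r.seq)}\n")


def split_pairs_to_fastq(store: ReadStore, path1, path2, quality_char: str = "I") -> None:
    """Write a paired store as two mate files in pair order."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in store.pairs():
            f1.write(f"@{r1.id}\n{r1.seq}\n+\n{quality_char * len(r1.seq)}\n")
            f2.write(f"@{r2.id}\n{r2.seq}\n+\n{quality_char * len(r2.seq)}\n")
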