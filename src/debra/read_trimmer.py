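"""Adapter/vector-aware read trimming via overrepresented 19-mers.

A 19-mer is *suspect* when the fraction of mates containing it at least
once, in either orientation, reaches V_f (default 0.05).  Adapters land on
defined read ends but the genome is double-stranded, so the census is
per-read presence of the canonical form.  Each mate is then scanned from
position 0 and clipped at the start of its first suspect 19-mer — the
suspect k-mer and everything after it is removed, so a suspect at position 0
empties the read.  Because the census is orientation-symmetric the suspect
set is closed under reverse complement, and scanning canonical keys in the
forward direction is exactly a forward-orientation scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import kmer_engine as ke

log = logging.getLogger(__name__)

TRIM_K = 19


@dataclass
class TrimReport:
    """Suspect 19-mers and the clipping they caused."""

    suspect_kmers: list[tuple[str, float]] = field(default_factory=list)
    reads_trimmed: int = 0
    most_frequent_suspect: str | None = None
    clip_position_histogram: dict[int, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tread_fraction\n")
            for kmer, frac in self.suspect_kmers:
                fh.write(f"{kmer}\t{frac:.6f}\n")


def find_suspect_kmers(store, v_f: float = 0.05):
    """Census of overrepresented 19-mers.

    Returns (suspect_keys, report): suspect_keys is a sorted 'S8' array of
    canonical packed 19-mers whose per-read presence fraction is >= v_f;
    the report lists them as strings (canonical orientation) with their
    fractions.
    """
    if not 0 < v_f <= 1:
        raise ValueError("v_f must be in (0, 1]")
    if len(store) == 0:
        raise ValueError("empty read store")
    n_mates = len(store)
    keys, rid, _ = ke.window_scan(store, TRIM_K)
    report = TrimReport()
    if len(keys) == 0:
        log.warning("all reads shorter than %d bases; no suspect k-mers", TRIM_K)
        return np.empty(0, dtype="S8"), report

    # distinct (k-mer, read) pairs -> number of reads containing each k-mer
    kb = keys.view(np.uint8).reshape(len(keys), 8)
    rb = rid.astype(">u4").view(np.uint8).reshape(len(rid), 4)
    pair = np.ascontiguousarray(np.hstack([kb, rb])).view("S12").ravel()
    uniq_pairs = np.unique(pair)
    pk = np.ascontiguousarray(uniq_pairs.view(np.uint8).reshape(len(uniq_pairs), 12)[:, :8]).view("S8").ravel()
    uniq_kmers, read_counts = np.unique(pk, return_counts=True)

    threshold = v_f * n_mates
    is_suspect = read_counts >= threshold
    suspects = uniq_kmers[is_suspect]
    fracs = read_counts[is_suspect] / n_mates

    for kb_, fr in sorted(zip(suspects.tolist(), fracs.tolist()), key=lambda t: (-t[1], t[0])):
        kmer_int = int.from_bytes(kb_.ljust(8, b"\x00"), "big")
        report.suspect_kmers.append((ke.decode_kmer(kmer_int, TRIM_K), float(fr)))
    if report.suspect_kmers:
        report.most_frequent_suspect = report.suspect_kmers[0][0]
        log.info(
            "%d suspect 19-mer(s); most frequent %s (%.1f%% of reads)",
            len(report.suspect_kmers),
            report.most_frequent_suspect,
            100 * report.suspect_kmers[0][1],
        )
    return suspects, report


def trim_reads(store, suspects: np.ndarray, report: TrimReport | None = None):
    """Clip every read at the start of its first suspect 19-mer.

    Idempotent for a fixed suspect set: after trimming, no retained read
    contains a suspect 19-mer.  T and A_read change implicitly (the store
    recomputes them from trimmed lengths).
    """
    if report is None:
        report = TrimReport()
    if len(suspects) == 0:
        return store, report
    keys, rid, offs = ke.window_scan(store, TRIM_K)
    hit = np.isin(keys, suspects)
    hit_rids = rid[hit]
    hit_offs = offs[hit]
    first_rids, first_idx = np.unique(hit_rids, return_index=True)
    # windows are emitted in order, so the first index per read is the
    # earliest offset
    for r_i, w_i in zip(first_rids.tolist(), first_idx.tolist()):
        p = int(hit_offs[w_i])
        read = store.reads[r_i]
        if p < read.trimmed_len:
            read.trimmed_len = p
            report.reads_trimmed += 1
            report.clip_position_histogram[p] = report.clip_position_histogram.get(p, 0) + 1
    if report.reads_trimmed:
        store.invalidate_cache()
        log.info("trimmed %d read(s)", report.reads_trimmed)
    return store, report


def trim_store(store, v_f: float = 0.05):
    """Census + clip in one call; returns the report."""
    suspects, report = find_suspect_kmers(store, v_f)
    _, report = trim_reads(store, suspects, report)
    return report
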