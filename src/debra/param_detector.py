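"""Auto-detection of every assembly constant.

From the trimmed read set the detector derives: the genome-size estimate G
(k-mer spectrum at K_min), the count floor C_min = max(2, T/(G*50)) and the
desired average count C_max = max(10, T/(G*10)) where T is the total length
of reads, the largest useful k-mer size K_max (walked down from the average
mate length until the average k-mer count reaches C_max), the ladder of S
evenly spread odd k-mer sizes between K_min and K_max, the insert size I
(median length of unambiguously connected sample pairs), the maximal insert
3*I, the three longer-than-mate k sizes {1.25*K_max, (1.25*K_max+I)/2, I},
and the buffer-zone margin M = I + 50 + F.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import kmer_engine as ke

log = logging.getLogger(__name__)

DEFAULT_KMIN = 21
DEFAULT_STEPS = 11
DEFAULT_VF = 0.05
DEFAULT_EXT_FRAC = 0.1
DEFAULT_BALANCE_FRAC = 0.25
DEFAULT_SEED = 17
INSERT_SAMPLE = 10_000
MIN_CONNECTED = 100


@dataclass
class AssemblyParams:
    """All auto-detected assembly constants."""

    K_min: int = DEFAULT_KMIN
    S: int = DEFAULT_STEPS
    K_max: int = 0
    k_ladder: list[int] = field(default_factory=list)
    C_min: int = 2
    C_max: int = 10
    V_f: float = DEFAULT_VF
    ext_frac: float = DEFAULT_EXT_FRAC
    balance_frac: float = DEFAULT_BALANCE_FRAC
    I: int = 0
    max_insert: int = 0
    long_k_ladder: list[int] = field(default_factory=list)
    G: int = 0
    T: int = 0
    A_read: float = 0.0
    seed: int = DEFAULT_SEED

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def compute_cmin(T: int, G: int) -> int:
    """Minimum k-mer frequency count: max(2, T/(G*50)), floored."""
    if G <= 0:
        raise ValueError("G must be positive (apply the 80% fallback upstream)")
    return max(2, T // (G * 50))


def compute_cmax(T: int, G: int) -> int:
    """Desired average k-mer count: max(10, T/(G*10)), floored."""
    if G <= 0:
        raise ValueError("G must be positive (apply the 80% fallback upstream)")
    return max(10, T // (G * 10))


def _mean_count_at(store, k: int, c_min: int, batches: int = 1) -> float:
    kc = ke.count_kmers(store, k, c_min=c_min, batches=batches)
    if len(kc) == 0:
        return 0.0
    return float(kc.totals.mean())


def tune_kmax(store, k_min: int, c_min: int, c_max: int, a_read: float,
              counts_at=None, batches: int = 1) -> int:
    """Largest k whose average above-threshold k-mer count reaches C_max.

    Starts at round(A_read) and walks down in steps of max(1, round(A_read/25))
    until the average count of k-mers with count >= C_min reaches C_max;
    falls back to K_min (with a warning) if no k qualifies.  ``counts_at``
    may inject an alternative k -> mean-count function (testing hook).
    """
    if counts_at is None:
        counts_at = lambda k: _mean_count_at(store, k, c_min, batches)
    k_max = int(round(a_read))
    if k_max < k_min:
        log.warning("average mate length %.1f below K_min=%d", a_read, k_min)
        return k_min
    step = max(1, round(a_read / 25))
    while True:
        if counts_at(k_max) >= c_max:
            return k_max
        if k_max - step < k_min:
            log.warning("no k reaches average count C_max=%d; K_max = K_min", c_max)
            return k_min
        k_max -= step


def _nearest_odd(x: float) -> int:
    """Nearest odd integer; exact ties go to the lower odd."""
    lo = int(math.floor(x))
    lo = lo if lo % 2 == 1 else lo - 1
    hi = lo + 2
    return lo if (x - lo) <= (hi - x) else hi


def choose_ladder(k_min: int, k_max: int, steps: int) -> list[int]:
    """S odd k-mer sizes spread evenly from K_min to K_max.

    Iterations are disabled (single-entry ladder) unless K_max exceeds
    1.5*K_min.  Interior values are rounded to the nearest odd integer;
    the endpoints are kept as given.
    """
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    if steps < 2 or k_max <= 1.5 * k_min:
        if k_max > k_min:
            log.warning("K_max=%d <= 1.5*K_min; iterations are disabled", k_max)
        return [k_min]
    ladder = [k_min]
    span = k_max - k_min
    for i in range(1, steps - 1):
        ladder.append(_nearest_odd(k_min + i * span / (steps - 1)))
    ladder.append(k_max)
    out = []
    for k in ladder:
        if k not in out and k_min <= k <= k_max:
            out.append(k)
    return sorted(out)


def long_k_ladder(k_max: int, insert: int) -> list[int]:
    """The three post-mate k sizes: 1.25*K_max, (1.25*K_max+I)/2 and I.

    Values are rounded to the nearest odd integer, capped at I, deduplicated
    and values not exceeding K_max (no new information) are dropped.
    """
    if insert <= 0:
        return []
    raw = [1.25 * k_max, (1.25 * k_max + insert) / 2, insert]
    vals = []
    for v in raw:
        v = min(_nearest_odd(v), insert)
        if v > k_max and v not in vals:
            vals.append(v)
    return sorted(vals)


def estimate_insert(store, graph, max_insert_guess: int | None = None,
                    sample_n: int = INSERT_SAMPLE, rng_seed: int = DEFAULT_SEED) -> int:
    """Median length of unambiguously connected sample pairs.

    A fixed-seed sample of up to ``sample_n`` pairs is connected through the
    K_min graph (mates as contig ends); the insert estimate is the median
    fragment length.  Raises if fewer than 100 pairs connect (advise an
    explicit --insert_size).
    """
    from .iteration_controller import connect_pair  # local: avoids an import cycle

    if not store.paired_mode:
        raise ValueError("insert estimation requires paired reads")
    pairs = store.pairs()
    if not pairs:
        raise ValueError("no pairs in store")
    rng = np.random.default_rng(rng_seed)
    n = min(sample_n, len(pairs))
    idx = sorted(rng.choice(len(pairs), size=n, replace=False).tolist())
    # working bound while I is unknown: Illumina inserts rarely exceed 4 mates
    cap = max_insert_guess if max_insert_guess else 4 * max(
        len(p[0].trimmed_seq) for p in pairs[:1000]
    )
    lengths = []
    for i in idx:
        r1, r2 = pairs[i]
        frag = connect_pair(r1.trimmed_seq, r2.trimmed_seq, graph, cap)
        if frag is not None:
            lengths.append(len(frag))
    if len(lengths) < MIN_CONNECTED:
        raise ValueError(
            f"only {len(lengths)} sample pairs connected; "
            "provide the insert size explicitly (--insert_size)"
        )
    est = int(round(float(np.median(lengths))))
    log.info("insert size estimate: %d (from %d connected pairs)", est, len(lengths))
    return est


def buffer_zone(insert: int, flank: int) -> int:
    """Buffer-zone margin M = I + 50 + F.

    F is K_max when retiring input reads and 0 for pair-assembled fragments.
    Unpaired runs use I = 0.
    """
    if insert < 0 or flank < 0:
        raise ValueError("I and F must be non-negative")
    return insert + 50 + flank
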