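"""Terminal inverted repeats, shared end homology, motif scans and dot plots.

A terminal inverted repeat (TIR) is detected by a deterministic
seed-and-extend procedure: an exact seed of length ``seed_len`` is required
between the left end of the molecule and the reverse complement of the right
end (both read inward), the alignment is then grown inward with a banded
unit-cost alignment (match 0, mismatch/indel 1), extension stops when
identity over the trailing ``window`` aligned columns falls below
``min_identity``, and the kept alignment is trimmed back to the column of
maximal cumulative score (match +1, mismatch/indel -1).  Identity counts
indels as differences, column-wise.

Coordinates in all reports are 1-based inclusive on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import Replicon, reverse_complement

logger = logging.getLogger("replichar")

_INF = np.int64(2 ** 30)

DEFAULT_SEED_LEN = 100
DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_WINDOW = 1000
DEFAULT_BAND = 50
DEFAULT_MAX_SCAN = 10_000


@dataclass
class TirReport:
    replicon_id: str
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    length: int                 # aligned columns kept
    percent_identity: float
    matches: int
    mismatches: int
    indels: int


@dataclass
class EndHomologyReport:
    replicon_a: str
    replicon_b: str
    end_a: str
    end_b: str
    length: int
    percent_identity: float
    matches: int
    mismatches: int
    indels: int


@dataclass
class MotifHits:
    motif: str
    replicon_id: str
    hits: list[tuple[int, str, int]]  # (1-based position, strand, mismatches)
    palindromic: bool


@dataclass
class DotPlot:
    seq_a_id: str
    seq_b_id: str
    k: int
    points: list[tuple[int, int, str]]  # (pos_a, pos_b, strand), 1-based
    n_total_points: int                 # before any downsampling


# ---------------------------------------------------------------------------
# Banded unit-cost global alignment
# ---------------------------------------------------------------------------

def banded_align(a: str, b: str, band: int) -> tuple[int, str]:
    """Global banded edit-distance alignment of two strings.

    Unit costs (match 0, mismatch/indel 1); cells further than ``band`` off
    the main diagonal are unreachable.  Returns (cost, column string) where
    each column is one of M (match), X (mismatch), I (gap in ``a``) or
    D (gap in ``b``).
    """
    n, m = len(a), len(b)
    if abs(n - m) > band:
        raise ValueError("length difference exceeds band width")
    if n == 0:
        return m, "I" * m
    if m == 0:
        return n, "D" * n
    A = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    B = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    width = 2 * band + 1
    idx = np.arange(width)
    dp = np.full((n + 1, width), _INF, dtype=np.int64)
    j0 = idx - band
    ok0 = (j0 >= 0) & (j0 <= m)
    dp[0, ok0] = j0[ok0]
    for i in range(1, n + 1):
        j = idx + i - band
        valid = (j >= 0) & (j <= m)
        jv = (j >= 1) & (j <= m)
        bj = np.where(jv, np.clip(j - 1, 0, m - 1), 0)
        mism = (A[i - 1] != B[bj]).astype(np.int64)
        sub = np.where(jv, dp[i - 1] + mism, _INF)
        dele = np.full(width, _INF, dtype=np.int64)
        dele[:-1] = dp[i - 1, 1:] + 1
        best = np.minimum(sub, np.where(valid, dele, _INF))
        # gap-in-a moves run within the row: dp[i,d] = min_{k<=d} best[k]+(d-k)
        ins = np.minimum.accumulate(best - idx) + idx
        dp[i] = np.where(valid, np.minimum(best, ins), _INF)
    d = m - n + band
    cost = int(dp[n, d])
    # traceback
    cols: list[str] = []
    i = n
    while i > 0 or d != _d_for(0, band):
        j = i + d - band
        if i > 0 and j > 0 and dp[i, d] == dp[i - 1, d] + (1 if a[i - 1] != b[j - 1] else 0):
            cols.append("M" if a[i - 1] == b[j - 1] else "X")
            i -= 1
        elif i > 0 and d + 1 < width and dp[i, d] == dp[i - 1, d + 1] + 1:
            cols.append("D")
            i -= 1
            d += 1
        elif d > 0 and dp[i, d] == dp[i, d - 1] + 1:
            cols.append("I")
            d -= 1
        else:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed")
    return cost, "".join(reversed(cols))


def _d_for(j: int, band: int) -> int:
    return j + band  # band-offset of column j in row i=0


# ---------------------------------------------------------------------------
# Seed and extend
# ---------------------------------------------------------------------------

def _find_seed(a: str, b: str, seed_len: int, max_scan: int) -> tuple[int, int] | None:
    """Smallest-offset exact match of length seed_len between prefixes."""
    scan_a = a[:max_scan]
    scan_b = b[:max_scan]
    kmer_pos: dict[str, int] = {}
    for j in range(len(scan_b) - seed_len, -1, -1):  # keep the smallest j per k-mer
        kmer_pos[scan_b[j:j + seed_len]] = j
    best: tuple[int, int] | None = None
    for i in range(len(scan_a) - seed_len + 1):
        if best is not None and i >= best[0] + best[1]:
            break
        j = kmer_pos.get(scan_a[i:i + seed_len])
        if j is not None and (best is None or i + j < best[0] + best[1]):
            best = (i, j)
    return best


def _columns_stats(cols: str) -> tuple[int, int, int]:
    return cols.count("M"), cols.count("X"), cols.count("I") + cols.count("D")


def _extend_inward(a: str, b: str, min_identity: float, window: int, band: int,
                   max_len: int) -> str:
    """Grow a banded alignment of a vs b from offset 0 until the trailing
    ``window``-column identity falls below ``min_identity`` or ``max_len``
    characters of either string are consumed; returns the trimmed columns."""
    chunk = max(2 * window, 2048)
    cols: list[str] = []
    a_pos = b_pos = 0
    stopped = False
    while not stopped:
        ca = a[a_pos:a_pos + chunk]
        cb = b[b_pos:b_pos + chunk]
        k = min(len(ca), len(cb), max_len - max(a_pos, b_pos))
        if k <= 0:
            break
        _, new_cols = banded_align(ca[:k], cb[:k], band)
        cols.append(new_cols)
        a_pos += k
        b_pos += k
        joined = "".join(cols)
        if _first_stop(joined, min_identity, window) is not None:
            stopped = True
        if k < chunk:
            break
    joined = "".join(cols)
    stop = _first_stop(joined, min_identity, window)
    if stop is not None:
        joined = joined[:stop]
    joined = _trim_to_peak(joined, min_identity)
    # greedy re-extension over literal matches: chunk-boundary indels can
    # displace the final repeat column, so claim any directly matching bases
    # just beyond the trimmed alignment
    n_a, n_b = _consumed(joined)
    extra = 0
    while (n_a + extra < min(len(a), max_len) and n_b + extra < min(len(b), max_len)
           and a[n_a + extra] == b[n_b + extra]):
        extra += 1
    return joined + "M" * extra


def _first_stop(cols: str, min_identity: float, window: int) -> int | None:
    """First column index at which trailing-window identity drops below
    threshold (None if it never does)."""
    if len(cols) < window:
        return None
    match = np.frombuffer(cols.encode("ascii"), dtype=np.uint8) == ord("M")
    c = np.concatenate([[0], np.cumsum(match)])
    trailing = c[window:] - c[:-window]   # matches in cols[t-window:t]
    bad = np.nonzero(trailing < (min_identity / 100.0) * window)[0]
    return int(bad[0]) + window if len(bad) else None


def _trim_to_peak(cols: str, min_identity: float) -> str:
    """Trim to the column of maximal cumulative score.

    A match scores +1 and a mismatch -q/(1-q) with q = min_identity/100
    (indels one point worse), so a stretch at exactly the identity threshold
    is score-neutral, genuine repeat columns score positive, and optimally
    banded-aligned *random* sequence — which on skewed base composition can
    reach ~60% identity by chasing matches with indels — scores strongly
    negative.  The peak therefore sits at the end of the true repeat instead
    of drifting into background.
    """
    if not cols:
        return cols
    q = min(max(min_identity / 100.0, 0.5), 0.999)
    mismatch_pen = q / (1.0 - q)
    arr = np.frombuffer(cols.encode("ascii"), dtype=np.uint8)
    score = np.full(len(arr), -(mismatch_pen + 1.0))
    score[arr == ord("M")] = 1.0
    score[arr == ord("X")] = -mismatch_pen
    cum = np.cumsum(score)
    peak = int(np.argmax(cum))
    if cum[peak] <= 0:
        return ""
    return cols[:peak + 1]


def _consumed(cols: str) -> tuple[int, int]:
    """Characters of (a, b) consumed by an alignment column string."""
    n_a = sum(1 for c in cols if c in "MXD")
    n_b = sum(1 for c in cols if c in "MXI")
    return n_a, n_b


def find_tir(replicon: Replicon, seed_len: int = DEFAULT_SEED_LEN,
             min_identity: float = DEFAULT_MIN_IDENTITY,
             window: int = DEFAULT_WINDOW, band: int = DEFAULT_BAND,
             max_scan: int = DEFAULT_MAX_SCAN) -> TirReport | None:
    """Detect a terminal inverted repeat on a linear replicon.

    Returns None when no exact seed of ``seed_len`` is found within the first
    ``max_scan`` bases of both ends, or when the alignment never reaches
    ``min_identity``.
    """
    if replicon.topology == "circular":
        raise ValueError("TIRs are defined for linear molecules")
    if seed_len < 8:
        raise ValueError("seed_len must be >= 8")
    seq = replicon.sequence
    L = len(seq)
    a = seq                       # left end read inward
    b = reverse_complement(seq)   # right end read inward
    seed = _find_seed(a, b, seed_len, min(max_scan, L // 2))
    if seed is None:
        return None
    i, j = seed
    cols = _extend_inward(a[i:], b[j:], min_identity, window, band,
                          max_len=L // 2 - max(i, j))
    if i or j:  # fold the pre-seed stubs into the alignment, anchored at the ends
        stub_band = max(band, abs(i - j) + 2)
        _, stub_cols = banded_align(a[:i][::-1], b[:j][::-1], stub_band)
        cols = stub_cols[::-1] + cols
        i = j = 0
    if not cols:
        return None
    matches, mismatches, indels = _columns_stats(cols)
    total = len(cols)
    identity = 100.0 * matches / total
    if identity < min_identity:
        return None
    n_a, n_b = _consumed(cols)
    return TirReport(
        replicon_id=replicon.id,
        left_interval=(1, n_a),
        right_interval=(L - n_b + 1, L),
        length=total, percent_identity=identity,
        matches=matches, mismatches=mismatches, indels=indels,
    )


def end_homology(replicon_a: Replicon, end_a: str, replicon_b: Replicon,
                 end_b: str, seed_len: int = DEFAULT_SEED_LEN,
                 min_identity: float = DEFAULT_MIN_IDENTITY,
                 window: int = DEFAULT_WINDOW, band: int = DEFAULT_BAND,
                 max_scan: int = DEFAULT_MAX_SCAN) -> EndHomologyReport | None:
    """Shared terminal homology between chosen ends of two linear replicons.

    Right-end comparisons operate on reverse-complemented suffixes so both
    sequences are read inward from their termini.
    """
    for rep in (replicon_a, replicon_b):
        if rep.topology == "circular":
            raise ValueError("end homology is defined for linear molecules")
    if end_a not in ("left", "right") or end_b not in ("left", "right"):
        raise ValueError("ends must be 'left' or 'right'")
    a = replicon_a.sequence if end_a == "left" else reverse_complement(replicon_a.sequence)
    b = replicon_b.sequence if end_b == "left" else reverse_complement(replicon_b.sequence)
    seed = _find_seed(a, b, seed_len, max_scan)
    if seed is None:
        return None
    i, j = seed
    max_len = min(len(a), len(b)) - max(i, j)
    cols = _extend_inward(a[i:], b[j:], min_identity, window, band, max_len=max_len)
    if i or j:
        stub_band = max(band, abs(i - j) + 2)
        _, stub_cols = banded_align(a[:i][::-1], b[:j][::-1], stub_band)
        cols = stub_cols[::-1] + cols
    if not cols:
        return None
    matches, mismatches, indels = _columns_stats(cols)
    total = len(cols)
    identity = 100.0 * matches / total
    if identity < min_identity:
        return None
    return EndHomologyReport(
        replicon_a=replicon_a.id, replicon_b=replicon_b.id,
        end_a=end_a, end_b=end_b, length=total, percent_identity=identity,
        matches=matches, mismatches=mismatches, indels=indels,
    )


# ---------------------------------------------------------------------------
# Motif scan
# ---------------------------------------------------------------------------

def _hamming_scan(seq: str, motif: str, max_mismatches: int) -> list[tuple[int, int]]:
    """(0-based position, mismatches) of approximate occurrences of motif."""
    n, m = len(seq), len(motif)
    if m > n:
        return []
    S = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for k, ch in enumerate(motif.encode("ascii")):
        mism += S[k:k + n - m + 1] != ch
    pos = np.nonzero(mism <= max_mismatches)[0]
    return [(int(p), int(mism[p])) for p in pos]


def find_motif(replicon: Replicon, motif: str, max_mismatches: int = 0) -> MotifHits:
    """All sites within Hamming distance ``max_mismatches`` of motif, both
    strands.  A palindromic motif (equal to its own reverse complement) is
    scanned on the forward strand only, each site reported once."""
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over {A,C,G,T}")
    seq = replicon.sequence
    palindromic = motif == reverse_complement(motif)
    hits: list[tuple[int, str, int]] = []
    for p, d in _hamming_scan(seq, motif, max_mismatches):
        hits.append((p + 1, "+", d))
    if not palindromic:
        rc = reverse_complement(motif)
        for p, d in _hamming_scan(seq, rc, max_mismatches):
            hits.append((p + 1, "-", d))
    hits.sort()
    return MotifHits(motif=motif, replicon_id=replicon.id, hits=hits,
                     palindromic=palindromic)


# ---------------------------------------------------------------------------
# k-mer dot plot
# ---------------------------------------------------------------------------

def dotplot_kmers(seq_a: str, seq_b: str, k: int = 12,
                  max_points: int = 500_000,
                  seq_a_id: str = "a", seq_b_id: str = "b") -> DotPlot:
    """Exact shared k-mers between two sequences, forward and reverse.

    A point (i, j, '+') means seq_a[i:i+k] == seq_b[j:j+k] (1-based starts);
    strand '-' means the k-mer of seq_b matches the reverse complement.
    When the point count exceeds ``max_points`` the list is downsampled
    uniformly (every ceil(n/max_points)-th point); the full count is reported.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        index.setdefault(seq_a[i:i + k], []).append(i + 1)
    points: list[tuple[int, int, str]] = []
    for j in range(len(seq_b) - k + 1):
        word = seq_b[j:j + k]
        for i in index.get(word, ()):
            points.append((i, j + 1, "+"))
        rc = reverse_complement(word)
        if rc != word:
            for i in index.get(rc, ()):
                points.append((i, j + 1, "-"))
    n_total = len(points)
    if n_total > max_points:
        stride = -(-n_total // max_points)
        points = points[::stride]
        logger.info("dotplot downsampled: %d of %d points kept", len(points), n_total)
    return DotPlot(seq_a_id=seq_a_id, seq_b_id=seq_b_id, k=k,
                   points=points, n_total_points=n_total)
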