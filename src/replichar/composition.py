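"""Per-replicon G+C content and sliding-window GC-skew profiles.

GC skew per window is (G - C)/(G + C); its cumulative sum changes slope near
the replication origin and terminus, so the cumulative-skew extrema are a
cheap origin/terminus locator.  The skew of a zero-(G+C) window is defined
as 0 so cumulative series stay total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Replicon

#: defaults: fine enough to localise features at ~0.1 Mb resolution,
#: coarse enough for desk-scale plots
DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 5_000


class UndefinedGcError(ValueError):
    """Sequence has no unambiguous bases, so G+C content is undefined."""


@dataclass
class SkewProfile:
    replicon_id: str
    window_size: int
    step: int
    centers: np.ndarray       # 1-based window centres
    gc_fraction: np.ndarray   # in [0, 1]
    skew: np.ndarray          # in [-1, 1]
    cumulative: np.ndarray    # running sum of skew
    short_last_window: bool = False

    @property
    def extrema(self) -> tuple[int, int]:
        return skew_extrema(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicon_id": self.replicon_id,
            "center": self.centers,
            "gc_percent": self.gc_fraction * 100.0,
            "skew": self.skew,
            "cumulative_skew": self.cumulative,
        })


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T); N and other ambiguity codes are excluded.

    Multiply by 100 for the mol% convention used in reports.
    """
    if not sequence:
        raise UndefinedGcError("empty sequence")
    seq = sequence.upper()
    g = seq.count("G")
    c = seq.count("C")
    denom = seq.count("A") + seq.count("T") + g + c
    if denom == 0:
        raise UndefinedGcError("sequence has no unambiguous bases")
    return (g + c) / denom


def _base_counts(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position indicator arrays for G, C and unambiguous bases."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(np.int64)
    return is_g, is_c, is_g + is_c + is_at


def window_skew(window: str) -> float:
    """(G - C)/(G + C) for one window; 0 when the window has no G or C."""
    seq = window.upper()
    g = seq.count("G")
    c = seq.count("C")
    return 0.0 if g + c == 0 else (g - c) / (g + c)


def sliding_windows(replicon: Replicon, window_size: int = DEFAULT_WINDOW,
                    step: int = DEFAULT_STEP) -> SkewProfile:
    """Sliding-window G+C and GC-skew profile with cumulative skew.

    Circular replicons wrap the end-start junction; on linear replicons the
    last short window is kept and flagged.  A window larger than a linear
    replicon degrades to a single whole-sequence window.
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    n = replicon.length
    seq = replicon.sequence.upper()
    short_last = False
    if window_size > n and replicon.topology != "circular":
        import logging
        logging.getLogger("replichar").warning(
            "window %d > length %d on linear %s; using one whole-sequence window",
            window_size, n, replicon.id)
        window_size = n
    if replicon.topology == "circular":
        ext = seq + seq[:window_size]  # wrap the junction
        starts = np.arange(0, n, step)
    else:
        ext = seq
        starts = np.arange(0, max(n - window_size, 0) + 1, step)
        if len(starts) == 0:
            starts = np.array([0])
        # keep a trailing short window if the tiling does not reach the end
        if starts[-1] + window_size < n:
            starts = np.append(starts, starts[-1] + step)
            short_last = True
    is_g, is_c, is_acgt = _base_counts(ext)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    ca = np.concatenate([[0], np.cumsum(is_acgt)])
    ends = np.minimum(starts + window_size, len(ext))
    g = cg[ends] - cg[starts]
    c = cc[ends] - cc[starts]
    unamb = ca[ends] - ca[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        gc_frac = np.where(unamb > 0, (g + c) / unamb, np.nan)
        skew = np.where(g + c > 0, (g - c) / np.maximum(g + c, 1), 0.0)
    centers = starts + (ends - starts + 1) // 2  # 1-based centre
    if replicon.topology == "circular":
        centers = (centers - 1) % n + 1
    return SkewProfile(
        replicon_id=replicon.id, window_size=window_size, step=step,
        centers=centers.astype(int), gc_fraction=gc_frac, skew=skew,
        cumulative=np.cumsum(skew), short_last_window=short_last,
    )


def skew_extrema(profile: SkewProfile) -> tuple[int, int]:
    """Centres of the global max and min of cumulative skew.

    Ties break to the smallest centre.  Under the (G-C)/(G+C) convention the
    cumulative minimum falls near the replication origin of genomes with
    leading/lagging strand bias, the maximum near the terminus.
    """
    if len(profile.centers) == 0:
        raise ValueError("empty profile")
    cum = profile.cumulative
    return int(profile.centers[int(np.argmax(cum))]), int(profile.centers[int(np.argmin(cum))])


def skew_segments(profile: SkewProfile, slope_threshold: float = 0.02,
                  min_run: int = 10) -> list[tuple[int, int, str]]:
    """Maximal runs of windows by skew sign.

    Runs of >= ``min_run`` consecutive windows with |skew| < ``slope_threshold``
    are labelled "plateau"; other runs are labelled "+" or "-" by sign.
    Returns (start_center, end_center, label) triples.
    """
    if slope_threshold <= 0 or min_run <= 0:
        raise ValueError("thresholds must be positive")
    labels = np.where(np.abs(profile.skew) < slope_threshold, "0",
                      np.where(profile.skew > 0, "+", "-"))
    segments: list[tuple[int, int, str]] = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        segments.append((i, j, labels[i]))
        i = j + 1
    # near-zero runs shorter than min_run are absorbed into neighbours by sign
    out: list[tuple[int, int, str]] = []
    for (i, j, lab) in segments:
        if lab == "0" and (j - i + 1) < min_run:
            mean = float(np.mean(profile.skew[i:j + 1]))
            lab = "+" if mean >= 0 else "-"
        name = "plateau" if lab == "0" else lab
        start_c = int(profile.centers[i])
        end_c = int(profile.centers[j])
        if out and out[-1][2] == name:
            out[-1] = (out[-1][0], end_c, name)
        else:
            out.append((start_c, end_c, name))
    return out
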