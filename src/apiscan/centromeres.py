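"""Pericentromere detection from reference GC content.

Honey-bee pericentromeric tracts are GC-poor over extended segments.  The
detector scores 10-kbp windows +1 below the genome-wide mean GC, -1 above and
0 at equality or where no bases are called, accumulates the scores left to
right per chromosome, seeds on the 0.5-Mb (50-window) span with the highest
net score gain, extends by 10-window blocks while a block adds at least +5,
and finally by single windows while each adds +1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SEED_WINDOWS = 50
BLOCK = 10
BLOCK_MIN_GAIN = 5


@dataclass
class GCWindow:
    chrom: str
    index: int
    start: int   # 1-based inclusive
    end: int
    gc_fraction: float  # nan when no bases called
    score: int


@dataclass
class CentromereRegion:
    chrom: str
    start_window: int
    end_window: int  # inclusive ordinals
    start: int       # bp, 1-based inclusive
    end: int
    score_gain: int


def gc_windows(
    sequences: dict[str, str] | str | Path, window_bp: int = 10_000
) -> tuple[list[GCWindow], float]:
    """Per-window GC fractions and the genome-wide mean GC.

    ``sequences`` is a dict of chromosome sequences or a FASTA path.  N (and
    any non-ACGT) bases are excluded from numerator and denominator; windows
    with no called bases get an undefined fraction and score 0.  The genome
    mean is computed over all called bases, then each window scores +1 below
    the mean, -1 above, 0 at equality.
    """
    if not isinstance(sequences, dict):
        from pyfaidx import Fasta

        fa = Fasta(str(sequences))
        sequences = {name: str(fa[name][:]) for name in fa.keys()}
    if not sequences or all(len(s) == 0 for s in sequences.values()):
        raise ValueError("empty FASTA input")

    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    total_gc = 0
    total_called = 0
    for c, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_at = (arr == ord("A")) | (arr == ord("T"))
        called = is_gc | is_at
        n_windows = (len(arr) - 1) // window_bp + 1 if len(arr) else 0
        idx = np.arange(len(arr)) // window_bp
        gc_counts = np.bincount(idx, weights=is_gc, minlength=n_windows)
        called_counts = np.bincount(idx, weights=called, minlength=n_windows)
        per_chrom[c] = (gc_counts, called_counts)
        total_gc += int(is_gc.sum())
        total_called += int(called.sum())
    if total_called == 0:
        raise ValueError("no called bases in input")
    genome_mean = total_gc / total_called

    out: list[GCWindow] = []
    for c, seq in sequences.items():
        gc_counts, called_counts = per_chrom[c]
        for k in range(len(gc_counts)):
            if called_counts[k] > 0:
                frac = gc_counts[k] / called_counts[k]
                score = 1 if frac < genome_mean else (-1 if frac > genome_mean else 0)
            else:
                frac, score = np.nan, 0
            out.append(GCWindow(
                chrom=c, index=k, start=k * window_bp + 1,
                end=min((k + 1) * window_bp, len(seq)),
                gc_fraction=frac, score=score,
            ))
    return out, genome_mean


def cumulative_scores(windows: list[GCWindow]) -> dict[str, np.ndarray]:
    """Left-to-right prefix sums of window scores per chromosome."""
    tracks: dict[str, np.ndarray] = {}
    for c in dict.fromkeys(w.chrom for w in windows):
        scores = np.array([w.score for w in windows if w.chrom == c])
        tracks[c] = np.cumsum(scores)
    return tracks


def detect_pericentromere(
    track: np.ndarray | None, windows: list[GCWindow]
) -> CentromereRegion | None:
    """Seed-and-extend pericentromere call for one chromosome.

    Seed: the contiguous 50-window span with the highest net increase of
    the cumulative track (ties to the leftmost); chromosomes shorter than
    50 windows, or whose best span has non-positive gain, yield no region.
    The seed is extended outward by 10-window blocks whenever the block's
    net score is at least +5 (partial blocks at chromosome edges are not
    absorbed), then by single windows while each scores +1.

    ``track`` may pass a precomputed cumulative-score track (as from
    :func:`cumulative_scores`); when None it is derived from the windows.
    """
    w_scores = np.array([w.score for w in windows])
    if track is not None and len(track) != len(w_scores):
        raise ValueError("track length does not match window count")
    n = len(w_scores)
    if n < SEED_WINDOWS:
        return None
    cum = np.concatenate([[0], np.cumsum(w_scores)])
    gains = cum[SEED_WINDOWS:] - cum[:-SEED_WINDOWS]
    best = int(np.argmax(gains))  # argmax takes the leftmost maximum
    if gains[best] <= 0:
        return None
    lo, hi = best, best + SEED_WINDOWS - 1  # inclusive window ordinals

    # block extension, left and right independently
    while lo - BLOCK >= 0 and w_scores[lo - BLOCK:lo].sum() >= BLOCK_MIN_GAIN:
        lo -= BLOCK
    while hi + BLOCK < n and w_scores[hi + 1:hi + 1 + BLOCK].sum() >= BLOCK_MIN_GAIN:
        hi += BLOCK
    # single-window extension
    while lo - 1 >= 0 and w_scores[lo - 1] == 1:
        lo -= 1
    while hi + 1 < n and w_scores[hi + 1] == 1:
        hi += 1

    return CentromereRegion(
        chrom=windows[0].chrom,
        start_window=lo, end_window=hi,
        start=windows[lo].start, end=windows[hi].end,
        score_gain=int(w_scores[lo:hi + 1].sum()),
    )


def detect_all(
    sequences: dict[str, str] | str | Path, window_bp: int = 10_000
) -> tuple[dict[str, CentromereRegion | None], float]:
    """Run the full detector for every chromosome in the input."""
    windows, mean_gc = gc_windows(sequences, window_bp)
    out: dict[str, CentromereRegion | None] = {}
    for c in dict.fromkeys(w.chrom for w in windows):
        ws = [w for w in windows if w.chrom == c]
        out[c] = detect_pericentromere(None, ws)
    return out, mean_gc


def regions_to_bed(regions: dict[str, CentromereRegion | None]) -> pd.DataFrame:
    """0-based half-open BED frame of detected regions."""
    rows = [
        {"chrom": c, "start": r.start - 1, "end": r.end, "score_gain": r.score_gain}
        for c, r in regions.items() if r is not None
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score_gain"])
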