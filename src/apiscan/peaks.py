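"""F_ST outlier peaks: quantile seeds, constrained extension, gene
annotation, gene-wise F_ST, hypergeometric enrichment and recombination
ratios.

A peak seeds on a contiguous run of 10-kbp windows at or above the 0.998
quantile of all defined window values.  It is then extended one adjacent
window at a time (alternating sides, left first): a window is accepted iff
its own value is at or above the 0.98 quantile and the peak's SNP-weighted
mean F_ST (ratio of summed variance components) stays at or above the 0.99
quantile; a side closes on its first rejection.  Gaps are never jumped and
adjacent seed runs merge before extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import WindowStat


@dataclass
class Thresholds:
    q998: float
    q99: float
    q98: float
    n_values: int


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    windows: list[WindowStat] = field(repr=False)
    weighted_mean_fst: float = np.nan
    genes: list[str] = field(default_factory=list)
    pericentromeric: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def quantile_thresholds(window_values: np.ndarray) -> Thresholds:
    """Empirical 0.998 / 0.99 / 0.98 quantiles of the defined window values
    (linear-interpolation definition); undefined windows are excluded."""
    v = np.asarray(window_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no defined window values")
    q998, q99, q98 = np.quantile(v, [0.998, 0.99, 0.98])
    return Thresholds(float(q998), float(q99), float(q98), int(v.size))


def _weighted_mean(windows: list[WindowStat]) -> float:
    num = sum(w.numerator_sum for w in windows if np.isfinite(w.numerator_sum))
    den = sum(w.denominator_sum for w in windows if np.isfinite(w.denominator_sum))
    return num / den if den != 0 else np.nan


def call_peaks(windows: list[WindowStat], thresholds: Thresholds) -> list[Peak]:
    """Seed-and-extend peak calling over per-chromosome window series.

    The SNP-count weighting of the peak mean is implicit in the ratio of
    summed per-window variance-component sums.
    """
    peaks: list[Peak] = []
    for c in dict.fromkeys(w.chrom for w in windows):
        ws = [w for w in windows if w.chrom == c]
        vals = np.array([w.value for w in ws])
        seed_mask = np.isfinite(vals) & (vals >= thresholds.q998)
        if not seed_mask.any():
            continue
        # contiguous seed runs (adjacent seed windows merge)
        runs = []
        i = 0
        n = len(ws)
        while i < n:
            if seed_mask[i]:
                j = i
                while j + 1 < n and seed_mask[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        for lo, hi in runs:
            lo, hi = _extend(ws, vals, lo, hi, thresholds)
            member = ws[lo:hi + 1]
            peaks.append(Peak(
                chrom=str(c), start=member[0].start, end=member[-1].end,
                windows=member, weighted_mean_fst=_weighted_mean(member),
            ))
    return peaks


def _extend(ws, vals, lo, hi, thr) -> tuple[int, int]:
    """Alternating-side extension, left first, per-acceptance mean check."""
    n = len(ws)
    open_left, open_right = True, True
    side_left = True
    while open_left or open_right:
        if side_left and not open_left:
            side_left = False
        if not side_left and not open_right:
            side_left = True
        if side_left:
            cand = lo - 1
            if cand < 0 or not np.isfinite(vals[cand]) or vals[cand] < thr.q98:
                open_left = False
            else:
                mean = _weighted_mean(ws[cand:hi + 1])
                if np.isfinite(mean) and mean >= thr.q99:
                    lo = cand
                else:
                    open_left = False
            side_left = False
        else:
            cand = hi + 1
            if cand >= n or not np.isfinite(vals[cand]) or vals[cand] < thr.q98:
                open_right = False
            else:
                mean = _weighted_mean(ws[lo:cand + 1])
                if np.isfinite(mean) and mean >= thr.q99:
                    hi = cand
                else:
                    open_right = False
            side_left = True
    return lo, hi


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _overlap(a_start, a_end, b_start, b_end) -> int:
    """Overlap length of two 1-based inclusive intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def annotate_peak_genes(peak: Peak, gene_models: pd.DataFrame) -> list[str]:
    """Genes belonging to a peak by the exon-overlap rule.

    A gene qualifies iff the fraction of its exons that overlap the peak by
    at least 50% of the exon's length is at least 30%.
    """
    out = []
    sub = gene_models[gene_models["chrom"] == peak.chrom]
    for _, g in sub.iterrows():
        exons = g["exons"]
        if not exons:
            continue
        qual = sum(
            1 for (a, b) in exons
            if _overlap(a, b, peak.start, peak.end) >= 0.5 * (b - a + 1)
        )
        if qual / len(exons) >= 0.30:
            out.append(g["gene_id"])
    peak.genes = out
    return out


def genewise_fst(per_snp: pd.DataFrame, gene_models: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ratio-of-sums F_ST over SNPs within the gene span
    (transcript bounds, introns included); genes with no usable SNPs get
    nan."""
    rows = []
    for _, g in gene_models.iterrows():
        sub = per_snp[
            (per_snp["chrom"] == g["chrom"])
            & (per_snp["pos"] >= g["start"])
            & (per_snp["pos"] <= g["end"])
        ]
        usable = sub[np.isfinite(sub["d"])]
        if len(usable) and usable["d"].sum() != 0:
            val = usable["a"].sum() / usable["d"].sum()
        else:
            val = np.nan
        rows.append({
            "gene_id": g["gene_id"], "chrom": g["chrom"],
            "start": g["start"], "end": g["end"],
            "n_snps": int(len(usable)), "fst": val,
        })
    return pd.DataFrame(rows)


def hypergeom_enrichment(
    foreground_ids: set[str] | list[str],
    background_ids: set[str] | list[str],
    term_sets: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with Benjamini–Hochberg FDR.

    For each term: N = |background|, K = |term & background|,
    n = |foreground|, k = |term & foreground|; p = P(X >= k).
    """
    fg = set(foreground_ids)
    bg = set(background_ids)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    rows = []
    for term, members in term_sets.items():
        K = len(members & bg)
        k = len(members & fg)
        p = float(stats.hypergeom.sf(k - 1, len(bg), K, len(fg))) if K else 1.0
        rows.append({"term": term, "K": K, "k": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < alpha
    return df


def recomb_ratio(peak: Peak, recomb_map: pd.DataFrame) -> float:
    """Length-weighted mean recombination rate inside the peak over the
    length-weighted chromosome mean.  The map is BED-like (0-based
    half-open) with a ``rate`` column."""
    sub = recomb_map[recomb_map["chrom"] == peak.chrom]
    if not len(sub):
        raise ValueError(f"no recombination intervals for {peak.chrom}")
    lens = (sub["end"] - sub["start"]).to_numpy(dtype=float)
    chrom_mean = float(np.average(sub["rate"], weights=lens))
    # peak in 0-based half-open coordinates
    ps, pe = peak.start - 1, peak.end
    ov = np.minimum(sub["end"], pe) - np.maximum(sub["start"], ps)
    ov = np.maximum(ov.to_numpy(dtype=float), 0.0)
    if ov.sum() == 0:
        return np.nan
    peak_mean = float(np.average(sub["rate"], weights=ov))
    return peak_mean / chrom_mean


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": p.chrom, "start": p.start, "end": p.end,
            "n_windows": p.n_windows, "weighted_mean_fst": p.weighted_mean_fst,
            "genes": ",".join(p.genes), "pericentromeric": p.pericentromeric,
        }
        for p in peaks
    ])
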