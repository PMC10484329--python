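"""Ancestry-probability reductions, correlations and the climate-class test.

Local-ancestry inference supplies, per SNP and individual, posterior
probabilities over the six diplotype states (CC, CM, CA, MM, MA, AA).  These
reduce to a per-SNP probability of African ancestry

    p(A) = p(AA) + (p(MA) + p(CA)) / 2

(and analogously p(C), p(M), the three summing to one).  Population tracks
average p(A) per SNP within each population; the lowland-minus-highland
difference is the per-SNP ancestry drop used in the correlation analyses.

The dependent-correlation comparison implements Dunn & Clark's z with the
Hittner, May & Silver (2003) backtransformed-average modification for two
overlapping correlations sharing one variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STATES = ("CC", "CM", "CA", "MM", "MA", "AA")


def combine_posterior_A(posterior_row) -> float:
    """p(A) = p(AA) + (p(MA) + p(CA))/2 for one 6-state posterior row."""
    row = np.asarray(posterior_row, dtype=float)
    if row.shape[-1] != 6:
        raise ValueError("expected 6 diplotype-state probabilities")
    total = row.sum(axis=-1)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise ValueError("posterior probabilities must sum to 1")
    iCA, iMA, iAA = STATES.index("CA"), STATES.index("MA"), STATES.index("AA")
    return row[..., iAA] + (row[..., iMA] + row[..., iCA]) / 2.0


def combine_posterior_all(posterior_row) -> np.ndarray:
    """(p(C), p(M), p(A)) for one row; the three sum to 1."""
    row = np.asarray(posterior_row, dtype=float)
    i = {s: k for k, s in enumerate(STATES)}
    pA = row[..., i["AA"]] + (row[..., i["MA"]] + row[..., i["CA"]]) / 2.0
    pC = row[..., i["CC"]] + (row[..., i["CM"]] + row[..., i["CA"]]) / 2.0
    pM = row[..., i["MM"]] + (row[..., i["CM"]] + row[..., i["MA"]]) / 2.0
    return np.stack([pC, pM, pA], axis=-1)


def population_ancestry_track(
    posteriors: pd.DataFrame,
    populations: dict[str, str],
    lowland: str = "lowland",
    highland: str = "highland",
) -> pd.DataFrame:
    """Per-SNP mean p(A) per population and the lowland-highland difference.

    ``posteriors`` has columns snp, sample, pCC..pAA; ``populations`` maps
    sample -> population label.  Returns a frame indexed by snp with one
    ``pA_<pop>`` column per population and ``delta`` = lowland - highland.
    """
    probs = posteriors[[f"p{s}" for s in STATES]].to_numpy()
    pA = combine_posterior_A(probs)
    df = pd.DataFrame({
        "snp": posteriors["snp"].to_numpy(),
        "pop": posteriors["sample"].map(populations),
        "pA": pA,
    })
    if df["pop"].isna().any():
        missing = posteriors.loc[df["pop"].isna(), "sample"].unique()
        raise ValueError(f"samples without population label: {missing[:5]}")
    track = df.pivot_table(index="snp", columns="pop", values="pA", aggfunc="mean")
    track.columns = [f"pA_{c}" for c in track.columns]
    for pop in (lowland, highland):
        if f"pA_{pop}" not in track:
            raise ValueError(f"empty population {pop!r}")
    track["delta"] = track[f"pA_{lowland}"] - track[f"pA_{highland}"]
    return track


def correlate_fst_ancestry(
    window_fst: pd.DataFrame,
    track: pd.DataFrame,
    positions: pd.DataFrame,
    window_bp: int = 10_000,
) -> tuple[float, float]:
    """Spearman correlation between windowed F_ST and window-averaged
    ancestry difference.

    ``positions`` maps snp id to (chrom, pos) so per-SNP delta can be
    averaged into the F_ST windows; windows lacking either quantity are
    dropped.
    """
    t = track.join(positions.set_index("snp"))
    t["widx"] = (t["pos"] - 1) // window_bp
    wdelta = t.groupby(["chrom", "widx"])["delta"].mean()
    wf = window_fst.copy()
    wf["widx"] = (wf["start"] - 1) // window_bp
    wf = wf.set_index(["chrom", "widx"])
    joined = wf.join(wdelta, how="inner").dropna(subset=["value", "delta"])
    if len(joined) < 3:
        raise ValueError("fewer than 3 paired windows")
    rho, p = stats.spearmanr(joined["value"], joined["delta"])
    return float(rho), float(p)


def correlate_clines(
    track: pd.DataFrame, steepness: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson correlation between per-SNP ancestry difference and cline
    steepness over the SNP intersection."""
    j = track.join(steepness.set_index("snp"), how="inner").dropna(
        subset=["delta", "steepness"]
    )
    if not len(j):
        raise ValueError("empty SNP intersection")
    r, p = stats.pearsonr(j["delta"], j["steepness"])
    return float(r), float(p), int(len(j))


@dataclass
class CorrelationComparison:
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    z: float
    p: float


def compare_dependent_correlations(
    r_jk: float, r_jh: float, r_kh: float, n: int
) -> CorrelationComparison:
    """Compare two overlapping correlations from dependent groups.

    r_jk and r_jh share variable j; r_kh is the correlation between the two
    non-shared variables.  Dunn & Clark's z with the covariance evaluated at
    the backtransformed average of the two Fisher Z transforms (Hittner,
    May & Silver 2003); two-sided p from the standard normal.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r_jk, r_jh, r_kh):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must be in [-1, 1]")
    if abs(r_jk) == 1.0 or abs(r_jh) == 1.0:
        raise ValueError("degenerate |r| = 1")
    z_jk = math.atanh(r_jk)
    z_jh = math.atanh(r_jh)
    rbar = math.tanh((z_jk + z_jh) / 2.0)
    r2 = rbar * rbar
    cov = (
        r_kh * (1.0 - 2.0 * r2) - 0.5 * r2 * (1.0 - 2.0 * r2 - r_kh * r_kh)
    ) / ((1.0 - r2) ** 2)
    z = (z_jk - z_jh) * math.sqrt((n - 3.0) / (2.0 - 2.0 * cov))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(r_jk, r_jh, r_kh, n, float(z), float(p))


def classify_and_test(
    comparisons: pd.DataFrame,
    hl_level: float,
    ll_level: float,
    alpha: float = 0.001,
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Climate-class contingency test.

    ``comparisons`` has one row per external population with columns
    ``A_ancestry`` (its genome-wide A proportion), ``z`` and ``p`` from the
    dependent-correlation comparison, where positive z means the correlation
    with the highland population is the higher one.  Populations with
    A_ancestry below ``hl_level`` form the first class; those between
    ``hl_level`` and ``ll_level`` the second; others are excluded (logged in
    the returned frame).  The 2x2 table of class x (significantly higher
    correlation with highland at ``alpha``) is tested with a two-sided
    Fisher's exact test (hypergeometric enumeration).
    """
    df = comparisons.copy()
    df["cls"] = np.where(
        df["A_ancestry"] < hl_level, "below_highland",
        np.where(df["A_ancestry"] <= ll_level, "between", "excluded"),
    )
    df["sig_higher_hl"] = (df["z"] > 0) & (df["p"] < alpha)
    used = df[df["cls"] != "excluded"]
    table = np.array([
        [
            int(((used["cls"] == "below_highland") & used["sig_higher_hl"]).sum()),
            int(((used["cls"] == "below_highland") & ~used["sig_higher_hl"]).sum()),
        ],
        [
            int(((used["cls"] == "between") & used["sig_higher_hl"]).sum()),
            int(((used["cls"] == "between") & ~used["sig_higher_hl"]).sum()),
        ],
    ])
    p = fisher_exact_two_sided(table)
    return table, p, df


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 table by summing the
    probabilities of all tables (same margins) no more probable than the
    observed one."""
    p = float(stats.fisher_exact(np.asarray(table))[1])
    return p
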