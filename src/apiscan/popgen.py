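"""Diversity and divergence statistics.

Windowed nucleotide diversity (pi), Watterson's theta, per-SNP and windowed
Weir & Cockerham (1984) F_ST, genome-wide Reynolds, Weir & Cockerham (1983)
F_ST, pseudodiploid pairing of haploid drones, and KING-robust kinship.

Window convention: 1-based inclusive tiles [k*w+1, (k+1)*w] from position 1
on each chromosome.  Windowed F_ST is the ratio-of-sums ("weighted")
estimator: the sum of per-SNP variance-component numerators over the sum of
denominators, so negative per-SNP components are retained rather than
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import SNPMatrix, MISSING


@dataclass
class WindowStat:
    chrom: str
    start: int          # 1-based inclusive
    end: int
    n_snps: int
    value: float
    numerator_sum: float = np.nan
    denominator_sum: float = np.nan


def _window_index(pos: np.ndarray, window_bp: int) -> np.ndarray:
    return (pos - 1) // window_bp


def windows_to_frame(windows: list[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame([w.__dict__ for w in windows])


# ---------------------------------------------------------------------------
# pseudodiploids
# ---------------------------------------------------------------------------

def pair_haploids(
    matrix: SNPMatrix, drone_ids: list[str], seed: int
) -> tuple[SNPMatrix, list[tuple[str, str]], list[str]]:
    """Randomly pair haploid drones into pseudodiploid samples.

    With an odd drone count, one drone (chosen by the seeded shuffle) is
    dropped and reported.  Returns a matrix in which each drone pair is
    replaced by one diploid pseudodiploid sample, the pairing, and the list
    of dropped drones.
    """
    if len(drone_ids) < 2:
        raise ValueError("need at least two drones to pair")
    rng = np.random.default_rng(seed)
    order = list(drone_ids)
    rng.shuffle(order)
    dropped = [order.pop()] if len(order) % 2 else []
    pairs = [(order[i], order[i + 1]) for i in range(0, len(order), 2)]

    keep_idx = [i for i, s in enumerate(matrix.samples) if s not in set(drone_ids)]
    base = matrix.take_samples(np.array(keep_idx, dtype=int)) if keep_idx else None

    cols = []
    names, pops = [], []
    for a, b in pairs:
        ja = matrix.samples.index(a)
        jb = matrix.samples.index(b)
        g = np.full((matrix.n_sites, 2), MISSING, dtype=np.int8)
        g[:, 0] = matrix.genotypes[:, ja, 0]
        g[:, 1] = matrix.genotypes[:, jb, 0]
        # a pseudodiploid genotype is called only when both haploids are
        both = (g[:, 0] >= 0) & (g[:, 1] >= 0)
        g[~both] = MISSING
        cols.append(g)
        names.append(f"{a}+{b}")
        pops.append(str(matrix.populations[ja]))
    geno_new = np.stack(cols, axis=1)

    if base is not None:
        geno = np.concatenate([base.genotypes, geno_new], axis=1)
        samples = base.samples + names
        populations = np.concatenate([base.populations, np.array(pops, dtype=object)])
        ploidy = np.concatenate([base.ploidy, np.full(len(names), 2, np.int8)])
    else:
        geno, samples = geno_new, names
        populations = np.array(pops, dtype=object)
        ploidy = np.full(len(names), 2, np.int8)
    out = SNPMatrix(
        chrom=matrix.chrom, pos=matrix.pos, ref=matrix.ref, alt=matrix.alt,
        genotypes=geno, samples=samples, populations=populations, ploidy=ploidy,
    )
    return out, pairs, dropped


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity_windows(
    matrix: SNPMatrix,
    population: str | None = None,
    window_bp: int = 50_000,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[WindowStat], float]:
    """Windowed nucleotide diversity and its genome average.

    Per-site pi is the unbiased pairwise heterozygosity 2*p*(1-p)*n/(n-1)
    over called allele copies; window pi is the sum over SNPs in the window
    divided by the window length in bp, and the genome value the unweighted
    mean over windows with at least one called site.
    """
    idx = matrix.sample_indices(population)
    n = matrix.called_alleles(idx)
    p = matrix.alt_freq(idx)
    ok = (n > 1) & np.isfinite(p)
    with np.errstate(invalid="ignore"):
        site_pi = np.where(ok, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1), 0.0)
    called = n > 0

    out: list[WindowStat] = []
    for c in pd.unique(matrix.chrom):
        m = matrix.chrom == c
        w = _window_index(matrix.pos[m], window_bp)
        length = chrom_lengths[c] if chrom_lengths else int(matrix.pos[m].max())
        n_windows = (length - 1) // window_bp + 1
        pi_sum = np.bincount(w, weights=site_pi[m], minlength=n_windows)
        n_called = np.bincount(w[called[m]], minlength=n_windows)
        n_snps = np.bincount(w, minlength=n_windows)
        for k in range(n_windows):
            out.append(WindowStat(
                chrom=str(c), start=k * window_bp + 1, end=(k + 1) * window_bp,
                n_snps=int(n_snps[k]),
                value=pi_sum[k] / window_bp if n_called[k] > 0 else np.nan,
            ))
    vals = np.array([w.value for w in out])
    genome = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
    return out, genome


def watterson_theta(
    matrix: SNPMatrix, total_bp: float, population: str | None = None
) -> float:
    """Watterson's theta per bp: S / (a_n * L), a_n the harmonic number over
    the sampled allele copies minus one."""
    idx = matrix.sample_indices(population)
    n_alleles = int(np.max(matrix.called_alleles(idx))) if matrix.n_sites else 0
    if n_alleles < 2:
        raise ValueError("need at least two sampled allele copies")
    p = matrix.alt_freq(idx)
    S = int(np.sum((p > 0) & (p < 1)))
    a_n = float(np.sum(1.0 / np.arange(1, n_alleles)))
    return S / (a_n * total_bp)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------

def wc_fst_components(
    matrix: SNPMatrix, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Per-SNP Weir & Cockerham (1984) two-population variance components.

    Returns a frame with columns chrom, pos, a (between-population
    component), d (total a+b+c) and fst (a/d, nan where d == 0).  Sample
    sizes are per-site called counts; haploid samples contribute a single
    allele copy with observed heterozygosity zero (entering as half an
    individual in the moment equations).
    """
    ia = matrix.sample_indices(pop_a)
    ib = matrix.sample_indices(pop_b)
    het = matrix.is_het()

    def pop_terms(idx):
        g = matrix.genotypes[:, idx, :]
        n_alleles = (g >= 0).sum(axis=(1, 2)).astype(float)
        alt = (g == 1).sum(axis=(1, 2)).astype(float)
        n_ind = n_alleles / 2.0  # haploids count half an individual
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / n_alleles, np.nan)
            h = np.where(n_ind > 0, het[:, idx].sum(axis=1) / n_ind, np.nan)
        return n_ind, p, h

    n1, p1, h1 = pop_terms(ia)
    n2, p2, h2 = pop_terms(ib)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        ntot = n1 + n2
        nc = (ntot - (n1 ** 2 + n2 ** 2) / ntot) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / ntot
        hbar = (n1 * h1 + n2 * h2) / ntot
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        pq = pbar * (1.0 - pbar)
        a = (nbar / nc) * (
            s2 - (pq - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pq - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        d = a + b + c
        fst = np.where(d != 0, a / d, np.nan)
    valid = (n1 >= 1) & (n2 >= 1) & np.isfinite(p1) & np.isfinite(p2)
    a = np.where(valid, a, np.nan)
    d = np.where(valid, d, np.nan)
    fst = np.where(valid, fst, np.nan)
    return pd.DataFrame({
        "chrom": matrix.chrom, "pos": matrix.pos,
        "a": a, "d": d, "fst": fst,
    })


def wc_fst_windowed(
    per_snp: pd.DataFrame,
    window_bp: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Windowed F_ST as the ratio of summed numerators over summed
    denominators; windows tile each chromosome from position 1."""
    out: list[WindowStat] = []
    for c, sub in per_snp.groupby("chrom", sort=False):
        w = _window_index(sub["pos"].to_numpy(), window_bp)
        length = chrom_lengths[c] if chrom_lengths else int(sub["pos"].max())
        n_windows = (length - 1) // window_bp + 1
        usable = np.isfinite(sub["d"].to_numpy())
        num = np.bincount(w[usable], weights=sub["a"].to_numpy()[usable],
                          minlength=n_windows)
        den = np.bincount(w[usable], weights=sub["d"].to_numpy()[usable],
                          minlength=n_windows)
        n_snps = np.bincount(w[usable], minlength=n_windows)
        for k in range(n_windows):
            out.append(WindowStat(
                chrom=str(c), start=k * window_bp + 1, end=(k + 1) * window_bp,
                n_snps=int(n_snps[k]),
                value=num[k] / den[k] if den[k] != 0 else np.nan,
                numerator_sum=float(num[k]), denominator_sum=float(den[k]),
            ))
    return out


def reynolds_terms(n1, n2, p1, p2):
    """Per-locus Reynolds, Weir & Cockerham (1983) coancestry numerator and
    denominator for two populations at a bi-allelic site.

    n_i: diploid-equivalent individuals sampled (called alleles / 2); p_i:
    alt allele frequency.  With a_i the sample-size-unbiased within-
    population gene diversity 2*p_i*(1-p_i)*2n_i/(2n_i - 1):

        num = (p1-p2)^2 - (n1+n2)(n1 a1 + n2 a2) / (4 n1 n2 (n1+n2-1))
        den = (p1-p2)^2 + (4 n1 n2 - n1 - n2)(n1 a1 + n2 a2)
                            / (4 n1 n2 (n1+n2-1))

    For identical populations E[num] ~ 0; for a fixed difference the ratio
    is exactly 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        ssd = (p1 - p2) ** 2
        a1 = 2.0 * p1 * (1.0 - p1) * (2.0 * n1) / (2.0 * n1 - 1.0)
        a2 = 2.0 * p2 * (1.0 - p2) * (2.0 * n2) / (2.0 * n2 - 1.0)
        mix = n1 * a1 + n2 * a2
        scale = 4.0 * n1 * n2 * (n1 + n2 - 1.0)
        num = ssd - (n1 + n2) * mix / scale
        den = ssd + (4.0 * n1 * n2 - n1 - n2) * mix / scale
    return num, den


def reynolds_fst_genomewide(matrix: SNPMatrix, pop_a: str, pop_b: str) -> float:
    """Genome-wide Reynolds coancestry F_ST: ratio of per-locus numerator
    and denominator sums across all usable SNPs."""
    ia = matrix.sample_indices(pop_a)
    ib = matrix.sample_indices(pop_b)

    def pop_terms(idx):
        n_alleles = matrix.called_alleles(idx).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0,
                         matrix.alt_alleles(idx) / n_alleles, np.nan)
        return n_alleles / 2.0, p

    n1, p1 = pop_terms(ia)
    n2, p2 = pop_terms(ib)
    valid = (n1 >= 1) & (n2 >= 1) & np.isfinite(p1) & np.isfinite(p2)
    num, den = reynolds_terms(n1[valid], n2[valid], p1[valid], p2[valid])
    num_sum = float(np.nansum(num))
    den_sum = float(np.nansum(den))
    if den_sum == 0:
        raise ValueError("zero Reynolds denominator genome-wide")
    return num_sum / den_sum


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipPair:
    sample_i: str
    sample_j: str
    phi: float
    n_shared_sites: int
    flagged: bool


def king_kinship(
    matrix: SNPMatrix,
    pairs: list[tuple[str, str]] | None = None,
    threshold: float = 0.044,
    min_shared: int = 100,
) -> list[KinshipPair]:
    """KING-robust pairwise kinship for diploid samples.

    phi = (N_het,het - 2*N_opposite_hom) / (N_het(i) + N_het(j)) over shared
    called sites; pairs with phi above ``threshold`` (the lowest value
    implying any degree of relatedness) are flagged.  A sample against
    itself gives phi = 0.5.
    """
    g = matrix.genotypes
    called = (g[:, :, 0] >= 0) & (g[:, :, 1] >= 0)
    het = matrix.is_het()
    dose = np.where(called, g[:, :, 0].astype(np.int16) + g[:, :, 1], -9)

    if pairs is None:
        dip = [s for s, pl in zip(matrix.samples, matrix.ploidy) if pl == 2]
        pairs = [(a, b) for k, a in enumerate(dip) for b in dip[k + 1:]]
    out = []
    for a, b in pairs:
        i = matrix.samples.index(a)
        j = matrix.samples.index(b)
        share = called[:, i] & called[:, j]
        hi = het[:, i] & share
        hj = het[:, j] & share
        n_hethet = int((hi & hj).sum())
        opp = share & (
            ((dose[:, i] == 0) & (dose[:, j] == 2))
            | ((dose[:, i] == 2) & (dose[:, j] == 0))
        )
        denom = int(hi.sum()) + int(hj.sum())
        if denom == 0 or int(share.sum()) < min_shared:
            phi = np.nan
        else:
            phi = (n_hethet - 2.0 * int(opp.sum())) / denom
        out.append(KinshipPair(a, b, phi, int(share.sum()),
                               bool(np.isfinite(phi) and phi > threshold)))
    return out
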