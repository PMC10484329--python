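"""Site and genotype filter cascade for joint-called honey-bee VCFs.

Order of the cascade: caller hard filters -> site filters (bi-allelic SNP,
QUAL > 100, mean depth <= 20, per-population missingness < 30%) -> drone
heterozygote handling -> minor-allele-count filter.  Re-running any step on
its own output is a no-op, and the removal log accounts for every input site.

Boundary semantics follow the printed inequalities: a site fails a hard
filter only strictly beyond its threshold (QD < 2, FS > 60, MQ < 40,
MQRankSum < -12.5, ReadPosRankSum < -8, SOR > 3); QUAL must strictly exceed
100; a mean depth of exactly 20 is retained; missingness of exactly 30% in
any population removes the site.  Missing hard-filter annotations never fail
a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import SNPMatrix, MISSING

HARD_FILTER_RULES = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
    "SOR": (">", 3.0),
}


@dataclass
class FilterLog:
    """Per-step removal counts; input = output + sum of removals."""

    input_sites: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    output_sites: int = 0

    def add(self, reason: str, n: int) -> None:
        self.removed[reason] = self.removed.get(reason, 0) + int(n)


def apply_hard_filters(annotations: pd.DataFrame) -> tuple[np.ndarray, list[list[str]]]:
    """Evaluate the caller hard filters per site.

    Returns a pass mask and, per site, the list of rules that fired.  A rule
    with a missing annotation does not fire.
    """
    n = len(annotations)
    reasons: list[list[str]] = [[] for _ in range(n)]
    ok = np.ones(n, dtype=bool)
    for key, (op, thr) in HARD_FILTER_RULES.items():
        if key not in annotations:
            continue
        col = pd.to_numeric(annotations[key], errors="coerce").to_numpy(dtype=float)
        if annotations[key].dtype == object:
            bad = annotations[key].notna() & ~np.isfinite(col)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric {key} annotation at site index {i}: "
                    f"{annotations[key].iloc[i]!r}"
                )
        with np.errstate(invalid="ignore"):
            fail = (col < thr) if op == "<" else (col > thr)
        fail &= np.isfinite(col)
        ok &= ~fail
        for i in np.flatnonzero(fail):
            reasons[i].append(key)
    return ok, reasons


def apply_site_filters(
    matrix: SNPMatrix,
    annotations: pd.DataFrame,
    max_mean_depth: float = 20.0,
    min_qual: float = 100.0,
    max_missing: float = 0.30,
    log: FilterLog | None = None,
) -> SNPMatrix:
    """Bi-allelic SNP / QUAL / depth / per-population missingness filters.

    Retains sites that are single-base bi-allelic SNPs with QUAL strictly
    above ``min_qual``, mean per-sample depth at most ``max_mean_depth``
    (sites lacking all DP values skip the depth rule), and missingness below
    ``max_missing`` in every population.
    """
    keep = np.ones(matrix.n_sites, dtype=bool)

    snp = np.array([
        len(str(r)) == 1 and len(str(a)) == 1 and str(a) != "."
        for r, a in zip(matrix.ref, matrix.alt)
    ])
    qual = pd.to_numeric(annotations["QUAL"], errors="coerce").to_numpy(dtype=float)
    qual_ok = np.isfinite(qual) & (qual > min_qual)

    dp_cols = [c for c in annotations.columns if c.startswith("DP:")]
    if dp_cols:
        dp = annotations[dp_cols].to_numpy(dtype=float)
        dp[dp < 0] = np.nan
        with np.errstate(invalid="ignore"):
            mean_dp = np.nanmean(dp, axis=1)
        depth_ok = ~(mean_dp > max_mean_depth)  # all-nan rows skip the rule
    else:
        depth_ok = np.ones(matrix.n_sites, dtype=bool)

    miss = matrix.is_missing()
    miss_ok = np.ones(matrix.n_sites, dtype=bool)
    for pop in np.unique(matrix.populations.astype(str)):
        idx = matrix.sample_indices(pop)
        frac = miss[:, idx].mean(axis=1)
        miss_ok &= frac < max_missing

    if log is not None:
        log.add("not_biallelic_snp", (~snp).sum())
        log.add("low_qual", (snp & ~qual_ok).sum())
        log.add("high_depth", (snp & qual_ok & ~depth_ok).sum())
        log.add("missingness", (snp & qual_ok & depth_ok & ~miss_ok).sum())
    keep = snp & qual_ok & depth_ok & miss_ok
    return matrix.take_sites(keep)


def handle_drone_heterozygotes(
    matrix: SNPMatrix,
    drone_samples: list[str] | np.ndarray,
    log: FilterLog | None = None,
) -> SNPMatrix:
    """Resolve artefactual heterozygous calls in haploid drones.

    Drones are diploid-coded by the caller.  Sites with exactly one
    heterozygous drone have that genotype set missing; sites with two or more
    are removed outright.  Surviving drone genotypes are converted to true
    haploid calls (single allele slot).
    """
    drone_set = set(drone_samples)
    if not drone_set:
        raise ValueError("drone sample set is empty")
    dcols = np.array([i for i, s in enumerate(matrix.samples) if s in drone_set])
    if dcols.size == 0:
        raise ValueError("no drone samples found in matrix")
    het = matrix.is_het()[:, dcols]
    n_het = het.sum(axis=1)

    g = matrix.genotypes.copy()
    one = n_het == 1
    for i in np.flatnonzero(one):
        j = dcols[np.flatnonzero(het[i])[0]]
        g[i, j, :] = MISSING
    # haploid-code all drones: keep slot 0, clear slot 1
    for j in dcols:
        g[:, j, 1] = MISSING
    ploidy = matrix.ploidy.copy()
    ploidy[dcols] = 1

    keep = n_het < 2
    if log is not None:
        log.add("multi_het_drone", (~keep).sum())
        log.removed.setdefault("single_het_drone_genotypes_masked", 0)
        log.removed["single_het_drone_genotypes_masked"] += int(one.sum())
    out = SNPMatrix(
        chrom=matrix.chrom, pos=matrix.pos, ref=matrix.ref, alt=matrix.alt,
        genotypes=g, samples=matrix.samples,
        populations=matrix.populations, ploidy=ploidy,
    )
    return out.take_sites(keep)


def mac_filter(
    matrix: SNPMatrix, min_count: int = 3, log: FilterLog | None = None
) -> SNPMatrix:
    """Remove sites with minor allele count below ``min_count``.

    Missing genotypes are excluded from the counts; haploid samples
    contribute one allele copy.
    """
    mac = matrix.minor_allele_count()
    keep = mac >= min_count
    if log is not None:
        log.add("low_mac", (~keep).sum())
    return matrix.take_sites(keep)


def run_filter_cascade(
    matrix: SNPMatrix,
    annotations: pd.DataFrame,
    drone_samples: list[str] | None = None,
    min_mac: int = 3,
) -> tuple[SNPMatrix, FilterLog]:
    """Full cascade: hard filters -> site filters -> drones -> MAC."""
    log = FilterLog(input_sites=matrix.n_sites)
    ok, _ = apply_hard_filters(annotations)
    log.add("hard_filter", (~ok).sum())
    matrix = matrix.take_sites(ok)
    annotations = annotations.loc[ok].reset_index(drop=True)
    matrix = apply_site_filters(matrix, annotations, log=log)
    if drone_samples:
        matrix = handle_drone_heterozygotes(matrix, drone_samples, log=log)
    matrix = mac_filter(matrix, min_count=min_mac, log=log)
    log.output_sites = matrix.n_sites
    return matrix, log


def inbreeding_coefficient(matrix: SNPMatrix, sample: str | int) -> float:
    """Method-of-moments inbreeding coefficient F for one diploid sample.

    F = (O - E) / (N - E) where O is the observed homozygous-site count, E
    the homozygosity expected from the sample allele frequencies, and N the
    number of usable (called, polymorphic-information) sites — the
    homozygosity-excess estimator reported per sample by vcftools --het.
    """
    j = matrix.samples.index(sample) if isinstance(sample, str) else int(sample)
    g = matrix.genotypes[:, j, :]
    called = (g[:, 0] >= 0) & (g[:, 1] >= 0)

    n = matrix.called_alleles()
    p = matrix.alt_freq()
    usable = called & (n > 1) & np.isfinite(p)
    if usable.sum() == 0:
        raise ValueError(f"no usable sites for sample {sample!r}")
    p = p[usable]
    nn = n[usable]
    # small-sample-corrected expected homozygosity, as in PLINK/vcftools --het
    exp_hom = 1.0 - 2.0 * p * (1.0 - p) * nn / (nn - 1.0)
    obs_hom = (g[usable, 0] == g[usable, 1]).astype(float)
    E = exp_hom.sum()
    O = obs_hom.sum()
    N = float(usable.sum())
    if N == E:
        raise ValueError("expected homozygosity equals site count; F undefined")
    return (O - E) / (N - E)


def thin_snps(matrix: SNPMatrix, min_bp: int = 500) -> SNPMatrix:
    """Greedy left-to-right thinning: keep a site iff it lies at least
    ``min_bp`` beyond the last kept site on its chromosome."""
    keep = np.zeros(matrix.n_sites, dtype=bool)
    last: dict[str, int] = {}
    for i in range(matrix.n_sites):
        c = matrix.chrom[i]
        if c not in last or matrix.pos[i] >= last[c] + min_bp:
            keep[i] = True
            last[c] = int(matrix.pos[i])
    return matrix.take_sites(keep)
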