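"""Neutral two-deme split null for per-SNP F_ST.

Simulates independent bi-allelic SNPs under a clean-split coalescent model:
an ancestral panmictic population splits into two demes of unchanged, equal
size, with no subsequent gene flow.  Each locus carries exactly one mutation,
placed uniformly at random along the total branch length of its genealogy, so
every simulated SNP is segregating in the pooled sample.

Time is measured in units of 4N generations, matching Hudson's ``ms``
convention: k lineages within a deme (or in the merged ancestral population)
coalesce at total rate k(k-1) per unit time.  The divergence-time parameter of
the split model is therefore half the 2N-scaled time T obtained from F_ST via
``fst_to_split_time`` ("used T/2 in the simulation").

The distribution of the exported SNP does not depend on the locus mutation
rate (exactly one segregating site is conditioned on); theta is retained in
the model for interface parity with the mutation-rate parameterisation and is
only logged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "SplitModel",
    "fst_to_split_time",
    "split_time_to_fst",
    "scale_theta",
    "simulate_genealogy",
    "drop_single_mutation",
    "simulate_snp_panel",
    "wc_fst_haploid_counts",
    "enrichment_test",
]


@dataclass
class SplitModel:
    """Parameters of the two-deme split null.

    n1, n2
        Sampled allele copies (haploid lineages) per deme.
    t_split
        Split time in units of 4N generations.
    theta_locus
        Scaled locus mutation rate 4*N*mu*L; logged only (one segregating
        site is conditioned on).
    n_loci
        Number of independent SNPs to simulate.
    """

    n1: int = 28
    n2: int = 30
    t_split: float = 0.0150
    theta_locus: float = 4.23
    n_loci: int = 248_598
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least two sampled copies per deme")
        if self.t_split < 0:
            raise ValueError("t_split must be non-negative")
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")


def fst_to_split_time(fst: float) -> float:
    """Convert an F_ST value to the scaled split time T = -ln(1 - F_ST)/2.

    T is in units of 2N generations; the ms-scaled simulation input is T/2.
    The inverse map is ``split_time_to_fst``.
    """
    if not 0 <= fst < 1:
        raise ValueError(f"fst must be in [0, 1), got {fst}")
    return -math.log(1.0 - fst) / 2.0


def split_time_to_fst(t: float) -> float:
    """Inverse of :func:`fst_to_split_time`: F_ST = 1 - exp(-2T)."""
    return 1.0 - math.exp(-2.0 * t)


def scale_theta(locus_bp: float, theta_per_bp: float) -> float:
    """Locus-scaled mutation rate: length in bp times per-bp theta."""
    if locus_bp < 0 or theta_per_bp < 0:
        raise ValueError("locus length and per-bp theta must be non-negative")
    return locus_bp * theta_per_bp


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sim_panel_kernel(n1, n2, t_split, n_loci, seed):  # pragma: no cover
    """Simulate n_loci genealogies, drop one mutation on each, and return
    per-deme derived allele counts.  Runs under numba; the pure-python
    reference path is `simulate_genealogy` + `drop_single_mutation`."""
    np.random.seed(seed)
    ntot = n1 + n2
    nlin = 2 * ntot - 1  # tips + internal nodes
    out1 = np.empty(n_loci, dtype=np.int64)
    out2 = np.empty(n_loci, dtype=np.int64)

    d1 = np.empty(nlin, dtype=np.int64)
    d2 = np.empty(nlin, dtype=np.int64)
    birth = np.empty(nlin, dtype=np.float64)
    length = np.empty(nlin, dtype=np.float64)
    act1 = np.empty(ntot, dtype=np.int64)
    act2 = np.empty(ntot, dtype=np.int64)

    for rep in range(n_loci):
        for i in range(n1):
            d1[i] = 1
            d2[i] = 0
            birth[i] = 0.0
            act1[i] = i
        for i in range(n2):
            d1[n1 + i] = 0
            d2[n1 + i] = 1
            birth[n1 + i] = 0.0
            act2[i] = n1 + i
        k1 = n1
        k2 = n2
        nxt = ntot
        t = 0.0
        # phase 1: independent coalescence within each deme until t_split
        while k1 + k2 > 1:
            r1 = k1 * (k1 - 1)
            r2 = k2 * (k2 - 1)
            rate = r1 + r2
            if rate == 0:
                t = t_split
                break
            dt = np.random.exponential(1.0 / rate)
            if t + dt >= t_split:
                t = t_split
                break
            t += dt
            if np.random.random() * rate < r1:
                ia = np.random.randint(k1)
                ib = np.random.randint(k1 - 1)
                if ib >= ia:
                    ib += 1
                a = act1[ia]
                b = act1[ib]
                d1[nxt] = d1[a] + d1[b]
                d2[nxt] = d2[a] + d2[b]
                length[a] = t - birth[a]
                length[b] = t - birth[b]
                birth[nxt] = t
                lo = min(ia, ib)
                hi = max(ia, ib)
                act1[lo] = nxt
                act1[hi] = act1[k1 - 1]
                k1 -= 1
            else:
                ia = np.random.randint(k2)
                ib = np.random.randint(k2 - 1)
                if ib >= ia:
                    ib += 1
                a = act2[ia]
                b = act2[ib]
                d1[nxt] = d1[a] + d1[b]
                d2[nxt] = d2[a] + d2[b]
                length[a] = t - birth[a]
                length[b] = t - birth[b]
                birth[nxt] = t
                lo = min(ia, ib)
                hi = max(ia, ib)
                act2[lo] = nxt
                act2[hi] = act2[k2 - 1]
                k2 -= 1
            nxt += 1
        # merge demes into a single ancestral population
        k = k1 + k2
        for i in range(k2):
            act1[k1 + i] = act2[i]
        # phase 2: panmictic coalescence to the MRCA
        while k > 1:
            rate = k * (k - 1)
            t += np.random.exponential(1.0 / rate)
            ia = np.random.randint(k)
            ib = np.random.randint(k - 1)
            if ib >= ia:
                ib += 1
            a = act1[ia]
            b = act1[ib]
            d1[nxt] = d1[a] + d1[b]
            d2[nxt] = d2[a] + d2[b]
            length[a] = t - birth[a]
            length[b] = t - birth[b]
            birth[nxt] = t
            lo = min(ia, ib)
            hi = max(ia, ib)
            act1[lo] = nxt
            act1[hi] = act1[k - 1]
            k -= 1
            nxt += 1
        # root branch has no length; mutation falls on one of the other
        # 2*ntot - 2 branches, weighted by branch length
        total = 0.0
        for i in range(nlin - 1):
            total += length[i]
        u = np.random.random() * total
        acc = 0.0
        hit = nlin - 2
        for i in range(nlin - 1):
            acc += length[i]
            if u < acc:
                hit = i
                break
        out1[rep] = d1[hit]
        out2[rep] = d2[hit]
    return out1, out2


@dataclass
class Genealogy:
    """Coalescent tree on n1+n2 tips, stored as parent pointers.

    Nodes 0..n1-1 are deme-1 tips, n1..n1+n2-1 deme-2 tips; internal nodes
    follow in coalescence order, the last being the MRCA.
    """

    n1: int
    n2: int
    parent: np.ndarray      # int, parent node id; -1 for the root
    branch_length: np.ndarray  # float, length of the branch above each node
    deme1_desc: np.ndarray  # descendant tip counts per node, deme 1
    deme2_desc: np.ndarray

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_length.sum())


def simulate_genealogy(model: SplitModel, rng: np.random.Generator) -> Genealogy:
    """Simulate one genealogy under the split model (pure-python path).

    Within each deme, k lineages coalesce at total rate k(k-1) per unit of
    4N-scaled time until ``t_split``; remaining lineages then merge into one
    panmictic ancestral population and coalesce to the MRCA.
    """
    n1, n2 = model.n1, model.n2
    ntot = n1 + n2
    nlin = 2 * ntot - 1
    parent = np.full(nlin, -1, dtype=np.int64)
    blen = np.zeros(nlin)
    d1 = np.zeros(nlin, dtype=np.int64)
    d2 = np.zeros(nlin, dtype=np.int64)
    d1[:n1] = 1
    d2[n1:ntot] = 1
    birth = np.zeros(nlin)
    act = [list(range(n1)), list(range(n1, ntot))]
    t = 0.0
    nxt = ntot

    def merge(pool: list[int], now: float) -> None:
        nonlocal nxt
        ia, ib = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[ia], pool[ib]
        for x in (a, b):
            parent[x] = nxt
            blen[x] = now - birth[x]
        d1[nxt] = d1[a] + d1[b]
        d2[nxt] = d2[a] + d2[b]
        birth[nxt] = now
        for x in sorted((ia, ib), reverse=True):
            pool.pop(x)
        pool.append(nxt)
        nxt += 1

    while len(act[0]) + len(act[1]) > 1:
        r1 = len(act[0]) * (len(act[0]) - 1)
        r2 = len(act[1]) * (len(act[1]) - 1)
        rate = r1 + r2
        if rate == 0:
            break
        dt = rng.exponential(1.0 / rate)
        if t + dt >= model.t_split:
            break
        t += dt
        merge(act[0] if rng.random() * rate < r1 else act[1], t)

    t = max(t, model.t_split)
    pool = act[0] + act[1]
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential(1.0 / (k * (k - 1)))
        merge(pool, t)
    return Genealogy(n1, n2, parent, blen, d1, d2)


@dataclass
class SimulatedSNP:
    """One simulated bi-allelic SNP: derived counts per deme and its F_ST."""

    derived1: int
    derived2: int
    fst: float


def drop_single_mutation(gen: Genealogy, rng: np.random.Generator) -> SimulatedSNP:
    """Place one mutation uniformly along the genealogy's branches.

    The derived allele is carried by all tips descending from the mutated
    branch; the root has no branch so the SNP always segregates.
    """
    total = gen.total_branch_length
    if total <= 0:
        raise ValueError("genealogy has zero total branch length")
    u = rng.random() * total
    node = int(np.searchsorted(np.cumsum(gen.branch_length), u, side="right"))
    c1 = int(gen.deme1_desc[node])
    c2 = int(gen.deme2_desc[node])
    fst = float(
        wc_fst_haploid_counts(
            np.array([c1]), np.array([c2]), gen.n1, gen.n2
        )[0]
    )
    return SimulatedSNP(c1, c2, fst)


def wc_fst_haploid_counts(
    derived1: np.ndarray, derived2: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Per-SNP Weir–Cockerham F_ST from haploid allele counts.

    Two-population variance-component estimator with the within-individual
    (heterozygosity) component absent, as appropriate for haploid allele
    copies.  Returns nan for sites monomorphic across both demes.
    """
    p1 = np.asarray(derived1, dtype=float) / n1
    p2 = np.asarray(derived2, dtype=float) / n2
    nbar = (n1 + n2) / 2.0
    nc = n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    pq = pbar * (1.0 - pbar)
    a = (nbar / nc) * (s2 - (pq - s2 / 2.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pq - s2 / 2.0)
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    return fst


@dataclass
class PanelSummary:
    """Summary of a simulated SNP panel.

    ``mean_fst`` averages all defined per-SNP estimates (negative
    finite-sample values included); ``mean_fst_positive`` averages only the
    SNPs showing positive differentiation, the convention used when quoting
    the panel's average divergence.
    """

    n_loci: int
    mean_fst: float
    mean_fst_positive: float
    threshold: float
    n_above_threshold: int
    theta_locus: float
    fst: np.ndarray = field(repr=False)
    derived1: np.ndarray = field(repr=False)
    derived2: np.ndarray = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("fst", "derived1", "derived2")}
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def simulate_snp_panel(model: SplitModel, threshold: float = 0.255) -> PanelSummary:
    """Simulate ``model.n_loci`` independent SNPs and summarise their F_ST.

    Reports the mean per-SNP Weir–Cockerham F_ST and the count of SNPs with
    F_ST strictly above ``threshold`` (default 0.255, the fine-scale 0.998
    quantile used for outlier calling).
    """
    c1, c2 = _sim_panel_kernel(
        model.n1, model.n2, model.t_split, model.n_loci, model.seed % (2**31)
    )
    fst = wc_fst_haploid_counts(c1, c2, model.n1, model.n2)
    finite = fst[np.isfinite(fst)]
    return PanelSummary(
        n_loci=model.n_loci,
        mean_fst=float(finite.mean()),
        mean_fst_positive=float(finite[finite > 0].mean())
        if (finite > 0).any() else np.nan,
        threshold=threshold,
        n_above_threshold=int((finite > threshold).sum()),
        theta_locus=model.theta_locus,
        fst=fst,
        derived1=c1,
        derived2=c2,
    )


def enrichment_test(
    empirical_fst: np.ndarray,
    simulated_fst: np.ndarray,
    threshold: float = 0.255,
) -> dict:
    """Enrichment of highly divergent SNPs over the neutral null.

    Counts SNPs above ``threshold`` in each distribution and reports the
    empirical/simulated ratio after scaling the simulated count to the
    empirical total, alongside both means.
    """
    emp = np.asarray(empirical_fst, dtype=float)
    sim = np.asarray(simulated_fst, dtype=float)
    emp = emp[np.isfinite(emp)]
    sim = sim[np.isfinite(sim)]
    if emp.size == 0 or sim.size == 0:
        raise ValueError("both distributions must be non-empty")
    n_emp = int((emp > threshold).sum())
    n_sim = int((sim > threshold).sum())
    expected = n_sim * emp.size / sim.size
    return {
        "threshold": threshold,
        "n_empirical": emp.size,
        "n_simulated": sim.size,
        "empirical_above": n_emp,
        "simulated_above": n_sim,
        "expected_above": expected,
        "enrichment_ratio": n_emp / expected if expected > 0 else math.inf,
        "mean_empirical": float(emp.mean()),
        "mean_simulated": float(sim.mean()),
    }
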