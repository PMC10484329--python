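"""Seeded synthetic inputs emulating admixed African/European honey-bee data.

The generator produces every input the analysis consumes — reference FASTA,
VCF of bi-allelic SNPs with caller-style INFO annotations, GFF3 gene models,
a recombination map, diplotype ancestry posteriors and a cline-steepness
table — together with a ground-truth record for parameter-recovery tests.

Population model.  Three divergent source lineages (A, C, M) draw per-SNP
allele frequencies from a Balding–Nichols (Beta) distribution around a shared
ancestral frequency, with per-lineage drift parameters setting their expected
differentiation.  Two admixed populations (lowland and highland) then draw
each allele copy's ancestry independently — A with the population's admixture
proportion, a trace amount of C, otherwise M — and the allele itself from the
chosen lineage's frequency.  A configurable minority of "selected" loci have
the highland A proportion reduced by a fixed shift, creating true
highland/lowland differentiation targets for the scan modules to recover.
Drones (M lineage) are haploid but are emitted diploid-coded in the VCF, with
a small injected fraction of artefactual heterozygous drone calls mirroring
what a joint diploid caller produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import SNPMatrix, write_vcf, HARD_FILTER_FIELDS

DIPLOTYPE_STATES = ("CC", "CM", "CA", "MM", "MA", "AA")

# caller-clean INFO draws: (mean, sd) per field, all comfortably inside the
# hard-filter pass region
_CLEAN_INFO = {
    "QD": (25.0, 5.0),
    "FS": (2.0, 1.5),
    "MQ": (59.0, 1.5),
    "MQRankSum": (0.0, 1.0),
    "ReadPosRankSum": (0.0, 1.0),
    "SOR": (1.0, 0.4),
}
# values guaranteed to fail each rule
_FAIL_INFO = {
    "QD": 1.0,
    "FS": 80.0,
    "MQ": 30.0,
    "MQRankSum": -20.0,
    "ReadPosRankSum": -12.0,
    "SOR": 5.0,
}


@dataclass
class SimConfig:
    """Study-design constants of the synthetic panel.

    Defaults mirror the real study: 15 lowland + 14 highland admixed workers,
    19 A and 9 C diploid references, 85 haploid M drones; mean A ancestry
    0.847 (lowland) and 0.686 (highland) with ~0.001 C contribution.
    """

    n_snps: int = 30_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 4_000_000, "chr2": 3_000_000, "chr3": 3_000_000}
    )
    window_bp: int = 10_000
    lineage_divergence: dict[str, float] = field(
        default_factory=lambda: {"A": 0.12, "C": 0.32, "M": 0.28}
    )
    # fraction of SNPs segregating in all lineages vs private to one lineage
    # (the real panel has far more A-segregating than C/M-segregating SNPs)
    snp_class_weights: dict[str, float] = field(
        default_factory=lambda: {"shared": 0.50, "A": 0.30, "M": 0.12, "C": 0.08}
    )
    private_freq_range: tuple[float, float] = (0.05, 0.30)
    # founder bottleneck of the introduced Africanized population: extra
    # drift applied to the admixed populations' source frequencies
    founder_drift: float = 0.06
    admix_A_lowland: float = 0.847
    admix_A_highland: float = 0.686
    admix_C: float = 0.001
    n_selected_loci: int = 60        # approximate total SNPs under selection
    selected_region_windows: int = 2  # contiguous analysis windows per region
    selection_ancestry_shift: float = 0.5
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "lowland": 15, "highland": 14, "A": 19, "C": 9, "M": 85,
        }
    )
    centromere_truth: dict[str, tuple[int, int, float]] = field(
        default_factory=lambda: {
            "chr1": (1_500_000, 2_300_000, 0.15),
            "chr2": (1_000_000, 1_700_000, 0.15),
            "chr3": (1_200_000, 1_900_000, 0.15),
        }
    )
    background_gc: float = 0.37
    posterior_noise: float = 50.0   # Dirichlet concentration; larger = cleaner
    cline_correlation: float = 0.3  # corr(steepness, true ancestry shift)
    ancestry_block_bp: int = 0      # 0 = per-copy independent ancestry
    het_drone_single_rate: float = 0.025
    het_drone_double_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("admix_A_lowland", self.admix_A_lowland),
            ("admix_A_highland", self.admix_A_highland),
            ("admix_C", self.admix_C),
            ("selection_ancestry_shift", self.selection_ancestry_shift),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for lin, d in self.lineage_divergence.items():
            if not 0.0 <= d < 1.0:
                raise ValueError(f"divergence for {lin} must be in [0, 1), got {d}")
        for pop, n in self.sample_sizes.items():
            if pop != "M" and n < 2:
                raise ValueError(f"diploid population {pop} needs >= 2 samples")
        for c, (s, e, depth) in self.centromere_truth.items():
            if c not in self.chrom_lengths:
                raise ValueError(f"centromere on unknown chromosome {c}")
            if not (0 <= s < e <= self.chrom_lengths[c]):
                raise ValueError(f"centromere interval out of bounds on {c}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")


@dataclass
class SimTruth:
    """Ground truth recorded during generation, for recovery tests."""

    ancestral_freq: np.ndarray
    lineage_freqs: pd.DataFrame           # columns A, C, M
    a_dosage: np.ndarray                  # (n_sites, n_admixed) copies of A
    admixed_samples: list[str]
    selected_index: np.ndarray            # site indices under selection
    centromeres: dict[str, tuple[int, int]]
    admix_A_lowland: float
    admix_A_highland: float

    def to_json(self, path: str | Path) -> None:
        d = {
            "selected_index": self.selected_index.tolist(),
            "centromeres": {k: list(v) for k, v in self.centromeres.items()},
            "admix_A_lowland": self.admix_A_lowland,
            "admix_A_highland": self.admix_A_highland,
            "admixed_samples": self.admixed_samples,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    """Beta(p(1-F)/F, (1-p)(1-F)/F) draw; fixed alleles stay fixed, F=0 is
    the zero-drift identity."""
    if f == 0.0:
        return p.copy()
    k = (1.0 - f) / f
    out = p.copy()
    seg = (p > 0.0) & (p < 1.0)
    out[seg] = rng.beta(p[seg] * k, (1.0 - p[seg]) * k)
    return out


def generate_lineage_frequencies(
    config: SimConfig, seed: int | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw per-SNP allele frequencies for the A, C and M source lineages.

    SNPs fall into classes by ``snp_class_weights``: "shared" SNPs give each
    lineage a Balding–Nichols Beta draw around a common ancestral frequency
    p ~ U(0.05, 0.95), with E[F_ST] to the ancestor approximately that
    lineage's drift parameter; lineage-private SNPs segregate at a low
    frequency (U over ``private_freq_range``) in one lineage only, emulating
    the strong excess of A-segregating sites in real panels.  SNPs
    monomorphic in all three lineages are rejected and redrawn.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_snps
    classes = list(config.snp_class_weights)
    w = np.array([config.snp_class_weights[c] for c in classes], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("snp_class_weights must be non-negative, not all zero")
    w = w / w.sum()
    lo, hi = config.private_freq_range

    anc = np.empty(n)
    klass = np.empty(n, dtype=object)
    freqs = {lin: np.empty(n) for lin in ("A", "C", "M")}
    todo = np.arange(n)
    while todo.size:
        cls = rng.choice(classes, size=todo.size, p=w)
        p = rng.uniform(0.05, 0.95, size=todo.size)
        draws = {
            lin: _balding_nichols(rng, p, config.lineage_divergence[lin])
            for lin in ("A", "C", "M")
        }
        for lin in ("A", "C", "M"):
            private = cls == lin
            if private.any():
                own = rng.uniform(lo, hi, size=int(private.sum()))
                for other in ("A", "C", "M"):
                    draws[other][private] = own if other == lin else 0.0
                p[private] = own * 0  # ancestral state is the ref allele
        anc[todo] = p
        klass[todo] = cls
        for lin in ("A", "C", "M"):
            freqs[lin][todo] = draws[lin]
        mono = np.ones(todo.size, dtype=bool)
        for lin in ("A", "C", "M"):
            mono &= (draws[lin] <= 0.0) | (draws[lin] >= 1.0)
        todo = todo[mono]
    out = pd.DataFrame(freqs)
    out["klass"] = klass
    return anc, out


def _positions(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Assign SNPs to chromosomes proportionally to length, uniform positions."""
    chroms = list(config.chrom_lengths)
    lens = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(config.n_snps * lens / lens.sum()).astype(int)
    counts[0] += config.n_snps - counts.sum()
    chrom_col, pos_col = [], []
    for c, k in zip(chroms, counts):
        pos = np.sort(rng.choice(config.chrom_lengths[c] - 1, size=k, replace=False)) + 1
        chrom_col.extend([c] * k)
        pos_col.append(pos)
    return np.array(chrom_col, dtype=object), np.concatenate(pos_col)


def generate_admixed_genotypes(
    freqs: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    ancestral: np.ndarray | None = None,
) -> tuple[SNPMatrix, SimTruth]:
    """Generate the five-population genotype panel plus ground truth.

    Reference populations (A, C diploid; M haploid drones) sample alleles
    directly from their lineage frequencies.  Admixed individuals draw each
    allele copy's ancestry independently, then the allele from the chosen
    lineage.  At selected loci the highland A proportion is reduced by
    ``selection_ancestry_shift``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(freqs)
    shifted = config.admix_A_highland - config.selection_ancestry_shift
    if not 0.0 <= shifted <= 1.0 and config.n_selected_loci > 0:
        raise ValueError(
            "selection shift drives highland A proportion outside [0, 1]"
        )
    chrom, pos = _positions(config, rng)
    p = {lin: freqs[lin].to_numpy() for lin in ("A", "C", "M")}

    samples, pops, ploidy, cols = [], [], [], []
    for i in range(config.sample_sizes["A"]):
        samples.append(f"A{i:03d}"); pops.append("A"); ploidy.append(2)
    for i in range(config.sample_sizes["C"]):
        samples.append(f"C{i:03d}"); pops.append("C"); ploidy.append(2)
    for i in range(config.sample_sizes["M"]):
        samples.append(f"M{i:03d}"); pops.append("M"); ploidy.append(1)
    for i in range(config.sample_sizes["lowland"]):
        samples.append(f"LL{i:03d}"); pops.append("lowland"); ploidy.append(2)
    for i in range(config.sample_sizes["highland"]):
        samples.append(f"HL{i:03d}"); pops.append("highland"); ploidy.append(2)

    # selection targets are contiguous regions spanning whole analysis
    # windows (divergence peaks are regional, tens of kbp, not single-SNP);
    # every SNP inside a target region is under the ancestry shift
    sel_mask = np.zeros(n, dtype=bool)
    if config.n_selected_loci > 0:
        w = config.window_bp
        region_bp = config.selected_region_windows * w
        density = n / sum(config.chrom_lengths.values())
        per_region = max(1.0, density * region_bp)
        n_regions = max(1, round(config.n_selected_loci / per_region))
        chroms = list(config.chrom_lengths)
        # candidate window-aligned region starts across the genome
        candidates = [
            (c, s)
            for c in chroms
            for s in range(0, config.chrom_lengths[c] - region_bp + 1, region_bp)
        ]
        picks = rng.choice(len(candidates), size=min(n_regions, len(candidates)),
                           replace=False)
        for k in np.sort(picks):
            c, s = candidates[k]
            sel_mask |= (chrom == c) & (pos > s) & (pos <= s + region_bp)
    sel = np.flatnonzero(sel_mask)

    geno = np.full((n, len(samples), 2), -1, dtype=np.int8)
    j = 0
    for pop, lin, count, pl in (
        ("A", "A", config.sample_sizes["A"], 2),
        ("C", "C", config.sample_sizes["C"], 2),
        ("M", "M", config.sample_sizes["M"], 1),
    ):
        for _ in range(count):
            geno[:, j, 0] = rng.random(n) < p[lin]
            if pl == 2:
                geno[:, j, 1] = rng.random(n) < p[lin]
            j += 1

    # founder bottleneck: the introduced Africanized gene pool carries extra
    # drift relative to the source lineages, shared by both admixed
    # populations (a single introduction event)
    p_found = {
        lin: _balding_nichols(rng, p[lin], config.founder_drift)
        for lin in ("A", "C", "M")
    }
    n_adm = config.sample_sizes["lowland"] + config.sample_sizes["highland"]
    a_dosage = np.zeros((n, n_adm), dtype=np.int8)
    adm_samples = []
    k = 0
    for pop, alpha in (("lowland", config.admix_A_lowland),
                       ("highland", config.admix_A_highland)):
        a_prop = np.full(n, alpha)
        if pop == "highland":
            a_prop[sel_mask] = np.clip(alpha - config.selection_ancestry_shift, 0, 1)
        for _ in range(config.sample_sizes[pop]):
            for slot in range(2):
                u = rng.random(n)
                anc_is_a = u < a_prop
                anc_is_c = (~anc_is_a) & (u < a_prop + config.admix_C)
                pp = np.where(anc_is_a, p_found["A"],
                              np.where(anc_is_c, p_found["C"], p_found["M"]))
                geno[:, j, slot] = rng.random(n) < pp
                a_dosage[:, k] += anc_is_a
            adm_samples.append(samples[j])
            j += 1
            k += 1

    mat = SNPMatrix(
        chrom=chrom,
        pos=pos,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        genotypes=geno,
        samples=samples,
        populations=np.array(pops, dtype=object),
        ploidy=np.array(ploidy, dtype=np.int8),
    )
    truth = SimTruth(
        ancestral_freq=ancestral if ancestral is not None else np.full(n, np.nan),
        lineage_freqs=freqs,
        a_dosage=a_dosage,
        admixed_samples=adm_samples,
        selected_index=sel,
        centromeres={c: (s, e) for c, (s, e, _) in config.centromere_truth.items()},
        admix_A_lowland=config.admix_A_lowland,
        admix_A_highland=config.admix_A_highland,
    )
    return mat, truth


def generate_annotations(
    matrix: SNPMatrix,
    config: SimConfig,
    seed: int | None = None,
    fail_fraction: dict[str, float] | None = None,
    mean_depth: float = 10.0,
) -> pd.DataFrame:
    """Caller-style site annotations with engineered hard-filter failures.

    ``fail_fraction`` maps INFO fields to the fraction of sites forced to
    fail that rule; remaining sites draw clean values.  QUAL is drawn well
    above the 100 cutoff and per-sample DP around ``mean_depth``.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = matrix.n_sites
    ann = pd.DataFrame(index=range(n))
    ann["QUAL"] = rng.gamma(shape=20, scale=40, size=n) + 150.0
    for k in HARD_FILTER_FIELDS:
        mu, sd = _CLEAN_INFO[k]
        ann[k] = rng.normal(mu, sd, size=n)
    # keep clean draws inside the pass region
    ann["QD"] = ann["QD"].clip(lower=3.0)
    ann["FS"] = ann["FS"].clip(lower=0.0, upper=50.0)
    ann["MQ"] = ann["MQ"].clip(lower=45.0)
    ann["MQRankSum"] = ann["MQRankSum"].clip(lower=-10.0)
    ann["ReadPosRankSum"] = ann["ReadPosRankSum"].clip(lower=-6.0)
    ann["SOR"] = ann["SOR"].clip(lower=0.0, upper=2.5)
    if fail_fraction:
        for k, frac in fail_fraction.items():
            m = rng.random(n) < frac
            ann.loc[m, k] = _FAIL_INFO[k]
    dp = pd.DataFrame(
        rng.poisson(mean_depth, size=(n, matrix.n_samples)).astype(np.int32),
        columns=[f"DP:{s}" for s in matrix.samples],
    )
    return pd.concat([ann, dp], axis=1)


def inject_drone_heterozygotes(
    matrix: SNPMatrix, config: SimConfig, seed: int | None = None
) -> tuple[SNPMatrix, dict]:
    """Flip a fraction of drone calls heterozygous, as a diploid caller would.

    A fraction ``het_drone_single_rate`` of sites gets exactly one
    heterozygous drone and ``het_drone_double_rate`` exactly two.  Returns the
    matrix with drones diploid-coded (slot 1 filled) plus the injection log.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    drones = np.flatnonzero(matrix.ploidy == 1)
    g = matrix.genotypes.copy()
    # diploid-code drones: duplicate the single allele
    for j in drones:
        g[:, j, 1] = g[:, j, 0]
    n = matrix.n_sites
    u = rng.random(n)
    one = u < config.het_drone_single_rate
    two = (~one) & (u < config.het_drone_single_rate + config.het_drone_double_rate)
    for i in np.flatnonzero(one):
        j = rng.choice(drones)
        g[i, j, 1] = 1 - g[i, j, 0]
    for i in np.flatnonzero(two):
        jj = rng.choice(drones, size=2, replace=False)
        for j in jj:
            g[i, j, 1] = 1 - g[i, j, 0]
    out = SNPMatrix(
        chrom=matrix.chrom, pos=matrix.pos, ref=matrix.ref, alt=matrix.alt,
        genotypes=g, samples=matrix.samples,
        populations=matrix.populations,
        ploidy=np.full(matrix.n_samples, 2, dtype=np.int8),
    )
    log = {"sites_one_het_drone": int(one.sum()), "sites_two_het_drones": int(two.sum())}
    return out, log


def generate_reference_and_genes(
    config: SimConfig, seed: int | None = None, out_dir: str | Path | None = None
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Reference FASTA, GFF3 gene models and a recombination map.

    The FASTA has background GC near ``background_gc`` with GC depressed by
    the configured depth inside each true centromere interval.  Genes carry
    several exons on both strands; the recombination map (BED-like, 0-based
    half-open, rate per interval) has reduced rates inside centromeres.
    Returns (sequences, genes frame, recombination frame) and optionally
    writes ref.fa, genes.gff3, recomb.bed under ``out_dir``.
    """
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    seqs: dict[str, str] = {}
    bases = np.array(list("ATGC"))
    for c, length in config.chrom_lengths.items():
        gc = np.full(length, config.background_gc)
        if c in config.centromere_truth:
            s, e, depth = config.centromere_truth[c]
            gc[s:e] -= depth
        is_gc = rng.random(length) < gc
        half = rng.random(length) < 0.5
        codes = np.where(
            is_gc,
            np.where(half, ord("G"), ord("C")),
            np.where(half, ord("A"), ord("T")),
        ).astype(np.uint8)
        seqs[c] = codes.tobytes().decode("ascii")

    rows = []
    gid = 0
    for c, length in config.chrom_lengths.items():
        n_genes = max(3, length // 100_000)
        starts = np.sort(rng.choice(length - 20_000, size=n_genes, replace=False))
        for s in starts:
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = rng.integers(2, 8)
            ex_start = s + 1
            exons = []
            for _ in range(n_ex):
                ex_len = int(rng.integers(100, 1500))
                exons.append((ex_start, min(ex_start + ex_len - 1, length)))
                ex_start += ex_len + int(rng.integers(200, 3000))
            gene_end = exons[-1][1]
            rows.append({
                "gene_id": f"gene{gid:05d}", "chrom": c, "start": int(s + 1),
                "end": int(gene_end), "strand": strand,
                "exons": [(int(a), int(b)) for a, b in exons],
            })
    genes = pd.DataFrame(rows)

    rmap_rows = []
    step = 100_000
    for c, length in config.chrom_lengths.items():
        cen = config.centromere_truth.get(c)
        for s in range(0, length, step):
            e = min(s + step, length)
            rate = float(rng.uniform(20, 30))  # cM/Mb scale
            if cen and not (e <= cen[0] or s >= cen[1]):
                rate *= 0.2
            rmap_rows.append({"chrom": c, "start": s, "end": e, "rate": rate})
    rmap = pd.DataFrame(rmap_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(seqs, out_dir / "ref.fa")
        write_gff3(genes, out_dir / "genes.gff3")
        rmap.to_csv(out_dir / "recomb.bed", sep="\t", header=False, index=False)
    return seqs, genes, rmap


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n"
                )


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Parse gene models (id, chrom, strand, exon list) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (e.start, e.end)
            for e in db.children(gene, featuretype="exon")
        )
        rows.append({
            "gene_id": gene.id, "chrom": gene.seqid, "start": gene.start,
            "end": gene.end, "strand": gene.strand, "exons": exons,
        })
    return pd.DataFrame(rows)


def generate_posteriors_and_clines(
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diplotype ancestry posteriors plus a cline-steepness table.

    Per SNP x admixed individual, a 6-state probability vector over
    (CC, CM, CA, MM, MA, AA) is drawn from a Dirichlet centred on the true
    diplotype (A dosage; non-A copies taken as M) with concentration
    ``posterior_noise``.  Cline steepness is generated with correlation
    ``cline_correlation`` against the true per-SNP ancestry shift.
    """
    rng = np.random.default_rng(config.seed + 5 if seed is None else seed)
    n, n_ind = truth.a_dosage.shape
    state_of_dosage = {0: "MM", 1: "MA", 2: "AA"}
    records = []
    conc = config.posterior_noise
    base = np.full(6, 0.02)
    for k, sample in enumerate(truth.admixed_samples):
        dos = truth.a_dosage[:, k]
        alpha = np.tile(base, (n, 1))
        for d, st in state_of_dosage.items():
            alpha[dos == d, DIPLOTYPE_STATES.index(st)] += conc
        probs = rng.gamma(alpha)
        probs /= probs.sum(axis=1, keepdims=True)
        df = pd.DataFrame(probs, columns=[f"p{s}" for s in DIPLOTYPE_STATES])
        df.insert(0, "sample", sample)
        df.insert(0, "snp", np.arange(n))
        records.append(df)
    cols = ["snp", "sample"] + [f"p{s}" for s in DIPLOTYPE_STATES]
    post = (pd.concat(records, ignore_index=True) if records
            else pd.DataFrame(columns=cols))

    # true per-SNP ancestry shift: selected loci carry the configured shift
    shift = np.zeros(n)
    shift[truth.selected_index] = config.selection_ancestry_shift
    z = (shift - shift.mean()) / (shift.std() + 1e-12)
    rho = config.cline_correlation
    noise = rng.standard_normal(n)
    steep = rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * noise
    clines = pd.DataFrame({"snp": np.arange(n), "steepness": steep})
    return post, clines


def generate_all(config: SimConfig, out_dir: str | Path) -> dict:
    """Run the full generator, writing every artefact under ``out_dir``.

    Emits ref.fa, genes.gff3, recomb.bed, panel.vcf, pops.tsv,
    posteriors.tsv, clines.tsv and truth.json; returns the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    anc, freqs = generate_lineage_frequencies(config)
    matrix, truth = generate_admixed_genotypes(freqs, config, ancestral=anc)
    coded, het_log = inject_drone_heterozygotes(matrix, config)
    ann = generate_annotations(coded, config)
    write_vcf(coded, out / "panel.vcf", annotations=ann)
    pd.DataFrame({
        "sample": matrix.samples,
        "population": matrix.populations,
        "ploidy": matrix.ploidy,
    }).to_csv(out / "pops.tsv", sep="\t", index=False)
    seqs, genes, rmap = generate_reference_and_genes(config, out_dir=out)
    post, clines = generate_posteriors_and_clines(truth, config)
    post.to_csv(out / "posteriors.tsv", sep="\t", index=False, float_format="%.5g")
    clines.to_csv(out / "clines.tsv", sep="\t", index=False, float_format="%.6g")
    truth.to_json(out / "truth.json")
    return {
        "matrix": matrix, "coded": coded, "annotations": ann, "truth": truth,
        "sequences": seqs, "genes": genes, "recomb": rmap,
        "posteriors": post, "clines": clines, "het_log": het_log,
    }
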