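"""Genotype matrix container and VCF 4.2 input/output.

The :class:`SNPMatrix` is the substrate of every statistic in the package: a
sites-by-samples array of allele calls with population labels and per-sample
ploidy.  Haploid samples (drones) occupy a single allele slot; the second slot
is permanently unset so a drone can never register as heterozygous and allele
counting over set slots is uniform across ploidies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

HARD_FILTER_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")


@dataclass
class SNPMatrix:
    """Bi-allelic SNP genotypes for samples x sites.

    Attributes
    ----------
    chrom, pos, ref, alt
        Site coordinates (pos is 1-based) and alleles.
    genotypes
        int8 array of shape (n_sites, n_samples, 2).  Allele codes are 0
        (ref), 1 (alt) and -1 (unset/missing).  Haploid samples keep slot 1
        at -1 permanently.
    samples
        Sample names, one per column.
    populations
        Population label per sample.
    ploidy
        1 or 2 per sample.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    populations: np.ndarray
    ploidy: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        if self.genotypes.shape != (self.n_sites, self.n_samples, 2):
            raise ValueError("genotype array shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str | None = None) -> np.ndarray:
        if population is None:
            return np.arange(self.n_samples)
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present")
        return idx

    def take_sites(self, mask_or_index: np.ndarray) -> "SNPMatrix":
        m = np.asarray(mask_or_index)
        return replace(
            self,
            chrom=self.chrom[m],
            pos=self.pos[m],
            ref=self.ref[m],
            alt=self.alt[m],
            genotypes=self.genotypes[m],
        )

    def take_samples(self, idx: np.ndarray) -> "SNPMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[:, idx, :],
            samples=[self.samples[i] for i in idx],
            populations=self.populations[idx],
            ploidy=self.ploidy[idx],
        )

    # -- per-site summaries -------------------------------------------------

    def called_alleles(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Number of called allele copies per site over the given samples."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx, :]
        return (g >= 0).sum(axis=(1, 2))

    def alt_alleles(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx, :]
        return (g == 1).sum(axis=(1, 2))

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        n = self.called_alleles(sample_idx)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, self.alt_alleles(sample_idx) / n, np.nan)

    def is_het(self) -> np.ndarray:
        """Boolean (site, sample): both slots called and unequal."""
        g = self.genotypes
        return (g[:, :, 0] >= 0) & (g[:, :, 1] >= 0) & (g[:, :, 0] != g[:, :, 1])

    def is_missing(self) -> np.ndarray:
        """Boolean (site, sample): no allele called for that sample."""
        return (self.genotypes >= 0).sum(axis=2) == 0

    def minor_allele_count(self) -> np.ndarray:
        n = self.called_alleles()
        alt = self.alt_alleles()
        return np.minimum(alt, n - alt)

    def sort(self) -> "SNPMatrix":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.take_sites(order)


def load_populations(path: str | Path) -> pd.DataFrame:
    """Read a two/three column TSV: sample, population[, ploidy]."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["sample", "population", "ploidy"][: df.shape[1]]
    if "ploidy" not in df:
        df["ploidy"] = 2
    return df


# ---------------------------------------------------------------------------
# VCF 4.2
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    populations: pd.DataFrame | None = None,
) -> tuple[SNPMatrix, pd.DataFrame]:
    """Read a VCF into an :class:`SNPMatrix` plus a site-annotation frame.

    All samples are read as coded in the file (haploid drones are normally
    diploid-coded upstream of drone handling).  The annotation frame carries
    QUAL, the hard-filter INFO fields and per-sample DP columns (``DP:<name>``,
    -1 where absent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, quals = [], [], [], [], []
    info_cols: dict[str, list] = {k: [] for k in HARD_FILTER_FIELDS}
    gts, dps = [], []
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        for k in HARD_FILTER_FIELDS:
            val = v.INFO.get(k)
            info_cols[k].append(np.nan if val is None else float(val))
        a = np.array(v.genotype.array(), dtype=np.int16)[:, :2]
        a[a < 0] = MISSING
        gts.append(a.astype(np.int8))
        d = v.format("DP")
        if d is None:
            dps.append(np.full(len(samples), -1, dtype=np.int32))
        else:
            d = d.astype(np.int32).reshape(-1)
            d[d < 0] = -1
            dps.append(d)
    vcf.close()

    if populations is not None:
        pop_map = dict(zip(populations["sample"], populations["population"]))
        ploidy_map = dict(zip(populations["sample"], populations["ploidy"]))
        pops = np.array([pop_map.get(s, "unknown") for s in samples], dtype=object)
        ploidy = np.array([ploidy_map.get(s, 2) for s in samples], dtype=np.int8)
    else:
        pops = np.array(["unknown"] * len(samples), dtype=object)
        ploidy = np.full(len(samples), 2, dtype=np.int8)

    mat = SNPMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.array(gts) if gts else np.empty((0, len(samples), 2), np.int8),
        samples=samples,
        populations=pops,
        ploidy=ploidy,
    )
    ann = pd.DataFrame({"QUAL": quals, **info_cols})
    dp = np.array(dps) if dps else np.empty((0, len(samples)), np.int32)
    dp_frame = pd.DataFrame(dp, columns=[f"DP:{s}" for s in samples])
    return mat, pd.concat([ann, dp_frame], axis=1)


def write_vcf(
    matrix: SNPMatrix,
    path: str | Path,
    annotations: pd.DataFrame | None = None,
    diploid_code_haploids: bool = True,
) -> None:
    """Write a minimal valid VCF 4.2.

    Haploid samples are emitted as diploid homozygotes when
    ``diploid_code_haploids`` (the upstream caller convention for drones);
    otherwise as single-allele calls.  Round-tripping through
    :func:`read_vcf` reproduces the genotype calls exactly.
    """
    path = Path(path)
    samples = matrix.samples
    have_dp = annotations is not None and any(
        c.startswith("DP:") for c in annotations.columns
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in np.unique(matrix.chrom.astype(str)):
            sub = matrix.pos[matrix.chrom == c]
            length = int(sub.max()) + 1000 if sub.size else 1000
            fh.write(f"##contig=<ID={c},length={length}>\n")
        for k in HARD_FILTER_FIELDS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if have_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        fmt = "GT:DP" if have_dp else "GT"
        for i in range(matrix.n_sites):
            if annotations is not None:
                qual = annotations["QUAL"].iloc[i]
                qual_s = f"{qual:g}" if np.isfinite(qual) else "."
                info = ";".join(
                    f"{k}={annotations[k].iloc[i]:g}"
                    for k in HARD_FILTER_FIELDS
                    if k in annotations and np.isfinite(annotations[k].iloc[i])
                ) or "."
            else:
                qual_s, info = ".", "."
            fields = [
                str(matrix.chrom[i]), str(matrix.pos[i]), ".",
                str(matrix.ref[i]), str(matrix.alt[i]), qual_s, "PASS", info, fmt,
            ]
            for j, s in enumerate(samples):
                a, b = matrix.genotypes[i, j]
                if matrix.ploidy[j] == 1:
                    gt = "." if a == MISSING else (
                        f"{a}/{a}" if diploid_code_haploids else str(a)
                    )
                elif a == MISSING or b == MISSING:
                    gt = "./."
                else:
                    gt = f"{a}/{b}"
                if have_dp:
                    d = annotations[f"DP:{s}"].iloc[i]
                    gt += ":" + (str(int(d)) if d >= 0 else ".")
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")
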