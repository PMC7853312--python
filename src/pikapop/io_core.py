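"""Core data containers and file I/O.

The pipeline's central object is :class:`GenotypeLikelihoodSet`: per-individual,
per-site genotype likelihoods (hom-ref, het, hom-alt) together with read depths
and site coordinates, as produced by likelihood-aware variant callers for
reduced-representation (ddRADseq/GBS) data.  All downstream stages — filtering,
admixture, PCA, diversity — consume this object rather than hard genotype
calls, so that genotype uncertainty at modest depth propagates through the
analysis.

Likelihoods are stored max-normalised per (individual, site) cell; every
computation downstream uses likelihood ratios only, so the normalisation is
lossless.  Sites with zero reads carry flat (uninformative) likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("pikapop")

SAMPLE_TABLE_COLUMNS = ["sample_id", "population", "latitude", "longitude", "elevation_m"]
CLIMATE_VARIABLES = [f"bio{i}" for i in range(1, 20)]
#: bio1..bio11 are the temperature-family bioclim variables; bio12..bio19 the
#: precipitation/seasonality family.
TEMPERATURE_VARIABLES = [f"bio{i}" for i in range(1, 12)]
PRECIPITATION_VARIABLES = [f"bio{i}" for i in range(12, 20)]


class VcfFormatError(ValueError):
    """Raised when a VCF lacks required fields or contains a malformed record."""


@dataclass
class GenotypeLikelihoodSet:
    """Genotype likelihoods, read depths and site coordinates for N x L data.

    Attributes
    ----------
    sample_ids:
        Length-N list of individual identifiers.
    sites:
        DataFrame with columns ``scaffold``, ``pos`` (1-based bp), ``ref``,
        ``alt``; positions strictly increasing within each scaffold.
    likelihoods:
        ``(N, L, 3)`` array of genotype likelihoods in the order
        (hom-ref, het, hom-alt), max-normalised per (i, l).
    depths:
        ``(N, L)`` integer read depths.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    likelihoods: np.ndarray
    depths: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def __post_init__(self) -> None:
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        n, L = len(self.sample_ids), len(self.sites)
        if self.likelihoods.shape != (n, L, 3):
            raise ValueError(
                f"likelihoods shape {self.likelihoods.shape} != ({n}, {L}, 3)"
            )
        if self.depths.shape != (n, L):
            raise ValueError(f"depths shape {self.depths.shape} != ({n}, {L})")
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.likelihoods)):
            raise ValueError("non-finite genotype likelihoods")
        if np.any(self.likelihoods < 0):
            raise ValueError("negative genotype likelihoods")
        if self.n_sites and np.any(self.likelihoods.max(axis=2) <= 0):
            raise ValueError("all-zero likelihood triple at some (individual, site)")
        for scaf, grp in self.sites.groupby("scaffold", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")
        zero = self.depths == 0
        if np.any(zero):
            lk = self.likelihoods[zero]
            if not np.allclose(lk, lk[:, :1]):
                raise ValueError("zero-depth cell with informative likelihoods")

    def subset_sites(self, mask: np.ndarray) -> "GenotypeLikelihoodSet":
        """Return a new set restricted to sites where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeLikelihoodSet(
            sample_ids=list(self.sample_ids),
            sites=self.sites.loc[mask].reset_index(drop=True),
            likelihoods=self.likelihoods[:, mask, :],
            depths=self.depths[:, mask],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeLikelihoodSet":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeLikelihoodSet(
            sample_ids=list(sample_ids),
            sites=self.sites.copy(),
            likelihoods=self.likelihoods[idx],
            depths=self.depths[idx],
        )

    def normalized(self) -> np.ndarray:
        """Likelihoods rescaled so each (i, l) triple sums to 1."""
        lk = self.likelihoods
        return lk / lk.sum(axis=2, keepdims=True)


@dataclass
class RunConfig:
    """Every tunable of the pipeline with its default.

    Filtering defaults follow the standard ddRADseq recipe (site kept when at
    least 92% of individuals have a read, minor allele frequency >= 5%, one SNP
    per 1000-bp block); MCMC defaults are full-length production chains; the
    diversity window is 50 kbp non-overlapping.
    """

    completeness_min: float = 0.92
    maf_min: float = 0.05
    thin_block: int = 1000
    mcmc_steps: int = 40_000
    mcmc_burn_in: int = 10_000
    mcmc_thin: int = 10
    mcmc_chains: int = 5
    window_bp: int = 50_000
    n_permutations: int = 999
    seed: int = 0


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_gl(path: str | Path, skip_multiallelic: bool = True) -> GenotypeLikelihoodSet:
    """Read a VCF with PL (or GL) and DP FORMAT fields into a GenotypeLikelihoodSet.

    Phred-scaled PL values are converted to likelihoods by ``10**(-PL/10)`` and
    max-normalised per cell.  Records with more than one ALT allele are skipped
    (and counted in the log) when ``skip_multiallelic`` is true, otherwise they
    raise.  A missing PL with DP=0 yields flat likelihoods.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    fmt_ids = set()
    for line in vcf.header_iter():
        info = line.info()
        if info.get("HeaderType") == "FORMAT":
            fmt_ids.add(info.get("ID"))
    use_gl = False
    if "PL" not in fmt_ids:
        if "GL" in fmt_ids:
            use_gl = True
        else:
            raise VcfFormatError(f"{path}: FORMAT lacks both PL and GL")
    if "DP" not in fmt_ids:
        raise VcfFormatError(f"{path}: FORMAT lacks DP")

    samples = list(vcf.samples)
    n = len(samples)
    rows, lk_cols, dp_cols = [], [], []
    n_multi = 0
    for rec_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1:
            if skip_multiallelic:
                n_multi += 1
                continue
            raise VcfFormatError(f"{path}: multi-allelic record #{rec_no} at {v.CHROM}:{v.POS}")
        dp = v.format("DP")
        if dp is None:
            raise VcfFormatError(f"{path}: record #{rec_no} missing DP values")
        dp = np.asarray(dp, dtype=float).reshape(n)
        dp = np.where(np.isfinite(dp) & (dp > 0), dp, 0).astype(np.int64)
        if use_gl:
            gl = v.format("GL")
            raw = None if gl is None else np.asarray(gl, dtype=float).reshape(n, 3)
            lk = None if raw is None else np.power(10.0, raw)
        else:
            pl = v.format("PL")
            raw = None if pl is None else np.asarray(pl, dtype=float).reshape(n, 3)
            # cyvcf2 encodes missing PL entries as negative sentinels; clip
            # before exponentiating to avoid overflow (masked to flat below)
            lk = None if raw is None else np.power(10.0, -np.maximum(raw, 0.0) / 10.0)
        if lk is None:
            lk = np.ones((n, 3))
        else:
            lk = np.where(np.isfinite(lk), lk, 1.0)
            if not use_gl:
                # cyvcf2 encodes missing PL entries as negative sentinels
                lk = np.where(raw < 0, 1.0, lk)
        lk[dp == 0] = 1.0
        lk /= lk.max(axis=1, keepdims=True)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        lk_cols.append(lk)
        dp_cols.append(dp)
    if n_multi:
        logger.info("read_vcf_gl: skipped %d multi-allelic records", n_multi)
    sites = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])
    L = len(sites)
    likelihoods = (
        np.stack(lk_cols, axis=1) if L else np.zeros((n, 0, 3))
    )
    depths = np.stack(dp_cols, axis=1) if L else np.zeros((n, 0), dtype=np.int64)
    gl = GenotypeLikelihoodSet(samples, sites, likelihoods, depths)
    gl.n_multiallelic_skipped = n_multi
    return gl


def write_vcf_gl(
    gl: GenotypeLikelihoodSet,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a GenotypeLikelihoodSet as VCF v4.2 with GT, PL and DP fields.

    GT is the maximum-likelihood genotype, or ``./.`` at zero depth.  PL values
    are phred-scaled, min-normalised and rounded to integers (the standard
    quantisation), capped at 255.
    """
    path = Path(path)
    lk = gl.likelihoods
    with np.errstate(divide="ignore"):
        pl = -10.0 * np.log10(np.where(lk > 0, lk, np.finfo(float).tiny))
    pl = pl - pl.min(axis=2, keepdims=True)
    pl = np.minimum(np.rint(pl), 255).astype(int)
    gt_idx = lk.argmax(axis=2)
    gt_str = np.array(["0/0", "0/1", "1/1"])
    scaffolds = list(dict.fromkeys(gl.sites["scaffold"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pikapop\n")
        for scaf in scaffolds:
            if contig_lengths and scaf in contig_lengths:
                fh.write(f"##contig=<ID={scaf},length={contig_lengths[scaf]}>\n")
            else:
                fh.write(f"##contig=<ID={scaf}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gl.sample_ids)
            + "\n"
        )
        sites = gl.sites
        for l in range(gl.n_sites):
            scaf = sites.at[l, "scaffold"]
            pos = sites.at[l, "pos"]
            ref = sites.at[l, "ref"]
            alt = sites.at[l, "alt"]
            cells = []
            for i in range(gl.n_samples):
                d = gl.depths[i, l]
                g = "./." if d == 0 else gt_str[gt_idx[i, l]]
                p = ",".join(str(x) for x in pl[i, l])
                cells.append(f"{g}:{p}:{d}")
            fh.write(f"{scaf}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:PL:DP\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample metadata CSV.

    Required columns: sample_id, population, latitude, longitude, elevation_m.
    """
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id: {sorted(set(dup))}")
    bad_lat = df.index[(df["latitude"] < -90) | (df["latitude"] > 90)]
    if len(bad_lat):
        raise ValueError(f"latitude out of range in rows {list(bad_lat)}")
    bad_lon = df.index[(df["longitude"] < -180) | (df["longitude"] > 180)]
    if len(bad_lon):
        raise ValueError(f"longitude out of range in rows {list(bad_lon)}")
    return df[SAMPLE_TABLE_COLUMNS].copy()


def read_climate_table(path: str | Path) -> pd.DataFrame:
    """Read a per-population climate CSV with the 19 bioclim-style variables."""
    df = pd.read_csv(path)
    missing = [c for c in ["population", *CLIMATE_VARIABLES] if c not in df.columns]
    if missing:
        raise ValueError(f"climate table missing columns: {missing}")
    extra = [c for c in df.columns if c not in ("population", *CLIMATE_VARIABLES)]
    if extra:
        raise ValueError(f"climate table must have exactly 19 variable columns; extra: {extra}")
    if df["population"].duplicated().any():
        raise ValueError("duplicate population rows in climate table")
    return df[["population", *CLIMATE_VARIABLES]].copy()


def check_population_consistency(gl: GenotypeLikelihoodSet, samples: pd.DataFrame) -> None:
    """Raise if the genotype data and the sample table disagree on sample IDs."""
    missing = set(gl.sample_ids) - set(samples["sample_id"])
    if missing:
        raise ValueError(f"samples in genotype data absent from metadata: {sorted(missing)}")
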