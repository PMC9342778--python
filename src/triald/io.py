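"""Reading cohorts from VCF, genetic-map handling, and surface file I/O.

Input is one or more VCF files containing the admixed samples and one or
two reference (source-population) panels.  Only biallelic autosomal SNPs
are retained; indels, multiallelic records and non-autosomal contigs are
dropped.  Genotypes are coded {0, 1/2, 1} as the fraction of alternate
alleles (phased haplotype mode yields {0, 1} rows, two per sample).
Genetic positions come from a plain-text genetic map (columns: chrom, bp,
cM) with linear interpolation, or from a constant cM/Mb rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import GenotypePanel, WeightedLDSurface

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "read_vcf_panel",
    "read_genetic_map",
    "assign_genetic_positions",
    "write_surface",
    "read_surface",
    "write_vcf",
]

_AUTOSOMES = {str(i) for i in range(1, 23)}


def _is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr") in _AUTOSOMES


@dataclass
class CohortSpec:
    """Everything needed to build panels for one analysis run."""

    vcf_paths: list[str]
    admixed_samples: list[str]
    ref1_samples: list[str] = field(default_factory=list)
    ref2_samples: list[str] = field(default_factory=list)
    map_path: str | None = None
    cM_per_Mb: float = 1.0
    M_total: float | None = None
    maf_threshold: float = 0.05
    max_missing: float = 0.10
    bin_width: float = 0.001  # Morgans
    P: int = 200
    phased: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        adm = set(self.admixed_samples)
        if adm & set(self.ref1_samples) or adm & set(self.ref2_samples):
            raise ValueError("admixed and reference sample sets must be disjoint")
        if self.M_total is not None and not 0.0 < self.M_total < 1.0:
            raise ValueError("M_total must lie strictly in (0, 1)")


def _genotype_rows(variant, phased: bool) -> np.ndarray:
    """Per-sample values: (n, 2) haplotypes if phased else (n, 1) genotypes."""
    if phased:
        gts = np.asarray([g[:2] for g in variant.genotypes], dtype=float)
        gts[gts < 0] = np.nan
        return gts
    gt = np.asarray(variant.gt_types, dtype=float)  # 0/1/2 alt copies, 3 unknown
    gt[gt == 3] = np.nan
    return gt[:, None] / 2.0


def read_vcf_panel(
    spec: CohortSpec,
) -> tuple[GenotypePanel, np.ndarray | None, np.ndarray | None]:
    """Load the admixed panel and aligned reference matrices from VCF.

    Returns ``(panel, F, G)`` where ``F``/``G`` are reference value
    matrices aligned to the panel's sites (None when that reference set is
    empty).  Panel positions are provisional Morgans at ``cM_per_Mb``;
    apply :func:`assign_genetic_positions` to use a genetic map.  Sites
    with more than ``spec.max_missing`` missing admixed genotypes are
    dropped, remaining missing values are mean-imputed.
    """
    from cyvcf2 import VCF

    all_samples = list(spec.admixed_samples) + list(spec.ref1_samples) + list(
        spec.ref2_samples
    )
    rows_adm, rows_f, rows_g, bps, chroms = [], [], [], [], []
    n_adm = len(spec.admixed_samples)
    n_r1 = len(spec.ref1_samples)
    for path in spec.vcf_paths:
        vcf = VCF(path, samples=all_samples, gts012=True)
        missing = set(all_samples) - set(vcf.samples)
        if missing:
            raise ValueError(f"samples absent from {path}: {sorted(missing)}")
        order = [vcf.samples.index(s) for s in all_samples]
        for v in vcf:
            if not _is_autosome(v.CHROM):
                continue
            if not v.is_snp or len(v.ALT) != 1:
                continue
            vals = _genotype_rows(v, spec.phased)[order].reshape(-1)
            k = 2 if spec.phased else 1
            adm = vals[: n_adm * k]
            frac_missing = np.isnan(adm).mean()
            if frac_missing > spec.max_missing:
                continue
            if np.isnan(adm).any():
                adm = np.where(np.isnan(adm), np.nanmean(adm), adm)
                # snap imputed values back onto the {0, 1/2, 1} alphabet
                adm = np.round(adm * 2.0) / 2.0 if not spec.phased else np.round(adm)
            rows_adm.append(adm)
            rows_f.append(vals[n_adm * k : (n_adm + n_r1) * k])
            rows_g.append(vals[(n_adm + n_r1) * k :])
            bps.append(v.POS)
            chroms.append(v.CHROM.removeprefix("chr"))
        vcf.close()
    if not rows_adm:
        raise ValueError("no biallelic autosomal SNPs retained from the input VCF(s)")
    bp = np.asarray(bps, dtype=np.int64)
    chrom = np.asarray(chroms)
    order = np.lexsort((bp, chrom))
    H = np.asarray(rows_adm).T[:, order]
    panel = GenotypePanel(
        H,
        positions=bp[order] * spec.cM_per_Mb * 1e-8,
        chrom=chrom[order],
        sample_ids=list(spec.admixed_samples),
        bp=bp[order],
    )
    F = np.asarray(rows_f).T[:, order] if n_r1 else None
    G = np.asarray(rows_g).T[:, order] if spec.ref2_samples else None
    return panel, F, G


def read_genetic_map(path: str) -> pd.DataFrame:
    """Plain-text genetic map with columns chrom, bp, cM (header optional)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, skip_blank_lines=True)
    if df.shape[1] < 3:
        raise ValueError("genetic map needs columns: chrom, bp, cM")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "bp", "cM"]
    if not np.issubdtype(df["bp"].dtype, np.number):  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    df["bp"] = df["bp"].astype(np.int64)
    df["cM"] = df["cM"].astype(float)
    for c, grp in df.groupby("chrom"):
        if np.any(np.diff(grp["bp"].to_numpy()) <= 0) or np.any(
            np.diff(grp["cM"].to_numpy()) < 0
        ):
            raise ValueError(f"genetic map not monotone on chromosome {c}")
    return df


def _interp_map(bp: np.ndarray, mbp: np.ndarray, mcM: np.ndarray) -> np.ndarray:
    """Linear interpolation with terminal-rate extrapolation beyond the map."""
    cM = np.interp(bp, mbp, mcM)
    if mbp.size >= 2:
        lo_rate = (mcM[1] - mcM[0]) / (mbp[1] - mbp[0])
        hi_rate = (mcM[-1] - mcM[-2]) / (mbp[-1] - mbp[-2])
        below = bp < mbp[0]
        above = bp > mbp[-1]
        cM[below] = mcM[0] + (bp[below] - mbp[0]) * lo_rate
        cM[above] = mcM[-1] + (bp[above] - mbp[-1]) * hi_rate
        if below.any() or above.any():
            logger.warning(
                "%d sites outside the genetic map; extrapolated with terminal rates",
                int(below.sum() + above.sum()),
            )
    return cM


def assign_genetic_positions(
    panel: GenotypePanel,
    map_path: str | None = None,
    cM_per_Mb: float = 1.0,
) -> GenotypePanel:
    """Replace panel positions with Morgans from a map or a constant rate."""
    if panel.bp is None:
        raise ValueError("panel carries no base-pair coordinates")
    if map_path is None:
        pos = panel.bp * cM_per_Mb * 1e-8
    else:
        gmap = read_genetic_map(map_path)
        pos = np.empty(panel.S)
        for c in np.unique(panel.chrom):
            sel = panel.chrom == c
            sub = gmap[gmap["chrom"] == str(c)]
            if sub.empty:
                raise ValueError(f"genetic map has no entries for chromosome {c}")
            pos[sel] = 0.01 * _interp_map(
                panel.bp[sel].astype(float), sub["bp"].to_numpy(float), sub["cM"].to_numpy()
            )
    return GenotypePanel(panel.H, pos, panel.chrom, panel.sample_ids, panel.bp)


def write_surface(surface: WeightedLDSurface, path: str) -> None:
    """Tab-separated long-format surface with per-chromosome partial sums.

    Header lines (``#``) carry the metadata needed to rebuild the object;
    data rows are (chrom, d_bin, d'_bin, numerator, count) for non-empty
    bins.  Round-trips losslessly at double precision.
    """
    meta = {
        "bin_width_morgans": surface.bin_width,
        "P": surface.P,
        "n_samples": surface.n,
        "bias": surface.bias,
        "chromosomes": [str(c) for c in surface.chromosomes],
    }
    with open(path, "w") as fh:
        fh.write("# triald weighted 3-locus LD surface\n")
        fh.write(f"# meta {json.dumps(meta)}\n")
        fh.write("chrom\td_bin\tdp_bin\tnumerator\tcount\n")
        for c in surface.chromosomes:
            num, den = surface.num_by_chrom[c], surface.den_by_chrom[c]
            ii, jj = np.nonzero((den != 0) | (num != 0))
            for i, j in zip(ii, jj):
                fh.write(f"{c}\t{i}\t{j}\t{num[i, j]:.17g}\t{den[i, j]:.17g}\n")


def read_surface(path: str) -> WeightedLDSurface:
    """Inverse of :func:`write_surface`."""
    meta = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta "):
                meta = json.loads(line[len("# meta ") :])
                break
    if meta is None:
        raise ValueError(f"{path} has no surface metadata header")
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"chrom": str}, float_precision="round_trip"
    )
    P = int(meta["P"])
    num_by, den_by = {}, {}
    for c in meta["chromosomes"]:
        sub = df[df["chrom"] == c]
        num = np.zeros((P + 1, P + 1))
        den = np.zeros((P + 1, P + 1))
        num[sub["d_bin"], sub["dp_bin"]] = sub["numerator"]
        den[sub["d_bin"], sub["dp_bin"]] = sub["count"]
        num_by[c] = num
        den_by[c] = den
    num_tot = sum(num_by.values()) if num_by else np.zeros((P + 1, P + 1))
    den_tot = sum(den_by.values()) if den_by else np.zeros((P + 1, P + 1))
    return WeightedLDSurface(
        float(meta["bin_width_morgans"]),
        P,
        int(meta["n_samples"]),
        float(meta["bias"]),
        num_tot,
        den_tot,
        num_by,
        den_by,
    )


def write_vcf(
    haplotypes: np.ndarray,
    bp: np.ndarray,
    chrom: np.ndarray,
    sample_ids: list[str],
    path: str,
    phased: bool = True,
) -> None:
    """Write {0,1} haplotype data (two rows per sample) as a VCF 4.2 file.

    Used by the simulator to emit synthetic cohorts; alleles are arbitrary
    A/G SNPs with the alternate allele counted by the haplotype value.
    """
    H = np.asarray(haplotypes)
    if H.shape[0] != 2 * len(sample_ids):
        raise ValueError("need two haplotype rows per sample")
    sep = "|" if phased else "/"
    contigs = []
    for c in chrom:
        if c not in contigs:
            contigs.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=triald-simulate\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for s in range(H.shape[1]):
            gts = "\t".join(
                f"{int(H[2 * i, s])}{sep}{int(H[2 * i + 1, s])}"
                for i in range(len(sample_ids))
            )
            fh.write(f"{chrom[s]}\t{int(bp[s])}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
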