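"""File formats: PLINK .raw/.map text genotypes, VCF 4.2, phenotype CSV,
run configuration.

Internally marker indices are 0-based; the VCF boundary uses 1-based
positions as the standard requires.  Missing genotype calls on read are
imputed to the marker's rounded mean dosage, with a logged count — the
simulator itself never emits missing data.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .markers import GenotypePanel, MarkerMap
from .traits import PhenotypePanel

logger = logging.getLogger("gpbench")

__all__ = [
    "read_genotypes", "write_plink_raw", "read_plink_raw", "write_plink_map",
    "write_vcf", "read_vcf", "write_phenotypes", "read_phenotypes",
    "load_config", "save_config", "config_hash",
]

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_plink_raw(panel: GenotypePanel, path) -> None:
    """PLINK .raw additive-dosage export (counted allele 'A')."""
    cols = [f"{mid}_A" for mid in panel.map.marker_ids]
    df = pd.DataFrame(panel.dosages, columns=cols)
    for c, v in zip(reversed(_RAW_META), ["-9", "0", "0", "0",
                                          panel.sample_ids, panel.sample_ids]):
        df.insert(0, c, v)
    df.to_csv(path, sep=" ", index=False)


def read_plink_raw(path) -> GenotypePanel:
    """Read a PLINK .raw text file into a panel (equidistant 1-chromosome map
    unless a .map sidecar is supplied separately)."""
    df = pd.read_csv(path, sep=r"\s+")
    missing_meta = [c for c in _RAW_META if c not in df.columns]
    if missing_meta:
        raise ValueError(f"malformed .raw header: missing {missing_meta}")
    markers = [c for c in df.columns if c not in _RAW_META]
    if not markers:
        raise ValueError("no marker columns in .raw file")
    M = df[markers].to_numpy(dtype=np.float64)
    M = _impute_missing(M, str(path))
    ids = np.array([f"{mid.rsplit('_', 1)[0]}" for mid in markers], dtype=object)
    mmap = MarkerMap(ids, np.ones(len(ids), dtype=int),
                     np.linspace(0, 1, len(ids)))
    return GenotypePanel(M.astype(np.int8), mmap,
                         df["IID"].astype(str).to_numpy(dtype=object))


def _impute_missing(M: np.ndarray, source: str) -> np.ndarray:
    nan_mask = ~np.isfinite(M)
    n_missing = int(nan_mask.sum())
    if n_missing:
        col_mean = np.nanmean(np.where(nan_mask, np.nan, M), axis=0)
        if not np.isfinite(col_mean).all():
            raise ValueError(f"{source}: marker with all calls missing")
        fill = np.clip(np.rint(col_mean), 0, 2)
        M = np.where(nan_mask, fill[np.newaxis, :], M)
        logger.info("imputed %d missing calls in %s to rounded mean dosage",
                    n_missing, source)
    bad = ~np.isin(M, (0.0, 1.0, 2.0))
    if bad.any():
        raise ValueError(f"{source}: dosages outside {{0,1,2}}")
    return M


def write_plink_map(mmap: MarkerMap, path) -> None:
    """PLINK .map: chromosome, id, genetic position (cM), bp ordinal."""
    rows = []
    for chrom, sl in mmap.chrom_slices().items():
        for j, k in enumerate(range(sl.start, sl.stop), start=1):
            rows.append((chrom, mmap.marker_ids[k],
                         100.0 * mmap.genetic_position[k], j))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF 4.2 with unphased GT calls (0/0, 0/1, 1/1)."""
    gt_strings = np.array(["0/0", "0/1", "1/1"], dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gpbench\n")
        for chrom in panel.map.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in panel.sample_ids) + "\n")
        for chrom, sl in panel.map.chrom_slices().items():
            for pos_in_chrom, j in enumerate(range(sl.start, sl.stop), start=1):
                calls = "\t".join(gt_strings[panel.dosages[:, j]])
                fh.write(f"{chrom}\t{pos_in_chrom}\t{panel.map.marker_ids[j]}"
                         f"\tA\tB\t.\t.\t.\tGT\t{calls}\n")


def read_vcf(path) -> GenotypePanel:
    """Read a VCF into a panel via cyvcf2, summing GT alleles per sample."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    ids, chroms, pos, rows = [], [], [], []
    for var in vcf:
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        dos = np.empty(len(samples))
        for i, g in enumerate(gts):
            if len(g) != 3:
                raise ValueError(f"{path}: ploidy != 2 at {var.ID}")
            a, b = g[0], g[1]
            dos[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append(dos)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(int(var.CHROM))
        pos.append(float(var.POS))
    if not rows:
        raise ValueError(f"{path}: no variants")
    M = _impute_missing(np.vstack(rows).T, str(path))
    # genetic position is unknown in a VCF; carry bp order as a surrogate map
    pos = np.asarray(pos)
    gpos = np.empty_like(pos)
    chrom_arr = np.asarray(chroms)
    for c in np.unique(chrom_arr):
        mask = chrom_arr == c
        span = pos[mask]
        gpos[mask] = ((span - span.min()) / max(span.max() - span.min(), 1.0))
    mmap = MarkerMap(np.array(ids, dtype=object), chrom_arr, gpos)
    return GenotypePanel(M.astype(np.int8), mmap, samples)


def read_genotypes(path, format: str | None = None) -> GenotypePanel:
    """Dispatch on format ('plink_raw' or 'vcf'; inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "plink_raw"
    if format == "plink_raw":
        return read_plink_raw(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_phenotypes(phen: PhenotypePanel, sample_ids, path) -> None:
    df = pd.DataFrame(phen.phenotypes, columns=list(phen.trait_names))
    df.insert(0, "sample_id", np.asarray(sample_ids, dtype=object))
    df.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("phenotype CSV must have a sample_id column")
    return df


_REQUIRED_CONFIG_KEYS = ("simulation", "traits", "models", "evaluation")


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    missing = [k for k in _REQUIRED_CONFIG_KEYS if k not in cfg]
    if missing:
        raise KeyError(f"missing config key(s): {', '.join(missing)}")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a resolved configuration, for run logging."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
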