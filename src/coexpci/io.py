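"""Readers and writers for the pipeline's tabular formats.

All user-facing tables are UTF-8, tab-delimited, with ``NA`` for missing
values. Genomic coordinates are 1-based closed intervals; BED-style
0-based half-open input is accepted only via an explicit flag and
converted on read. A minimal VCF reader (biallelic sites, GT field only)
is provided for genotype input; dosages count the minor allele.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CovariateTable, ExpressionMatrix, GenotypeMatrix, ValidationError
from .synthetic import SyntheticCohort

__all__ = [
    "read_expression",
    "write_expression",
    "read_genotypes",
    "write_genotypes",
    "read_covariates",
    "read_snp_meta",
    "read_gene_coords",
    "read_vcf",
    "read_phenotypes",
    "write_cohort",
]

log = logging.getLogger(__name__)

NA = "NA"


def read_expression(path, quality: pd.Series | None = None) -> ExpressionMatrix:
    """Expression TSV: first column gene id, header row sample ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    if frame.index.name is None:
        frame.index.name = "gene"
    return ExpressionMatrix(frame, quality)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t", na_rep=NA)


def read_genotypes(path, meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Dosage TSV: samples x SNPs, header = SNP ids, NA = missing.

    Values outside {0, 1, 2, NA} are rejected with the offending row and
    column named.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    arr = frame.to_numpy(dtype=float)
    bad = ~(np.isnan(arr) | np.isin(arr, [0.0, 1.0, 2.0]))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: dosage {arr[i, j]!r} outside {{0,1,2,NA}} at data line "
            f"{i + 2} (sample {frame.index[i]!r}), column {frame.columns[j]!r}"
        )
    return GenotypeMatrix(frame.astype(float), meta)


def write_genotypes(geno: GenotypeMatrix, path, meta_path=None) -> None:
    out = geno.dosages.copy()
    out.index.name = out.index.name or "sample"
    out.to_csv(path, sep="\t", na_rep=NA)
    if meta_path is not None:
        m = geno.meta.copy()
        m.index.name = m.index.name or "snp"
        m.to_csv(meta_path, sep="\t", na_rep=NA)


def read_covariates(path) -> CovariateTable:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    return CovariateTable(frame)


def read_snp_meta(path) -> pd.DataFrame:
    """SNP metadata TSV: columns id (index), chrom, pos, minor, major[, maf]."""
    meta = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], dtype={"chrom": str})
    required = {"chrom", "pos"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"{path}: SNP metadata missing columns {sorted(missing)}")
    return meta


def read_gene_coords(path, bed: bool = False) -> pd.DataFrame:
    """Gene coordinates TSV: gene (index), chrom, start, end.

    1-based closed intervals by default; ``bed=True`` accepts 0-based
    half-open rows and converts them on read (start+1, end unchanged).
    """
    coords = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    missing = {"chrom", "start", "end"} - set(coords.columns)
    if missing:
        raise ValidationError(f"{path}: gene coordinates missing columns {sorted(missing)}")
    if bed:
        coords = coords.assign(start=coords["start"] + 1)
        log.info("converted BED half-open coordinates to 1-based closed")
    return coords


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])


def read_vcf(path) -> GenotypeMatrix:
    """Minimal biallelic VCF reader (GT field only).

    Multi-allelic sites are skipped with a logged count; ``chr``-prefixed
    chromosome names are normalized. Dosage counts the minor allele: if
    the ALT frequency exceeds 0.5 the site is flipped so REF becomes the
    counted allele, recorded in the metadata.
    """
    samples: list[str] = []
    rows = []
    meta_rows = []
    skipped = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValidationError(f"{path}:{line_no}: VCF has no sample columns")
                samples = fields[9:]
                continue
            if not samples:
                raise ValidationError(f"{path}:{line_no}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValidationError(f"{path}:{line_no}: truncated VCF record")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                skipped += 1
                continue
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise ValidationError(f"{path}:{line_no}: record lacks GT field") from None
            doses = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    doses.append(np.nan)
                else:
                    doses.append(float(sum(int(a) for a in alleles)))
            chrom_norm = chrom[3:] if chrom.lower().startswith("chr") else chrom
            vid = vid if vid not in (".", "") else f"{chrom_norm}:{pos}"
            rows.append((vid, doses))
            alt_freq = np.nanmean(doses) / 2.0 if np.isfinite(np.nanmean(doses)) else 0.0
            if alt_freq > 0.5:
                doses_flipped = [2.0 - d if np.isfinite(d) else np.nan for d in doses]
                rows[-1] = (vid, doses_flipped)
                minor, major, maf = ref, alt, 1.0 - alt_freq
            else:
                minor, major, maf = alt, ref, alt_freq
            meta_rows.append((vid, chrom_norm, int(pos), minor, major, maf))
    if skipped:
        log.info("skipped %d multi-allelic VCF sites", skipped)
    if not rows:
        raise ValidationError(f"{path}: no biallelic records found")
    dosages = pd.DataFrame(
        {vid: d for vid, d in rows}, index=pd.Index(samples, name="sample")
    )
    meta = pd.DataFrame(
        meta_rows, columns=["snp", "chrom", "pos", "minor", "major", "maf"]
    ).set_index("snp")
    if meta.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate variant ids in VCF")
    gm = GenotypeMatrix(dosages, meta)
    gm.n_skipped_multiallelic = skipped  # type: ignore[attr-defined]
    return gm


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write a simulated cohort: expression/genotypes/covariates/phenotypes/truth.

    Quality scores are stored as a ``quality`` column of the covariates
    table (they are per-sample metadata, not confounds; the prep stage
    reads them from there).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if cohort.expression is not None:
        write_expression(cohort.expression, out / "expression.tsv")
        paths["expression"] = str(out / "expression.tsv")
    write_genotypes(cohort.genotypes, out / "genotypes.tsv", out / "snp_meta.tsv")
    paths["genotypes"] = str(out / "genotypes.tsv")
    paths["snp_meta"] = str(out / "snp_meta.tsv")
    cov = cohort.covariates.table.copy()
    if cohort.expression is not None and cohort.expression.quality is not None:
        cov["quality"] = cohort.expression.quality
    cov.index.name = "sample"
    cov.to_csv(out / "covariates.tsv", sep="\t", na_rep=NA)
    paths["covariates"] = str(out / "covariates.tsv")
    if cohort.phenotypes is not None:
        ph = cohort.phenotypes.copy()
        ph.index.name = "sample"
        ph.to_csv(out / "phenotypes.tsv", sep="\t", na_rep=NA)
        paths["phenotypes"] = str(out / "phenotypes.tsv")
    if hasattr(cohort, "gene_coords"):
        gc = cohort.gene_coords.copy()
        gc.index.name = "gene"
        gc.to_csv(out / "gene_coords.tsv", sep="\t")
        paths["gene_coords"] = str(out / "gene_coords.tsv")
    truth = cohort.truth
    payload = {
        "module_gene_ids": truth.module_gene_ids,
        "seed_gene_id": truth.seed_gene_id,
        "causal_snp_ids": truth.causal_snp_ids,
        "causal_betas": truth.causal_betas.to_dict(),
        "loadings": truth.loadings.to_dict(),
        "latent": truth.latent.to_dict(),
        "noise_sd": truth.noise_sd,
        "genetic_variance_share": truth.genetic_variance_share,
        "expected_pc1_fraction": truth.expected_pc1_fraction,
        "expected_me_latent_cor2": truth.expected_me_latent_cor2,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    paths["truth"] = str(out / "truth.json")
    return paths
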