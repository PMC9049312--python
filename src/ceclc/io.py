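"""Reading genotype/phenotype/covariate files and assembling analysis inputs.

Phenotypes and covariates are delimited text (TSV or CSV) with a header row
and the sample ID in the first column. Genotypes come either from a delimited
text file with one 0/1/2 minor-allele count column keyed by sample ID, or
from a VCF (one test per biallelic site, minor-allele dosage; multi-allelic
sites are skipped). All matrices are joined on sample ID in the phenotype
file's row order; incomplete rows are dropped (complete-case).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import AssociationInput, drop_incomplete_rows

logger = logging.getLogger(__name__)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df.astype(float)


def read_phenotypes(path) -> pd.DataFrame:
    """N x K phenotype table indexed by sample ID."""
    return _read_table(path)


def read_covariates(path) -> pd.DataFrame:
    """N x p covariate table indexed by sample ID."""
    return _read_table(path)


def read_genotype_text(path) -> pd.Series:
    """Single genotype column (0/1/2 counts) keyed by sample ID."""
    df = _read_table(path)
    if df.shape[1] != 1:
        raise ValueError("genotype text file must have exactly one data column")
    return df.iloc[:, 0]


def iter_vcf_genotypes(path):
    """Yield (variant_id, dosage Series) per biallelic site of a VCF.

    The dosage is the count of the *minor* allele: if the ALT frequency
    exceeds 0.5 the coding is flipped to 2 - alt_count. Multi-allelic sites
    are skipped with a warning; missing genotypes become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = [str(s) for s in vcf.samples]
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic site %s", var.ID or var.POS)
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        freq = np.nanmean(dose) / 2.0
        if freq > 0.5:
            dose = 2.0 - dose
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        yield vid, pd.Series(dose, index=samples)


def assemble(
    genotypes: pd.Series,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> tuple[AssociationInput, pd.Index]:
    """Join genotype/phenotype/covariate tables on sample ID (phenotype order).

    Returns the complete-case AssociationInput and the retained sample IDs.
    """
    ids = phenotypes.index
    g = genotypes.reindex(ids).to_numpy()
    y = phenotypes.to_numpy()
    z = covariates.reindex(ids).to_numpy() if covariates is not None else None
    g2, y2, z2, _ = drop_incomplete_rows(g, y, z)
    keep = np.isfinite(genotypes.reindex(ids).to_numpy())
    keep &= np.all(np.isfinite(y), axis=1)
    if z is not None:
        keep &= np.all(np.isfinite(z), axis=1)
    return AssociationInput(genotypes=g2, phenotypes=y2, covariates=z2), ids[keep]


def write_dataset(prefix, genotypes: np.ndarray, phenotypes: np.ndarray) -> tuple[Path, Path]:
    """Write simulated data as <prefix>.geno.tsv / <prefix>.pheno.tsv."""
    prefix = Path(prefix)
    ids = [f"S{i + 1}" for i in range(len(genotypes))]
    gpath = Path(str(prefix) + ".geno.tsv")
    ppath = Path(str(prefix) + ".pheno.tsv")
    pd.DataFrame({"sample": ids, "G": np.asarray(genotypes)}).to_csv(
        gpath, sep="\t", index=False
    )
    pheno = pd.DataFrame(
        np.asarray(phenotypes),
        columns=[f"Y{k + 1}" for k in range(np.asarray(phenotypes).shape[1])],
    )
    pheno.insert(0, "sample", ids)
    pheno.to_csv(ppath, sep="\t", index=False)
    return gpath, ppath
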