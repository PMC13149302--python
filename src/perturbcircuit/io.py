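"""Readers and writers for the pipeline's on-disk formats.

Counts travel as a CellRanger-style triplet (Matrix-Market .mtx in
feature x barcode orientation, 1-based on disk and 0-based in memory, plus
barcodes.tsv and features.tsv); guides as a four-column TSV; pathways as
GMT; PPI edges as a scored TSV; cohorts as clinical + expression CSVs.
Gene identity is plain case-sensitive symbols with no alias resolution.
All readers accept gzip-compressed (.gz) variants.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Mapping, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .synthetic import SurvivalCohort


class FormatError(ValueError):
    """Malformed or inconsistent input files."""


def _open(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Counts triplet
# ---------------------------------------------------------------------------


def read_counts(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> ad.AnnData:
    """Read a feature x barcode Matrix-Market triplet into cell x gene AnnData."""
    with _open(mtx_path, "rb") as fh:
        M = scipy.io.mmread(fh)
    M = sp.csr_matrix(M)
    with _open(barcodes_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open(features_path) as fh:
        features = [line.strip().split("\t")[0] for line in fh if line.strip()]
    n_feat, n_bc = M.shape
    if len(features) != n_feat:
        raise FormatError(
            f"{features_path}: {len(features)} features listed but matrix "
            f"has {n_feat} rows"
        )
    if len(barcodes) != n_bc:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes listed but matrix "
            f"has {n_bc} columns"
        )
    X = M.T.tocsr()
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )


def write_counts(
    adata: ad.AnnData,
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> None:
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    with _open(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(X.T), field="integer")
    with _open(barcodes_path, "wt") as fh:
        fh.writelines(f"{bc}\n" for bc in adata.obs_names)
    with _open(features_path, "wt") as fh:
        fh.writelines(f"{g}\t{g}\tGene Expression\n" for g in adata.var_names)


# ---------------------------------------------------------------------------
# Guide table
# ---------------------------------------------------------------------------

GUIDE_COLUMNS = ["barcode", "sgRNA_id", "target_gene", "umi_count"]


def read_guides(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GUIDE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing guide columns {sorted(missing)}")
    if (df["umi_count"] < 0).any():
        raise FormatError(f"{path}: negative guide UMI counts")
    return df[GUIDE_COLUMNS]


def write_guides(df: pd.DataFrame, path: str | Path) -> None:
    df[GUIDE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT pathway sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ... per line."""
    sets: dict[str, list[str]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                                  "description and at least one gene")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "perturbcircuit") -> None:
    with _open(path, "wt") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------


def read_ppi(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_a", "gene_b", "score"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: PPI table needs columns {sorted(needed)}")
    bad = ~((df["score"] > 0) & (df["score"] <= 1))
    if bad.any():
        raise FormatError(
            f"{path}: {int(bad.sum())} PPI scores outside (0, 1]"
        )
    return df[["gene_a", "gene_b", "score"]]


def write_ppi(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_a", "gene_b", "score"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def read_cohort(
    clinical_path: str | Path,
    expression_path: Optional[str | Path] = None,
) -> SurvivalCohort:
    """Clinical CSV (sample_id, time, event, covariates...) plus an optional
    sample x gene expression CSV indexed by sample_id."""
    clin = pd.read_csv(clinical_path).set_index("sample_id")
    for col in ("time", "event"):
        if col not in clin.columns:
            raise FormatError(f"{clinical_path}: missing column {col!r}")
    if clin["time"].isna().any() or clin["event"].isna().any():
        raise FormatError(f"{clinical_path}: missing time/event values")
    if (clin["time"] <= 0).any():
        raise FormatError(f"{clinical_path}: non-positive survival times")
    if not clin["event"].isin([0, 1]).all():
        raise FormatError(f"{clinical_path}: event must be 0/1")
    if expression_path is not None:
        expr = pd.read_csv(expression_path, index_col=0)
        expr = expr.loc[clin.index]
    else:
        expr = pd.DataFrame(index=clin.index)
    covariates = clin.drop(columns=["time", "event"])
    return SurvivalCohort(
        expr=expr,
        time=clin["time"].astype(float),
        event=clin["event"].astype(int),
        covariates=covariates,
    )


def write_cohort(
    cohort: SurvivalCohort,
    clinical_path: str | Path,
    expression_path: Optional[str | Path] = None,
) -> None:
    clin = pd.DataFrame({"time": cohort.time, "event": cohort.event})
    clin = clin.join(cohort.covariates)
    clin.index.name = "sample_id"
    clin.to_csv(clinical_path)
    if expression_path is not None:
        out = cohort.expr.copy()
        out.index.name = "sample_id"
        out.to_csv(expression_path)
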