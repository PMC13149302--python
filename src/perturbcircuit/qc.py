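"""Cell-level quality control and guide-based perturbation assignment.

Filtering keeps cells with >= 200 detected genes, >= 1000 total counts and
<= 20% mitochondrial reads (inclusive boundaries: the removal rules are
"fewer than", "below" and "more than"). Guide calling thresholds each cell's
captured sgRNA UMIs and requires the top guide to dominate the runner-up.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger("perturbcircuit")

STATUS_SINGLET = "singlet"
STATUS_DOUBLET = "doublet"
STATUS_UNASSIGNED = "unassigned"


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> ad.AnnData:
    """Populate per-cell QC metrics (in place; returns ``adata`` for chaining).

    Adds obs columns ``n_genes_detected``, ``total_counts`` and ``pct_mito``
    (fraction in [0, 1], over genes whose symbol starts with ``mito_prefix``)
    and the var column ``mito``.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    X = X.tocsr()
    mito = adata.var_names.str.startswith(mito_prefix)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_det = X.getnnz(axis=1)
    mito_counts = np.asarray(X[:, np.flatnonzero(mito)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    adata.obs["n_genes_detected"] = n_det.astype(int)
    adata.obs["total_counts"] = total.astype(int)
    adata.obs["pct_mito"] = pct
    adata.var["mito"] = mito
    return adata


def filter_cells(
    adata: ad.AnnData,
    min_genes: int = 200,
    min_counts: int = 1000,
    max_mito: float = 0.20,
) -> tuple[ad.AnnData, dict[str, int]]:
    """Apply the three cell-level filters; returns (filtered, report).

    A cell is retained iff n_genes_detected >= min_genes AND
    total_counts >= min_counts AND pct_mito <= max_mito. The report counts
    cells failing each criterion (a cell can fail several).
    """
    for col in ("n_genes_detected", "total_counts", "pct_mito"):
        if col not in adata.obs:
            raise ValueError("QC metrics missing; run compute_qc_metrics first")
    obs = adata.obs
    fail_genes = obs["n_genes_detected"].to_numpy() < min_genes
    fail_counts = obs["total_counts"].to_numpy() < min_counts
    fail_mito = obs["pct_mito"].to_numpy() > max_mito
    keep = ~(fail_genes | fail_counts | fail_mito)
    report = {
        "n_input": int(adata.n_obs),
        "n_removed_min_genes": int(fail_genes.sum()),
        "n_removed_min_counts": int(fail_counts.sum()),
        "n_removed_max_mito": int(fail_mito.sum()),
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        warnings.warn("all cells removed by QC filters", stacklevel=2)
    log.info("QC filter: %s", report)
    return adata[keep].copy(), report


def assign_guides(
    guide_table: pd.DataFrame,
    min_umi: int = 3,
    dominance_ratio: float = 2.0,
    control_label: str = "NTC",
    cell_ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Call each cell's perturbation from its captured guide UMIs.

    Guides with ``umi_count >= min_umi`` are candidates. A cell with no
    candidate is unassigned; with one candidate, a singlet; with several, a
    singlet for the top guide iff its UMIs are at least ``dominance_ratio``
    times the runner-up's, otherwise a doublet. ``perturbation`` is the
    called guide's target gene (or the control label) and is only defined
    for singlets. Cells listed in ``cell_ids`` but absent from the table are
    reported unassigned.
    """
    required = {"barcode", "sgRNA_id", "target_gene", "umi_count"}
    if not required.issubset(guide_table.columns):
        raise ValueError(f"guide table needs columns {sorted(required)}")

    records: dict[str, dict] = {}
    for bc, grp in guide_table.groupby("barcode", sort=True):
        grp = grp.sort_values(["umi_count", "sgRNA_id"],
                              ascending=[False, True])
        cand = grp[grp["umi_count"] >= min_umi]
        if len(cand) == 0:
            records[bc] = dict(status=STATUS_UNASSIGNED, sgRNA_id="",
                               perturbation="", n_called=0,
                               top_umi=int(grp["umi_count"].iloc[0]))
            continue
        top = cand.iloc[0]
        if len(cand) == 1 or top["umi_count"] >= dominance_ratio * cand["umi_count"].iloc[1]:
            records[bc] = dict(status=STATUS_SINGLET,
                               sgRNA_id=top["sgRNA_id"],
                               perturbation=top["target_gene"],
                               n_called=int(len(cand)),
                               top_umi=int(top["umi_count"]))
        else:
            records[bc] = dict(status=STATUS_DOUBLET, sgRNA_id="",
                               perturbation="", n_called=int(len(cand)),
                               top_umi=int(top["umi_count"]))

    if cell_ids is not None:
        for bc in cell_ids:
            if bc not in records:
                records[bc] = dict(status=STATUS_UNASSIGNED, sgRNA_id="",
                                   perturbation="", n_called=0, top_umi=0)
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "barcode"
    out = out.sort_index()
    out["is_control"] = (out["perturbation"] == control_label) & (
        out["status"] == STATUS_SINGLET
    )
    return out


def coverage_summary(
    assignments: pd.DataFrame,
    targets: Optional[Iterable[str]] = None,
    guides: Optional[Iterable[str]] = None,
) -> dict:
    """Cells per target and per guide among singlets, with median/min/max.

    Targets or guides supplied but absent from the assignments are reported
    with zero cells rather than dropped.
    """
    singlets = assignments[assignments["status"] == STATUS_SINGLET]
    per_target = singlets.groupby("perturbation").size()
    per_guide = singlets.groupby("sgRNA_id").size()
    if targets is not None:
        per_target = per_target.reindex(list(targets), fill_value=0)
    if guides is not None:
        per_guide = per_guide.reindex(list(guides), fill_value=0)
    per_target = per_target.astype(int).sort_index()
    per_guide = per_guide.astype(int).sort_index()

    def _summ(s: pd.Series) -> dict:
        if len(s) == 0:
            return {"median": 0.0, "min": 0, "max": 0}
        return {"median": float(s.median()), "min": int(s.min()),
                "max": int(s.max())}

    return {
        "per_target": per_target,
        "per_guide": per_guide,
        "target_summary": _summ(per_target),
        "guide_summary": _summ(per_guide),
        "n_singlet": int(len(singlets)),
        "n_doublet": int((assignments["status"] == STATUS_DOUBLET).sum()),
        "n_unassigned": int((assignments["status"] == STATUS_UNASSIGNED).sum()),
    }
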