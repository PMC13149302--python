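"""Per-perturbation differential expression against non-targeting controls.

Only genes detected in more than half of the control cells are tested
(strict inequality). The test is a two-sided Wilcoxon rank-sum on the
log-normalized values — exact enumeration for small tie-free groups, a
tie-corrected normal approximation otherwise — followed by Benjamini–
Hochberg adjustment within each perturbation's family.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("perturbcircuit")

EXACT_MAX_N = 8  # per-group size up to which the exact rank-split null is used


def control_expressed_genes(
    counts: ad.AnnData, control_cells: Sequence[str]
) -> list[str]:
    """Genes with a nonzero count in strictly more than 50% of control cells."""
    control_cells = list(control_cells)
    if len(control_cells) < 2:
        raise ValueError("need at least 2 control cells")
    sub = counts[control_cells]
    X = sub.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    frac = X.getnnz(axis=0) / len(control_cells)
    return list(np.asarray(sub.var_names)[frac > 0.5])


def control_expressed_fraction(
    counts: ad.AnnData, control_cells: Sequence[str]
) -> pd.Series:
    """Per-gene fraction of control cells with a nonzero count."""
    control_cells = list(control_cells)
    if len(control_cells) < 2:
        raise ValueError("need at least 2 control cells")
    sub = counts[control_cells]
    X = sub.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    return pd.Series(X.getnnz(axis=0) / len(control_cells),
                     index=sub.var_names, name="frac_control_expressed")


def _dense(adata: ad.AnnData, cells: Sequence[str], genes: Sequence[str]) -> np.ndarray:
    sub = adata[list(cells), list(genes)]
    X = sub.X
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def wilcoxon_de(
    norm: ad.AnnData,
    perturbation_cells: Sequence[str],
    control_cells: Sequence[str],
    genes: Iterable[str],
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Two-sided rank-sum DE of perturbed vs control cells per gene.

    ``norm`` holds log-normalized expression. log2FC compares group means on
    the de-logged (expm1) scale with a pseudocount. Genes with identical
    values across both groups get p = 1 and log2FC = 0.
    """
    genes = list(genes)
    xp = _dense(norm, perturbation_cells, genes)
    xc = _dense(norm, control_cells, genes)
    n1, n2 = xp.shape[0], xc.shape[0]
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 cells per group")

    mean_p = np.expm1(xp).mean(axis=0)
    mean_c = np.expm1(xc).mean(axis=0)
    lfc = np.log2((mean_p + pseudocount) / (mean_c + pseudocount))

    combined_min = np.minimum(xp.min(axis=0), xc.min(axis=0))
    combined_max = np.maximum(xp.max(axis=0), xc.max(axis=0))
    degenerate = combined_min == combined_max

    pvals = np.ones(len(genes))
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        for j in range(len(genes)):
            if degenerate[j]:
                continue
            both = np.concatenate([xp[:, j], xc[:, j]])
            method = "exact" if len(np.unique(both)) == len(both) else "asymptotic"
            pvals[j] = stats.mannwhitneyu(
                xp[:, j], xc[:, j], alternative="two-sided", method=method
            ).pvalue
    else:
        ok = ~degenerate
        if ok.any():
            res = stats.mannwhitneyu(
                xp[:, ok], xc[:, ok], alternative="two-sided",
                method="asymptotic", axis=0,
            )
            pvals[ok] = np.atleast_1d(res.pvalue)

    lfc = np.where(degenerate, 0.0, lfc)
    return pd.DataFrame(
        {"gene": genes, "log2_fold_change": lfc, "p_value": pvals}
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1] and non-NaN")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: ad.AnnData,
    norm: ad.AnnData,
    assignments: pd.DataFrame,
    control_label: str = "NTC",
    perturbations: Optional[Sequence[str]] = None,
    pseudocount: float = 1e-9,
    fdr_scope: str = "per_perturbation",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Full DE table across perturbations, with the control-expression filter
    applied and BH adjustment within each perturbation (or globally)."""
    singlets = assignments[assignments["status"] == "singlet"]
    ctrl = [c for c in singlets.index[singlets["perturbation"] == control_label]
            if c in norm.obs_names]
    if len(ctrl) < 2:
        raise ValueError("no (or too few) control cells")
    frac = control_expressed_fraction(counts, ctrl)
    genes = list(frac.index[frac > 0.5])
    log.info("DE: %d genes pass the control-expression filter", len(genes))
    if perturbations is None:
        perturbations = sorted(
            p for p in singlets["perturbation"].unique() if p != control_label
        )
    tables = []
    for pert in perturbations:
        cells = [c for c in singlets.index[singlets["perturbation"] == pert]
                 if c in norm.obs_names]
        if len(cells) < min_cells:
            log.warning("DE: skipping %s (%d cells)", pert, len(cells))
            continue
        tab = wilcoxon_de(norm, cells, ctrl, genes, pseudocount=pseudocount)
        tab.insert(0, "perturbation", pert)
        tab["frac_control_expressed"] = frac.loc[tab["gene"]].to_numpy()
        if fdr_scope == "per_perturbation":
            tab["fdr"] = bh_adjust(tab["p_value"].to_numpy())
        tables.append(tab)
    out = pd.concat(tables, ignore_index=True)
    if fdr_scope == "global":
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out
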