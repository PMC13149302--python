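"""PPI-weighted perturbation interaction indices.

Two perturbations' effects on a fitness pathway are compared with the
weighted cosine S(a, b) = <a, b>_Omega / sqrt(<a, a>_Omega <b, b>_Omega),
where <a, b>_Omega = a' Omega b and Omega is a gene-gene similarity matrix
built from protein-protein interaction scores (unit diagonal, symmetrized,
repaired to positive semidefinite so |S| <= 1 by Cauchy-Schwarz). The
pathway-averaged S maps linearly onto a Synergistic Index (SI, S > 0) and an
Antagonistic Index (AI, S < 0) on the 0-100 scale.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("perturbcircuit")


@dataclass
class SimilarityMatrixOmega:
    genes: list[str]
    omega: np.ndarray
    repaired: bool = False
    max_eigenvalue_change: float = 0.0


@dataclass
class TargetVector:
    perturbation_id: str
    pathway_id: str
    values: pd.Series  # gene -> signed effect over the pathway space
    all_zero: bool = False


@dataclass
class InteractionScores:
    pert_a: str
    pert_b: str
    per_pathway_S: dict[str, Optional[float]] = field(default_factory=dict)
    S_aggregate: Optional[float] = None
    synergistic_index: Optional[float] = None
    antagonistic_index: Optional[float] = None


def build_omega(
    edges: pd.DataFrame,
    gene_space: Sequence[str],
    psd_repair: bool = True,
) -> SimilarityMatrixOmega:
    """Omega = I + symmetrized off-diagonal PPI scores over ``gene_space``.

    Self-edges are ignored with a warning; edges touching genes outside the
    space are dropped. With ``psd_repair``, negative eigenvalues are clipped
    to zero and the diagonal re-normalized to 1, guaranteeing |S| <= 1.
    """
    genes = list(gene_space)
    if not genes:
        raise ValueError("empty gene space")
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    omega = np.eye(n)
    n_self = 0
    for ga, gb, score in edges[["gene_a", "gene_b", "score"]].itertuples(index=False):
        if ga == gb:
            n_self += 1
            continue
        if ga in idx and gb in idx:
            i, j = idx[ga], idx[gb]
            s = float(score)
            omega[i, j] = max(omega[i, j] if omega[i, j] != 0 else 0.0, s)
            omega[j, i] = omega[i, j]
    if n_self:
        warnings.warn(f"{n_self} self-edges ignored", stacklevel=2)

    repaired = False
    max_change = 0.0
    if psd_repair:
        vals, vecs = np.linalg.eigh(omega)
        if vals.min() < 0:
            clipped = np.clip(vals, 0.0, None)
            max_change = float(np.max(np.abs(clipped - vals)))
            omega = (vecs * clipped) @ vecs.T
            d = np.sqrt(np.clip(np.diag(omega), 1e-12, None))
            omega = omega / np.outer(d, d)
            omega = 0.5 * (omega + omega.T)
            np.fill_diagonal(omega, 1.0)
            repaired = True
            if max_change > 1e-6:
                log.warning("Omega PSD repair shifted an eigenvalue by %.3g",
                            max_change)
    return SimilarityMatrixOmega(genes=genes, omega=omega, repaired=repaired,
                                 max_eigenvalue_change=max_change)


def target_vector(
    de: pd.DataFrame,
    perturbation: str,
    pathway: Sequence[str],
    fdr_cut: float = 0.05,
) -> TargetVector:
    """Signed pathway effect vector: log2FC where FDR < cut, else 0."""
    pathway = sorted(set(pathway))
    sub = de[de["perturbation"] == perturbation].set_index("gene")
    vals = pd.Series(0.0, index=pathway)
    hits = [g for g in pathway if g in sub.index]
    for g in hits:
        row = sub.loc[g]
        if float(row["fdr"]) < fdr_cut:
            vals[g] = float(row["log2_fold_change"])
    all_zero = bool((vals == 0).all())
    if all_zero:
        log.info("target vector %s/%d-gene pathway is all zero", perturbation,
                 len(pathway))
    return TargetVector(perturbation_id=perturbation, pathway_id="",
                        values=vals, all_zero=all_zero)


def weighted_similarity(
    a: TargetVector | pd.Series,
    b: TargetVector | pd.Series,
    omega: SimilarityMatrixOmega,
) -> Optional[float]:
    """S(a, b) under the Omega inner product; None when a norm is zero."""
    va = (a.values if isinstance(a, TargetVector) else a).reindex(
        omega.genes).fillna(0.0).to_numpy()
    vb = (b.values if isinstance(b, TargetVector) else b).reindex(
        omega.genes).fillna(0.0).to_numpy()
    O = omega.omega
    naa = float(va @ O @ va)
    nbb = float(vb @ O @ vb)
    if naa <= 0 or nbb <= 0:
        return None
    s = float(va @ O @ vb) / np.sqrt(naa * nbb)
    return float(np.clip(s, -1.0, 1.0))


def interaction_indices(
    per_pathway_S: Mapping[str, Optional[float]],
    pathway_weights: Optional[Mapping[str, float]] = None,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(S_aggregate, SI, AI) from per-pathway similarities.

    S_aggregate is the weight-averaged S over pathways where S is defined;
    SI = 100 * max(0, S_aggregate), AI = 100 * max(0, -S_aggregate). All
    three are None when every pathway is undefined.
    """
    defined = {k: v for k, v in per_pathway_S.items() if v is not None}
    if not defined:
        return None, None, None
    if pathway_weights is None:
        pathway_weights = {k: 1.0 for k in defined}
    wsum = sum(pathway_weights.get(k, 1.0) for k in defined)
    s_agg = sum(v * pathway_weights.get(k, 1.0) for k, v in defined.items()) / wsum
    si = 100.0 * max(0.0, s_agg)
    ai = 100.0 * max(0.0, -s_agg)
    return float(s_agg), float(si), float(ai)


def pairwise_interactions(
    de: pd.DataFrame,
    pathways: Mapping[str, Sequence[str]],
    ppi_edges: pd.DataFrame,
    fdr_cut: float = 0.05,
    psd_repair: bool = True,
    pathway_weights: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """All pairwise interaction scores across perturbations in the DE table.

    One Omega is built per pathway gene space. Returns a tidy table with one
    row per unordered perturbation pair: per-pathway S columns, S_aggregate,
    SI and AI (NaN where undefined).
    """
    perts = sorted(de["perturbation"].unique())
    omegas = {name: build_omega(ppi_edges, genes, psd_repair=psd_repair)
              for name, genes in pathways.items()}
    vectors = {
        (p, name): target_vector(de, p, pathways[name], fdr_cut=fdr_cut)
        for p in perts for name in pathways
    }
    rows = []
    for pa, pb in itertools.combinations(perts, 2):
        per_path: dict[str, Optional[float]] = {}
        for name in pathways:
            per_path[name] = weighted_similarity(
                vectors[(pa, name)], vectors[(pb, name)], omegas[name]
            )
        s_agg, si, ai = interaction_indices(per_path, pathway_weights)
        row: dict = {"pert_a": pa, "pert_b": pb}
        for name, s in per_path.items():
            row[f"S_{name}"] = np.nan if s is None else s
        row["S_aggregate"] = np.nan if s_agg is None else s_agg
        row["synergistic_index"] = np.nan if si is None else si
        row["antagonistic_index"] = np.nan if ai is None else ai
        rows.append(row)
    return pd.DataFrame(rows)
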