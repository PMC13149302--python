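"""Transcriptional programs: gene clustering, signatures, activity scores.

Genes are clustered on their perturbation-response profiles (columns of the
regulatory matrix) with a mutual-union k-nearest-neighbor graph (k = 5,
Euclidean) and Louvain community detection. Each program's signature is its
top 25% of genes by regulatory weight; activity is scored per cell (or
sample) as mean signature expression minus a bin-matched control-gene mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.spatial.distance import cdist

from .diffexpr import bh_adjust
from .regmatrix import RegulatoryMatrix

log = logging.getLogger("perturbcircuit")


@dataclass
class GeneProgram:
    program_id: str
    member_genes: list[str]
    gene_weights: pd.Series  # gene -> regulatory weight used for ranking
    top_perturbations: list[str]

    @property
    def size(self) -> int:
        return len(self.member_genes)


@dataclass
class ProgramSignature:
    program_id: str
    genes: list[str]  # ordered, highest weight first
    fraction: float


# ---------------------------------------------------------------------------
# Graph construction and clustering
# ---------------------------------------------------------------------------


def build_gene_knn(
    R: RegulatoryMatrix | pd.DataFrame, k: int = 5, metric: str = "cosine"
) -> nx.Graph:
    """Mutual-union kNN graph over genes from their coefficient profiles.

    The default cosine distance treats a program as a shared *direction* of
    perturbation response, which is invariant to each gene's response
    magnitude; all-zero profiles (genes no perturbation touches) are defined
    as mutually identical (distance 0) and maximally far (2) from any
    responsive gene. Euclidean distance is available via ``metric``. Genes
    are pre-sorted lexicographically so ties in distance (duplicate
    profiles) break deterministically by gene id. Edge (g, h) exists iff h
    is among g's k nearest or vice versa; weights are 1.
    """
    beta = R.beta if isinstance(R, RegulatoryMatrix) else R
    genes = sorted(beta.columns)
    if len(genes) < k + 1:
        raise ValueError("need at least k+1 genes")
    M = beta[genes].to_numpy().T  # gene x perturbation
    D = cdist(M, M, metric=metric)
    if metric == "cosine":
        zero = np.linalg.norm(M, axis=1) == 0
        D[np.ix_(zero, zero)] = 0.0
        D[np.ix_(zero, ~zero)] = 2.0
        D[np.ix_(~zero, zero)] = 2.0
    np.fill_diagonal(D, np.inf)
    G = nx.Graph()
    G.add_nodes_from(genes)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    for i, gi in enumerate(genes):
        for j in order[i]:
            G.add_edge(gi, genes[j], weight=1.0)
    return G


def _mean_profile(beta: pd.DataFrame, members: Sequence[str]) -> np.ndarray:
    return beta[list(members)].to_numpy().mean(axis=1)


def _profile_corr(beta: pd.DataFrame, a: Sequence[str], b: Sequence[str]) -> float:
    pa, pb = _mean_profile(beta, a), _mean_profile(beta, b)
    if np.std(pa) == 0 or np.std(pb) == 0:
        return 1.0 if not np.any(pa != pb) else -np.inf
    return float(np.corrcoef(pa, pb)[0, 1])


def louvain_programs(
    graph: nx.Graph,
    R: RegulatoryMatrix | pd.DataFrame,
    resolution: float = 1.0,
    seed: int = 0,
    min_program_size: int = 10,
    top_perturbations: int = 3,
    corr_merge: float = 0.8,
) -> list[GeneProgram]:
    """Louvain partition of the gene graph into programs.

    Louvain on a kNN graph over-fragments when genes of one program differ
    in which weak coefficients survived penalization, so clusters whose mean
    coefficient profiles correlate above ``corr_merge`` are agglomerated
    first (highest correlation first; 0 disables). Communities below
    ``min_program_size`` are then merged into the cluster whose mean profile
    correlates best with theirs (smallest first). Programs are labeled P-0,
    P-1, ... in decreasing size. Each gene's regulatory weight is the mean
    |beta| over the program's top-loading perturbations (top
    ``top_perturbations`` by mean |beta| over members).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty gene graph")
    beta = R.beta if isinstance(R, RegulatoryMatrix) else R
    comms = nx.community.louvain_communities(
        graph, resolution=resolution, seed=seed
    )
    clusters = [sorted(c) for c in comms]
    clusters.sort(key=lambda c: (-len(c), c[0]))

    # agglomerate over-fragmented clusters with near-identical profiles
    while corr_merge > 0 and len(clusters) > 1:
        best_pair, best_r = None, -np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                r = _profile_corr(beta, clusters[i], clusters[j])
                if r > best_r:
                    best_pair, best_r = (i, j), r
        if best_r < corr_merge:
            break
        i, j = best_pair
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
        clusters.sort(key=lambda c: (-len(c), c[0]))

    # merge undersized clusters by profile correlation
    while len(clusters) > 1:
        sizes = [len(c) for c in clusters]
        small = [i for i, s in enumerate(sizes) if s < min_program_size]
        if not small:
            break
        i = min(small, key=lambda idx: sizes[idx])
        prof_i = _mean_profile(beta, clusters[i])
        best_j, best_r = None, -np.inf
        for j, cl in enumerate(clusters):
            if j == i:
                continue
            prof_j = _mean_profile(beta, cl)
            if np.std(prof_i) == 0 or np.std(prof_j) == 0:
                r = -np.inf if np.any(prof_i != prof_j) else 1.0
            else:
                r = float(np.corrcoef(prof_i, prof_j)[0, 1])
            if r > best_r or (r == best_r and best_j is None):
                best_j, best_r = j, r
        clusters[best_j] = sorted(clusters[best_j] + clusters[i])
        del clusters[i]
        clusters.sort(key=lambda c: (-len(c), c[0]))

    programs: list[GeneProgram] = []
    for rank, members in enumerate(clusters):
        loading = beta[members].abs().mean(axis=1)
        top = list(loading.sort_values(ascending=False)
                   .index[:top_perturbations])
        weights = beta.loc[top, members].abs().mean(axis=0)
        programs.append(GeneProgram(
            program_id=f"P-{rank}",
            member_genes=list(members),
            gene_weights=weights,
            top_perturbations=top,
        ))
    log.info("programs: %d clusters, sizes %s", len(programs),
             [p.size for p in programs])
    return programs


def program_labels(programs: Sequence[GeneProgram]) -> pd.Series:
    """gene -> program_id over all clustered genes."""
    pairs = [(g, p.program_id) for p in programs for g in p.member_genes]
    s = pd.Series(dict(pairs), name="program")
    return s


def program_signature(p: GeneProgram, fraction: float = 0.25) -> ProgramSignature:
    """Top ``fraction`` of member genes by regulatory weight (ceil; ties by
    gene id)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = math.ceil(fraction * p.size)
    ranked = sorted(p.member_genes,
                    key=lambda g: (-float(p.gene_weights[g]), g))
    return ProgramSignature(program_id=p.program_id, genes=ranked[:n],
                            fraction=fraction)


# ---------------------------------------------------------------------------
# Activity scoring
# ---------------------------------------------------------------------------


def _expr_frame(expr: ad.AnnData | pd.DataFrame) -> pd.DataFrame:
    if isinstance(expr, pd.DataFrame):
        return expr
    X = expr.X
    if sp.issparse(X):
        X = X.toarray()
    return pd.DataFrame(np.asarray(X), index=expr.obs_names,
                        columns=expr.var_names)


def score_units(
    expr: ad.AnnData | pd.DataFrame,
    sig: ProgramSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    method: str = "bin_control",
) -> pd.Series:
    """Per-unit activity score of a signature.

    ``bin_control`` (default): genes are binned into ``n_bins`` groups of
    matched average expression; each signature gene is compared with up to
    ``n_ctrl`` control genes sampled (seeded) from its bin, and the score is
    the mean over signature genes of (gene expression - control mean). The
    per-cell pairing makes the score exactly invariant to adding a constant
    to all genes of a unit. ``zmean``: plain mean of per-gene z-scores.
    """
    df = _expr_frame(expr)
    present = [g for g in sig.genes if g in df.columns]
    if len(present) < 0.5 * len(sig.genes):
        raise ValueError(
            f"only {len(present)}/{len(sig.genes)} signature genes present"
        )
    if len(present) < len(sig.genes):
        log.warning("score_units: %d signature genes missing",
                    len(sig.genes) - len(present))

    if method == "zmean":
        sub = df[present]
        sd = sub.std(axis=0).replace(0.0, np.nan)
        z = (sub - sub.mean(axis=0)) / sd
        return z.mean(axis=1).fillna(0.0).rename(sig.program_id)
    if method != "bin_control":
        raise ValueError(f"unknown scoring method {method!r}")

    rng = np.random.default_rng(seed)
    gene_means = df.mean(axis=0)
    ranks = gene_means.rank(method="first")
    bins = np.ceil(ranks / len(ranks) * n_bins).astype(int)
    sig_set = set(present)
    values = df.to_numpy()
    col_index = {g: i for i, g in enumerate(df.columns)}

    total = np.zeros(len(df))
    for g in present:
        # control pool: non-signature genes from the gene's expression bin,
        # widening to neighboring bins when the bin is signature-dominated
        width = 0
        pool: list = []
        while not pool and width < n_bins:
            lo, hi = bins[g] - width, bins[g] + width
            pool = [h for h in bins.index[(bins >= lo) & (bins <= hi)]
                    if h not in sig_set]
            width += 1
        if not pool:
            pool = [h for h in bins.index if h != g]
        take = min(n_ctrl, len(pool))
        ctrl = rng.choice(len(pool), size=take, replace=False)
        ctrl_idx = [col_index[pool[i]] for i in sorted(ctrl)]
        total += values[:, col_index[g]] - values[:, ctrl_idx].mean(axis=1)
    score = total / len(present)
    return pd.Series(score, index=df.index, name=sig.program_id)


def score_all_programs(
    expr: ad.AnnData | pd.DataFrame,
    signatures: Sequence[ProgramSignature],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    method: str = "bin_control",
) -> pd.DataFrame:
    cols = {
        s.program_id: score_units(expr, s, n_bins=n_bins, n_ctrl=n_ctrl,
                                  seed=seed, method=method)
        for s in signatures
    }
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Per-perturbation program enrichment
# ---------------------------------------------------------------------------


def program_enrichment(
    scores: pd.DataFrame,
    assignments: pd.DataFrame,
    control_label: str = "NTC",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Welch t-test of each perturbation's program scores against control.

    Returns rows (perturbation, program, delta_score, p, fdr); delta_score is
    mean(perturbed) - mean(control); BH across all pairs. Exactly equal
    degenerate groups get p = 1.
    """
    singlets = assignments[assignments["status"] == "singlet"]
    ctrl_cells = [c for c in singlets.index[singlets["perturbation"] == control_label]
                  if c in scores.index]
    if len(ctrl_cells) < min_cells:
        raise ValueError("too few control cells with scores")
    rows = []
    perts = sorted(p for p in singlets["perturbation"].unique()
                   if p != control_label)
    for pert in perts:
        cells = [c for c in singlets.index[singlets["perturbation"] == pert]
                 if c in scores.index]
        if len(cells) < min_cells:
            continue
        for prog in scores.columns:
            xp = scores.loc[cells, prog].to_numpy()
            xc = scores.loc[ctrl_cells, prog].to_numpy()
            delta = float(xp.mean() - xc.mean())
            if np.ptp(xp) == 0 and np.ptp(xc) == 0:
                p = 1.0 if xp[0] == xc[0] else 0.0
            else:
                p = float(stats.ttest_ind(xp, xc, equal_var=False).pvalue)
            rows.append({"perturbation": pert, "program": prog,
                         "delta_score": delta, "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def match_programs_to_truth(
    programs: Sequence[GeneProgram], truth_assignment: pd.Series
) -> pd.DataFrame:
    """Best-Jaccard match of fitted programs to planted ones (for benchmarks)."""
    rows = []
    planted = {
        int(p): set(truth_assignment.index[truth_assignment == p])
        for p in truth_assignment.unique() if p != -1
    }
    for prog in programs:
        mem = set(prog.member_genes)
        best, best_j = None, 0.0
        for pid, genes in planted.items():
            j = len(mem & genes) / len(mem | genes) if mem | genes else 0.0
            if j > best_j:
                best, best_j = pid, j
        rows.append({"program_id": prog.program_id, "size": prog.size,
                     "matched_truth": best, "jaccard": best_j})
    return pd.DataFrame(rows)
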