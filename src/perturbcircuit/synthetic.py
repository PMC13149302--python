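"""Ground-truthed synthetic inputs for the circuit-mapping pipeline.

The generator plants a block-structured perturbation -> program -> gene
architecture: each transcriptional program is a set of co-regulated genes,
each target gene perturbation shifts the mean expression of the programs it
regulates by a log-scale effect, and counts are drawn from a negative
binomial with per-gene dispersion. Companion generators produce a PPI edge
list with within-program enrichment, pathway gene sets, survival cohorts with
a planted proportional-hazards link to program activity, and drug-response
tables with a planted Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import ConfigurationError, SimulationConfig, stream_rng

BACKGROUND = -1

_MITO_NAMES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6",
    "MT-CO3", "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated screen."""

    genes: list[str]
    targets: list[str]
    guides: pd.DataFrame  # sgRNA_id, target_gene (control guides included)
    program_assignment: pd.Series  # gene -> program id, BACKGROUND for none
    beta_true: pd.DataFrame  # (targets + control) x genes, log-scale shifts
    baseline_mu: pd.Series  # gene -> mean counts per cell (before lib size)
    dispersion: pd.Series  # gene -> NB dispersion phi, var = mu + phi mu^2
    control_label: str
    seed: int
    config: Optional[SimulationConfig] = None

    @property
    def n_programs(self) -> int:
        labels = self.program_assignment[self.program_assignment != BACKGROUND]
        return int(labels.nunique())

    def program_genes(self, program: int) -> list[str]:
        mask = self.program_assignment == program
        return list(self.program_assignment.index[mask])


@dataclass
class SurvivalCohort:
    """Bulk cohort: expression, follow-up and covariates per sample."""

    expr: pd.DataFrame  # sample x gene
    time: pd.Series
    event: pd.Series
    covariates: pd.DataFrame
    true_score: Optional[pd.Series] = None
    hr_per_unit: Optional[float] = None
    seed: Optional[int] = None


def nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative-binomial counts with var = mu + phi * mu^2 (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if np.any(pois):
        out[pois] = rng.poisson(mu[pois])
    if np.any(~pois):
        r = 1.0 / phi[~pois]
        lam = rng.gamma(shape=r, scale=mu[~pois] / r)
        out[~pois] = rng.poisson(lam)
    return out


def generate_truth(config: SimulationConfig, seed: int = 0) -> SyntheticTruth:
    """Draw the planted regulatory architecture for one simulated screen.

    Program membership, per-program regulator sets (with signs), effect
    magnitudes, baseline means and dispersions are all drawn from ``seed``;
    two calls with the same config and seed return identical truths.
    """
    config.validate()
    rng = stream_rng(seed, "truth")
    P = config.n_programs

    targets = [f"TGT{i:02d}" for i in range(config.n_targets)]
    n_mito = min(config.n_mito_genes, len(_MITO_NAMES))
    mito = _MITO_NAMES[:n_mito]
    n_plain = config.n_genes - n_mito
    genes = [f"G{i:04d}" for i in range(n_plain)] + mito

    # program membership: background fraction stays unassigned; mito genes
    # are always background so QC structure is independent of the circuit
    assign = np.full(config.n_genes, BACKGROUND, dtype=int)
    n_program_genes = int(round(n_plain * (1.0 - config.background_fraction)))
    chosen = rng.choice(n_plain, size=n_program_genes, replace=False)
    assign[chosen] = rng.integers(0, P, size=n_program_genes)
    # guarantee every program is populated
    for p in range(P):
        if not np.any(assign == p):
            pool = np.flatnonzero(assign == BACKGROUND)[:1]
            assign[pool] = p
    program_assignment = pd.Series(assign, index=genes, name="program")

    # regulator sets: each program is shifted by 2-3 targets with signs;
    # patterns are kept distinct so programs are separable from the fitted
    # coefficient profiles
    seen: set[tuple] = set()
    regulators: list[list[tuple[int, float]]] = []
    for _ in range(P):
        for _attempt in range(200):
            k = int(rng.integers(config.min_regulators, config.max_regulators + 1))
            k = min(k, config.n_targets)
            idx = np.sort(rng.choice(config.n_targets, size=k, replace=False))
            signs = rng.choice([-1.0, 1.0], size=k)
            key = tuple(zip(idx.tolist(), signs.tolist()))
            if key not in seen:
                seen.add(key)
                break
        regulators.append([(int(i), float(s)) for i, s in zip(idx, signs)])

    # every target must regulate at least one program
    covered = {i for regs in regulators for i, _ in regs}
    for t in range(config.n_targets):
        if t not in covered:
            p = int(rng.integers(0, P))
            regulators[p].append((t, float(rng.choice([-1.0, 1.0]))))

    perts = targets + [config.control_label]
    beta = np.zeros((len(perts), config.n_genes))
    gene_jitter = rng.uniform(0.8, 1.2, size=config.n_genes)
    for p, regs in enumerate(regulators):
        members = np.flatnonzero(assign == p)
        for t, sign in regs:
            mag = rng.uniform(config.effect_low, config.effect_high)
            beta[t, members] = sign * mag * gene_jitter[members]
    beta_true = pd.DataFrame(beta, index=perts, columns=genes)

    mu = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma,
                       size=config.n_genes)
    # scale mitochondrial means to the configured fraction of total counts
    if n_mito:
        is_mito = np.array([g in set(mito) for g in genes])
        tot_plain = mu[~is_mito].sum()
        want = config.mito_fraction / (1.0 - config.mito_fraction) * tot_plain
        mu[is_mito] *= want / mu[is_mito].sum()
    phi = rng.uniform(config.dispersion_low, config.dispersion_high,
                      size=config.n_genes)

    guide_rows = []
    for t in targets:
        for g in range(config.n_guides_per_target):
            guide_rows.append((f"sg{t}_{g + 1}", t))
    for g in range(config.n_control_guides):
        guide_rows.append((f"sg{config.control_label}_{g + 1}", config.control_label))
    guides = pd.DataFrame(guide_rows, columns=["sgRNA_id", "target_gene"])

    return SyntheticTruth(
        genes=genes,
        targets=targets,
        guides=guides,
        program_assignment=program_assignment,
        beta_true=beta_true,
        baseline_mu=pd.Series(mu, index=genes, name="mu"),
        dispersion=pd.Series(phi, index=genes, name="phi"),
        control_label=config.control_label,
        seed=seed,
        config=config,
    )


# ---------------------------------------------------------------------------
# Counts + guide capture
# ---------------------------------------------------------------------------


def simulate_counts(
    truth: SyntheticTruth,
    cells_per_guide: Optional[int] = None,
    n_control_cells: Optional[int] = None,
    doublet_rate: Optional[float] = None,
    seed: int = 0,
    chunk_cells: int = 2000,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate the cell x gene UMI matrix and the per-cell guide table.

    Returns an AnnData of raw integer counts (obs carries the generator's
    true perturbation labels for benchmarking) and a guide-capture table with
    columns barcode / sgRNA_id / target_gene / umi_count, one row per
    (cell, guide) with at least one captured UMI.
    """
    cfg = truth.config or SimulationConfig()
    if cells_per_guide is None:
        cells_per_guide = cfg.cells_per_guide
    if n_control_cells is None:
        n_control_cells = cfg.n_control_cells
    if doublet_rate is None:
        doublet_rate = cfg.doublet_rate
    if not 0 <= doublet_rate < 0.5:
        raise ConfigurationError("doublet_rate must be in [0, 0.5)")
    if cells_per_guide < 20:
        raise ConfigurationError("cells_per_guide must be >= 20")

    rng = stream_rng(seed, "counts")
    guides = truth.guides
    target_guides = guides[guides.target_gene != truth.control_label]
    control_guides = guides[guides.target_gene == truth.control_label]

    primary: list[str] = []
    for sg in target_guides.sgRNA_id:
        primary.extend([sg] * cells_per_guide)
    n_ctrl_g = len(control_guides)
    base, extra = divmod(n_control_cells, n_ctrl_g)
    for j, sg in enumerate(control_guides.sgRNA_id):
        primary.extend([sg] * (base + (1 if j < extra else 0)))

    n_cells = len(primary)
    order = rng.permutation(n_cells)
    primary = [primary[i] for i in order]
    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]

    guide_to_target = dict(zip(guides.sgRNA_id, guides.target_gene))
    all_guides = list(guides.sgRNA_id)

    is_doublet = rng.random(n_cells) < doublet_rate
    secondary: list[Optional[str]] = [None] * n_cells
    for i in np.flatnonzero(is_doublet):
        while True:
            other = all_guides[int(rng.integers(len(all_guides)))]
            if other != primary[i]:
                secondary[i] = other
                break

    # per-cell expected expression: baseline * exp(sum of carried betas)
    beta = truth.beta_true
    mu0 = truth.baseline_mu.to_numpy()
    phi = truth.dispersion.to_numpy()
    lib = rng.lognormal(0.0, cfg.library_sigma, size=n_cells)
    mito_mask = np.array([g.startswith("MT-") for g in truth.genes])
    mito_mult = rng.lognormal(0.0, cfg.mito_cell_sigma, size=n_cells)

    blocks = []
    for start in range(0, n_cells, chunk_cells):
        stop = min(start + chunk_cells, n_cells)
        shift = np.zeros((stop - start, len(truth.genes)))
        for row, i in enumerate(range(start, stop)):
            shift[row] = beta.loc[guide_to_target[primary[i]]].to_numpy()
            if secondary[i] is not None:
                shift[row] += beta.loc[guide_to_target[secondary[i]]].to_numpy()
        mu = mu0[None, :] * np.exp(shift) * lib[start:stop, None]
        mu[:, mito_mask] *= mito_mult[start:stop, None]
        counts = nb_sample(rng, mu, phi[None, :])
        blocks.append(sp.csr_matrix(counts))
    X = sp.vstack(blocks).tocsr()

    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["true_guide"] = primary
    obs["true_guide_2"] = [s if s is not None else "" for s in secondary]
    obs["true_status"] = np.where(is_doublet, "doublet", "singlet")
    obs["true_perturbation"] = [guide_to_target[g] for g in primary]
    var = pd.DataFrame(index=pd.Index(truth.genes, name="gene"))
    adata = ad.AnnData(X=X, obs=obs, var=var)

    # guide capture UMIs: carried guides are NB(mean, phi); every guide also
    # has a small ambient Poisson background so the caller has to threshold
    rows = []
    for i, bc in enumerate(barcodes):
        carried = [primary[i]] + ([secondary[i]] if secondary[i] else [])
        umis: dict[str, int] = {}
        for sg in carried:
            umis[sg] = int(
                nb_sample(rng, np.array([cfg.guide_umi_mean]),
                          np.array([cfg.guide_umi_dispersion]))[0]
            )
        n_amb = rng.poisson(cfg.ambient_guide_rate * len(all_guides))
        for _ in range(n_amb):
            sg = all_guides[int(rng.integers(len(all_guides)))]
            umis[sg] = umis.get(sg, 0) + 1
        for sg, u in sorted(umis.items()):
            if u > 0:
                rows.append((bc, sg, guide_to_target[sg], u))
    guide_table = pd.DataFrame(
        rows, columns=["barcode", "sgRNA_id", "target_gene", "umi_count"]
    )
    return adata, guide_table


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------


def simulate_ppi(
    truth: SyntheticTruth,
    within_program_edge_prob: float = 0.3,
    between_prob: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Stochastic-block PPI edge list over the truth's gene universe.

    Pairs of genes in the same program are connected with probability
    ``within_program_edge_prob`` (scores U(0.5, 1]), any other pair with
    ``between_prob`` (scores U(0.1, 0.5)). Undirected, no self edges.
    """
    if not 0 <= between_prob < within_program_edge_prob <= 1:
        raise ConfigurationError(
            "need 0 <= between_prob < within_program_edge_prob <= 1"
        )
    rng = stream_rng(seed, "ppi")
    genes = np.asarray(truth.program_assignment.index)
    labels = truth.program_assignment.to_numpy()
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    same = (labels[iu] == labels[ju]) & (labels[iu] != BACKGROUND)
    prob = np.where(same, within_program_edge_prob, between_prob)
    keep = rng.random(len(iu)) < prob
    iu, ju, same = iu[keep], ju[keep], same[keep]
    score = np.where(
        same,
        rng.uniform(0.5, 1.0, size=len(iu)),
        rng.uniform(0.1, 0.5, size=len(iu)),
    )
    return pd.DataFrame(
        {"gene_a": genes[iu], "gene_b": genes[ju], "score": np.round(score, 6)}
    )


def simulate_pathways(
    truth: SyntheticTruth,
    n_pathways: int = 3,
    names: Sequence[str] = ("APOPTOSIS", "CELL_CYCLE", "CHECKPOINT"),
) -> dict[str, list[str]]:
    """Synthetic fitness pathway sets: one per planted program (plumbing for
    the interaction stage; deterministic given the truth)."""
    out: dict[str, list[str]] = {}
    for k in range(min(n_pathways, truth.n_programs)):
        name = names[k] if k < len(names) else f"FITNESS_{k}"
        out[f"SYNTHETIC_{name}"] = truth.program_genes(k)
    return out


# ---------------------------------------------------------------------------
# Cohorts and drug response
# ---------------------------------------------------------------------------

COVARIATE_FLAGS = ["FLT3", "NPM1", "TP53", "DNMT3A", "CEBPA", "RUNX1"]


def _cohort_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cov = pd.DataFrame(index=[f"S{i:04d}" for i in range(n)])
    cov["age"] = np.round(rng.normal(60.0, 12.0, size=n), 1)
    cov["cytogenetic_risk"] = rng.choice(
        ["favorable", "intermediate", "adverse"], size=n, p=[0.25, 0.5, 0.25]
    )
    for flag in COVARIATE_FLAGS:
        cov[flag] = rng.binomial(1, 0.2, size=n)
    return cov


def _covariate_linpred(cov: pd.DataFrame) -> np.ndarray:
    risk_code = cov["cytogenetic_risk"].map(
        {"favorable": 0, "intermediate": 1, "adverse": 2}
    ).to_numpy(dtype=float)
    lp = 0.02 * (cov["age"].to_numpy() - 60.0) + 0.3 * (risk_code - 1.0)
    for flag in COVARIATE_FLAGS:
        lp = lp + 0.15 * (cov[flag].to_numpy() - 0.2)
    return lp


def simulate_cohort(
    truth: SyntheticTruth,
    signature: Sequence[str],
    n_samples: int = 500,
    hr_per_unit: float = 0.5,
    censor_rate: float = 0.3,
    seed: int = 0,
    noise_sd: float = 0.3,
) -> SurvivalCohort:
    """Bulk cohort whose hazard follows a proportional-hazards link to the
    true program score.

    Each sample has a latent activity a ~ N(0, 1); signature genes read out
    a plus N(0, noise_sd) noise, all other genes are independent noise. The
    hazard is h0 * exp(log(hr_per_unit) * a + covariate effects); censoring
    is independent of a.
    """
    signature = list(signature)
    if not signature:
        raise ValueError("signature is empty")
    missing = set(signature) - set(truth.genes)
    if missing:
        raise ValueError(f"signature genes outside universe: {sorted(missing)[:5]}")
    if hr_per_unit <= 0:
        raise ConfigurationError("hr_per_unit must be > 0")
    if not 0 <= censor_rate < 1:
        raise ConfigurationError("censor_rate must be in [0, 1)")

    rng = stream_rng(seed, "cohort")
    genes = truth.genes
    a = rng.normal(0.0, 1.0, size=n_samples)
    base = rng.normal(5.0, 1.0, size=len(genes))
    expr = base[None, :] + rng.normal(0.0, 1.0, size=(n_samples, len(genes)))
    sig_idx = [genes.index(g) for g in signature]
    expr[:, sig_idx] = (
        base[sig_idx][None, :]
        + a[:, None]
        + rng.normal(0.0, noise_sd, size=(n_samples, len(sig_idx)))
    )
    cov = _cohort_covariates(rng, n_samples)

    h0 = 0.1
    lp = np.log(hr_per_unit) * a + _covariate_linpred(cov)
    t_event = rng.exponential(1.0 / (h0 * np.exp(lp)))
    if censor_rate > 0:
        rate_c = h0 * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)

    idx = cov.index
    return SurvivalCohort(
        expr=pd.DataFrame(np.round(expr, 6), index=idx, columns=genes),
        time=pd.Series(np.round(time, 6), index=idx, name="time"),
        event=pd.Series(event, index=idx, name="event"),
        covariates=cov,
        true_score=pd.Series(a, index=idx, name="true_score"),
        hr_per_unit=hr_per_unit,
        seed=seed,
    )


def simulate_drug_response(
    truth: SyntheticTruth,
    signature: Sequence[str],
    n_samples: int = 500,
    r_target: float = -0.35,
    seed: int = 0,
    n_null_drugs: int = 10,
    activity: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Drug AUC table with one drug correlated to the true program score.

    Returns a DataFrame indexed by sample with a ``score`` column (the true
    program activity), ``DRUG_TARGETED`` with population Pearson correlation
    ``r_target`` to the score, and ``DRUG_NULL_k`` columns independent of it.
    Lower AUC means higher drug sensitivity, so a drug to which high-score
    samples are sensitive carries a negative r_target. Pass ``activity``
    (e.g. a simulated cohort's true score) to tie the table to an existing
    set of samples instead of drawing fresh ones.
    """
    if not -1 < r_target < 1:
        raise ConfigurationError("r_target must be in (-1, 1)")
    rng = stream_rng(seed, "drug")
    if activity is not None:
        a = activity.to_numpy(dtype=float)
        a = (a - a.mean()) / a.std(ddof=0)
        n_samples = len(a)
    else:
        a = rng.normal(0.0, 1.0, size=n_samples)
    latent = r_target * a + np.sqrt(1.0 - r_target**2) * rng.normal(size=n_samples)
    cols = {"score": a, "DRUG_TARGETED": np.round(100.0 + 20.0 * latent, 6)}
    for k in range(n_null_drugs):
        cols[f"DRUG_NULL_{k + 1:02d}"] = np.round(
            100.0 + 20.0 * rng.normal(size=n_samples), 6
        )
    index = (activity.index if activity is not None
             else [f"S{i:04d}" for i in range(n_samples)])
    return pd.DataFrame(cols, index=index)
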