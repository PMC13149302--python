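"""Cohort-level translation of program signatures.

Bulk samples are scored as the mean of per-gene z-scored signature
expression; the score's survival association is estimated with Cox
proportional-hazards regression (Efron ties), optionally adjusted for age,
cytogenetic risk and recurrent-mutation flags; Kaplan-Meier stratification
and the log-rank test visualize/confirm it; a size-matched random-gene-set
permutation null quantifies signature specificity; and drug sensitivity is
related to the score by Pearson correlation of AUC values (lower AUC =
higher sensitivity, so protective "sensitizing" drugs show negative r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .config import stream_rng
from .diffexpr import bh_adjust
from .programs import ProgramSignature
from .synthetic import SurvivalCohort

log = logging.getLogger("perturbcircuit")

RISK_LEVELS = ["favorable", "intermediate", "adverse"]


@dataclass
class SurvivalResult:
    hazard_ratio: float
    ci95: tuple[float, float]
    p: float
    n: int
    adjusted: bool
    converged: bool = True
    coefficient: float = 0.0
    se: float = 0.0


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def score_bulk(
    expr: pd.DataFrame,
    sig: ProgramSignature | Sequence[str],
    method: str = "zmean",
) -> pd.Series:
    """Per-sample signature score from a sample x gene expression table.

    ``zmean``: mean over signature genes of expression z-scored across
    samples (constant genes are excluded with a log entry; all-constant
    input scores 0). ``rank``: mean per-gene percentile rank, centered.
    """
    genes = list(sig.genes) if isinstance(sig, ProgramSignature) else list(sig)
    present = [g for g in genes if g in expr.columns]
    if len(present) < 0.5 * len(genes):
        raise ValueError(f"only {len(present)}/{len(genes)} signature genes "
                         "present in the expression table")
    sub = expr[present]
    if method == "rank":
        pct = sub.rank(axis=0, pct=True) - 0.5
        return pct.mean(axis=1).rename("score")
    if method != "zmean":
        raise ValueError(f"unknown bulk scoring method {method!r}")
    sd = sub.std(axis=0)
    keep = sd > 0
    if (~keep).any():
        log.info("score_bulk: %d constant genes excluded", int((~keep).sum()))
    if not keep.any():
        return pd.Series(0.0, index=expr.index, name="score")
    z = (sub.loc[:, keep] - sub.loc[:, keep].mean(axis=0)) / sd[keep]
    return z.mean(axis=1).rename("score")


def _covariate_frame(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns: ordered-categorical risk with treatment
    contrasts (favorable as baseline), mutation flags and age as-is."""
    out = pd.DataFrame(index=cov.index)
    for col in cov.columns:
        if col == "cytogenetic_risk":
            cat = pd.Categorical(cov[col], categories=RISK_LEVELS, ordered=True)
            dummies = pd.get_dummies(cat, prefix="risk", drop_first=True)
            dummies.index = cov.index
            out = out.join(dummies.astype(float))
        else:
            out[col] = pd.to_numeric(cov[col])
    return out


# ---------------------------------------------------------------------------
# Cox association
# ---------------------------------------------------------------------------


def cox_association(
    scores: pd.Series,
    cohort: SurvivalCohort,
    adjust: bool = True,
) -> SurvivalResult:
    """Cox PH fit of survival on the signature score (HR per unit score)."""
    if int(cohort.event.sum()) < 10:
        raise ValueError("need at least 10 events")
    df = pd.DataFrame({
        "time": cohort.time,
        "event": cohort.event,
        "score": scores.reindex(cohort.time.index),
    })
    if adjust:
        df = df.join(_covariate_frame(cohort.covariates))
    df = df.dropna()
    cph = CoxPHFitter()
    converged = True
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception:  # separation / non-convergence: ridge-stabilized retry
        log.warning("Cox fit failed; retrying with a small L2 penalty")
        converged = False
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    ci = (float(np.exp(coef - 1.959963984540054 * se)),
          float(np.exp(coef + 1.959963984540054 * se)))
    p = float(cph.summary.loc["score", "p"])
    return SurvivalResult(
        hazard_ratio=float(np.exp(coef)), ci95=ci, p=p, n=int(len(df)),
        adjusted=adjust, converged=converged, coefficient=coef, se=se,
    )


def km_stratify(
    scores: pd.Series,
    cohort: SurvivalCohort,
    cut: str | float = "median",
) -> dict:
    """Median (or custom-threshold) stratification with the log-rank test.

    The low group includes samples at the threshold, so with an odd n the
    larger group contains the median sample. Returns the strata masks,
    fitted KM curves and the two-group log-rank statistic and p.
    """
    s = scores.reindex(cohort.time.index)
    thresh = float(s.median()) if cut == "median" else float(cut)
    high = s > thresh
    low = ~high
    if high.sum() == 0 or low.sum() == 0:
        raise ValueError("stratification impossible: all scores on one side")
    res = logrank_test(
        cohort.time[high], cohort.time[low],
        event_observed_A=cohort.event[high], event_observed_B=cohort.event[low],
    )
    km = {}
    for name, mask in (("high", high), ("low", low)):
        f = KaplanMeierFitter()
        f.fit(cohort.time[mask], cohort.event[mask], label=name)
        km[name] = f
    return {
        "threshold": thresh,
        "high": high,
        "low": low,
        "n_high": int(high.sum()),
        "n_low": int(low.sum()),
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "km": km,
    }


# ---------------------------------------------------------------------------
# Fast single-covariate Cox (Efron) for the permutation null
# ---------------------------------------------------------------------------


class CoxNewton1D:
    """Newton-Raphson maximizer of the single-covariate Efron partial
    likelihood, with the survival layout precomputed so thousands of
    covariate vectors can be fitted against one cohort cheaply."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        order = np.argsort(time, kind="stable")
        self.order = order
        self.t = time[order]
        self.d = event[order]
        self.n = len(self.t)
        _, self.starts = np.unique(self.t, return_index=True)
        self.m = np.add.reduceat(self.d, self.starts)  # events per tied time
        self.has_events = self.m > 0

    def _suffix_at_starts(self, v: np.ndarray) -> np.ndarray:
        c = np.cumsum(v[::-1])[::-1]
        return c[self.starts]

    def fit(self, x: np.ndarray, max_iter: int = 60, tol: float = 1e-9):
        """Returns (coef, se, converged); x in original sample order."""
        x = np.asarray(x, dtype=float)[self.order]
        beta = 0.0
        converged = False
        hess = -1.0
        for _ in range(max_iter):
            eta = np.clip(beta * x, -500, 500)
            w = np.exp(eta)
            wx = w * x
            wx2 = wx * x
            SRw = self._suffix_at_starts(w)
            SRwx = self._suffix_at_starts(wx)
            SRwx2 = self._suffix_at_starts(wx2)
            SDw = np.add.reduceat(w * self.d, self.starts)
            SDwx = np.add.reduceat(wx * self.d, self.starts)
            SDwx2 = np.add.reduceat(wx2 * self.d, self.starts)
            grad = float(np.sum(self.d * x))
            hess = 0.0
            ks = np.flatnonzero(self.has_events)
            for k in ks:
                m = int(self.m[k])
                for ell in range(m):
                    f = ell / m
                    denom = SRw[k] - f * SDw[k]
                    num1 = SRwx[k] - f * SDwx[k]
                    num2 = SRwx2[k] - f * SDwx2[k]
                    grad -= num1 / denom
                    hess -= num2 / denom - (num1 / denom) ** 2
            if hess >= 0:
                break
            step = grad / hess
            beta_new = beta - step
            if abs(beta_new - beta) < tol:
                beta = beta_new
                converged = True
                break
            beta = beta_new
        se = float(np.sqrt(-1.0 / hess)) if hess < 0 else np.nan
        return float(beta), se, converged


def permutation_specificity(
    cohort: SurvivalCohort,
    sig: ProgramSignature | Sequence[str],
    n_perm: int = 10000,
    seed: int = 0,
    candidate_pool: Optional[Sequence[str]] = None,
    score_method: str = "zmean",
) -> tuple[np.ndarray, float, dict]:
    """Size-matched random-gene-set null for the signature's hazard ratio.

    Draws ``n_perm`` uniform random gene sets of the signature's size from
    ``candidate_pool``, scores each and fits an unadjusted single-covariate
    Cox model. Every score (observed and null) is scaled to unit variance
    before the fit, so hazard ratios are per standard deviation of score and
    comparable across gene sets whose raw score variances differ.
    empirical_p = (1 + #{null HR <= observed HR}) / (n_perm + 1), i.e. small
    when the observed protective HR is extreme. Non-converging draws are
    dropped and counted.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    genes = list(sig.genes) if isinstance(sig, ProgramSignature) else list(sig)
    if candidate_pool is None:
        candidate_pool = [g for g in cohort.expr.columns]
    pool = sorted(set(candidate_pool))
    if len(pool) < 10 * len(genes):
        raise ValueError("candidate pool must be >= 10x the signature size")

    # precompute z-scored expression once; every draw is then a column mean
    sub = cohort.expr[pool]
    sd = sub.std(axis=0)
    keep = sd > 0
    Z = ((sub.loc[:, keep] - sub.loc[:, keep].mean(axis=0)) / sd[keep]).to_numpy()
    kept_pool = list(sub.columns[keep])
    pos = {g: i for i, g in enumerate(kept_pool)}

    def _unit_sd(x: np.ndarray) -> np.ndarray:
        s = x.std(ddof=0)
        return x / s if s > 0 else x

    solver = CoxNewton1D(cohort.time.to_numpy(), cohort.event.to_numpy())
    obs_score = score_bulk(cohort.expr, genes, method=score_method)
    beta_obs, _, ok = solver.fit(_unit_sd(obs_score.to_numpy()))
    if not ok:
        log.warning("observed-signature Cox fit did not converge")
    observed_hr = float(np.exp(beta_obs))

    rng = stream_rng(seed, "perm")
    null_hrs = np.full(n_perm, np.nan)
    n_failed = 0
    k = len(genes)
    for i in range(n_perm):
        draw = rng.choice(len(kept_pool), size=min(k, len(kept_pool)),
                          replace=False)
        x = _unit_sd(Z[:, draw].mean(axis=1))
        beta, _, ok = solver.fit(x)
        if ok and np.isfinite(beta):
            null_hrs[i] = np.exp(beta)
        else:
            n_failed += 1
    null_hrs = null_hrs[np.isfinite(null_hrs)]
    empirical_p = (1.0 + np.sum(null_hrs <= observed_hr)) / (len(null_hrs) + 1.0)
    info = {"observed_hr": observed_hr, "n_failed": n_failed,
            "n_used": int(len(null_hrs))}
    return null_hrs, float(empirical_p), info


# ---------------------------------------------------------------------------
# Drug sensitivity
# ---------------------------------------------------------------------------


def drug_correlation(
    scores: pd.Series,
    drug_auc: pd.DataFrame,
    min_pairs: int = 20,
) -> pd.DataFrame:
    """Pearson correlation of the program score with each drug's AUC.

    Pairwise-complete per drug; BH across drugs. Negative r means high-score
    samples have low AUC, i.e. the drug is "sensitizing" for them. Constant
    AUC columns are flagged with r = NaN and excluded from the BH family.
    """
    rows = []
    for drug in drug_auc.columns:
        pair = pd.concat([scores, drug_auc[drug]], axis=1, join="inner").dropna()
        if len(pair) < min_pairs:
            rows.append({"drug": drug, "n": int(len(pair)), "pearson_r": np.nan,
                         "p": np.nan, "flag": "too_few_pairs"})
            continue
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            rows.append({"drug": drug, "n": int(len(pair)), "pearson_r": np.nan,
                         "p": np.nan, "flag": "constant"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"drug": drug, "n": int(len(pair)),
                     "pearson_r": float(r), "p": float(p), "flag": ""})
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["sensitizing"] = out["pearson_r"] < 0
    return out
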