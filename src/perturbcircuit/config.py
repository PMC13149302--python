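"""Parameter dataclasses, seed-stream derivation and logging setup.

Every stage draws randomness from its own :func:`stream_rng` derived from one
master seed, so stages are reproducible independently of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

log = logging.getLogger("perturbcircuit")


class ConfigurationError(ValueError):
    """Raised for invalid parameter combinations or malformed config files."""


def stream_seed(master_seed: int, label: str) -> int:
    """Derive a child seed (< 2**31) from a master seed and a stream label."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stream_rng(master_seed: int, label: str) -> np.random.Generator:
    """A NumPy generator for the named stream of the master seed."""
    return np.random.default_rng(stream_seed(master_seed, label))


def setup_logging(level: int = logging.INFO) -> None:
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level)


# ---------------------------------------------------------------------------
# Stage parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Ground-truth generator settings.

    Defaults emulate the screen layout the pipeline is designed for: 16 target
    genes x 3 sgRNAs plus non-targeting controls, ~182 captured cells per
    guide, 17 planted transcriptional programs, and negative-binomial counts
    with log-scale perturbation effects of magnitude 0.2-0.6.
    """

    n_genes: int = 2000
    n_targets: int = 16
    n_guides_per_target: int = 3
    n_control_guides: int = 3
    n_programs: int = 17
    background_fraction: float = 0.15
    effect_low: float = 0.2
    effect_high: float = 0.6
    min_regulators: int = 2
    max_regulators: int = 3
    control_label: str = "NTC"
    # count model
    baseline_log_mean: float = 0.0
    baseline_log_sigma: float = 1.0
    dispersion_low: float = 0.05
    dispersion_high: float = 0.5
    library_sigma: float = 0.3
    n_mito_genes: int = 10
    mito_fraction: float = 0.08
    mito_cell_sigma: float = 0.5
    # guide capture
    guide_umi_mean: float = 50.0
    guide_umi_dispersion: float = 0.05
    ambient_guide_rate: float = 0.05
    # cell numbers
    cells_per_guide: int = 182
    n_control_cells: int = 500
    doublet_rate: float = 0.3

    def validate(self) -> None:
        if self.n_genes < 200:
            raise ConfigurationError("n_genes must be >= 200")
        if self.n_programs < 2:
            raise ConfigurationError("need at least 2 programs")
        if self.n_programs > self.n_genes / 5:
            raise ConfigurationError("too many programs for this many genes")
        if not 0 <= self.doublet_rate < 0.5:
            raise ConfigurationError("doublet_rate must be in [0, 0.5)")
        if self.cells_per_guide < 20:
            raise ConfigurationError("cells_per_guide must be >= 20")


@dataclass
class QCParams:
    min_genes: int = 200
    min_counts: int = 1000
    max_mito: float = 0.20
    mito_prefix: str = "MT-"


@dataclass
class GuideCallParams:
    min_umi: int = 3
    dominance_ratio: float = 2.0


@dataclass
class DEParams:
    pseudocount: float = 1e-9
    fdr_scope: str = "per_perturbation"  # or "global"
    min_cells: int = 3


@dataclass
class FitParams:
    alpha: float = 0.5
    n_lambdas: int = 40
    lambda_min_ratio: float = 1e-5
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    max_iter: int = 2000
    tol: float = 1e-6
    scale_factor: float = 1e4
    hvg_min_mean: float = 0.0125
    hvg_max_mean: float = 3.0
    hvg_min_dispersion: float = 0.5
    lambda_selection: str = "bic"  # or "min" / "1se"
    standardize: bool = True
    adaptive_gamma: float = 2.0  # 0 disables adaptive L1 weights
    debias: bool = True


@dataclass
class ProgramParams:
    k: int = 5
    metric: str = "cosine"  # or "euclidean"
    resolution: float = 1.0
    min_program_size: int = 10
    corr_merge: float = 0.8  # agglomerate clusters above this profile corr
    signature_fraction: float = 0.25
    score_n_bins: int = 24
    score_n_ctrl: int = 100
    score_method: str = "bin_control"  # or "zmean"
    top_perturbations: int = 3


@dataclass
class InteractionParams:
    fdr_cut: float = 0.05
    psd_repair: bool = True


@dataclass
class ClinicalParams:
    adjust: bool = True
    cut: str = "median"
    n_perm: int = 1000
    perm_adjusted: bool = False


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    output_dir: str = "perturbcircuit_out"
    master_seed: int = 0
    # input paths; when ``simulate`` is set the simulate stage writes them
    counts_mtx: Optional[str] = None
    barcodes: Optional[str] = None
    features: Optional[str] = None
    guides: Optional[str] = None
    ppi: Optional[str] = None
    pathways: Optional[str] = None
    cohort_clinical: Optional[str] = None
    cohort_expression: Optional[str] = None
    drug_auc: Optional[str] = None
    simulate: Optional[SimulationConfig] = None
    qc: QCParams = field(default_factory=QCParams)
    guide_call: GuideCallParams = field(default_factory=GuideCallParams)
    de: DEParams = field(default_factory=DEParams)
    fit: FitParams = field(default_factory=FitParams)
    programs: ProgramParams = field(default_factory=ProgramParams)
    interaction: InteractionParams = field(default_factory=InteractionParams)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d.get("fit"):
            d["fit"]["split"] = list(d["fit"]["split"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        out: dict[str, Any] = {}
        blocks = {
            "simulate": SimulationConfig,
            "qc": QCParams,
            "guide_call": GuideCallParams,
            "de": DEParams,
            "fit": FitParams,
            "programs": ProgramParams,
            "interaction": InteractionParams,
            "clinical": ClinicalParams,
        }
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key, val in d.items():
            if key in blocks and val is not None:
                block_cls = blocks[key]
                names = {f.name for f in dataclasses.fields(block_cls)}
                bad = set(val) - names
                if bad:
                    raise ConfigurationError(
                        f"unknown keys in '{key}': {sorted(bad)}"
                    )
                if key == "fit" and "split" in val:
                    val = {**val, "split": tuple(val["split"])}
                out[key] = block_cls(**val)
            else:
                out[key] = val
        return cls(**out)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
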