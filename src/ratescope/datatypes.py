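"""Core containers for the reporter-trace analysis pipeline.

The forward model follows a two-state (telegraph) switch: each cell carries
``c`` reporter plasmid copies transcribed at a basal per-copy rate ``tau0``
until the switch time ``T``, and at the active rate ``tau1`` afterwards.
mRNA ``M`` and protein ``P`` evolve under a chemical Langevin pair and are
observed through fluorescence ``F = kappa * P + noise``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DataError

#: canonical order of the per-cell latent quantities
PARAM_NAMES = ("c", "tau0", "tau1", "T", "M0", "P0")

_FAMILIES = ("lognormal", "uniform", "point", "fraction")


@dataclass(frozen=True)
class KineticConstants:
    """Fixed kinetic and observation constants shared by all cells.

    Units: rates in 1/min, ``alpha`` in protein/min per mRNA, ``kappa`` in
    AU per protein molecule, ``sigma2`` in AU^2.
    """

    delta_M: float = np.log(2.0) / 180.0   # ~3 h mRNA half-life
    delta_P: float = np.log(2.0) / 1440.0  # stable reporter, ~24 h half-life
    alpha: float = 1.0
    kappa: float = 1e-3
    sigma2: float = 4.0e4                  # measurement noise SD ~200 AU

    def __post_init__(self) -> None:
        for name in ("delta_M", "delta_P", "alpha", "sigma2"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be > 0")


@dataclass(frozen=True)
class CellParams:
    """Latent quantities of one cell (see module docstring for semantics)."""

    c: float
    tau0: float
    tau1: float
    T: float
    M0: float = 0.0
    P0: float = 0.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ConfigurationError("copy number c must be > 0")
        if not (0.0 <= self.tau0 <= self.tau1):
            raise ConfigurationError("rates must satisfy 0 <= tau0 <= tau1")
        if self.T < 0:
            raise ConfigurationError("switch time T must be >= 0")
        if self.M0 < 0 or self.P0 < 0:
            raise ConfigurationError("initial states must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.tau0, self.tau1, self.T, self.M0, self.P0])


@dataclass(frozen=True)
class DistSpec:
    """One population-layer distribution: a family tag plus parameters (a, b).

    Families
    --------
    lognormal : a = log-median, b = log-scale sigma (b = 0 is degenerate)
    uniform   : a = lower, b = upper bound (a == b is degenerate)
    point     : a = the value, b ignored
    fraction  : tau0 only — tau0 = u * tau1 with u ~ Uniform[a, b),
                0 <= a <= b <= 1, so the basal rate never exceeds the
                active one by construction
    """

    family: str
    a: float
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        if self.family == "lognormal" and self.b < 0:
            raise ConfigurationError("lognormal sigma must be >= 0")
        if self.family == "uniform" and self.b < self.a:
            raise ConfigurationError("uniform upper bound below lower bound")
        if self.family == "fraction" and not (0 <= self.a <= self.b <= 1):
            raise ConfigurationError("fraction bounds must satisfy 0<=a<=b<=1")


@dataclass(frozen=True)
class PopulationHyper:
    """Population-layer distributions for the six per-cell quantities.

    ``c`` may be ``None`` on per-construct instances; a study then injects
    the single copy-number distribution shared by every construct.
    """

    tau1: DistSpec
    tau0: DistSpec = DistSpec("fraction", 0.0, 1.0)
    T: DistSpec = DistSpec("uniform", 0.0, 2880.0)
    M0: DistSpec = DistSpec("lognormal", 0.0, 0.5)
    P0: DistSpec = DistSpec("lognormal", np.log(10.0), 0.5)
    c: Optional[DistSpec] = None

    def __post_init__(self) -> None:
        if self.tau0.family == "fraction" and self.tau1.family == "fraction":
            raise ConfigurationError("tau1 cannot be a fraction of itself")

    def with_copy_number(self, c: DistSpec) -> "PopulationHyper":
        return replace(self, c=c)


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a multi-construct imaging study.

    Defaults mirror a 19-construct transient-transfection experiment imaged
    every 30 min for 48 h with 30-35 cells per construct and one
    copy-number distribution shared across all constructs.
    """

    rate_hypers: dict  # construct label -> PopulationHyper (c ignored)
    copy_number: DistSpec = DistSpec("lognormal", np.log(10.0), 1.0)
    cells_per_construct: int = 30
    sampling_interval: float = 30.0
    duration: float = 2880.0
    seed: int = 0
    division_time: Optional[float] = None  # synthetic division marker, off by default

    def __post_init__(self) -> None:
        if not self.rate_hypers:
            raise ConfigurationError("study needs at least one construct")
        if self.cells_per_construct < 15:
            raise ConfigurationError(
                "cells per construct must be >= 15 for robust rate estimates"
            )
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling interval must be > 0")
        n = self.duration / self.sampling_interval
        if abs(n - round(n)) > 1e-9 or self.duration <= 0:
            raise ConfigurationError(
                "duration must be a positive multiple of the sampling interval"
            )

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.duration / self.sampling_interval))
        return np.arange(n + 1) * self.sampling_interval

    def effective_hyper(self, construct: str) -> PopulationHyper:
        return self.rate_hypers[construct].with_copy_number(self.copy_number)


@dataclass
class FluorescenceTrace:
    """One cell's observed fluorescence time course on a uniform grid."""

    cell_id: str
    construct_id: str
    times: np.ndarray
    values: np.ndarray
    divisions: np.ndarray = field(default_factory=lambda: np.empty(0))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.divisions = np.asarray(self.divisions, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise DataError(
                f"trace {self.cell_id}: times and values must be equal-length 1-d"
            )
        if self.times.size == 0:
            raise DataError(f"trace {self.cell_id}: empty trace")
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.times)):
            raise DataError(f"trace {self.cell_id}: non-finite entries")
        if self.times.size > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise DataError(f"trace {self.cell_id}: times must strictly increase")
            if np.ptp(steps) > 1e-6 * steps[0]:
                raise DataError(f"trace {self.cell_id}: non-uniform time grid")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def interval(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass
class QCReport:
    """Disposition record for every trace passing through preprocessing."""

    seed: Optional[int] = None
    records: list = field(default_factory=list)  # (cell_id, stage, kept, reason)
    counts: dict = field(default_factory=dict)   # stage -> (before, after)
    warnings: list = field(default_factory=list)

    def record(self, cell_id: str, stage: str, kept: bool, reason: str = "") -> None:
        self.records.append((cell_id, stage, kept, reason))

    def count(self, stage: str, before: int, after: int) -> None:
        self.counts[stage] = (before, after)

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "counts": {k: list(v) for k, v in self.counts.items()},
                "records": [list(r) for r in self.records],
                "warnings": self.warnings,
            },
            indent=2,
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Budget and proposal tuning for the hierarchical sampler.

    Proposal step sizes are log-scale random-walk SDs except ``T`` (minutes,
    reflected at the window edges) and ``swap`` (log-scale SD of the
    likelihood-invariant c/tau exchange move).
    """

    iterations: int = 50_000
    burn_in: int = 20_000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0
    steps: dict = field(
        default_factory=lambda: {
            "c": 0.15, "tau0": 0.35, "tau1": 0.15,
            "T": 45.0, "M0": 0.6, "P0": 0.6,
            "swap": 0.25, "sigma2": 0.2,
        }
    )
    update: tuple = PARAM_NAMES
    sample_sigma2: bool = True
    sample_hypers: bool = True
    nsub: int = 4  # filter substeps per observation interval

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ConfigurationError("burn-in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1 or self.n_chains < 1 or self.nsub < 1:
            raise ConfigurationError("thin, n_chains and nsub must be >= 1")
        for name, s in self.steps.items():
            if s <= 0:
                raise ConfigurationError(f"step size for {name!r} must be > 0")
        unknown = set(self.update) - set(PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown update parameters: {sorted(unknown)}")


@dataclass
class PosteriorChains:
    """Retained MCMC samples for every cell and the population layer.

    ``cell_params`` has shape (n_chains, n_kept, n_cells, 6) on the natural
    scale, ordered as :data:`PARAM_NAMES`.  ``hypers`` has shape
    (n_chains, n_kept, n_hyper) with names in ``hyper_names``
    (sigma2, s_c, then per construct mu_tau1, s_tau1, mu_tau0, s_tau0).
    """

    cell_params: np.ndarray
    hypers: np.ndarray
    log_post: np.ndarray
    cell_ids: list
    constructs: list            # construct label per cell
    construct_labels: list      # unique labels, hyper block order
    hyper_names: list
    accept_rates: np.ndarray
    config: MCMCConfig

    def __post_init__(self) -> None:
        nc, nk, ncell, npar = self.cell_params.shape
        if npar != len(PARAM_NAMES) or ncell != len(self.cell_ids):
            raise DataError("cell_params shape inconsistent with cell ids")
        if self.hypers.shape[:2] != (nc, nk):
            raise DataError("hyper chain length differs from cell chain length")

    @property
    def n_cells(self) -> int:
        return self.cell_params.shape[2]

    def samples(self, param: str, cell: Optional[int] = None) -> np.ndarray:
        """Pooled post-burn-in samples of one parameter (all chains merged)."""
        j = PARAM_NAMES.index(param)
        if cell is None:
            return self.cell_params[:, :, :, j].reshape(-1, self.n_cells)
        return self.cell_params[:, :, cell, j].ravel()

    def hyper_samples(self, name: str) -> np.ndarray:
        return self.hypers[:, :, self.hyper_names.index(name)].ravel()
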