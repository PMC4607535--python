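"""Delimited-text formats, configuration files, and chain persistence.

Trace tables are tab-separated with columns
``cell_id  construct_id  time_min  fluorescence_au  division_flag``;
ground truth is a companion table keyed by cell_id; study/pipeline
configuration is YAML with a documented schema; chains persist as a
directory of TSV tables plus a JSON metadata file.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    DistSpec,
    FluorescenceTrace,
    KineticConstants,
    MCMCConfig,
    PopulationHyper,
    PosteriorChains,
    StudyDesign,
)
from .errors import ConfigurationError, DataError, ParseError

TRACE_COLUMNS = ["cell_id", "construct_id", "time_min",
                 "fluorescence_au", "division_flag"]


def write_traces(traces: list[FluorescenceTrace], path) -> None:
    rows = []
    for tr in traces:
        div = set(np.asarray(tr.divisions).tolist())
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.cell_id, tr.construct_id, t, v,
                         1 if t in div else 0))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_traces(path) -> list[FluorescenceTrace]:
    """Parse a trace table; schema violations name the offending row."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"trace file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trace file")
        return []
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty trace file")
        return []
    for col in ("time_min", "fluorescence_au", "division_flag"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy())[0]
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric {col} at data row {bad[0] + 1}")
        df[col] = coerced
    traces = []
    for (cell, construct), grp in df.groupby(
            ["cell_id", "construct_id"], sort=False):
        times = grp["time_min"].to_numpy(dtype=float)
        try:
            tr = FluorescenceTrace(
                cell_id=str(cell), construct_id=str(construct),
                times=times,
                values=grp["fluorescence_au"].to_numpy(dtype=float),
                divisions=times[grp["division_flag"].to_numpy() > 0],
            )
        except DataError as exc:
            first_row = int(grp.index[0]) + 1
            raise ParseError(f"{path} (rows from {first_row}): {exc}") from exc
        traces.append(tr)
    return traces


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", float_format="%.17g")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_id",
                       float_precision="round_trip")


def write_chains(chains: PosteriorChains, directory) -> None:
    """Persist chains as cells.tsv + hypers.tsv + meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nc, nk, ncell, _ = chains.cell_params.shape
    recs = []
    for ch in range(nc):
        for d in range(nk):
            for i in range(ncell):
                recs.append((ch, d, chains.cell_ids[i], chains.constructs[i],
                             *chains.cell_params[ch, d, i]))
    pd.DataFrame(
        recs, columns=["chain", "draw", "cell_id", "construct_id",
                       "c", "tau0", "tau1", "T", "M0", "P0"],
    ).to_csv(directory / "cells.tsv", sep="\t", index=False,
             float_format="%.17g")
    hyp = []
    for ch in range(nc):
        for d in range(nk):
            hyp.append((ch, d, chains.log_post[ch, d], *chains.hypers[ch, d]))
    pd.DataFrame(
        hyp, columns=["chain", "draw", "log_post", *chains.hyper_names],
    ).to_csv(directory / "hypers.tsv", sep="\t", index=False,
             float_format="%.17g")
    meta = {
        "cell_ids": chains.cell_ids,
        "constructs": chains.constructs,
        "construct_labels": chains.construct_labels,
        "hyper_names": chains.hyper_names,
        "accept_rates": chains.accept_rates.tolist(),
        "config": {**asdict(chains.config), "update": list(chains.config.update)},
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def read_chains(directory) -> PosteriorChains:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    cells = pd.read_csv(directory / "cells.tsv", sep="\t",
                        float_precision="round_trip")
    hypers = pd.read_csv(directory / "hypers.tsv", sep="\t",
                         float_precision="round_trip")
    cell_ids = meta["cell_ids"]
    nc = int(cells["chain"].max()) + 1
    nk = int(cells["draw"].max()) + 1
    ncell = len(cell_ids)
    cp = np.empty((nc, nk, ncell, 6))
    order = {cid: i for i, cid in enumerate(cell_ids)}
    idx = cells["cell_id"].map(order).to_numpy()
    cp[cells["chain"], cells["draw"], idx] = cells[
        ["c", "tau0", "tau1", "T", "M0", "P0"]].to_numpy()
    hnames = meta["hyper_names"]
    hy = np.empty((nc, nk, len(hnames)))
    lp = np.empty((nc, nk))
    hy[hypers["chain"], hypers["draw"]] = hypers[hnames].to_numpy()
    lp[hypers["chain"], hypers["draw"]] = hypers["log_post"].to_numpy()
    cfg_d = meta["config"]
    cfg_d["update"] = tuple(cfg_d["update"])
    cfg = MCMCConfig(**cfg_d)
    return PosteriorChains(
        cell_params=cp, hypers=hy, log_post=lp,
        cell_ids=cell_ids, constructs=meta["constructs"],
        construct_labels=meta["construct_labels"], hyper_names=hnames,
        accept_rates=np.array(meta["accept_rates"]), config=cfg,
    )


# ---------------------------------------------------------------------------
# configuration

_TOP_KEYS = {"seed", "kinetics", "design", "preprocessing", "mcmc", "analysis"}
_PRE_DEFAULTS = {"threshold": 8000.0, "min_points": 10,
                 "subsample_low": 30, "subsample_high": 35}
_ANALYSIS_DEFAULTS = {"rate": "tau1"}


@dataclass
class PipelineConfig:
    """Validated configuration for the four-stage pipeline."""

    seed: int = 0
    kinetics: KineticConstants = field(default_factory=KineticConstants)
    design: Optional[StudyDesign] = None
    preprocessing: dict = field(default_factory=lambda: dict(_PRE_DEFAULTS))
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))

    def config_hash(self) -> str:
        blob = json.dumps({
            "seed": self.seed,
            "kinetics": asdict(self.kinetics),
            "design": None if self.design is None else {
                **{k: v for k, v in asdict(self.design).items()
                   if k != "rate_hypers"},
                "rate_hypers": {c: asdict(h)
                                for c, h in self.design.rate_hypers.items()},
            },
            "preprocessing": self.preprocessing,
            "mcmc": {**asdict(self.mcmc), "update": list(self.mcmc.update)},
            "analysis": self.analysis,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _dist_from_list(v, where: str, errors: list) -> Optional[DistSpec]:
    try:
        fam, *params = v
        return DistSpec(str(fam), *[float(p) for p in params])
    except (ConfigurationError, TypeError, ValueError) as exc:
        errors.append(f"{where}: {exc}")
        return None


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config, filling defaults.

    Unknown keys are rejected; all invariant violations are reported in a
    single error.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level key(s): {sorted(unknown)}")

    kin_raw = raw.get("kinetics", {}) or {}
    kin_fields = set(KineticConstants.__dataclass_fields__)
    bad = set(kin_raw) - kin_fields
    if bad:
        errors.append(f"kinetics: unknown key(s) {sorted(bad)}")
    kinetics = KineticConstants()
    try:
        kinetics = KineticConstants(**{k: float(v) for k, v in kin_raw.items()
                                       if k in kin_fields})
    except ConfigurationError as exc:
        errors.append(f"kinetics: {exc}")

    mcmc_raw = raw.get("mcmc", {}) or {}
    mcmc_fields = set(MCMCConfig.__dataclass_fields__)
    bad = set(mcmc_raw) - mcmc_fields
    if bad:
        errors.append(f"mcmc: unknown key(s) {sorted(bad)}")
    mcmc = MCMCConfig()
    try:
        kw = {k: v for k, v in mcmc_raw.items() if k in mcmc_fields}
        if "update" in kw:
            kw["update"] = tuple(kw["update"])
        mcmc = MCMCConfig(**kw)
    except (ConfigurationError, TypeError) as exc:
        errors.append(f"mcmc: {exc}")

    pre = dict(_PRE_DEFAULTS)
    pre_raw = raw.get("preprocessing", {}) or {}
    bad = set(pre_raw) - set(_PRE_DEFAULTS)
    if bad:
        errors.append(f"preprocessing: unknown key(s) {sorted(bad)}")
    pre.update({k: v for k, v in pre_raw.items() if k in _PRE_DEFAULTS})
    if pre["threshold"] < 0:
        errors.append("preprocessing: threshold must be >= 0")

    ana = dict(_ANALYSIS_DEFAULTS)
    ana_raw = raw.get("analysis", {}) or {}
    bad = set(ana_raw) - set(_ANALYSIS_DEFAULTS)
    if bad:
        errors.append(f"analysis: unknown key(s) {sorted(bad)}")
    ana.update({k: v for k, v in ana_raw.items() if k in _ANALYSIS_DEFAULTS})

    design = None
    if "design" in raw and raw["design"]:
        d = raw["design"]
        d_keys = {"constructs", "copy_number", "cells_per_construct",
                  "sampling_interval", "duration", "division_time"}
        bad = set(d) - d_keys
        if bad:
            errors.append(f"design: unknown key(s) {sorted(bad)}")
        hypers = {}
        for cname, spec in (d.get("constructs") or {}).items():
            kw = {}
            for q in ("tau1", "tau0", "T", "M0", "P0"):
                if q in spec:
                    ds = _dist_from_list(spec[q], f"design.{cname}.{q}", errors)
                    if ds is not None:
                        kw[q] = ds
            extra = set(spec) - {"tau1", "tau0", "T", "M0", "P0"}
            if extra:
                errors.append(f"design.{cname}: unknown key(s) {sorted(extra)}")
            if "tau1" not in kw:
                errors.append(f"design.{cname}: tau1 distribution required")
                continue
            hypers[str(cname)] = PopulationHyper(**kw)
        copy_number = StudyDesign.__dataclass_fields__["copy_number"].default
        if "copy_number" in d:
            ds = _dist_from_list(d["copy_number"], "design.copy_number", errors)
            if ds is not None:
                copy_number = ds
        if hypers and not errors:
            try:
                design = StudyDesign(
                    rate_hypers=hypers, copy_number=copy_number,
                    cells_per_construct=int(d.get("cells_per_construct", 30)),
                    sampling_interval=float(d.get("sampling_interval", 30.0)),
                    duration=float(d.get("duration", 2880.0)),
                    seed=int(raw.get("seed", 0)),
                    division_time=d.get("division_time"),
                )
            except ConfigurationError as exc:
                errors.append(f"design: {exc}")

    if errors:
        raise ConfigurationError(
            "invalid configuration:\n  " + "\n  ".join(errors))
    return PipelineConfig(seed=int(raw.get("seed", 0)), kinetics=kinetics,
                          design=design, preprocessing=pre, mcmc=mcmc,
                          analysis=ana)
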