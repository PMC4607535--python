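"""Forward model and study-scale fixture generation.

Simulates latent mRNA/protein dynamics of transiently transfected reporter
constructs under a two-state transcription switch and renders noisy
fluorescence traces for multi-construct studies.  The stochastic integrator
uses the exact closed-form flow of the linear drift over each substep and
adds a chemical-Langevin noise kick sqrt(Q(x) h) dW, reflecting at zero, so
the noise-free limit reproduces the deterministic ODE to machine precision.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from ._kernels import propagators
from .datatypes import (
    CellParams,
    DistSpec,
    FluorescenceTrace,
    KineticConstants,
    PopulationHyper,
    StudyDesign,
)
from .errors import ConfigurationError, IntegrationError


class ODEPath(NamedTuple):
    """Noise-free mean trajectory of one cell."""

    times: np.ndarray
    M: np.ndarray
    P: np.ndarray
    F: np.ndarray


def _draw(spec: DistSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.family == "lognormal":
        return np.exp(spec.a + spec.b * rng.standard_normal(n))
    if spec.family == "uniform":
        if spec.b == spec.a:
            return np.full(n, spec.a)
        return rng.uniform(spec.a, spec.b, n)
    if spec.family == "point":
        return np.full(n, spec.a)
    raise ConfigurationError(f"family {spec.family!r} cannot be drawn directly")


def sample_cell_params(
    hyper: PopulationHyper, n: int, rng: np.random.Generator
) -> list[CellParams]:
    """Draw ``n`` independent cells from the population layer.

    The basal/active ordering tau0 <= tau1 is enforced by construction when
    tau0 uses the ``fraction`` family (tau0 = u * tau1), and by rejection
    otherwise.
    """
    if n < 1:
        raise ConfigurationError("need n >= 1 cells")
    if hyper.c is None:
        raise ConfigurationError("hyper has no copy-number entry")
    c = _draw(hyper.c, n, rng)
    tau1 = _draw(hyper.tau1, n, rng)
    if hyper.tau0.family == "fraction":
        if hyper.tau0.b == hyper.tau0.a:
            u = np.full(n, hyper.tau0.a)
        else:
            u = rng.uniform(hyper.tau0.a, hyper.tau0.b, n)
        tau0 = u * tau1
    else:
        tau0 = _draw(hyper.tau0, n, rng)
        for _ in range(1000):
            bad = tau0 > tau1
            if not bad.any():
                break
            tau0[bad] = _draw(hyper.tau0, int(bad.sum()), rng)
        else:
            raise ConfigurationError(
                "could not satisfy tau0 <= tau1 by rejection; "
                "check the rate hyper distributions"
            )
    T = _draw(hyper.T, n, rng)
    M0 = _draw(hyper.M0, n, rng)
    P0 = _draw(hyper.P0, n, rng)
    return [
        CellParams(c=c[i], tau0=tau0[i], tau1=tau1[i], T=T[i], M0=M0[i], P0=P0[i])
        for i in range(n)
    ]


def _em1_np(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x elementwise, stable near zero."""
    small = np.abs(x) < 1e-5
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x / 2.0 + x * x / 6.0, -np.expm1(-safe) / safe)


def _props_np(h: np.ndarray, dM_: float, dP_: float, alpha: float):
    """Vectorized closed-form drift flow over heterogeneous step lengths."""
    a = np.exp(-dM_ * h)
    c = np.exp(-dP_ * h)
    d = dP_ - dM_
    b = alpha * h * a * _em1_np(d * h)
    iM = h * _em1_np(dM_ * h)
    if abs(d) < 1e-12:
        db = 0.5 * (dM_ + dP_)
        x = db * h
        small = np.abs(x) < 1e-4
        safe = np.where(small, 1.0, x)
        g = np.where(small, 0.5 - x / 3.0 + x * x / 8.0,
                     (1.0 - (1.0 + safe) * np.exp(-safe)) / (safe * safe))
        J = h * h * g
    else:
        J = h * (_em1_np(dM_ * h) - _em1_np(dP_ * h)) / d
    return a, b, c, iM, alpha * J


def _simulate_vectorized(
    c, tau0, tau1, T, M0, P0,
    k: KineticConstants,
    grid: np.ndarray,
    rng: Optional[np.random.Generator],
    dt: float,
    stochastic: bool,
):
    """Integrate n paths jointly; parameter arguments are length-n arrays.

    Returns M, P of shape (n, len(grid)).  The drift is propagated with its
    exact closed-form flow per substep (splitting exactly at each path's
    switch time), so the noise-free limit reproduces the ODE solution.
    """
    grid = np.asarray(grid, dtype=float)
    c = np.asarray(c, dtype=float)
    tau0 = np.asarray(tau0, dtype=float)
    tau1 = np.asarray(tau1, dtype=float)
    T = np.asarray(T, dtype=float)
    n = c.size
    L = grid.size
    M = np.empty((n, L))
    P = np.empty((n, L))
    M[:, 0] = M0
    P[:, 0] = P0
    if L == 1:
        return M, P
    steps_ = np.diff(grid)
    if np.any(steps_ <= 0) or np.ptp(steps_) > 1e-9 * steps_[0]:
        raise ConfigurationError("simulation grid must be uniform increasing")
    interval = float(grid[1] - grid[0])
    nsub = max(1, int(np.ceil(interval / dt)))
    h = interval / nsub
    a, b, cc, iM, iP = propagators(h, k.delta_M, k.delta_P, k.alpha)
    u_pre = c * tau0
    u_post = c * tau1
    x = np.array(M0, dtype=float, copy=True)
    y = np.array(P0, dtype=float, copy=True)
    for j in range(1, L):
        for s in range(nsub):
            t = grid[j - 1] + s * h
            tn = grid[j - 1] + (s + 1) * h if s + 1 < nsub else grid[j]
            u = np.where(t < T, u_pre, u_post)
            if stochastic:
                qM = u + k.delta_M * x
                qP = k.alpha * x + k.delta_P * y
            x_new = a * x + u * iM
            y_new = b * x + cc * y + u * iP
            cross = (T > t) & (T < tn)
            if cross.any():
                h1 = T[cross] - t
                h2 = tn - T[cross]
                a1, b1, c1, iM1, iP1 = _props_np(h1, k.delta_M, k.delta_P, k.alpha)
                x1 = a1 * x[cross] + u_pre[cross] * iM1
                y1 = b1 * x[cross] + c1 * y[cross] + u_pre[cross] * iP1
                a2, b2, c2, iM2, iP2 = _props_np(h2, k.delta_M, k.delta_P, k.alpha)
                x_new[cross] = a2 * x1 + u_post[cross] * iM2
                y_new[cross] = b2 * x1 + c2 * y1 + u_post[cross] * iP2
            if stochastic:
                x_new = np.abs(x_new + np.sqrt(qM * h) * rng.standard_normal(n))
                y_new = np.abs(y_new + np.sqrt(qP * h) * rng.standard_normal(n))
            x, y = x_new, y_new
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise IntegrationError(f"non-finite state at t = {grid[j]:.3f} min")
        M[:, j] = x
        P[:, j] = y
    return M, P


def simulate_ensemble(
    params: CellParams,
    k: KineticConstants,
    grid: np.ndarray,
    rng: Optional[np.random.Generator],
    n_rep: int,
    dt: float = 0.1,
    stochastic: bool = True,
):
    """n_rep independent stochastic replicates of one cell's latent paths."""
    rep = lambda v: np.full(n_rep, v)  # noqa: E731
    return _simulate_vectorized(
        rep(params.c), rep(params.tau0), rep(params.tau1), rep(params.T),
        rep(params.M0), rep(params.P0), k, grid, rng, dt, stochastic)


def simulate_latent_paths(
    params: CellParams,
    k: KineticConstants,
    grid: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    dt: float = 0.1,
    stochastic: bool = True,
):
    """One pair of latent (M, P) paths sampled on ``grid``.

    With ``stochastic=False`` (or zero diffusion) this is exact for the
    drift ODE at the grid points, up to switch placement on the substep grid.
    """
    if stochastic and rng is None:
        raise ConfigurationError("stochastic simulation needs an rng")
    M, P = simulate_ensemble(params, k, grid, rng, 1, dt=dt, stochastic=stochastic)
    return M[0], P[0]


def render_trace(
    protein_path: np.ndarray,
    k: KineticConstants,
    rng: np.random.Generator,
    times: np.ndarray,
    cell_id: str = "cell",
    construct_id: str = "construct",
    kappa: Optional[float] = None,
    divisions: Optional[np.ndarray] = None,
) -> FluorescenceTrace:
    """Observe a protein path: F_i = kappa * P(t_i) + N(0, sigma^2)."""
    if k.sigma2 < 0:
        raise ConfigurationError("sigma2 must be >= 0")
    kap = k.kappa if kappa is None else kappa
    if kap < 0:
        raise ConfigurationError("kappa must be >= 0")
    protein_path = np.asarray(protein_path, dtype=float)
    noise = rng.normal(0.0, np.sqrt(k.sigma2), protein_path.size)
    meta = {}
    if kap == 0.0:
        meta["degenerate_zero_gain"] = True
    return FluorescenceTrace(
        cell_id=cell_id,
        construct_id=construct_id,
        times=np.asarray(times, dtype=float),
        values=kap * protein_path + noise,
        divisions=np.empty(0) if divisions is None else np.asarray(divisions),
        metadata=meta,
    )


def simulate_study(
    design: StudyDesign,
    rng: Optional[np.random.Generator] = None,
    k: Optional[KineticConstants] = None,
    dt: float = 0.1,
):
    """Generate a full multi-construct study with ground truth.

    Every construct draws its rates from its own hyper but all constructs
    share the single copy-number distribution of the design.  Returns
    ``(traces, truth)`` where ``truth`` is a DataFrame keyed by cell_id with
    the true CellParams fields.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if k is None:
        k = KineticConstants()
    grid = design.grid
    traces: list[FluorescenceTrace] = []
    truth_rows = []
    for construct in design.rate_hypers:
        hyper = design.effective_hyper(construct)
        cells = sample_cell_params(hyper, design.cells_per_construct, rng)
        arr = np.array([p.as_array() for p in cells])
        _, P = _simulate_vectorized(
            arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4], arr[:, 5],
            k, grid, rng, dt, stochastic=True)
        for i, p in enumerate(cells):
            cell_id = f"{construct}_{i:03d}"
            path = P[i]
            divisions = None
            if design.division_time is not None:
                divisions = np.array([design.division_time])
                halve = grid >= design.division_time
                path = np.where(halve, 0.5 * path, path)
            tr = render_trace(path, k, rng, grid, cell_id=cell_id,
                              construct_id=construct, divisions=divisions)
            traces.append(tr)
            truth_rows.append({
                "cell_id": cell_id, "construct_id": construct,
                "c": p.c, "tau0": p.tau0, "tau1": p.tau1, "T": p.T,
                "M0": p.M0, "P0": p.P0,
            })
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    return traces, truth


def ode_trajectory(
    params: CellParams, k: KineticConstants, grid: np.ndarray
) -> ODEPath:
    """Noise-free solution of the drift ODE pair, exact at the grid times.

    Uses the closed-form flow of the piecewise-constant-input linear system,
    splitting exactly at the switch time T.  Serves as the oracle for the
    stochastic integrator and as the mean-path reference of the model.
    """
    grid = np.asarray(grid, dtype=float)
    M = np.empty(grid.size)
    P = np.empty(grid.size)
    mM, mP = params.M0, params.P0
    tprev = float(grid[0])
    for j, t in enumerate(grid):
        while t > tprev + 1e-12:
            if tprev < params.T < t:
                seg_end, u = params.T, params.c * params.tau0
            elif t <= params.T:
                seg_end, u = t, params.c * params.tau0
            else:
                seg_end, u = t, params.c * params.tau1
            a, b, cc, iM, iP = propagators(
                seg_end - tprev, k.delta_M, k.delta_P, k.alpha)
            mM, mP = a * mM + u * iM, b * mM + cc * mP + u * iP
            tprev = seg_end
        if not (np.isfinite(mM) and np.isfinite(mP)):
            raise IntegrationError(f"non-finite state at t = {t:.3f} min")
        M[j], P[j] = mM, mP
    return ODEPath(times=grid, M=M, P=P, F=k.kappa * P)


def default_study_design(
    n_constructs: int = 19,
    cells_per_construct: int = 30,
    seed: int = 0,
) -> StudyDesign:
    """The study-scale default: n constructs spanning a range of active
    rates, 30 cells each, 48 h imaged every 30 min, one shared copy-number
    distribution (log-normal, median 10)."""
    log_means = np.linspace(np.log(2.0), np.log(15.0), n_constructs)
    hypers = {
        f"construct_{j:02d}": PopulationHyper(
            tau1=DistSpec("lognormal", float(log_means[j]), 0.3),
            tau0=DistSpec("fraction", 0.0, 0.3),
            T=DistSpec("uniform", 0.0, 2880.0),
        )
        for j in range(n_constructs)
    }
    return StudyDesign(rate_hypers=hypers, cells_per_construct=cells_per_construct,
                       seed=seed)
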