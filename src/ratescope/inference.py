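"""Two-layer estimation: Gaussian-filter likelihood and hierarchical MCMC.

The single-cell likelihood is a continuous-discrete Gaussian filter: between
observations the latent (mRNA, protein) mean follows the exact flow of the
linear drift while the covariance accumulates the chemical-Langevin
diffusion evaluated along the predicted mean; each fluorescence sample
triggers a Kalman update.  Because copy number and per-copy rate enter the
model only through their product c*tau, the likelihood is exactly invariant
under (c, tau) -> (g*c, tau/g); the hierarchical population layer resolves
the ridge, with the copy-number population log-median anchored at zero
(median c = 1) and one copy-number distribution shared by every construct
so per-copy rates are comparable across constructs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import _kernels
from .datatypes import (
    PARAM_NAMES,
    CellParams,
    DistSpec,
    FluorescenceTrace,
    KineticConstants,
    MCMCConfig,
    PosteriorChains,
)
from .errors import ConfigurationError, DataError, RatescopeError

# fixed broad log-normal priors for the initial states (log-scale mean, sd)
_M0_PRIOR = (0.0, 1.5)
_P0_PRIOR = (np.log(10.0), 1.5)
# inverse-gamma priors for population log-variances: the copy-number layer
# is kept loose (transient transfection spreads copies over orders of
# magnitude) while per-construct rate layers favour tight distributions, so
# the c*tau ridge resolves toward cell-to-cell copy-number variation the way
# the biology dictates; normal prior for the rate log-means
_A0_C, _B0_C = 2.0, 1.0
_A0_R, _B0_R = 2.0, 0.1
_HYPER_M0, _HYPER_V0 = 0.0, 10.0


def trace_loglik(
    trace: FluorescenceTrace,
    params: CellParams,
    k: KineticConstants,
    nsub: int = 4,
) -> float:
    """Log-density of one trace under the state-space model.

    Returns -inf when sigma^2 = 0 leaves a degenerate observation law and
    the data fall off the deterministic path.
    """
    if trace.n_points == 0:
        raise DataError("empty trace")
    return float(
        _kernels.filter_loglik(
            trace.times, trace.values, trace.n_points,
            params.c, params.tau0, params.tau1, params.T, params.M0, params.P0,
            k.delta_M, k.delta_P, k.alpha, k.kappa, k.sigma2, nsub,
        )
    )


def _moment_init(trace: FluorescenceTrace, k: KineticConstants) -> np.ndarray:
    """Method-of-moments start: (log c, log tau0, log tau1, T, log M0, log P0).

    The late-time fluorescence slope estimates the product c*tau1 through
    dP/dt ~ alpha*M - dP_*P with M near its quasi-steady value c*tau1/dM_;
    the start anchors c at the population median 1.
    """
    t, f = trace.times, trace.values
    n = t.size
    lo = max(0, n - max(3, n // 3))
    if n >= 2 and t[-1] > t[lo]:
        slope = (f[-1] - f[lo]) / (t[-1] - t[lo]) / k.kappa
    else:
        slope = 1.0
    pbar = max(float(np.mean(f[lo:])) / k.kappa, 0.0)
    ctau1 = k.delta_M * max(slope + k.delta_P * pbar, 1e-3) / k.alpha
    f0 = f - f[0]
    fmax = max(float(f0.max()), 1e-9)
    above = np.nonzero(f0 > 0.2 * fmax)[0]
    T = float(t[above[0]]) if above.size else float(t[n // 2])
    T = min(max(T, 0.0), float(t[-1]))
    p0 = max(f[0] / k.kappa, 1e-2)
    return np.array([
        0.0, np.log(ctau1) + np.log(0.1), np.log(ctau1), T, 0.0, np.log(p0),
    ])


def _pack(traces: Sequence[FluorescenceTrace]):
    n = len(traces)
    lmax = max(tr.n_points for tr in traces)
    obs_t = np.zeros((n, lmax))
    obs_f = np.zeros((n, lmax))
    n_obs = np.zeros(n, dtype=np.int64)
    tmax = np.zeros(n)
    for i, tr in enumerate(traces):
        obs_t[i, : tr.n_points] = tr.times
        obs_f[i, : tr.n_points] = tr.values
        n_obs[i] = tr.n_points
        tmax[i] = tr.times[-1]
    return obs_t, obs_f, n_obs, tmax


def run_hierarchical_mcmc(
    traces: Sequence[FluorescenceTrace],
    k: KineticConstants,
    config: MCMCConfig,
    init_params: Optional[Sequence[CellParams]] = None,
    init_hypers: Optional[dict] = None,
    swap_move: bool = True,
) -> PosteriorChains:
    """Fit all cells of all constructs jointly.

    Per sweep: log-scale random-walk Metropolis updates of (c, tau0, tau1,
    M0, P0) and a reflected window proposal for T per cell, a
    likelihood-invariant c/tau scale exchange, a global Metropolis update of
    sigma^2, and Gibbs updates of the population layer (copy-number scale
    shared across constructs; per-construct log-normal rate distributions).

    ``init_params`` starts every chain at the given cell values (jittered
    per chain); ``init_hypers`` with ``config.sample_hypers=False`` pins the
    population layer, e.g. ``{"s_c": 0.5, "constructA": (mu1, s1, mu0, s0)}``.
    """
    if not traces:
        raise DataError("no traces to fit")
    labels: list[str] = []
    for tr in traces:
        if tr.construct_id not in labels:
            labels.append(tr.construct_id)
    cons = np.array([labels.index(tr.construct_id) for tr in traces],
                    dtype=np.int64)
    n_cons = len(labels)
    ncell = len(traces)
    obs_t, obs_f, n_obs, tmax = _pack(traces)

    if init_params is not None:
        if len(init_params) != ncell:
            raise ConfigurationError("init_params length != number of traces")
        base = np.array([
            [np.log(p.c), np.log(max(p.tau0, 1e-12)), np.log(p.tau1),
             p.T, np.log(max(p.M0, 1e-6)), np.log(max(p.P0, 1e-6))]
            for p in init_params
        ])
    else:
        base = np.array([_moment_init(tr, k) for tr in traces])

    s_c0 = 0.5
    mu1_0 = np.zeros(n_cons)
    s1_0 = np.full(n_cons, 0.5)
    mu0_0 = np.zeros(n_cons)
    s0_0 = np.full(n_cons, 0.7)
    for j in range(n_cons):
        mu1_0[j] = float(np.mean(base[cons == j, 2]))
        mu0_0[j] = float(np.mean(base[cons == j, 1]))
    if init_hypers is not None:
        s_c0 = float(init_hypers.get("s_c", s_c0))
        for j, lab in enumerate(labels):
            if lab in init_hypers:
                mu1_0[j], s1_0[j], mu0_0[j], s0_0[j] = init_hypers[lab]

    steps = np.array([
        config.steps.get("c", 0.15), config.steps.get("tau0", 0.35),
        config.steps.get("tau1", 0.15), config.steps.get("T", 45.0),
        config.steps.get("M0", 0.6), config.steps.get("P0", 0.6),
        config.steps.get("swap", 0.25), config.steps.get("sigma2", 0.2),
    ])
    mask = np.array([name in config.update for name in PARAM_NAMES])

    n_keep = (config.iterations - config.burn_in + config.thin - 1) // config.thin
    cells_out = np.empty((config.n_chains, n_keep, ncell, 6))
    hyper_out = np.empty((config.n_chains, n_keep, 2 + 4 * n_cons))
    lp_out = np.empty((config.n_chains, n_keep))
    acc_out = np.empty((config.n_chains, 8))

    master = np.random.default_rng(config.seed)
    for chain in range(config.n_chains):
        theta0 = base.copy()
        if chain > 0 or init_params is None:
            jit = master.normal(0.0, 0.1 if chain > 0 else 0.0, size=(ncell, 6))
            theta0[:, [0, 1, 2, 4, 5]] += jit[:, [0, 1, 2, 4, 5]]
            theta0[:, 3] = np.clip(
                theta0[:, 3] + (30.0 * jit[:, 3] if chain > 0 else 0.0),
                0.0, tmax)
        # tau0 <= tau1 must hold at the start
        theta0[:, 1] = np.minimum(theta0[:, 1], theta0[:, 2])
        seed_c = int((config.seed * 1000003 + 7919 * chain + 1) % (2**31 - 1))
        lik0 = np.array([
            _kernels.filter_loglik(
                obs_t[i], obs_f[i], n_obs[i],
                np.exp(theta0[i, 0]), np.exp(theta0[i, 1]), np.exp(theta0[i, 2]),
                theta0[i, 3], np.exp(theta0[i, 4]), np.exp(theta0[i, 5]),
                k.delta_M, k.delta_P, k.alpha, k.kappa, k.sigma2, config.nsub)
            for i in range(ncell)
        ])
        if not np.all(np.isfinite(lik0)):
            bad = [traces[i].cell_id for i in np.nonzero(~np.isfinite(lik0))[0]]
            raise RatescopeError(
                f"non-finite log-posterior at initialization for cells {bad}; "
                "check kinetic constants and starting values")
        kc, kh, klp, acc, prop = _kernels.run_chain(
            obs_t, obs_f, n_obs, tmax, cons, n_cons,
            k.delta_M, k.delta_P, k.alpha, k.kappa, k.sigma2,
            theta0, s_c0, mu1_0, s1_0, mu0_0, s0_0,
            _M0_PRIOR[0], _M0_PRIOR[1], _P0_PRIOR[0], _P0_PRIOR[1],
            _A0_C, _B0_C, _A0_R, _B0_R, _HYPER_M0, _HYPER_V0,
            steps, mask, swap_move, config.sample_sigma2, config.sample_hypers,
            config.iterations, config.burn_in, config.thin, config.nsub, seed_c)
        cells_out[chain] = kc
        hyper_out[chain] = kh
        lp_out[chain] = klp
        with np.errstate(invalid="ignore"):
            acc_out[chain] = np.where(prop > 0, acc / np.maximum(prop, 1), np.nan)

    hyper_names = ["sigma2", "s_c"]
    for lab in labels:
        hyper_names += [f"mu_tau1[{lab}]", f"s_tau1[{lab}]",
                        f"mu_tau0[{lab}]", f"s_tau0[{lab}]"]
    return PosteriorChains(
        cell_params=cells_out,
        hypers=hyper_out,
        log_post=lp_out,
        cell_ids=[tr.cell_id for tr in traces],
        constructs=[tr.construct_id for tr in traces],
        construct_labels=labels,
        hyper_names=hyper_names,
        accept_rates=acc_out,
        config=config,
    )


def _prior_logpdf(spec: DistSpec, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if spec.family == "lognormal":
        if spec.b <= 0:
            raise ConfigurationError("degenerate prior has no density")
        z = (np.log(x) - spec.a) / spec.b
        return -0.5 * z * z - np.log(x * spec.b)
    if spec.family == "uniform":
        out = np.where((x >= spec.a) & (x <= spec.b),
                       -np.log(spec.b - spec.a), -np.inf)
        return out
    raise ConfigurationError(f"no grid prior for family {spec.family!r}")


def grid_posterior_oracle(
    trace: FluorescenceTrace,
    free: dict,
    priors: dict,
    fixed: CellParams,
    k: KineticConstants,
    nsub: int = 4,
) -> np.ndarray:
    """Brute-force posterior of one or two free parameters on a grid.

    ``free`` maps parameter names to grid arrays; ``priors`` maps the same
    names to DistSpec priors.  All other parameters stay at ``fixed``.
    Returns the pointwise prior x likelihood normalized to sum to one
    (1-d or 2-d matching the grids).
    """
    names = list(free)
    if len(names) not in (1, 2) or any(n not in PARAM_NAMES for n in names):
        raise ConfigurationError("free must name one or two cell parameters")
    grids = [np.asarray(free[n], dtype=float) for n in names]
    base = {name: getattr(fixed, name) for name in PARAM_NAMES}

    def loglik_at(values: dict) -> float:
        p = dict(base, **values)
        return float(_kernels.filter_loglik(
            trace.times, trace.values, trace.n_points,
            p["c"], p["tau0"], p["tau1"], p["T"], p["M0"], p["P0"],
            k.delta_M, k.delta_P, k.alpha, k.kappa, k.sigma2, nsub))

    if len(names) == 1:
        g = grids[0]
        logp = _prior_logpdf(priors[names[0]], g)
        for i, v in enumerate(g):
            if np.isfinite(logp[i]):
                logp[i] += loglik_at({names[0]: v})
    else:
        g1, g2 = grids
        logp = (_prior_logpdf(priors[names[0]], g1)[:, None]
                + _prior_logpdf(priors[names[1]], g2)[None, :])
        for i, v1 in enumerate(g1):
            for j, v2 in enumerate(g2):
                if np.isfinite(logp[i, j]):
                    logp[i, j] += loglik_at({names[0]: v1, names[1]: v2})
    total = logsumexp(logp[np.isfinite(logp)]) if np.any(np.isfinite(logp)) else -np.inf
    if not np.isfinite(total):
        raise RatescopeError("grid posterior has zero total mass")
    return np.exp(logp - total)


def diagnostics(chains: PosteriorChains) -> pd.DataFrame:
    """Convergence report: split-Rhat and bulk ESS per sampled parameter.

    With a single chain the draws are split in half (within-chain
    diagnostics only) and a warning is attached in ``df.attrs``.
    """
    import arviz as az

    arrs: dict[str, np.ndarray] = {}
    for p_idx, pname in enumerate(PARAM_NAMES):
        for c_idx, cid in enumerate(chains.cell_ids):
            arrs[f"{pname}[{cid}]"] = chains.cell_params[:, :, c_idx, p_idx]
    for h_idx, hname in enumerate(chains.hyper_names):
        arrs[hname] = chains.hypers[:, :, h_idx]

    warnings = []
    rows = []
    for name, arr in arrs.items():
        if arr.shape[0] == 1:
            half = arr.shape[1] // 2
            arr = np.stack([arr[0, :half], arr[0, half: 2 * half]])
        if np.ptp(arr) == 0:
            rows.append((name, np.nan, np.nan, "degenerate"))
            continue
        with np.errstate(all="ignore"):
            r = float(az.rhat(arr))
            e = float(az.ess(arr))
        flag = ""
        if not np.isfinite(r) or r > 1.05:
            flag = "rhat"
        elif e < 100:
            flag = "low_ess"
        rows.append((name, r, e, flag))
    df = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk", "flag"])
    if chains.cell_params.shape[0] == 1:
        warnings.append("single chain: split-half within-chain diagnostics only")
    df.attrs["warnings"] = warnings
    return df
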