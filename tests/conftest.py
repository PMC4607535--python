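"""Shared fixtures: kinetic constants, synthetic studies, and one full
hierarchical fit reused by every test that needs converged chains."""

import numpy as np
import pytest

from ratescope.datatypes import (
    DistSpec,
    KineticConstants,
    MCMCConfig,
    PopulationHyper,
    PosteriorChains,
    StudyDesign,
)
from ratescope.inference import run_hierarchical_mcmc
from ratescope.preprocessing import preprocess
from ratescope.synthetic import simulate_study

# proposal steps tuned for high-signal traces (the c*tau product is pinned
# tightly by the data, so product-direction moves must be small; the swap
# move mixes the ridge direction)
RECOVERY_STEPS = {
    "c": 0.02, "tau0": 0.3, "tau1": 0.02, "T": 12.0,
    "M0": 0.6, "P0": 0.6, "swap": 0.25, "sigma2": 0.1,
}


@pytest.fixture(scope="session")
def kinetics() -> KineticConstants:
    return KineticConstants()


def two_construct_design(seed: int = 11) -> StudyDesign:
    """Two constructs with a true population-mean active-rate ratio of 2,
    sharing one broad copy-number distribution; expression strong enough
    that essentially every cell clears the preselection threshold."""
    window = DistSpec("uniform", 120.0, 720.0)
    return StudyDesign(
        rate_hypers={
            "A": PopulationHyper(tau1=DistSpec("lognormal", np.log(4.0), 0.3),
                                 tau0=DistSpec("fraction", 0.0, 0.3), T=window),
            "B": PopulationHyper(tau1=DistSpec("lognormal", np.log(8.0), 0.3),
                                 tau0=DistSpec("fraction", 0.0, 0.3), T=window),
        },
        copy_number=DistSpec("lognormal", np.log(100.0), 1.0),
        cells_per_construct=24,
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_study(kinetics):
    """Preprocessed two-construct study (20 cells per construct) plus its
    ground truth."""
    design = two_construct_design()
    traces, truth = simulate_study(design, np.random.default_rng(design.seed),
                                   kinetics)
    kept, report = preprocess(traces, seed=12, n_low=20, n_high=20)
    return kept, truth, report


@pytest.fixture(scope="session")
def recovery_chains(recovery_study, kinetics) -> PosteriorChains:
    """Reduced-budget joint fit of the two-construct study (2 x 20k)."""
    kept, _, _ = recovery_study
    config = MCMCConfig(iterations=20_000, burn_in=8_000, thin=10, n_chains=2,
                        seed=5, steps=RECOVERY_STEPS)
    return run_hierarchical_mcmc(kept, kinetics, config)


def chains_from_samples(
    rate_samples: dict,
    switch_samples: dict | None = None,
    constructs: dict | None = None,
) -> PosteriorChains:
    """Build a single-chain PosteriorChains object from given per-cell
    tau1 (and optional T) sample arrays, for analysis-layer tests."""
    cell_ids = list(rate_samples)
    n_keep = len(next(iter(rate_samples.values())))
    ncell = len(cell_ids)
    cp = np.ones((1, n_keep, ncell, 6))
    for i, cid in enumerate(cell_ids):
        s = np.asarray(rate_samples[cid], dtype=float)
        cp[0, :, i, 2] = s
        cp[0, :, i, 1] = 0.1 * s
        if switch_samples and cid in switch_samples:
            cp[0, :, i, 3] = switch_samples[cid]
        else:
            cp[0, :, i, 3] = 100.0
    cons = [constructs.get(cid, "X") if constructs else "X" for cid in cell_ids]
    labels = list(dict.fromkeys(cons))
    hyper_names = ["sigma2", "s_c"]
    for lab in labels:
        hyper_names += [f"mu_tau1[{lab}]", f"s_tau1[{lab}]",
                        f"mu_tau0[{lab}]", f"s_tau0[{lab}]"]
    return PosteriorChains(
        cell_params=cp,
        hypers=np.ones((1, n_keep, len(hyper_names))),
        log_post=np.zeros((1, n_keep)),
        cell_ids=cell_ids,
        constructs=cons,
        construct_labels=labels,
        hyper_names=hyper_names,
        accept_rates=np.full((1, 8), 0.3),
        config=MCMCConfig(iterations=max(n_keep, 2), burn_in=0, thin=1,
                          n_chains=1),
    )
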