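"""Trajectory ensembles, reduced density matrices, and error diagnostics.

The reduced density matrix is assembled from independent stochastic
trajectories: for the normalized/nonlinear variants as the plain average of
normalized pure-state projectors, for the linear variant as the
norm-weighted average (sum of raw projectors divided by the summed norm
squared).  Trajectory i uses seed ``master_seed + i``, so results are
independent of any parallel execution layout and two ensembles run with the
same master seed share their noise realizations trajectory-by-trajectory —
the pairing used to measure adaptive error with the statistical error
cancelled at leading order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import (RunConfig, SimulationContext, TrajectoryResult,
                         integrate)

__all__ = ["EnsembleResult", "run_ensemble", "adaptive_error", "bootstrap_se",
           "basis_size_summary"]

_DENSITY_SITE_CAP = 64  # store full rho only for systems up to this size


@dataclass
class EnsembleResult:
    """Ensemble-averaged dynamics with statistical diagnostics."""

    t: np.ndarray
    rho: np.ndarray | None  # (n_t, n, n) or None for large aggregates
    populations: np.ndarray  # (n_t, n)
    population_se: np.ndarray
    traj_populations: np.ndarray | None  # (n_traj, n_t, n) when affordable
    traj_weights: np.ndarray | None  # (n_traj, n_t); ones except linear variant
    aux_sizes: np.ndarray  # (n_traj, n_t)
    state_sizes: np.ndarray
    n_traj: int
    seeds: np.ndarray
    diverged: np.ndarray = field(default=None)

    def mean_aux_size(self) -> np.ndarray:
        """Per-trajectory time-averaged adaptive auxiliary basis size."""
        return self.aux_sizes.mean(axis=1)

    def mean_state_size(self) -> np.ndarray:
        return self.state_sizes.mean(axis=1)


def run_ensemble(
    config: RunConfig,
    n_traj: int | None = None,
    master_seed: int | None = None,
    keep_trajectories: bool | None = None,
) -> EnsembleResult:
    """Run ``n_traj`` independent trajectories and average them.

    Per-trajectory populations are retained (for bootstrap error bars) when
    the memory cost is modest; otherwise the standard error falls back to
    the per-time-point sample standard deviation.
    """
    if n_traj is None:
        n_traj = config.n_traj
    if master_seed is None:
        master_seed = config.seed
    seeds = np.arange(master_seed, master_seed + n_traj)

    t_axis = None
    rho_sum = None
    pop_list = []
    w_list = []
    aux_list, state_list, div_list = [], [], []
    weight_sum = None
    linear = config.variant == "linear"
    n_sites = config.n_sites if config.hamiltonian is None else config.hamiltonian.shape[0]
    store_rho = n_sites <= _DENSITY_SITE_CAP
    if keep_trajectories is None:
        keep_trajectories = n_traj * (config.t_max / config.dt + 1) * n_sites <= 2e7

    context = SimulationContext(config)
    for s in seeds:
        res: TrajectoryResult = integrate(config, int(s), context=context)
        if t_axis is None:
            t_axis = res.t
            if store_rho:
                rho_sum = np.zeros((len(t_axis), n_sites, n_sites), dtype=complex)
            weight_sum = np.zeros(len(t_axis))
        if res.diverged:
            div_list.append(True)
            continue
        div_list.append(False)
        psi = res.psi
        # linear-variant psi is stored raw, so |psi|^2 is already the
        # norm-weighted projector diagonal; the weights only normalize
        w = res.norms**2 if linear else np.ones(len(t_axis))
        weight_sum += w
        w_list.append(w)
        if store_rho:
            rho_sum += psi[:, :, None] * np.conj(psi[:, None, :])
        pop_list.append(np.abs(psi) ** 2)
        aux_list.append(res.aux_sizes)
        state_list.append(res.state_sizes)

    n_used = len(pop_list)
    if n_used == 0:
        raise RuntimeError("all trajectories diverged")
    pops = np.array(pop_list)  # (n_used, n_t, n): weighted projector diagonals
    weights = np.array(w_list)  # (n_used, n_t)
    wsum = weight_sum[:, None]
    pop_mean = pops.sum(axis=0) / wsum
    if store_rho:
        rho = rho_sum / weight_sum[:, None, None]
        # enforce exact unit trace (weighting makes it exact up to roundoff)
        tr = np.trace(rho, axis1=1, axis2=2).real
        rho = rho / tr[:, None, None]
        pop_mean = np.real(np.einsum("tii->ti", rho))
    if n_used > 1:
        # delta-method standard error of the ratio estimator sum(p)/sum(w)
        resid = pops - weights[:, :, None] * pop_mean[None, :, :]
        se = resid.std(axis=0, ddof=1) / np.sqrt(n_used) / (weight_sum[:, None] / n_used)
    else:
        se = np.zeros_like(pop_mean)

    return EnsembleResult(
        t=t_axis,
        rho=rho if store_rho else None,
        populations=pop_mean,
        population_se=se,
        traj_populations=pops if keep_trajectories else None,
        traj_weights=weights if keep_trajectories else None,
        aux_sizes=np.array(aux_list),
        state_sizes=np.array(state_list),
        n_traj=n_used,
        seeds=seeds,
        diverged=np.array(div_list),
    )


def bootstrap_se(result: EnsembleResult, n_resamples: int = 200,
                 seed: int = 0) -> np.ndarray:
    """Bootstrap standard error of the site populations (needs kept trajectories)."""
    if result.traj_populations is None:
        raise ValueError("per-trajectory populations were not retained")
    rng = np.random.default_rng(seed)
    pops = result.traj_populations
    weights = result.traj_weights
    n = pops.shape[0]
    means = np.empty((n_resamples,) + pops.shape[1:])
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        means[b] = pops[idx].sum(axis=0) / weights[idx].sum(axis=0)[:, None]
    return means.std(axis=0, ddof=1)


def adaptive_error(
    adhops: EnsembleResult, hops: EnsembleResult, sites=None
) -> float:
    """Mean absolute site-population difference between two shared-noise runs.

    Averaged over all stored time points and (by default) all sites; pass
    ``sites`` to restrict, e.g. to the initially excited site.
    """
    if len(adhops.t) != len(hops.t) or not np.allclose(adhops.t, hops.t):
        raise ValueError("ensembles have mismatched time axes")
    diff = np.abs(adhops.populations - hops.populations)
    if sites is not None:
        diff = diff[:, np.atleast_1d(sites)]
    return float(diff.mean())


def basis_size_summary(result: EnsembleResult) -> str:
    """Tab-separated quantile table of per-trajectory mean basis sizes."""
    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    aux = np.quantile(result.mean_aux_size(), qs)
    states = np.quantile(result.mean_state_size(), qs)
    lines = ["quantile\tmean_aux_size\tmean_state_size"]
    for q, a, st in zip(qs, aux, states):
        lines.append(f"{q:.2f}\t{a:.2f}\t{st:.2f}")
    return "\n".join(lines) + "\n"
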