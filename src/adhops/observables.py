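"""Physical observables: site populations, mean-squared displacement,
diffusion coefficients, and auxiliary-occupation diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import EnsembleResult
from .trajectory import TrajectoryResult

__all__ = [
    "populations",
    "msd",
    "diffusion_coefficient",
    "DiffusionFit",
    "aux_occupation_map",
    "export_populations",
]


def populations(result: EnsembleResult) -> np.ndarray:
    """Site-population series (n_t, n_sites): the diagonal of rho(t)."""
    if result.rho is not None:
        return np.real(np.einsum("tii->ti", result.rho))
    return result.populations


def msd(pops: np.ndarray, start_site: int, l_0: float = 1.0) -> np.ndarray:
    """Mean-squared displacement sum_n P_n(t) ((n - start) l_0)^2."""
    pops = np.asarray(pops)
    n = pops.shape[1]
    disp2 = ((np.arange(n) - start_site) * l_0) ** 2
    return pops @ disp2


@dataclass
class DiffusionFit:
    """Least-squares linear fit MSD ~ 2 D t over a window (1-D convention).

    ``D`` is in units of l_0^2/fs; ``residual`` is the RMS deviation of the
    fit relative to the MSD range over the window — large values flag
    non-diffusive (e.g. ballistic) transport.
    """

    D: float
    intercept: float
    window: tuple[float, float]
    residual: float
    msd_series: np.ndarray
    t: np.ndarray

    def D_cm2_per_s(self, l_0_cm: float) -> float:
        """Convert to cm^2/s given the molecular spacing in cm."""
        return self.D * l_0_cm**2 * 1e15


def diffusion_coefficient(
    t: np.ndarray,
    msd_series: np.ndarray,
    window: tuple[float, float] | None = None,
    msd_factor: float = 2.0,
) -> DiffusionFit:
    """Diffusion coefficient from a linear fit to the MSD.

    The default window is the second half of the series (skipping the
    initial ballistic transient); ``msd_factor`` is the dimensional constant
    in MSD = factor * D * t (2 in one dimension).
    """
    t = np.asarray(t, dtype=float)
    msd_series = np.asarray(msd_series, dtype=float)
    if window is None:
        window = (t[len(t) // 2], t[-1])
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise ValueError("fit window must contain at least two points")
    tw, mw = t[mask], msd_series[mask]
    slope, intercept = np.polyfit(tw, mw, 1)
    fit = slope * tw + intercept
    scale = max(mw.max() - mw.min(), 1e-300)
    residual = float(np.sqrt(np.mean((mw - fit) ** 2)) / scale)
    return DiffusionFit(
        D=float(slope / msd_factor),
        intercept=float(intercept),
        window=(float(lo), float(hi)),
        residual=residual,
        msd_series=msd_series,
        t=t,
    )


def aux_occupation_map(traj: TrajectoryResult, aux_indices=None) -> dict:
    """Time series of squared auxiliary norms captured during a trajectory.

    Keys are the sparse ``(mode, k)`` pair tuples of each captured index.
    Requires the trajectory to have been run with ``aux_capture`` set.
    """
    if not traj.aux_capture:
        raise ValueError("trajectory was run without aux_capture")
    if aux_indices is None:
        return dict(traj.aux_capture)
    out = {}
    for a in aux_indices:
        key = tuple(a.pairs) if hasattr(a, "pairs") else tuple(a)
        if key not in traj.aux_capture:
            raise KeyError(f"auxiliary {key} was not captured")
        out[key] = traj.aux_capture[key]
    return out


def export_populations(result: EnsembleResult, path: str,
                       start_site: int | None = None, l_0: float = 1.0) -> None:
    """Write a tab-separated table of time, site populations, and MSD."""
    pops = populations(result)
    n = pops.shape[1]
    if start_site is None:
        start_site = n // 2
    series = msd(pops, start_site, l_0)
    header = "t_fs\t" + "\t".join(f"P{s}" for s in range(n)) + "\tmsd"
    data = np.column_stack([result.t, pops, series])
    np.savetxt(path, data, delimiter="\t", header=header, comments="")
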