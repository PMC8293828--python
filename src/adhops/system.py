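"""Electronic system model: Frenkel exciton Hamiltonian with site-projection
system-bath coupling.

The aggregate's electronic Hamiltonian collects site energies on the
diagonal and electronic couplings V off the diagonal (cm^-1).  Each site n
couples to its own bath through the projector L_n = |n><n|, so the bath
modulates site energies only (diagonal, "Holstein-like" coupling).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["SystemModel"]


class SystemModel:
    """Hermitian site Hamiltonian with per-site projection coupling operators.

    ``hamiltonian`` may be dense or ``scipy.sparse``; mesoscale chains should
    pass a sparse matrix so the model never densifies.
    """

    def __init__(self, hamiltonian):
        if sp.issparse(hamiltonian):
            h = hamiltonian.tocsr()
            herm_dev = abs(h - h.conj().T)
            if herm_dev.nnz and herm_dev.max() > 1e-12:
                raise ValueError("hamiltonian must be Hermitian within 1e-12")
        else:
            h = np.asarray(hamiltonian, dtype=complex)
            if h.ndim != 2 or h.shape[0] != h.shape[1]:
                raise ValueError("hamiltonian must be square")
            if np.max(np.abs(h - h.conj().T)) > 1e-12:
                raise ValueError("hamiltonian must be Hermitian within 1e-12")
        self.hamiltonian = h
        self.n_sites = h.shape[0]

    def sub_hamiltonian(self, sites: np.ndarray) -> np.ndarray:
        """Dense restriction of H onto a (small) set of sites."""
        h = self.hamiltonian
        if sp.issparse(h):
            return np.asarray(h[np.ix_(sites, sites)].todense())
        return h[np.ix_(sites, sites)]

    def coupled_sites(self, sites: np.ndarray) -> np.ndarray:
        """All sites reachable from ``sites`` through one off-diagonal H element."""
        h = self.hamiltonian
        if sp.issparse(h):
            cols = h[sites].nonzero()[1]
        else:
            cols = np.nonzero(h[sites])[1]
        return np.unique(cols)
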