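"""Random sparse connectivity of the sensory network.

Three directed classes exist: E->E (no self-connections), E->I and I->E.
There are no I->I synapses; inhibitory neurons interact only through the
excitatory population.  Each ordered pair in an allowed class is connected
independently with probability ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse


@dataclass(frozen=True)
class ConnectivityGraph:
    """Adjacency of the three synapse classes, stored presynaptically.

    Each matrix is boolean CSR with shape (n_pre, n_post), so ``row j``
    lists the targets of presynaptic neuron ``j`` — the layout the
    propagation step needs when scattering a spike to its targets.
    """

    ee: sparse.csr_matrix  # (N_E, N_E), no diagonal
    ei: sparse.csr_matrix  # (N_E, N_I)
    ie: sparse.csr_matrix  # (N_I, N_E)

    @property
    def n_e(self) -> int:
        return self.ee.shape[0]

    @property
    def n_i(self) -> int:
        return self.ie.shape[0]

    def edge_counts(self) -> dict[str, int]:
        return {"ee": int(self.ee.nnz), "ei": int(self.ei.nnz), "ie": int(self.ie.nnz)}


def _bernoulli_csr(rng: np.random.Generator, n_pre: int, n_post: int,
                   p: float, no_self: bool) -> sparse.csr_matrix:
    mask = rng.random((n_pre, n_post)) < p
    if no_self:
        np.fill_diagonal(mask, False)
    return sparse.csr_matrix(mask)


def build_connectivity(n_e: int, n_i: int, p: float,
                       seed: int | np.random.Generator) -> ConnectivityGraph:
    """Draw a random graph: every allowed ordered pair connects with prob. ``p``.

    Parameters
    ----------
    n_e, n_i
        Numbers of excitatory and inhibitory neurons.
    p
        Connection probability, in [0, 1].
    seed
        Integer seed or a ``numpy.random.Generator``.  The draw is
        deterministic given an integer seed.
    """
    if n_e < 0 or n_i < 0:
        raise ValueError("population sizes must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise ValueError("connection probability must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ee = _bernoulli_csr(rng, n_e, n_e, p, no_self=True)
    ei = _bernoulli_csr(rng, n_e, n_i, p, no_self=False)
    ie = _bernoulli_csr(rng, n_i, n_e, p, no_self=False)
    return ConnectivityGraph(ee=ee, ei=ei, ie=ie)
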