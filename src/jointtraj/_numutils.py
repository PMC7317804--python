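"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["fd_hessian", "spawn_seeds"]


def fd_hessian(f, x, rel_step: float = 1e-5):
    """Hessian of scalar ``f`` at ``x`` by central finite differences.

    Steps are relative, ``h_i = rel_step * (1 + |x_i|)``, adequate for the
    smooth log-likelihoods used here (observed-information matrices).
    """
    x = np.asarray(x, float)
    k = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
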