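"""Independent oracles used by the tests (kept free of qfadd internals)."""

import numpy as np


def exact_trap_occupancy(mask: np.ndarray, trap: np.ndarray, n_iter: int) -> np.ndarray:
    """Exact expected normalized trap occupancy of the diagonal-hop walk.

    Propagates the single-particle probability distribution of a fully
    mobile population through the absorbing Markov chain: from each free
    pixel the four (±1, ±1) hops have probability 1/4 each; a hop leaving
    the mask is rejected (self-loop); trap pixels absorb.  The start
    distribution is uniform over the mask.  Returns occupancy normalized to
    the initial trap mass, one value per iteration (0..n_iter).
    """
    rows, cols = mask.shape
    coords = np.argwhere(mask)
    idx = {(r, c): i for i, (r, c) in enumerate(coords)}
    n = len(coords)
    in_trap = trap[coords[:, 0], coords[:, 1]]
    p = np.full(n, 1.0 / n)
    absorbed = p[in_trap].sum()
    p[in_trap] = 0.0
    occ = [absorbed]
    moves = ((1, 1), (1, -1), (-1, 1), (-1, -1))
    for _ in range(n_iter):
        new_p = np.zeros(n)
        for i, (r, c) in enumerate(coords):
            if p[i] == 0.0:
                continue
            for dr, dc in moves:
                dest = (r + dr, c + dc)
                j = idx.get(dest)
                if j is None:
                    new_p[i] += 0.25 * p[i]
                else:
                    new_p[j] += 0.25 * p[i]
        absorbed += new_p[in_trap].sum()
        new_p[in_trap] = 0.0
        p = new_p
        occ.append(absorbed)
    occ = np.asarray(occ)
    return occ / occ[0]


def welch_t(xa: np.ndarray, xb: np.ndarray) -> tuple[float, float]:
    """Closed-form Welch t statistic and Welch–Satterthwaite df."""
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
    t = (xa.mean() - xb.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1))
    return float(t), float(df)
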