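"""Independent oracles used by the test suite.

These deliberately avoid the package's m-array/likelihood code paths: the
individual-history likelihood works bird by bird, the grid search scans the
constant-parameter deviance surface directly, and power iteration provides
an eigenvalue reference.
"""

from __future__ import annotations

import numpy as np


def individual_nll2(chs, phi_fn, p_fn) -> float:
    """-2 log CJS likelihood computed per individual history.

    ``phi_fn(age, interval)`` and ``p_fn(age, occasion)`` take 1-based age
    (years since marking) and 0-based time indices.
    """
    t = len(chs.occasions)
    total = 0.0
    for h in chs.histories:
        dets = [i for i, x in enumerate(h.detections) if x]
        c, last = dets[0], dets[-1]
        lp = 0.0
        for k in range(c, last):
            lp += np.log(phi_fn(k - c + 1, k))
            pk = p_fn(k + 1 - c, k + 1)
            lp += np.log(pk if h.detections[k + 1] else 1.0 - pk)

        def chi(tt: int) -> float:
            if tt == t - 1:
                return 1.0
            ph = phi_fn(tt - c + 1, tt)
            pk = p_fn(tt + 1 - c, tt + 1)
            return (1.0 - ph) + ph * (1.0 - pk) * chi(tt + 1)

        lp += np.log(chi(last))
        total += -2.0 * lp
    return total


def constant_model_grid(chs, resolution: float = 1e-3
                        ) -> tuple[float, float, float]:
    """Exhaustive grid minimum of the constant-(phi, p) deviance surface.

    Returns (phi, p, nll2) at the grid optimum.  Vectorized over the grid so
    a 1e-3 resolution stays fast on tiny instances.
    """
    grid = np.arange(resolution, 1.0, resolution)
    phi = grid[:, None]
    p = grid[None, :]
    t = len(chs.occasions)
    ll = np.zeros((grid.size, grid.size))
    for h in chs.histories:
        dets = [i for i, x in enumerate(h.detections) if x]
        c, last = dets[0], dets[-1]
        for k in range(c, last):
            ll += np.log(phi)
            ll += np.log(p) if h.detections[k + 1] else np.log(1.0 - p)
        chi = np.ones((grid.size, grid.size))
        for tt in range(t - 2, last - 1, -1):
            chi = (1.0 - phi) + phi * (1.0 - p) * chi
        ll += np.log(chi)
    nll2 = -2.0 * ll
    i, j = np.unravel_index(np.argmin(nll2), nll2.shape)
    return float(grid[i]), float(grid[j]), float(nll2[i, j])


def power_iteration(a: np.ndarray, iters: int = 10_000,
                    tol: float = 1e-14) -> float:
    """Dominant eigenvalue modulus of a non-negative matrix."""
    rng = np.random.default_rng(12345)
    v = rng.random(a.shape[0]) + 1e-3
    lam = 0.0
    for _ in range(iters):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:
            return 0.0
        w /= norm
        new_lam = float(w @ a @ w)
        if abs(new_lam - lam) < tol:
            return abs(new_lam)
        lam, v = new_lam, w
    return abs(lam)


def enumerate_marray(chs):
    """Hand-rolled m-array enumeration (releases, first re-encounters).

    Independent of the package implementation: scans histories and tallies
    (release occasion -> first next detection) transitions per group.
    """
    t = len(chs.occasions)
    out: dict[str, dict] = {}
    for h in chs.histories:
        g = out.setdefault(
            h.group,
            {
                "R": np.zeros(t, dtype=int),
                "m": np.zeros((t, t), dtype=int),
                "never": np.zeros(t, dtype=int),
            },
        )
        dets = [i for i, x in enumerate(h.detections) if x]
        for a, b in zip(dets, dets[1:]):
            g["R"][a] += 1
            g["m"][a, b] += 1
        if dets[-1] < t - 1:
            g["R"][dets[-1]] += 1
            g["never"][dets[-1]] += 1
    return out
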