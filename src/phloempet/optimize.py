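"""Shuffled complex evolution (SCE-UA) global minimizer.

Population-based search over a box: the population is sorted and dealt
into complexes, each complex evolves by competitive simplex steps
(reflection, contraction, random replacement), and complexes are
periodically merged and re-dealt ("shuffled").  Canonical defaults for
an n-dimensional problem: 2n+1 points per complex, subcomplexes of
n+1 points selected with triangular probability, one offspring per
subcomplex, 2n+1 evolution steps per complex per shuffling loop.

Deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SceResult:
    x: np.ndarray
    fun: float
    nfev: int
    n_loops: int
    converged: bool
    best_per_loop: list = field(default_factory=list)


def sce_minimize(
    func,
    bounds,
    seed=0,
    n_complexes: int | None = None,
    points_per_complex: int | None = None,
    subcomplex_size: int | None = None,
    n_evolution_steps: int | None = None,
    max_evaluations: int = 4500,
    accuracy: float = 1e-5,
    k_loops: int = 5,
) -> SceResult:
    """Minimize ``func`` over the box ``bounds`` (sequence of (lo, hi)).

    Stops when the best objective has improved by less than ``accuracy``
    (relative) over the last ``k_loops`` shuffling loops, or when
    ``max_evaluations`` function evaluations have been spent
    (``converged=False`` in that case).
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a sequence of (lo, hi) pairs")
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(hi <= lo):
        raise ValueError("each upper bound must exceed its lower bound")
    n = bounds.shape[0]
    p = n_complexes if n_complexes is not None else 2 * n + 1
    if p < 2:
        raise ValueError("need at least 2 complexes")
    m = points_per_complex if points_per_complex is not None else 2 * n + 1
    q = subcomplex_size if subcomplex_size is not None else n + 1
    beta = n_evolution_steps if n_evolution_steps is not None else 2 * n + 1
    rng = np.random.default_rng(seed)

    nfev = 0

    def evaluate(x):
        nonlocal nfev
        nfev += 1
        return float(func(x))

    s = p * m
    X = lo + rng.random((s, n)) * (hi - lo)
    F = np.array([evaluate(x) for x in X])

    # triangular selection probabilities over ranks within a complex
    sel_p = 2.0 * (m - np.arange(m)) / (m * (m + 1))

    best_per_loop: list[float] = []
    converged = False
    n_loops = 0
    while nfev < max_evaluations:
        order = np.argsort(F, kind="stable")
        X, F = X[order], F[order]
        # deal into complexes: complex k takes ranks k, k+p, k+2p, ...
        for ci in range(p):
            idx = np.arange(ci, s, p)[:m]
            Cx, Cf = X[idx], F[idx]
            for _ in range(beta):
                if nfev >= max_evaluations:
                    break
                ranks = rng.choice(m, size=q, replace=False, p=sel_p)
                ranks.sort()
                worst = ranks[-1]
                centroid = Cx[ranks[:-1]].mean(axis=0)
                # mutation falls back to the smallest hypercube containing
                # the complex, so late-stage moves stay local
                cube_lo, cube_hi = Cx.min(axis=0), Cx.max(axis=0)
                # reflection
                xr = 2.0 * centroid - Cx[worst]
                if np.any(xr < lo) | np.any(xr > hi):
                    xr = cube_lo + rng.random(n) * (cube_hi - cube_lo)
                fr = evaluate(xr)
                if fr < Cf[worst]:
                    Cx[worst], Cf[worst] = xr, fr
                else:
                    # contraction
                    xc = 0.5 * (centroid + Cx[worst])
                    fc = evaluate(xc)
                    if fc < Cf[worst]:
                        Cx[worst], Cf[worst] = xc, fc
                    else:
                        xm = cube_lo + rng.random(n) * (cube_hi - cube_lo)
                        Cx[worst], Cf[worst] = xm, evaluate(xm)
                csort = np.argsort(Cf, kind="stable")
                Cx, Cf = Cx[csort], Cf[csort]
            X[idx], F[idx] = Cx, Cf
        n_loops += 1
        best = float(F.min())
        best_per_loop.append(best)
        if len(best_per_loop) > k_loops:
            prev = best_per_loop[-k_loops - 1]
            rel = (prev - best) / max(abs(prev), 1e-300)
            if rel < accuracy:
                converged = True
                break

    i = int(np.argmin(F))
    return SceResult(
        x=X[i].copy(), fun=float(F[i]), nfev=nfev, n_loops=n_loops,
        converged=converged, best_per_loop=best_per_loop,
    )
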