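"""Independent oracles used by the test suite.

These deliberately avoid the package's solver path: closed-form quadratic
for 1:1 binding, polynomial root finding (numpy companion-matrix roots plus
Newton polishing of the scalar cubic) for 1:2 binding, and term-by-term
series summation for polymers.
"""

from __future__ import annotations

import numpy as np


def free_conc_1to1(K: float, t_h: float, t_g: float) -> tuple[float, float]:
    """Free host and guest for H + G <-> HG from the closed-form quadratic,
    evaluated in the cancellation-free branch."""
    b = 1.0 + K * (t_g - t_h)
    disc = np.sqrt(b * b + 4.0 * K * t_h)
    h = 2.0 * t_h / (b + disc) if b >= 0 else (-b + disc) / (2.0 * K)
    g = t_g / (1.0 + K * h)
    return float(h), float(g)


def free_conc_1to2(b1: float, b2: float, t_h: float, t_g: float) -> tuple[float, float]:
    """Free host and guest for the 1:2 system (complexes HG, HG2) from the
    cubic in free guest, via exhaustive root search + Newton polishing."""
    c = np.array([b2, b1 + 2.0 * t_h * b2 - t_g * b2, 1.0 + t_h * b1 - t_g * b1, -t_g])
    roots = np.roots(c)
    real = roots[np.abs(roots.imag) < 1e-8 * (np.abs(roots.real) + 1e-300)].real

    def mass_balance_err(g):
        h = t_h / (1.0 + b1 * g + b2 * g * g)
        return abs(t_g - g - b1 * h * g - 2.0 * b2 * h * g * g)

    candidates = [r for r in real if r > 0] or [abs(r) for r in real]
    g = min(candidates, key=mass_balance_err)
    for _ in range(100):  # polish the root to machine accuracy
        p = ((c[0] * g + c[1]) * g + c[2]) * g + c[3]
        dp = (3.0 * c[0] * g + 2.0 * c[1]) * g + c[2]
        step = p / dp
        if not np.isfinite(step):
            break
        step = float(np.clip(step, -0.5 * g, 0.5 * g))
        g_new = g - step
        if abs(g_new - g) <= 1e-17 * abs(g):
            g = g_new
            break
        g = g_new
    h = t_h / (1.0 + b1 * g + b2 * g * g)
    return float(h), float(g)


def polymer_sums_by_summation(s: float, k2: float, kn: float, n_max: int = 400000):
    """(sum n*c_n, sum c_n) for chains c_n = K2 Kn^(n-2) s^n summed term by
    term in log space until the terms underflow."""
    n = np.arange(2, n_max)
    with np.errstate(divide="ignore"):
        log_cn = np.log(k2) + (n - 2) * (np.log(kn) if kn > 0 else -np.inf) + n * np.log(s)
        if kn == 0:
            log_cn = np.full(n.shape, -np.inf)
            log_cn[0] = np.log(k2) + 2 * np.log(s)
    cn = np.exp(log_cn)
    return float((n * cn).sum()), float(cn.sum())


def random_network(rng, max_components: int = 4, max_complexes: int = 6):
    """A random valid stoichiometry matrix (components x complexes) with
    coefficients in 0..2, no duplicate or empty columns."""
    n_comp = int(rng.integers(2, max_components + 1))
    n_cplx = int(rng.integers(1, max_complexes + 1))
    cols, seen = [], set()
    while len(cols) < n_cplx:
        col = rng.integers(0, 3, size=n_comp)
        key = tuple(col)
        if col.sum() == 0 or key in seen:
            continue
        seen.add(key)
        cols.append(col)
    return np.column_stack(cols)
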