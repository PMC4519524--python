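"""Scalar likelihood kernel for the hybrid model.

The per-trial recursion mirrors :mod:`twostep.agents` exactly; the kernel
is written with scalar arithmetic so it can be JIT-compiled with numba
when available.  The pure-Python function and the compiled one are the
same object code-wise, so both code paths give identical results.
"""

from __future__ import annotations

import math

import numpy as np


def _nll_core(choice1, state2, choice2, outcome, omitted,
              alpha, beta, rho, omega, lam, p_common):
    """Negative log-likelihood of one trial log under the hybrid model.

    Both stage choices of every non-omitted trial contribute a term.
    Omitted trials contribute nothing, perform no update and reset the
    perseveration reference.  Returns ``(nll, n_obs)``.
    """
    q1a = 0.0
    q1b = 0.0
    q200 = 0.0  # q2[state, choice]
    q201 = 0.0
    q210 = 0.0
    q211 = 0.0
    prev = -1
    nll = 0.0
    n_obs = 0
    for t in range(choice1.shape[0]):
        if omitted[t]:
            prev = -1
            continue
        # model-based stage-1 values from the fixed transition structure
        m0 = q200 if q200 > q201 else q201
        m1 = q210 if q210 > q211 else q211
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = p_common * m1 + (1.0 - p_common) * m0
        v0 = omega * qmb0 + (1.0 - omega) * q1a
        v1 = omega * qmb1 + (1.0 - omega) * q1b
        x0 = beta * v0
        x1 = beta * v1
        if prev == 0:
            x0 += rho
        elif prev == 1:
            x1 += rho
        mx = x0 if x0 > x1 else x1
        z = math.exp(x0 - mx) + math.exp(x1 - mx)
        c1 = choice1[t]
        nll -= (x0 - mx if c1 == 0 else x1 - mx) - math.log(z)

        s = state2[t]
        if s == 0:
            y0 = beta * q200
            y1 = beta * q201
        else:
            y0 = beta * q210
            y1 = beta * q211
        my = y0 if y0 > y1 else y1
        zz = math.exp(y0 - my) + math.exp(y1 - my)
        c2 = choice2[t]
        nll -= (y0 - my if c2 == 0 else y1 - my) - math.log(zz)
        n_obs += 2

        # SARSA updates
        if s == 0:
            q2sc = q200 if c2 == 0 else q201
        else:
            q2sc = q210 if c2 == 0 else q211
        if c1 == 0:
            q1a += alpha * (q2sc - q1a)
        else:
            q1b += alpha * (q2sc - q1b)
        d2 = outcome[t] - q2sc
        q2sc += alpha * d2
        if s == 0:
            if c2 == 0:
                q200 = q2sc
            else:
                q201 = q2sc
        else:
            if c2 == 0:
                q210 = q2sc
            else:
                q211 = q2sc
        if c1 == 0:
            q1a += alpha * lam * d2
        else:
            q1b += alpha * lam * d2
        prev = c1
    return nll, n_obs


try:  # JIT-compile when numba is available; the plain function is the fallback
    from numba import njit

    _nll_fast = njit(cache=True, fastmath=False)(_nll_core)
except Exception:  # pragma: no cover - exercised only without numba
    _nll_fast = _nll_core


def nll_arrays(choice1: np.ndarray, state2: np.ndarray, choice2: np.ndarray,
               outcome: np.ndarray, omitted: np.ndarray,
               alpha: float, beta: float, rho: float, omega: float,
               lam: float, p_common: float, fast: bool = True):
    """Dispatch to the compiled kernel (default) or the pure-Python one."""
    fn = _nll_fast if fast else _nll_core
    return fn(
        np.ascontiguousarray(choice1, dtype=np.int64),
        np.ascontiguousarray(state2, dtype=np.int64),
        np.ascontiguousarray(choice2, dtype=np.int64),
        np.ascontiguousarray(outcome, dtype=np.float64),
        np.ascontiguousarray(omitted, dtype=np.bool_),
        float(alpha), float(beta), float(rho), float(omega),
        float(lam), float(p_common),
    )
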