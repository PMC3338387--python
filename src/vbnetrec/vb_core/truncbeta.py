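"""Moments of a Beta(a, b) distribution truncated to (0, bound].

Needed for the variational factor of the inclusion fraction, whose prior is
capped at the model-size bound. The fast path brackets the log-kernel's
effective support (everything within 45 nats of its maximum, found by
bisection from the mode) and applies composite Gauss-Legendre quadrature on
that window — accurate whether the mass sits at the bound, at an interior
mode, or far below the bound. Adaptive scipy quadrature is the fallback and
closed-form digamma identities are used when bound == 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, special

__all__ = ["TruncatedBetaMoments", "truncated_beta_moments"]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)
_DROP = 45.0  # exp(-45) ~ 3e-20: negligible relative mass outside the window


@dataclass(frozen=True)
class TruncatedBetaMoments:
    """Expectations under Beta(a, b) restricted to (0, bound]."""

    a: float
    b: float
    bound: float
    mean: float
    elog: float        # E[log theta]
    elog1m: float      # E[log(1 - theta)]
    log_norm: float    # log integral of theta^(a-1) (1-theta)^(b-1) over (0, bound]


def _untruncated(a: float, b: float) -> TruncatedBetaMoments:
    return TruncatedBetaMoments(
        a=a,
        b=b,
        bound=1.0,
        mean=a / (a + b),
        elog=float(special.digamma(a) - special.digamma(a + b)),
        elog1m=float(special.digamma(b) - special.digamma(a + b)),
        log_norm=float(special.betaln(a, b)),
    )


def _logkernel(a: float, b: float):
    def g(t):
        return (a - 1.0) * np.log(t) + (b - 1.0) * np.log1p(-t)

    return g


def _bisect_drop(g, g_target: float, lo: float, hi: float, increasing: bool) -> float:
    """Point in [lo, hi] where g crosses g_target; g monotone on the interval.

    40 halvings give far more precision than the window needs (the crossing
    only has to be bracketed; everything outside is below exp(-45) relative).
    """
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if (g(mid) < g_target) == increasing:
            lo = mid
        else:
            hi = mid
    # return the outer edge so the window always contains the crossing
    return lo if increasing else hi


def _moments_window(a: float, b: float, s: float) -> TruncatedBetaMoments | None:
    """Composite GL over the Laplace window; None if not applicable (a < 1)."""
    if a < 1.0:
        return None  # integrable singularity at 0: leave to adaptive quad
    g = _logkernel(a, b)
    if a == 1.0:
        mode = 0.0 if b >= 1.0 else s
    else:
        interior = (a - 1.0) / (a + b - 2.0) if a + b > 2.0 else 1.0
        mode = min(interior, s)
    mode = min(max(mode, 0.0), s)
    gmax = float(g(mode)) if mode > 0.0 else 0.0  # a == 1: kernel -> 1 at 0
    target = gmax - _DROP

    tiny = s * 1e-300
    if mode == 0.0 or float(g(tiny)) >= target:
        lo = 0.0
    else:
        lo = _bisect_drop(g, target, tiny, mode, increasing=True)
    if mode >= s or float(g(s)) >= target:
        hi = s
    else:
        hi = _bisect_drop(g, target, mode, s, increasing=False)

    knots = sorted({lo, min(max(mode, lo), hi), hi})
    first = knots[1] if len(knots) > 1 else knots[0]

    z = m_t = m_log = m_log1m = 0.0
    # the log-theta moment is singular at 0: below eps0 the (1-theta) factor
    # is 1 to ~1e-9 relative, so that head is integrated in closed form, and
    # the stretch up to the first knot is covered by decade-wide panels
    eps0 = min(0.5 * first, 1e-9 / max(b - 1.0, 1.0))
    start = knots[0]
    if start < eps0:
        ea = math.exp(min(a * math.log(eps0) - gmax, 700.0))  # eps0^a, shifted
        z += ea / a
        m_log += ea * (a * math.log(eps0) - 1.0) / (a * a)
        m_t += ea * eps0 / (a + 1.0)
        m_log1m += -ea * eps0 / (a + 1.0)  # log1p(-t) ~ -t below eps0
        start = eps0
    knots = sorted({start} | {k for k in knots if k > start})
    # geometric refinement toward both integrand singularities (log theta at
    # 0, log(1-theta) at 1) so no panel spans more than a decade of distance
    # to either endpoint
    refined: set[float] = set(knots)
    for p, q in zip(knots[:-1], knots[1:]):
        edge = q
        while edge > 10.0 * p:
            edge *= 0.1
            refined.add(edge)
        edge = p
        while q < 1.0 and (1.0 - edge) > 10.0 * (1.0 - q):
            edge = 1.0 - 0.1 * (1.0 - edge)
            refined.add(edge)
    knots = sorted(k for k in refined if start <= k <= hi)
    panels = [(knots[i], knots[i + 1]) for i in range(len(knots) - 1)
              if knots[i + 1] > knots[i]]
    if not panels:
        return None
    for left, right in panels:
        half = 0.5 * (right - left)
        t = left + half * (_GL_NODES + 1.0)
        w = half * _GL_WEIGHTS
        f = np.exp(g(t) - gmax)
        wf = w * f
        z += float(wf.sum())
        m_t += float(wf @ t)
        m_log += float(wf @ np.log(t))
        m_log1m += float(wf @ np.log1p(-t))
    if not math.isfinite(z) or z <= 0.0:
        return None
    return TruncatedBetaMoments(
        a=a,
        b=b,
        bound=s,
        mean=m_t / z,
        elog=m_log / z,
        elog1m=m_log1m / z,
        log_norm=gmax + math.log(z),
    )


def _moments_quad(a: float, b: float, s: float) -> TruncatedBetaMoments:
    """Adaptive quadrature in theta = s*v, normalized at the integrand max."""

    def logf(v):
        return (a - 1.0) * np.log(v) + (b - 1.0) * np.log1p(-s * v)

    if a + b > 2.0:
        v_star = min(max((a - 1.0) / (s * (a + b - 2.0)), 1e-12), 1.0)
    else:
        v_star = 1.0
    fmax = float(max(logf(np.asarray(v)) for v in (1e-12, v_star, 1.0)))

    def h(v, g):
        return np.exp(logf(v) - fmax) * g(v)

    pts = [v_star] if 0.0 < v_star < 1.0 else None
    kw = dict(points=pts, limit=200)
    z, _ = integrate.quad(h, 0.0, 1.0, args=(lambda v: 1.0,), **kw)
    if not np.isfinite(z) or z <= 0.0:
        raise FloatingPointError(
            f"truncated-Beta normalizer failed for a={a}, b={b}, bound={s}"
        )
    m_v, _ = integrate.quad(h, 0.0, 1.0, args=(lambda v: v,), **kw)
    m_logv, _ = integrate.quad(h, 0.0, 1.0, args=(np.log,), **kw)
    m_log1m, _ = integrate.quad(h, 0.0, 1.0, args=(lambda v: np.log1p(-s * v),), **kw)
    return TruncatedBetaMoments(
        a=a,
        b=b,
        bound=s,
        mean=s * m_v / z,
        elog=np.log(s) + m_logv / z,
        elog1m=m_log1m / z,
        log_norm=a * np.log(s) + fmax + np.log(z),
    )


@lru_cache(maxsize=8192)
def _moments_cached(a: float, b: float, bound: float) -> TruncatedBetaMoments:
    if bound == 1.0:
        return _untruncated(a, b)
    out = _moments_window(a, b, bound)
    if out is None:
        out = _moments_quad(a, b, bound)
    return out


def truncated_beta_moments(a: float, b: float, bound: float) -> TruncatedBetaMoments:
    """Mean, E[log theta], E[log(1-theta)] and log-mass of the truncated Beta.

    Parameters must satisfy a > 0, b > 0, 0 < bound <= 1.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"Beta parameters must be positive, got a={a}, b={b}")
    if not 0.0 < bound <= 1.0:
        raise ValueError(f"bound must lie in (0, 1], got {bound}")
    return _moments_cached(float(a), float(b), float(bound))
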