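"""Independent brute-force oracle for the assignment rules.

Deliberately written with plain Python loops and scalar vector algebra,
without reusing any code path from the package, so that exact agreement
with the library's vectorised implementation is a meaningful check.
"""

from __future__ import annotations

import math


def _sub(a, b):
    return (a[0] - b[0], a[1] - b[1], a[2] - b[2])


def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _cross(a, b):
    return (a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0])


def _norm(a):
    return math.sqrt(_dot(a, a))


def _dist(a, b):
    return _norm(_sub(a, b))


def brute_theta(x, n):
    """Bond angle at 1-based position n of point list x, degrees, or None."""
    if n < 2 or n > len(x) - 1:
        return None
    u = _sub(x[n - 2], x[n - 1])
    v = _sub(x[n], x[n - 1])
    nu, nv = _norm(u), _norm(v)
    if nu < 1e-8 or nv < 1e-8:
        return None
    c = max(-1.0, min(1.0, _dot(u, v) / (nu * nv)))
    return math.degrees(math.acos(c))


def brute_gamma(x, n):
    """Pseudo-torsion at 1-based position n, degrees in (-180, 180], or None.

    Sign convention: positive for a right-handed helix, computed from the
    triple product of the two plane normals with the central bond.
    """
    if n < 2 or n > len(x) - 2:
        return None
    p0, p1, p2, p3 = x[n - 2], x[n - 1], x[n], x[n + 1]
    b1, b2, b3 = _sub(p1, p0), _sub(p2, p1), _sub(p3, p2)
    n1, n2 = _cross(b1, b2), _cross(b2, b3)
    if _norm(n1) < 1e-8 or _norm(n2) < 1e-8:
        return None
    cosv = _dot(n1, n2) / (_norm(n1) * _norm(n2))
    cosv = max(-1.0, min(1.0, cosv))
    ang = math.degrees(math.acos(cosv))
    # sign from the triple product (n1 x n2) . b2
    sign = _dot(_cross(n1, n2), b2)
    if sign < 0:
        ang = -ang
    if ang == -180.0:
        ang = 180.0
    return ang


def _angles_with_breaks(trace):
    x = [tuple(p) for p in trace.coords]
    n = len(x)
    theta = {}
    gamma = {}
    for pos in range(2, n):
        if any(b in trace.breaks for b in (pos - 1, pos)):
            theta[pos] = None
        else:
            theta[pos] = brute_theta(x, pos)
    for pos in range(2, n - 1):
        if any(b in trace.breaks for b in (pos - 1, pos, pos + 1)):
            gamma[pos] = None
        else:
            gamma[pos] = brute_gamma(x, pos)
    return x, theta, gamma


def brute_assign(trace, params):
    """Full-enumeration assignment: every helix window, every duplet pair.

    Returns a code string identical in semantics to the library output.
    """
    x, theta, gamma = _angles_with_breaks(trace)
    n = len(x)

    def t_ok(pos, lo, hi):
        v = theta.get(pos)
        return v is not None and lo <= v <= hi

    def g_in(pos, lo, hi):
        v = gamma.get(pos)
        return v is not None and lo <= v <= hi

    def g_abs(pos, m):
        v = gamma.get(pos)
        return v is not None and abs(v) > m

    hlo, hhi = params.helix_theta
    glo, ghi = params.helix_gamma
    helix = set()
    for k in range(2, n - 3):
        if all(t_ok(k + j, hlo, hhi) for j in range(4)) and \
                g_in(k + 1, glo, ghi) and g_in(k + 2, glo, ghi):
            helix.update(range(k, k + 4))

    slo, shi = params.sheet_theta
    sheet = set()
    for k in range(2, n - 1):
        if k in trace.breaks:
            continue
        if any(p in helix for p in (k, k + 1)):
            continue
        if not (t_ok(k, slo, shi) and t_ok(k + 1, slo, shi)
                and g_abs(k, params.sheet_gamma_abs_min)):
            continue
        for i in range(k + params.min_seq_separation, n - 1):
            if i in trace.breaks or i + 2 > n:
                continue
            if any(p in helix for p in (i, i + 1)):
                continue
            if not (t_ok(i, slo, shi) and t_ok(i + 1, slo, shi)
                    and g_abs(i, params.sheet_gamma_abs_min)):
                continue
            par = (_dist(x[k - 1], x[i - 1]) < params.d_pair_max
                   and _dist(x[k], x[i]) < params.d_pair_max
                   and _dist(x[k], x[i + 1]) < params.d_diag_max)
            anti = (_dist(x[k - 1], x[i]) < params.d_pair_max
                    and _dist(x[k], x[i - 1]) < params.d_pair_max
                    and _dist(x[k - 1], x[i + 1]) < params.d_diag_max)
            if par or anti:
                sheet.update((k, k + 1, i, i + 1))

    codes = []
    for pos in range(1, n + 1):
        if pos in helix:
            codes.append("H")
        elif pos in sheet:
            codes.append("E")
        else:
            codes.append("C")
    return "".join(codes)


def random_small_trace(rng, max_len=30):
    """A random short trace drawn from the generator zoo (used by the
    oracle-equivalence checks)."""
    from cutabi.synthetic import (Segment, SegmentPlan, build_chimera,
                                  build_coil, build_hairpin, build_helix)
    kind = rng.integers(0, 4)
    if kind == 0:
        n = int(rng.integers(3, max_len + 1))
        trace, _ = build_helix(n)
    elif kind == 1:
        L = int(rng.integers(2, (max_len - 2) // 2 + 1))
        trace, _ = build_hairpin(L)
    elif kind == 2:
        n = int(rng.integers(3, max_len + 1))
        trace, _ = build_coil(n, seed=rng)
    else:
        plan = SegmentPlan((Segment("helix", int(rng.integers(5, 10))),
                            Segment("coil", int(rng.integers(3, 7))),
                            Segment("strand-pair", int(rng.integers(2, 5)))),
                           noise_sigma=float(rng.uniform(0, 0.25)))
        trace, _ = build_chimera(plan, rng=rng)
    return trace
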