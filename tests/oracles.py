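"""Independent reference implementations used to check the package.

Everything here deliberately avoids the package's own code paths: circuit
evaluation uses scalar ``cmath`` in admittance form, the ROC oracle
enumerates every distinct threshold with plain loops, and the combination
oracle enumerates every derangement.
"""

from __future__ import annotations

import cmath
import itertools
import math


def zblock_admittance(rs: float, rp: float, cp: float, f: float) -> complex:
    """Z-block impedance via the admittance of the parallel branch."""
    return rs + 1.0 / (1.0 / rp + 1j * 2.0 * math.pi * f * cp)


def pair_total_magnitude(blocks, f: float) -> float:
    """|Z1 + (Z2 || Z3) + Z4| with the parallel section via admittances.

    ``blocks`` is a sequence of four (rs, rp, cp) triples.
    """
    z1, z2, z3, z4 = (zblock_admittance(*b, f) for b in blocks)
    parallel = 1.0 / (1.0 / z2 + 1.0 / z3)
    return abs(z1 + parallel + z4)


def brute_force_roc(genuine, impostor):
    """(EER fraction, AUC) by exhaustive threshold enumeration.

    Sweeps every distinct score plus a sentinel above the maximum; FAR(t)
    is the impostor fraction >= t and FRR(t) the genuine fraction < t.
    The EER interpolates linearly across the bracketing thresholds; the
    AUC sums trapezoids under the (FAR, 1-FRR) polyline.
    """
    scores = sorted(set(genuine) | set(impostor))
    thresholds = scores + [scores[-1] + 1.0]
    points = []
    for t in thresholds:
        far = sum(1 for s in impostor if s >= t) / len(impostor)
        frr = sum(1 for s in genuine if s < t) / len(genuine)
        points.append((far, frr))

    eer = None
    for (far1, frr1), (far2, frr2) in zip(points, points[1:]):
        d1, d2 = far1 - frr1, far2 - frr2
        if d1 >= 0 and d2 <= 0:
            w = 0.0 if d1 == d2 else d1 / (d1 - d2)
            eer = far1 + w * (far2 - far1)
            break
    assert eer is not None

    curve = sorted((far, 1.0 - frr) for far, frr in points)
    auc = 0.0
    for (x1, y1), (x2, y2) in zip(curve, curve[1:]):
        auc += (x2 - x1) * (y1 + y2) / 2.0
    return eer, auc


def brute_force_balanced_derangement(means):
    """Optimal derangement by full enumeration (small n only).

    Returns (lexicographically smallest arg-min, optimal objective).
    """
    n = len(means)
    best_obj, best_sigma = None, None
    for sigma in itertools.permutations(range(n)):
        if any(sigma[i] == i for i in range(n)):
            continue
        obj = sum((means[i] - means[sigma[i]]) ** 2 for i in range(n))
        if best_obj is None or obj < best_obj - 1e-12 * max(1.0, abs(obj)):
            best_obj, best_sigma = obj, sigma
    return best_sigma, best_obj


def enumerate_optimal_derangements(means, rtol=1e-9):
    """All derangements whose objective ties the optimum (small n only)."""
    _, best = brute_force_balanced_derangement(means)
    tol = rtol * max(1.0, abs(best))
    n = len(means)
    out = []
    for sigma in itertools.permutations(range(n)):
        if any(sigma[i] == i for i in range(n)):
            continue
        obj = sum((means[i] - means[sigma[i]]) ** 2 for i in range(n))
        if obj <= best + tol:
            out.append(sigma)
    return out
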