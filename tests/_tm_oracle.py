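"""Independent TM-score re-implementation used as a test oracle.

Deliberately written on a different numerical route from the library:
quaternion (Horn) absolute-orientation superposition instead of SVD
Kabsch, and plain-Python seed iteration. Kept free of imports from the
package so the two paths share no code.
"""

import numpy as np


def horn_superpose(mobile, target):
    """Optimal rotation via the eigenvector of Horn's 4x4 quaternion matrix."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    b = target - tc
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(K)
    q = vecs[:, np.argmax(vals)]
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - target) ** 2).sum() / len(mobile)))
    return R, t, rmsd


def oracle_d0(length):
    if length > 15:
        return max(1.24 * (length - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def oracle_tm(query_ca, template_ca, d0_reference_length=None):
    """Fixed-alignment TM-score by exhaustive seed-fragment iteration."""
    q = np.asarray(query_ca, float)
    t = np.asarray(template_ca, float)
    L = len(q)
    d0 = oracle_d0(L if d0_reference_length is None else d0_reference_length)
    best = 0.0
    sl = L
    lengths = []
    while sl >= 4:
        lengths.append(sl)
        sl //= 2
    for seg in lengths:
        for start in range(L - seg + 1):
            subset = list(range(start, start + seg))
            prev = None
            for _ in range(20):
                if len(subset) < 3:
                    break
                R, tr, _ = horn_superpose(q[subset], t[subset])
                moved = q @ R.T + tr
                d = np.sqrt(((moved - t) ** 2).sum(axis=1))
                tm = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
                best = max(best, tm)
                cut = d0
                new = [i for i in range(L) if d[i] < cut]
                while len(new) < 3:
                    cut += 0.5
                    new = [i for i in range(L) if d[i] < cut]
                if prev is not None and new == prev:
                    break
                prev = subset
                subset = new
    return min(best, 1.0)
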