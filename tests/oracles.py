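"""Independent brute-force reference implementations used as oracles.

Everything here is written with explicit loops, explicit sorting and a
pseudo-inverse solve, deliberately sharing no code path with the package
implementations it checks.
"""

import math

import numpy as np


def brute_simplex(lib_rows, lib_targets, lib_times, q_rows, q_times,
                  exclude_same_time=False):
    """Explicit-loop simplex projection (E+1 neighbors, exp weights)."""
    lib_rows = np.asarray(lib_rows, dtype=float)
    q_rows = np.asarray(q_rows, dtype=float)
    k = lib_rows.shape[1] + 1
    out = []
    for qi in range(len(q_rows)):
        cand = []
        for j in range(len(lib_rows)):
            if exclude_same_time and lib_times[j] == q_times[qi]:
                continue
            d = math.sqrt(sum((lib_rows[j, m] - q_rows[qi, m]) ** 2
                              for m in range(lib_rows.shape[1])))
            cand.append((d, j))
        cand.sort(key=lambda t: (t[0], t[1]))
        nbrs = cand[:k]
        d1 = nbrs[0][0]
        if d1 == 0.0:
            ws = [1.0 if d == 0.0 else 0.0 for d, _ in nbrs]
        else:
            ws = [math.exp(-d / d1) for d, _ in nbrs]
        num = sum(w * lib_targets[j] for w, (_, j) in zip(ws, nbrs))
        out.append(num / sum(ws))
    return np.array(out)


def brute_smap(lib_rows, lib_targets, lib_times, q_rows, q_times, theta,
               exclude_same_time=False):
    """Explicit-loop S-map: exp(-theta*d/dbar) weights, pinv solve."""
    lib_rows = np.asarray(lib_rows, dtype=float)
    q_rows = np.asarray(q_rows, dtype=float)
    dim = lib_rows.shape[1]
    preds, coefs = [], []
    for qi in range(len(q_rows)):
        idx = [j for j in range(len(lib_rows))
               if not (exclude_same_time and lib_times[j] == q_times[qi])]
        ds = [math.sqrt(sum((lib_rows[j, m] - q_rows[qi, m]) ** 2
                            for m in range(dim))) for j in idx]
        if theta == 0.0:
            ws = [1.0] * len(idx)
        else:
            dbar = sum(ds) / len(ds)
            ws = [math.exp(-theta * d / dbar) for d in ds]
        A = np.array([[lib_rows[j, m] for m in range(dim)] + [1.0]
                      for j in idx])
        b = np.array([lib_targets[j] for j in idx])
        sw = np.sqrt(np.array(ws))
        beta = np.linalg.pinv(A * sw[:, None], rcond=1e-10) @ (b * sw)
        coefs.append(beta)
        preds.append(float(np.dot(q_rows[qi], beta[:dim]) + beta[dim]))
    return np.array(preds), np.array(coefs)


def brute_map_lyapunov(step_fn, x0s, delta0=1e-8, n_steps=15):
    """Mean log-divergence rate of twin trajectories of a 1-D map."""
    lams = []
    for x0 in x0s:
        x, xp = x0, x0 + delta0
        for _ in range(n_steps):
            x, xp = step_fn(x), step_fn(xp)
        if x != xp:
            lams.append(math.log(abs(x - xp) / delta0) / n_steps)
    return float(np.mean(lams))
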