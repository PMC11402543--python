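"""Independent straight-loop reference implementations used as test oracles.

These transcribe the defining formulas directly with plain Python loops and
no vectorization, sharing only the documented conventions (initialisation,
fixed prior, probability clamping, stopping rule) with the package.
"""

import math

import numpy as np

CLAMP = 1e-6


def reference_staple(decision_lists, prior=None, max_iterations=200, tolerance=1e-7):
    """Plain-loop binary STAPLE EM.

    ``decision_lists`` is a list of per-observer flat 0/1 decision sequences.
    Returns (W, p, q, iterations, converged).
    """
    n_obs = len(decision_lists)
    n_vox = len(decision_lists[0])
    d = [[int(v) for v in obs] for obs in decision_lists]
    if prior is None:
        prior = sum(sum(obs) for obs in d) / (n_obs * n_vox)
        prior = min(prior, 1.0 - CLAMP)
    W = [sum(d[j][i] for j in range(n_obs)) / n_obs for i in range(n_vox)]
    p = [0.5] * n_obs
    q = [0.5] * n_obs
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        w_sum = sum(W)
        c_sum = n_vox - w_sum
        for j in range(n_obs):
            num_p = sum(W[i] * d[j][i] for i in range(n_vox))
            num_q = sum((1.0 - W[i]) * (1 - d[j][i]) for i in range(n_vox))
            p[j] = min(max(num_p / max(w_sum, CLAMP), CLAMP), 1.0 - CLAMP)
            q[j] = min(max(num_q / max(c_sum, CLAMP), CLAMP), 1.0 - CLAMP)
        change = 0.0
        W_new = [0.0] * n_vox
        for i in range(n_vox):
            log_a = math.log(prior)
            log_b = math.log(1.0 - prior)
            for j in range(n_obs):
                if d[j][i]:
                    log_a += math.log(p[j])
                    log_b += math.log(1.0 - q[j])
                else:
                    log_a += math.log(1.0 - p[j])
                    log_b += math.log(q[j])
            m = max(log_a, log_b)
            a = math.exp(log_a - m)
            b = math.exp(log_b - m)
            W_new[i] = a / (a + b)
            change += abs(W_new[i] - W[i])
        change /= n_vox
        W = W_new
        if change < tolerance:
            converged = True
            break
    return np.array(W), np.array(p), np.array(q), iterations, converged


def brute_force_dice(a_values, b_values):
    """Dice via explicit voxel counting loops."""
    na = nb = ni = 0
    for av, bv in zip(a_values.ravel(), b_values.ravel()):
        na += bool(av)
        nb += bool(bv)
        ni += bool(av) and bool(bv)
    return 2.0 * ni / (na + nb)


def brute_force_coverage(gtv_values, lesion_values):
    nl = ni = 0
    for gv, lv in zip(gtv_values.ravel(), lesion_values.ravel()):
        nl += bool(lv)
        ni += bool(gv) and bool(lv)
    return ni / nl


def brute_force_expand(mask, radius_mm):
    """Margin expansion by all-pairs voxel-center distance check."""
    grid = mask.grid
    fg = np.argwhere(mask.values)
    out = np.zeros(grid.shape, dtype=bool)
    spacing = np.asarray(grid.spacing_mm)
    for idx in np.ndindex(grid.shape):
        pt = np.asarray(idx) * spacing
        for f in fg:
            if np.linalg.norm(pt - f * spacing) <= radius_mm + 1e-9:
                out[idx] = True
                break
    return out


def lesion_components_oracle(delineations):
    """Union-find over the delineation graph (consecutive-slice in-plane overlap)."""
    n = len(delineations)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(n):
            if delineations[j].slice_index == delineations[i].slice_index + 1 and np.any(
                delineations[i].region & delineations[j].region
            ):
                union(i, j)
    roots = [find(i) for i in range(n)]
    ids = {}
    labels = []
    for r in roots:
        if r not in ids:
            ids[r] = len(ids) + 1
        labels.append(ids[r])
    return labels
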