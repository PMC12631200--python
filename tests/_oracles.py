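"""Independent brute-force oracles used by unit and acceptance tests."""

import itertools

import numpy as np


def brute_force_isic(X, y):
    """Scalar-loop ISIC: mean over unordered class pairs of
    (sd_z + sd_j) / |mean_z - mean_j| per band, +inf on coincident means."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    B = X.shape[1]
    out = np.zeros(B)
    pairs = list(itertools.combinations(classes, 2))
    for i in range(B):
        total = 0.0
        for a, b in pairs:
            va, vb = X[y == a, i], X[y == b, i]
            sep = abs(va.mean() - vb.mean())
            spread = va.std(ddof=1) + vb.std(ddof=1)
            scale = max(abs(va.mean()), abs(vb.mean()), spread)
            if sep <= 1e-12 * scale:
                total = np.inf
                break
            total += spread / sep
        out[i] = total / len(pairs)
    return out


def brute_force_spa(X, start, k_max, tol=1e-10):
    """SPA chain via explicit Gram-Schmidt at every step.

    Residual of each candidate column is recomputed from scratch against
    an orthonormal basis of the selected columns.
    """
    X = np.asarray(X, dtype=float)
    n, B = X.shape
    k_max = min(k_max, B, n)
    scale = max(np.linalg.norm(X, axis=0).max(), 1.0)
    chain = [start]
    basis = []
    v = X[:, start].astype(float)
    for q in basis:
        v = v - (q @ v) * q
    if np.linalg.norm(v) > tol * scale:
        basis.append(v / np.linalg.norm(v))
    else:
        return []
    while len(chain) < k_max:
        best_norm, best_j = -1.0, None
        for j in range(B):
            if j in chain:
                continue
            r = X[:, j].astype(float)
            for q in basis:
                r = r - (q @ r) * q
            nrm = np.linalg.norm(r)
            if nrm > best_norm + 1e-15:
                best_norm, best_j = nrm, j
        if best_j is None or best_norm <= tol * scale:
            break
        chain.append(best_j)
        r = X[:, best_j].astype(float)
        for q in basis:
            r = r - (q @ r) * q
        basis.append(r / np.linalg.norm(r))
    return chain


def residual_norms_along_chain(X, chain):
    """Residual norm of each chain element at the moment it was picked."""
    X = np.asarray(X, dtype=float)
    norms, basis = [], []
    for j in chain:
        r = X[:, j].astype(float)
        for q in basis:
            r = r - (q @ r) * q
        norms.append(np.linalg.norm(r))
        basis.append(r / np.linalg.norm(r))
    return norms
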