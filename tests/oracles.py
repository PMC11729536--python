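"""Independent oracles used to validate the package's fast implementations.

These deliberately avoid the package's m-array code paths: the likelihood
oracle enumerates latent death times individual by individual, and the
m-array oracle is a direct pairwise scan over the detection matrix.
"""

from __future__ import annotations

import numpy as np


def latent_fate_nll(matrix, phi, p_seen, p_unseen):
    """Exhaustive-enumeration negative log-likelihood of 0/1 histories.

    For each individual, sums over every latent "last occasion alive"
    compatible with the observed detections, conditioning on first capture.
    ``phi[u]`` is survival over interval u (occasion u -> u+1, 0-based);
    ``p_seen[u]`` / ``p_unseen[u]`` are detection probabilities at occasion
    u+1 given detection state at occasion u.
    """
    X = np.asarray(matrix, int)
    phi = np.asarray(phi, float)
    ps = np.asarray(p_seen, float)
    pu = np.asarray(p_unseen, float)
    n_occ = X.shape[1]
    total = 0.0
    for y in X:
        f = int(np.argmax(y))
        last_det = int(np.max(np.nonzero(y)[0]))
        lik = 0.0
        for a in range(last_det, n_occ):  # last occasion alive
            surv = np.prod(phi[f:a])
            death = (1.0 - phi[a]) if a < n_occ - 1 else 1.0
            det = 1.0
            for j in range(f + 1, a + 1):
                p = ps[j - 1] if y[j - 1] == 1 else pu[j - 1]
                det *= p if y[j] == 1 else (1.0 - p)
            lik += surv * death * det
        total += np.log(lik)
    return -total


def classic_cjs_nll(marray_releases, marray_m, phi, p):
    """Multinomial CJS negative log-likelihood without trap structure.

    ``marray_m[i, j]`` counts releases at occasion i (0-based) next detected
    at occasion j; ``p[u]`` is detection at occasion u+1.
    """
    phi = np.asarray(phi, float)
    p = np.asarray(p, float)
    T = len(phi)
    nll = 0.0
    for i in range(T):
        if marray_releases[i] == 0:
            continue
        cell_sum = 0.0
        for j in range(i + 1, T + 1):
            prob = np.prod(phi[i:j]) * np.prod(1.0 - p[i : j - 1]) * p[j - 1]
            cell_sum += prob
            if marray_m[i, j] > 0:
                nll -= marray_m[i, j] * np.log(prob)
        never = marray_releases[i] - marray_m[i, i + 1 :].sum()
        if never > 0:
            nll -= never * np.log(1.0 - cell_sum)
    return nll


def marray_pairwise_scan(matrix):
    """Direct O(n * T^2) m-array: for every individual and every detection
    before the final occasion, find the next detection."""
    X = np.asarray(matrix, int)
    n_occ = X.shape[1]
    releases = np.zeros(n_occ, int)
    m = np.zeros((n_occ, n_occ), int)
    for y in X:
        occs = np.nonzero(y)[0]
        for k, i in enumerate(occs):
            if i == n_occ - 1:
                continue
            releases[i] += 1
            if k + 1 < len(occs):
                m[i, occs[k + 1]] += 1
    return releases, m


def pearson_chi2_by_hand(table):
    table = np.asarray(table, float)
    n = table.sum()
    e = np.outer(table.sum(1), table.sum(0)) / n
    return float(((table - e) ** 2 / e).sum())
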