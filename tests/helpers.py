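"""Independent oracles used by the test suite.

These deliberately share no code with the package's solvers: a
closed-form piecewise-constant solution of the screened Stokes equation
(matrix of exponentials with flux matching), and an exhaustive
enumeration of short self-avoiding walks on the cubic lattice.
"""

from __future__ import annotations

import numpy as np

NM = 1e-9
V_PER_NM = 1e9


def solve_piecewise_constant_bvp(boundaries, mu_segs, c_segs, f_segs):
    """Exact solution of (mu u')' - c u + f = 0 with piecewise-constant
    mu, c, f on segments [x_k, x_{k+1}]; u(0) = 0, u'(L) = 0.

    ``boundaries`` are the K+1 segment edges in meters starting at 0.
    Returns a callable u(x). Per segment the general solution is
    A e^{lam xi} + B e^{-lam xi} + f/c (xi measured from the segment
    start; lam = sqrt(c/mu)), or A + B xi - f xi^2 / (2 mu) when c = 0;
    coefficients follow from continuity of u and of the flux mu u'.
    """
    K = len(mu_segs)
    assert len(boundaries) == K + 1
    M = np.zeros((2 * K, 2 * K))
    rhs = np.zeros(2 * K)

    def basis(k, xi):
        """(u_A, u_B, u'_A, u'_B, u_part, u'_part) at local coordinate xi."""
        mu, c, f = mu_segs[k], c_segs[k], f_segs[k]
        if c > 0:
            lam = np.sqrt(c / mu)
            ep, em = np.exp(lam * xi), np.exp(-lam * xi)
            return ep, em, lam * ep, -lam * em, f / c, 0.0
        return 1.0, xi, 0.0, 1.0, -f * xi**2 / (2 * mu), -f * xi / mu

    row = 0
    # u(0) = 0
    uA, uB, _, _, up, _ = basis(0, 0.0)
    M[row, 0], M[row, 1] = uA, uB
    rhs[row] = -up
    row += 1
    # interface continuity of u and mu u'
    for k in range(K - 1):
        xiL = boundaries[k + 1] - boundaries[k]
        uA, uB, dA, dB, up, dp = basis(k, xiL)
        uA2, uB2, dA2, dB2, up2, dp2 = basis(k + 1, 0.0)
        M[row, 2 * k], M[row, 2 * k + 1] = uA, uB
        M[row, 2 * k + 2], M[row, 2 * k + 3] = -uA2, -uB2
        rhs[row] = up2 - up
        row += 1
        M[row, 2 * k], M[row, 2 * k + 1] = mu_segs[k] * dA, mu_segs[k] * dB
        M[row, 2 * k + 2], M[row, 2 * k + 3] = -mu_segs[k + 1] * dA2, -mu_segs[k + 1] * dB2
        rhs[row] = mu_segs[k + 1] * dp2 - mu_segs[k] * dp
        row += 1
    # u'(L) = 0
    xiL = boundaries[K] - boundaries[K - 1]
    _, _, dA, dB, _, dp = basis(K - 1, xiL)
    M[row, 2 * K - 2], M[row, 2 * K - 1] = dA, dB
    rhs[row] = -dp

    coef = np.linalg.solve(M, rhs)

    def u(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty_like(x)
        for i, xi in enumerate(x):
            k = min(np.searchsorted(boundaries, xi, side="right") - 1, K - 1)
            k = max(k, 0)
            local = xi - boundaries[k]
            uA, uB, _, _, up, _ = basis(k, local)
            out[i] = coef[2 * k] * uA + coef[2 * k + 1] * uB + up
        return out

    return u


def segments_to_nodes(z_nm, width_nm, face_fracs, values):
    """Sample piecewise-constant segment values (segments of the half
    slit [0, w/2] delimited at fractions ``face_fracs`` of w/2) onto the
    full-slit node grid, mirrored about the midpoint."""
    half = width_nm / 2.0
    edges = np.concatenate([[0.0], np.asarray(face_fracs) * half, [half]])
    d = np.minimum(z_nm, width_nm - z_nm)  # distance to nearest wall
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(values) - 1)
    return np.asarray(values)[idx]


def enumerate_saw_rg2(n_steps):
    """Mean squared gyration radius over ALL n-step cubic-lattice SAWs,
    by exhaustive depth-first enumeration. Returns (count, mean_rg2)."""
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    total = 0
    rg2_sum = 0.0

    def rg2(path):
        arr = np.array(path, dtype=float)
        c = arr.mean(axis=0)
        return float(np.mean(np.sum((arr - c) ** 2, axis=1)))

    def dfs(path, visited):
        nonlocal total, rg2_sum
        if len(path) == n_steps + 1:
            total += 1
            rg2_sum += rg2(path)
            return
        x, y, z = path[-1]
        for dx, dy, dz in steps:
            nxt = (x + dx, y + dy, z + dz)
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(path, visited)
                path.pop()
                visited.remove(nxt)

    dfs([(0, 0, 0)], {(0, 0, 0)})
    return total, rg2_sum / total
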