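"""Independent numerical oracles used by the test suite.

Everything here is implemented from first principles, deliberately on a
different route than the package code it checks:

* a Biot-Savart oracle for the conducting-sphere forward field
  (primary dipole term plus the Geselowitz surface integral over the
  boundary potential, the latter from a Legendre-series solution of the
  insulated-sphere Neumann problem);
* a dense normal-equations solve of the penalized least-squares problem
  behind the minimum-norm inverse;
* full enumeration of the Kruskal-Wallis permutation null from rank sums;
* the classical rank-difference formula for Spearman correlation.
"""

from __future__ import annotations

import itertools

import numpy as np

MU0_OVER_4PI = 1e-7


# ---------------------------------------------------------------------------
# forward-model oracle


def _legendre_and_deriv(nmax: int, u: np.ndarray):
    """P_n(u) and P_n'(u) for n = 0..nmax via stable recurrences."""
    p = np.empty((nmax + 1,) + u.shape)
    dp = np.empty_like(p)
    p[0] = 1.0
    dp[0] = 0.0
    if nmax >= 1:
        p[1] = u
        dp[1] = 1.0
    for n in range(1, nmax):
        p[n + 1] = ((2 * n + 1) * u * p[n] - n * p[n - 1]) / (n + 1)
        dp[n + 1] = (n + 1) * p[n] + u * dp[n]
    return p, dp


def sphere_surface_potential(
    surf_points: np.ndarray,
    r0_vec: np.ndarray,
    q_vec: np.ndarray,
    radius: float,
    nmax: int = 80,
    sigma: float = 1.0,
) -> np.ndarray:
    """Electric potential on an insulated homogeneous conducting sphere.

    Dipole ``q_vec`` (A*m) at ``r0_vec`` inside a sphere of ``radius``;
    the boundary condition dV/dr = 0 at the surface gives the series

        V = 1/(4 pi sigma) sum_n (2n+1)/n r0^(n-1)/R^(n+1)
            [ n q_r P_n(u) + q_t sin(gamma) cos(phi) P_n'(u) ]

    with u = cos(gamma) the cosine of the angle to the dipole axis and
    phi the azimuth about it measured from the tangential moment.
    """
    r0 = np.linalg.norm(r0_vec)
    e3 = r0_vec / r0
    q_r = float(q_vec @ e3)
    q_t_vec = q_vec - q_r * e3
    q_t = np.linalg.norm(q_t_vec)
    e1 = q_t_vec / q_t if q_t > 0 else np.zeros(3)
    w_hat = surf_points / radius
    u = w_hat @ e3
    x1 = w_hat @ e1  # sin(gamma) cos(phi)
    p, dp = _legendre_and_deriv(nmax, u)
    v = np.zeros(len(surf_points))
    for n in range(1, nmax + 1):
        coef = (2 * n + 1) / n * r0 ** (n - 1) / radius ** (n + 1)
        v += coef * (n * q_r * p[n] + q_t * x1 * dp[n])
    return v / (4.0 * np.pi * sigma)


def fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def biot_savart_sphere_field(
    sensor: np.ndarray,
    r0_vec: np.ndarray,
    q_vec: np.ndarray,
    radius: float,
    n_quad: int = 20000,
    nmax: int = 80,
) -> np.ndarray:
    """Numerical field of a dipole in a conducting sphere (center at 0).

    Primary Biot-Savart term of the point current dipole plus the volume
    current contribution reduced to a surface integral over the boundary
    potential (Geselowitz), evaluated on a Fibonacci quadrature grid.
    """
    sensor = np.asarray(sensor, dtype=float)
    d = sensor - r0_vec
    b_primary = MU0_OVER_4PI * np.cross(q_vec, d) / np.linalg.norm(d) ** 3
    w = radius * fibonacci_sphere(n_quad)
    v = sphere_surface_potential(w, r0_vec, q_vec, radius, nmax=nmax)
    ds = 4.0 * np.pi * radius**2 / n_quad
    rw = sensor[None, :] - w
    kern = rw / np.linalg.norm(rw, axis=1)[:, None] ** 3
    n_hat = w / radius
    b_volume = -MU0_OVER_4PI * (np.cross(n_hat, kern) * v[:, None]).sum(axis=0) * ds
    return b_primary + b_volume


# ---------------------------------------------------------------------------
# inverse oracle


def penalized_least_squares_solve(
    gain: np.ndarray,
    noise_cov: np.ndarray,
    lambda2: float,
    weights: np.ndarray,
    data: np.ndarray,
) -> np.ndarray:
    """Direct normal-equations solve of the regularized source estimate.

    Minimizes ||C^(-1/2)(b - G s)||^2 + lambda2 ||R^(-1/2) s||^2 with the
    same trace-normalized prior R = nu diag(w) convention as the package:
    (G' C^(-1) G + lambda2 R^(-1)) s = G' C^(-1) b.
    """
    c_inv = np.linalg.inv(noise_cov)
    lw = np.linalg.cholesky(c_inv).T @ gain  # any C^(-1/2); only L'L matters
    nu = gain.shape[0] / float(weights @ np.einsum("ij,ij->j", lw, lw))
    r_inv = np.diag(1.0 / (nu * weights))
    lhs = gain.T @ c_inv @ gain + lambda2 * r_inv
    rhs = gain.T @ c_inv @ data
    return np.linalg.solve(lhs, rhs)


# ---------------------------------------------------------------------------
# rank-statistics oracles


def kw_h_statistic(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H from explicit rank sums (no tie correction)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)


def kw_exact_null_distribution(sizes: tuple[int, int, int]) -> np.ndarray:
    """All H values over the distinct partitions of ranks 1..N into groups.

    For tie-free data the permutation null of H depends only on the group
    sizes, so this distribution serves every continuous instance.
    """
    n = sum(sizes)
    ranks = np.arange(1, n + 1, dtype=float)
    total = ranks.sum()
    values = []
    idx = list(range(n))
    for c1 in itertools.combinations(idx, sizes[0]):
        s1 = ranks[list(c1)].sum()
        rest = [i for i in idx if i not in set(c1)]
        for c2 in itertools.combinations(rest, sizes[1]):
            s2 = ranks[list(c2)].sum()
            s3 = total - s1 - s2
            h = (
                12.0 / (n * (n + 1))
                * (s1**2 / sizes[0] + s2**2 / sizes[1] + s3**2 / sizes[2])
                - 3.0 * (n + 1)
            )
            values.append(h)
    return np.sort(np.asarray(values))


def kw_exact_p(
    h_observed: float, null_distribution: np.ndarray, mid_p: bool = False
) -> float:
    ge = np.mean(null_distribution >= h_observed - 1e-12)
    if mid_p:
        eq = np.mean(np.abs(null_distribution - h_observed) <= 1e-12)
        return float(ge - eq / 2.0)
    return float(ge)


def spearman_rank_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Classical 1 - 6 sum d^2 / (n(n^2-1)) for tie-free data."""
    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        return r

    d = ranks(np.asarray(x)) - ranks(np.asarray(y))
    n = len(d)
    return 1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1))
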