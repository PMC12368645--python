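"""Independent reference implementations used to check the package.

These deliberately avoid the production code paths:

* :func:`trajectory_ascent_labels` — an exhaustive, pure-Python per-voxel
  steepest-ascent walker implementing the documented near-grid stepping
  rule, used to validate the compiled basin-assignment kernel.
* :func:`pearson_r2` — the textbook closed-form squared Pearson
  correlation.
* :func:`analytic_density_sum` — per-term scalar evaluation of a
  Gaussian-atom density with ``math`` only.
"""

from __future__ import annotations

import math


def analytic_density_sum(atoms, point) -> float:
    """Sum of N (a/pi)^{3/2} exp(-a r^2) terms, evaluated term by term."""
    total = 0.0
    for center, population, exponent in atoms:
        r2 = sum((p - c) ** 2 for p, c in zip(point, center))
        total += population * (exponent / math.pi) ** 1.5 * math.exp(-exponent * r2)
    return total


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation from the closed-form sum formula."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return (num / den) ** 2


def _gradient(rho, i, j, k):
    nx, ny, nz = rho.shape
    if i == 0:
        gx = rho[i + 1, j, k] - rho[i, j, k]
    elif i == nx - 1:
        gx = rho[i, j, k] - rho[i - 1, j, k]
    else:
        gx = (rho[i + 1, j, k] - rho[i - 1, j, k]) / 2.0
    if j == 0:
        gy = rho[i, j + 1, k] - rho[i, j, k]
    elif j == ny - 1:
        gy = rho[i, j, k] - rho[i, j - 1, k]
    else:
        gy = (rho[i, j + 1, k] - rho[i, j - 1, k]) / 2.0
    if k == 0:
        gz = rho[i, j, k + 1] - rho[i, j, k]
    elif k == nz - 1:
        gz = rho[i, j, k] - rho[i, j, k - 1]
    else:
        gz = (rho[i, j, k + 1] - rho[i, j, k - 1]) / 2.0
    return gx, gy, gz


def _best_ongrid_neighbor(rho, i, j, k):
    """Steepest higher 26-neighbor; ties broken by lowest linear index."""
    nx, ny, nz = rho.shape
    rv = rho[i, j, k]
    best_score = -1.0
    best = None
    best_lin = -1
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                ni, nj, nk = i + di, j + dj, k + dk
                if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz):
                    continue
                rn = rho[ni, nj, nk]
                if rn <= rv:
                    continue
                dist = math.sqrt(float(di * di + dj * dj + dk * dk))
                score = (rn - rv) / dist
                lin = (ni * ny + nj) * nz + nk
                if score > best_score or (score == best_score and lin < best_lin):
                    best_score = score
                    best = (ni, nj, nk)
                    best_lin = lin
    return best


def _walk(rho, start):
    """Full near-grid trajectory from one voxel to its local maximum."""
    i, j, k = start
    nx, ny, nz = rho.shape
    cx = cy = cz = 0.0
    while True:
        best = _best_ongrid_neighbor(rho, i, j, k)
        if best is None:
            return (i, j, k)
        gx, gy, gz = _gradient(rho, i, j, k)
        gmax = max(abs(gx), abs(gy), abs(gz))
        accepted = False
        if gmax > 0.0:
            px, py, pz = gx / gmax, gy / gmax, gz / gmax
            si = int(math.floor(px + 0.5))
            sj = int(math.floor(py + 0.5))
            sk = int(math.floor(pz + 0.5))
            cx += px - si
            cy += py - sj
            cz += pz - sk
            if cx > 0.5:
                si += 1
                cx -= 1.0
            elif cx < -0.5:
                si -= 1
                cx += 1.0
            if cy > 0.5:
                sj += 1
                cy -= 1.0
            elif cy < -0.5:
                sj -= 1
                cy += 1.0
            if cz > 0.5:
                sk += 1
                cz -= 1.0
            elif cz < -0.5:
                sk -= 1
                cz += 1.0
            ti, tj, tk = i + si, j + sj, k + sk
            if (
                (si, sj, sk) != (0, 0, 0)
                and 0 <= ti < nx
                and 0 <= tj < ny
                and 0 <= tk < nz
                and rho[ti, tj, tk] > rho[i, j, k]
            ):
                i, j, k = ti, tj, tk
                accepted = True
        if not accepted:
            i, j, k = best
            cx = cy = cz = 0.0


def trajectory_ascent_labels(rho, grid_origin, spacing, nuclei_positions, density_floor):
    """Exhaustive per-voxel trajectory ascent; mirrors the production rule.

    Returns an int array like ``assign_basins``: 0 below the floor,
    otherwise the 1-based index of the nearest nucleus to the trajectory's
    terminal maximum (in voxel coordinates).
    """
    import numpy as np

    nx, ny, nz = rho.shape
    labels = np.zeros(rho.shape, dtype=int)
    nuc_vox = [
        tuple((p - o) / spacing for p, o in zip(pos, grid_origin))
        for pos in nuclei_positions
    ]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if rho[i, j, k] < density_floor:
                    continue
                ti, tj, tk = _walk(rho, (i, j, k))
                best_d = math.inf
                best_n = 1
                for a, (vx, vy, vz) in enumerate(nuc_vox):
                    d2 = (ti - vx) ** 2 + (tj - vy) ** 2 + (tk - vz) ** 2
                    if d2 < best_d:
                        best_d = d2
                        best_n = a + 1
                labels[i, j, k] = best_n
    return labels
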