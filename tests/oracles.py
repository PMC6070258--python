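"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here re-derives a quantity from its textbook definition with
plain loops (or an exhaustive search), deliberately sharing no code with the
package implementation it checks.
"""

import numpy as np


def covariance_brute(coords: np.ndarray) -> np.ndarray:
    """3N x 3N covariance by an explicit double loop over coordinate pairs."""
    flat = coords.reshape(coords.shape[0], -1)
    nf, dim = flat.shape
    mean = np.array([flat[:, i].sum() / nf for i in range(dim)])
    cov = np.zeros((dim, dim))
    for i in range(dim):
        for j in range(dim):
            s = 0.0
            for f in range(nf):
                s += (flat[f, i] - mean[i]) * (flat[f, j] - mean[j])
            cov[i, j] = s / nf
    return cov


def dccm_brute(coords: np.ndarray) -> np.ndarray:
    """Normalized displacement-vector cross-correlations, per definition."""
    nf, na, _ = coords.shape
    mean = coords.sum(axis=0) / nf
    c = np.zeros((na, na))
    for i in range(na):
        for j in range(na):
            s = 0.0
            for f in range(nf):
                s += np.dot(coords[f, i] - mean[i], coords[f, j] - mean[j])
            c[i, j] = s / nf
    out = np.zeros((na, na))
    for i in range(na):
        for j in range(na):
            out[i, j] = c[i, j] / np.sqrt(c[i, i] * c[j, j])
    return out


def pearson_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation from raw sums."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def _rotation_from_euler(a: float, b: float, c: float) -> np.ndarray:
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def rmsd_min_grid(mobile: np.ndarray, reference: np.ndarray, n_grid: int = 24) -> float:
    """Minimum RMSD over rotations by grid search + simplex refinement.

    Centers both sets (the optimal translation), scans an Euler-angle grid,
    then polishes the best grid point with Nelder-Mead.  Independent of any
    SVD-based superposition.
    """
    from scipy.optimize import minimize

    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)

    def objective(angles):
        r = _rotation_from_euler(*angles)
        d = a @ r.T - b
        return np.sqrt((d**2).sum(axis=1).mean())

    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    half = np.linspace(0, np.pi, n_grid // 2 + 1)
    best, best_angles = np.inf, None
    for ga in grid:
        for gb in half:
            for gc in grid:
                val = objective((ga, gb, gc))
                if val < best:
                    best, best_angles = val, (ga, gb, gc)
    res = minimize(objective, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    return min(best, res.fun)


def triangle_enm_eigenvalues() -> np.ndarray:
    """Nonzero eigenvalues of the unit-spring equilateral-triangle Hessian.

    Exact symbolic Hessian of E = sum 1/2 (|r_ij| - |r_ij0|)^2 at equilibrium,
    via sympy.
    """
    import sympy as sp

    xs = sp.symbols("x0:9")
    pts0 = [[0, 0, 0], [1, 0, 0], [sp.Rational(1, 2), sp.sqrt(3) / 2, 0]]
    energy = 0
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        d = sp.sqrt(sum((xs[3 * i + a] - xs[3 * j + a]) ** 2 for a in range(3)))
        d0 = sp.sqrt(
            sum((sp.sympify(pts0[i][a]) - pts0[j][a]) ** 2 for a in range(3))
        )
        energy += sp.Rational(1, 2) * (d - d0) ** 2
    hess = sp.hessian(energy, xs)
    subs = {xs[3 * i + a]: pts0[i][a] for i in range(3) for a in range(3)}
    hnum = np.array(hess.subs(subs).evalf(30), dtype=float)
    w = np.linalg.eigvalsh(hnum)
    return np.sort(w[np.abs(w) > 1e-10])


def gaussian_kld_closed_form(mu1: float, s1: float, mu2: float, s2: float) -> float:
    """KLD( N(mu1,s1) || N(mu2,s2) ) closed form."""
    return (
        np.log(s2 / s1) + (s1**2 + (mu1 - mu2) ** 2) / (2 * s2**2) - 0.5
    )
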