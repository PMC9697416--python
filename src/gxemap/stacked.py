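"""Stacked line-by-environment kernel models.

Both the G-by-E association scan and multi-environment GBLUP work on
records stacked over environments with two polygenic terms,

    y = X beta + u + u_GE + eps,
    u ~ N(0, K_g sigma_g^2) repeated across environments,
    u_GE ~ N(0, K_GE sigma_GE^2),  K_GE = K_g within an environment, 0 across,

with homogeneous variances.  When every line is observed in every
environment the covariance is (J_E kron K_g) sigma_g^2 +
(I_E kron K_g) sigma_GE^2 + I sigma_e^2, which the orthonormal pair
(F, U) — F any orthonormal basis with first column 1/sqrt(E), U the
eigenvectors of K_g — rotates to a diagonal matrix.  REML then costs one
pass over n*E scalars per likelihood evaluation and single-marker
generalized-least-squares tests are a few small dot products each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


def minimize_loglik(fun, start: np.ndarray, lo: float, hi: float):
    """Robust minimisation of a cheap low-dimensional -2 log likelihood:
    bounded L-BFGS-B followed by a Nelder-Mead polish (the likelihood has a
    hard invalid region that can defeat gradient line searches)."""
    res = optimize.minimize(
        fun, start, method="L-BFGS-B", bounds=[(lo, hi)] * start.size,
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8, "eps": 1e-6},
    )
    x = res.x if res.fun <= fun(start) else start
    res2 = optimize.minimize(
        fun, x, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    best = min((res.fun, res.x), (res2.fun, np.clip(res2.x, lo, hi)),
               key=lambda t: t[0])
    return best[1], best[0]


def sumzero_basis(E: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^E (E-1 columns)."""
    A = np.eye(E)
    A[:, 0] = 1.0
    Q, _ = np.linalg.qr(A)
    return Q[:, 1:]


@dataclass
class StackedVariances:
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float


class StackedKernelModel:
    """Complete stacked design, rotated to the diagonalizing basis.

    Parameters
    ----------
    Y
        Complete lines x environments table.
    Kg
        Line kinship aligned with ``Y``'s rows.
    X_line
        Optional per-line covariate columns (principal components,
        population contrasts); each is expanded as constant across
        environments.  Environment indicators are always included.
    """

    def __init__(self, Y: pd.DataFrame, Kg: np.ndarray, X_line: np.ndarray | None = None):
        Ymat = Y.to_numpy(dtype=float)
        if np.isnan(Ymat).any():
            raise ValueError("stacked models require a complete line x environment table")
        self.lines = list(Y.index)
        self.envs = list(Y.columns)
        self.n, self.E = Ymat.shape
        lam, U = np.linalg.eigh((np.asarray(Kg, float) + np.asarray(Kg, float).T) / 2.0)
        self.lam = np.maximum(lam, 0.0)
        self.U = U
        A = np.eye(self.E)
        A[:, 0] = 1.0
        F, _ = np.linalg.qr(A)
        if F[0, 0] < 0:
            F[:, 0] = -F[:, 0]
        self.F = F  # first column = 1/sqrt(E)

        self.Yt = (F.T @ Ymat.T @ U)              # E x n, rotated
        self.yt = self.Yt.ravel()                  # e-major flattening

        cols, names = [], []
        for j in range(self.E):
            ej = np.zeros(self.E)
            ej[j] = 1.0
            cols.append(np.outer(F.T @ ej, np.ones(self.n) @ U).ravel())
            names.append(f"env[{self.envs[j]}]")
        if X_line is not None:
            X_line = np.atleast_2d(np.asarray(X_line, float))
            if X_line.shape[0] != self.n:
                X_line = X_line.T
            for c in range(X_line.shape[1]):
                cols.append(self.rotate_rank1(np.ones(self.E), X_line[:, c]))
                names.append(f"cov{c}")
        self.Xt = np.column_stack(cols)
        self.x_names = names
        if np.linalg.matrix_rank(self.Xt) < self.Xt.shape[1]:
            bad = ", ".join(names)
            raise ValueError(f"singular fixed-effect design (columns: {bad})")
        # eigenvalue pattern per (e, k) cell
        self._lam_grid = np.tile(self.lam, self.E)
        self._is_e0 = np.repeat(np.arange(self.E) == 0, self.n)

    # -- rotation helpers ------------------------------------------------

    def rotate_rank1(self, env_profile: np.ndarray, line_vector: np.ndarray) -> np.ndarray:
        """Rotated flat column of the stacked matrix env_profile x line_vector'."""
        return np.outer(self.F.T @ env_profile, self.U.T @ line_vector).ravel()

    def weights(self, v: StackedVariances) -> np.ndarray:
        return (v.sigma_g2 * self.E * self._is_e0 * self._lam_grid
                + v.sigma_ge2 * self._lam_grid + v.sigma_e2)

    # -- REML ------------------------------------------------------------

    def neg2_reml(self, theta: np.ndarray, include_gxe: bool = True) -> float:
        if include_gxe:
            v = StackedVariances(*np.exp(theta))
        else:
            v = StackedVariances(np.exp(theta[0]), 0.0, np.exp(theta[1]))
        penalty = 1e7 + 1e5 * float(theta @ theta)
        w = self.weights(v)
        if (w <= 0).any():
            return penalty
        d = 1.0 / w
        Xd = self.Xt * d[:, None]
        XdX = self.Xt.T @ Xd
        Xdy = Xd.T @ self.yt
        try:
            cf = np.linalg.cholesky(XdX)
        except np.linalg.LinAlgError:
            return penalty
        b = np.linalg.solve(XdX, Xdy)
        ypy = float(self.yt @ (d * self.yt)) - float(Xdy @ b)
        if ypy <= 0:
            return penalty
        return float(np.log(w).sum() + 2 * np.log(np.diag(cf)).sum() + ypy)

    def reml(self, include_gxe: bool = True, return_criterion: bool = False):
        vy = max(self.yt.var(), 1e-12)
        k = 3 if include_gxe else 2
        start = np.full(k, np.log(vy / (k + 1)))
        lo, hi = np.log(vy * 1e-8), np.log(vy * 1e6)
        x, fun = minimize_loglik(lambda t: self.neg2_reml(t, include_gxe),
                                 start, lo, hi)
        if not np.isfinite(fun):
            raise RuntimeError("stacked REML did not converge")
        e = np.exp(x)
        v = StackedVariances(e[0], e[1] if include_gxe else 0.0,
                             e[-1] if include_gxe else e[1])
        return (v, float(fun)) if return_criterion else v

    # -- GLS -------------------------------------------------------------

    def gls(self, v: StackedVariances, extra_cols: np.ndarray | None = None):
        """Generalized least squares of y on [X, extra_cols] given variances.

        Returns (coef, cov) where cov is the coefficient covariance.
        """
        d = 1.0 / self.weights(v)
        A = self.Xt if extra_cols is None else np.hstack([self.Xt, extra_cols])
        Ad = A * d[:, None]
        M = A.T @ Ad
        rhs = Ad.T @ self.yt
        cov = np.linalg.inv(M)
        return cov @ rhs, cov

    def residual_rotated(self, v: StackedVariances, coef: np.ndarray) -> np.ndarray:
        return self.yt - self.Xt @ coef

    def vinv_residual(self, v: StackedVariances, coef: np.ndarray) -> np.ndarray:
        """V^{-1} (y - X beta) back in original coordinates, as an E x n array."""
        et = (self.residual_rotated(v, coef) / self.weights(v)).reshape(self.E, self.n)
        return self.F @ et @ self.U.T
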