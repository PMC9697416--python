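"""REML machinery for the trial mixed models.

The engine fits Gaussian mixed models of the form

    y = X tau + sum_k Z_k u_k + c + eps,   u_k ~ N(0, sigma_k^2 I),

with a residual variance free per declared group (replicate or
environment) and an optional exchangeable "cell" effect ``c`` (one level
per line-by-environment cell) that is absorbed analytically into the
residual covariance: within a cell of size n the covariance is
``sigma_c^2 J + sigma_r^2 I``, whose inverse and determinant are closed
form.  That absorption keeps the mixed-model-equations coefficient matrix
small (fixed effects plus the remaining random factors), so one REML
log-likelihood evaluation costs a few sparse products and one dense
Cholesky, and the profile likelihood can simply be maximised numerically
over the log-variances with L-BFGS-B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve


@dataclass
class RandomTerm:
    """An iid random factor: per-record level index and level count."""

    name: str
    index: np.ndarray
    n_levels: int
    labels: list | None = None


@dataclass
class MixedFit:
    """A converged REML fit."""

    beta: np.ndarray
    beta_names: list[str]
    variances: dict[str, float]
    resid_variances: np.ndarray       # per residual group
    resid_group_labels: list
    blups: dict[str, np.ndarray]
    cell_blups: np.ndarray | None
    loglik: float
    n_obs: int
    n_fixed: int
    model: "MixedModel" = field(repr=False, default=None)
    _cinv: np.ndarray = field(repr=False, default=None)

    def blup_pev(self, term: str) -> np.ndarray:
        """Prediction-error (co)variance matrix of a random term's BLUPs
        (the corresponding diagonal block of the inverse MME matrix)."""
        sl = self.model._term_slice(term)
        return self._cinv[sl, sl]

    def fitted(self, include_random: bool = True) -> np.ndarray:
        return self.model.fitted(self, include_random=include_random)

    def conditional_residuals(self) -> np.ndarray:
        return self.model.y_raw - self.fitted(include_random=True)


class MixedModel:
    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        beta_names: list[str],
        random_terms: list[RandomTerm],
        resid_group: np.ndarray,
        resid_group_labels: list,
        cell_index: np.ndarray | None = None,
    ):
        self.y_raw = np.asarray(y, dtype=float)
        n = self.y_raw.size
        self.X = np.asarray(X, dtype=float)
        self.beta_names = beta_names
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        # standardize the response internally so the likelihood is well
        # conditioned regardless of the trait's location and scale; results
        # are mapped back at the end of fit()
        sd = float(self.y_raw.std())
        self._scale = sd if sd > 0 else 1.0
        w, *_ = np.linalg.lstsq(self.X, np.ones(n), rcond=None)
        if np.allclose(self.X @ w, 1.0, atol=1e-8):
            self._intercept_w = w
            self._offset = float(self.y_raw.mean())
        else:
            self._intercept_w = None
            self._offset = 0.0
        self.y = (self.y_raw - self._offset) / self._scale
        self.random_terms = random_terms
        self.resid_group = np.asarray(resid_group)
        self.n_resid_groups = len(resid_group_labels)
        self.resid_group_labels = resid_group_labels
        self.cell_index = None if cell_index is None else np.asarray(cell_index)

        blocks = [sparse.csr_matrix(self.X)]
        self._slices = {}
        start = self.X.shape[1]
        for t in random_terms:
            Z = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), t.index)), shape=(n, t.n_levels)
            )
            self._slices[t.name] = slice(start, start + t.n_levels)
            start += t.n_levels
            blocks.append(Z)
        self.W = sparse.hstack(blocks, format="csr")
        self.q = start

        if self.cell_index is not None:
            self.n_cells = int(self.cell_index.max()) + 1
            A = sparse.csr_matrix(
                (np.ones(n), (self.cell_index, np.arange(n))), shape=(self.n_cells, n)
            )
            self.A = A
            self.T = (A @ self.W).tocsr()          # cell sums of W rows
            self.cell_sizes = np.asarray(A.sum(axis=1)).ravel()
            self.Ty = A @ self.y
            # residual group must be constant within a cell
            cell_group = np.full(self.n_cells, -1, dtype=int)
            cell_group[self.cell_index] = self.resid_group
            if not np.all(cell_group[self.cell_index] == self.resid_group):
                raise ValueError("residual group varies within a cell")
            self.cell_group = cell_group
        self._group_counts = np.bincount(self.resid_group, minlength=self.n_resid_groups)

    def _term_slice(self, name: str) -> slice:
        return self._slices[name]

    # -- likelihood ----------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        k = len(self.random_terms)
        var_k = np.exp(theta[:k])
        pos = k
        var_c = None
        if self.cell_index is not None:
            var_c = float(np.exp(theta[pos]))
            pos += 1
        var_r = np.exp(theta[pos:pos + self.n_resid_groups])
        return var_k, var_c, var_r

    def _assemble(self, var_k, var_c, var_r):
        d = 1.0 / var_r[self.resid_group]
        WdW = (self.W.T @ self.W.multiply(d[:, None])).toarray()
        Wdy = self.W.T @ (d * self.y)
        yVy = float(np.dot(d * self.y, self.y))
        logdet_r = float(np.dot(self._group_counts, np.log(var_r)))
        if self.cell_index is not None and var_c is not None:
            sr2 = var_r[self.cell_group]
            ncell = self.cell_sizes
            k_cell = var_c / (sr2 * (sr2 + ncell * var_c))
            WdW -= (self.T.T @ self.T.multiply(k_cell[:, None])).toarray()
            Wdy -= self.T.T @ (k_cell * self.Ty)
            yVy -= float(np.dot(k_cell, self.Ty ** 2))
            logdet_r = float(
                np.dot(ncell - 1, np.log(sr2)) + np.log(sr2 + ncell * var_c).sum()
            )
        C = WdW
        for t, v in zip(self.random_terms, var_k):
            sl = self._slices[t.name]
            idx = np.arange(sl.start, sl.stop)
            C[idx, idx] += 1.0 / v
        return C, Wdy, yVy, logdet_r

    @staticmethod
    def _penalty(theta: np.ndarray) -> float:
        # finite, sloped penalty for numerically invalid parameter points so
        # line searches can back out of them (a constant cliff defeats the
        # quadratic interpolation inside L-BFGS-B)
        return 1e7 + 1e5 * float(theta @ theta)

    def neg2_reml(self, theta: np.ndarray) -> float:
        var_k, var_c, var_r = self._unpack(theta)
        C, rhs, yVy, logdet_r = self._assemble(var_k, var_c, var_r)
        try:
            cf = cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return self._penalty(theta)
        logdet_c = 2.0 * np.log(np.diag(cf[0])).sum()
        sol = cho_solve(cf, rhs, check_finite=False)
        ypy = yVy - float(rhs @ sol)
        if ypy <= 0:
            return self._penalty(theta)
        logdet_g = sum(
            t.n_levels * np.log(v) for t, v in zip(self.random_terms, var_k)
        )
        return logdet_r + logdet_g + logdet_c + ypy

    def _moment_start(self) -> np.ndarray:
        """Crude method-of-moments starting values: residual variances from
        deviations within the finest grouping, the rest split evenly."""
        vy = max(self.y.var(), 1e-12)
        k = len(self.random_terms)
        floor = vy * 1e-4
        if self.cell_index is not None:
            csum = np.bincount(self.cell_index, weights=self.y, minlength=self.n_cells)
            cmean = csum / self.cell_sizes
            dev = self.y - cmean[self.cell_index]
            resid = np.empty(self.n_resid_groups)
            for gidx in range(self.n_resid_groups):
                recs = self.resid_group == gidx
                cells = np.unique(self.cell_index[recs])
                df = max(int(recs.sum()) - cells.size, 1)
                resid[gidx] = max(float((dev[recs] ** 2).sum()) / df, floor)
            rem = max(vy - float(np.mean(resid)), floor)
            theta = np.concatenate([
                np.full(k + 1, rem / (k + 1)),
                resid,
            ])
        elif k > 0:
            t = max(self.random_terms, key=lambda t: t.n_levels)
            lsum = np.bincount(t.index, weights=self.y, minlength=t.n_levels)
            lcount = np.bincount(t.index, minlength=t.n_levels)
            lmean = lsum / np.maximum(lcount, 1)
            dev = self.y - lmean[t.index]
            resid = np.empty(self.n_resid_groups)
            for gidx in range(self.n_resid_groups):
                recs = self.resid_group == gidx
                resid[gidx] = max(float((dev[recs] ** 2).mean()) * 2.0, floor)
            rem = max(vy - float(np.mean(resid)), floor)
            theta = np.concatenate([np.full(k, rem / k), resid])
        else:
            theta = np.full(self.n_resid_groups, vy)
        return np.log(np.maximum(theta, floor))

    def fit(self, start: np.ndarray | None = None, maxiter: int = 300) -> MixedFit:
        vy = max(self.y.var(), 1e-12)
        k = len(self.random_terms)
        n_par = k + (1 if self.cell_index is not None else 0) + self.n_resid_groups
        if start is None:
            start = self._moment_start()
        lo, hi = np.log(vy * 1e-8), np.log(vy * 1e6)
        opts = {"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8, "eps": 1e-6}
        res = optimize.minimize(
            self.neg2_reml, np.clip(start, lo, hi), method="L-BFGS-B",
            bounds=[(lo, hi)] * n_par, options=opts,
        )
        # fall back to alternative starts if the first run barely moved
        f_start = self.neg2_reml(np.clip(start, lo, hi))
        if res.fun > f_start - 1e-6 * max(abs(f_start), 1.0):
            for alt in (np.full(n_par, np.log(vy / max(n_par, 2))),
                        np.clip(start, lo, hi) + 0.5):
                res_alt = optimize.minimize(
                    self.neg2_reml, np.clip(alt, lo, hi), method="L-BFGS-B",
                    bounds=[(lo, hi)] * n_par, options=opts | {"eps": 1e-7},
                )
                if res_alt.fun < res.fun:
                    res = res_alt
        if not np.isfinite(res.fun):
            raise RuntimeError(f"REML did not converge: {res.message}")
        theta = res.x
        var_k, var_c, var_r = self._unpack(theta)
        C, rhs, yVy, _ = self._assemble(var_k, var_c, var_r)
        cf = cho_factor(C, lower=True, check_finite=False)
        sol = cho_solve(cf, rhs, check_finite=False)
        cinv = cho_solve(cf, np.eye(self.q), check_finite=False)

        # map back to the original response scale
        s2 = self._scale**2
        var_k = var_k * s2
        var_c = None if var_c is None else var_c * s2
        var_r = var_r * s2
        sol = sol * self._scale
        cinv = cinv * s2

        p = self.X.shape[1]
        beta = sol[:p]
        if self._intercept_w is not None:
            beta = beta + self._offset * self._intercept_w
            sol[:p] = beta
        blups = {t.name: sol[self._slices[t.name]] for t in self.random_terms}
        variances = {t.name: float(v) for t, v in zip(self.random_terms, var_k)}
        if var_c is not None:
            variances["cell"] = var_c
        fit = MixedFit(
            beta=beta,
            beta_names=self.beta_names,
            variances=variances,
            resid_variances=var_r,
            resid_group_labels=self.resid_group_labels,
            blups=blups,
            cell_blups=None,
            loglik=-0.5 * float(res.fun),
            n_obs=self.y.size,
            n_fixed=p,
            model=self,
            _cinv=cinv,
        )
        if self.cell_index is not None and var_c is not None:
            fit.cell_blups = self._cell_blups(fit, var_c, var_r)
        return fit

    def _cell_blups(self, fit: MixedFit, var_c: float, var_r: np.ndarray) -> np.ndarray:
        resid = self.y_raw - self._linear_predictor(fit)
        s = self.A @ resid
        sr2 = var_r[self.cell_group]
        return var_c * s / (sr2 + self.cell_sizes * var_c)

    def _linear_predictor(self, fit: MixedFit) -> np.ndarray:
        sol = np.concatenate([fit.beta] + [fit.blups[t.name] for t in self.random_terms])
        return self.W @ sol

    def fitted(self, fit: MixedFit = None, include_random: bool = True) -> np.ndarray:
        if not include_random:
            return self.X @ fit.beta
        out = self._linear_predictor(fit)
        if fit.cell_blups is not None:
            out = out + fit.cell_blups[self.cell_index]
        return out

    def residual_sd_per_record(self, fit: MixedFit) -> np.ndarray:
        return np.sqrt(fit.resid_variances[self.resid_group])


def design_onehot(values: pd.Series | np.ndarray, prefix: str) -> tuple[np.ndarray, list[str], list]:
    """One-hot design for a factor; returns (matrix, names, levels)."""
    values = pd.Series(values)
    levels = list(dict.fromkeys(values))
    lut = {v: i for i, v in enumerate(levels)}
    idx = values.map(lut).to_numpy()
    X = np.zeros((len(values), len(levels)))
    X[np.arange(len(values)), idx] = 1.0
    return X, [f"{prefix}[{v}]" for v in levels], levels


def design_sumzero(values: pd.Series | np.ndarray, prefix: str) -> tuple[np.ndarray, list[str], list]:
    """Sum-to-zero contrast design (levels - 1 columns, last level is the
    negative sum), so remaining effects are deviations from the mean."""
    values = pd.Series(values)
    levels = list(dict.fromkeys(values))
    lut = {v: i for i, v in enumerate(levels)}
    idx = values.map(lut).to_numpy()
    L = len(levels)
    X = np.zeros((len(values), L - 1))
    for j in range(L - 1):
        X[idx == j, j] = 1.0
    X[idx == L - 1, :] = -1.0
    return X, [f"{prefix}[{v}]" for v in levels[:-1]], levels


def factor_index(values: pd.Series | np.ndarray) -> tuple[np.ndarray, list]:
    values = pd.Series(values)
    levels = list(dict.fromkeys(values))
    lut = {v: i for i, v in enumerate(levels)}
    return values.map(lut).to_numpy(), levels
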