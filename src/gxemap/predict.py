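"""Multi-environment GBLUP with and without a G-by-E kernel.

The prediction model on stacked per-environment records is

    y = X beta + u + u_GE + eps,

with X holding environment and population indicators, u the main polygenic
effect (kernel K_g repeated over environments) and u_GE the G-by-E
polygenic effect (K_g within an environment, zero across).  Dropping u_GE
gives the main-effect model.  Variances are estimated by REML on the
rotated (diagonal) form and BLUPs for unobserved lines follow from the
kernel rows against V^{-1}(y - X beta).  Predictive ability is assessed by
the CV2 scheme: whole lines are masked from every environment, so the test
set consists of material never evaluated in any trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import design_sumzero
from .stacked import StackedKernelModel, StackedVariances

logger = logging.getLogger(__name__)


def build_kge(
    Kg: np.ndarray,
    line_idx: np.ndarray,
    env_idx: np.ndarray,
) -> np.ndarray:
    """G-by-E kernel on stacked records: entry (a, b) equals
    Kg(line_a, line_b) when the records share an environment, else 0."""
    Kg = np.asarray(Kg, dtype=float)
    line_idx = np.asarray(line_idx, dtype=int)
    if line_idx.max() >= Kg.shape[0] or line_idx.min() < 0:
        raise ValueError("record refers to a line outside the kinship")
    env_idx = np.asarray(env_idx)
    K = Kg[np.ix_(line_idx, line_idx)].copy()
    same = env_idx[:, None] == env_idx[None, :]
    K[~same] = 0.0
    return K


@dataclass
class GBLUPFit:
    """A fitted multi-environment GBLUP model."""

    variances: StackedVariances
    beta: np.ndarray
    include_gxe: bool
    model: StackedKernelModel = field(repr=False, default=None)
    Kg_full: np.ndarray = field(repr=False, default=None)
    train_pos: np.ndarray = field(repr=False, default=None)   # rows of Kg_full
    pop_X_full: np.ndarray = field(repr=False, default=None)
    _vinv_resid: np.ndarray = field(repr=False, default=None)  # E x n_train

    def predict(self, test_pos: np.ndarray) -> np.ndarray:
        """Predicted values for lines indexed into the full kinship, for
        every training environment; returns a (n_test, E) array."""
        v = self.variances
        Ktt = self.Kg_full[np.ix_(np.asarray(test_pos, int), self.train_pos)]
        Em = self._vinv_resid                       # E x n_train
        u = v.sigma_g2 * Ktt @ Em.sum(axis=0)
        uge = v.sigma_ge2 * (Ktt @ Em.T)            # n_test x E
        E = Em.shape[0]
        fixed = np.empty((len(test_pos), E))
        env_beta = self.beta[:E]
        pop_part = (self.pop_X_full[test_pos] @ self.beta[E:]
                    if self.pop_X_full is not None and len(self.beta) > E
                    else np.zeros(len(test_pos)))
        for j in range(E):
            fixed[:, j] = env_beta[j] + pop_part
        return fixed + u[:, None] + uge


def fit_gblup(
    blues: pd.DataFrame,
    Kg: np.ndarray,
    pop_labels: np.ndarray | None = None,
    include_gxe: bool = True,
    Kg_full: np.ndarray | None = None,
    train_pos: np.ndarray | None = None,
    pop_X_full: np.ndarray | None = None,
    boundary_lrt: float = 2.706,
) -> GBLUPFit:
    """REML + BLUP fit of the stacked model on a complete BLUE table.

    ``blues`` holds the training lines; to predict other lines pass the
    full-population kinship ``Kg_full`` with ``train_pos`` giving the row
    positions of the training lines (defaults assume training = full set).

    Because sigma_GE^2 sits on the boundary of its parameter space, a fit
    with ``include_gxe`` keeps the interaction component only when it
    improves -2 log REML by more than ``boundary_lrt`` (default the 5%
    point of the boundary null, 0.5 chi2_0 + 0.5 chi2_1); otherwise the
    model reduces to the main-effect model exactly.  Pass 0 to disable.
    """
    n = len(blues)
    if pop_labels is not None and pop_X_full is None:
        pop_X_full, _, _ = design_sumzero(pd.Series(pop_labels), "pop")
    X_line = None if pop_X_full is None else pop_X_full[
        np.arange(n) if train_pos is None else train_pos]
    model = StackedKernelModel(blues, Kg, X_line=X_line)
    if include_gxe and boundary_lrt > 0:
        v_full, crit_full = model.reml(include_gxe=True, return_criterion=True)
        v_main, crit_main = model.reml(include_gxe=False, return_criterion=True)
        v = v_full if (crit_main - crit_full) > boundary_lrt else v_main
    else:
        v = model.reml(include_gxe=include_gxe)
    coef, _ = model.gls(v)
    fit = GBLUPFit(
        variances=v, beta=coef, include_gxe=include_gxe, model=model,
        Kg_full=Kg if Kg_full is None else Kg_full,
        train_pos=np.arange(n) if train_pos is None else np.asarray(train_pos, int),
        pop_X_full=pop_X_full,
    )
    fit._vinv_resid = model.vinv_residual(v, coef)
    return fit


@dataclass
class PredictionResult:
    """Per-environment predictive ability of one model over CV replicates."""

    model_tag: str
    abilities: pd.DataFrame      # replicates x environments (NaN = skipped cell)

    @property
    def mean(self) -> pd.Series:
        return self.abilities.mean()

    @property
    def sd(self) -> pd.Series:
        return self.abilities.std()


def cross_validate_cv2(
    blues: pd.DataFrame,
    Kg: np.ndarray,
    pop_labels: np.ndarray | None = None,
    train_frac: float = 0.7,
    reps: int = 50,
    seed: int = 0,
    min_test_lines: int = 5,
) -> tuple[PredictionResult, PredictionResult, pd.DataFrame]:
    """CV2 comparison of the main-effect and main+G-by-E models.

    In each replicate ``train_frac`` of the *lines* form the training set
    and the remaining lines are masked in every environment, emulating
    material never evaluated in any trial.  Predictive ability is the
    Pearson correlation between observed and predicted values per
    environment; the two models are compared per environment with a paired
    two-sided t-test over replicates.

    Returns (main result, main+gxe result, comparison table).
    """
    if reps < 2:
        raise ValueError("need at least 2 CV replicates")
    n = len(blues)
    envs = list(blues.columns)
    rng = np.random.default_rng(seed)
    pop_X = None
    if pop_labels is not None:
        pop_X, _, _ = design_sumzero(pd.Series(pop_labels), "pop")
    abil = {tag: np.full((reps, len(envs)), np.nan) for tag in ("main", "main+gxe")}
    n_train = int(round(train_frac * n))
    Y = blues.to_numpy(dtype=float)
    for r in range(reps):
        perm = rng.permutation(n)
        train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        assert np.intersect1d(train, test).size == 0
        sub = blues.iloc[train]
        K_train = Kg[np.ix_(train, train)]
        for tag, use_gxe in (("main", False), ("main+gxe", True)):
            fit = fit_gblup(
                sub, K_train, include_gxe=use_gxe,
                Kg_full=Kg, train_pos=train, pop_X_full=pop_X,
            )
            pred = fit.predict(test)
            for j in range(len(envs)):
                obs = Y[test, j]
                ok = np.isfinite(obs)
                if ok.sum() < min_test_lines:
                    logger.info("rep %d env %s: <%d test lines, skipped", r, envs[j], min_test_lines)
                    continue
                abil[tag][r, j] = np.corrcoef(obs[ok], pred[ok, j])[0, 1]
    res_main = PredictionResult("main", pd.DataFrame(abil["main"], columns=envs))
    res_gxe = PredictionResult("main+gxe", pd.DataFrame(abil["main+gxe"], columns=envs))
    rows = []
    for j, env in enumerate(envs):
        a, b = abil["main"][:, j], abil["main+gxe"][:, j]
        ok = np.isfinite(a) & np.isfinite(b)
        tt = stats.ttest_rel(b[ok], a[ok]) if ok.sum() >= 2 else None
        rows.append({
            "environment": env,
            "ability_main": float(np.nanmean(a)),
            "ability_gxe": float(np.nanmean(b)),
            "diff": float(np.nanmean(b - a)),
            "t": float(tt.statistic) if tt else np.nan,
            "p": float(tt.pvalue) if tt else np.nan,
        })
    return res_main, res_gxe, pd.DataFrame(rows).set_index("environment")
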