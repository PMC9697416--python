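"""Per-environment and joint multi-environment trial models.

Two linear mixed models underpin the phenotypic analysis of the trials.
Within one environment,

    y_im = mu + G_i + R_m + B_n(R_m) + e_im,    e_im ~ N(0, sigma_m^2),

with a free residual variance per replicate; across environments,

    y_ijm = mu + G_i + E_j + GE_ij + R_m(E_j) + B_n(E_j R_m) + e_ijm,
    e_ijm ~ N(0, sigma_j^2),

with a free residual variance per environment.  Genotype is fixed when
best linear unbiased estimates (BLUEs) are wanted and random for variance
components and heritability; replicates are fixed and blocks random, the
usual treatment for augmented alpha designs.  Broad-sense heritability
uses Cullis' prediction-error-variance form.  A single-pass studentized
residual razor removes gross outliers before model fitting.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .mixedlm import (
    MixedFit,
    MixedModel,
    RandomTerm,
    design_onehot,
    design_sumzero,
    factor_index,
)
from .simulate import TrialData


@dataclass
class JointFit:
    """Result of the across-environment model.

    Either BLUEs (genotype fixed) or variance components, the genotype-by-
    environment interaction ratio sigma_ge^2 / sigma_g^2, and Cullis
    heritability (genotype random) are populated.
    """

    mu: float
    lines: list[str]
    environments: list[str]
    blues: pd.Series | None
    env_effects: pd.Series
    sigma_g2: float | None
    sigma_ge2: float | None
    resid_variances: pd.Series
    genotype_fixed: bool
    h2: float | None = None
    fit: MixedFit = field(repr=False, default=None)

    @property
    def ratio(self) -> float | None:
        if self.sigma_g2 is None:
            return None
        return variance_ratio(self.sigma_g2, self.sigma_ge2)


def variance_ratio(sigma_g2: float, sigma_ge2: float) -> float:
    """Interaction-to-genetic variance ratio sigma_ge^2 / sigma_g^2."""
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive to form the ratio")
    return sigma_ge2 / sigma_g2


def _records(data: TrialData, env: str | None = None) -> pd.DataFrame:
    df = data.plots
    if env is not None:
        df = df[df["env"] == env]
        if df.empty:
            raise ValueError(f"no records for environment {env!r}")
    return df.reset_index(drop=True)


def _rep_within_env_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero replicate contrasts nested in environment."""
    cols, names = [], []
    for env in dict.fromkeys(df["env"]):
        sub = df["env"] == env
        reps = list(dict.fromkeys(df.loc[sub, "rep"]))
        for r in reps[:-1]:
            col = np.zeros(len(df))
            col[(df["env"] == env) & (df["rep"] == r)] = 1.0
            col[(df["env"] == env) & (df["rep"] == reps[-1])] = -1.0
            cols.append(col)
            names.append(f"rep[{env}:{r}]")
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names


def fit_env_model(
    data: TrialData,
    env: str,
    genotype_fixed: bool = True,
) -> MixedFit:
    """Single-environment model with per-replicate residual variances.

    Genotype fixed yields BLUEs (stored under ``beta``; see
    :func:`extract_blues`); genotype random yields variance components.
    Blocks are random, replicates fixed (sum-to-zero), residual variance
    free per replicate.  Genotypes observed once get a BLUE equal to their
    adjusted single observation and are flagged with a warning.
    """
    df = _records(data, env)
    reps = df["rep"].nunique()
    if reps < 2:
        warnings.warn("fewer than 2 replicates: residual variances not separable", stacklevel=2)
    counts = df.groupby("line").size()
    singles = counts[counts == 1]
    if len(singles):
        warnings.warn(
            f"{len(singles)} unreplicated genotypes; their BLUEs equal the "
            "adjusted single observation", stacklevel=2,
        )
    rep_X, rep_names = _rep_within_env_design(df.assign(env=env))
    block_idx, block_levels = factor_index(df["block"])
    random_terms = [RandomTerm("block", block_idx, len(block_levels), block_levels)]
    if genotype_fixed:
        gX, g_names, _ = design_onehot(df["line"], "line")
        X = np.hstack([gX, rep_X])
        names = g_names + rep_names
    else:
        X = np.hstack([np.ones((len(df), 1)), rep_X])
        names = ["mu"] + rep_names
        g_idx, g_levels = factor_index(df["line"])
        random_terms.insert(0, RandomTerm("genotype", g_idx, len(g_levels), g_levels))
    rep_idx, rep_levels = factor_index(df["rep"])
    model = MixedModel(
        df["value"].to_numpy(), X, names, random_terms,
        resid_group=rep_idx, resid_group_labels=rep_levels,
    )
    return model.fit()


def extract_blues(fit: MixedFit, prefix: str = "line") -> pd.Series:
    """Line BLUEs from a genotype-fixed fit (coefficients of the one-hot
    line columns, i.e. adjusted means at the average replicate/environment)."""
    vals, idx = [], []
    for name, b in zip(fit.beta_names, fit.beta):
        if name.startswith(f"{prefix}["):
            idx.append(name[len(prefix) + 1:-1])
            vals.append(b)
    return pd.Series(vals, index=idx, name="BLUE")


def fit_joint_model(
    data: TrialData,
    genotype_fixed: bool = False,
    include_checks: bool = True,
) -> JointFit:
    """Across-environment model with heterogeneous residuals per environment.

    Genotype fixed returns across-environment BLUEs; genotype random
    returns sigma_g^2, sigma_ge^2 (the line-by-environment cell effect,
    absorbed analytically) and Cullis heritability.
    """
    df = _records(data)
    if not include_checks:
        df = df[~df["is_check"]].reset_index(drop=True)
    envs = list(dict.fromkeys(df["env"]))
    if len(envs) < 2:
        raise ValueError("joint model needs at least two environments")

    env_X, env_names, env_levels = design_sumzero(df["env"], "env")
    rep_X, rep_names = _rep_within_env_design(df)
    block_idx, block_levels = factor_index(df["block"])
    cell_idx, _ = factor_index(list(zip(df["line"], df["env"])))
    env_idx, _ = factor_index(df["env"])
    random_terms = [RandomTerm("block", block_idx, len(block_levels), block_levels)]

    if genotype_fixed:
        gX, g_names, _ = design_onehot(df["line"], "line")
        X = np.hstack([gX, env_X, rep_X])
        names = g_names + env_names + rep_names
    else:
        X = np.hstack([np.ones((len(df), 1)), env_X, rep_X])
        names = ["mu"] + env_names + rep_names
        g_idx, g_levels = factor_index(df["line"])
        random_terms.insert(0, RandomTerm("genotype", g_idx, len(g_levels), g_levels))

    rep_idx_na, _ = factor_index(df["rep"])  # unused; residual grouped by env
    model = MixedModel(
        df["value"].to_numpy(), X, names, random_terms,
        resid_group=env_idx, resid_group_labels=envs,
        cell_index=cell_idx,
    )
    fit = model.fit()

    env_eff = _sumzero_effects(fit, "env", env_levels)
    resid = pd.Series(fit.resid_variances, index=envs, name="sigma_j2")
    if genotype_fixed:
        blues = extract_blues(fit)
        return JointFit(
            mu=float(blues.mean()), lines=list(blues.index), environments=envs,
            blues=blues, env_effects=env_eff, sigma_g2=None, sigma_ge2=None,
            resid_variances=resid, genotype_fixed=True, fit=fit,
        )
    g_levels = fit.model.random_terms[0].labels
    sigma_g2 = fit.variances["genotype"]
    sigma_ge2 = fit.variances["cell"]
    jf = JointFit(
        mu=float(fit.beta[0]), lines=list(g_levels), environments=envs,
        blues=None, env_effects=env_eff, sigma_g2=sigma_g2, sigma_ge2=sigma_ge2,
        resid_variances=resid, genotype_fixed=False, fit=fit,
    )
    jf.h2 = cullis_h2(jf)
    return jf


def _sumzero_effects(fit: MixedFit, prefix: str, levels: list) -> pd.Series:
    eff = {}
    for name, b in zip(fit.beta_names, fit.beta):
        if name.startswith(f"{prefix}["):
            eff[name[len(prefix) + 1:-1]] = b
    vals = [eff.get(str(l), eff.get(l)) for l in levels[:-1]]
    vals.append(-float(np.sum(vals)))
    return pd.Series(vals, index=levels, name=f"{prefix}_effect")


def cullis_h2(jfit: JointFit) -> float:
    """Broad-sense heritability from genotype-BLUP prediction-error variance:

        H^2 = 1 - mean pairwise PEV of genotype BLUP differences / (2 sigma_g^2).
    """
    if jfit.genotype_fixed:
        raise ValueError("Cullis heritability needs a genotype-random fit")
    sigma_g2 = jfit.sigma_g2
    if sigma_g2 <= 0:
        return 0.0
    P = jfit.fit.blup_pev("genotype")
    n = P.shape[0]
    mean_pair_pev = (2 * n * np.trace(P) - 2 * P.sum()) / (n * (n - 1))
    return float(np.clip(1.0 - mean_pair_pev / (2 * sigma_g2), 0.0, 1.0))


def razor_outliers(
    data: TrialData,
    threshold: float = 2.8,
    studentized: str = "external",
) -> TrialData:
    """Studentized-residual razor on the across-environment model.

    The joint genotype-random model is fitted once; records whose absolute
    studentized conditional residual exceeds ``threshold`` are removed (a
    single pass, no re-fit).  Residuals are studentized with their exact
    conditional variance ``diag(R - W C^{-1} W')``; ``studentized=
    "external"`` additionally applies the leave-one-out t transformation.
    """
    if not np.isfinite(threshold):
        return data
    df = _records(data)
    jf = fit_joint_model(data, genotype_fixed=False)
    resid, resid_var = _conditional_residual_variance(df, jf)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = resid / np.sqrt(np.maximum(resid_var, 1e-12))
    if studentized == "external":
        nu = len(df) - jf.fit.n_fixed
        t2 = np.minimum(t**2, nu - 1e-9)
        t = np.sign(t) * np.abs(t) * np.sqrt((nu - 1) / np.maximum(nu - t2, 1e-9))
    elif studentized != "internal":
        raise ValueError("studentized must be 'internal' or 'external'")
    keep = np.abs(t) <= threshold
    frac = 1 - keep.mean()
    if frac > 0.10:
        warnings.warn(f"razor removed {frac:.1%} of records", stacklevel=2)
    return TrialData(plots=df[keep].reset_index(drop=True), trait=data.trait, truth=data.truth)


def _conditional_residual_variance(df: pd.DataFrame, jf: JointFit):
    """Exact variance of conditional residuals, with the line-by-environment
    interaction expanded as an explicit random effect."""
    m = jf.fit.model
    fitted = m.fitted(jf.fit, include_random=True)
    resid = m.y_raw - fitted

    import scipy.sparse as sp
    n = len(df)
    cell_idx = m.cell_index
    n_cells = m.n_cells
    Zc = sp.csr_matrix((np.ones(n), (np.arange(n), cell_idx)), shape=(n, n_cells))
    W2 = sp.hstack([m.W, Zc], format="csr")
    d = 1.0 / jf.fit.resid_variances[m.resid_group]
    C2 = (W2.T @ W2.multiply(d[:, None])).toarray()
    pos = m.X.shape[1]
    for t in m.random_terms:
        idx = np.arange(pos, pos + t.n_levels)
        C2[idx, idx] += 1.0 / jf.fit.variances[t.name]
        pos += t.n_levels
    idx = np.arange(pos, pos + n_cells)
    C2[idx, idx] += 1.0 / max(jf.fit.variances["cell"], 1e-10)
    cf = cho_factor(C2, lower=True, check_finite=False)
    B = cho_solve(cf, W2.T.toarray(), check_finite=False)
    quad = np.einsum("ij,ji->i", W2.toarray(), B)
    return resid, 1.0 / d - quad


def lsd_groups(
    means: pd.Series,
    mse: float,
    n: int,
    df_resid: int,
    alpha: float = 0.05,
) -> pd.Series:
    """Least-significant-difference letter display.

    Two means share a letter iff their absolute difference is below
    ``t(1 - alpha/2, df) * sqrt(2 * mse / n)``.  Letters are assigned
    greedily from the largest mean; for means sorted descending the
    non-significant groups are maximal runs, each lettered in order.
    """
    if mse <= 0:
        raise ValueError("mse must be positive")
    if n < 2:
        raise ValueError("per-mean replication must be >= 2")
    lsd = stats.t.ppf(1 - alpha / 2, df_resid) * np.sqrt(2 * mse / n)
    order = means.sort_values(ascending=False)
    vals = order.to_numpy()
    k = len(vals)
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and vals[i] - vals[j + 1] < lsd:
            j += 1
        runs.append((i, j))
    # keep only maximal runs
    maximal = [r for r in runs if not any(
        (a <= r[0] and r[1] <= b and (a, b) != r) for a, b in runs)]
    letters = {name: "" for name in order.index}
    for letter, (a, bnd) in zip(string.ascii_lowercase, maximal):
        for name in order.index[a:bnd + 1]:
            letters[name] += letter
    return pd.Series(letters).reindex(means.index)


def blues_table(data: TrialData, include_checks: bool = False) -> pd.DataFrame:
    """Per-environment BLUEs (lines x environments), the input to the
    plasticity regression and the stacked G-by-E analyses."""
    df = data.plots if include_checks else data.plots[~data.plots["is_check"]]
    sub = TrialData(plots=df.reset_index(drop=True), trait=data.trait)
    cols = {}
    for env in sub.environments:
        fit = fit_env_model(sub, env, genotype_fixed=True)
        cols[env] = extract_blues(fit)
    return pd.DataFrame(cols)


def summary_table(entries: dict[str, dict]) -> pd.DataFrame:
    """Trait summary in the conventional multi-environment layout:
    Min, Max, Mean, sigma_g2, sigma_ge2, Ratio (= sigma_ge2/sigma_g2), H2.

    ``entries`` maps trait name to a dict with keys ``min``, ``max``,
    ``mean``, ``sigma_g2``, ``sigma_ge2`` and optionally ``h2``; the Ratio
    column is always recomputed from the two variance components.
    """
    rows = []
    for trait, e in entries.items():
        rows.append({
            "Trait": trait,
            "Min": e.get("min"),
            "Max": e.get("max"),
            "Mean": e.get("mean"),
            "sigma_g2": e["sigma_g2"],
            "sigma_ge2": e["sigma_ge2"],
            "Ratio": variance_ratio(e["sigma_g2"], e["sigma_ge2"]),
            "H2": e.get("h2"),
        })
    return pd.DataFrame(rows).set_index("Trait")
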