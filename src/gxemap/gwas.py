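"""Association mapping: Q+K scans, main/G-by-E decomposition, QTL intervals.

Two scans are provided.  ``scan_qk`` is the classical single-phenotype
mixed-model GWAS with principal components as fixed covariates and a
polygenic kinship term (variances estimated once on the null model and
reused per marker).  ``scan_gxe`` stacks the per-environment BLUEs and
decomposes every marker's total effect into a constant main effect gamma
plus environment-specific interaction effects delta (constrained to sum to
zero, so gamma is the environment-average effect), on top of main and
G-by-E polygenic kernels.  Per-environment GGE effects gamma + delta_j are
reported with 1-df Wald tests.  Significant markers are grouped into QTL
by LD-based interval delimitation, merged when pleiotropic, and annotated
with overlapping gene models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .stacked import (StackedKernelModel, StackedVariances, minimize_loglik,
                      sumzero_basis)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# single-phenotype Q+K scan
# ---------------------------------------------------------------------------

def scan_qk(
    pheno: np.ndarray,
    numeric: np.ndarray,
    pcs: np.ndarray,
    K: np.ndarray,
    markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Q+K mixed-model scan for one phenotype vector.

    The polygenic covariance K sigma_g^2 + I sigma_e^2 is estimated once on
    the marker-free null model (the population-parameters-previously-
    determined scheme) and every marker is then tested by generalized least
    squares; p-values use the t distribution with n - p - 1 df.
    Monomorphic markers are skipped (NaN row, logged).
    """
    y = np.asarray(pheno, dtype=float)
    n = y.size
    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    X = np.column_stack([np.ones(n), np.atleast_2d(pcs)])
    Xt = U.T @ X

    def neg2(theta):
        penalty = 1e7 + 1e5 * float(theta @ theta)
        sg2, se2 = np.exp(theta)
        w = sg2 * lam + se2
        d = 1.0 / w
        XdX = Xt.T @ (Xt * d[:, None])
        Xdy = Xt.T @ (d * yt)
        sign, logdet = np.linalg.slogdet(XdX)
        if sign <= 0:
            return penalty
        b = np.linalg.solve(XdX, Xdy)
        ypy = float(yt @ (d * yt)) - float(Xdy @ b)
        if ypy <= 0:
            return penalty
        return float(np.log(w).sum() + logdet + ypy)

    vy = max(y.var(), 1e-12)
    lo, hi = np.log(vy * 1e-8), np.log(vy * 1e6)
    x, _ = minimize_loglik(neg2, np.log([vy / 2, vy / 2]), lo, hi)
    sg2, se2 = np.exp(x)
    w = sg2 * lam + se2
    d = 1.0 / w

    M = np.asarray(numeric, dtype=float)
    mono = M.std(axis=0) == 0
    if mono.any():
        logger.info("scan_qk: %d monomorphic markers skipped", int(mono.sum()))
    p_fixed = X.shape[1]
    df_t = n - p_fixed - 1
    eff = np.full(M.shape[1], np.nan)
    se = np.full(M.shape[1], np.nan)
    pv = np.full(M.shape[1], np.nan)
    XdX = Xt.T @ (Xt * d[:, None])
    Xdy = Xt.T @ (d * yt)
    for k in range(M.shape[1]):
        if mono[k]:
            continue
        zt = U.T @ M[:, k]
        zdz = float(zt @ (d * zt))
        zdX = Xt.T @ (d * zt)
        zdy = float(zt @ (d * yt))
        A = np.empty((p_fixed + 1, p_fixed + 1))
        A[:p_fixed, :p_fixed] = XdX
        A[:p_fixed, -1] = zdX
        A[-1, :p_fixed] = zdX
        A[-1, -1] = zdz
        rhs = np.append(Xdy, zdy)
        cov = np.linalg.inv(A)
        coef = cov @ rhs
        eff[k] = coef[-1]
        se[k] = np.sqrt(max(cov[-1, -1], 1e-300))
        t = eff[k] / se[k]
        pv[k] = 2 * stats.t.sf(abs(t), df_t)
    out = pd.DataFrame({"effect": eff, "se": se, "p": pv})
    if markers is not None:
        out = pd.concat([markers.reset_index(drop=True), out], axis=1)
    out.attrs["sigma_g2"] = float(sg2)
    out.attrs["sigma_e2"] = float(se2)
    return out


# ---------------------------------------------------------------------------
# main + G-by-E scan on stacked per-environment BLUEs
# ---------------------------------------------------------------------------

@dataclass
class GxEScan:
    """Per-marker main/interaction decomposition over environments."""

    table: pd.DataFrame               # marker, gamma, p_main, p_gxe, ...
    env_effects: np.ndarray           # markers x environments (gamma + delta_j)
    env_wald_p: np.ndarray            # markers x environments
    environments: list[str]
    variances: StackedVariances
    markers: pd.DataFrame | None = field(default=None, repr=False)


def scan_gxe(
    blues: pd.DataFrame,
    numeric: np.ndarray,
    pcs: np.ndarray,
    Kg: np.ndarray,
    markers: pd.DataFrame | None = None,
) -> GxEScan:
    """Main-effect and interaction GWAS on stacked per-environment BLUEs.

    Per marker k the model adds a main column (the marker codes, constant
    across environments) with effect gamma_k and interaction columns
    W_k delta_k with delta_k summing to zero across environments.  gamma_k
    is tested with a 1-df Wald chi-square, delta_k jointly with
    (n_env - 1) df.  The polygenic structure has a main kernel K_g and a
    G-by-E kernel (K_g within environment, zero across); all variances are
    homogeneous and estimated once on the marker-free null model.  The
    per-environment GGE effect gamma_k + delta_kj is returned with its
    1-df Wald test.
    """
    model = StackedKernelModel(blues, Kg, X_line=pcs)
    v = model.reml(include_gxe=True)
    E, n = model.E, model.n
    C = sumzero_basis(E)
    M = np.asarray(numeric, dtype=float)
    m = M.shape[1]
    mono = M.std(axis=0) == 0
    if mono.any():
        logger.info("scan_gxe: %d monomorphic markers skipped", int(mono.sum()))

    p_fixed = model.Xt.shape[1]
    d = 1.0 / model.weights(v)
    Xd = model.Xt * d[:, None]
    XdX = model.Xt.T @ Xd
    Xdy = Xd.T @ model.yt
    ones_E = np.ones(E)

    gamma = np.full(m, np.nan)
    se_g = np.full(m, np.nan)
    p_main = np.full(m, np.nan)
    p_gxe = np.full(m, np.nan)
    env_eff = np.full((m, E), np.nan)
    env_p = np.full((m, E), np.nan)

    # map from (gamma, alpha) to per-environment effects gamma + (C alpha)_j
    L = np.hstack([np.ones((E, 1)), C])  # E x E

    for k in range(m):
        if mono[k]:
            continue
        cols = [model.rotate_rank1(ones_E, M[:, k])]
        cols += [model.rotate_rank1(C[:, j], M[:, k]) for j in range(E - 1)]
        A = np.column_stack(cols)
        Ad = A * d[:, None]
        T11 = A.T @ Ad
        T10 = A.T @ Xd
        rhs = np.concatenate([Xdy, Ad.T @ model.yt])
        top = np.hstack([XdX, T10.T])
        bot = np.hstack([T10, T11])
        Mfull = np.vstack([top, bot])
        cov = np.linalg.inv(Mfull)
        coef = cov @ rhs
        g = coef[p_fixed]
        alpha = coef[p_fixed + 1:]
        cov_ga = cov[p_fixed:, p_fixed:]
        gamma[k] = g
        se_g[k] = np.sqrt(max(cov_ga[0, 0], 1e-300))
        p_main[k] = stats.chi2.sf((g / se_g[k]) ** 2, df=1)
        cov_a = cov_ga[1:, 1:]
        wald = float(alpha @ np.linalg.solve(cov_a, alpha))
        p_gxe[k] = stats.chi2.sf(wald, df=E - 1)
        effs = L @ np.concatenate([[g], alpha])
        var_eff = np.einsum("ij,jk,ik->i", L, cov_ga, L)
        env_eff[k] = effs
        with np.errstate(invalid="ignore", divide="ignore"):
            env_p[k] = stats.chi2.sf(effs**2 / np.maximum(var_eff, 1e-300), df=1)

    table = pd.DataFrame({
        "gamma": gamma, "se_gamma": se_g, "p_main": p_main, "p_gxe": p_gxe,
    })
    if markers is not None:
        table = pd.concat([markers.reset_index(drop=True), table], axis=1)
    return GxEScan(
        table=table, env_effects=env_eff, env_wald_p=env_p,
        environments=list(blues.columns), variances=v, markers=markers,
    )


def gge_env_effects(scan: GxEScan, marker_index: int) -> pd.DataFrame:
    """Per-environment GGE effects and Wald p-values for one marker."""
    if not 0 <= marker_index < scan.env_effects.shape[0]:
        raise KeyError(f"marker index {marker_index} not in scan")
    eff = scan.env_effects[marker_index]
    p = scan.env_wald_p[marker_index]
    if np.isnan(eff).all():
        raise ValueError("marker was skipped (monomorphic)")
    return pd.DataFrame({"environment": scan.environments, "effect": eff, "wald_p": p})


# ---------------------------------------------------------------------------
# FDR, QTL intervals, pleiotropy, gene overlap
# ---------------------------------------------------------------------------

def fdr_select(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up selection; returns indices of discoveries."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = ~np.isnan(p)
    rej = np.zeros(p.size, dtype=bool)
    if ok.any():
        rej[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return np.flatnonzero(rej)


@dataclass
class QTLInterval:
    """An LD-delimited QTL region around a lead SNP."""

    trait: str
    phenotype_type: str
    chrom: str
    lead_marker: str
    lead_pos: int
    lead_p: float
    start: int
    end: int
    members: list[str]
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start <= self.lead_pos <= self.end:
            raise ValueError("lead SNP must lie inside its interval")


def delimit_qtl(
    sig_idx: np.ndarray,
    pvals: np.ndarray,
    numeric: np.ndarray,
    markers: pd.DataFrame,
    window: float = 11e6,
    r2_min: float = 0.2,
    trait: str = "trait",
    phenotype_type: str = "blue",
) -> list[QTLInterval]:
    """Greedy LD-based QTL interval delimitation.

    Repeatedly take the most significant remaining marker as lead (ties
    broken toward the smaller position), compute r^2 to every marker within
    ``window`` bp on its chromosome, extend left and right until r^2 drops
    below ``r2_min``, and remove significant markers inside the interval.
    A lead without linked neighbours yields a single-marker interval.
    """
    M = np.asarray(numeric, dtype=float)
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    ids = markers["marker"].to_numpy()
    remaining = sorted(
        np.asarray(sig_idx, dtype=int).tolist(),
        key=lambda i: (pvals[i], pos[i]),
    )
    out = []
    claimed = set()
    for lead in remaining:
        if lead in claimed:
            continue
        sel = np.flatnonzero((chroms == chroms[lead]) & (np.abs(pos - pos[lead]) <= window))
        x = M[:, lead]
        xc = x - x.mean()
        denom_x = float(xc @ xc)
        r2 = np.zeros(sel.size)
        for t, j in enumerate(sel):
            yc = M[:, j] - M[:, j].mean()
            dy = float(yc @ yc)
            r2[t] = (float(xc @ yc) ** 2) / (denom_x * dy) if dy > 0 else 0.0
        lead_t = int(np.flatnonzero(sel == lead)[0])
        left = lead_t
        while left - 1 >= 0 and r2[left - 1] >= r2_min:
            left -= 1
        right = lead_t
        while right + 1 < sel.size and r2[right + 1] >= r2_min:
            right += 1
        span = sel[left:right + 1]
        member_mask = r2[left:right + 1] >= r2_min
        members = span[member_mask]
        start, end = int(pos[span[0]]), int(pos[span[-1]])
        out.append(QTLInterval(
            trait=trait, phenotype_type=phenotype_type, chrom=str(chroms[lead]),
            lead_marker=str(ids[lead]), lead_pos=int(pos[lead]),
            lead_p=float(pvals[lead]), start=start, end=end,
            members=[str(i) for i in ids[members]],
        ))
        for j in remaining:
            if chroms[j] == chroms[lead] and start <= pos[j] <= end:
                claimed.add(j)
    return out


def merge_pleiotropic(
    qtls: list[QTLInterval],
    peak_dist: float = 1e6,
) -> list[list[QTLInterval]]:
    """Group QTL whose intervals overlap or whose peaks are within
    ``peak_dist`` bp (transitive closure)."""
    G = nx.Graph()
    G.add_nodes_from(range(len(qtls)))
    for i in range(len(qtls)):
        for j in range(i + 1, len(qtls)):
            a, b = qtls[i], qtls[j]
            if a.chrom != b.chrom:
                continue
            overlap = a.start <= b.end and b.start <= a.end
            close = abs(a.lead_pos - b.lead_pos) <= peak_dist
            if overlap or close:
                G.add_edge(i, j)
    return [[qtls[i] for i in sorted(comp)] for comp in
            sorted(nx.connected_components(G), key=min)]


def overlap_genes(interval: QTLInterval, genes: pd.DataFrame) -> list[str]:
    """Gene ids whose [start, end] (1-based closed) intersects the interval."""
    g = genes[genes["type"] == "gene"] if "type" in genes.columns else genes
    hit = g[(g["chrom"] == interval.chrom)
            & (g["start"] <= interval.end)
            & (g["end"] >= interval.start)]
    return list(dict.fromkeys(hit["gene_id"]))
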