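"""Population structure: IBS distance, neighbor-joining tree, PCA, LD decay."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import skbio

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def ibs_matrix(geno: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state distance.

    Distance between two lines is the mean allele-sharing mismatch over
    markers where both are called: 0 for identical calls, 1 for opposite
    homozygotes, 1/2 for a het vs a homozygote.  Errors if any pair of
    lines shares no called marker.
    """
    calls = geno.calls.astype(float)
    obs = calls != MISSING
    calls[~obs] = 0.0
    obs_f = obs.astype(float)
    n_shared = obs_f @ obs_f.T
    if (n_shared == 0).any():
        raise ValueError("some line pair shares no non-missing markers")
    # |d_a - d_b| / 2 summed over shared markers, via the dosage identity
    # sum|x-y| = sum(x^2) + sum(y^2) - 2 sum(xy) only for 0/1, so do it blockwise
    n = calls.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(calls[i][None, :] - calls) / 2.0
        diff[~(obs[i][None, :] & obs)] = 0.0
        dist[i] = diff.sum(axis=1) / n_shared[i]
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=geno.lines, columns=geno.lines)


def nj_tree(dist: pd.DataFrame) -> str:
    """Unrooted neighbor-joining tree (Newick text) from a distance matrix.

    For an additive (tree-metric) input, NJ reconstructs the generating
    topology and branch lengths exactly.
    """
    arr = dist.to_numpy()
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if arr.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = skbio.DistanceMatrix(arr, ids=[str(i) for i in dist.index])
    tree = skbio.tree.nj(dm)
    return str(tree).strip()


def pca_genotypes(
    numeric: np.ndarray,
    n_components: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Column-centred genotype PCA.

    Returns (scores, explained-variance fractions) for the leading
    ``n_components`` axes; fractions are non-increasing and sum to <= 1.
    """
    X = np.asarray(numeric, dtype=float)
    if X.shape[0] < n_components:
        raise ValueError("need at least as many lines as components")
    Xc = X - X.mean(axis=0, keepdims=True)
    total = (Xc**2).sum()
    if total <= 0:
        raise ValueError("genotype matrix has no variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    frac = (s[:n_components] ** 2) / total
    return scores, frac


def ld_r2_pairs(
    numeric: np.ndarray,
    pos: np.ndarray,
    chrom: np.ndarray,
    max_dist: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(distance, r^2) for every intra-chromosomal marker pair within
    ``max_dist`` bp.  Monomorphic markers are skipped (count logged)."""
    X = np.asarray(numeric, dtype=float)
    sd = X.std(axis=0)
    mono = sd == 0
    if mono.any():
        logger.info("ld: skipped %d monomorphic markers", int(mono.sum()))
    dists, r2s = [], []
    for c in dict.fromkeys(chrom.tolist()):
        sel = (chrom == c) & ~mono
        p = pos[sel]
        Z = (X[:, sel] - X[:, sel].mean(axis=0)) / sd[sel]
        m = p.size
        for i in range(m):
            j_hi = np.searchsorted(p, p[i] + max_dist, side="right")
            if j_hi <= i + 1:
                continue
            r = Z[:, i] @ Z[:, i + 1:j_hi] / Z.shape[0]
            dists.append(p[i + 1:j_hi] - p[i])
            r2s.append(r**2)
    if not dists:
        return np.array([]), np.array([])
    return np.concatenate(dists).astype(float), np.concatenate(r2s)


def ld_decay_curve(
    geno_numeric: np.ndarray,
    pos: np.ndarray,
    chrom: np.ndarray,
    max_dist: float = 12e6,
    bin_width: float = 5e5,
    r2_target: float = 0.2,
    smooth: str = "isotonic",
) -> pd.DataFrame:
    """Mean r^2 per physical-distance bin, with the interpolated distance at
    which the (optionally isotonic-smoothed) curve first crosses
    ``r2_target``.

    Returns a frame with columns ``bin_mid``, ``mean_r2``, ``smoothed_r2``
    and attribute ``crossing`` (np.nan when the curve never crosses).
    """
    d, r2 = ld_r2_pairs(geno_numeric, pos, chrom, max_dist)
    if d.size == 0:
        raise ValueError("no marker pairs within max_dist")
    edges = np.arange(0, max_dist + bin_width, bin_width)
    which = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(which, weights=r2, minlength=len(edges) - 1)
    counts = np.bincount(which, minlength=len(edges) - 1)
    mask = counts > 0
    mids = (edges[:-1] + edges[1:]) / 2.0
    mean_r2 = np.full(len(mids), np.nan)
    mean_r2[mask] = sums[mask] / counts[mask]
    mids, mean_r2 = mids[mask], mean_r2[mask]
    if smooth == "isotonic":
        from sklearn.isotonic import IsotonicRegression
        iso = IsotonicRegression(increasing=False)
        smoothed = iso.fit_transform(mids, mean_r2, sample_weight=counts[mask])
    elif smooth == "none":
        smoothed = mean_r2.copy()
    else:
        raise ValueError("smooth must be 'isotonic' or 'none'")
    crossing = np.nan
    below = smoothed < r2_target
    if below.any() and not below[0]:
        k = int(np.argmax(below))
        x0, x1 = mids[k - 1], mids[k]
        y0, y1 = smoothed[k - 1], smoothed[k]
        crossing = x0 + (y0 - r2_target) / max(y0 - y1, 1e-12) * (x1 - x0)
    elif below.all():
        crossing = float(mids[0])
    out = pd.DataFrame({"bin_mid": mids, "mean_r2": mean_r2, "smoothed_r2": smoothed})
    out.attrs["crossing"] = float(crossing) if np.isfinite(crossing) else np.nan
    return out
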