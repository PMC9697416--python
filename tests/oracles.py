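"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (plain loops, textbook formulas) and
shares no code with the package paths it checks.
"""

import numpy as np


def window_correct_oracle(origin_row: np.ndarray, window: int):
    """Naive sliding-window corrector on a parental-origin row.

    Codes: 0 = P1, 1 = P2, 2 = het, -1 = missing.  Window genotype is P1
    when the P1 count strictly exceeds 11/15 of non-missing calls in the
    centred window (P2 symmetric, het between), inconsistent calls are
    corrected, and the scan repeats to a fixed point.
    """
    cur = origin_row.copy()
    m = cur.size
    half = window // 2
    while True:
        win = np.empty(m, dtype=np.int8)
        for s in range(m):
            lo = max(0, s - half)
            hi = min(m - 1, s + (window - 1 - half))
            seg = cur[lo:hi + 1]
            p1 = int((seg == 0).sum())
            p2 = int((seg == 1).sum())
            nm = int((seg != -1).sum())
            if nm == 0:
                win[s] = -1
            elif p1 > (11.0 / 15.0) * nm:
                win[s] = 0
            elif p2 > (11.0 / 15.0) * nm:
                win[s] = 1
            else:
                win[s] = 2
        new = cur.copy()
        for s in range(m):
            if win[s] in (0, 1) and cur[s] != -1 and cur[s] != win[s]:
                new[s] = win[s]
        if (new == cur).all():
            return cur, win
        cur = new


def marker_filter_oracle(calls: np.ndarray, maf_min, missing_max, het_max):
    """Per-marker keep decision by explicit counting."""
    n, m = calls.shape
    keep = []
    for k in range(m):
        col = calls[:, k]
        missing = (col == -1).sum()
        called = n - missing
        het = (col == 1).sum()
        alt = 2 * (col == 2).sum() + het
        tot = 2 * called
        if called == 0:
            keep.append(False)
            continue
        af = alt / tot
        maf = min(af, 1 - af)
        keep.append(
            maf >= maf_min and missing / n <= missing_max and het / called <= het_max
        )
    return np.array(keep)


def ibs_oracle(calls: np.ndarray):
    """Pairwise IBS distance by explicit double loop."""
    n = calls.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i], calls[j]
            ok = (a != -1) & (b != -1)
            D[i, j] = D[j, i] = np.abs(a[ok] - b[ok]).sum() / 2.0 / ok.sum()
    return D


def pca_oracle(X: np.ndarray, n_components: int):
    """Dense eigendecomposition of the centred Gram matrix."""
    Xc = X - X.mean(axis=0)
    G = Xc @ Xc.T
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:n_components]
    scores = V[:, order] * np.sqrt(np.maximum(w[order], 0))
    frac = w[order] / w.sum()
    return scores, frac


def bh_oracle(pvals, alpha):
    """Benjamini-Hochberg step-up by the textbook definition."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    if passed.size == 0:
        return np.array([], dtype=int)
    k = passed.max()
    return np.sort(order[: k + 1])


def qtl_boundaries_oracle(M, pos, chrom, lead, window, r2_min):
    """All-pairs r^2 scan from a lead marker, walking out to the first
    marker below the threshold on each side."""
    sel = [j for j in range(M.shape[1])
           if chrom[j] == chrom[lead] and abs(pos[j] - pos[lead]) <= window]
    sel.sort(key=lambda j: pos[j])
    r2 = {}
    for j in sel:
        r = np.corrcoef(M[:, lead], M[:, j])[0, 1]
        r2[j] = 0.0 if np.isnan(r) else r * r
    at = sel.index(lead)
    left = at
    while left - 1 >= 0 and r2[sel[left - 1]] >= r2_min:
        left -= 1
    right = at
    while right + 1 < len(sel) and r2[sel[right + 1]] >= r2_min:
        right += 1
    return pos[sel[left]], pos[sel[right]]


def region_assign_oracle(chrom, p, genes):
    """Single-marker region category by explicit interval checks."""
    def inside(row):
        return row.chrom == chrom and row.start <= p <= row.end

    for t, cat in (("CDS", "cds"), ("five_prime_UTR", "utr5"),
                   ("three_prime_UTR", "utr3")):
        for row in genes.itertuples(index=False):
            if row.type == t and inside(row):
                return cat
    for row in genes.itertuples(index=False):
        if row.type != "gene" or row.chrom != chrom or row.strand not in "+-":
            continue
        if row.strand == "+":
            up = (row.start - 2000, row.start - 1)
            down = (row.end + 1, row.end + 2000)
        else:
            up = (row.end + 1, row.end + 2000)
            down = (row.start - 2000, row.start - 1)
        if up[0] <= p <= up[1]:
            return "upstream2kb"
    for row in genes.itertuples(index=False):
        if row.type != "gene" or row.chrom != chrom or row.strand not in "+-":
            continue
        if row.strand == "+":
            down = (row.end + 1, row.end + 2000)
        else:
            down = (row.start - 2000, row.start - 1)
        if down[0] <= p <= down[1]:
            return "downstream2kb"
    return "intergenic"
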