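"""Genotype container, quality control, and bin-map construction.

Genotypes of multi-family biparental doubled-haploid (DH) populations are
held as allele-dosage calls together with the parental haplotypes of every
family.  The pipeline mirrors the standard low-coverage workflow for such
populations: marker-level filters (mapping quality, missingness, minor
allele frequency, heterozygosity), a per-family segregation-distortion
test, sliding-window correction of genotyping errors with breakpoint/bin
calling, projection of the high-coverage parental genotypes onto progeny
bins, and numeric (+1/-1) coding for downstream linear models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# allele-dosage call codes (count of the alternate allele; DH lines are
# homozygous so HET only appears as a genotyping artefact)
MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

# parental-origin codes used inside a single family
ORIG_P1 = 0
ORIG_P2 = 1
ORIG_HET = 2
ORIG_MISS = -1

CROSS_TYPES = ("F1DH", "BC1DH")


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype calls with map positions and family labels.

    Parameters
    ----------
    lines
        Line identifiers, length ``n``.
    families
        Family label per line, length ``n``.
    markers
        Marker table with columns ``marker``, ``chrom``, ``pos`` (bp,
        1-based, sorted within chromosome) and optionally ``mq``.
    calls
        ``(n, m)`` int8 array of alternate-allele dosages in
        ``{-1, 0, 1, 2}`` (missing, hom-ref, het, hom-alt).
    parents
        Per family, a mapping ``{parent_label: dosage vector}`` with fully
        homozygous calls (values in ``{0, 2}``) at every marker.  The first
        key is parent 1 (the recurrent parent for BC1DH families).
    numeric
        Optional ``(n, m)`` float array of +1/-1 codes set by
        :func:`encode_numeric`.
    """

    lines: list[str]
    families: np.ndarray
    markers: pd.DataFrame
    calls: np.ndarray
    parents: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    numeric: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.families = np.asarray(self.families)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        if len(self.families) != len(self.lines):
            raise ValueError("one family label required per line")
        bad = ~np.isin(self.calls, (MISSING, HOM_REF, HET, HOM_ALT))
        if bad.any():
            raise ValueError("calls outside {-1, 0, 1, 2}")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"marker positions not sorted on {chrom}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def family_lines(self, family: str) -> np.ndarray:
        return np.flatnonzero(self.families == family)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        parents = {
            fam: {p: hap[keep] for p, hap in haps.items()}
            for fam, haps in self.parents.items()
        }
        return GenotypeMatrix(
            lines=list(self.lines),
            families=self.families.copy(),
            markers=self.markers.iloc[keep].reset_index(drop=True),
            calls=self.calls[:, keep].copy(),
            parents=parents,
            numeric=None if self.numeric is None else self.numeric[:, keep].copy(),
        )

    def subset_lines(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            lines=[self.lines[i] for i in keep],
            families=self.families[keep].copy(),
            markers=self.markers.copy(),
            calls=self.calls[keep].copy(),
            parents={fam: {p: h.copy() for p, h in hp.items()} for fam, hp in self.parents.items()},
            numeric=None if self.numeric is None else self.numeric[keep].copy(),
        )

    def parent_haplotypes(self, family: str) -> tuple[np.ndarray, np.ndarray]:
        """Dosage vectors of (parent 1, parent 2) for a family."""
        haps = list(self.parents[family].values())
        if len(haps) != 2:
            raise ValueError(f"family {family} needs exactly two parents")
        return haps[0], haps[1]

    def to_origin(self, family: str) -> np.ndarray:
        """Recode a family's calls as parental origins.

        Markers where the two parents carry the same allele are
        uninformative and coded missing.
        """
        idx = self.family_lines(family)
        p1, p2 = self.parent_haplotypes(family)
        calls = self.calls[idx]
        out = np.full(calls.shape, ORIG_MISS, dtype=np.int8)
        poly = p1 != p2
        eq_p1 = poly[None, :] & (calls == p1[None, :])
        eq_p2 = poly[None, :] & (calls == p2[None, :])
        out[eq_p1] = ORIG_P1
        out[eq_p2] = ORIG_P2
        out[poly[None, :] & (calls == HET)] = ORIG_HET
        return out


@dataclass
class BinMap:
    """Recombination bins per line: segments of constant parental origin.

    ``bins`` is a table with columns ``line``, ``family``, ``chrom``,
    ``start``, ``end`` (bp, 1-based closed) and ``parent`` (``"P1"`` /
    ``"P2"``).  Breakpoints are the boundaries between adjacent bins.
    """

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        for (_, chrom), sub in self.bins.groupby(["line", "chrom"], sort=False):
            starts = sub["start"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                raise ValueError(f"bins not ordered for chromosome {chrom}")
            par = sub["parent"].to_numpy()
            if np.any(par[1:] == par[:-1]):
                raise ValueError("adjacent bins share a source parent")

    def n_breakpoints(self, line: str | None = None) -> int:
        sub = self.bins if line is None else self.bins[self.bins["line"] == line]
        return sum(len(g) - 1 for _, g in sub.groupby(["line", "chrom"], sort=False))

    def to_bed(self) -> pd.DataFrame:
        """BED-like frame (0-based half-open)."""
        bed = self.bins[["chrom", "start", "end", "line", "parent"]].copy()
        bed["start"] = bed["start"] - 1
        return bed


def _marker_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (maf, missing rate, het rate) from dosage calls."""
    n = calls.shape[0]
    missing = (calls == MISSING).sum(axis=0)
    het = (calls == HET).sum(axis=0)
    hom_ref = (calls == HOM_REF).sum(axis=0)
    hom_alt = (calls == HOM_ALT).sum(axis=0)
    n_called = n - missing
    alt_count = 2 * hom_alt + het
    total = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(total > 0, alt_count / np.maximum(total, 1), 0.0)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    maf[n_called == 0] = 0.0
    missing_rate = missing / n
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(n_called > 0, het / np.maximum(n_called, 1), 0.0)
    return maf, missing_rate, het_rate


def filter_by_mq(geno: GenotypeMatrix, min_mq: float = 5.0) -> GenotypeMatrix:
    """Drop markers whose mapping quality (``mq`` marker column) is below
    ``min_mq``.  Markers without an ``mq`` column are all retained."""
    if "mq" not in geno.markers.columns:
        return geno
    keep = geno.markers["mq"].to_numpy() >= min_mq
    return geno.subset_markers(keep)


def filter_variants(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.3,
    het_max: float = 0.3,
) -> GenotypeMatrix:
    """Marker-level QC: keep markers with MAF >= ``maf_min``, missing rate
    <= ``missing_max`` and heterozygosity rate <= ``het_max``.

    Boundary values are retained (a marker at exactly MAF 0.05 passes).
    Marker order is preserved.
    """
    maf, miss, het = _marker_stats(geno.calls)
    keep = (maf >= maf_min) & (miss <= missing_max) & (het <= het_max)
    if not keep.any():
        warnings.warn("all markers removed by variant filters", stacklevel=2)
    return geno.subset_markers(keep)


def set_het_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Recode residual heterozygous calls as missing (DH lines are expected
    to be fully homozygous, so remaining hets are treated as call errors)."""
    calls = geno.calls.copy()
    calls[calls == HET] = MISSING
    return replace(geno, calls=calls, numeric=None)


def segregation_filter(
    geno: GenotypeMatrix,
    cross_types: dict[str, str],
    alpha: float = 0.005,
    min_informative: int = 10,
) -> GenotypeMatrix:
    """Remove markers showing segregation distortion in any family.

    A 1-df chi-square goodness-of-fit test on homozygous parental-origin
    counts against the expected ratio: 1:1 for F1DH families, 3:1 toward
    the recurrent parent (parent 1) for BC1DH families.  A marker is
    removed when p < ``alpha`` in at least one family with at least
    ``min_informative`` informative (homozygous, polymorphic) calls;
    families below that count are skipped for that marker.
    """
    m = geno.n_markers
    remove = np.zeros(m, dtype=bool)
    for fam in dict.fromkeys(geno.families.tolist()):
        cross = cross_types.get(fam, "F1DH")
        if cross not in CROSS_TYPES:
            raise ValueError(f"unknown cross type {cross!r} for family {fam}")
        p_expected = 0.5 if cross == "F1DH" else 0.75
        orig = geno.to_origin(fam)
        n1 = (orig == ORIG_P1).sum(axis=0).astype(float)
        n2 = (orig == ORIG_P2).sum(axis=0).astype(float)
        n = n1 + n2
        testable = n >= min_informative
        skipped = int((~testable).sum())
        if skipped:
            logger.warning(
                "family %s: %d markers with < %d informative calls skipped",
                fam, skipped, min_informative,
            )
        e1 = n * p_expected
        e2 = n * (1 - p_expected)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = (n1 - e1) ** 2 / np.maximum(e1, 1e-300) + (n2 - e2) ** 2 / np.maximum(e2, 1e-300)
        pvals = stats.chi2.sf(chi2, df=1)
        remove |= testable & (pvals < alpha)
    return geno.subset_markers(~remove)


def _window_genotypes(origin_row: np.ndarray, window: int) -> np.ndarray:
    """Per-SNP window genotype for one line on one chromosome.

    The window for SNP ``s`` spans ``window`` consecutive SNPs centred on
    ``s`` (truncated at chromosome ends).  The window is called P1 when the
    P1 count strictly exceeds 11/15 of the non-missing calls in the window
    (the "over 11:4" rule applied as a fraction so truncated and
    missing-containing windows use the same threshold), P2 symmetrically,
    and heterozygous in between.  Heterozygous calls count toward neither
    parent but do count as non-missing.
    """
    m = origin_row.size
    half = window // 2
    is_p1 = (origin_row == ORIG_P1).astype(np.int64)
    is_p2 = (origin_row == ORIG_P2).astype(np.int64)
    nonmiss = (origin_row != ORIG_MISS).astype(np.int64)
    c1 = np.concatenate(([0], np.cumsum(is_p1)))
    c2 = np.concatenate(([0], np.cumsum(is_p2)))
    cn = np.concatenate(([0], np.cumsum(nonmiss)))
    idx = np.arange(m)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (window - 1 - half), m - 1) + 1
    p1 = c1[hi] - c1[lo]
    p2 = c2[hi] - c2[lo]
    nm = cn[hi] - cn[lo]
    out = np.full(m, ORIG_HET, dtype=np.int8)
    thresh = 11.0 / 15.0
    out[p1 > thresh * nm] = ORIG_P1
    out[p2 > thresh * nm] = ORIG_P2
    out[nm == 0] = ORIG_MISS
    return out


def window_correct(
    family_geno: GenotypeMatrix,
    window: int = 15,
    max_passes: int = 25,
) -> tuple[GenotypeMatrix, BinMap]:
    """Sliding-window error correction and breakpoint calling for one family.

    Each SNP's window genotype is evaluated from the ``window`` SNPs
    centred on it; SNP calls inconsistent with a homozygous window genotype
    (the other parent's allele, or a heterozygous call) are corrected to
    the window's parent.  Because corrections change window counts, the
    scan is repeated until a fixed point, which makes the operation
    idempotent.  A breakpoint is recorded where consecutive window
    genotypes switch homozygous parent; the fragments between breakpoints
    are the bins.
    """
    fams = set(family_geno.families.tolist())
    if len(fams) != 1:
        raise ValueError("window_correct expects a single-family genotype matrix")
    fam = fams.pop()
    p1, p2 = family_geno.parent_haplotypes(fam)
    calls = family_geno.calls.copy()
    chroms = family_geno.markers["chrom"].to_numpy()
    pos = family_geno.markers["pos"].to_numpy()
    chrom_slices = _chrom_slices(chroms)
    for _, sl in chrom_slices:
        if sl.stop - sl.start < window:
            warnings.warn(
                f"window ({window}) exceeds chromosome marker count "
                f"({sl.stop - sl.start}); processed as a single window",
                stacklevel=2,
            )

    bin_rows = []
    for li, line in enumerate(family_geno.lines):
        for chrom, sl in chrom_slices:
            sub_p1, sub_p2 = p1[sl], p2[sl]
            poly = sub_p1 != sub_p2
            row = calls[li, sl]
            origin = _origin_from_calls(row, sub_p1, sub_p2, poly)
            win = _window_genotypes(origin, window)
            for _ in range(max_passes):
                corr_p1 = (win == ORIG_P1) & poly & (origin != ORIG_P1) & (origin != ORIG_MISS)
                corr_p2 = (win == ORIG_P2) & poly & (origin != ORIG_P2) & (origin != ORIG_MISS)
                if not (corr_p1.any() or corr_p2.any()):
                    break
                origin[corr_p1] = ORIG_P1
                origin[corr_p2] = ORIG_P2
                win = _window_genotypes(origin, window)
            row = row.copy()
            row[origin == ORIG_P1] = sub_p1[origin == ORIG_P1]
            row[origin == ORIG_P2] = sub_p2[origin == ORIG_P2]
            calls[li, sl] = row
            bin_rows.extend(
                _bins_from_windows(win, pos[sl], line, fam, chrom)
            )
    corrected = replace(family_geno, calls=calls, numeric=None)
    return corrected, BinMap(pd.DataFrame(
        bin_rows, columns=["line", "family", "chrom", "start", "end", "parent"]
    ))


def _origin_from_calls(row, p1, p2, poly):
    out = np.full(row.shape, ORIG_MISS, dtype=np.int8)
    out[poly & (row == p1)] = ORIG_P1
    out[poly & (row == p2)] = ORIG_P2
    out[poly & (row == HET)] = ORIG_HET
    return out


def _bins_from_windows(win, pos, line, fam, chrom):
    """Segment the window-genotype track into parental bins.

    Only homozygous window calls anchor bins; the breakpoint between two
    opposite homozygous stretches is placed at the midpoint between the
    last SNP of one stretch and the first SNP of the next.
    """
    hom_idx = np.flatnonzero((win == ORIG_P1) | (win == ORIG_P2))
    if hom_idx.size == 0:
        return []
    rows = []
    seg_parent = win[hom_idx[0]]
    seg_start = pos[0]
    prev_hom = hom_idx[0]
    for i in hom_idx[1:]:
        if win[i] != seg_parent:
            mid = (pos[prev_hom] + pos[i]) // 2
            rows.append((line, fam, chrom, int(seg_start), int(mid), _pname(seg_parent)))
            seg_start = mid + 1
            seg_parent = win[i]
        prev_hom = i
    rows.append((line, fam, chrom, int(seg_start), int(pos[-1]), _pname(seg_parent)))
    return rows


def _pname(code: int) -> str:
    return "P1" if code == ORIG_P1 else "P2"


def _chrom_slices(chroms: np.ndarray) -> list[tuple[str, slice]]:
    out = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out.append((chroms[start], slice(start, i)))
            start = i
    return out


def build_bins_and_project(
    bin_maps: dict[str, BinMap],
    family_genos: dict[str, GenotypeMatrix],
) -> GenotypeMatrix:
    """Project parental genotypes onto progeny bins and merge families.

    Within each progeny bin all markers receive the source parent's allele,
    which both fills missing calls and supplies genotypes at loci that are
    monomorphic within the family (treated as missing before the merge and
    recovered here because both parents share the allele).  The merged
    matrix covers the union of loci polymorphic in at least one family.
    Bins that never received a parental assignment stay missing and are
    counted in the log.
    """
    fams = list(family_genos)
    ref = family_genos[fams[0]].markers
    for fam in fams[1:]:
        if not family_genos[fam].markers["marker"].equals(ref["marker"]):
            raise ValueError("family matrices must share one marker table")

    projected = []
    unassigned = 0
    for fam in fams:
        geno = family_genos[fam]
        p1, p2 = geno.parent_haplotypes(fam)
        chroms = geno.markers["chrom"].to_numpy()
        pos = geno.markers["pos"].to_numpy()
        calls = np.full_like(geno.calls, MISSING)
        bins = bin_maps[fam].bins
        line_idx = {ln: i for i, ln in enumerate(geno.lines)}
        covered = np.zeros_like(calls, dtype=bool)
        for row in bins.itertuples(index=False):
            li = line_idx[row.line]
            sel = (chroms == row.chrom) & (pos >= row.start) & (pos <= row.end)
            src = p1 if row.parent == "P1" else p2
            calls[li, sel] = src[sel]
            covered[li, sel] = True
        unassigned += int((~covered).sum())
        projected.append(calls)
    if unassigned:
        logger.info("projection left %d calls missing (outside assigned bins)", unassigned)

    poly_any = np.zeros(len(ref), dtype=bool)
    for fam in fams:
        p1, p2 = family_genos[fam].parent_haplotypes(fam)
        poly_any |= p1 != p2

    merged = GenotypeMatrix(
        lines=[ln for fam in fams for ln in family_genos[fam].lines],
        families=np.concatenate([family_genos[fam].families for fam in fams]),
        markers=ref.copy(),
        calls=np.vstack(projected),
        parents={fam: dict(family_genos[fam].parents[fam].items()) for fam in fams},
    )
    return merged.subset_markers(poly_any)


def encode_numeric(geno: GenotypeMatrix, mean_fill: bool = False) -> GenotypeMatrix:
    """Numeric coding: major allele +1, minor allele -1.

    With no missing data the per-marker mean is ``1 - 2*MAF``.  Ties at
    exactly 50:50 give the reference (lexicographically smaller) allele +1.
    Residual missing calls raise unless ``mean_fill`` imputes them at the
    marker mean; heterozygous calls are coded 0.
    """
    calls = geno.calls
    if (calls == MISSING).any() and not mean_fill:
        raise ValueError("missing calls remain; project bins first or set mean_fill=True")
    hom_ref = (calls == HOM_REF).sum(axis=0)
    hom_alt = (calls == HOM_ALT).sum(axis=0)
    ref_major = hom_ref >= hom_alt  # tie -> ref (allele 0) coded +1
    sign = np.where(ref_major, -1.0, 1.0)  # multiply dosage-centred code
    x = (calls.astype(float) - 1.0) * sign[None, :]  # hom 0 -> -sign, hom 2 -> +sign, het -> 0
    x[calls == MISSING] = np.nan
    if mean_fill:
        col_mean = np.nanmean(x, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(x))
        x[nan_r, nan_c] = col_mean[nan_c]
    return replace(geno, numeric=x)


def qc_report(steps: dict[str, GenotypeMatrix]) -> dict[str, int]:
    """Marker counts after each named pipeline step (JSON-serializable)."""
    return {name: g.n_markers for name, g in steps.items()}
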