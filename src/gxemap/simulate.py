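"""Synthetic multi-family DH populations and multi-environment trials.

The generator emulates the structure of a multi-family maize experiment:
several biparental doubled-haploid (DH or BC1DH) families genotyped at a
shared marker panel, evaluated in augmented alpha designs with replicated
checks across several macro-environments.  Meiosis follows the Haldane
model (crossovers as a Poisson process on the genetic map, no
interference).  Phenotypes are built from a genotype main effect, planted
QTL with environment-specific effects, a Finlay-Wilkinson linear-response
term, replicate and block effects, and heteroscedastic plot errors, and
every simulated effect is kept in a truth ledger so recovery tests never
re-derive truth from the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import HOM_ALT, HOM_REF, HET, MISSING, CROSS_TYPES, GenotypeMatrix

DEFAULT_FAMILY_SIZES = {
    "SYLO": 17, "HBYLZS": 22, "DDY": 35, "BJNL": 38, "HNND": 44, "SXDF": 78,
}
DEFAULT_BC1DH_FAMILY = "SXDF"
DEFAULT_ENV_NAMES = (
    "SZ.2019.P0", "SZ.2019.P1", "SZ.2020.P0", "SZ.2020.P1",
    "SZ.2021.P2", "QZ.2020.P3", "QZ.2020.P4",
)
DEFAULT_CHECKS = ("Zheng58", "Chang7-2")


@dataclass
class GeneticMap:
    """Marker map: physical (bp, 1-based) and genetic (cM) positions."""

    table: pd.DataFrame  # columns: chrom, pos, cm

    def __post_init__(self) -> None:
        for chrom, sub in self.table.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError(f"physical positions not strictly increasing on {chrom}")
            if not np.all(np.diff(sub["cm"].to_numpy()) >= 0):
                raise ValueError(f"cM not non-decreasing with bp on {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chrom_lengths_cm(self) -> dict[str, float]:
        return {c: float(s["cm"].max() - s["cm"].min())
                for c, s in self.table.groupby("chrom", sort=False)}

    def total_length_cm(self) -> float:
        return float(sum(self.chrom_lengths_cm().values()))


@dataclass
class FamilySpec:
    """A biparental DH family: name, parents, cross type, size.

    For BC1DH families ``parent1`` is the recurrent parent (expected
    allele ratio 3:1 in its favour); F1DH families segregate 1:1.
    """

    name: str
    parent1: str
    parent2: str
    cross: str = "F1DH"
    size: int = 2

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("family size must be >= 2")
        if self.cross not in CROSS_TYPES:
            raise ValueError(f"cross must be one of {CROSS_TYPES}")


@dataclass
class QtlSpec:
    """A planted QTL: marker index, trait, per-environment additive effects.

    The effect is in trait units per allele substitution on the +1/-1
    numeric scale.  ``qtl_type`` labels the pattern across environments:
    ``additive`` (identical effects), ``divergence``/``convergence``
    (same sign, different sizes) or ``crossover`` (at least one sign flip).
    """

    marker: int
    trait: str
    effects: np.ndarray
    qtl_type: str = "additive"

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        signs = np.sign(self.effects[self.effects != 0])
        if self.qtl_type == "crossover":
            if signs.size and (signs == signs[0]).all():
                raise ValueError("crossover QTL needs a sign change across environments")
        if self.qtl_type == "additive":
            if not np.allclose(self.effects, self.effects[0]):
                raise ValueError("additive QTL needs identical effects across environments")


@dataclass
class EnvSpec:
    """A macro-environment (year.location.Plevel): main effect and plot-error SD."""

    name: str
    effect: float
    resid_sd: float

    def __post_init__(self) -> None:
        if self.resid_sd <= 0:
            raise ValueError("residual sd must be > 0")


@dataclass
class TrialDesign:
    """Augmented alpha design: replicates with nested blocks, replicated checks."""

    replicates: int = 2
    block_size: int = 20
    checks: tuple[str, ...] = DEFAULT_CHECKS
    block_sd: float = 0.5
    rep_sd: float = 0.5


def make_genetic_map(
    n_chrom: int,
    markers_per_chrom: int,
    chrom_length_bp: int,
    cm_per_mb: float = 1.0,
    seed: int = 0,
) -> GeneticMap:
    """Uniformly spaced (jittered) marker map with a constant cM/Mb rate."""
    if n_chrom < 1 or markers_per_chrom < 1 or chrom_length_bp < 1:
        raise ValueError("map sizing inputs must be positive")
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be > 0")
    if chrom_length_bp <= 2 * markers_per_chrom:
        raise ValueError("chromosome too short for the requested marker count")
    rng = np.random.default_rng(seed)
    rows = []
    idx = np.arange(markers_per_chrom)
    for c in range(n_chrom):
        spacing = chrom_length_bp / markers_per_chrom
        base = (idx + 0.5) * spacing
        jitter = rng.uniform(-0.4, 0.4, markers_per_chrom) * spacing
        pos = np.floor(np.sort(base + jitter)).astype(np.int64) + 1
        # enforce strict increase after rounding (monotone-envelope trick)
        pos = np.maximum.accumulate(pos - idx) + idx
        cm = pos / 1e6 * cm_per_mb
        chrom = f"chr{c + 1}"
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "cm": cm}))
    table = pd.concat(rows, ignore_index=True)
    return GeneticMap(table)


def _meiosis_mosaic(cm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Origin (0/1) of each marker on one gamete chromosome, Haldane model.

    Crossovers form a Poisson process with intensity 1 per Morgan along the
    genetic map; the starting homolog is fair.  Zero cM between two markers
    implies zero recombination between them.
    """
    length_m = (cm[-1] - cm[0]) / 100.0
    n_xo = rng.poisson(length_m)
    start = rng.integers(0, 2)
    if n_xo == 0:
        return np.full(cm.size, start, dtype=np.int8)
    xo = np.sort(rng.uniform(cm[0], cm[-1], n_xo))
    crossings = np.searchsorted(xo, cm, side="left")
    return ((start + crossings) % 2).astype(np.int8)


def simulate_dh_family(
    spec: FamilySpec,
    gmap: GeneticMap,
    seed: int = 0,
    parent_haplotypes: tuple[np.ndarray, np.ndarray] | None = None,
) -> GenotypeMatrix:
    """Simulate one DH family as mosaics of the two parental haplotypes.

    Parents must be fully homozygous; by default they carry opposite
    alleles at every marker (parent 1 all-reference, parent 2
    all-alternate).  F1DH lines are doubled gametes of the F1 (1:1
    segregation); BC1DH lines are doubled gametes of an F1 x parent-1
    backcross individual (3:1 toward the recurrent parent 1).  The parental
    origin of every call is stored in ``origins`` for truth-based tests.
    """
    m = gmap.n_markers
    if parent_haplotypes is None:
        p1 = np.full(m, HOM_REF, dtype=np.int8)
        p2 = np.full(m, HOM_ALT, dtype=np.int8)
    else:
        p1 = np.asarray(parent_haplotypes[0], dtype=np.int8)
        p2 = np.asarray(parent_haplotypes[1], dtype=np.int8)
        for hap in (p1, p2):
            if np.isin(hap, (HET, MISSING)).any():
                raise ValueError("parents must be fully homozygous")
    rng = np.random.default_rng(seed)
    chrom_vals = gmap.table["chrom"].to_numpy()
    cms = gmap.table["cm"].to_numpy()
    bounds = np.flatnonzero(np.r_[True, chrom_vals[1:] != chrom_vals[:-1], True])
    origins = np.empty((spec.size, m), dtype=np.int8)
    for i in range(spec.size):
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            mosaic = _meiosis_mosaic(cms[b0:b1], rng)
            if spec.cross == "BC1DH":
                # the BC1 plant carries (F1 gamete, recurrent haplotype);
                # its own gamete recombines between those two homologs
                pick = _meiosis_mosaic(cms[b0:b1], rng)
                mosaic = np.where(pick == 0, mosaic, 0).astype(np.int8)
            origins[i, b0:b1] = mosaic
    calls = np.where(origins == 0, p1[None, :], p2[None, :]).astype(np.int8)
    lines = [f"{spec.name}-{i + 1:03d}" for i in range(spec.size)]
    geno = GenotypeMatrix(
        lines=lines,
        families=np.array([spec.name] * spec.size),
        markers=gmap.table[["chrom", "pos"]].assign(
            marker=[f"{c}_{p}" for c, p in zip(chrom_vals, gmap.table["pos"])]
        )[["marker", "chrom", "pos"]].reset_index(drop=True),
        calls=calls,
        parents={spec.name: {spec.parent1: p1, spec.parent2: p2}},
    )
    geno.origins = origins
    return geno


def simulate_families(
    specs: list[FamilySpec],
    gmap: GeneticMap,
    seed: int = 0,
    polymorphic_frac: float = 0.7,
) -> dict[str, GenotypeMatrix]:
    """Simulate several families on a shared marker panel.

    Founder haplotypes are drawn per family: a marker is polymorphic within
    a family with probability ``polymorphic_frac``; otherwise both parents
    share a random allele (the within-family monomorphic loci that the
    cross-family merge must handle).
    """
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    out = {}
    for k, spec in enumerate(specs):
        poly = rng.random(m) < polymorphic_frac
        base = rng.integers(0, 2, m) * 2
        p1 = base.astype(np.int8)
        p2 = np.where(poly, 2 - base, base).astype(np.int8)
        out[spec.name] = simulate_dh_family(
            spec, gmap, seed=int(rng.integers(0, 2**31 - 1)),
            parent_haplotypes=(p1, p2),
        )
    return out


def merge_families(fams: dict[str, GenotypeMatrix]) -> GenotypeMatrix:
    """Stack per-family genotype matrices (shared marker panel) into one
    multi-family matrix, keeping every family's parental haplotypes."""
    names = list(fams)
    ref = fams[names[0]].markers
    for nm in names[1:]:
        if not fams[nm].markers["marker"].equals(ref["marker"]):
            raise ValueError("families must share one marker table")
    merged = GenotypeMatrix(
        lines=[l for nm in names for l in fams[nm].lines],
        families=np.concatenate([fams[nm].families for nm in names]),
        markers=ref.copy(),
        calls=np.vstack([fams[nm].calls for nm in names]),
        parents={nm: dict(fams[nm].parents[nm].items()) for nm in names},
    )
    if all(hasattr(fams[nm], "origins") for nm in names):
        merged.origins = np.vstack([fams[nm].origins for nm in names])
    return merged


def corrupt_genotypes(
    geno: GenotypeMatrix,
    error_rate: float = 0.0,
    het_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Inject genotyping noise: allele flips, spurious hets, missing calls.

    Each call independently becomes flipped / heterozygous / missing with
    the given probabilities (mutually exclusive; rates must sum to <= 1).
    The input matrix is not modified.
    """
    rates = np.array([error_rate, het_rate, missing_rate])
    if ((rates < 0) | (rates > 1)).any() or rates.sum() > 1:
        raise ValueError("rates must be in [0, 1] and sum to <= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(geno.calls.shape)
    calls = geno.calls.copy()
    hom = (calls == HOM_REF) | (calls == HOM_ALT)
    flip = (u < error_rate) & hom
    het = (u >= error_rate) & (u < error_rate + het_rate)
    miss = (u >= error_rate + het_rate) & (u < rates.sum())
    calls[flip] = 2 - calls[flip]
    calls[het] = HET
    calls[miss] = MISSING
    new = GenotypeMatrix(
        lines=list(geno.lines),
        families=geno.families.copy(),
        markers=geno.markers.copy(),
        calls=calls,
        parents={f: {p: h.copy() for p, h in hp.items()} for f, hp in geno.parents.items()},
    )
    if hasattr(geno, "origins"):
        new.origins = geno.origins.copy()
    return new


@dataclass
class TrialData:
    """Plot-level phenotypes of a multi-environment trial.

    ``plots`` has columns ``line``, ``env``, ``rep``, ``block``,
    ``is_check`` and ``value``; ``trait`` names the measured trait and
    ``truth`` (when simulated) holds every generating effect.
    """

    plots: pd.DataFrame
    trait: str = "trait"
    truth: dict = field(default_factory=dict)

    @property
    def environments(self) -> list[str]:
        return list(dict.fromkeys(self.plots["env"]))

    def truth_json(self) -> str:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        return json.dumps(self.truth, default=conv)


def simulate_trial(
    geno: GenotypeMatrix,
    qtls: list[QtlSpec],
    envs: list[EnvSpec],
    design: TrialDesign | None = None,
    fw_slopes: np.ndarray | None = None,
    mu: float = 0.0,
    sigma_g: float = 1.0,
    sigma_ge: float = 0.0,
    polygenic: str = "markers",
    n_background: int = 200,
    trait: str = "trait",
    seed: int = 0,
) -> TrialData:
    """Simulate plot values for an augmented alpha multi-environment trial.

    Plot value = mu + g_i + ge_ij + sum_q x_iq * beta_q(env) + (1 + b_i) * h_j
    + replicate + block + heteroscedastic error, where ``h_j`` is the
    environment main effect, ``ge_ij ~ N(0, sigma_ge^2)`` an exchangeable
    line-by-environment interaction, ``b_i`` the per-line linear-plasticity
    deviation (slopes default to 1) and ``x`` the +1/-1 marker code.  The
    genotype main effect ``g_i`` is built either from ``n_background``
    random marker effects scaled to variance ``sigma_g**2`` (family
    structure then propagates into the phenotype) or drawn iid normal.
    Checks receive fixed genotypic values, appear in every block, and are
    flagged so downstream analyses can exclude them.
    """
    if len(envs) < 2:
        raise ValueError("at least two environments required for a G-by-E trial")
    design = design or TrialDesign()
    rng = np.random.default_rng(seed)
    n = geno.n_lines
    env_names = [e.name for e in envs]
    for q in qtls:
        if not 0 <= q.marker < geno.n_markers:
            raise ValueError(f"QTL marker index {q.marker} not in genotype matrix")
        if q.effects.size != len(envs):
            raise ValueError("QTL effect vector length must equal number of environments")

    x = geno.calls.astype(float) - 1.0  # -1 / +1 for DH lines
    if polygenic == "markers":
        bg = rng.choice(geno.n_markers, size=min(n_background, geno.n_markers), replace=False)
        eff = rng.normal(0, 1, bg.size)
        g = x[:, bg] @ eff
        sd = g.std()
        g = g / sd * sigma_g if sd > 0 else g
    elif polygenic == "iid":
        g = rng.normal(0, sigma_g, n)
    else:
        raise ValueError("polygenic must be 'markers' or 'iid'")

    slopes = np.ones(n) if fw_slopes is None else np.asarray(fw_slopes, dtype=float)
    if slopes.size != n:
        raise ValueError("one slope per line required")
    b = slopes - 1.0

    qtl_value = np.zeros((n, len(envs)))
    for q in qtls:
        qtl_value += np.outer(x[:, q.marker], q.effects)
    ge = rng.normal(0, sigma_ge, (n, len(envs))) if sigma_ge > 0 else np.zeros((n, len(envs)))

    check_g = {c: rng.normal(0, sigma_g) for c in design.checks}
    n_blocks = max(1, int(np.ceil(n / design.block_size)))

    rows = []
    truth_blocks = {}
    truth_reps = {}
    for j, env in enumerate(envs):
        rep_eff = rng.normal(0, design.rep_sd, design.replicates)
        truth_reps[env.name] = rep_eff
        for r in range(design.replicates):
            order = rng.permutation(n)
            blk_eff = rng.normal(0, design.block_sd, n_blocks)
            truth_blocks[f"{env.name}.rep{r + 1}"] = blk_eff
            for bi in range(n_blocks):
                members = order[bi * design.block_size:(bi + 1) * design.block_size]
                block_id = f"{env.name}.rep{r + 1}.b{bi + 1}"
                for li in members:
                    val = (mu + g[li] + ge[li, j] + qtl_value[li, j] + slopes[li] * env.effect
                           + rep_eff[r] + blk_eff[bi]
                           + rng.normal(0, env.resid_sd))
                    rows.append((geno.lines[li], env.name, f"rep{r + 1}", block_id, False, val))
                for check in design.checks:
                    val = (mu + check_g[check] + env.effect
                           + rep_eff[r] + blk_eff[bi]
                           + rng.normal(0, env.resid_sd))
                    rows.append((check, env.name, f"rep{r + 1}", block_id, True, val))
    plots = pd.DataFrame(rows, columns=["line", "env", "rep", "block", "is_check", "value"])
    truth = {
        "mu": mu,
        "lines": list(geno.lines),
        "g": g,
        "ge": ge,
        "sigma_ge": sigma_ge,
        "slopes": slopes,
        "h": np.array([e.effect for e in envs]),
        "envs": env_names,
        "resid_sd": np.array([e.resid_sd for e in envs]),
        "qtl": [
            {"marker": q.marker, "effects": q.effects, "type": q.qtl_type}
            for q in qtls
        ],
        "checks": check_g,
        "rep_effects": truth_reps,
        "block_effects": truth_blocks,
        "sigma_g": sigma_g,
    }
    return TrialData(plots=plots, trait=trait, truth=truth)


def make_gene_models(
    chrom_lengths: dict[str, int],
    n_genes_per_chrom: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic single-exon gene models for region-annotation tests.

    Each gene carries a 5' UTR, a CDS and a 3' UTR laid out strand-aware on
    a random strand; genes are spaced so that models (with their 2 kb
    flanks) never overlap.  Returns a feature table compatible with
    :func:`gxemap.io.read_gff3_features` (columns chrom, start, end,
    strand, type, gene_id).
    """
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    for chrom, length in chrom_lengths.items():
        slot = length // n_genes_per_chrom
        if slot < 10_000:
            raise ValueError("chromosome too short for the requested gene count")
        for k in range(n_genes_per_chrom):
            gid += 1
            utr5 = int(rng.integers(300, 1500))
            cds = int(rng.integers(1000, 5000))
            utr3 = int(rng.integers(300, 2000))
            glen = utr5 + cds + utr3
            lo = k * slot + FLANK_MARGIN
            hi = (k + 1) * slot - FLANK_MARGIN - glen
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + glen - 1
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"Gene{gid:05d}"
            rows.append((chrom, start, end, strand, "gene", name))
            if strand == "+":
                rows.append((chrom, start, start + utr5 - 1, strand, "five_prime_UTR", name))
                rows.append((chrom, start + utr5, start + utr5 + cds - 1, strand, "CDS", name))
                rows.append((chrom, start + utr5 + cds, end, strand, "three_prime_UTR", name))
            else:
                rows.append((chrom, end - utr5 + 1, end, strand, "five_prime_UTR", name))
                rows.append((chrom, start + utr3, end - utr5, strand, "CDS", name))
                rows.append((chrom, start, start + utr3 - 1, strand, "three_prime_UTR", name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "type", "gene_id"])


FLANK_MARGIN = 2500  # keeps synthetic genes plus 2 kb flanks disjoint


def default_family_specs(
    bc1dh_family: str = DEFAULT_BC1DH_FAMILY,
    sizes: dict[str, int] | None = None,
) -> list[FamilySpec]:
    """The six-family layout used throughout the package's examples:
    sizes 17/22/35/38/44/78 with one BC1DH family."""
    sizes = sizes or DEFAULT_FAMILY_SIZES
    specs = []
    for name, size in sizes.items():
        cross = "BC1DH" if name == bc1dh_family else "F1DH"
        specs.append(FamilySpec(
            name=name, parent1=f"{name}.P1", parent2=f"{name}.P2",
            cross=cross, size=size,
        ))
    return specs


def default_env_specs(
    effects: np.ndarray | None = None,
    resid_sds: np.ndarray | None = None,
) -> list[EnvSpec]:
    """Seven macro-environments with centred main effects and heterogeneous
    plot-error SDs (defaults picked to resemble a mid-heritability trait)."""
    names = DEFAULT_ENV_NAMES
    if effects is None:
        effects = np.array([4.0, 1.0, 2.5, -0.5, -1.5, -2.0, -3.5])
    if resid_sds is None:
        resid_sds = np.array([1.4, 1.0, 1.2, 0.9, 1.1, 1.3, 1.0])
    return [EnvSpec(n, float(e), float(s)) for n, e, s in zip(names, effects, resid_sds)]
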