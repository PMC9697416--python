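"""Reading and writing the standard interchange formats.

Genotypes travel as VCF (GT field, contigs from the marker table, mapping
quality in INFO/MQ), phenotypes as plain CSV, gene models as GFF3, bin
maps as BED-like TSV, and simulation truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, BinMap, GenotypeMatrix

_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write genotype calls as an uncompressed VCF 4.2 file."""
    path = Path(path)
    markers = geno.markers
    contigs = list(dict.fromkeys(markers["chrom"]))
    lengths = {c: int(markers.loc[markers["chrom"] == c, "pos"].max()) for c in contigs}
    mq = markers["mq"] if "mq" in markers.columns else pd.Series(60.0, index=markers.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gxemap\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.lines) + "\n")
        calls = geno.calls
        for k in range(geno.n_markers):
            row = markers.iloc[k]
            gts = "\t".join(_GT[int(v)] for v in calls[:, k])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['marker']}\tA\tT\t.\tPASS\t"
                     f"MQ={float(mq.iloc[k]):g}\tGT\t{gts}\n")


def read_vcf(path: str | Path, families: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    ``families`` maps line id to family label (defaults to a single family
    ``"pop"``); parental haplotypes are not stored in VCF and stay empty.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    rows, calls, mqs = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS))
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types
        col = np.full(len(lines), MISSING, dtype=np.int8)
        col[gt == 0] = HOM_REF
        col[gt == 1] = HET
        col[gt == 3] = HOM_ALT
        calls.append(col)
        mq = var.INFO.get("MQ")
        mqs.append(np.nan if mq is None else float(mq))
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos"])
    if not np.isnan(mqs).all():
        markers["mq"] = mqs
    fam = np.array([(families or {}).get(l, "pop") for l in lines])
    return GenotypeMatrix(
        lines=lines, families=fam, markers=markers,
        calls=np.column_stack(calls) if calls else np.empty((len(lines), 0), dtype=np.int8),
    )


def write_phenotypes(data, path: str | Path) -> None:
    df = data.plots.copy()
    df["trait"] = data.trait
    df.to_csv(path, index=False)


def read_phenotypes(path: str | Path):
    from .simulate import TrialData

    df = pd.read_csv(path)
    trait = df["trait"].iloc[0] if "trait" in df.columns else "trait"
    cols = [c for c in df.columns if c != "trait"]
    if "is_check" not in df.columns:
        df["is_check"] = False
        cols.append("is_check")
    return TrialData(plots=df[cols], trait=str(trait))


def write_truth(data, path: str | Path) -> None:
    Path(path).write_text(data.truth_json())


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_binmap_bed(binmap: BinMap, path: str | Path) -> None:
    binmap.to_bed().to_csv(path, sep="\t", header=False, index=False)


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write a gene-model feature table (chrom, start, end, strand, type,
    gene_id) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            if row.type == "gene":
                attrs = f"ID=gene:{row.gene_id};Name={row.gene_id}"
            else:
                attrs = f"Parent=gene:{row.gene_id}"
            fh.write(f"{row.chrom}\tgxemap\t{row.type}\t{row.start}\t{row.end}"
                     f"\t.\t{row.strand}\t.\t{attrs}\n")


def read_gff3_features(path: str | Path) -> pd.DataFrame:
    """Extract gene/CDS/UTR features from a GFF3 file into the flat table
    used by :func:`gxemap.regions.annotate_snp_regions`."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True,
    )
    wanted = {"gene", "CDS", "five_prime_UTR", "three_prime_UTR"}
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in wanted:
            continue
        if feat.featuretype == "gene":
            raw = feat.attributes.get("ID", [feat.id])[0]
        else:
            raw = feat.attributes.get("Parent", [feat.id])[0]
        gene_id = raw.split(":", 1)[-1]
        rows.append((feat.seqid, feat.start, feat.end,
                     feat.strand if feat.strand in "+-" else ".",
                     feat.featuretype, gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "type", "gene_id"])


def write_qc_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
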