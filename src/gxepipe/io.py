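"""Plain-text readers and writers for every format the pipeline touches.

Dialects:

* expression TSV — genes x samples, first column ``gene``, header row of
  sample IDs; sidecar metadata TSV with columns ``sample_id``, ``line``,
  ``environment``, ``sex``, ``replicate`` plus covariates.
* genotype TSV — variants x lines, columns ``variant``, ``chrom``,
  ``pos`` then one 0/1 column per line.
* minimal VCF — CHROM, POS (1-based), ID, REF, ALT, QUAL, FILTER, INFO,
  FORMAT=GT, one GT column per line; only ``0/0`` and ``1/1`` (or ``0|0``
  / ``1|1``) are legal because the panel is fully inbred.
* BED — 0-based half-open intervals, 4th column = TF name.
* GMT — set name, description, tab-separated gene IDs.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .datatypes import ExpressionStudy, GeneSetCollection, GenotypeMatrix, TfbsIntervalSet


# ---------------------------------------------------------------- expression

def write_expression(study: ExpressionStudy, expr_path, meta_path) -> None:
    study.expr.to_csv(expr_path, sep="\t", index_label="gene")
    study.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_expression(expr_path, meta_path) -> ExpressionStudy:
    expr = pd.read_csv(expr_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return ExpressionStudy(expr, meta)


# ----------------------------------------------------------------- genotypes

def write_genotypes_tsv(genos: GenotypeMatrix, path) -> None:
    out = genos.variants.copy()
    out = out.join(genos.calls)
    out.to_csv(path, sep="\t", index_label="variant")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="variant")
    variants = df[["chrom", "pos"]]
    calls = df.drop(columns=["chrom", "pos"])
    return GenotypeMatrix(calls, variants)


def write_vcf(genos: GenotypeMatrix, path) -> None:
    lines = list(genos.lines)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(lines) + "\n")
        calls = genos.calls.to_numpy()
        for i, (vid, row) in enumerate(genos.variants.iterrows()):
            gts = "\t".join("1/1" if a else "0/0" for a in calls[i])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a minimal VCF of an inbred panel; heterozygous GTs are an error."""
    header = None
    records = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("##"):
                continue
            if raw.startswith("#CHROM"):
                header = raw.rstrip("\n").split("\t")
                continue
            if header is None:
                raise ValueError("VCF missing #CHROM header line")
            records.append(raw.rstrip("\n").split("\t"))
    if header is None:
        raise ValueError("VCF missing #CHROM header line")
    sample_names = header[9:]
    ids, chroms, poss, rows = [], [], [], []
    for rec in records:
        chrom, pos, vid = rec[0], int(rec[1]), rec[2]
        alleles = []
        for sample, gt_field in zip(sample_names, rec[9:]):
            gt = gt_field.split(":")[0].replace("|", "/")
            if gt in ("0/0", "0"):
                alleles.append(0)
            elif gt in ("1/1", "1"):
                alleles.append(1)
            else:
                raise ValueError(
                    f"non-homozygous genotype {gt!r} for sample {sample} at variant "
                    f"{vid} ({chrom}:{pos}); inbred panel requires 0/0 or 1/1"
                )
        ids.append(vid)
        chroms.append(chrom)
        poss.append(pos)
        rows.append(alleles)
    calls = pd.DataFrame(rows, index=ids, columns=sample_names)
    variants = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    return GenotypeMatrix(calls, variants)


# ----------------------------------------------------------------------- BED

def write_bed(sites: list[TfbsIntervalSet], path) -> None:
    with open(path, "w") as fh:
        for ts in sites:
            for _, row in ts.intervals.iterrows():
                fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{ts.tf}\n")


def read_bed(path) -> list[TfbsIntervalSet]:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "tf"],
    )
    out = []
    for tf, grp in df.groupby("tf", sort=False):
        out.append(TfbsIntervalSet(tf, grp[["chrom", "start", "end"]].reset_index(drop=True)))
    return out


# ----------------------------------------------------------------------- GMT

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    sets, descs = {}, {}
    with open(path) as fh:
        for raw in fh:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, genes = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} in GMT")
            sets[name] = genes
            descs[name] = desc
    return GeneSetCollection(sets, descs)


# ---------------------------------------------------------------------- JSON

def _json_sanitize(obj):
    """Replace non-finite floats by None so the output is strict JSON."""
    if isinstance(obj, dict):
        return {k: _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if hasattr(obj, "item"):  # numpy scalar
        return _json_sanitize(obj.item())
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_json_sanitize(obj), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
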