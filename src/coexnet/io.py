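"""Readers and writers for the plain-text formats used by the pipeline.

Formats
-------
expression TSV   genes in rows (first column ``gene``), samples in columns.
phenotype TSV    columns ``sample``, ``group``.
annotation TSV   columns ``gene chrom start end strand``; written 1-based
                 inclusive with a ``# coords=1-based-inclusive`` header line,
                 converted to 0-based half-open on read.
BED6             native 0-based half-open.
GMT              term, description, then member genes (tab-separated).
regulon TSV      columns ``tf target chrom site_start site_end`` (0-based
                 half-open sites).
edge TSV         columns ``gene_a gene_b score p_value cis`` sorted by
                 descending score.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import (
    BED_COLUMNS,
    CoexpressionNetwork,
    ExpressionStudy,
    IntervalTrack,
    RegulonMap,
    validate_annotation,
)

_COORD_FLAG = "# coords=1-based-inclusive"


# -- expression / phenotype -------------------------------------------------

def write_expression(study: ExpressionStudy, path: str | os.PathLike) -> None:
    df = study.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_phenotype(study: ExpressionStudy, path: str | os.PathLike) -> None:
    pd.DataFrame({"sample": study.groups.index, "group": study.groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_expression(expr_path: str | os.PathLike, pheno_path: str | os.PathLike) -> ExpressionStudy:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    pheno = pd.read_csv(pheno_path, sep="\t")
    groups = pd.Series(pheno["group"].values, index=pheno["sample"].values)
    return ExpressionStudy(values=values, groups=groups)


# -- gene annotation --------------------------------------------------------

def write_annotation(annotation: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene annotation TSV, converting to 1-based inclusive on disk."""
    df = validate_annotation(annotation)
    out = df.copy()
    out["start"] = out["start"] + 1  # half-open 0-based -> inclusive 1-based
    with open(path, "w") as fh:
        fh.write(_COORD_FLAG + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene annotation TSV back to 0-based half-open coordinates."""
    with open(path) as fh:
        first = fh.readline()
        one_based = first.strip() == _COORD_FLAG
        if not one_based:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    if one_based:
        df["start"] = df["start"] - 1
    return validate_annotation(df)


# -- BED --------------------------------------------------------------------

def write_bed(track: IntervalTrack, path: str | os.PathLike) -> None:
    track.intervals[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | os.PathLike) -> IntervalTrack:
    if os.path.getsize(path) == 0:
        return IntervalTrack(pd.DataFrame(columns=BED_COLUMNS))
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    return IntervalTrack(df)


# -- GMT --------------------------------------------------------------------

def write_gmt(term_sets: dict[str, set[str]], path: str | os.PathLike,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(term_sets):
            genes = sorted(term_sets[term])
            fh.write("\t".join([term, descriptions.get(term, "na"), *genes]) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = set(parts[2:])
    return terms


# -- regulons ---------------------------------------------------------------

def write_regulons(regulons: RegulonMap, path: str | os.PathLike) -> None:
    regulons.to_table().to_csv(path, sep="\t", index=False)


def read_regulons(path: str | os.PathLike) -> RegulonMap:
    return RegulonMap.from_table(pd.read_csv(path, sep="\t"))


# -- networks ---------------------------------------------------------------

def write_network(network: CoexpressionNetwork, path: str | os.PathLike) -> None:
    out = network.edges.copy()
    cis = out["cis"]
    out["cis"] = np.where(cis.isna(), "", cis.map({True: "1", False: "0"}))
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_network(path: str | os.PathLike, score_kind: str = "mi",
                 n_samples_used: int = 0) -> CoexpressionNetwork:
    df = pd.read_csv(path, sep="\t")
    if "cis" in df.columns:
        df["cis"] = pd.array(
            [bool(int(v)) if v == v and v != "" else pd.NA for v in df["cis"]], dtype="boolean"
        )
    return CoexpressionNetwork(edges=df, score_kind=score_kind, n_samples_used=n_samples_used)


# -- community tables -------------------------------------------------------

def write_membership(membership: pd.DataFrame, path: str | os.PathLike) -> None:
    membership.to_csv(path, sep="\t", index=False)


def read_membership(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
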