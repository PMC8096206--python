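"""Core data containers shared across the pipeline.

Conventions
-----------
* Genomic coordinates are 0-based half-open ``[start, end)`` everywhere in
  memory.  On disk, BED keeps this convention natively while the gene
  annotation TSV is written 1-based inclusive (GTF-like); the readers and
  writers in :mod:`coexnet.io` translate.
* Chromosome names are normalized to a bare dialect (``"1"`` not ``"chr1"``)
  on load.
* An expression matrix is genes x samples, log2 scale, no missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["gene", "chrom", "start", "end", "strand"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
EDGE_COLUMNS = ["gene_a", "gene_b", "score", "p_value", "cis"]


def normalize_chrom(name: str) -> str:
    """Strip an optional ``chr`` prefix so both dialects compare equal."""
    s = str(name)
    return s[3:] if s.lower().startswith("chr") else s


@dataclass
class ExpressionStudy:
    """Two-group log2 expression matrix.

    Parameters
    ----------
    values : DataFrame, genes in rows (index = gene ids), samples in columns.
    groups : Series mapping sample id -> group label.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes)[:5]}")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])[:5]
            raise ValueError(f"samples without a group label: {missing}")
        counts = self.groups.value_counts()
        if (counts < 2).any():
            raise ValueError(f"every group needs >=2 samples, got {counts.to_dict()}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def subset(self, group: str) -> pd.DataFrame:
        """Expression sub-matrix for one phenotype group."""
        cols = self.groups.index[self.groups == group]
        if len(cols) == 0:
            raise KeyError(f"unknown group {group!r}; have {self.group_names}")
        return self.values[cols]


@dataclass
class CoexpressionNetwork:
    """Weighted gene co-expression edge list.

    ``edges`` columns: gene_a, gene_b, score, p_value (may be NaN before
    permutation testing), cis (nullable boolean; set by
    :func:`coexnet.inference.label_cis_trans`).  Edges are kept with
    ``gene_a < gene_b`` lexicographically and sorted by descending score with
    a (gene_a, gene_b) tie-break so the ordering is total and deterministic.
    """

    edges: pd.DataFrame
    score_kind: str = "mi"
    n_samples_used: int = 0

    def __post_init__(self) -> None:
        if self.score_kind not in ("mi", "pearson"):
            raise ValueError(f"score_kind must be 'mi' or 'pearson', got {self.score_kind!r}")
        e = self.edges
        for col in ("gene_a", "gene_b", "score"):
            if col not in e.columns:
                raise ValueError(f"edge table missing column {col!r}")
        if "p_value" not in e.columns:
            e = e.assign(p_value=np.nan)
        if "cis" not in e.columns:
            e = e.assign(cis=pd.array([pd.NA] * len(e), dtype="boolean"))
        bad = e["gene_a"] >= e["gene_b"]
        if bad.any():
            raise ValueError("edges must satisfy gene_a < gene_b (no self/duplicate edges)")
        p = e["p_value"].to_numpy(dtype=float)
        ok = np.isnan(p) | ((p >= 0.0) & (p <= 1.0))
        if not ok.all():
            raise ValueError("p_value outside [0, 1]")
        e = e.sort_values(
            ["score", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
        self.edges = e[EDGE_COLUMNS]

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    def cis_fraction(self) -> float:
        cis = self.edges["cis"]
        if cis.isna().any():
            raise ValueError("cis labels not set; run label_cis_trans first")
        return float(cis.astype(bool).mean())


@dataclass
class IntervalTrack:
    """Strand-aware genomic intervals (BED6 semantics, 0-based half-open)."""

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intervals.copy()
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[BED_COLUMNS]
        df["chrom"] = df["chrom"].map(normalize_chrom)
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("intervals must satisfy start < end")
        if len(df) and (df["start"] < 0).any():
            raise ValueError("negative interval coordinates")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def chroms(self) -> set[str]:
        return set(self.intervals["chrom"].unique())

    def on(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == normalize_chrom(chrom)]


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Normalize and sanity-check a gene annotation table.

    Expected columns: gene, chrom, start, end, strand; coordinates 0-based
    half-open.  Returns a copy sorted by (chrom, start).
    """
    df = annotation.copy()
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].unique()
        raise ValueError(f"duplicate gene ids in annotation: {list(dupes)[:5]}")
    if not (df["start"] < df["end"]).all():
        raise ValueError("annotation rows must satisfy start < end")
    if (df["start"] < 0).any():
        raise ValueError("negative gene coordinates")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


@dataclass
class CommunityPartition:
    """Result of one community-detection run on a network."""

    algorithm: str
    assignment: dict[str, int]
    modularity: float
    seed: int = 0

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for gene, cid in self.assignment.items():
            out.setdefault(cid, set()).add(gene)
        return out

    def sizes(self) -> dict[int, int]:
        return {cid: len(g) for cid, g in self.communities().items()}


@dataclass
class PromoterWindow:
    """Strand-aware promoter window anchored at the transcription start."""

    upstream_bp: int = 1000
    downstream_bp: int = 100

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("promoter window extents must be >= 0")
        if self.upstream_bp == 0 and self.downstream_bp == 0:
            raise ValueError("degenerate promoter window (width 0)")


# the three window definitions used for regulon annotation, minimal TSS
# windows, and CTCF site classification respectively
PROMOTER_PRESETS: dict[str, PromoterWindow] = {
    "regulon": PromoterWindow(1000, 100),
    "tss_minimal": PromoterWindow(100, 10),
    "ctcf": PromoterWindow(1000, 500),
}


@dataclass
class RegulonMap:
    """TF gene -> set of (target gene, promoter binding-site interval)."""

    regulons: dict[str, set[tuple[str, tuple[str, int, int]]]] = field(default_factory=dict)

    def targets_of(self, tf: str) -> set[str]:
        return {t for t, _ in self.regulons.get(tf, set())}

    @property
    def tfs(self) -> set[str]:
        return set(self.regulons)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for tf in sorted(self.regulons):
            for target, (chrom, s, e) in sorted(self.regulons[tf]):
                rows.append((tf, target, chrom, s, e))
        return pd.DataFrame(rows, columns=["tf", "target", "chrom", "site_start", "site_end"])

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "RegulonMap":
        reg: dict[str, set] = {}
        for row in table.itertuples(index=False):
            reg.setdefault(row.tf, set()).add(
                (row.target, (normalize_chrom(row.chrom), int(row.site_start), int(row.site_end)))
            )
        return cls(reg)
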