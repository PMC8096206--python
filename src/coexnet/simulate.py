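"""Seeded synthetic inputs for the co-expression pipeline.

Generates a toy genome annotation, a two-group log2 expression matrix with
planted co-expression modules, BED peak tracks, TF regulon tables and
GMT-style term sets.  The expression model is a Gaussian latent-factor model:
a gene in a module with target correlation ``rho`` is

    x = baseline + global_factor + sqrt(rho) * F_module
        + sqrt(1 - rho) * idiosyncratic + noise_sd * eps  (+ mean shift)

so realized within-module Pearson correlation is rho / (1 + noise_sd**2),
converging to ``rho`` as ``noise_sd`` goes to 0.  Raising the number and
strength of chromosome-contiguous ("cis") modules while weakening
cross-chromosome ("trans") modules reproduces the loss-of-trans contrast the
analysis is designed to measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionStudy,
    IntervalTrack,
    PromoterWindow,
    RegulonMap,
    normalize_chrom,
    validate_annotation,
)
from .context import promoter_of

# hg38 autosome sizes in Mb, scaled to a desk-size toy genome
_HG38_AUTOSOME_MB = (
    248, 242, 198, 190, 181, 171, 159, 145, 138, 133, 135,
    133, 114, 107, 101, 90, 83, 80, 58, 64, 46, 50,
)


@dataclass
class GenomeModel:
    """Toy genome layout: chromosome lengths plus gene size/spacing ranges."""

    n_chromosomes: int
    chrom_lengths: tuple[int, ...]
    n_genes: int
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    intergenic_gap_range: tuple[int, int] = (1_000, 50_000)

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths must have n_chromosomes entries")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")
        for lo, hi in (self.gene_length_range, self.intergenic_gap_range):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must satisfy 0 <= lo <= hi")

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]


def default_genome(n_genes: int = 2000, bp_per_mb: int = 100_000) -> GenomeModel:
    """22 autosomes with hg38-proportional lengths, ~2,000 genes."""
    lengths = tuple(mb * bp_per_mb for mb in _HG38_AUTOSOME_MB)
    return GenomeModel(n_chromosomes=22, chrom_lengths=lengths, n_genes=n_genes)


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``kind="cis"`` modules occupy contiguous genes on one chromosome;
    ``kind="trans"`` modules span at least two chromosomes.
    ``mean_shift_log2`` is added to member genes in the condition the module
    belongs to (a differential-expression effect).
    """

    module_id: str
    kind: str
    gene_ids: tuple[str, ...]
    latent_correlation: float
    mean_shift_log2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("cis", "trans"):
            raise ValueError(f"kind must be 'cis' or 'trans', got {self.kind!r}")
        if not 0.0 <= self.latent_correlation < 1.0:
            raise ValueError("latent_correlation must lie in [0, 1)")
        if len(self.gene_ids) < 2:
            raise ValueError("a module needs >=2 genes")


@dataclass
class SyntheticStudyConfig:
    """Full recipe for a two-group synthetic expression study."""

    genome: GenomeModel
    modules: dict[str, list[ModuleSpec]] = field(default_factory=dict)
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 113, "tumor": 217}
    )
    noise_sd: float = 0.3
    global_factor_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_samples_per_group.values()):
            raise ValueError("every group needs >=2 samples")
        if self.noise_sd < 0 or self.global_factor_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        unknown = set(self.modules) - set(self.n_samples_per_group)
        if unknown:
            raise ValueError(f"modules declared for unknown conditions: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def largest_remainder_allocation(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` items proportionally to ``weights``.

    Floors the exact quotas, then hands remaining items to the largest
    fractional parts (ties broken by lower index, so the result is
    deterministic).
    """
    weights = np.asarray(weights, dtype=float)
    quotas = total * weights / weights.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = quotas - np.floor(quotas)
        order = np.lexsort((np.arange(len(weights)), -frac))
        counts[order[:remainder]] += 1
    return counts


def generate_annotation(genome: GenomeModel, seed: int = 0) -> pd.DataFrame:
    """Lay out non-overlapping genes along each chromosome.

    Gene counts per chromosome are proportional to chromosome length
    (largest-remainder rounding).  Genes are named in genomic order and
    placed sequentially with random gaps; raises if the sampled footprint
    exceeds a chromosome.
    """
    rng = np.random.default_rng(seed)
    counts = largest_remainder_allocation(np.array(genome.chrom_lengths, float), genome.n_genes)
    glo, ghi = genome.gene_length_range
    ilo, ihi = genome.intergenic_gap_range
    width = len(str(genome.n_genes))
    rows = []
    idx = 0
    for chrom, length, n_on_chrom in zip(genome.chrom_names, genome.chrom_lengths, counts):
        pos = int(rng.integers(ilo, ihi + 1))
        for _ in range(n_on_chrom):
            glen = int(rng.integers(glo, ghi + 1))
            start, end = pos, pos + glen
            if end > length:
                raise ValueError(
                    f"gene footprint exceeds chromosome {chrom} "
                    f"(length {length}, needed >= {end})"
                )
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"G{idx:0{width}d}", chrom, start, end, strand))
            pos = end + int(rng.integers(ilo, ihi + 1))
    return validate_annotation(
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _check_modules(config: SyntheticStudyConfig, annotation: pd.DataFrame) -> None:
    known = set(annotation["gene"])
    for condition, modules in config.modules.items():
        claimed: dict[str, str] = {}
        for mod in modules:
            missing = set(mod.gene_ids) - known
            if missing:
                raise ValueError(
                    f"module {mod.module_id!r} references unknown genes: {sorted(missing)[:5]}"
                )
            for g in mod.gene_ids:
                if g in claimed:
                    raise ValueError(
                        f"gene {g} claimed by modules {claimed[g]!r} and "
                        f"{mod.module_id!r} in condition {condition!r}"
                    )
                claimed[g] = mod.module_id


def generate_expression(
    config: SyntheticStudyConfig, annotation: pd.DataFrame | None = None
) -> ExpressionStudy:
    """Draw the two-group expression matrix from the latent-factor model."""
    if annotation is None:
        annotation = generate_annotation(config.genome, seed=config.seed)
    _check_modules(config, annotation)

    genes = list(annotation["gene"])
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    rng = np.random.default_rng(config.seed)
    baseline = rng.uniform(4.0, 12.0, size=n_genes)

    blocks = []
    sample_ids: list[str] = []
    group_labels: list[str] = []
    for condition in sorted(config.n_samples_per_group):
        n_s = config.n_samples_per_group[condition]
        # per-gene idiosyncratic scale: sqrt(1 - rho) inside a module, 1 outside
        idio_sd = np.ones(n_genes)
        shift = np.zeros(n_genes)
        modules = sorted(config.modules.get(condition, []), key=lambda m: m.module_id)
        member_idx = [np.array([gene_pos[g] for g in m.gene_ids]) for m in modules]
        for mod, idx in zip(modules, member_idx):
            idio_sd[idx] = np.sqrt(1.0 - mod.latent_correlation)
            shift[idx] += mod.mean_shift_log2

        x = np.broadcast_to((baseline + shift)[:, None], (n_genes, n_s)).copy()
        if config.global_factor_sd > 0:
            x += config.global_factor_sd * rng.standard_normal(n_s)[None, :]
        for mod, idx in zip(modules, member_idx):
            factor = rng.standard_normal(n_s)
            x[idx, :] += np.sqrt(mod.latent_correlation) * factor[None, :]
        x = x + idio_sd[:, None] * rng.standard_normal((n_genes, n_s))
        if config.noise_sd > 0:
            x = x + config.noise_sd * rng.standard_normal((n_genes, n_s))
        blocks.append(x)
        sample_ids += [f"{condition}_{i + 1:04d}" for i in range(n_s)]
        group_labels += [condition] * n_s

    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=sample_ids)
    return ExpressionStudy(values=values, groups=pd.Series(group_labels, index=sample_ids))


# ---------------------------------------------------------------------------
# module helpers
# ---------------------------------------------------------------------------

def make_cis_modules(
    annotation: pd.DataFrame,
    n_modules: int,
    genes_per_module: int,
    latent_correlation: float,
    seed: int = 0,
    prefix: str = "cis",
    mean_shift_log2: float = 0.0,
) -> list[ModuleSpec]:
    """Carve contiguous same-chromosome gene runs into cis modules."""
    rng = np.random.default_rng(seed)
    ann = validate_annotation(annotation)
    specs: list[ModuleSpec] = []
    used: set[str] = set()
    chroms = list(ann["chrom"].unique())
    attempts = 0
    while len(specs) < n_modules and attempts < 50 * n_modules:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        on_chrom = ann.loc[ann["chrom"] == chrom, "gene"].tolist()
        if len(on_chrom) < genes_per_module:
            continue
        start = int(rng.integers(0, len(on_chrom) - genes_per_module + 1))
        members = tuple(on_chrom[start : start + genes_per_module])
        if used & set(members):
            continue
        used.update(members)
        specs.append(
            ModuleSpec(
                module_id=f"{prefix}{len(specs) + 1:03d}",
                kind="cis",
                gene_ids=members,
                latent_correlation=latent_correlation,
                mean_shift_log2=mean_shift_log2,
            )
        )
    if len(specs) < n_modules:
        raise ValueError("could not place the requested number of cis modules")
    return specs


def make_trans_modules(
    annotation: pd.DataFrame,
    n_modules: int,
    genes_per_module: int,
    latent_correlation: float,
    seed: int = 0,
    prefix: str = "trans",
    mean_shift_log2: float = 0.0,
    exclude: set[str] | None = None,
) -> list[ModuleSpec]:
    """Sample multi-chromosome gene sets as trans modules."""
    rng = np.random.default_rng(seed)
    ann = validate_annotation(annotation)
    chrom_of = dict(zip(ann["gene"], ann["chrom"]))
    pool = [g for g in ann["gene"] if not (exclude and g in exclude)]
    used: set[str] = set()
    specs: list[ModuleSpec] = []
    attempts = 0
    while len(specs) < n_modules and attempts < 50 * n_modules:
        attempts += 1
        free = [g for g in pool if g not in used]
        if len(free) < genes_per_module:
            break
        pick = rng.choice(len(free), size=genes_per_module, replace=False)
        members = tuple(free[i] for i in sorted(pick))
        if len({chrom_of[g] for g in members}) < 2:
            continue
        used.update(members)
        specs.append(
            ModuleSpec(
                module_id=f"{prefix}{len(specs) + 1:03d}",
                kind="trans",
                gene_ids=members,
                latent_correlation=latent_correlation,
                mean_shift_log2=mean_shift_log2,
            )
        )
    if len(specs) < n_modules:
        raise ValueError("could not place the requested number of trans modules")
    return specs


def loss_of_trans_configs(
    genome: GenomeModel | None = None,
    seed: int = 0,
    n_modules: int = 24,
    genes_per_module: int = 30,
    strong: float = 0.9,
    weak: float = 0.25,
    noise_sd: float = 0.3,
    n_samples_per_group: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, SyntheticStudyConfig]:
    """Annotation plus a paired healthy/tumor config planting the contrast.

    The healthy condition carries strong trans modules; the tumor condition
    replaces them with strong chromosome-contiguous cis blocks plus weakened
    trans modules (with a mean shift, so DE has signal), so top tumor edges
    concentrate within chromosomes at every cut.
    """
    genome = genome or default_genome()
    annotation = generate_annotation(genome, seed=seed)
    cis_strong = make_cis_modules(
        annotation, n_modules, genes_per_module, strong, seed=seed + 1, prefix="cis"
    )
    cis_genes = {g for m in cis_strong for g in m.gene_ids}
    trans_strong = make_trans_modules(
        annotation, n_modules, genes_per_module, strong, seed=seed + 2,
        prefix="trans", exclude=cis_genes,
    )

    def reweight(mods: list[ModuleSpec], rho: float, shift: float = 0.0) -> list[ModuleSpec]:
        return [
            ModuleSpec(m.module_id, m.kind, m.gene_ids, rho, mean_shift_log2=shift)
            for m in mods
        ]

    config = SyntheticStudyConfig(
        genome=genome,
        modules={
            "healthy": trans_strong,
            "tumor": cis_strong + reweight(trans_strong, weak, shift=1.0),
        },
        n_samples_per_group=n_samples_per_group or {"healthy": 113, "tumor": 217},
        noise_sd=noise_sd,
        seed=seed,
    )
    return annotation, config


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def generate_peak_track(
    annotation: pd.DataFrame,
    n_peaks: int,
    placement: str = "uniform",
    seed: int = 0,
    *,
    chrom_lengths: dict[str, int] | None = None,
    peak_length_range: tuple[int, int] = (200, 2_000),
    target_genes: list[str] | None = None,
    boundaries: list[tuple[str, int, int]] | None = None,
    flank: int = 50_000,
    enrichment_ratio: float = 10.0,
) -> IntervalTrack:
    """Place peaks on the toy genome.

    placement:
      ``uniform``          uniform over chromosomes weighted by length
      ``gene_spanning``    each peak fully contains one sampled gene
      ``boundary_enriched`` peaks fall in ``flank``-sized windows around the
                           given ``boundaries`` spans with odds
                           ``enrichment_ratio : 1`` against a uniform draw
    """
    if n_peaks < 0:
        raise ValueError("n_peaks must be >= 0")
    if placement not in ("uniform", "gene_spanning", "boundary_enriched"):
        raise ValueError(f"unknown placement {placement!r}")
    ann = validate_annotation(annotation)
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(sub["end"].max()) + flank + 10_000 for c, sub in ann.groupby("chrom")
        }
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    rows: list[tuple] = []

    def uniform_peak() -> tuple[str, int, int]:
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        chrom = chroms[ci]
        plen = int(rng.integers(peak_length_range[0], peak_length_range[1] + 1))
        plen = min(plen, chrom_lengths[chrom] - 1)
        start = int(rng.integers(0, chrom_lengths[chrom] - plen))
        return chrom, start, start + plen

    if placement == "gene_spanning":
        if target_genes is None:
            n = min(n_peaks, len(ann))
            pick = rng.choice(len(ann), size=n, replace=False)
            target_genes = list(ann.iloc[sorted(pick)]["gene"])
        if len(target_genes) != n_peaks:
            raise ValueError("gene_spanning needs exactly one target gene per peak")
        ann_ix = ann.set_index("gene")
        for g in target_genes:
            row = ann_ix.loc[g]
            pad_l = int(rng.integers(10, 400))
            pad_r = int(rng.integers(10, 400))
            rows.append((row["chrom"], max(0, int(row["start"]) - pad_l), int(row["end"]) + pad_r))
    elif placement == "boundary_enriched":
        if not boundaries:
            raise ValueError("boundary_enriched placement needs boundary spans")
        windows = []
        for chrom, s, e in boundaries:
            chrom = normalize_chrom(chrom)
            windows.append((chrom, max(0, s - flank), s))
            windows.append((chrom, e, e + flank))
        windows = [(c, a, b) for c, a, b in windows if b > a]
        p_flank = enrichment_ratio / (enrichment_ratio + 1.0)
        for _ in range(n_peaks):
            if rng.random() < p_flank:
                c, a, b = windows[int(rng.integers(len(windows)))]
                plen = int(rng.integers(peak_length_range[0], peak_length_range[1] + 1))
                plen = min(plen, b - a - 1) or 1
                start = int(rng.integers(a, max(a + 1, b - plen)))
                rows.append((c, start, start + plen))
            else:
                rows.append(uniform_peak())
    else:
        for _ in range(n_peaks):
            rows.append(uniform_peak())

    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    df["name"] = [f"peak_{i + 1:05d}" for i in range(len(df))]
    df["score"] = 0.0
    df["strand"] = "."
    return IntervalTrack(df)


# ---------------------------------------------------------------------------
# regulons
# ---------------------------------------------------------------------------

def generate_regulons(
    annotation: pd.DataFrame,
    modules: list[ModuleSpec] | None,
    n_tfs: int,
    targets_per_tf: int,
    seed: int = 0,
    window: PromoterWindow | None = None,
) -> tuple[RegulonMap, pd.DataFrame]:
    """Assign TFs and promoter binding sites for their targets.

    TFs are planted inside the given modules (one per module, in order) so
    their targets co-express; once modules run out, TFs and targets are drawn
    uniformly.  Returns the map plus its flat table form.
    """
    if n_tfs < 0 or targets_per_tf < 0:
        raise ValueError("n_tfs and targets_per_tf must be >= 0")
    window = window or PromoterWindow(1000, 100)
    ann = validate_annotation(annotation)
    ann_ix = ann.set_index("gene")
    rng = np.random.default_rng(seed)
    all_genes = list(ann["gene"])
    modules = list(modules or [])
    reg: dict[str, set] = {}
    for i in range(n_tfs):
        if i < len(modules):
            members = list(modules[i].gene_ids)
            tf = members[0]
            pool = [g for g in members[1:]]
        else:
            tf = all_genes[int(rng.integers(len(all_genes)))]
            pool = []
        extra = [g for g in all_genes if g != tf and g not in pool]
        while len(pool) < targets_per_tf:
            pool.append(extra[int(rng.integers(len(extra)))])
            extra = [g for g in extra if g not in pool]
        targets = pool[:targets_per_tf]
        sites = set()
        for t in targets:
            row = ann_ix.loc[t]
            ps, pe = promoter_of(row["chrom"], int(row["start"]), int(row["end"]),
                                 row["strand"], window)[1:]
            slen = int(rng.integers(8, 21))
            slen = min(slen, pe - ps)
            s0 = int(rng.integers(ps, max(ps + 1, pe - slen + 1)))
            sites.add((t, (row["chrom"], s0, s0 + slen)))
        reg[tf] = sites
    rmap = RegulonMap(reg)
    return rmap, rmap.to_table()


# ---------------------------------------------------------------------------
# term sets
# ---------------------------------------------------------------------------

def generate_term_sets(
    annotation: pd.DataFrame,
    modules: list[ModuleSpec] | None,
    n_terms: int,
    seed: int = 0,
    planted_fraction: float = 0.5,
    min_size: int = 10,
    max_size: int = 100,
    noise_genes: int = 0,
) -> dict[str, set[str]]:
    """GMT-style term -> gene-set map with recoverable planted terms.

    Roughly ``planted_fraction`` of the terms copy a planted module's gene
    set (padded with up to ``noise_genes`` random genes); the rest are
    uniform decoys with sizes in ``[min_size, max_size]``.
    """
    if n_terms < 0:
        raise ValueError("n_terms must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(validate_annotation(annotation)["gene"])
    modules = list(modules or [])
    n_planted = min(len(modules), int(round(planted_fraction * n_terms)))
    terms: dict[str, set[str]] = {}
    for i in range(n_terms):
        if i < n_planted:
            members = set(modules[i].gene_ids)
            for _ in range(noise_genes):
                members.add(genes[int(rng.integers(len(genes)))])
            while len(members) < min_size:
                members.add(genes[int(rng.integers(len(genes)))])
            terms[f"T{i + 1:04d}_{modules[i].module_id}"] = members
        else:
            size = int(rng.integers(min_size, max_size + 1))
            pick = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
            terms[f"T{i + 1:04d}_decoy"] = {genes[j] for j in pick}
    return terms
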