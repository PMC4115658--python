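"""Synthetic pipeline inputs with planted truth.

Everything is driven by a :class:`TruthConfig`; the same config (including
its seed) always reproduces byte-identical outputs.  Allele counts are
generated directly at the informative-read level (read alignment is out of
scope); a separate read simulator exists to exercise the SNP classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allelic import ORIGIN_A, ORIGIN_B, ReadRecord, SNPRecord

BIALLELIC = "biallelic"
MEG_CLASS = "MEG"
PEG_CLASS = "PEG"
AS_MEG = "allele_specific_MEG"
AS_PEG = "allele_specific_PEG"
SEEDCOAT = "seedcoat_dominant"

GENE_CLASSES = (BIALLELIC, MEG_CLASS, PEG_CLASS, AS_MEG, AS_PEG, SEEDCOAT)

# endosperm carries two maternal genomes and one paternal one
BIALLELIC_FRACTION = {"endosperm": 2.0 / 3.0, "embryo": 0.5, "whole_seed": 0.5}

DEFAULT_FRACTIONS = {
    MEG_CLASS: {"endosperm": 0.95, "embryo": 0.95},
    PEG_CLASS: {"endosperm": 0.40, "embryo": 0.25},
}


@dataclass(frozen=True)
class GeneClass:
    name: str
    strain: str | None = None
    role: str | None = None  # parental role the exception applies to

    def __post_init__(self):
        if self.name not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.name!r}")
        if self.name in (AS_MEG, AS_PEG):
            if self.strain is None or self.role not in ("mother", "father"):
                raise ValueError(f"{self.name} needs a strain and a role (mother/father)")


@dataclass(frozen=True)
class Cross:
    mother: str
    father: str
    tissue: str = "endosperm"
    replicate: int = 1


@dataclass(frozen=True)
class PlantedDMR:
    chrom: str
    start: int
    end: int
    context: str
    level_a: float
    level_b: float


@dataclass(frozen=True)
class PopulationPlan:
    dmr_id: str
    variability_class: str
    weight: float = 0.9  # major-component weight for bimodal mixtures
    n_missing: int = 0

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("mixture weight outside [0, 1]")


@dataclass
class TruthConfig:
    """All knobs of the simulator; invalid values raise at construction."""

    seed: int = 0
    gene_classes: dict[str, GeneClass] = field(default_factory=dict)
    maternal_fraction_by_class: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FRACTIONS.items()}
    )
    depth_mean: float = 300.0
    depth_dispersion: float = 0.3
    strains: tuple[str, ...] = ("colA", "colB", "colC")
    crosses: list[Cross] = field(default_factory=list)
    error_rate: float = 0.0
    # methylome
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    site_density: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.04, "CHG": 0.02, "CHH": 0.06}
    )
    coverage_lambda: float = 12.0
    background_levels: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.25, "CHG": 0.10, "CHH": 0.04}
    )
    te_levels: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.60, "CHH": 0.10}
    )
    methylome_plan: list[PlantedDMR] = field(default_factory=list)
    # population
    n_population_strains: int = 140
    population_plan: list[PopulationPlan] = field(default_factory=list)

    def __post_init__(self):
        if self.depth_mean <= 0:
            raise ValueError("depth model mean must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth dispersion must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate outside [0, 1)")
        for cls, by_tissue in self.maternal_fraction_by_class.items():
            for tissue, f in by_tissue.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"maternal fraction {f} for {cls}/{tissue} outside [0, 1]")


def default_crosses(
    strains=("colA", "colB", "colC"), tissue="endosperm", n_replicates=3
) -> list[Cross]:
    """All reciprocal cross pairs among the strains, replicated."""
    out = []
    s = sorted(strains)
    for i in range(len(s)):
        for j in range(i + 1, len(s)):
            for rep in range(1, n_replicates + 1):
                out.append(Cross(s[i], s[j], tissue, rep))
                out.append(Cross(s[j], s[i], tissue, rep))
    return out


def make_gene_classes(
    n_biallelic: int = 0,
    n_meg: int = 0,
    n_peg: int = 0,
    allele_specific: list[tuple[str, str, str]] | None = None,
    n_seedcoat: int = 0,
) -> dict[str, GeneClass]:
    """Convenience builder; allele_specific items are (class, strain, role)."""
    classes = {}
    idx = 0
    for name, n in ((BIALLELIC, n_biallelic), (MEG_CLASS, n_meg), (PEG_CLASS, n_peg),
                    (SEEDCOAT, n_seedcoat)):
        for _ in range(n):
            classes[f"g{idx:05d}"] = GeneClass(name)
            idx += 1
    for name, strain, role in allele_specific or []:
        classes[f"g{idx:05d}"] = GeneClass(name, strain, role)
        idx += 1
    return classes


def planted_maternal_fraction(cls: GeneClass, cross: Cross, config: TruthConfig) -> float:
    """The maternal read fraction the simulator uses for one gene in one cross."""
    tissue = cross.tissue
    biallelic = BIALLELIC_FRACTION[tissue]
    table = config.maternal_fraction_by_class
    if cls.name in (BIALLELIC, SEEDCOAT):
        return biallelic
    if cls.name == MEG_CLASS:
        return table[MEG_CLASS][tissue]
    if cls.name == PEG_CLASS:
        return table[PEG_CLASS][tissue]
    holds_role = (cls.role == "mother" and cross.mother == cls.strain) or (
        cls.role == "father" and cross.father == cls.strain
    )
    if cls.name == AS_MEG:
        return biallelic if holds_role else table[MEG_CLASS][tissue]
    if cls.name == AS_PEG:
        return biallelic if holds_role else table[PEG_CLASS][tissue]
    raise ValueError(f"unknown gene class {cls.name!r}")


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean, size=n)
    # NB parameterised by mean and dispersion alpha: var = mu + alpha mu^2
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def simulate_allele_counts(config: TruthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Informative-read allele counts for every gene x cross, plus the truth table."""
    if not config.gene_classes:
        raise ValueError("config has no genes")
    if not config.crosses:
        raise ValueError("config has no crosses")
    rng = np.random.default_rng(config.seed)
    genes = sorted(config.gene_classes)
    rows = []
    for cross in config.crosses:
        depths = _draw_depths(rng, len(genes), config.depth_mean, config.depth_dispersion)
        fracs = np.array(
            [planted_maternal_fraction(config.gene_classes[g], cross, config) for g in genes]
        )
        maternal = rng.binomial(depths, fracs)
        for g, d, m in zip(genes, depths, maternal):
            rows.append(
                (g, cross.mother, cross.father, cross.tissue, cross.replicate, int(m), int(d - m))
            )
    counts = pd.DataFrame(
        rows,
        columns=["gene_id", "mother", "father", "tissue", "replicate",
                 "maternal_reads", "paternal_reads"],
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_class": [config.gene_classes[g].name for g in genes],
            "strain": [config.gene_classes[g].strain or "" for g in genes],
            "role": [config.gene_classes[g].role or "" for g in genes],
        }
    )
    return counts, truth


def make_expression_table(config: TruthConfig, base: float = 100.0) -> pd.DataFrame:
    """Linear-scale compartment expression; seed-coat-dominant genes get a
    4x seed-coat excess (log2 difference 2, failing the seed-coat filter)."""
    genes = sorted(config.gene_classes)
    sc = [base * 4 if config.gene_classes[g].name == SEEDCOAT else base for g in genes]
    return pd.DataFrame(
        {"endosperm": base, "embryo": base, "seed_coat": sc}, index=pd.Index(genes, name="gene_id")
    )


def _check_plan(plan: list[PlantedDMR]):
    by_ctx: dict[str, list[PlantedDMR]] = {}
    for p in plan:
        by_ctx.setdefault((p.chrom, p.context), []).append(p)
    for group in by_ctx.values():
        group = sorted(group, key=lambda p: p.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end and (a.level_a, a.level_b) != (b.level_a, b.level_b):
                raise ValueError(
                    f"overlapping planted DMRs with contradictory levels at "
                    f"{a.chrom}:{b.start}-{a.end}"
                )


def simulate_methylome_pair(
    config: TruthConfig,
    annotation: pd.DataFrame | None = None,
    sample_names: tuple[str, str] = ("sample_a", "sample_b"),
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Two per-sample cytosine tables sharing positions, plus the DMR truth.

    Cytosine positions are placed uniformly per context at the configured
    density; per-site coverage is Poisson; methylation probability is the
    background level of the context (TE annotation overrides it) except
    inside planted DMR intervals, where each sample uses its planted level.
    """
    _check_plan(config.methylome_plan)
    rng = np.random.default_rng(config.seed + 1)
    frames = {name: [] for name in sample_names}
    truth_rows = []
    te_intervals = []
    if annotation is not None and "feature_class" in annotation.columns:
        te = annotation[annotation["feature_class"] == "TE"]
        te_intervals = list(zip(te["start"], te["end"]))
    for context in ("CG", "CHG", "CHH"):
        density = config.site_density.get(context, 0.0)
        n_sites = int(config.chrom_length * density)
        if n_sites == 0:
            continue
        pos0 = np.sort(rng.choice(config.chrom_length, size=n_sites, replace=False))
        strand = np.where(rng.random(n_sites) < 0.5, "+", "-")
        level = np.full(n_sites, config.background_levels.get(context, 0.0))
        for s, e in te_intervals:
            inside = (pos0 >= s) & (pos0 < e)
            level[inside] = config.te_levels.get(context, level[0] if n_sites else 0.0)
        levels = {name: level.copy() for name in sample_names}
        for planted in config.methylome_plan:
            if planted.context != context or planted.chrom != config.chrom:
                continue
            inside = (pos0 >= planted.start) & (pos0 < planted.end)
            levels[sample_names[0]][inside] = planted.level_a
            levels[sample_names[1]][inside] = planted.level_b
        for name in sample_names:
            cov = rng.poisson(config.coverage_lambda, size=n_sites)
            meth = rng.binomial(cov, levels[name])
            frames[name].append(
                pd.DataFrame(
                    {
                        "chrom": config.chrom,
                        "pos": pos0 + 1,
                        "strand": strand,
                        "count_methylated": meth,
                        "count_unmethylated": cov - meth,
                        "context": context,
                    }
                )
            )
    samples = {
        name: pd.concat(parts, ignore_index=True).sort_values(["pos", "context"]).reset_index(drop=True)
        if parts
        else pd.DataFrame(columns=["chrom", "pos", "strand", "count_methylated",
                                   "count_unmethylated", "context"])
        for name, parts in frames.items()
    }
    for planted in config.methylome_plan:
        truth_rows.append(
            {
                "chrom": planted.chrom, "start": planted.start, "end": planted.end,
                "context": planted.context, "level_a": planted.level_a,
                "level_b": planted.level_b,
                "magnitude": planted.level_a - planted.level_b,
            }
        )
    return samples, pd.DataFrame(truth_rows)


def _population_scores(plan: PopulationPlan, n: int, rng: np.random.Generator) -> np.ndarray:
    cls = plan.variability_class
    if cls == "very_low":
        c = rng.uniform(0.2, 0.8)
        return c + rng.uniform(-0.075, 0.075, size=n)
    if cls == "low":
        c = rng.uniform(0.2, 0.75)
        s = c + rng.uniform(-0.125, 0.125, size=n)
        s[0], s[1] = c - 0.125, c + 0.125  # pin the range to exactly 0.25
        return s
    if cls == "not_bimodal":
        s = rng.uniform(0.2, 0.75, size=n)
        s[0], s[1] = 0.2, 0.75  # pin the range to 0.55
        return s
    if cls in ("weakly_bimodal", "strongly_bimodal"):
        lo_c, hi_c = (0.05, 0.90) if cls == "strongly_bimodal" else (0.20, 0.80)
        n_major = int(round(plan.weight * n))
        n_major = min(max(n_major, 1), n - 1)
        centers = np.concatenate([np.full(n_major, hi_c), np.full(n - n_major, lo_c)])
        s = centers + rng.uniform(-0.03, 0.03, size=n)
        return s[rng.permutation(n)]
    raise ValueError(f"unknown variability class {cls!r}")


def simulate_population_matrix(config: TruthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DMR x strain methylation score matrix with planted variability classes."""
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_population_strains
    strains = [f"strain_{i:03d}" for i in range(n)]
    rows, truth = {}, []
    for plan in config.population_plan:
        scores = np.clip(_population_scores(plan, n, rng), 0.0, 1.0)
        if plan.n_missing:
            miss = rng.choice(n, size=plan.n_missing, replace=False)
            scores[miss] = np.nan
        rows[plan.dmr_id] = scores
        truth.append({"dmr_id": plan.dmr_id, "true_class": plan.variability_class,
                      "n_missing": plan.n_missing})
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
    matrix.index.name = "dmr_id"
    return matrix, pd.DataFrame(truth)


def make_strain_genomes(
    length: int, n_snps: int, rng: np.random.Generator, chrom: str = "chr1"
) -> tuple[dict[str, str], list[SNPRecord]]:
    """A random genome and a SNP-substituted sibling; strains differ only at SNPs."""
    bases = np.array(list("ACGT"))
    genome_a = rng.choice(bases, size=length)
    positions = np.sort(rng.choice(length, size=n_snps, replace=False))
    genome_b = genome_a.copy()
    snps = []
    for p in positions:
        ref = genome_a[p]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        genome_b[p] = alt
        snps.append(SNPRecord(chrom, int(p) + 1, str(ref), str(alt)))
    return {"strain_a": "".join(genome_a), "strain_b": "".join(genome_b)}, snps


def simulate_reads(
    genomes: dict[str, str],
    n_reads: int,
    read_length: int,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    chrom: str = "chr1",
) -> list[tuple[ReadRecord, str]]:
    """Fixed-length reads from known haplotypes with per-base substitution error.

    Returns (read, true origin) pairs; origin labels match the classifier's
    ``strain_a``/``strain_b``.
    """
    glen = len(genomes["strain_a"])
    if read_length > glen:
        raise ValueError("read length exceeds genome length")
    labels = (ORIGIN_A, ORIGIN_B)
    keys = ("strain_a", "strain_b")
    out = []
    for _ in range(n_reads):
        which = int(rng.integers(2))
        start = int(rng.integers(0, glen - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = list(genomes[keys[which]][start: start + read_length])
        if error_rate > 0:
            errs = rng.random(read_length) < error_rate
            for i in np.nonzero(errs)[0]:
                seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
        out.append(
            (ReadRecord(chrom, start, strand, "".join(seq), quality_sum=float(read_length) * 30),
             labels[which])
        )
    return out
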