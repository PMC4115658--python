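"""Imprinted-gene calling from reciprocal-cross allele counts.

The exact test compares strain-of-origin read proportions between the two
directions of a reciprocal cross.  In endosperm the null for a non-imprinted
locus is a maternal read fraction of 2/3 in each direction (two maternal
genome copies to one paternal); the default test construction halves the
maternal counts (round half up) so that the null becomes an odds ratio of 1
and a standard two-sided Fisher test applies.  An optional exact mode keeps
raw counts and tests against a noncentral-hypergeometric null odds ratio of
4 (endosperm) or 1 (embryo).

Counts are always maternal/paternal as observed in each cross direction:
``m1, p1`` for A-female x B-male and ``m2, p2`` for B-female x A-male.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats import bh_adjust, binom_one_sided, fisher_two_sided

logger = logging.getLogger(__name__)

ENDOSPERM_NULL_MATERNAL_FRACTION = 2.0 / 3.0  # 2 maternal : 1 paternal genomes
EMBRYO_NULL_MATERNAL_FRACTION = 0.5

MEG = "MEG"
PEG = "PEG"
NONE = "none"
NOT_ASSESSABLE = "not_assessable"


@dataclass(frozen=True)
class ImprintingParams:
    """Thresholds of the imprinting filter chain (endosperm/embryo defaults)."""

    alpha: float = 0.01
    min_imprinting_factor: float = 2.0
    maternal_cutoff_endosperm: float = 0.85
    paternal_cutoff_endosperm: float = 0.50
    maternal_cutoff_embryo: float = 0.70
    maternal_peg_cutoff_embryo: float = 0.30
    min_replicate_calls: int = 2
    seedcoat_max_log2_diff: float = 1.0
    test_mode: str = "adjusted"  # or "noncentral"


def _half_up(n: int) -> int:
    return (int(n) + 1) // 2


def imprinting_test(m1, p1, m2, p2, tissue: str = "endosperm", mode: str = "adjusted") -> float:
    """Two-sided exact p-value against the dosage null for one gene.

    Table columns are the strain-of-origin classes, rows the two cross
    directions; with the maternal counts halved (endosperm) both rows have
    expected odds 1:1 under the null.
    """
    m1, p1, m2, p2 = int(m1), int(p1), int(m2), int(p2)
    if min(m1, p1, m2, p2) < 0:
        raise ValueError("negative allele counts")
    if m1 + p1 + m2 + p2 == 0:
        raise ValueError("all four counts are zero")
    if tissue not in ("endosperm", "embryo"):
        raise ValueError(f"unknown tissue {tissue!r}")
    # strain-A reads: maternal in direction 1, paternal in direction 2
    if mode == "adjusted":
        if tissue == "endosperm":
            table = [[_half_up(m1), p1], [p2, _half_up(m2)]]
        else:
            table = [[m1, p1], [p2, m2]]
        return fisher_two_sided(table)
    if mode == "noncentral":
        odds = 4.0 if tissue == "endosperm" else 1.0
        return _noncentral_two_sided([[m1, p1], [p2, m2]], odds)
    raise ValueError(f"unknown mode {mode!r}")


def _noncentral_two_sided(table, odds: float) -> float:
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    dist = _st.nchypergeom_fisher(n, r1, c1, odds)
    pmf = dist.pmf(support)
    obs = pmf[a - lo]
    return float(min(pmf[pmf <= obs * (1.0 + 1e-7)].sum(), 1.0))


def imprinting_factor(m1, p1, m2, p2, direction: str, dosage: float = 2.0) -> float:
    """Fold deviation from the maternal:paternal dosage expectation,
    minimised over the two cross directions.

    maternal: min over directions of ((m+1)/(p+1)) / dosage; paternal: min
    over directions of dosage * (p+1)/(m+1).  Pseudocounts keep the factor
    finite; ``dosage`` is 2 for endosperm and 1 for embryo.
    """
    pairs = [(m1, p1), (m2, p2)]
    if direction == "maternal":
        return min((m + 1) / (p + 1) / dosage for m, p in pairs)
    if direction == "paternal":
        return min(dosage * (p + 1) / (m + 1) for m, p in pairs)
    raise ValueError(f"unknown direction {direction!r}")


def seedcoat_filter(
    gene_id,
    table: pd.DataFrame | None,
    tissue: str = "endosperm",
    max_log2_diff: float = 1.0,
) -> bool:
    """True when the gene is not seed-coat dominant.

    ``table`` holds linear-scale mean expression per compartment (columns
    ``endosperm``, ``embryo``, ``seed_coat``).  The gene passes when
    log2(seed_coat) - log2(tissue) < max_log2_diff.  Genes absent from the
    table pass with a warning; averaging across compartment samples is
    assumed to have happened upstream, before the log transform.
    """
    if table is None or gene_id not in table.index:
        logger.warning("gene %s absent from tissue-expression table; seed-coat filter passes", gene_id)
        return True
    sc = float(table.loc[gene_id, "seed_coat"])
    tv = float(table.loc[gene_id, tissue])
    if sc < 0 or tv < 0:
        raise ValueError(f"negative expression for {gene_id}")
    if sc == 0:
        return True
    if tv == 0:
        return False
    return math.log2(sc) - math.log2(tv) < max_log2_diff


def bias_factor(m, p) -> float:
    """Parental bias b = log2(m + 1) - log2(2p + 1); 0 at the 2:1 dosage point."""
    if m < 0 or p < 0:
        raise ValueError("negative counts")
    return math.log2(m + 1) - math.log2(2 * p + 1)


def normalize_bias(b_values) -> np.ndarray:
    """Standardize bias factors: (b - mean) / sample stdev (ddof=1)."""
    b = np.asarray(b_values, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 loci to normalize")
    sd = b.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation of bias factors")
    return (b - b.mean()) / sd


def binomial_validation(maternal: int, total: int, direction: str = "less") -> float:
    """One-sided exact binomial p against the 2:3 maternal:total null."""
    return binom_one_sided(maternal, total, 2.0 / 3.0, direction)


def _pair_key(mother: str, father: str) -> tuple[str, str]:
    return tuple(sorted((mother, father)))


def _reciprocal_tables(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot long allele counts into one row per gene x pair x replicate.

    Direction 1 is the cross with the alphabetically first strain as mother.
    """
    df = counts.copy()
    df["strain_a"] = np.minimum(df["mother"], df["father"])
    df["strain_b"] = np.maximum(df["mother"], df["father"])
    df["direction"] = np.where(df["mother"] == df["strain_a"], 1, 2)
    wide = df.pivot_table(
        index=["gene_id", "strain_a", "strain_b", "tissue", "replicate"],
        columns="direction",
        values=["maternal_reads", "paternal_reads"],
        aggfunc="sum",
    )
    wide.columns = [f"{v}_{d}" for v, d in wide.columns]
    wide = wide.reset_index()
    for col in ("maternal_reads_1", "paternal_reads_1", "maternal_reads_2", "paternal_reads_2"):
        if col not in wide:
            raise ValueError("missing reciprocal direction in allele counts")
    return wide


def call_imprinting(
    counts: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    tissue: str = "endosperm",
    params: ImprintingParams | None = None,
) -> pd.DataFrame:
    """Call MEGs/PEGs per reciprocal cross pair with the full filter chain.

    Per replicate pair of reciprocal crosses: exact test p-values are
    BH-corrected across all assessable genes of that replicate; a gene is a
    replicate-level MEG when q < alpha, the maternal imprinting factor is
    >= the minimum, the seed-coat filter passes and the maternal fraction
    meets the tissue cutoff in both directions (PEG analogously).  The final
    endosperm call requires the replicate-level call in at least
    ``min_replicate_calls`` replicates; embryo uses the single replicate.

    Returns one row per gene x cross pair with status, q-value (minimum over
    called replicates, else over assessable ones), imprinting factors,
    pooled maternal fractions, replicate call counts and a filter trail.
    """
    params = params or ImprintingParams()
    tables = _reciprocal_tables(counts[counts["tissue"] == tissue])
    if tables.empty:
        return pd.DataFrame(
            columns=[
                "gene_id", "strain_a", "strain_b", "status", "p_adj",
                "imprinting_factor", "maternal_fraction_dir1", "maternal_fraction_dir2",
                "replicates_called", "replicates_assessable", "filter_trail",
            ]
        )
    min_calls = params.min_replicate_calls if tissue == "endosperm" else 1

    results = []
    for (sa, sb), pair_df in tables.groupby(["strain_a", "strain_b"]):
        per_gene: dict[str, dict] = {}
        n_replicates = pair_df["replicate"].nunique()
        for rep, rep_df in pair_df.groupby("replicate"):
            rep_df = rep_df.reset_index(drop=True)
            m1 = rep_df["maternal_reads_1"].to_numpy(int)
            p1 = rep_df["paternal_reads_1"].to_numpy(int)
            m2 = rep_df["maternal_reads_2"].to_numpy(int)
            p2 = rep_df["paternal_reads_2"].to_numpy(int)
            assessable = (m1 + p1 > 0) & (m2 + p2 > 0)
            pvals = np.full(len(rep_df), np.nan)
            for i in np.nonzero(assessable)[0]:
                pvals[i] = imprinting_test(
                    m1[i], p1[i], m2[i], p2[i], tissue=tissue, mode=params.test_mode
                )
            qvals = bh_adjust(pvals)
            f1 = np.where(m1 + p1 > 0, m1 / np.maximum(m1 + p1, 1), np.nan)
            f2 = np.where(m2 + p2 > 0, m2 / np.maximum(m2 + p2, 1), np.nan)
            for i, row in rep_df.iterrows():
                g = row["gene_id"]
                rec = per_gene.setdefault(
                    g,
                    {"meg": 0, "peg": 0, "assessable": 0, "q": [], "trail": [],
                     "m1": 0, "p1": 0, "m2": 0, "p2": 0},
                )
                rec["m1"] += m1[i]; rec["p1"] += p1[i]
                rec["m2"] += m2[i]; rec["p2"] += p2[i]
                if not assessable[i]:
                    rec["trail"].append(f"rep{rep}:not_assessable")
                    continue
                rec["assessable"] += 1
                rec["q"].append(qvals[i])
                trail = [f"rep{rep}:q={qvals[i]:.3g}"]
                if qvals[i] >= params.alpha:
                    trail.append("fail:alpha")
                    rec["trail"].append(",".join(trail))
                    continue
                sc_pass = seedcoat_filter(
                    g, expression, tissue, params.seedcoat_max_log2_diff
                )
                if not sc_pass:
                    trail.append("fail:seedcoat")
                    rec["trail"].append(",".join(trail))
                    continue
                dosage = 2.0 if tissue == "endosperm" else 1.0
                if_mat = imprinting_factor(m1[i], p1[i], m2[i], p2[i], "maternal", dosage)
                if_pat = imprinting_factor(m1[i], p1[i], m2[i], p2[i], "paternal", dosage)
                if tissue == "endosperm":
                    meg_ok = (f1[i] >= params.maternal_cutoff_endosperm
                              and f2[i] >= params.maternal_cutoff_endosperm)
                    peg_ok = ((1 - f1[i]) >= params.paternal_cutoff_endosperm
                              and (1 - f2[i]) >= params.paternal_cutoff_endosperm)
                else:
                    meg_ok = (f1[i] >= params.maternal_cutoff_embryo
                              and f2[i] >= params.maternal_cutoff_embryo)
                    peg_ok = (f1[i] < params.maternal_peg_cutoff_embryo
                              and f2[i] < params.maternal_peg_cutoff_embryo)
                if meg_ok and if_mat >= params.min_imprinting_factor:
                    rec["meg"] += 1
                    trail.append("call:MEG")
                elif peg_ok and if_pat >= params.min_imprinting_factor:
                    rec["peg"] += 1
                    trail.append("call:PEG")
                else:
                    trail.append("fail:cutoff_or_IF")
                rec["trail"].append(",".join(trail))
        if n_replicates < 3 and tissue == "endosperm":
            logger.warning(
                "pair %s-%s has %d replicate pair(s); proceeding", sa, sb, n_replicates
            )
        for g, rec in per_gene.items():
            if rec["assessable"] == 0:
                status = NOT_ASSESSABLE
            elif rec["meg"] >= min_calls:
                status = MEG
            elif rec["peg"] >= min_calls:
                status = PEG
            else:
                status = NONE
            tot1 = rec["m1"] + rec["p1"]
            tot2 = rec["m2"] + rec["p2"]
            results.append(
                {
                    "gene_id": g,
                    "strain_a": sa,
                    "strain_b": sb,
                    "status": status,
                    "p_adj": float(np.min(rec["q"])) if rec["q"] else np.nan,
                    "imprinting_factor": imprinting_factor(
                        rec["m1"], rec["p1"], rec["m2"], rec["p2"],
                        "paternal" if status == PEG else "maternal",
                        2.0 if tissue == "endosperm" else 1.0,
                    ),
                    "maternal_fraction_dir1": rec["m1"] / tot1 if tot1 else np.nan,
                    "maternal_fraction_dir2": rec["m2"] / tot2 if tot2 else np.nan,
                    "replicates_called": max(rec["meg"], rec["peg"]),
                    "replicates_assessable": rec["assessable"],
                    "filter_trail": ";".join(rec["trail"]),
                }
            )
    out = pd.DataFrame(results)
    return out.sort_values(["strain_a", "strain_b", "gene_id"]).reset_index(drop=True)


def detect_allele_specific(
    counts: pd.DataFrame,
    calls: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    retention_distance: float = 1.0,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> pd.DataFrame:
    """Detect strain-dependent (allele-specific) imprinting patterns.

    Replicates are summed per cross direction.  For each cross pair, loci
    with informative reads in both directions (and passing the seed-coat
    filter) get ratio-plane coordinates x = (m+1)/(p+1) per direction; loci
    within ``retention_distance`` of either no-imprinting line (coordinate
    = 2) are retained.  Per direction the parental bias b is standardized
    over retained loci; a locus is flagged as biased in one direction when
    its standardized bias is beyond the stated percentile there while the
    other direction stays within the retention distance of its line.  Bias
    flags are keyed by (strain, parental role) and intersected across the
    two cross pairs sharing that key, then intersected with the MEG/PEG
    calls of the remaining pair to emit patterns such as
    "PEG except when C is the father".
    """
    pooled = (
        counts[counts["tissue"] == "endosperm"]
        .groupby(["gene_id", "mother", "father"], as_index=False)[
            ["maternal_reads", "paternal_reads"]
        ]
        .sum()
    )
    strains = sorted(set(pooled["mother"]) | set(pooled["father"]))
    if len(strains) != 3:
        raise ValueError(f"allele-specific detection needs exactly 3 strains, got {strains}")

    # bias flags: (strain, role, bias_type) -> per-pair list of gene sets
    flags: dict[tuple[str, str, str], dict[tuple, set]] = {}

    for i in range(3):
        for j in range(i + 1, 3):
            sa, sb = strains[i], strains[j]
            d1 = pooled[(pooled["mother"] == sa) & (pooled["father"] == sb)]
            d2 = pooled[(pooled["mother"] == sb) & (pooled["father"] == sa)]
            if d1.empty or d2.empty:
                raise ValueError(f"missing reciprocal direction for pair {sa}-{sb}")
            merged = d1.merge(d2, on="gene_id", suffixes=("_1", "_2"))
            merged = merged[
                (merged["maternal_reads_1"] + merged["paternal_reads_1"] > 0)
                & (merged["maternal_reads_2"] + merged["paternal_reads_2"] > 0)
            ]
            if expression is not None:
                ok = merged["gene_id"].map(
                    lambda g: seedcoat_filter(g, expression, "endosperm")
                )
                merged = merged[ok]
            x = (merged["maternal_reads_1"] + 1) / (merged["paternal_reads_1"] + 1)
            y = (merged["maternal_reads_2"] + 1) / (merged["paternal_reads_2"] + 1)
            near_x = (x - 2).abs() <= retention_distance
            near_y = (y - 2).abs() <= retention_distance
            retained = merged[near_x | near_y].reset_index(drop=True)
            if len(retained) < 2:
                continue
            for direction, (mother, father), other_near in (
                (1, (sa, sb), near_y[near_x | near_y].to_numpy()),
                (2, (sb, sa), near_x[near_x | near_y].to_numpy()),
            ):
                b = np.array(
                    [
                        bias_factor(m, p)
                        for m, p in zip(
                            retained[f"maternal_reads_{direction}"],
                            retained[f"paternal_reads_{direction}"],
                        )
                    ]
                )
                b_norm = normalize_bias(b)
                hi = np.percentile(b_norm, upper_pct)
                lo = np.percentile(b_norm, lower_pct)
                maternal_hits = set(
                    retained.loc[(b_norm > hi) & other_near, "gene_id"]
                )
                paternal_hits = set(
                    retained.loc[(b_norm < lo) & other_near, "gene_id"]
                )
                for btype, hits in (("maternal", maternal_hits), ("paternal", paternal_hits)):
                    for strain, role in ((mother, "mother"), (father, "father")):
                        flags.setdefault((strain, role, btype), {})[(sa, sb)] = hits

    call_lists: dict[tuple[str, tuple], set] = {}
    for (sa, sb), grp in calls.groupby(["strain_a", "strain_b"]):
        call_lists[("MEG", (sa, sb))] = set(grp.loc[grp["status"] == MEG, "gene_id"])
        call_lists[("PEG", (sa, sb))] = set(grp.loc[grp["status"] == PEG, "gene_id"])

    rows = []
    role_names = {"mother": "the mother", "father": "the father"}
    for (strain, role, btype), per_pair in flags.items():
        if len(per_pair) < 2:
            continue
        consistent = set.intersection(*per_pair.values())
        if not consistent:
            continue
        others = tuple(sorted(s for s in strains if s != strain))
        status = MEG if btype == "maternal" else PEG
        imprinted_other = call_lists.get((status, others), set())
        exception_role = "father" if role == "mother" else "mother"
        for g in sorted(consistent & imprinted_other):
            rows.append(
                {
                    "gene_id": g,
                    "status": status,
                    "strain": strain,
                    "exception_role": exception_role,
                    "pattern": f"{status} except when {strain} is {role_names[exception_role]}",
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "status", "strain", "exception_role", "pattern"]
    ).drop_duplicates().reset_index(drop=True)
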