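"""Population-scale methylation variability classification of merged DMRs.

Each merged DMR gets one weighted-methylation score per strain (CpG sites
with >= 5 reads; strains need >= 5 qualifying sites).  Score vectors are
classified into five variability classes from their range R (max - min of
present scores) and the fraction f of strains in the outer quarter-bands of
the range (score < min + 0.25 R or > max - 0.25 R, strict, so boundary
values count as middle):

- censored: more missing strains than allowed (70 of 140 by default)
- very_low: R < 0.2
- low: 0.2 <= R < 0.4
- strongly_bimodal: R > 0.7 and f >= 0.8
- weakly_bimodal: (R > 0.7 and f >= 0.5) or (0.4 <= R <= 0.7 and f >= 0.8)
- not_bimodal: everything else
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .methylation import region_wmeth

VERY_LOW = "very_low"
LOW = "low"
NOT_BIMODAL = "not_bimodal"
WEAKLY_BIMODAL = "weakly_bimodal"
STRONGLY_BIMODAL = "strongly_bimodal"
CENSORED = "censored"

CLASSES = (VERY_LOW, LOW, NOT_BIMODAL, WEAKLY_BIMODAL, STRONGLY_BIMODAL, CENSORED)


def default_max_missing(n_strains: int) -> int:
    """70 for the 140-strain population, else half the population (ceil)."""
    return 70 if n_strains == 140 else math.ceil(n_strains / 2)


def score_dmr(
    dmr,
    strain_cytosines: dict[str, pd.DataFrame],
    min_sites: int = 5,
    min_cov: int = 5,
) -> pd.Series:
    """Per-strain weighted CpG methylation of one merged DMR.

    ``dmr`` needs attributes/keys chrom, start, end (0-based half-open).
    Strains with fewer than ``min_sites`` CpG sites at >= ``min_cov`` reads
    get NaN.
    """
    chrom, start, end = dmr["chrom"], int(dmr["start"]), int(dmr["end"])
    if end <= start:
        raise ValueError("empty DMR interval")
    scores = {}
    for strain, cyt in strain_cytosines.items():
        cg = cyt[cyt["context"] == "CG"]
        sel = cg[
            (cg["chrom"] == chrom)
            & (cg["pos"] - 1 >= start)
            & (cg["pos"] - 1 < end)
            & (cg["count_methylated"] + cg["count_unmethylated"] >= min_cov)
        ]
        if len(sel) < min_sites:
            scores[strain] = np.nan
        else:
            scores[strain] = region_wmeth(sel, chrom, start, end, min_cov=min_cov, context="CG")
    return pd.Series(scores, name=dmr.get("dmr_id") if hasattr(dmr, "get") else None)


def classify_variability(scores, max_missing: int | None = None) -> dict:
    """Classify one per-strain score vector; returns class plus diagnostics."""
    s = np.asarray(scores, dtype=float)
    n = s.size
    present = s[~np.isnan(s)]
    n_missing = n - present.size
    limit = default_max_missing(n) if max_missing is None else max_missing
    diag = {"n_strains": n, "n_present": int(present.size),
            "range": np.nan, "outer_fraction": np.nan}
    if n_missing > limit or present.size < 2:
        diag["variability_class"] = CENSORED
        return diag
    lo, hi = float(present.min()), float(present.max())
    r = hi - lo
    outer = np.count_nonzero((present < lo + 0.25 * r) | (present > hi - 0.25 * r))
    f = outer / present.size
    diag["range"] = r
    diag["outer_fraction"] = f
    if r < 0.2:
        cls = VERY_LOW
    elif r < 0.4:
        cls = LOW
    elif r > 0.7 and f >= 0.8:
        cls = STRONGLY_BIMODAL
    elif (r > 0.7 and f >= 0.5) or (0.4 <= r <= 0.7 and f >= 0.8):
        cls = WEAKLY_BIMODAL
    else:
        cls = NOT_BIMODAL
    diag["variability_class"] = cls
    return diag


def classify_matrix(matrix: pd.DataFrame, max_missing: int | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every row of a DMR x strain score matrix.

    Returns (per-DMR table with class and diagnostics, summary fractions by
    class over all DMRs).
    """
    rows = []
    for dmr_id, row in matrix.iterrows():
        diag = classify_variability(row.to_numpy(dtype=float), max_missing=max_missing)
        diag["dmr_id"] = dmr_id
        rows.append(diag)
    table = pd.DataFrame(
        rows, columns=["dmr_id", "variability_class", "range", "outer_fraction",
                       "n_present", "n_strains"]
    )
    if table.empty:
        return table, pd.Series(dtype=float)
    summary = table["variability_class"].value_counts(normalize=True).sort_index()
    return table, summary


def classify_all(
    dmrs: pd.DataFrame,
    strain_cytosines: dict[str, pd.DataFrame] | None = None,
    matrix: pd.DataFrame | None = None,
    min_sites: int = 5,
    min_cov: int = 5,
    max_missing: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Score (if needed) and classify a set of merged DMRs.

    Either pass per-strain cytosine tables (scoring is done here) or a
    precomputed dmr_id x strain matrix.
    """
    if matrix is None:
        if strain_cytosines is None:
            raise ValueError("need strain cytosines or a precomputed matrix")
        vectors = {}
        for _, dmr in dmrs.iterrows():
            vectors[dmr["dmr_id"]] = score_dmr(dmr, strain_cytosines, min_sites, min_cov)
        matrix = pd.DataFrame(vectors).T
    return classify_matrix(matrix, max_missing=max_missing)
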