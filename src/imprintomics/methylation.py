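"""Windowed weighted methylation and differential methylation calling.

Input cytosine tables are CX-report-like: one row per cytosine with a
1-based position, strand, context (CG/CHG/CHH) and methylated/unmethylated
read counts.  Internally positions are converted to 0-based half-open
intervals; emitted BED records are 0-based.

Weighted methylation of a region is pooled methylated reads divided by
pooled total reads over the informative sites (total >= min coverage); this
is deliberately not the mean of per-site fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats import bh_adjust, fisher_two_sided

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: context -> (min |weighted methylation difference|, min shared informative Cs)
DMR_THRESHOLDS = {"CG": (0.35, 3), "CHG": (0.35, 3), "CHH": (0.10, 10)}

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context"]


def _prep(cytosines: pd.DataFrame, context: str | None) -> pd.DataFrame:
    df = cytosines
    if context is not None:
        df = df[df["context"] == context]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos0": df["pos"].to_numpy(int) - 1,
            "strand": df["strand"].to_numpy(),
            "meth": df["count_methylated"].to_numpy(int),
            "total": df["count_methylated"].to_numpy(int) + df["count_unmethylated"].to_numpy(int),
        }
    )
    if (out["meth"] > out["total"]).any():
        raise ValueError("methylated count exceeds total")
    # duplicate rows for one position (e.g. split records) are aggregated
    out = out.groupby(["chrom", "pos0", "strand"], as_index=False)[["meth", "total"]].sum()
    return out


def _window_starts(pos0: np.ndarray, window: int, step: int) -> list[np.ndarray]:
    """For each overlap layer, the window start containing each site."""
    layers = []
    n_layers = -(-window // step)  # ceil
    for j in range(n_layers):
        k = pos0 // step - j
        start = k * step
        valid = (k >= 0) & (pos0 < start + window)
        layers.append(np.where(valid, start, -1))
    return layers


def window_methylation(
    cytosines: pd.DataFrame,
    window: int = 300,
    step: int = 200,
    min_cov: int = 5,
    context: str | None = None,
) -> pd.DataFrame:
    """Weighted methylation in sliding windows for one sample.

    Windows start at multiples of ``step`` and span ``window`` bp (the
    default 300/200 grid makes adjacent windows share 100 bp).  Only sites
    with total coverage >= ``min_cov`` contribute; windows without any
    informative site are omitted.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    sites = _prep(cytosines, context)
    sites = sites[sites["total"] >= min_cov]
    records = []
    for chrom, grp in sites.groupby("chrom"):
        pos0 = grp["pos0"].to_numpy()
        for starts in _window_starts(pos0, window, step):
            ok = starts >= 0
            agg = (
                pd.DataFrame(
                    {"start": starts[ok], "meth": grp["meth"].to_numpy()[ok],
                     "total": grp["total"].to_numpy()[ok]}
                )
                .groupby("start")
                .agg(sum_meth=("meth", "sum"), sum_total=("total", "sum"), n=("meth", "size"))
            )
            for start, row in agg.iterrows():
                records.append((chrom, int(start), int(start) + window,
                                int(row["sum_meth"]), int(row["sum_total"]), int(row["n"])))
    if not records:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "wmeth", "n_informative", "sum_meth", "sum_total"]
        )
    out = (
        pd.DataFrame(records, columns=["chrom", "start", "end", "sum_meth", "sum_total", "n_informative"])
        .groupby(["chrom", "start", "end"], as_index=False)
        .sum()
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    out["wmeth"] = out["sum_meth"] / out["sum_total"]
    return out[["chrom", "start", "end", "wmeth", "n_informative", "sum_meth", "sum_total"]]


def compare_windows(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    context: str,
    window: int = 300,
    step: int = 200,
    min_cov: int = 5,
    q_threshold: float = 0.01,
    min_diff: float | None = None,
    min_shared: int | None = None,
) -> pd.DataFrame:
    """Pairwise differential methylation on the sliding-window grid.

    Both samples are restricted to cytosine positions informative (total >=
    ``min_cov``) in BOTH; weighted methylation, the difference (a - b) and a
    two-sided Fisher test on the pooled methylated/unmethylated counts are
    computed on that shared site set.  BH correction runs across all tested
    windows of this comparison.  A window is a DMR candidate when q <
    ``q_threshold`` and |diff| and the shared-site count meet the context
    thresholds (0.35 / 3 Cs for CG and CHG; 0.10 / 10 Cs for CHH).
    """
    if context not in DMR_THRESHOLDS:
        raise ValueError(f"unknown context {context!r}")
    default_diff, default_shared = DMR_THRESHOLDS[context]
    min_diff = default_diff if min_diff is None else min_diff
    min_shared = default_shared if min_shared is None else min_shared

    a = _prep(sample_a, context)
    b = _prep(sample_b, context)
    a = a[a["total"] >= min_cov]
    b = b[b["total"] >= min_cov]
    shared = a.merge(b, on=["chrom", "pos0", "strand"], suffixes=("_a", "_b"))
    if shared.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "context", "wmeth_a", "wmeth_b",
                     "diff", "n_shared", "p_raw", "q", "direction", "is_dmr"]
        )
    records = []
    for chrom, grp in shared.groupby("chrom"):
        pos0 = grp["pos0"].to_numpy()
        for starts in _window_starts(pos0, window, step):
            ok = starts >= 0
            sub = grp.loc[ok].copy()
            sub["start"] = starts[ok]
            agg = sub.groupby("start").agg(
                meth_a=("meth_a", "sum"), total_a=("total_a", "sum"),
                meth_b=("meth_b", "sum"), total_b=("total_b", "sum"),
                n=("pos0", "size"),
            )
            for start, row in agg.iterrows():
                records.append((chrom, int(start), int(start) + window, row))
    rows = []
    for chrom, start, end, row in records:
        rows.append(
            {
                "chrom": chrom, "start": start, "end": end, "context": context,
                "meth_a": int(row["meth_a"]), "total_a": int(row["total_a"]),
                "meth_b": int(row["meth_b"]), "total_b": int(row["total_b"]),
                "n_shared": int(row["n"]),
            }
        )
    out = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    # aggregate duplicated (chrom,start) coming from different layers
    out = out.groupby(["chrom", "start", "end", "context"], as_index=False).sum()
    out["wmeth_a"] = out["meth_a"] / out["total_a"]
    out["wmeth_b"] = out["meth_b"] / out["total_b"]
    out["diff"] = out["wmeth_a"] - out["wmeth_b"]
    out["p_raw"] = [
        fisher_two_sided(
            [[r.meth_a, r.total_a - r.meth_a], [r.meth_b, r.total_b - r.meth_b]]
        )
        for r in out.itertuples()
    ]
    out["q"] = bh_adjust(out["p_raw"].to_numpy())
    out["direction"] = np.sign(out["diff"]).astype(int)
    out["is_dmr"] = (
        (out["q"] < q_threshold)
        & (out["diff"].abs() >= min_diff)
        & (out["n_shared"] >= min_shared)
    )
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out[
        ["chrom", "start", "end", "context", "wmeth_a", "wmeth_b", "diff",
         "n_shared", "p_raw", "q", "direction", "is_dmr"]
    ]


def merge_dmrs(dmr_windows: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping or book-ended DMR windows of one context/direction.

    Merged records carry the minimum q, the maximum |diff| and the window
    count; rows flagged ``is_dmr`` == False are ignored if the column exists.
    """
    df = dmr_windows
    if "is_dmr" in df.columns:
        df = df[df["is_dmr"]]
    merged = []
    for (chrom, context, direction), grp in df.groupby(["chrom", "context", "direction"]):
        grp = grp.sort_values("start")
        cur = None
        for r in grp.itertuples():
            if cur is None or r.start > cur["end"]:
                if cur is not None:
                    merged.append(cur)
                cur = {"chrom": chrom, "start": int(r.start), "end": int(r.end),
                       "context": context, "direction": int(direction),
                       "q": float(r.q), "max_abs_diff": abs(float(r.diff)), "n_windows": 1}
            else:
                cur["end"] = max(cur["end"], int(r.end))
                cur["q"] = min(cur["q"], float(r.q))
                cur["max_abs_diff"] = max(cur["max_abs_diff"], abs(float(r.diff)))
                cur["n_windows"] += 1
        if cur is not None:
            merged.append(cur)
    out = pd.DataFrame(
        merged,
        columns=["chrom", "start", "end", "context", "direction", "q", "max_abs_diff", "n_windows"],
    )
    if out.empty:
        return out
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out.insert(0, "dmr_id", [f"dmr_{i:05d}" for i in range(len(out))])
    return out


def annotate_dmrs(dmrs: pd.DataFrame, features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign DMRs to overlapping features (>= 1 bp) and summarize by class.

    ``features`` needs columns feature_id, chrom, start, end, feature_class
    (e.g. gene/TE).  Returns (per-DMR table with a comma-joined feature
    list, summary with distinct-feature counts per class plus the number of
    intergenic DMRs).
    """
    feat_by_chrom: dict[str, pd.DataFrame] = {
        c: g for c, g in features.groupby("chrom")
    }
    hits_col, classes_col = [], []
    hit_features: dict[str, set] = {}
    n_intergenic = 0
    for r in dmrs.itertuples():
        feats = feat_by_chrom.get(r.chrom)
        if feats is None:
            over = []
        else:
            sel = (feats["start"] < r.end) & (feats["end"] > r.start)
            over = list(feats.loc[sel, ["feature_id", "feature_class"]].itertuples(index=False))
        if not over:
            n_intergenic += 1
        hits_col.append(",".join(f.feature_id for f in over))
        classes_col.append(",".join(sorted({f.feature_class for f in over})))
        for f in over:
            hit_features.setdefault(f.feature_class, set()).add(f.feature_id)
    annotated = dmrs.copy()
    annotated["features"] = hits_col
    annotated["feature_classes"] = classes_col
    summary_rows = [
        {"feature_class": cls, "n_features": len(ids)} for cls, ids in sorted(hit_features.items())
    ]
    summary_rows.append({"feature_class": "intergenic", "n_features": n_intergenic})
    return annotated, pd.DataFrame(summary_rows)


def region_wmeth(
    cytosines: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    min_cov: int = 5,
    context: str | None = None,
) -> float:
    """Weighted methylation of an arbitrary 0-based half-open region (NaN if
    no informative site)."""
    if end <= start:
        raise ValueError("empty region")
    sites = _prep(cytosines, context)
    sel = sites[
        (sites["chrom"] == chrom)
        & (sites["pos0"] >= start)
        & (sites["pos0"] < end)
        & (sites["total"] >= min_cov)
    ]
    if sel.empty:
        return float("nan")
    return float(sel["meth"].sum() / sel["total"].sum())


def metaprofile(
    cytosines: pd.DataFrame,
    features: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 200,
    body_bins: int = 10,
    min_cov: int = 5,
    context: str | None = None,
) -> pd.DataFrame:
    """Average methylation profile over stranded features.

    Fixed ``flank``/``bin_size`` bins upstream and downstream plus
    ``body_bins`` proportionally scaled bins over the feature body; per
    feature and bin the weighted methylation; the profile is the mean over
    features ignoring missing bins.  Minus-strand features are reversed so
    bin 0 is always the distal 5' flank.
    """
    n_flank = flank // bin_size
    n_bins = 2 * n_flank + body_bins
    sites = _prep(cytosines, context)
    sites = sites[sites["total"] >= min_cov]
    meth = np.zeros((len(features), n_bins))
    meth[:] = np.nan
    for fi, f in enumerate(features.itertuples()):
        edges = []
        for j in range(n_flank):
            edges.append((f.start - flank + j * bin_size, f.start - flank + (j + 1) * bin_size))
        body_edges = np.linspace(f.start, f.end, body_bins + 1)
        for j in range(body_bins):
            edges.append((body_edges[j], body_edges[j + 1]))
        for j in range(n_flank):
            edges.append((f.end + j * bin_size, f.end + (j + 1) * bin_size))
        sel = sites[sites["chrom"] == f.chrom]
        vals = []
        for s, e in edges:
            sub = sel[(sel["pos0"] >= s) & (sel["pos0"] < e)]
            vals.append(sub["meth"].sum() / sub["total"].sum() if len(sub) else np.nan)
        if getattr(f, "strand", "+") == "-":
            vals = vals[::-1]
        meth[fi] = vals
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(meth, axis=0)
    labels = (
        [f"up_{i}" for i in range(n_flank)]
        + [f"body_{i}" for i in range(body_bins)]
        + [f"down_{i}" for i in range(n_flank)]
    )
    return pd.DataFrame({"bin": labels, "position": np.arange(n_bins), "wmeth": profile})


def compare_strain_feature_methylation(
    feature_wmeth: pd.DataFrame,
    reference: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Strain-vs-strain comparison of per-feature methylation levels.

    ``feature_wmeth`` is a feature x strain table of weighted methylation.
    Values are scaled by the reference strain's mean (first column by
    default), tested by one-way ANOVA and compared pairwise with Tukey's
    HSD at ``alpha``.  Returns one row per strain pair with the mean scaled
    difference and a significance flag.
    """
    df = feature_wmeth.dropna()
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise ValueError("need >= 2 strains and >= 2 features with complete data")
    reference = reference or df.columns[0]
    ref_mean = df[reference].mean()
    if ref_mean == 0:
        raise ValueError("reference strain mean is zero")
    scaled = df / ref_mean
    groups = [scaled[c].to_numpy() for c in scaled.columns]
    anova = _st.f_oneway(*groups)
    tukey = _st.tukey_hsd(*groups)
    rows = []
    cols = list(scaled.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rows.append(
                {
                    "strain_1": cols[i],
                    "strain_2": cols[j],
                    "mean_scaled_diff": float(scaled[cols[i]].mean() - scaled[cols[j]].mean()),
                    "tukey_p": float(tukey.pvalue[i, j]),
                    "significant": bool(tukey.pvalue[i, j] < alpha),
                    "anova_p": float(anova.pvalue),
                }
            )
    return pd.DataFrame(rows)
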