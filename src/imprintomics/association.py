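"""Gene-DMR association, enrichment testing and TE proximity matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import fisher_two_sided


def associate_genes_dmrs(
    genes: pd.DataFrame, dmrs: pd.DataFrame, flank: int = 2000
) -> pd.DataFrame:
    """Associate each gene with DMRs overlapping its body or 2 kb flanks.

    ``genes`` needs gene_id, chrom, start, end, strand; ``dmrs`` needs
    dmr_id, chrom, start, end (all 0-based half-open).  Body overlap takes
    precedence over flank overlap; flank relations are strand-aware
    (upstream = 5' side).  Distance is the gap between the DMR and the
    nearest gene end (0 for body hits).
    """
    rows = []
    dmr_by_chrom = {c: g for c, g in dmrs.groupby("chrom")}
    for g in genes.itertuples():
        cand = dmr_by_chrom.get(g.chrom)
        if cand is None:
            continue
        for d in cand.itertuples():
            if d.start < g.end and d.end > g.start:
                relation, dist = "body", 0
            elif d.end <= g.start and g.start - d.end < flank:
                dist = g.start - d.end
                relation = "upstream_2kb" if g.strand == "+" else "downstream_2kb"
            elif d.start >= g.end and d.start - g.end < flank:
                dist = d.start - g.end
                relation = "downstream_2kb" if g.strand == "+" else "upstream_2kb"
            else:
                continue
            rows.append(
                {"gene_id": g.gene_id, "dmr_id": d.dmr_id, "relation": relation,
                 "distance": int(dist)}
            )
    return pd.DataFrame(rows, columns=["gene_id", "dmr_id", "relation", "distance"])


def enrichment_test(query_genes, flagged_genes, background_genes) -> dict:
    """Fisher enrichment of an association flag in a query gene set.

    2x2 table: (query vs rest of background) x (flagged vs not).  Returns
    the two-sided p-value, the fold ratio of flag rates and the table.
    """
    query = set(query_genes)
    background = set(background_genes)
    flagged = set(flagged_genes) & background
    if not background:
        raise ValueError("empty background")
    if not query:
        raise ValueError("empty query set")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    rest = background - query
    a = len(query & flagged)
    b = len(query) - a
    c = len(rest & flagged)
    d = len(rest) - c
    p = fisher_two_sided([[a, b], [c, d]])
    query_rate = a / len(query)
    bg_rate = len(flagged) / len(background)
    fold = query_rate / bg_rate if bg_rate > 0 else np.inf
    return {"pvalue": p, "fold": fold, "table": ((a, b), (c, d)),
            "query_rate": query_rate, "background_rate": bg_rate}


def te_proximity(
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 200,
    body_extent: int = 1000,
) -> pd.DataFrame:
    """Binary TE-presence matrix in strand-oriented bins around each gene.

    Columns cover the 5' flank, the first ``body_extent`` bp of the body,
    the last ``body_extent`` bp and the 3' flank, in ``bin_size`` steps.
    """
    n_flank = flank // bin_size
    n_body = body_extent // bin_size
    labels = (
        [f"up_{i}" for i in range(n_flank)]
        + [f"body5_{i}" for i in range(n_body)]
        + [f"body3_{i}" for i in range(n_body)]
        + [f"down_{i}" for i in range(n_flank)]
    )
    te_by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in tes.groupby("chrom")}
    mat = np.zeros((len(genes), len(labels)), dtype=int)
    gene_ids = []
    for gi, g in enumerate(genes.itertuples()):
        gene_ids.append(g.gene_id)
        fwd = getattr(g, "strand", "+") != "-"
        bins = []
        for i in range(n_flank):
            bins.append((g.start - flank + i * bin_size, g.start - flank + (i + 1) * bin_size))
        for i in range(n_body):
            bins.append((g.start + i * bin_size, g.start + (i + 1) * bin_size))
        for i in range(n_body):
            bins.append((g.end - body_extent + i * bin_size, g.end - body_extent + (i + 1) * bin_size))
        for i in range(n_flank):
            bins.append((g.end + i * bin_size, g.end + (i + 1) * bin_size))
        if not fwd:
            bins = bins[::-1]
        arr = te_by_chrom.get(g.chrom)
        if arr is None:
            continue
        for bi, (s, e) in enumerate(bins):
            if ((arr[:, 0] < e) & (arr[:, 1] > s)).any():
                mat[gi, bi] = 1
    return pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=labels)
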