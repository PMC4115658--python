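"""Readers/writers for the plain-text interchange formats.

All tables are tab-separated; intervals are emitted as BED (0-based
half-open).  Cytosine files follow the CX-report dialect with 1-based
positions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allelic import SNPRecord

ALLELE_COUNT_COLUMNS = [
    "gene_id", "mother", "father", "tissue", "replicate", "maternal_reads", "paternal_reads",
]
CYTOSINE_COLUMNS = [
    "chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context",
]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_allele_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALLELE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-count table missing columns {sorted(missing)}")
    return df


def read_cytosines(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CYTOSINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cytosine table missing columns {sorted(missing)}")
    return df


def read_snps(path) -> list[SNPRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SNPRecord(str(r.chrom), int(r.pos), str(r.base_a), str(r.base_b))
        for r in df.itertuples()
    ]


def write_snps(snps, path) -> None:
    df = pd.DataFrame(
        [(s.chrom, s.pos, s.base_a, s.base_b) for s in snps],
        columns=["chrom", "pos", "base_a", "base_b"],
    )
    write_tsv(df, path)


def read_bed(path) -> pd.DataFrame:
    """BED3/BED6 into a DataFrame (name -> feature_id when present)."""
    names = ["chrom", "start", "end", "feature_id", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, name_col: str | None = None, score_col: str | None = None) -> None:
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df[name_col] if name_col else ".",
            "score": df[score_col] if score_col else 0,
            "strand": df["strand"] if "strand" in df.columns else ".",
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", header=False, index=False)


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Merged DMRs as BED6+; score is -log10 q (capped at 320)."""
    df = dmrs.copy()
    with np.errstate(divide="ignore"):
        df["score"] = np.minimum(-np.log10(np.maximum(df["q"], 1e-320)), 320.0).round(3)
    df["strand"] = np.where(df["direction"] >= 0, "+", "-")
    out = df[["chrom", "start", "end", "context", "score", "strand"]].copy()
    for extra in ("dmr_id", "max_abs_diff", "n_windows", "q"):
        if extra in df.columns:
            out[extra] = df[extra]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_score_matrix(path) -> pd.DataFrame:
    """dmr_id x strain matrix with NA for missing scores."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    return df


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
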