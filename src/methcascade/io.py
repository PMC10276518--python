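"""Plain-text readers/writers: TSV count matrices, CSV sample sheets,
BED region files, truth tables, and YAML configs.

Count matrices are written with one row per sample and a pair of columns
``<region>.methylated`` / ``<region>.detected`` per region, so that a
write -> read -> write cycle is byte-identical.  BED is 0-based
half-open; the strand column is carried but ignored (region-level
methylation aggregates are strandless).
"""

from __future__ import annotations

import logging

import pandas as pd
import yaml

from .quantify import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_count_matrix", "write_count_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_bed", "write_bed",
    "read_truth", "write_truth",
    "read_allowlist",
    "load_yaml",
]

SAMPLE_SHEET_REQUIRED = ("sample", "group")
BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


class FormatError(ValueError):
    pass


def write_count_matrix(matrix: MethylationMatrix, path) -> None:
    cols = {}
    for region in matrix.regions:
        cols[f"{region}.methylated"] = matrix.methylated[region]
        cols[f"{region}.detected"] = matrix.detected[region]
    wide = pd.DataFrame(cols, index=matrix.samples)
    wide.index.name = "sample"
    wide.to_csv(path, sep="\t")


def read_count_matrix(path) -> MethylationMatrix:
    wide = pd.read_csv(path, sep="\t", index_col="sample")
    if wide.index.has_duplicates:
        dups = wide.index[wide.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    meth_cols = [c for c in wide.columns if c.endswith(".methylated")]
    regions = [c[: -len(".methylated")] for c in meth_cols]
    missing = [r for r in regions if f"{r}.detected" not in wide.columns]
    if missing or not regions:
        raise FormatError(
            f"{path}: expected '<region>.methylated'/'<region>.detected' column "
            f"pairs{'; unpaired: ' + str(missing) if missing else ''}"
        )
    meth = wide[[f"{r}.methylated" for r in regions]].copy()
    det = wide[[f"{r}.detected" for r in regions]].copy()
    meth.columns = det.columns = regions
    return MethylationMatrix(meth.astype(int), det.astype(int))


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    df = samples.copy()
    df.index.name = "sample"
    df.to_csv(path)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: sample sheet missing required column(s) {missing}; "
            f"required: {list(SAMPLE_SHEET_REQUIRED)}"
        )
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    return df.set_index("sample")


def write_bed(regions: pd.DataFrame, path) -> None:
    regions[list(BED_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            score = parts[4] if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in (".", ""):
                logger.warning(
                    "%s:%d: strand %r ignored (regions are strandless aggregates)",
                    path, lineno, strand,
                )
            rows.append((parts[0], start, end, name, score, strand or "."))
    return pd.DataFrame(rows, columns=list(BED_COLUMNS))


def write_truth(truth: pd.Series, path) -> None:
    df = truth.rename("informative").to_frame()
    df.index.name = "region"
    df.to_csv(path, sep="\t")


def read_truth(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="region")
    return df["informative"].astype(bool)


def read_allowlist(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
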