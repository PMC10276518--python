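"""Region-level methylation quantification and QC.

The primary readout is the average methylation fraction (AMF) of a genomic
region in one sample: the number of methylated CpG observations divided by
the number of detected CpG observations.  A :class:`MethylationMatrix` holds
the paired methylated/detected count matrices (samples x regions) and derives
AMF on demand; cells with zero detected CpGs have an undefined (missing) AMF.

A coverage filter drops regions whose detected-CpG depth is inadequate
(default 100x) and masks individual under-covered cells, and a small qPCR
layer converts marker/reference Ct pairs into a fraction-scale relative
signal via the standard 2^(-dCt) transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataIntegrityError",
    "NoRegionsPassCoverage",
    "MethylationMatrix",
    "average_methylation_fraction",
    "coverage_filter",
    "qpcr_relative_signal",
    "quantify_qpcr",
    "QPCR_MAX_CYCLES",
]

QPCR_MAX_CYCLES = 40.0


class DataIntegrityError(ValueError):
    """Counts violate the methylated <= detected contract."""


class NoRegionsPassCoverage(ValueError):
    """Coverage filtering removed every region."""


@dataclass
class MethylationMatrix:
    """Paired per-sample, per-region CpG count matrices.

    Attributes
    ----------
    methylated, detected:
        Integer DataFrames with identical sample index and region columns;
        ``0 <= methylated <= detected`` cell-wise.
    """

    methylated: pd.DataFrame
    detected: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.methylated.index.equals(self.detected.index):
            raise DataIntegrityError("methylated/detected sample indexes differ")
        if not self.methylated.columns.equals(self.detected.columns):
            raise DataIntegrityError("methylated/detected region columns differ")
        if self.methylated.index.has_duplicates:
            dups = self.methylated.index[self.methylated.index.duplicated()].tolist()
            raise DataIntegrityError(f"duplicate sample ids: {dups}")
        meth = self.methylated.to_numpy()
        det = self.detected.to_numpy()
        if (meth < 0).any() or (det < 0).any():
            raise DataIntegrityError("negative CpG counts")
        bad = meth > det
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataIntegrityError(
                "methylated > detected at sample "
                f"{self.methylated.index[i]!r}, region {self.methylated.columns[j]!r}"
            )

    @property
    def samples(self) -> pd.Index:
        return self.methylated.index

    @property
    def regions(self) -> pd.Index:
        return self.methylated.columns

    @property
    def amf(self) -> pd.DataFrame:
        """Average methylation fraction per cell; NaN where detected == 0."""
        det = self.detected.to_numpy(dtype=float)
        meth = self.methylated.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(det > 0, meth / np.where(det > 0, det, 1.0), np.nan)
        return pd.DataFrame(frac, index=self.samples, columns=self.regions)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(
            self.methylated.loc[sample_ids], self.detected.loc[sample_ids]
        )

    def subset_regions(self, region_ids) -> "MethylationMatrix":
        return MethylationMatrix(
            self.methylated.loc[:, region_ids], self.detected.loc[:, region_ids]
        )


def average_methylation_fraction(methylated, detected):
    """AMF = methylated CpGs / detected CpGs; NaN when nothing was detected.

    Accepts scalars or array-likes.  Raises :class:`DataIntegrityError` if
    any methylated count exceeds its detected count or is negative.
    """
    meth = np.asarray(methylated, dtype=float)
    det = np.asarray(detected, dtype=float)
    if (meth < 0).any() or (det < 0).any():
        raise DataIntegrityError("negative CpG counts")
    # detected == 0 means no data for the cell, so its AMF is missing and
    # the methylated count is not checked against it.
    if ((det > 0) & (meth > det)).any():
        raise DataIntegrityError("methylated count exceeds detected count")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(det > 0, meth / np.where(det > 0, det, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def coverage_filter(
    matrix: MethylationMatrix, min_coverage: int = 100
) -> MethylationMatrix:
    """Drop low-coverage regions; mask under-covered cells.

    A region is retained when its *median* detected-CpG count across samples
    is at least ``min_coverage``.  Within retained regions, any cell whose
    detected count falls below the threshold is zeroed out so its AMF reads
    as missing rather than as a noisy estimate.  Idempotent.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be non-negative")
    med = matrix.detected.median(axis=0)
    keep = med[med >= min_coverage].index
    dropped = matrix.regions.difference(keep)
    if len(keep) == 0:
        raise NoRegionsPassCoverage(
            f"no regions pass coverage >= {min_coverage} (median across samples)"
        )
    logger.info(
        "coverage_filter: kept %d/%d regions at min_coverage=%d (dropped %d)",
        len(keep), len(matrix.regions), min_coverage, len(dropped),
    )
    meth = matrix.methylated.loc[:, keep].copy()
    det = matrix.detected.loc[:, keep].copy()
    low = det.to_numpy() < min_coverage
    if low.any():
        m = meth.to_numpy()
        d = det.to_numpy()
        m[low] = 0
        d[low] = 0
        meth = pd.DataFrame(m, index=meth.index, columns=meth.columns)
        det = pd.DataFrame(d, index=det.index, columns=det.columns)
    return MethylationMatrix(meth, det)


def qpcr_relative_signal(
    ct_marker: float, ct_reference: float, max_cycles: float = QPCR_MAX_CYCLES
) -> float:
    """Relative template abundance from a marker/reference Ct pair.

    Standard relative quantification: ``2 ** (ct_reference - ct_marker)``.
    A marker Ct at or beyond ``max_cycles`` (no amplification) is treated as
    censored and returns 0.  Missing reference Ct raises ValueError — the
    sample failed its internal quality control.
    """
    if ct_reference is None or np.isnan(ct_reference):
        raise ValueError("missing reference-gene Ct: sample fails qPCR QC")
    if ct_marker is None or np.isnan(ct_marker) or ct_marker >= max_cycles:
        return 0.0
    return float(2.0 ** (ct_reference - ct_marker))


def quantify_qpcr(
    plate: pd.DataFrame, max_cycles: float = QPCR_MAX_CYCLES
) -> pd.DataFrame:
    """Convert a long qPCR plate table into a samples x markers signal matrix.

    ``plate`` needs columns ``sample``, ``marker``, ``ct_marker``,
    ``ct_reference``.  Samples with a missing reference Ct in any record are
    excluded entirely (QC failure) and logged.
    """
    required = {"sample", "marker", "ct_marker", "ct_reference"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    bad_ref = plate.loc[plate["ct_reference"].isna(), "sample"].unique()
    if len(bad_ref):
        logger.warning(
            "quantify_qpcr: excluding %d sample(s) with missing reference Ct: %s",
            len(bad_ref), list(bad_ref),
        )
    ok = plate[~plate["sample"].isin(bad_ref)].copy()
    ok["relative_signal"] = [
        qpcr_relative_signal(cm, cr, max_cycles)
        for cm, cr in zip(ok["ct_marker"], ok["ct_reference"])
    ]
    wide = ok.pivot_table(
        index="sample", columns="marker", values="relative_signal", aggfunc="mean"
    )
    wide.index.name = "sample"
    return wide
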