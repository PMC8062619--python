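"""Housekeeping-based content normalization and detection-limit filtering.

Digital probe-count platforms correct for sample-to-sample differences in
RNA input by scaling each sample so that the geometric mean of its
housekeeping genes matches a common reference (the across-sample arithmetic
mean of those geometric means). Separately, the lowest positive spike-in of
the control ladder (POS_F) marks the lower limit of detection: a measured
transcript whose mean raw count across samples falls strictly below the mean
POS_F count is considered undetectable and its row is normalized to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PanelManifest

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Raised when a sample cannot be normalized."""


@dataclass(frozen=True)
class NormalizedMatrix:
    """Scaled expression values with the filtering provenance attached."""

    values: pd.DataFrame  # genes x samples, nonnegative reals
    lod_zeroed: frozenset[str]
    scale_factors: pd.Series  # per sample, positive
    log2: bool = False

    def __post_init__(self) -> None:
        if (self.scale_factors <= 0).any():
            raise NormalizationError("scale factors must be positive")
        zeroed = [g for g in self.lod_zeroed if g in self.values.index]
        if zeroed and not (self.values.loc[zeroed] == 0).all().all():
            raise NormalizationError("LOD-zeroed genes must have all-zero rows")

    def log_values(self) -> pd.DataFrame:
        """Values on the log2 scale (log2(x + 1) applied if not already)."""
        if self.log2:
            return self.values
        return np.log2(self.values + 1.0)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def compute_housekeeping_factors(raw: pd.DataFrame, manifest: PanelManifest) -> pd.Series:
    """Per-sample scale factors from housekeeping geometric means.

    factor(s) = mean_over_samples(geomean_hk) / geomean_hk(s). Zero counts
    are excluded from a sample's geometric mean (with a logged warning); a
    sample whose housekeeping counts are all zero is an error.
    """
    hk = [g for g in manifest.housekeeping_genes if g in raw.index]
    if not hk:
        raise NormalizationError("no housekeeping genes present in the count matrix")
    geomeans = {}
    for sample in raw.columns:
        counts = raw.loc[hk, sample].to_numpy(dtype=float)
        positive = counts[counts > 0]
        if positive.size == 0:
            raise NormalizationError(
                f"sample {sample!r}: all housekeeping counts are zero"
            )
        if positive.size < counts.size:
            logger.warning(
                "sample %s: %d zero-count housekeeping genes excluded from geometric mean",
                sample,
                counts.size - positive.size,
            )
        geomeans[sample] = float(np.exp(np.mean(np.log(positive))))
    geo = pd.Series(geomeans)
    reference = geo.mean()
    return reference / geo


def apply_lod_filter(raw: pd.DataFrame, manifest: PanelManifest) -> frozenset[str]:
    """Measured genes whose mean raw count falls below the POS_F mean.

    The threshold is the across-sample mean of the POS_F raw counts; the
    comparison is strict, so a gene exactly at the threshold is kept.
    Control probes are never zeroed.
    """
    posf = manifest.positive_control("F")
    if posf.gene_id not in raw.index:
        raise NormalizationError("POS_F counts missing from the matrix")
    threshold = float(raw.loc[posf.gene_id].mean())
    measured = [g for g in manifest.measured_genes if g in raw.index]
    means = raw.loc[measured].mean(axis=1)
    return frozenset(means.index[means < threshold])


def normalize(
    raw: pd.DataFrame, manifest: PanelManifest, log_transform: bool = False
) -> NormalizedMatrix:
    """Scale by housekeeping factors, zero sub-LOD genes, optionally log2.

    The log transform (log2(x + 1)) is applied after zeroing so that
    filtered rows map to exactly zero.
    """
    factors = compute_housekeeping_factors(raw, manifest)
    zeroed = apply_lod_filter(raw, manifest)
    values = raw.astype(float).mul(factors, axis=1)
    present = [g for g in zeroed if g in values.index]
    values.loc[present] = 0.0
    logger.info(
        "normalized %d genes x %d samples; %d genes below detection limit",
        values.shape[0],
        values.shape[1],
        len(present),
    )
    if log_transform:
        values = np.log2(values + 1.0)
    return NormalizedMatrix(
        values=values, lod_zeroed=zeroed, scale_factors=factors, log2=log_transform
    )
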