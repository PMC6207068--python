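"""Probe-level preprocessing: median normalization, Y removal, artefact masking."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


def median_normalize(profile: pd.DataFrame) -> pd.DataFrame:
    """Shift one sample's log2 ratios so their median is zero.

    Idempotent; probe order and positions are untouched. Non-finite
    values are ignored when computing the median but propagated.
    """
    values = profile["log2_ratio"].to_numpy(dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValidationError("profile has no finite log2 ratios")
    out = profile.copy()
    out["log2_ratio"] = values - np.median(values[finite])
    return out


def drop_chrY(profile: pd.DataFrame) -> pd.DataFrame:
    """Remove chromosome Y rows (unreliable without gender-matched references)."""
    mask = profile["chrom"].astype(str) == "Y"
    if mask.all() and len(profile):
        logger.warning("profile consists only of chromosome Y probes; result is empty")
    return profile[~mask].reset_index(drop=True)


def mask_artefacts(
    cohort: pd.DataFrame,
    gain_cutoff: float,
    loss_cutoff: float,
    recurrence_fraction: float = 0.20,
    variance_quantile: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag recurrent high-variance probe positions as platform artefacts.

    A genomic position is masked when the probe value is outside the
    platform's gain/loss cutoffs in more than ``recurrence_fraction`` of
    the platform's samples *and* its cross-sample variance exceeds the
    ``variance_quantile`` quantile of all positions' variances. Such
    positions reflect platform artefacts rather than tumor biology and
    are excluded before segmentation.

    Parameters
    ----------
    cohort
        Probe table of one platform (all samples).

    Returns
    -------
    (masked_cohort, report)
        The cohort without masked positions, and a BED-style report of
        the masked positions (chrom, start, end, recurrence, variance).
    """
    n_samples = cohort.sample_id.nunique()
    if n_samples < 2:
        raise ValidationError("artefact masking needs at least two samples on the platform")
    wide = cohort.pivot_table(index=["chrom", "position"], columns="sample_id", values="log2_ratio")
    values = wide.to_numpy(dtype=float)
    aberrant = (values > gain_cutoff) | (values < loss_cutoff)
    recurrence = np.nanmean(np.where(np.isnan(values), np.nan, aberrant), axis=1)
    variance = np.nanvar(values, axis=1)
    var_threshold = np.nanquantile(variance, variance_quantile)
    flagged = (recurrence > recurrence_fraction) & (variance > var_threshold)
    report = pd.DataFrame(
        {
            "chrom": wide.index.get_level_values("chrom")[flagged],
            "start": wide.index.get_level_values("position")[flagged],
            "end": wide.index.get_level_values("position")[flagged] + 1,
            "recurrence": recurrence[flagged],
            "variance": variance[flagged],
        }
    ).reset_index(drop=True)
    bad = set(zip(report.chrom, report.start))
    keep = ~cohort.apply(lambda r: (r.chrom, r.position) in bad, axis=1) if bad else np.ones(len(cohort), bool)
    return cohort[keep].reset_index(drop=True), report
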