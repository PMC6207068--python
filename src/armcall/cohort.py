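"""Cohort-level summaries: frequency tracks, region matrices, co-occurrence, QC."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .arms import FLAG_NAMES, classify_profile
from .calling import CALL_LABELS, GAIN_CLASS, LOSS_CLASS
from .errors import ValidationError
from .genome import ArmTable

DEFAULT_WINDOW = 1_000_000

# precedence for label cells in region matrices: stronger events win
_LABEL_RANK = {label: i for i, label in enumerate(
    ("normal", "gain", "loss", "amplification", "homozygous_deletion"))}


def genome_windows(arms: ArmTable, window_size: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Fixed non-overlapping windows tiling every chromosome."""
    if window_size <= 0:
        raise ValidationError("window_size must be positive")
    rows = []
    for chrom in arms.chromosomes:
        length = arms.chrom_length(chrom)
        starts = np.arange(0, length, window_size)
        for s in starts:
            rows.append({"chrom": chrom, "start": int(s), "end": int(min(s + window_size, length))})
    return pd.DataFrame(rows)


def aberration_frequency(
    cohort_segments: pd.DataFrame,
    arms: ArmTable,
    window_size: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-window fraction of samples with an overlapping gain-class or
    loss-class segment. Gains and losses are counted independently, so
    the two fractions may sum above 1."""
    if cohort_segments.empty:
        raise ValidationError("empty cohort")
    windows = genome_windows(arms, window_size)
    samples = cohort_segments.sample_id.unique()
    n = len(samples)
    gain_frac = np.zeros(len(windows))
    loss_frac = np.zeros(len(windows))
    win_by_chrom = {c: g for c, g in windows.groupby("chrom", sort=False)}
    for _, segs in cohort_segments.groupby("sample_id", sort=False):
        for cls, acc in ((GAIN_CLASS, gain_frac), (LOSS_CLASS, loss_frac)):
            hit = np.zeros(len(windows), dtype=bool)
            sub = segs[segs.annotation.isin(cls)]
            for seg in sub.itertuples():
                win = win_by_chrom.get(str(seg.chrom))
                if win is None:
                    continue
                mask = (win.start.values < seg.end) & (win.end.values > seg.start)
                hit[win.index[mask]] = True
            acc += hit
    out = windows.copy()
    out["gain_fraction"] = gain_frac / n
    out["loss_fraction"] = loss_frac / n
    return out


def region_matrix(
    cohort_segments: pd.DataFrame,
    regions: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x region matrices of log2 values and of call labels.

    ``regions`` needs columns chrom/start/end and either ``gene`` or
    window coordinates as identity. The log2 cell is the mean of
    overlapping segments weighted by the estimated number of probes each
    contributes to the region (n_probes scaled by overlapped fraction);
    the label cell is the highest-precedence overlapping label. Regions
    without coverage are NaN / empty.
    """
    if "gene" in regions.columns:
        names = list(regions.gene)
    else:
        names = [f"{r.chrom}:{r.start}-{r.end}" for r in regions.itertuples()]
    samples = list(cohort_segments.sample_id.unique())
    values = pd.DataFrame(np.nan, index=samples, columns=names)
    labels = pd.DataFrame("", index=samples, columns=names)
    for sample, segs in cohort_segments.groupby("sample_id", sort=False):
        for name, region in zip(names, regions.itertuples()):
            sub = segs[
                (segs.chrom.astype(str) == str(region.chrom))
                & (segs.start < region.end)
                & (segs.end > region.start)
            ]
            if sub.empty:
                continue
            overlap = np.minimum(sub.end, region.end) - np.maximum(sub.start, region.start)
            weights = sub.n_probes * overlap / (sub.end - sub.start)
            values.loc[sample, name] = float(np.average(sub.log2_ratio, weights=weights))
            labels.loc[sample, name] = max(sub.annotation, key=lambda a: _LABEL_RANK.get(a, -1))
    return values, labels


def cooccurrence_test(flags_a, flags_b) -> dict:
    """Fisher's exact test for co-occurrence of two boolean lesions.

    Returns the 2x2 table, the odds ratio (Haldane-corrected when a cell
    is zero) and the two-sided exact hypergeometric p-value.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if len(a) != len(b) or len(a) == 0:
        raise ValidationError("flag vectors must be non-empty and equal length")
    table = np.array(
        [[np.sum(a & b), np.sum(a & ~b)], [np.sum(~a & b), np.sum(~a & ~b)]], dtype=int
    )
    degenerate = a.all() or (~a).all() or b.all() or (~b).all()
    if degenerate:
        warnings.warn("degenerate margins in co-occurrence test; p = 1", stacklevel=2)
        p = 1.0
    else:
        _, p = fisher_exact(table, alternative="two-sided")
    t = table.astype(float)
    if (table == 0).any():
        t = t + 0.5
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {"table": table, "odds_ratio": float(odds_ratio), "p_value": float(p)}


def cooccurrence_matrix(flags: pd.DataFrame) -> pd.DataFrame:
    """All pairwise co-occurrence tests over the 8 arm flags, BH-adjusted."""
    rows = []
    for name_a, name_b in itertools.combinations(FLAG_NAMES, 2):
        res = cooccurrence_test(flags[name_a], flags[name_b])
        rows.append(
            {
                "flag_a": name_a,
                "flag_b": name_b,
                "n_both": int(res["table"][0, 0]),
                "odds_ratio": res["odds_ratio"],
                "p_value": res["p_value"],
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out.p_value, method="fdr_bh")[1]
    return out


def qc_partition(
    cohort_segments: pd.DataFrame,
    arms: ArmTable,
    near_silent_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Partition samples into retained / silent / near-silent QC classes.

    Silent profiles carry no aberrant segment at all; near-silent ones
    carry aberrations totalling less than ``near_silent_bp`` of genome.
    Both suggest normal-cell contamination and were excluded from the
    study cohort.
    """
    rows = []
    for sample, segs in cohort_segments.groupby("sample_id", sort=False):
        aberrant = segs[segs.annotation.isin(GAIN_CLASS | LOSS_CLASS)]
        if aberrant.empty:
            qc = "silent"
        elif (aberrant.end - aberrant.start).sum() < near_silent_bp:
            qc = "near_silent"
        else:
            qc = "retained"
        rows.append({"sample_id": sample, "qc_class": qc})
    return pd.DataFrame(rows)


def cohort_summary(flags: pd.DataFrame, annotations: pd.DataFrame | None = None) -> dict:
    """Cohort-level fractions: segmental presence (two definitions),
    per-arm flag frequencies, and MYCN-status cross-tabs when available.

    The segmental fraction is reported both ways the statistic can be
    read: counting a sample when any arm carries a qualifying
    aberration (``fraction_any_segmental``) and counting only the eight
    recurrent arms (``fraction_segmental_8_arms``).
    """
    if flags.empty:
        raise ValidationError("empty flag table")
    n = len(flags)
    summary = {
        "n_samples": n,
        "fraction_any_segmental": float(flags.any_segmental.mean()),
        "fraction_segmental_8_arms": float(flags[FLAG_NAMES].any(axis=1).mean()),
        "flag_frequencies": {name: float(flags[name].mean()) for name in FLAG_NAMES},
        "profile_class_counts": flags.profile_class.value_counts().to_dict(),
    }
    if annotations is not None and "mycn_status" in annotations.columns:
        merged = flags.merge(annotations[["sample_id", "mycn_status"]], on="sample_id")
        summary["mycn_crosstab"] = {
            name: merged.groupby("mycn_status")[name].mean().to_dict() for name in FLAG_NAMES
        }
    return summary


def write_bedgraph(frequency: pd.DataFrame, path, column: str = "gain_fraction") -> None:
    out = frequency[["chrom", "start", "end", column]]
    out.to_csv(path, sep="\t", index=False, header=False)
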