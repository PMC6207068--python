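"""Platform-specific cutoffs, cutoff calibration, and per-segment calling.

Array platforms differ sharply in log2-ratio dynamic range: two-color
aCGH arrays (Agilent, NimbleGen) spread further from zero than SNP
arrays (Affymetrix, Illumina), and Illumina compresses amplifications
most. Gains and losses are therefore called with platform-specific
cutoffs (+0.15/-0.25 for SNP arrays, +0.2/-0.3 for aCGH arrays),
amplifications with cutoffs chosen to separate MYCN-amplified from
nonamplified samples per platform (1.5 Affymetrix/NimbleGen, 2 Agilent,
0.7 Illumina), and homozygous deletions below log2 -2 on every platform.

Two calibration routines recover cutoffs from data: a probe-count
weighted 3-component Gaussian mixture of segment means whose
density-intersection points give the gain/loss cutoffs, and an
exhaustive accuracy scan against FISH/qPCR MYCN labels for the
amplification cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import CallingError
from .genome import GeneTable

logger = logging.getLogger(__name__)

FAMILIES = ("affymetrix_snp", "illumina_snp", "agilent_acgh", "nimblegen_acgh")

CALL_LABELS = ("homozygous_deletion", "loss", "normal", "gain", "amplification")

GAIN_CLASS = {"gain", "amplification"}
LOSS_CLASS = {"loss", "homozygous_deletion"}


@dataclass(frozen=True)
class PlatformModel:
    """Calling cutoffs plus simulation parameters for one array family.

    ``noise_sd`` and ``amp_center`` are simulation-side descriptors of
    the platform (probe noise and the typical log2 of a true
    amplification); they do not affect calling.
    """

    family: str
    gain_cutoff: float
    loss_cutoff: float
    amp_cutoff: float
    homdel_cutoff: float = -2.0
    noise_sd: float = 0.15
    amp_center: float = 2.0

    def __post_init__(self):
        if not (self.loss_cutoff < 0 < self.gain_cutoff < self.amp_cutoff):
            raise CallingError("cutoffs must satisfy loss < 0 < gain < amp")
        if not self.homdel_cutoff < self.loss_cutoff:
            raise CallingError("homozygous-deletion cutoff must lie below the loss cutoff")


_DEFAULTS = {
    "affymetrix_snp": PlatformModel("affymetrix_snp", 0.15, -0.25, 1.5, noise_sd=0.15, amp_center=2.0),
    "illumina_snp": PlatformModel("illumina_snp", 0.15, -0.25, 0.7, noise_sd=0.10, amp_center=1.0),
    "agilent_acgh": PlatformModel("agilent_acgh", 0.20, -0.30, 2.0, noise_sd=0.20, amp_center=3.0),
    "nimblegen_acgh": PlatformModel("nimblegen_acgh", 0.20, -0.30, 1.5, noise_sd=0.18, amp_center=2.0),
}


def default_platform_model(family: str) -> PlatformModel:
    """The published default cutoffs for one of the four array families."""
    try:
        return _DEFAULTS[family]
    except KeyError:
        raise CallingError(f"unknown platform family {family!r}; expected one of {FAMILIES}") from None


def call_segment(log2: float, model: PlatformModel) -> str:
    """Call one segment mean. Precedence: homdel > loss, amp > gain.

    Gain/loss/amplification cutoffs are inclusive; homozygous deletion
    is strict (log2 strictly below -2).
    """
    if not np.isfinite(log2):
        raise CallingError(f"non-finite segment value {log2!r}")
    if log2 < model.homdel_cutoff:
        return "homozygous_deletion"
    if log2 <= model.loss_cutoff:
        return "loss"
    if log2 >= model.amp_cutoff:
        return "amplification"
    if log2 >= model.gain_cutoff:
        return "gain"
    return "normal"


def call_table(segments: pd.DataFrame, model: PlatformModel) -> pd.DataFrame:
    """Fill the annotation column of a segment table."""
    out = segments.copy()
    out["annotation"] = [call_segment(v, model) for v in out.log2_ratio]
    return out


# --- gain/loss calibration: weighted 3-component 1-D Gaussian mixture ------


def _weighted_gmm_1d(x, w, n_components=3, tol=1e-8, max_iter=500):
    """EM for a 1-D Gaussian mixture with per-observation weights.

    Initialized from the 10th/50th/90th weighted percentiles. Returns
    (means, sds, mixing weights, converged) with components sorted by
    mean.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    order = np.argsort(x)
    cw = np.cumsum(w[order]) / w.sum()
    qs = np.interp([0.10, 0.50, 0.90], cw, x[order])
    mu = np.array(qs, dtype=float)
    global_sd = np.sqrt(np.average((x - np.average(x, weights=w)) ** 2, weights=w))
    sd = np.full(n_components, max(global_sd / n_components, 1e-3))
    pi = np.full(n_components, 1.0 / n_components)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        log_dens = norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(pi)[None, :]
        m = log_dens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
        resp = np.exp(log_dens - lse[:, None])
        ll = float((w * lse).sum())
        nk = (w[:, None] * resp).sum(axis=0)
        pi = nk / nk.sum()
        mu = (w[:, None] * resp * x[:, None]).sum(axis=0) / nk
        var = (w[:, None] * resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, 1e-8))
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            converged = True
            break
        prev_ll = ll
    order = np.argsort(mu)
    return mu[order], sd[order], pi[order], converged


def _density_intersection(mu1, sd1, w1, mu2, sd2, w2):
    """Root of w1*N(mu1,sd1) - w2*N(mu2,sd2) strictly between the means."""
    f = lambda x: w1 * norm.pdf(x, mu1, sd1) - w2 * norm.pdf(x, mu2, sd2)
    lo, hi = sorted((mu1, mu2))
    eps = 1e-9 * (1 + hi - lo)
    if f(lo + eps) * f(hi - eps) > 0:
        return None
    return float(brentq(f, lo + eps, hi - eps))


def calibrate_gain_loss(
    log2_values,
    probe_counts,
    model: PlatformModel,
    min_component_weight: float = 0.01,
) -> tuple[float, float]:
    """Fit loss/neutral/gain mixture and place cutoffs at density intersections.

    Falls back to the platform defaults (with a warning) when a mixture
    component is nearly empty or the fit/root-finding fails — e.g. on
    single-state input.
    """
    x = np.asarray(log2_values, dtype=float)
    w = np.asarray(probe_counts, dtype=float)
    if len(x) < 100:
        raise CallingError("gain/loss calibration needs at least 100 segments")
    mu, sd, pi, converged = _weighted_gmm_1d(x, w)
    fallback = (model.gain_cutoff, model.loss_cutoff)
    if not converged or (pi < min_component_weight).any():
        warnings.warn(
            f"{model.family}: mixture degenerate or non-converged (weights {np.round(pi, 4)}); "
            "falling back to default cutoffs",
            stacklevel=2,
        )
        return fallback
    gain = _density_intersection(mu[1], sd[1], pi[1], mu[2], sd[2], pi[2])
    loss = _density_intersection(mu[0], sd[0], pi[0], mu[1], sd[1], pi[1])
    if gain is None or loss is None or not (loss < 0 < gain):
        warnings.warn(f"{model.family}: no usable density intersection; falling back to defaults", stacklevel=2)
        return fallback
    return float(gain), float(loss)


def calibrated_model(log2_values, probe_counts, model: PlatformModel) -> PlatformModel:
    gain, loss = calibrate_gain_loss(log2_values, probe_counts, model)
    return replace(model, gain_cutoff=gain, loss_cutoff=loss)


# --- amplification calibration: accuracy scan vs FISH/qPCR labels ----------


def calibrate_amp_cutoff(log2_values, amplified_labels) -> float:
    """Threshold maximizing agreement with MYCN FISH/qPCR labels.

    Scans the midpoints between consecutive sorted MYCN-locus log2
    values; a sample is predicted amplified when its value is >= the
    threshold. Among equally accurate thresholds the largest is
    returned, so high-level gains fall below the cutoff.
    """
    x = np.asarray(log2_values, dtype=float)
    y = np.asarray(amplified_labels, dtype=bool)
    if y.all() or not y.any():
        raise CallingError("amplification calibration needs both amplified and nonamplified samples")
    xs = np.unique(x)
    candidates = (xs[:-1] + xs[1:]) / 2.0
    best_t, best_acc = None, -1.0
    for t in candidates:
        acc = float(((x >= t) == y).mean())
        if acc > best_acc or (acc == best_acc and t > best_t):
            best_t, best_acc = float(t), acc
    return best_t


# --- MYCN status from called segments ---------------------------------------


def mycn_call(
    sample_segments: pd.DataFrame,
    model: PlatformModel,
    genes: GeneTable | None = None,
) -> str:
    """'amplified' | 'nonamplified' | 'unknown' from segments over the MYCN locus."""
    genes = genes or GeneTable.hg19()
    chrom, start, end = genes.interval("MYCN")
    seg = sample_segments[sample_segments.chrom.astype(str) == chrom]
    overlapping = seg[(seg.start < end) & (seg.end > start)]
    if overlapping.empty:
        return "unknown"
    return "amplified" if (overlapping.log2_ratio >= model.amp_cutoff).any() else "nonamplified"


def mycn_concordance(segments: pd.DataFrame, annotations: pd.DataFrame, genes: GeneTable | None = None) -> pd.DataFrame:
    """Per-platform fraction of samples whose MYCN call matches FISH/qPCR status.

    Samples with unknown annotated status or without MYCN coverage are
    excluded from the fraction and counted separately.
    """
    genes = genes or GeneTable.hg19()
    rows = []
    for platform, ann in annotations.groupby("platform"):
        model = default_platform_model(platform)
        known = ann[ann.mycn_status.isin(["amplified", "nonamplified"])]
        n_match = n_eval = n_unknown = 0
        for row in known.itertuples():
            sample_segs = segments[segments.sample_id == row.sample_id]
            call = mycn_call(sample_segs, model, genes)
            if call == "unknown":
                n_unknown += 1
                continue
            n_eval += 1
            n_match += int(call == row.mycn_status)
        rows.append(
            {
                "platform": platform,
                "n_evaluated": n_eval,
                "n_no_coverage": n_unknown,
                "concordance": n_match / n_eval if n_eval else np.nan,
            }
        )
    return pd.DataFrame(rows)
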