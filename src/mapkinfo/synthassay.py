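"""Synthetic single-cell fluorescence assay with known ground truth.

Emulates a microscopy dose-response experiment on a two-channel reporter
strain: each cell's true reporter signal is a sigmoidal function of dose
times a median-1 log-normal cell factor; the observed channel-1 intensity
adds autofluorescence and a linear bleed-through from the channel-2
(constitutive marker) signal.  The module also implements the standard
reductions applied to such data: percentile trimming per field of view,
autofluorescence/bleed-through correction calibrated on single-colour
control populations, sigmoidal EC50 fitting, and twofold induced/repressed
classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SyntheticAssayConfig",
    "CorrectionModel",
    "SigmoidFit",
    "generate_population",
    "generate_control_population",
    "trim_percentiles",
    "estimate_correction",
    "correct_fluorescence",
    "fit_sigmoid_ec50",
    "classify_induction",
    "hill",
]

TABLE_COLUMNS = ("dose_nM", "field_of_view", "time_point", "cell_id",
                 "ch1_raw", "ch2_raw", "ch1_corrected")


def hill(theta, basal, amplitude, ec50, slope):
    """Sigmoidal dose response y = basal + amplitude * theta^h/(theta^h + EC50^h)."""
    theta = np.asarray(theta, dtype=float)
    th = np.power(theta, slope)
    return basal + amplitude * th / (th + ec50 ** slope)


@dataclass
class SyntheticAssayConfig:
    """Generator settings for one synthetic microscopy experiment.

    The mean dose response is ``hill(dose, basal, amplitude, ec50, slope)``;
    per-cell variability is a median-1 log-normal factor with CV ``cv_cell``.
    Channel 2 carries a constitutive marker (mean ``ch2_mean``, CV
    ``ch2_cv``); ``bleed21`` of the channel-2 signal leaks into channel 1.
    """

    doses: Sequence[float] = field(default_factory=lambda: list(1e-4 * 3.0 ** np.arange(15)))
    n_cells: int = 300
    basal: float = 20.0
    amplitude: float = 400.0
    ec50: float = 4.0
    slope: float = 1.0
    cv_cell: float = 0.25
    af1_mean: float = 50.0
    af1_sd: float = 5.0
    af2_mean: float = 30.0
    af2_sd: float = 3.0
    bleed21: float = 0.05
    ch2_mean: float = 500.0
    ch2_cv: float = 0.3
    cells_per_fov: int = 100
    time_point: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be > 0")
        if min(self.cv_cell, self.ch2_cv, self.af1_sd, self.af2_sd) < 0:
            raise ValueError("spreads must be >= 0")
        if not (0 <= self.bleed21 < 1):
            raise ValueError("bleed-through must lie in [0, 1)")
        if self.n_cells < 2:
            raise ValueError("need >= 2 cells per dose")


def _ln_factors(rng, cv, n):
    # mean-1 log-normal so the population mean equals the configured sigmoid
    if cv == 0:
        return np.ones(n)
    s = np.sqrt(np.log1p(cv * cv))
    return np.exp(s * rng.standard_normal(n) - 0.5 * s * s)


def generate_population(
    config: SyntheticAssayConfig,
    amplitude: Optional[float] = None,
    ch2_present: bool = True,
    ch1_present: bool = True,
) -> pd.DataFrame:
    """Simulate raw two-channel intensities for every (dose, cell).

    Returns a SingleCellTable frame with columns
    (dose_nM, field_of_view, time_point, cell_id, ch1_raw, ch2_raw,
    ch1_corrected); the corrected column starts as NaN until
    :func:`correct_fluorescence` fills it.
    """
    config.validate()
    amp = config.amplitude if amplitude is None else amplitude
    rng = np.random.default_rng(config.seed)
    frames = []
    for dose in config.doses:
        n = config.n_cells
        signal1 = (hill(dose, config.basal, amp, config.ec50, config.slope)
                   * _ln_factors(rng, config.cv_cell, n)) if ch1_present else np.zeros(n)
        signal2 = (config.ch2_mean * _ln_factors(rng, config.ch2_cv, n)) if ch2_present else np.zeros(n)
        af1 = config.af1_mean + config.af1_sd * rng.standard_normal(n)
        af2 = config.af2_mean + config.af2_sd * rng.standard_normal(n)
        ch1 = np.maximum(signal1 + af1 + config.bleed21 * signal2, 0.0)
        ch2 = np.maximum(signal2 + af2, 0.0)
        frames.append(pd.DataFrame({
            "dose_nM": float(dose),
            "field_of_view": np.arange(n) // config.cells_per_fov,
            "time_point": config.time_point,
            "cell_id": np.arange(n),
            "ch1_raw": ch1,
            "ch2_raw": ch2,
            "ch1_corrected": np.nan,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_control_population(config: SyntheticAssayConfig, which: str) -> pd.DataFrame:
    """Single-colour control strains used to calibrate the correction.

    ``gfp_only``: no channel-2 marker (channel 2 shows pure autofluorescence).
    ``mcherry_only``: no reporter signal in channel 1, so channel 1 shows
    autofluorescence plus bleed-through only.  Controls are generated at a
    single dose (dose is irrelevant without the respective fluorophore).
    """
    offsets = {"gfp_only": 1001, "mcherry_only": 2002}
    if which not in offsets:
        raise ValueError("which must be 'gfp_only' or 'mcherry_only'")
    cfg = SyntheticAssayConfig(**{**config.__dict__, "doses": [config.doses[0]],
                                  "seed": config.seed + offsets[which]})
    if which == "gfp_only":
        return generate_population(cfg, ch2_present=False)
    return generate_population(cfg, amplitude=0.0, ch1_present=False)


def trim_percentiles(
    table: pd.DataFrame,
    lower: float = 3.0,
    upper: float = 3.0,
    group_cols: Tuple[str, ...] = ("field_of_view", "time_point"),
    channels: Tuple[str, ...] = ("ch1_raw", "ch2_raw"),
) -> pd.DataFrame:
    """Drop cells outside the [lower, 100-upper] percentiles in either channel.

    Percentiles are computed per group (field of view x time point) with
    linear interpolation; cells exactly at a cut survive, so an all-ties
    group loses nothing.  Empty groups are dropped with a warning.
    """
    if lower < 0 or upper < 0 or lower + upper >= 100:
        raise ValueError("invalid percentile bounds")
    kept = []
    for key, grp in table.groupby(list(group_cols)):
        if len(grp) == 0:  # pragma: no cover
            warnings.warn(f"empty group {key} dropped")
            continue
        mask = np.ones(len(grp), dtype=bool)
        for ch in channels:
            x = grp[ch].to_numpy()
            lo, hi = np.percentile(x, [lower, 100.0 - upper])
            mask &= (x >= lo) & (x <= hi)
        kept.append(grp[mask])
    return pd.concat(kept, ignore_index=True)


@dataclass
class CorrectionModel:
    """Autofluorescence means and channel-2 -> channel-1 bleed coefficient."""

    af1_mean: float
    af2_mean: float
    bleed21: float


def estimate_correction(gfp_only: pd.DataFrame, mcherry_only: pd.DataFrame) -> CorrectionModel:
    """Calibrate correction constants from single-colour control populations.

    Channel-2 autofluorescence is the mean channel-2 intensity of the
    GFP-only strain; channel-1 autofluorescence and the bleed coefficient are
    the intercept and slope of regressing channel 1 on (channel 2 - af2) in
    the mCherry-only strain, whose channel 1 contains no reporter signal.
    """
    af2 = float(gfp_only["ch2_raw"].mean())
    x = mcherry_only["ch2_raw"].to_numpy() - af2
    y = mcherry_only["ch1_raw"].to_numpy()
    bleed, af1 = np.polyfit(x, y, 1)
    return CorrectionModel(af1_mean=float(af1), af2_mean=af2, bleed21=float(bleed))


def correct_fluorescence(
    table: pd.DataFrame,
    af1_mean: float,
    af2_mean: float,
    bleed21: float,
) -> pd.DataFrame:
    """Fill ``ch1_corrected = ch1_raw - af1 - bleed21*(ch2_raw - af2)``.

    Corrected values may dip slightly below zero within noise; a negative
    bleed coefficient is rejected as unphysical.
    """
    if bleed21 < 0:
        raise ValueError("bleed-through coefficient must be >= 0")
    out = table.copy()
    out["ch1_corrected"] = (out["ch1_raw"] - af1_mean
                            - bleed21 * (out["ch2_raw"] - af2_mean))
    return out


@dataclass
class SigmoidFit:
    """Least-squares Hill fit of a dose-response curve with diagnostics."""

    basal: float
    amplitude: float
    ec50: float
    slope: float
    converged: bool
    ec50_identifiable: bool
    residual_rms: float
    cov: Optional[np.ndarray] = None


def fit_sigmoid_ec50(doses: Sequence[float], responses: Sequence[float]) -> SigmoidFit:
    """Fit y = basal + amplitude*theta^h/(theta^h + EC50^h) by least squares.

    EC50 is fitted on a log10 scale with multiplicative-error weighting
    (residuals scaled by the response magnitude).  Requires >= 4 doses
    spanning the transition; flat data are flagged as EC50-unidentifiable
    rather than raising.
    """
    th = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(th) < 4:
        raise ValueError("need >= 4 dose points")
    if np.any(th <= 0):
        raise ValueError("doses must be positive")
    span = y.max() - y.min()
    scale = max(np.abs(y).max(), 1e-12)

    def model(t, basal, amplitude, log_ec50, h):
        return hill(t, basal, amplitude, 10.0 ** log_ec50, h)

    p0 = (y.min(), span if span > 0 else scale * 0.1,
          float(np.log10(np.sqrt(th.min() * th.max()))), 1.0)
    w = np.maximum(np.abs(y), 0.05 * scale)  # multiplicative-error weighting
    try:
        popt, pcov = curve_fit(model, th, y, p0=p0, sigma=w, maxfev=20000,
                               bounds=([-np.inf, -np.inf, np.log10(th.min()) - 3, 0.05],
                                       [np.inf, np.inf, np.log10(th.max()) + 3, 10.0]))
        converged = True
    except RuntimeError:
        resid = y - np.full_like(y, y.mean())
        return SigmoidFit(basal=float(y.mean()), amplitude=0.0, ec50=np.nan,
                          slope=np.nan, converged=False, ec50_identifiable=False,
                          residual_rms=float(np.sqrt(np.mean(resid ** 2))))
    basal, amplitude, log_ec50, h = popt
    resid = y - model(th, *popt)
    # EC50 means nothing if the curve is flat or its uncertainty spans decades
    log_ec50_sd = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    identifiable = bool(abs(amplitude) > 0.02 * scale and log_ec50_sd < 1.0)
    return SigmoidFit(
        basal=float(basal), amplitude=float(amplitude), ec50=float(10.0 ** log_ec50),
        slope=float(h), converged=converged, ec50_identifiable=identifiable,
        residual_rms=float(np.sqrt(np.mean(resid ** 2))), cov=pcov,
    )


def classify_induction(treated: float, untreated: float) -> str:
    """Twofold-change call: 'induced' (ratio >= 2), 'repressed' (<= 0.5),
    else 'unchanged'.  Non-positive baselines are undefined."""
    if untreated <= 0 or treated <= 0:
        raise ValueError("expression values must be > 0 for a fold-change call")
    ratio = treated / untreated
    if ratio >= 2.0:
        return "induced"
    if ratio <= 0.5:
        return "repressed"
    return "unchanged"
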