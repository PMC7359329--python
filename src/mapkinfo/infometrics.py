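"""Noise and information measures of single-cell dose-response channels.

The channel input is the pheromone dose on a log10 scale (the grid is
geometric); the output is a single-cell reporter or Fus3-PP level.  Fisher
information is computed under a Gaussian output assumption by numerical
quadrature of the squared score over the output distribution (which for a
Gaussian equals the closed form (mu'^2 + 2 sigma'^2)/sigma^2); mean and SD
dose dependences are smoothed with a cubic smoothing spline (GCV-selected
penalty) to obtain the derivatives.  Local mutual information is estimated in
a sliding window of three neighbouring inputs with equal prior weight, by
binning the pooled outputs into equal-width bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.interpolate import PchipInterpolator, make_smoothing_spline

__all__ = [
    "DoseResponseTable",
    "SmoothedChannel",
    "InfoProfile",
    "noise_cv",
    "smooth_dose_response",
    "fisher_information",
    "local_mutual_information",
    "aggregate_information",
    "information_profile",
    "project_noise",
]

LN10 = np.log(10.0)


class DoseResponseTable:
    """Doses with per-cell output samples; mean, SD and CV per dose.

    Backed by a long DataFrame with columns (dose_nM, cell_id, output).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"dose_nM", "cell_id", "output"}
        if not required <= set(frame.columns):
            raise ValueError(f"table needs columns {sorted(required)}")
        frame = frame.sort_values(["dose_nM", "cell_id"]).reset_index(drop=True)
        doses = np.asarray(sorted(frame["dose_nM"].unique()), dtype=float)
        if np.any(doses <= 0):
            raise ValueError("doses must be positive (log-dose coordinate)")
        counts = frame.groupby("dose_nM").size()
        if counts.min() < 2:
            raise ValueError("need >= 2 samples per dose for an SD estimate")
        self.frame = frame
        self.doses = doses

    @classmethod
    def from_samples(cls, doses: Sequence[float], samples: Sequence[Sequence[float]]) -> "DoseResponseTable":
        rows = []
        for d, xs in zip(doses, samples):
            for i, x in enumerate(np.asarray(xs, dtype=float)):
                rows.append((float(d), i, x))
        return cls(pd.DataFrame(rows, columns=["dose_nM", "cell_id", "output"]))

    @classmethod
    def read_tsv(cls, path) -> "DoseResponseTable":
        df = pd.read_csv(path, sep="\t")
        if "output" not in df.columns and "ch1_corrected" in df.columns:
            df = df.rename(columns={"ch1_corrected": "output"})
        return cls(df[["dose_nM", "cell_id", "output"]])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    # -- per-dose statistics -------------------------------------------
    def samples(self, dose: float) -> np.ndarray:
        return self.frame.loc[self.frame["dose_nM"] == dose, "output"].to_numpy()

    @property
    def log10_doses(self) -> np.ndarray:
        return np.log10(self.doses)

    def mean(self) -> np.ndarray:
        return self.frame.groupby("dose_nM")["output"].mean().to_numpy()

    def sd(self) -> np.ndarray:
        return self.frame.groupby("dose_nM")["output"].std(ddof=1).to_numpy()

    def cv(self) -> np.ndarray:
        return noise_cv(self)


def noise_cv(table_or_samples) -> np.ndarray:
    """Coefficient of variation (n-1 SD over mean) per dose.

    Doses with non-positive mean yield NaN (flagged with a warning): total
    noise is undefined there.
    """
    if isinstance(table_or_samples, DoseResponseTable):
        mu, sd = table_or_samples.mean(), table_or_samples.sd()
    else:
        arr = np.asarray(table_or_samples, dtype=float)
        mu = np.atleast_1d(arr.mean(axis=-1))
        sd = np.atleast_1d(arr.std(axis=-1, ddof=1))
    bad = mu <= 0
    if np.any(bad):
        warnings.warn("CV undefined at doses with non-positive mean output")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, sd / np.where(bad, np.nan, mu))
    return out


@dataclass
class SmoothedChannel:
    """Smoothed mean/SD dose dependences and their log-dose derivatives."""

    u: np.ndarray                      # log10 dose grid of the source table
    mu: Callable[[np.ndarray], np.ndarray]
    sigma: Callable[[np.ndarray], np.ndarray]
    dmu: Callable[[np.ndarray], np.ndarray]
    dsigma: Callable[[np.ndarray], np.ndarray]
    sigma_floor: float = 0.0

    def arrays(self, u: Optional[np.ndarray] = None):
        u = self.u if u is None else np.asarray(u, dtype=float)
        sig = np.maximum(self.sigma(u), self.sigma_floor)
        return u, self.mu(u), sig, self.dmu(u), self.dsigma(u)

    def fisher(self, u: Optional[np.ndarray] = None) -> np.ndarray:
        u, mu, sig, dmu, dsig = self.arrays(u)
        return np.array([fisher_information(m, s, dm, ds)
                         for m, s, dm, ds in zip(mu, sig, dmu, dsig)])


def smooth_dose_response(
    table: DoseResponseTable,
    lam: Optional[float] = None,
) -> SmoothedChannel:
    """Cubic smoothing splines of mean and SD versus u = log10(dose).

    ``lam=None`` selects the penalty by generalized cross-validation.  The SD
    spline is floor-clamped at a small positive fraction of the response range
    so downstream Fisher calculations never divide by zero.
    """
    u = table.log10_doses
    if len(u) < 4:
        raise ValueError("need >= 4 doses for cubic smoothing")
    if np.any(np.diff(u) <= 0):
        raise ValueError("dose grid must be strictly increasing")
    mu_spl = make_smoothing_spline(u, table.mean(), lam=lam)
    sd_spl = make_smoothing_spline(u, table.sd(), lam=lam)
    scale = float(np.max(np.abs(table.mean()))) or 1.0
    return SmoothedChannel(
        u=u,
        mu=mu_spl, sigma=sd_spl,
        dmu=mu_spl.derivative(), dsigma=sd_spl.derivative(),
        sigma_floor=1e-6 * scale,
    )


_GH_NODES, _GH_WEIGHTS = hermegauss(21)  # probabilists' Hermite: weight e^{-z^2/2}
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def fisher_information(mu: float, sigma: float, dmu: float, dsigma: float) -> float:
    """Fisher information of a Gaussian output channel at one input.

    Numerical quadrature of E[(d/du log N(x; mu(u), sigma(u)))^2] over the
    output distribution (Gauss-Hermite; exact for the degree-4 integrand, so
    it matches the closed form (mu'^2 + 2 sigma'^2)/sigma^2 to rounding).
    Units: nats per (log10 dose)^2 when u is log10 dose.
    """
    if sigma <= 0:
        if dmu != 0 or dsigma != 0:
            raise ZeroDivisionError(
                "sigma -> 0 with non-zero derivative: infinite-information pathology")
        return 0.0
    z = _GH_NODES
    score = -dsigma / sigma + z * (dmu / sigma) + z * z * (dsigma / sigma)
    return float(np.sum(_GH_WEIGHTS * score * score))


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]  # 0 log 0 = 0
    return float(-np.sum(p * np.log2(p)))


def local_mutual_information(
    table: DoseResponseTable,
    window: int = 3,
    n_bins: int = 20,
) -> np.ndarray:
    """Local MI (bits) per window centre; NaN at grid edges.

    For each run of ``window`` consecutive inputs with uniform prior, outputs
    are pooled to set common equal-width bin edges; I = H(pooled) - mean of
    per-input entropies.  Bounded by log2(window).
    """
    if window < 2:
        raise ValueError("window must span >= 2 inputs")
    doses = table.doses
    half = window // 2
    out = np.full(len(doses), np.nan)
    for c in range(half, len(doses) - (window - 1 - half)):
        block = [table.samples(doses[c - half + j]) for j in range(window)]
        pooled = np.concatenate(block)
        lo, hi = pooled.min(), pooled.max()
        if hi <= lo:
            out[c] = 0.0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        cond = []
        for xs in block:
            h, _ = np.histogram(xs, bins=edges)
            cond.append(h / len(xs))
        p_pool = np.mean(cond, axis=0)  # equal prior weight per input
        mi = _entropy_bits(p_pool) - float(np.mean([_entropy_bits(p) for p in cond]))
        out[c] = max(mi, 0.0)
    return out


@dataclass
class InfoProfile:
    """Per-input information measures mapped to doses and output levels."""

    doses: np.ndarray
    u: np.ndarray
    mu: np.ndarray                 # smoothed mean output per input
    sigma: np.ndarray
    fisher: Optional[np.ndarray] = None      # nats / (log10 dose)^2
    mi: Optional[np.ndarray] = None          # bits; NaN at window edges
    meta: dict = field(default_factory=dict)

    def aggregated_fisher(self) -> float:
        return aggregate_information(self.fisher, self.u, mode="aggregated")

    def total_fisher(self) -> float:
        return aggregate_information(self.fisher, self.u, mode="total")

    def total_mi(self) -> float:
        return aggregate_information(self.mi, self.u, mode="total")

    def to_frame(self) -> pd.DataFrame:
        d = {"dose_nM": self.doses, "log10_dose": self.u,
             "mean_output": self.mu, "sd_output": self.sigma}
        if self.fisher is not None:
            d["fisher"] = self.fisher
        if self.mi is not None:
            d["mi_bits"] = self.mi
        return pd.DataFrame(d)


def information_profile(
    table: DoseResponseTable,
    metrics: Sequence[str] = ("fisher", "mi"),
    window: int = 3,
    n_bins: int = 20,
    lam: Optional[float] = None,
) -> InfoProfile:
    """Smooth the channel and evaluate the requested per-input measures."""
    chan = smooth_dose_response(table, lam=lam)
    u, mu, sig, _, _ = chan.arrays()
    prof = InfoProfile(doses=table.doses, u=u, mu=mu, sigma=sig,
                       meta={"window": window, "n_bins": n_bins})
    if "fisher" in metrics:
        prof.fisher = chan.fisher()
    if "mi" in metrics:
        prof.mi = local_mutual_information(table, window=window, n_bins=n_bins)
    return prof


def aggregate_information(
    values: np.ndarray,
    u: Optional[np.ndarray] = None,
    mode: str = "aggregated",
    output_levels: Optional[np.ndarray] = None,
    output_bins: int = 0,
):
    """Reduce a per-input profile to a scalar (or output-level partition).

    mode="aggregated": trapezoid integral over the log-dose grid ``u``.
    mode="total": unweighted mean over inputs (NaN-aware, so MI edge points
    are skipped).  With ``output_bins`` > 0 and ``output_levels`` given, the
    aggregated integral is split by equal-width bins of the output level.
    """
    values = np.asarray(values, dtype=float)
    if mode == "total":
        return float(np.nanmean(values))
    if mode != "aggregated":
        raise ValueError("mode must be 'aggregated' or 'total'")
    if u is None:
        raise ValueError("aggregated mode needs the log-dose grid u")
    u = np.asarray(u, dtype=float)
    good = ~np.isnan(values)
    total = float(np.trapezoid(values[good], u[good]))
    if output_bins <= 0:
        return total
    # per-point trapezoid weights, assigned to output-level bins
    ug, vg = u[good], values[good]
    w = np.zeros_like(ug)
    w[:-1] += 0.5 * np.diff(ug)
    w[1:] += 0.5 * np.diff(ug)
    contrib = vg * w
    lv = np.asarray(output_levels, dtype=float)[good]
    edges = np.linspace(lv.min(), lv.max(), output_bins + 1)
    idx = np.clip(np.digitize(lv, edges) - 1, 0, output_bins - 1)
    part = np.bincount(idx, weights=contrib, minlength=output_bins)
    return total, pd.Series(part, index=pd.IntervalIndex.from_breaks(edges))


def project_noise(
    response_from: DoseResponseTable,
    noise_from: DoseResponseTable,
    n_fine: int = 400,
    lam: Optional[float] = None,
) -> SmoothedChannel:
    """Hybrid channel: mean response of one table, noise of another.

    sigma is taken from ``noise_from`` at matched *output level* (sigma as a
    function of the smoothed mean, interpolated on a fine log-dose grid) and
    evaluated at the response table's own mean; derivatives follow by the
    chain rule.  Used to decompose Fisher-information differences into
    output-range versus noise contributions.  Doses whose mean falls outside
    the donor's output range are dropped (extrapolation refused); no overlap
    at all is an error.
    """
    resp = smooth_dose_response(response_from, lam=lam)
    donor = smooth_dose_response(noise_from, lam=lam)

    uf = np.linspace(donor.u[0], donor.u[-1], n_fine)
    m_d = donor.mu(uf)
    if not (np.all(np.diff(m_d) > 0) or np.all(np.diff(m_d) < 0)):
        # keep the longest monotone run around the dynamic range
        sign = np.sign(np.median(np.diff(m_d)))
        keep = np.concatenate([[True], np.sign(np.diff(m_d)) == sign])
        uf, m_d = uf[keep], m_d[keep]
    order = np.argsort(m_d)
    u_of_m = PchipInterpolator(m_d[order], uf[order])  # inverse dose of an output level

    m_r = resp.mu(resp.u)
    lo, hi = m_d.min(), m_d.max()
    inside = (m_r >= lo) & (m_r <= hi)
    if not inside.any():
        raise ValueError("output ranges of the two tables do not overlap; "
                         "noise projection refused")
    if not inside.all():
        warnings.warn(f"dropping {int((~inside).sum())} dose(s) outside the "
                      "donor output range (no extrapolation)")
    u_kept = resp.u[inside]

    def sigma(u):
        m = np.clip(resp.mu(u), lo, hi)
        return donor.sigma(u_of_m(m))

    def dsigma(u):
        m = np.clip(resp.mu(u), lo, hi)
        ud = u_of_m(m)
        return donor.dsigma(ud) * u_of_m.derivative()(m) * resp.dmu(u)

    return SmoothedChannel(
        u=u_kept, mu=resp.mu, sigma=sigma, dmu=resp.dmu, dsigma=dsigma,
        sigma_floor=donor.sigma_floor,
    )
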