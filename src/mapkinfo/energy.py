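"""Energy-consumption profiles, the information-per-energy functional, and
sweeps over feedback-promoter affinities.

Efficiency is the prior-weighted integral of Fisher information per unit
energy-dissipation rate over the informative input range,

    efficiency = integral_{theta1}^{theta2} F(theta)/E(theta) P(theta) dtheta,

evaluated here on the log10-dose grid with a trapezoid rule and a prior that
defaults to uniform in log dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cascade import ModelParameters, default_parameters
from .ensemble import EnsembleConfig, EnsembleError, EnsembleResult, run_ensemble
from .infometrics import DoseResponseTable, aggregate_information, information_profile

__all__ = ["EnergyProfile", "SweepResult", "energy_profile", "efficiency", "kd_sweep"]


@dataclass
class EnergyProfile:
    """Per-dose mean hydrolysis rates (molecules-equiv nM/s per cell)."""

    doses: np.ndarray
    e_total: np.ndarray
    e_gtp: np.ndarray
    e_atp: np.ndarray
    rel_output: np.ndarray   # mean Fus3-PP normalized to its per-profile max
    genotype: str = "wt"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_nM": self.doses, "rel_Fpp": self.rel_output,
            "E_total": self.e_total, "E_gtp": self.e_gtp, "E_atp": self.e_atp,
        })


def energy_profile(ensemble: EnsembleResult) -> EnergyProfile:
    """Population-mean energy rates per dose, with the (relative Fus3-PP, E)
    curve used to compare genotypes at matched output."""
    s = ensemble.summary
    mean_fpp = s["mean_Fpp"].to_numpy()
    top = mean_fpp.max()
    return EnergyProfile(
        doses=s["dose_nM"].to_numpy(),
        e_total=s["mean_jtotal"].to_numpy(),
        e_gtp=s["mean_jgtp"].to_numpy(),
        e_atp=s["mean_jatp"].to_numpy(),
        rel_output=mean_fpp / top if top > 0 else mean_fpp,
        genotype=ensemble.config.genotype,
    )


def efficiency(
    fisher: Sequence[float],
    energy: Sequence[float],
    doses: Sequence[float],
    prior: Optional[Sequence[float]] = None,
    theta_range: Optional[Tuple[float, float]] = None,
) -> float:
    """Prior-weighted information per energy over [theta1, theta2].

    ``prior`` is a density over u = log10 dose on the restricted grid; if
    omitted it is uniform there.  It is renormalized to integrate to 1 on the
    restricted range.  Zero or negative energy anywhere in range is rejected.
    """
    F = np.asarray(fisher, dtype=float)
    E = np.asarray(energy, dtype=float)
    th = np.asarray(doses, dtype=float)
    if theta_range is not None:
        lo, hi = theta_range
        keep = (th >= lo) & (th <= hi)
        F, E, th = F[keep], E[keep], th[keep]
    if len(th) < 2:
        raise ValueError("need >= 2 doses inside the integration range")
    if np.any(E <= 0):
        bad = th[E <= 0]
        raise ValueError(f"energy rate must be > 0 on the range; zero at doses {bad}")
    u = np.log10(th)
    P = np.ones_like(u) if prior is None else np.asarray(prior, dtype=float)
    norm = np.trapezoid(P, u)
    if norm <= 0:
        raise ValueError("prior must have positive mass on the range")
    P = P / norm
    return float(np.trapezoid(F / E * P, u))


@dataclass
class SweepResult:
    """Long-format grid of feedback-affinity combinations and their totals."""

    table: pd.DataFrame   # kd_sst2, kd_msg5, total_fisher, aggregated_fisher, mean_energy, efficiency
    kd_sst2_grid: np.ndarray
    kd_msg5_grid: np.ndarray
    output: str
    provenance: dict = field(default_factory=dict)

    def pivot(self, value: str = "efficiency") -> pd.DataFrame:
        """Heat-map layout: rows KD_SST2, columns KD_MSG5."""
        return self.table.pivot(index="kd_sst2", columns="kd_msg5", values=value)

    def corner(self, value: str, sst2: str, msg5: str) -> float:
        """Value at a grid corner; ``sst2``/``msg5`` in {"low", "high"}."""
        ks = self.kd_sst2_grid[0 if sst2 == "low" else -1]
        km = self.kd_msg5_grid[0 if msg5 == "low" else -1]
        row = self.table[(self.table.kd_sst2 == ks) & (self.table.kd_msg5 == km)]
        return float(row[value].iloc[0])


def kd_sweep(
    base: Optional[ModelParameters] = None,
    kd_grid_sst2: Sequence[float] = (8.0,),
    kd_grid_msg5: Sequence[float] = (700.0,),
    config: Optional[EnsembleConfig] = None,
    output: str = "Fpp_end",
    prior: Optional[Sequence[float]] = None,
) -> SweepResult:
    """Run an ensemble per (KD_SST2, KD_MSG5) pair and score each cell of the
    grid by total Fisher information, mean energy rate and efficiency.

    ``output`` selects the channel output ("Fpp_end" for the kinase level,
    "Rep_end" for the transcriptional reporter).  A failing grid cell is
    recorded as NaN, never silently zero.
    """
    if base is None:
        base = default_parameters()
    if config is None:
        config = EnsembleConfig(n_cells=100)
    ks_grid = np.asarray(kd_grid_sst2, dtype=float)
    km_grid = np.asarray(kd_grid_msg5, dtype=float)
    if np.any(ks_grid <= 0) or np.any(km_grid <= 0):
        raise ValueError("KD grids must be positive")
    rows = []
    for ks in ks_grid:
        for km in km_grid:
            p = base.copy()
            p.genes["SST2"].KD = float(ks)
            p.genes["MSG5"].KD = float(km)
            rec = {"kd_sst2": float(ks), "kd_msg5": float(km)}
            try:
                ens = run_ensemble(config, p)
                prof = information_profile(
                    DoseResponseTable(ens.dose_response(output)), metrics=("fisher",))
                eprof = energy_profile(ens)
                rec["total_fisher"] = prof.total_fisher()
                rec["aggregated_fisher"] = prof.aggregated_fisher()
                rec["mean_energy"] = float(np.mean(eprof.e_total))
                rec["efficiency"] = efficiency(prof.fisher, eprof.e_total,
                                               prof.doses, prior=prior)
            except (EnsembleError, ValueError) as exc:
                rec.update(total_fisher=np.nan, aggregated_fisher=np.nan,
                           mean_energy=np.nan, efficiency=np.nan, error=str(exc))
            rows.append(rec)
    return SweepResult(
        table=pd.DataFrame(rows),
        kd_sst2_grid=ks_grid,
        kd_msg5_grid=km_grid,
        output=output,
        provenance={"seed": config.seed, "n_cells": config.n_cells,
                    "dose_grid": list(map(float, np.asarray(config.dose_grid))),
                    "config_hash": config.content_hash()},
    )
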