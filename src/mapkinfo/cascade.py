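"""Deterministic single-cell model of the yeast pheromone MAPK cascade.

The model is a two-step phosphorylation cascade driven by alpha-pheromone:
active receptor/G-protein signal ``A`` activates the MAP kinase Fus3
(``Fpp`` = doubly phosphorylated, active Fus3), which phosphorylates the
transcription factor Ste12 (``Tp`` = active Ste12-P).  Ste12-P drives five
pheromone-responsive promoters: the positive feedbacks *STE2* (receptor) and
*FUS3* (kinase), the negative feedbacks *SST2* (GAP, accelerates upstream
deactivation) and *MSG5* (phosphatase, accelerates Fus3 dephosphorylation),
and the transcriptional reporter *FUS1*.

Energy bookkeeping: every upstream deactivation event hydrolyses one GTP;
every Fus3 activation costs ``natp_fus3`` ATP (two phosphorylations lumped
into one step) and every Ste12 activation costs ``natp_ste12`` ATP.  The
state carries cumulative GTP/ATP counters so that steady signalling shows up
as a futile-cycle dissipation rate.

Concentrations are in nM, time in seconds.
"""

from __future__ import annotations

import copy as _copy
import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import odeint

__all__ = [
    "GENES",
    "GENE_TARGETS",
    "GeneParams",
    "ModelParameters",
    "CascadeState",
    "EnergyFluxes",
    "CellTrajectory",
    "IntegrationError",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "basal_state",
    "steady_state",
    "rhs",
    "simulate_cell",
    "energy_rate_at_endpoint",
    "fus3_steady_state",
    "apply_genotype",
    "GENOTYPES",
]

#: induced genes and the state variable each synthesis rate feeds
GENES = ("STE2", "FUS3", "SST2", "MSG5", "FUS1")
GENE_TARGETS = {
    "STE2": "Rtot",
    "FUS3": "Ftot",
    "SST2": "Sst2",
    "MSG5": "Msg5",
    "FUS1": "Rep",
}

#: state vector layout used by the integrator
STATE_FIELDS = ("A", "Rtot", "Ftot", "Fpp", "Tp", "Sst2", "Msg5", "Rep", "Egtp", "Eatp")


class IntegrationError(RuntimeError):
    """ODE solver failure, annotated with the dose and parameter context."""


@dataclass
class GeneParams:
    """Promoter/synthesis parameters of one Ste12-P-induced gene.

    beta0   basal synthesis rate, nM/s
    beta    maximal induced synthesis rate on top of beta0, nM/s
    KD      Ste12-P concentration at half-maximal promoter occupancy, nM
    n       Hill coefficient (1 = no cooperativity)
    gamma   first-order degradation/dilution rate, 1/s
    """

    beta0: float
    beta: float
    KD: float
    n: float = 1.0
    gamma: float = 5.0e-4

    def validate(self) -> None:
        if self.beta0 < 0 or self.beta < 0:
            raise ValueError("synthesis rates must be non-negative")
        if self.KD <= 0 or self.n <= 0 or self.gamma <= 0:
            raise ValueError("KD, n and gamma must be positive")


@dataclass
class ModelParameters:
    """Full parameter set of the cascade model for one cell.

    ``theta`` is the pheromone dose (nM); ``KD`` of the SST2 and MSG5 promoter
    blocks are the two sweepable feedback-induction sensitivities.
    """

    theta: float
    KR: float
    kact: float
    kgap0: float
    kgap: float
    kf: float
    kd0: float
    kd: float
    kt: float
    ktb: float
    Ttot: float
    kact0: float = 0.0     # dose-independent basal activation rate, 1/s
    natp_fus3: float = 2.0
    natp_ste12: float = 1.0
    genes: Dict[str, GeneParams] = field(default_factory=dict)

    def validate(self) -> None:
        if self.theta < 0:
            raise ValueError("pheromone dose theta must be >= 0")
        for name in ("KR", "kact", "kgap0", "kgap", "kf", "kd0", "kd", "kt", "ktb", "Ttot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")
        if self.natp_fus3 < 0 or self.natp_ste12 < 0:
            raise ValueError("ATP stoichiometries must be >= 0")
        if self.kact0 < 0:
            raise ValueError("basal activation rate kact0 must be >= 0")
        missing = set(GENES) - set(self.genes)
        if missing:
            raise ValueError(f"missing gene parameter blocks: {sorted(missing)}")
        for g in self.genes.values():
            g.validate()

    def copy(self) -> "ModelParameters":
        return _copy.deepcopy(self)

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = _copy.deepcopy(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        genes_raw = d.pop("genes", {})
        genes = {}
        gene_known = {f.name for f in dataclasses.fields(GeneParams)}
        for name, block in genes_raw.items():
            if name not in GENES:
                raise ValueError(f"unknown gene block: {name}")
            bad = set(block) - gene_known
            if bad:
                raise ValueError(f"unknown keys in gene block {name}: {sorted(bad)}")
            genes[name] = GeneParams(**block)
        p = cls(genes=genes, **d)
        p.validate()
        return p


@dataclass
class CascadeState:
    """Snapshot of one cell: concentrations plus cumulative energy counters."""

    A: float
    Rtot: float
    Ftot: float
    Fpp: float
    Ttot: float
    Tp: float
    Sst2: float
    Msg5: float
    Rep: float
    Egtp: float = 0.0
    Eatp: float = 0.0

    def validate(self) -> None:
        for name in ("A", "Rtot", "Ftot", "Fpp", "Ttot", "Tp", "Sst2", "Msg5", "Rep"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration: {name}")
        tol = 1e-9
        if self.Fpp > self.Ftot * (1 + tol) + tol:
            raise ValueError("Fpp exceeds total Fus3")
        if self.Tp > self.Ttot * (1 + tol) + tol:
            raise ValueError("Tp exceeds total Ste12")
        if self.A > self.Rtot * (1 + tol) + tol:
            raise ValueError("A exceeds total receptor")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, y: Sequence[float], Ttot: float) -> "CascadeState":
        d = dict(zip(STATE_FIELDS, map(float, y)))
        return cls(Ttot=Ttot, **d)


@dataclass
class EnergyFluxes:
    """Instantaneous (or window-averaged) hydrolysis rates, molecules-equiv nM/s."""

    jgtp: float
    jatp1: float
    jatp2: float

    @property
    def jatp(self) -> float:
        return self.jatp1 + self.jatp2

    @property
    def jtotal(self) -> float:
        return self.jgtp + self.jatp1 + self.jatp2


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------

def load_parameters(path) -> ModelParameters:
    """Load a ModelParameters YAML file (unknown keys are rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ModelParameters.from_dict(data)


def save_parameters(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def default_parameters() -> ModelParameters:
    """Wild-type calibration (versioned in ``mapkinfo/params/default.yaml``)."""
    ref = importlib.resources.files("mapkinfo").joinpath("params/default.yaml")
    data = yaml.safe_load(ref.read_text())
    return ModelParameters.from_dict(data)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

GENOTYPES = ("wt", "msg5d", "sst2d", "msg5_sensitized")

#: promoter affinity given to MSG5 in the sensitized genotype: same as the
#: sensitive upstream promoters (P_FUS1-style early induction)
SENSITIZED_KD_MSG5 = 8.0


def apply_genotype(base: ModelParameters, genotype: str) -> ModelParameters:
    """Return a parameter set for a genotype.

    ``msg5d``/``sst2d`` delete the gene (no basal or induced synthesis, so the
    species stays at zero if it starts at zero); ``msg5_sensitized`` lowers
    KD_MSG5 to the sensitive-promoter value.
    """
    p = base.copy()
    if genotype == "wt":
        return p
    if genotype == "msg5d":
        p.genes["MSG5"].beta0 = 0.0
        p.genes["MSG5"].beta = 0.0
        return p
    if genotype == "sst2d":
        p.genes["SST2"].beta0 = 0.0
        p.genes["SST2"].beta = 0.0
        return p
    if genotype == "msg5_sensitized":
        p.genes["MSG5"].KD = SENSITIZED_KD_MSG5
        return p
    raise ValueError(f"unknown genotype: {genotype!r} (choose from {GENOTYPES})")


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _pack(params: ModelParameters) -> tuple:
    g = params.genes
    return (
        params.kact * params.theta / (params.theta + params.KR) + params.kact0,
        params.kgap0,
        params.kgap,
        params.kf,
        params.kd0,
        params.kd,
        params.kt,
        params.ktb,
        params.Ttot,
        params.natp_fus3,
        params.natp_ste12,
    ) + tuple(
        (g[name].beta0, g[name].beta, g[name].KD, g[name].n, g[name].gamma)
        for name in GENES
    )


def _rhs(y, t, act, kgap0, kgap, kf, kd0, kd, kt, ktb, Ttot, nf, ns,
         ste2, fus3, sst2, msg5, fus1):
    A, Rtot, Ftot, Fpp, Tp, Sst2, Msg5, Rep, Egtp, Eatp = y
    deact = kgap0 + kgap * Sst2
    dA = act * (Rtot - A) - deact * A
    phos = kf * A * (Ftot - Fpp)
    dFpp = phos - (kd0 + kd * Msg5) * Fpp
    tphos = kt * Fpp * (Ttot - Tp)
    dTp = tphos - ktb * Tp
    tp = Tp if Tp > 0.0 else 0.0

    def induction(block):
        beta0, beta, KD, n, gamma = block
        if n == 1.0:
            occ = tp / (tp + KD)
        else:
            tpn = tp ** n
            occ = tpn / (tpn + KD ** n)
        return beta0 + beta * occ, gamma

    sR, gR = induction(ste2)
    sF, gF = induction(fus3)
    sS, gS = induction(sst2)
    sM, gM = induction(msg5)
    sRep, gRep = induction(fus1)
    return (
        dA,
        sR - gR * Rtot,
        sF - gF * Ftot,
        dFpp,
        dTp,
        sS - gS * Sst2,
        sM - gM * Msg5,
        sRep - gRep * Rep,
        deact * A,
        nf * phos + ns * tphos,
    )


def rhs(state: CascadeState, params: ModelParameters) -> CascadeState:
    """Time derivatives of the cascade state (validated public entry point).

    Rejects negative concentrations and negative doses; the returned
    ``CascadeState`` holds derivative values in each field (``Ttot`` slot is 0
    since total Ste12 is conserved).
    """
    params.validate()
    state.validate()
    dy = _rhs(state.to_vector(), 0.0, *_pack(params))
    d = dict(zip(STATE_FIELDS, dy))
    return CascadeState(Ttot=0.0, **d)


def instantaneous_fluxes(state: CascadeState, params: ModelParameters) -> EnergyFluxes:
    """GTP/ATP hydrolysis rates of the three futile cycles at one instant."""
    jgtp = (params.kgap0 + params.kgap * state.Sst2) * state.A
    jatp1 = params.natp_fus3 * params.kf * state.A * (state.Ftot - state.Fpp)
    jatp2 = params.natp_ste12 * params.kt * state.Fpp * (params.Ttot - state.Tp)
    return EnergyFluxes(jgtp=jgtp, jatp1=jatp1, jatp2=jatp2)


# ---------------------------------------------------------------------------
# initial condition and simulation
# ---------------------------------------------------------------------------

def steady_state(params: ModelParameters, theta: Optional[float] = None) -> CascadeState:
    """Deterministic steady state of the cascade at a given dose.

    The fixed point reduces to a one-dimensional root problem in Tp: a value
    of Tp sets every induced total (X_g = (beta0 + beta*occupancy)/gamma),
    which sets A, then Fpp, then Tp again; the self-consistent Tp is bracketed
    in [0, Ttot] and found with Brent's method.  With no basal activity
    (kact0 = 0) and theta = 0 this collapses to the closed form
    A = Fpp = Tp = 0, X_g = beta0/gamma.
    """
    from scipy.optimize import brentq

    th = params.theta if theta is None else theta
    act = params.kact * th / (th + params.KR) + params.kact0
    g = params.genes

    def levels(Tp):
        X = {}
        for name in GENES:
            b = g[name]
            occ = Tp ** b.n / (Tp ** b.n + b.KD ** b.n) if Tp > 0 else 0.0
            X[name] = (b.beta0 + b.beta * occ) / b.gamma
        deact = params.kgap0 + params.kgap * X["SST2"]
        A = X["STE2"] * act / (act + deact) if act > 0 else 0.0
        drive = params.kf * A
        Fpp = X["FUS3"] * drive / (drive + params.kd0 + params.kd * X["MSG5"])
        Tp_new = params.Ttot * params.kt * Fpp / (params.kt * Fpp + params.ktb)
        return X, A, Fpp, Tp_new

    def residual(Tp):
        return levels(Tp)[3] - Tp

    if act == 0.0 or residual(0.0) <= 0.0:
        Tp = 0.0
    else:
        Tp = brentq(residual, 0.0, params.Ttot, xtol=1e-12, rtol=1e-14)
    X, A, Fpp, _ = levels(Tp)
    return CascadeState(
        A=A, Rtot=X["STE2"], Ftot=X["FUS3"], Fpp=Fpp, Ttot=params.Ttot, Tp=Tp,
        Sst2=X["SST2"], Msg5=X["MSG5"], Rep=X["FUS1"], Egtp=0.0, Eatp=0.0,
    )


def basal_state(params: ModelParameters) -> CascadeState:
    """Pre-stimulus steady state (theta = 0), the default initial condition."""
    return steady_state(params, theta=0.0)


@dataclass
class CellTrajectory:
    """Time course of one simulated cell on a fixed output grid."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), len(STATE_FIELDS))
    params: ModelParameters

    def state_at(self, i: int) -> CascadeState:
        return CascadeState.from_vector(self.states[i], self.params.Ttot)

    def endpoint(self) -> CascadeState:
        return self.state_at(-1)

    def endpoint_summary(self, window: float = 100.0) -> dict:
        """(Fpp, Rep, mean energy rates over the terminal window)."""
        end = self.endpoint()
        fluxes = energy_rate_at_endpoint(self, window)
        return {
            "Fpp_end": end.Fpp,
            "Rep_end": end.Rep,
            "Tp_end": end.Tp,
            "jgtp": fluxes.jgtp,
            "jatp": fluxes.jatp,
            "jtotal": fluxes.jtotal,
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time_s", self.times)
        return df

    def to_tsv(self, path, sidecar: Optional[dict] = None) -> None:
        """Write the trajectory as tidy TSV plus a JSON parameter sidecar."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {"params": self.params.to_dict()}
        if sidecar:
            meta.update(sidecar)
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def simulate_cell(
    params: ModelParameters,
    t_end: float = 1000.0,
    dt_out: float = 10.0,
    y0: Optional[CascadeState] = None,
    t_eval: Optional[np.ndarray] = None,
    rtol: float = 1e-7,
    atol: float = 1e-7,
) -> CellTrajectory:
    """Integrate one cell from its pre-stimulus state through a pheromone step.

    The initial condition defaults to the basal steady state of ``params`` at
    theta = 0; the dose step is ``params.theta`` applied at t = 0.  LSODA with
    absolute tolerance on the nM scale; halving the tolerances moves the
    endpoint Fpp by far less than 0.1 % (asserted in the tests).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    params.validate()
    if y0 is None:
        y0 = basal_state(params)
    y0.validate()
    if t_eval is None:
        n = max(int(round(t_end / dt_out)), 1)
        t_eval = np.linspace(0.0, t_end, n + 1)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval[0] != 0.0:
            t_eval = np.concatenate([[0.0], t_eval])
    out, info = odeint(
        _rhs, y0.to_vector(), t_eval, args=_pack(params),
        rtol=rtol, atol=atol, full_output=True, mxstep=20000,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"ODE integration failed at theta={params.theta} nM: {info['message']}"
        )
    return CellTrajectory(times=t_eval, states=out, params=params)


def energy_rate_at_endpoint(traj: CellTrajectory, window: float) -> EnergyFluxes:
    """Time-averaged hydrolysis fluxes over the terminal ``window`` seconds.

    Components are reconstructed from the state on the output grid and
    trapezoid-averaged; the GTP+ATP sum is consistent with differencing the
    cumulative counters (quadrature check in the tests).
    """
    t_end = traj.times[-1]
    if window <= 0:
        raise ValueError("window must be > 0")
    if window > t_end:
        raise ValueError("window exceeds simulated duration")
    mask = traj.times >= t_end - window - 1e-9
    t = traj.times[mask]
    if len(t) < 2:
        raise ValueError("terminal window contains fewer than 2 output points")
    rows = traj.states[mask]
    comp = np.array(
        [dataclasses.astuple(
            instantaneous_fluxes(CascadeState.from_vector(r, traj.params.Ttot), traj.params))
         for r in rows]
    )
    span = t[-1] - t[0]
    means = [float(np.trapezoid(comp[:, k], t) / span) for k in range(3)]
    return EnergyFluxes(*means)


def fus3_steady_state(params: ModelParameters, A: float, Ftot: float, Msg5: float) -> float:
    """Closed-form fixed point of the isolated Fus3 push-pull cycle.

    Fpp* = Ftot * kf*A / (kf*A + kd0 + kd*Msg5); the independent oracle for the
    frozen-synthesis integrator checks.
    """
    num = params.kf * A
    return Ftot * num / (num + params.kd0 + params.kd * Msg5)
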