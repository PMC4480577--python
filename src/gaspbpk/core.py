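"""Whole-body gas PBPK model: lung exchange, dosing schedules, ODE engine.

The model tracks an inert, non-metabolised gas through a set of well-mixed
compartments: arterial blood (including pulmonary capillary blood), venous
blood, and one perfusion-limited compartment per tissue.  Gas enters through
the lung, where alveolar gas and pulmonary blood are assumed to equilibrate
instantaneously according to the blood:gas partition coefficient; a fixed
fraction of cardiac output is shunted past the lung without exchange.  Each
tissue equilibrates instantaneously with its effluent venous blood via its
tissue:blood partition coefficient, so uptake is limited by perfusion, not
diffusion.  Excretion is purely the reverse of uptake (exhalation).

All concentrations are mol of gas per litre of compartment, time is in
minutes, flows in L/min and volumes in L.  The resulting ODE system is
linear and time-invariant between dose transitions, which the integrator
exploits by restarting at every episode boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .parameters import SubjectModel

__all__ = [
    "GasExchangeConfig",
    "DoseEpisode",
    "DosingSchedule",
    "SolverConfig",
    "SimulationResult",
    "SolverError",
    "inhaled_concentration",
    "lung_exchange",
    "exhaled_concentration",
    "PBPKSystem",
    "rhs",
    "simulate",
    "steady_state",
    "body_burden",
    "ARTERIAL",
    "VENOUS",
]

#: Compartment keys used for the two blood pools in every result.
ARTERIAL = "blood_arterial"
VENOUS = "blood_venous"


class SolverError(RuntimeError):
    """Raised when the stiff integrator fails; carries solver diagnostics."""


@dataclass(frozen=True)
class GasExchangeConfig:
    """Constants of the lung gas-exchange and ideal-gas conversion.

    shunt_fraction
        Fraction of cardiac output bypassing the lung without exchange.
    ventilatory_mixing_factor
        Factor multiplying alveolar ventilation inside the lung-exchange
        equation (accounts for incomplete ventilatory mixing).
    exhaled_alveolar_fraction
        Alveolar share of the exhaled gas mixture (the remainder is
        unexchanged inhaled gas).  A derived-output description only; it
        does not feed back into uptake.
    dead_space_fraction
        Fraction of minute ventilation that never reaches the alveolar
        exchange region; used only to derive alveolar ventilation when it
        is not tabulated.
    """

    shunt_fraction: float = 0.10
    ventilatory_mixing_factor: float = 0.90
    exhaled_alveolar_fraction: float = 0.90
    dead_space_fraction: float = 0.325
    temperature_k: float = 298.0
    total_pressure_pa: float = 1.01325e5
    gas_constant: float = 8314.4621  # Pa·L·mol⁻¹·K⁻¹

    def __post_init__(self) -> None:
        for name in (
            "shunt_fraction",
            "ventilatory_mixing_factor",
            "exhaled_alveolar_fraction",
            "dead_space_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.temperature_k <= 0 or self.total_pressure_pa <= 0:
            raise ValueError("temperature and pressure must be positive")
        if self.gas_constant <= 0:
            raise ValueError("gas constant must be positive")


def inhaled_concentration(
    inhaled_percent: float, exchange: GasExchangeConfig | None = None
) -> float:
    """Molar concentration (mol/L) of the gas in the inhaled mixture.

    Ideal-gas conversion of a percentage by volume (equivalently molar
    percentage): C = P_total / (R T) × (%gas / 100).
    """
    cfg = exchange or GasExchangeConfig()
    if not 0.0 <= inhaled_percent <= 100.0:
        raise ValueError(
            f"inhaled_percent must be in [0, 100], got {inhaled_percent}"
        )
    molar_density = cfg.total_pressure_pa / (cfg.gas_constant * cfg.temperature_k)
    return molar_density * inhaled_percent / 100.0


def lung_exchange(
    c_inhaled: float,
    c_venous: float,
    alveolar_ventilation: float,
    cardiac_output: float,
    pc_blood_gas: float,
    exchange: GasExchangeConfig | None = None,
) -> float:
    """Concentration of gas in blood leaving the lung (mol/L).

    Instantaneous (algebraic) equilibrium between alveolar gas and the
    non-shunted pulmonary blood::

        C = (1-s) * (m·AV·C_in + CO·C_ven) / (CO + m·AV / PC) + s·C_ven

    where ``s`` is the pulmonary shunt fraction and ``m`` the ventilatory
    mixing factor.  At the fixed point C_ven = PC·C_in the expression
    returns PC·C_in for any shunt — saturation is shunt-independent.
    """
    cfg = exchange or GasExchangeConfig()
    if alveolar_ventilation <= 0 or cardiac_output <= 0 or pc_blood_gas <= 0:
        raise ValueError("alveolar ventilation, cardiac output and PC must be > 0")
    if c_inhaled < 0 or c_venous < 0:
        raise ValueError("concentrations must be non-negative")
    m = cfg.ventilatory_mixing_factor
    s = cfg.shunt_fraction
    exchanged = (m * alveolar_ventilation * c_inhaled + cardiac_output * c_venous) / (
        cardiac_output + m * alveolar_ventilation / pc_blood_gas
    )
    return (1.0 - s) * exchanged + s * c_venous


def exhaled_concentration(
    c_arterial_lung: float,
    c_inhaled: float,
    pc_blood_gas: float,
    exchange: GasExchangeConfig | None = None,
) -> float:
    """Exhaled-gas concentration: a mix of alveolar and unexchanged gas.

    Derived output only — it does not feed back into uptake.
    """
    cfg = exchange or GasExchangeConfig()
    f = cfg.exhaled_alveolar_fraction
    return f * (c_arterial_lung / pc_blood_gas) + (1.0 - f) * c_inhaled


# ---------------------------------------------------------------------------
# Dosing schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseEpisode:
    """One constant-concentration inhalation episode."""

    start_min: float
    duration_min: float
    inhaled_percent: float

    def __post_init__(self) -> None:
        if self.start_min < 0:
            raise ValueError("episode start must be >= 0")
        if self.duration_min <= 0:
            raise ValueError("episode duration must be > 0")
        if not 0.0 <= self.inhaled_percent <= 100.0:
            raise ValueError("inhaled_percent must be in [0, 100]")

    @property
    def end_min(self) -> float:
        return self.start_min + self.duration_min


@dataclass(frozen=True)
class DosingSchedule:
    """Piecewise-constant inhaled gas fraction over time.

    Episodes must be time-ordered and non-overlapping.  Between episodes
    the inhaled fraction is zero (the ambient atmospheric baseline is
    neglected; it can be emulated with an explicit low-percent episode).
    """

    gas_name: str
    episodes: tuple[DoseEpisode, ...]

    def __post_init__(self) -> None:
        if not self.episodes:
            raise ValueError("schedule needs at least one episode")
        eps = tuple(sorted(self.episodes, key=lambda e: e.start_min))
        for a, b in zip(eps, eps[1:]):
            if b.start_min < a.end_min:
                raise ValueError(
                    f"episodes overlap: one ends at {a.end_min} min, "
                    f"next starts at {b.start_min} min"
                )
        object.__setattr__(self, "episodes", eps)

    @classmethod
    def single(
        cls, gas_name: str, inhaled_percent: float, duration_min: float,
        start_min: float = 0.0,
    ) -> "DosingSchedule":
        return cls(gas_name, (DoseEpisode(start_min, duration_min, inhaled_percent),))

    @classmethod
    def repeated(
        cls,
        gas_name: str,
        inhaled_percent: float,
        duration_min: float,
        period_min: float,
        count: int,
        start_min: float = 0.0,
    ) -> "DosingSchedule":
        """Expand one episode template into ``count`` repetitions."""
        if count < 1:
            raise ValueError("repetition count must be >= 1")
        if period_min < duration_min:
            raise ValueError("repetition period must be >= episode duration")
        eps = tuple(
            DoseEpisode(start_min + i * period_min, duration_min, inhaled_percent)
            for i in range(count)
        )
        return cls(gas_name, eps)

    @property
    def end_of_dosing(self) -> float:
        return max(e.end_min for e in self.episodes)

    def inhaled_percent_at(self, t: float) -> float:
        for e in self.episodes:
            if e.start_min <= t < e.end_min:
                return e.inhaled_percent
        return 0.0

    def segments(self, horizon_min: float) -> list[tuple[float, float, float]]:
        """Constant-percent intervals (start, end, percent) covering [0, horizon]."""
        bounds = {0.0, horizon_min}
        for e in self.episodes:
            if e.start_min < horizon_min:
                bounds.add(e.start_min)
            if e.end_min < horizon_min:
                bounds.add(e.end_min)
        cuts = sorted(bounds)
        return [
            (t0, t1, self.inhaled_percent_at(t0))
            for t0, t1 in zip(cuts, cuts[1:])
        ]


# ---------------------------------------------------------------------------
# Solver configuration and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverConfig:
    """Integration and output-sampling settings.

    ``max_step_min`` defaults to 0.5 s (1/120 min).  Output is sampled on a
    coarse grid, refined right after every dose transition so that the fast
    arterial dynamics (half-times down to ~0.05 min in small animals) are
    resolved.
    """

    max_step_min: float = 1.0 / 120.0
    rtol: float = 1e-8
    atol: float = 1e-12
    sample_interval_min: float = 0.1
    fine_sample_interval_min: float = 0.01
    fine_window_min: float = 5.0
    post_dose_horizon_min: float = 1440.0

    def __post_init__(self) -> None:
        if self.max_step_min <= 0:
            raise ValueError("max_step_min must be > 0")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be > 0")
        if self.sample_interval_min <= 0 or self.fine_sample_interval_min <= 0:
            raise ValueError("sampling intervals must be > 0")
        if self.post_dose_horizon_min < 0:
            raise ValueError("post-dose horizon must be >= 0")


@dataclass(frozen=True)
class SimulationResult:
    """Concentration trajectories for every compartment on a shared grid.

    ``concentrations`` maps compartment key (``blood_arterial``,
    ``blood_venous``, tissue names) to a mol/L series; ``uptake_mol`` is the
    cumulative net amount of gas transferred from alveolar gas to blood,
    integrated by the solver alongside the state (for mass-balance audits).
    """

    time_min: np.ndarray
    concentrations: dict[str, np.ndarray]
    uptake_mol: np.ndarray
    subject: "SubjectModel"
    schedule: DosingSchedule
    solver: SolverConfig

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be 1-D and strictly increasing")
        for name, series in self.concentrations.items():
            if len(series) != len(t):
                raise ValueError(f"series length mismatch for {name}")
            if not np.all(np.isfinite(series)):
                raise ValueError(f"non-finite concentrations in {name}")

    @property
    def compartments(self) -> list[str]:
        return list(self.concentrations)

    def series(self, compartment: str) -> np.ndarray:
        try:
            return self.concentrations[compartment]
        except KeyError:
            raise KeyError(
                f"unknown compartment {compartment!r}; "
                f"available: {', '.join(self.concentrations)}"
            ) from None

    def to_frame(self):
        """Tidy long-format DataFrame (time_min, compartment, concentration)."""
        import pandas as pd

        frames = []
        for name, series in self.concentrations.items():
            frames.append(
                pd.DataFrame(
                    {
                        "time_min": self.time_min,
                        "compartment": name,
                        "concentration_mol_per_l": series,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# The ODE system
# ---------------------------------------------------------------------------


def tissue_uptake_rate(
    c_arterial: float, c_tissue: float, perfusion: float, volume: float,
    pc_tissue_blood: float,
) -> float:
    """dC_tissue/dt for one perfusion-limited compartment.

    dC/dt = Q × (C_arterial − C_tissue / PC_tissue:blood) / V
    """
    return perfusion * (c_arterial - c_tissue / pc_tissue_blood) / volume


class PBPKSystem:
    """Linear state-space form of the model for one subject.

    State vector: [C_arterial, C_venous, C_tissue_1..n, cumulative_uptake].
    Between dose transitions dx/dt = A x + b·C_inhaled with constant A, b.
    """

    def __init__(self, subject: "SubjectModel"):
        self.subject = subject
        cfg = subject.exchange
        co = subject.physiology.cardiac_output
        av = subject.physiology.alveolar_ventilation
        pc_bg = subject.blood_gas_pc
        comps = subject.compartments
        n = len(comps)
        self.tissue_names = [c.name for c in comps]
        self.dim = n + 3  # arterial, venous, tissues..., cumulative uptake

        q = np.array([c.perfusion for c in comps])
        v = np.array([c.volume for c in comps])
        pc = np.array([c.pc_tissue_blood for c in comps])
        self.q, self.v, self.pc = q, v, pc

        m = cfg.ventilatory_mixing_factor
        s = cfg.shunt_fraction
        den = co + m * av / pc_bg
        # C_arterial_lung = a_in·C_inhaled + a_ven·C_venous
        self.a_in = (1.0 - s) * m * av / den
        self.a_ven = (1.0 - s) * co / den + s

        v_art = subject.arterial_volume
        v_ven = subject.venous_volume
        bypass = co - q.sum()  # residual cardiac output, arteriovenous bypass

        A = np.zeros((self.dim, self.dim))
        b = np.zeros(self.dim)
        # arterial pool fed at CO with lung effluent
        A[0, 0] = -co / v_art
        A[0, 1] = co * self.a_ven / v_art
        b[0] = co * self.a_in / v_art
        # venous pool fed at CO with mixed venous return
        A[1, 0] = bypass / v_ven
        A[1, 1] = -co / v_ven
        A[1, 2 : 2 + n] = q / (pc * v_ven)
        # perfusion-limited tissues
        A[2 : 2 + n, 0] = q / v
        idx = np.arange(n)
        A[2 + idx, 2 + idx] = -q / (pc * v)
        # cumulative net lung uptake (moles): CO·(C_arterial_lung − C_venous)
        A[-1, 1] = co * (self.a_ven - 1.0)
        b[-1] = co * self.a_in
        self.A = A
        self.b = b

    def rhs(self, t: float, state: np.ndarray, c_inhaled: float) -> np.ndarray:
        """Time derivative of the state under a given inhaled concentration."""
        return self.A.dot(state) + self.b * c_inhaled

    def unpack(self, states: np.ndarray) -> dict[str, np.ndarray]:
        out = {ARTERIAL: states[:, 0], VENOUS: states[:, 1]}
        for i, name in enumerate(self.tissue_names):
            out[name] = states[:, 2 + i]
        return out


def rhs(
    state: Mapping[str, float],
    t: float,
    subject: "SubjectModel",
    schedule: DosingSchedule,
) -> dict[str, float]:
    """Model right-hand side on named compartments (mol/L per min).

    Convenience/diagnostic form of :meth:`PBPKSystem.rhs` keyed by
    compartment name; the integrator uses the vectorised state-space form.
    """
    system = PBPKSystem(subject)
    x = np.zeros(system.dim)
    x[0] = state[ARTERIAL]
    x[1] = state[VENOUS]
    for i, name in enumerate(system.tissue_names):
        x[2 + i] = state[name]
    u = inhaled_concentration(schedule.inhaled_percent_at(t), subject.exchange)
    dx = system.rhs(t, x, u)
    out = {ARTERIAL: dx[0], VENOUS: dx[1]}
    for i, name in enumerate(system.tissue_names):
        out[name] = dx[2 + i]
    return out


def _segment_grid(t0: float, t1: float, cfg: SolverConfig) -> np.ndarray:
    """Output grid for one constant-dose segment: fine right after the
    transition at ``t0``, coarse afterwards."""
    fine_end = min(t0 + cfg.fine_window_min, t1)
    n_fine = int(round((fine_end - t0) / cfg.fine_sample_interval_min))
    fine = t0 + cfg.fine_sample_interval_min * np.arange(n_fine + 1)
    fine = fine[fine <= t1 + 1e-12]
    coarse_start = fine[-1]
    n_coarse = int(math.floor((t1 - coarse_start) / cfg.sample_interval_min + 1e-9))
    coarse = coarse_start + cfg.sample_interval_min * np.arange(1, n_coarse + 1)
    grid = np.concatenate([fine, coarse])
    if grid[-1] < t1 - 1e-9:
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1
    return grid


def simulate(
    subject: "SubjectModel",
    schedule: DosingSchedule,
    solver: SolverConfig | None = None,
) -> SimulationResult:
    """Integrate the model from a gas-naive state over the full schedule.

    Starts at t = 0 with zero body burden, runs to the end of the last
    episode plus the post-dose horizon.  Integration restarts at every
    episode boundary so the stiff solver never steps across a dosing
    discontinuity.
    """
    cfg = solver or SolverConfig()
    horizon = schedule.end_of_dosing + cfg.post_dose_horizon_min
    system = PBPKSystem(subject)
    A, b = system.A, system.b

    x = np.zeros(system.dim)
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    first = True
    for t0, t1, percent in schedule.segments(horizon):
        u = inhaled_concentration(percent, subject.exchange)
        bu = b * u
        grid = _segment_grid(t0, t1, cfg)
        sol, info = odeint(
            lambda y, t: A.dot(y) + bu,
            x,
            grid,
            Dfun=lambda y, t: A,
            rtol=cfg.rtol,
            atol=cfg.atol,
            hmax=cfg.max_step_min,
            full_output=True,
        )
        if info["message"] != "Integration successful.":
            raise SolverError(
                f"stiff integration failed on segment [{t0}, {t1}] min: "
                f"{info['message']}"
            )
        x = sol[-1]
        if first:
            times.append(grid)
            states.append(sol)
            first = False
        else:  # drop the duplicated boundary point
            times.append(grid[1:])
            states.append(sol[1:])

    t = np.concatenate(times)
    y = np.concatenate(states)
    # clip solver-tolerance-level negative excursions
    y[:, :-1] = np.maximum(y[:, :-1], 0.0)
    return SimulationResult(
        time_min=t,
        concentrations=system.unpack(y),
        uptake_mol=y[:, -1],
        subject=subject,
        schedule=schedule,
        solver=cfg,
    )


def steady_state(subject: "SubjectModel", inhaled_percent: float) -> dict[str, float]:
    """Closed-form saturation concentrations under constant inhalation.

    Blood (arterial and venous) saturates at PC_blood:gas × C_inhaled;
    every tissue at PC_tissue:blood × PC_blood:gas × C_inhaled.  These are
    independent of the shunt fraction and of all flows.
    """
    c_in = inhaled_concentration(inhaled_percent, subject.exchange)
    c_blood = subject.blood_gas_pc * c_in
    out = {ARTERIAL: c_blood, VENOUS: c_blood}
    for comp in subject.compartments:
        out[comp.name] = comp.pc_tissue_blood * c_blood
    return out


def body_burden(result: SimulationResult) -> np.ndarray:
    """Total moles of gas in the body at each grid time.

    Σ_i V_i·C_i(t) over both blood pools and all tissue compartments.  For
    a mass-conserving model this equals the cumulative net lung uptake flux
    ``result.uptake_mol`` to within solver tolerance.
    """
    subject = result.subject
    burden = (
        subject.arterial_volume * result.concentrations[ARTERIAL]
        + subject.venous_volume * result.concentrations[VENOUS]
    )
    for comp in subject.compartments:
        burden = burden + comp.volume * result.concentrations[comp.name]
    return burden
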