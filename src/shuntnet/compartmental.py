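"""Three-compartment conductance neuron model.

A soma coupled to two dendritic compartments carrying one excitatory and one
inhibitory synapse.  This is the "ground truth" model against which the
reduced single-compartment descriptions are validated: it provides an exact
steady-state solver (a 3x3 linear system), a forward ODE integrator, an
empirical extraction of the shunting strength kappa from steady-state
voltages, and the distance-dependent transfer-conductance geometry used to
scan kappa against synapse placement.

Sign/usage conventions
----------------------
Voltages in mV, conductances in nS, capacitances in pF, times in ms
(pF/nS = ms, nS*mV = pA throughout).  The ``on_path`` arrangement places the
inhibitory synapse between the excitatory synapse and the soma; ``out_of_path``
exchanges the two synapse labels (including the transfer-conductance labels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ON_PATH = "on_path"
OUT_OF_PATH = "out_of_path"
_ARRANGEMENTS = (ON_PATH, OUT_OF_PATH)


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of the three-compartment neuron.

    The antidromic transfer conductances default to ``alpha`` times their
    orthodromic counterparts (``g_IS = alpha*g_SI`` etc.), reflecting the
    amplification of depolarizing signals by active channels; they can be
    overridden individually.
    """

    E_L: float = -70.0  # resting potential (mV)
    E_E: float = 10.0   # excitatory reversal (mV)
    E_I: float = -80.0  # inhibitory reversal (mV)
    C_S: float = 740.0  # somatic capacitance (pF)
    C_D: float = 50.0   # dendritic capacitance (pF)
    g_S: float = 30.0   # somatic leak (nS)
    g_D: float = 20.0   # dendritic leak (nS)
    g_SI: float = 5.0   # transfer soma -> I site (nS)
    g_SE: float = 10.0  # transfer soma -> E site (nS)
    g_IE: float = 1.0   # transfer I site -> E site (nS)
    alpha: float = 5.0  # amplification of antidromic transfers (dimensionless)
    g_IS: float = field(default=None)  # type: ignore[assignment]
    g_ES: float = field(default=None)  # type: ignore[assignment]
    g_EI: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.g_IS is None:
            object.__setattr__(self, "g_IS", self.alpha * self.g_SI)
        if self.g_ES is None:
            object.__setattr__(self, "g_ES", self.alpha * self.g_SE)
        if self.g_EI is None:
            object.__setattr__(self, "g_EI", self.alpha * self.g_IE)
        if self.C_S <= 0 or self.C_D <= 0:
            raise ValueError("capacitances must be positive")
        for name in ("g_S", "g_D", "g_SI", "g_SE", "g_IE", "g_IS", "g_ES", "g_EI"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if not (self.E_I <= self.E_L < self.E_E):
            raise ValueError("require E_I <= E_L < E_E")

    # -- characteristic time constants -------------------------------------
    @property
    def tau_S(self) -> float:
        """Somatic time constant C_S/(g_S+g_IS) (ms)."""
        return self.C_S / (self.g_S + self.g_IS)

    @property
    def tau_DI(self) -> float:
        """Time constant of the proximal (inhibitory) dendritic site (ms)."""
        return self.C_D / (self.g_D + self.g_SI + self.g_EI)

    @property
    def tau_DE(self) -> float:
        """Time constant of the distal (excitatory) dendritic site (ms)."""
        return self.C_D / (self.g_D + self.g_IE)


@dataclass(frozen=True)
class SynapticDrive:
    """Pair of synaptic conductances; scalars or aligned time series (nS)."""

    g_E: float | np.ndarray = 0.0
    g_I: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.g_E) < 0) or np.any(np.asarray(self.g_I) < 0):
            raise ValueError("synaptic conductances must be non-negative")


@dataclass(frozen=True)
class PathConfig:
    arrangement: str = ON_PATH

    def __post_init__(self) -> None:
        if self.arrangement not in _ARRANGEMENTS:
            raise ValueError(
                f"arrangement must be one of {_ARRANGEMENTS}, got {self.arrangement!r}"
            )


@dataclass(frozen=True)
class DistanceModel:
    """Inverse-linear distance dependence of transfer conductances.

    ``transfer(x) = g_max / (mu_spatial * x + 1)`` so that two co-localized
    points (x = 0) couple with ``g_max`` and the coupling decays
    monotonically with cable distance.
    """

    g_max: float = 300.0
    mu_spatial: float = 3.0

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        if self.mu_spatial <= 0:
            raise ValueError("mu_spatial must be positive")

    def transfer(self, x: float | np.ndarray) -> float | np.ndarray:
        if np.any(np.asarray(x) < 0):
            raise ValueError("distance must be non-negative")
        return self.g_max / (self.mu_spatial * np.asarray(x) + 1.0)

    def position_of(self, g_trf: float) -> float:
        """Distance at which the transfer conductance equals ``g_trf``."""
        if not 0 < g_trf <= self.g_max:
            raise ValueError("g_trf must lie in (0, g_max]")
        return (self.g_max / g_trf - 1.0) / self.mu_spatial


class TriSteadyState:
    """Steady-state potentials (mV) of soma and the two dendritic sites."""

    __slots__ = ("v_S", "v_I", "v_E")

    def __init__(self, v_S: float, v_I: float, v_E: float):
        self.v_S = v_S
        self.v_I = v_I
        self.v_E = v_E

    def __iter__(self):
        return iter((self.v_S, self.v_I, self.v_E))

    def __repr__(self) -> str:
        return f"TriSteadyState(v_S={self.v_S:.4f}, v_I={self.v_I:.4f}, v_E={self.v_E:.4f})"


def _circuit(params: NeuronParams, arrangement: str):
    """Transfer conductances and synapse placement for a given arrangement.

    Returns (t_ps, t_sp, t_dp, t_pd, E_prox, E_dist) where "prox" is the
    compartment adjacent to the soma and "dist" the outer one; t_xy is the
    transfer conductance appearing in compartment y's equation for the
    current from x.  Out-of-path is the on-path system with all E and I
    labels interchanged.
    """
    p = params
    if arrangement == ON_PATH:
        # proximal = inhibitory site, distal = excitatory site
        return p.g_IS, p.g_SI, p.g_EI, p.g_IE, p.E_I, p.E_E
    if arrangement == OUT_OF_PATH:
        return p.g_ES, p.g_SE, p.g_IE, p.g_EI, p.E_E, p.E_I
    raise ValueError(f"unknown arrangement {arrangement!r}")


def _system_matrix(params: NeuronParams, g_prox: float, g_dist: float, arrangement: str):
    """Coefficient matrix and RHS for u = v - E_L of (soma, prox, dist)."""
    p = params
    t_ps, t_sp, t_dp, t_pd, E_prox, E_dist = _circuit(p, arrangement)
    A = np.array(
        [
            [p.g_S + t_ps, -t_ps, 0.0],
            [-t_sp, p.g_D + t_sp + t_dp + g_prox, -t_dp],
            [0.0, -t_pd, p.g_D + t_pd + g_dist],
        ]
    )
    rhs = np.array(
        [0.0, g_prox * (E_prox - p.E_L), g_dist * (E_dist - p.E_L)]
    )
    return A, rhs


def steady_state_three_compartment(
    params: NeuronParams,
    drive: SynapticDrive,
    config: PathConfig = PathConfig(),
) -> TriSteadyState:
    """Exact steady state of the three-compartment model for constant drive.

    Solves the 3x3 linear system obtained by zeroing the time derivatives of
    the coupled compartment equations; no small-transfer-conductance
    approximation is made.
    """
    g_E = float(np.asarray(drive.g_E))
    g_I = float(np.asarray(drive.g_I))
    if g_E < 0 or g_I < 0:
        raise ValueError("drive conductances must be non-negative")
    if config.arrangement == ON_PATH:
        g_prox, g_dist = g_I, g_E
    else:
        g_prox, g_dist = g_E, g_I
    A, rhs = _system_matrix(params, g_prox, g_dist, config.arrangement)
    try:
        u = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # all-zero conductances
        raise ValueError("singular compartment system (degenerate conductances)") from exc
    v = u + params.E_L
    if config.arrangement == ON_PATH:
        return TriSteadyState(v_S=v[0], v_I=v[1], v_E=v[2])
    return TriSteadyState(v_S=v[0], v_I=v[2], v_E=v[1])


def simulate_three_compartment(
    params: NeuronParams,
    drive: SynapticDrive,
    config: PathConfig = PathConfig(),
    duration: float = 200.0,
    dt: float = 0.01,
    v0: tuple[float, float, float] | None = None,
) -> dict[str, np.ndarray]:
    """Forward-Euler integration of the three coupled compartment ODEs.

    ``drive`` holds scalars or per-step series of length ``n_steps``.
    Returns a dict with keys ``t``, ``v_S``, ``v_I``, ``v_E`` (arrays of
    length ``n_steps + 1``).  Raises ``RuntimeError`` naming the offending
    step if the solution diverges (dt too large for stability).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    n = int(round(duration / dt))
    gE = np.broadcast_to(np.asarray(drive.g_E, dtype=float), (n,))
    gI = np.broadcast_to(np.asarray(drive.g_I, dtype=float), (n,))

    p = params
    t_ps, t_sp, t_dp, t_pd, E_prox, E_dist = _circuit(p, config.arrangement)
    if config.arrangement == ON_PATH:
        g_prox, g_dist = gI, gE
    else:
        g_prox, g_dist = gE, gI

    vS = np.empty(n + 1)
    vP = np.empty(n + 1)
    vD = np.empty(n + 1)
    if v0 is None:
        vS[0] = vP[0] = vD[0] = p.E_L
    else:
        if config.arrangement == ON_PATH:
            vS[0], vP[0], vD[0] = v0
        else:
            vS[0], vP[0], vD[0] = v0[0], v0[2], v0[1]

    check_every = max(1, n // 50)
    for k in range(n):
        s, pr, d = vS[k], vP[k], vD[k]
        dvS = (-p.g_S * (s - p.E_L) - t_ps * (s - pr)) / p.C_S
        dvP = (
            -p.g_D * (pr - p.E_L)
            - t_sp * (pr - s)
            - t_dp * (pr - d)
            - g_prox[k] * (pr - E_prox)
        ) / p.C_D
        dvD = (
            -p.g_D * (d - p.E_L) - t_pd * (d - pr) - g_dist[k] * (d - E_dist)
        ) / p.C_D
        vS[k + 1] = s + dt * dvS
        vP[k + 1] = pr + dt * dvP
        vD[k + 1] = d + dt * dvD
        if (k % check_every == 0 or k == n - 1) and not (
            math.isfinite(vS[k + 1]) and math.isfinite(vP[k + 1]) and math.isfinite(vD[k + 1])
            and abs(vP[k + 1]) < 1e4
        ):
            raise RuntimeError(
                f"integration diverged at step {k} (t={k * dt:.3f} ms); reduce dt"
            )
    t = np.arange(n + 1) * dt
    if config.arrangement == ON_PATH:
        return {"t": t, "v_S": vS, "v_I": vP, "v_E": vD}
    return {"t": t, "v_S": vS, "v_I": vD, "v_E": vP}


def extract_shunting_strength(
    params: NeuronParams,
    g_E: float,
    g_I: float,
    config: PathConfig = PathConfig(),
) -> float:
    """Empirical shunting strength kappa (mV^-1) from the full model.

    Computes the steady somatic depolarization with both inputs, with the
    excitatory input alone, and with the inhibitory input alone, then solves
    the multiplicative combination rule
    ``dv_both = dv_E + dv_I + kappa * dv_E * dv_I`` for kappa.
    """
    if g_E <= 0 or g_I <= 0:
        raise ZeroDivisionError(
            "kappa extraction is undefined for single inputs (need g_E > 0 and g_I > 0)"
        )
    EL = params.E_L
    dv_both = steady_state_three_compartment(params, SynapticDrive(g_E, g_I), config).v_S - EL
    dv_E = steady_state_three_compartment(params, SynapticDrive(g_E, 0.0), config).v_S - EL
    dv_I = steady_state_three_compartment(params, SynapticDrive(0.0, g_I), config).v_S - EL
    return (dv_both - dv_E - dv_I) / (dv_E * dv_I)


def transfer_conductance_from_distance(x: float, model: DistanceModel) -> float:
    """Transfer conductance (nS) between two sites a distance ``x`` apart."""
    if x < 0:
        raise ValueError("distance must be non-negative")
    return float(model.transfer(x))


def params_at_positions(
    base: NeuronParams,
    g_SI_anchor: float,
    x_E: float,
    model: DistanceModel,
) -> tuple[NeuronParams, PathConfig]:
    """Neuron parameters for an excitatory site at ``x_E`` given a fixed I site.

    The inhibitory site position is implied by the anchored soma->I transfer
    conductance ``g_SI_anchor`` through the distance model.  For ``x_E`` at or
    beyond the inhibitory site the arrangement is on-path and the inter-site
    coupling follows the distance rule on the separation.  For ``x_E`` inside
    the inhibitory site the arrangement is out-of-path and the inter-site
    coupling is fixed by the series-resistance identity
    ``1/g_SE + 1/g_IE = 1/g_SI``.
    """
    x_I = model.position_of(g_SI_anchor)
    if x_E >= x_I:  # on-path: I between E and soma
        g_IE = float(model.transfer(x_E - x_I))
        p = NeuronParams(
            E_L=base.E_L, E_E=base.E_E, E_I=base.E_I, C_S=base.C_S, C_D=base.C_D,
            g_S=base.g_S, g_D=base.g_D, alpha=base.alpha,
            g_SI=g_SI_anchor, g_SE=base.g_SE, g_IE=g_IE,
        )
        return p, PathConfig(ON_PATH)
    g_SE = float(model.transfer(x_E))
    if g_SE <= g_SI_anchor:
        raise ValueError(
            "series-resistance constraint requires g_SE > g_SI for out-of-path sites"
        )
    g_IE = 1.0 / (1.0 / g_SI_anchor - 1.0 / g_SE)
    p = NeuronParams(
        E_L=base.E_L, E_E=base.E_E, E_I=base.E_I, C_S=base.C_S, C_D=base.C_D,
        g_S=base.g_S, g_D=base.g_D, alpha=base.alpha,
        g_SI=g_SI_anchor, g_SE=g_SE, g_IE=g_IE,
    )
    return p, PathConfig(OUT_OF_PATH)


def kappa_distance_scan(
    base: NeuronParams,
    anchors: Sequence[float],
    x_E_positions: Iterable[float],
    model: DistanceModel = DistanceModel(),
    g_E: float = 2.0,
    g_I: float = 2.0,
) -> pd.DataFrame:
    """Scan kappa (full-model extraction) against excitatory-site distance.

    ``anchors`` are soma->I transfer conductances pinning the inhibitory site
    at fixed positions; for each anchor the excitatory site sweeps over
    ``x_E_positions``, switching from out-of-path to on-path where it crosses
    the inhibitory site.  Returns a tidy table with columns
    ``x_E, g_SI_anchor, kappa, arrangement`` (kappa is NaN where the
    out-of-path series constraint cannot be met).
    """
    if len(list(anchors)) == 0:
        raise ValueError("anchor list must not be empty")
    rows = []
    for anchor in anchors:
        for x_E in x_E_positions:
            try:
                p, cfg = params_at_positions(base, anchor, x_E, model)
                kappa = extract_shunting_strength(p, g_E, g_I, cfg)
                arr = cfg.arrangement
            except ValueError:
                kappa, arr = float("nan"), "invalid"
            rows.append((x_E, anchor, kappa, arr))
    return pd.DataFrame(rows, columns=["x_E", "g_SI_anchor", "kappa", "arrangement"])
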