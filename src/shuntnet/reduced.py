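"""Reduced single-compartment neuron models with multiplicative shunting.

Separation of time scales (fast dendrites, slow soma) collapses the
three-compartment model into a first-order equation for the somatic
potential driven by closed-form response functions of the synaptic
conductances:

    tau_S dv/dt = -(v - E_L) + F(g_E, g_I),
    F = f_exc(g_E) + f_inh(g_I) + kappa * f_exc(g_E) * f_inh(g_I)

with a geometry-dependent shunting strength kappa.  Five synaptic geometries
are supported: the two-site ``on_path`` / ``out_of_path`` arrangements,
``single_per_branch`` (one synapse per branch, purely additive),
``paired_on_path`` (an E/I pair per branch, per-branch shunting), and
``global_shunting`` (peri-somatic inhibition gating the summed excitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compartmental import NeuronParams

ON_PATH = "on_path"
OUT_OF_PATH = "out_of_path"
SINGLE_PER_BRANCH = "single_per_branch"
PAIRED_ON_PATH = "paired_on_path"
GLOBAL_SHUNTING = "global_shunting"
GEOMETRIES = (ON_PATH, OUT_OF_PATH, SINGLE_PER_BRANCH, PAIRED_ON_PATH, GLOBAL_SHUNTING)


@dataclass(frozen=True)
class DendriticConfig:
    """Synaptic geometry plus branch count."""

    geometry: str = ON_PATH
    N: int = 1

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}")
        if self.geometry in (ON_PATH, OUT_OF_PATH):
            if self.N != 1:
                raise ValueError("two-site geometries require N = 1")
        elif self.N < 1:
            raise ValueError("branch geometries require N >= 1")


@dataclass(frozen=True)
class ResponseDecomposition:
    """Decomposition of the steady somatic potential.

    ``v_steady = E_L + f_exc + f_inh + cross`` where ``cross`` is the
    multiplicative shunting contribution.  For the two-site and global
    geometries ``cross == kappa * f_exc * f_inh``; for paired branches the
    shunting acts per branch and ``cross`` is the sum of per-branch products.
    """

    f_exc: float
    f_inh: float
    kappa: float
    cross: float
    v_steady: float


def point_neuron_steady_state(
    g_E: float, g_I: float, params: NeuronParams, g_leak: float | None = None
) -> float:
    """Steady potential of a single-compartment conductance neuron (mV).

    Both synapses sit directly on the soma: the steady state is the
    conductance-weighted mixture of the reversal potentials, the textbook
    illustration of divisive E/I interaction.
    """
    if g_E < 0 or g_I < 0:
        raise ValueError("conductances must be non-negative")
    g = params.g_S if g_leak is None else g_leak
    gamma = g + g_E + g_I
    return params.E_L + (g_E / gamma) * (params.E_E - params.E_L) + (g_I / gamma) * (
        params.E_I - params.E_L
    )


# ---------------------------------------------------------------------------
# closed-form response functions
# ---------------------------------------------------------------------------

def _fd_on(g_E, p: NeuronParams):
    """Distal excitatory response, on-path geometry."""
    num = p.g_IS * p.g_EI * g_E * (p.E_E - p.E_L)
    den = (
        p.g_S * p.g_D + p.g_S * p.g_SI + p.g_S * p.g_EI + p.g_D * p.g_IS + p.g_EI * p.g_IS
    ) * (p.g_D + g_E + p.g_IE)
    return num / den


def _fp_on(g_I, p: NeuronParams):
    """Proximal inhibitory response, on-path geometry."""
    num = p.g_IS * g_I * (p.E_I - p.E_L)
    den = (
        p.g_S * p.g_D + p.g_S * p.g_SI + p.g_D * p.g_IS
        + (p.g_S + p.g_IS) * (p.g_EI + g_I)
    )
    return num / den


def _fp_out(g_E, p: NeuronParams):
    """Proximal excitatory response, out-of-path geometry."""
    num = p.g_ES * g_E * (p.E_E - p.E_L)
    den = (
        p.g_S * p.g_D + p.g_S * p.g_SE + p.g_D * p.g_ES
        + (p.g_S + p.g_ES) * (p.g_IE + g_E)
    )
    return num / den


def _fd_out(g_I, p: NeuronParams):
    """Distal inhibitory response, out-of-path geometry."""
    num = p.g_ES * p.g_IE * g_I * (p.E_I - p.E_L)
    den = (
        p.g_S * p.g_D + p.g_S * p.g_SE + p.g_S * p.g_IE + p.g_D * p.g_ES + p.g_IE * p.g_ES
    ) * (p.g_D + g_I + p.g_EI)
    return num / den


def _fN(g, reversal, g_TS, N, p: NeuronParams):
    """Single-synapse-per-branch response (type-specific transfer g_TS)."""
    return g_TS * g * (reversal - p.E_L) / ((p.g_S + N * g_TS) * (p.g_D + g))


def _fNd(g_E, N, p: NeuronParams):
    """Per-branch distal excitatory response, paired on-path branches."""
    return p.g_IS * p.g_EI * g_E * (p.E_E - p.E_L) / (
        p.g_D * (p.g_D + g_E) * (p.g_S + N * p.g_IS)
    )


def _fNp(g_I, N, p: NeuronParams):
    """Per-branch proximal inhibitory response, paired on-path branches."""
    return p.g_IS * g_I * (p.E_I - p.E_L) / (
        (p.g_S + N * p.g_IS) * (p.g_D + g_I + p.g_IE)
    )


def _fGd(g_E, N, p: NeuronParams, g_ES: float | None = None):
    """Per-branch excitatory response under global shunting."""
    g_ES = p.g_ES if g_ES is None else g_ES
    return g_ES * g_E * (p.E_E - p.E_L) / ((p.g_D + g_E) * (p.g_S + N * g_ES))


def _fGp(g_I, N, p: NeuronParams, g_ES: float | None = None):
    """Peri-somatic inhibitory response under global shunting."""
    g_ES = p.g_ES if g_ES is None else g_ES
    return g_I * (p.E_I - p.E_L) / (p.g_S + g_I + N * g_ES)


def somatic_response_excitatory(
    g_E, params: NeuronParams, config: DendriticConfig = DendriticConfig()
):
    """Somatic depolarization due to excitation alone (mV).

    Zero at g_E = 0, strictly increasing and saturating to a finite limit.
    Accepts scalars or arrays.
    """
    g = np.asarray(g_E, dtype=float)
    if np.any(g < 0):
        raise ValueError("g_E must be non-negative")
    geo = config.geometry
    if geo == ON_PATH:
        out = _fd_on(g, params)
    elif geo == OUT_OF_PATH:
        out = _fp_out(g, params)
    elif geo == SINGLE_PER_BRANCH:
        out = _fN(g, params.E_E, params.g_ES, config.N, params)
    elif geo == PAIRED_ON_PATH:
        out = _fNd(g, config.N, params)
    elif geo == GLOBAL_SHUNTING:
        out = _fGd(g, config.N, params)
    else:  # pragma: no cover - guarded by DendriticConfig
        raise ValueError(f"unknown geometry {geo!r}")
    return out if np.ndim(g_E) else float(out)


def somatic_response_inhibitory(
    g_I, params: NeuronParams, config: DendriticConfig = DendriticConfig()
):
    """Somatic deflection due to inhibition alone (mV, non-positive)."""
    g = np.asarray(g_I, dtype=float)
    if np.any(g < 0):
        raise ValueError("g_I must be non-negative")
    geo = config.geometry
    if geo == ON_PATH:
        out = _fp_on(g, params)
    elif geo == OUT_OF_PATH:
        out = _fd_out(g, params)
    elif geo == SINGLE_PER_BRANCH:
        out = _fN(g, params.E_I, params.g_IS, config.N, params)
    elif geo == PAIRED_ON_PATH:
        out = _fNp(g, config.N, params)
    elif geo == GLOBAL_SHUNTING:
        out = _fGp(g, config.N, params)
    else:  # pragma: no cover
        raise ValueError(f"unknown geometry {geo!r}")
    return out if np.ndim(g_I) else float(out)


def shunting_strength(
    params: NeuronParams, config: DendriticConfig = DendriticConfig()
) -> float:
    """Closed-form shunting strength kappa (mV^-1) of the configured geometry.

    Positive for on-path-style geometries (E_I below rest), small and
    negative for out-of-path, exactly zero for independent branches.
    """
    p = params
    geo = config.geometry
    if geo == ON_PATH:
        if p.g_IS == 0:
            raise ZeroDivisionError("kappa_on undefined: transfer conductance g_IS is zero")
        if p.E_L == p.E_I:
            raise ZeroDivisionError("kappa_on undefined: E_L equals E_I")
        return (p.g_S + p.g_IS) / (p.g_IS * (p.E_L - p.E_I))
    if geo == OUT_OF_PATH:
        if p.g_ES == 0:
            raise ZeroDivisionError("kappa_out undefined: transfer conductance g_ES is zero")
        if p.E_L == p.E_E:
            raise ZeroDivisionError("kappa_out undefined: E_L equals E_E")
        return (p.g_S + p.g_ES) / (p.g_ES * (p.E_L - p.E_E))
    if geo == SINGLE_PER_BRANCH:
        return 0.0
    if geo == PAIRED_ON_PATH:
        if p.g_IS == 0:
            raise ZeroDivisionError("kappa_N_on undefined: transfer conductance g_IS is zero")
        if p.E_L == p.E_I:
            raise ZeroDivisionError("kappa_N_on undefined: E_L equals E_I")
        return (p.g_S + config.N * p.g_IS) / (p.g_IS * (p.E_L - p.E_I))
    if geo == GLOBAL_SHUNTING:
        if p.E_L == p.E_I:
            raise ZeroDivisionError("kappa_G undefined: E_L equals E_I")
        return 1.0 / (p.E_L - p.E_I)
    raise ValueError(f"unknown geometry {geo!r}")  # pragma: no cover


def tau_soma(params: NeuronParams, config: DendriticConfig = DendriticConfig()) -> float:
    """Effective somatic time constant (ms) of the reduced model."""
    p = params
    geo = config.geometry
    if geo == ON_PATH:
        return p.C_S / (p.g_S + p.g_IS)
    if geo == OUT_OF_PATH:
        return p.C_S / (p.g_S + p.g_ES)
    if geo in (SINGLE_PER_BRANCH, PAIRED_ON_PATH):
        return p.C_S / (p.g_S + config.N * p.g_IS)
    if geo == GLOBAL_SHUNTING:
        return p.C_S / p.g_S
    raise ValueError(f"unknown geometry {geo!r}")  # pragma: no cover


def _as_branch_vector(g, N: int, name: str) -> np.ndarray:
    g = np.atleast_1d(np.asarray(g, dtype=float))
    if g.size == 1 and N > 1:
        g = np.full(N, g[0])
    if g.size != N:
        raise ValueError(f"{name} must have length {N}, got {g.size}")
    if np.any(g < 0):
        raise ValueError(f"{name} must be non-negative")
    return g


def steady_state_soma(
    g_E,
    g_I,
    params: NeuronParams,
    config: DendriticConfig = DendriticConfig(),
) -> ResponseDecomposition:
    """Steady somatic potential and its additive/multiplicative decomposition.

    For the two-site geometries ``g_E``/``g_I`` are scalars.  For
    ``paired_on_path`` both are per-branch vectors of length N; for
    ``single_per_branch`` the two vectors together occupy the N branches
    (len(g_E) + len(g_I) == N); for ``global_shunting`` ``g_E`` is a
    per-branch vector of length N and ``g_I`` is a scalar or a vector summed
    over all peri-somatic inhibitory synapses.
    """
    p = params
    geo = config.geometry
    if geo in (ON_PATH, OUT_OF_PATH):
        gE = float(np.asarray(g_E))
        gI = float(np.asarray(g_I))
        fe = somatic_response_excitatory(gE, p, config)
        fi = somatic_response_inhibitory(gI, p, config)
        kappa = shunting_strength(p, config)
        cross = kappa * fe * fi
    elif geo == SINGLE_PER_BRANCH:
        gE = np.atleast_1d(np.asarray(g_E, dtype=float))
        gI = np.atleast_1d(np.asarray(g_I, dtype=float))
        if gE.size + gI.size != config.N:
            raise ValueError(
                f"single_per_branch needs len(g_E)+len(g_I) == N={config.N}, "
                f"got {gE.size}+{gI.size}"
            )
        if np.any(gE < 0) or np.any(gI < 0):
            raise ValueError("conductances must be non-negative")
        fe = float(np.sum(_fN(gE, p.E_E, p.g_ES, config.N, p)))
        fi = float(np.sum(_fN(gI, p.E_I, p.g_IS, config.N, p)))
        kappa, cross = 0.0, 0.0
    elif geo == PAIRED_ON_PATH:
        gE = _as_branch_vector(g_E, config.N, "g_E")
        gI = _as_branch_vector(g_I, config.N, "g_I")
        kappa = shunting_strength(p, config)
        fed = _fNd(gE, config.N, p)
        fip = _fNp(gI, config.N, p)
        fe = float(np.sum(fed))
        fi = float(np.sum(fip))
        cross = float(kappa * np.sum(fed * fip))
    elif geo == GLOBAL_SHUNTING:
        gE = _as_branch_vector(g_E, config.N, "g_E")
        gI_total = float(np.sum(np.asarray(g_I, dtype=float)))
        if gI_total < 0:
            raise ValueError("g_I must be non-negative")
        fe = float(np.sum(_fGd(gE, config.N, p)))
        fi = float(_fGp(gI_total, config.N, p))
        kappa = shunting_strength(p, config)
        cross = kappa * fe * fi
    else:  # pragma: no cover
        raise ValueError(f"unknown geometry {geo!r}")
    v = p.E_L + fe + fi + cross
    return ResponseDecomposition(f_exc=fe, f_inh=fi, kappa=kappa, cross=cross, v_steady=v)


def simulate_reduced_neuron(
    params: NeuronParams,
    config: DendriticConfig,
    g_E_trace,
    g_I_trace,
    duration: float,
    dt: float,
    threshold: float | None = None,
    reset: float | None = None,
    v0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the reduced somatic equation, optionally with spiking.

    The soma relaxes exponentially (exact exponential update per step)
    toward the instantaneous steady-state target given by the synaptic
    conductances at that step.  ``g_E_trace``/``g_I_trace`` are scalars,
    per-step series of length n_steps, or (n_steps, N) arrays for branch
    geometries.  With ``threshold`` set, crossing emits a spike and the
    potential resets to ``reset`` (default E_L).

    Returns ``(t, v, spike_times)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt))
    tau = tau_soma(params, config)
    decay = np.exp(-dt / tau)
    if reset is None:
        reset = params.E_L

    def _per_step(trace):
        a = np.asarray(trace, dtype=float)
        if a.ndim == 0:
            return lambda k: a
        return lambda k: a[k]

    getE, getI = _per_step(g_E_trace), _per_step(g_I_trace)
    v = np.empty(n + 1)
    v[0] = params.E_L if v0 is None else v0
    spikes = []
    for k in range(n):
        target = steady_state_soma(getE(k), getI(k), params, config).v_steady
        v[k + 1] = target + (v[k] - target) * decay
        if threshold is not None and v[k + 1] >= threshold:
            spikes.append((k + 1) * dt)
            v[k + 1] = reset
    return np.arange(n + 1) * dt, v, np.asarray(spikes)


def decompose_multiplicative(h, beta: float, gamma: float, g_I):
    """Exact multiplicative split of the mixed E/I term ``(h + beta*g_I)/(gamma + g_I)``.

    Returns ``(f1, f2, reconstruction)`` with ``f1 = beta*g_I/(gamma+g_I)``,
    ``f2 = h/gamma`` and ``reconstruction = f1 + f2 - f1*f2/beta``, which
    equals the mixed term identically — the algebraic core of the
    multiplicative shunting rule.
    """
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(beta == 0):
        raise ZeroDivisionError("decomposition undefined for beta = 0")
    if np.any(gamma <= 0):
        raise ValueError("gamma must be positive")
    g_I = np.asarray(g_I, dtype=float)
    if np.any(gamma + g_I <= 0):
        raise ValueError("gamma + g_I must be positive")
    h = np.asarray(h, dtype=float)
    f1 = beta * g_I / (gamma + g_I)
    f2 = h / gamma
    recon = f1 + f2 - f1 * f2 / beta
    return f1, f2, recon
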