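"""Mean-field reduction of the global-shunting spiking network.

Population-averaged synaptic conductances follow linear filters of the
population rates; the branch and peri-somatic response functions are
linearized around an operating point (f_Gd ~ a*g+b, f_Gp ~ c*G+d); rates are
threshold-linear, r_T = mu_T [J_T - beta]_+.  Self-consistency then reduces
the fixed point to one quadratic in the excitatory rate, and linear
stability to a 2x2 Jacobian whose eigenvalues are available in closed form
(lambda_1 = -1 identically).

Units: rates in Hz, conductances in nS, synaptic time constants entered in
ms but converted to seconds inside every w*tau*r product so that
g = w*tau*r is in nS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .compartmental import NeuronParams


@dataclass(frozen=True)
class MeanFieldParams:
    """Gains, linearization constants and network constants of the reduction.

    The linearization constants (a, b, c, d) may be supplied directly (the
    mode used to reproduce the reference operating point) or computed from
    the closed-form response functions via :func:`linearize_global_responses`.
    Sign conventions: a > 0, b >= 0, c < 0, d <= 0.
    """

    mu_E: float = 3.2      # Hz/mV
    mu_I: float = 6.4      # Hz/mV
    beta: float = 17.5     # rate threshold (mV)
    a: float = 0.002       # mV/nS
    b: float = 0.175       # mV
    c: float = -0.113      # mV/nS
    d: float = -0.6218     # mV
    kappa_G: float = 0.1   # mV^-1
    w_E: float = 24.0      # nS
    w_I: float = 2.0       # nS
    tau_E: float = 100.0   # ms
    tau_I: float = 10.0    # ms
    p: float = 0.1
    N_E: int = 2000
    N_I: int = 500

    def __post_init__(self) -> None:
        if self.mu_E <= 0 or self.mu_I <= 0:
            raise ValueError("gains must be positive")
        if not (self.a > 0 and self.b >= 0 and self.c < 0 and self.d <= 0):
            raise ValueError("require a > 0, b >= 0, c < 0, d <= 0")

    @property
    def tau_E_s(self) -> float:
        return self.tau_E / 1000.0

    @property
    def tau_I_s(self) -> float:
        return self.tau_I / 1000.0


@dataclass(frozen=True)
class MeanFieldSolution:
    A1: float
    A2: float
    A3: float
    A4: float
    B1: float
    B2: float
    B3: float
    r_E_bar: float       # Hz
    r_I_bar: float       # Hz
    g_E_bar: float       # nS (per-branch mean excitatory conductance)
    g_I_bar: float       # nS (mean conductance of one inhibitory synapse)
    J_bar: float         # mV
    lambda1: float
    lambda2: float
    stable: bool


def linearize_global_responses(
    neuron: NeuronParams,
    N: int,
    operating_point: tuple[float, float],
    g_ES: float | None = None,
) -> tuple[float, float, float, float]:
    """Tangent-line coefficients (a, b, c, d) of f_Gd and f_Gp.

    ``operating_point`` is (per-branch excitatory conductance, summed
    peri-somatic inhibitory conductance), both in nS.  ``g_ES`` overrides the
    dendrite-to-soma transfer conductance (the network context uses a much
    smaller value than the single-neuron default).
    """
    g0, G0 = operating_point
    if g0 < 0 or G0 < 0:
        raise ValueError("operating point must be non-negative")
    p = neuron
    g_ES = p.g_ES if g_ES is None else g_ES
    S = p.g_S + N * g_ES
    dEE = p.E_E - p.E_L
    dEI = p.E_I - p.E_L
    a = g_ES * dEE * p.g_D / ((p.g_D + g0) ** 2 * S)
    fgd0 = g_ES * g0 * dEE / ((p.g_D + g0) * S)
    b = fgd0 - a * g0
    c = dEI * S / (S + G0) ** 2
    fgp0 = G0 * dEI / (S + G0)
    d = fgp0 - c * G0
    return a, b, c, d


def meanfield_coefficients(mf: MeanFieldParams) -> tuple[float, float, float, float]:
    """Closed-form input coefficients (A1..A4) of J = A1 r_E + A2 r_I + A3 r_E r_I + A4."""
    kG = mf.kappa_G
    eE = mf.a * mf.w_E * mf.tau_E_s * mf.p * mf.N_E
    eI = mf.c * mf.w_I * mf.tau_I_s * mf.p * mf.N_I
    A1 = eE * (1.0 + mf.d * kG)
    A2 = eI * (1.0 + mf.b * kG * mf.p * mf.N_E)
    A3 = kG * eE * eI
    A4 = mf.b * mf.p * mf.N_E * (1.0 + mf.d * kG) + mf.d
    return A1, A2, A3, A4


def _input_at(mf: MeanFieldParams, r_E: float, r_I: float) -> float:
    """Mean input J (mV) at given population rates, via the linearized drive."""
    gE = mf.w_E * mf.tau_E_s * r_E
    GI = mf.N_I * mf.p * mf.w_I * mf.tau_I_s * r_I
    fgd = mf.a * gE + mf.b
    fgp = mf.c * GI + mf.d
    return mf.N_E * mf.p * fgd + fgp + mf.kappa_G * mf.N_E * mf.p * fgd * fgp


def meanfield_fixed_point(mf: MeanFieldParams) -> MeanFieldSolution:
    """Self-consistent population rates of the mean-field equations.

    Solves B3 r^2 + B2 r + B1 = 0 through the rationalized root
    r_E = 2*B1 / (-B2 + sqrt(B2^2 - 4*B1*B3)); the result is verified to be
    an admissible (non-negative, finite) root, falling back to the companion
    root when the rationalized form is degenerate.
    """
    A1, A2, A3, A4 = meanfield_coefficients(mf)
    B1 = mf.mu_E * A4 - mf.mu_E * mf.beta
    B2 = mf.mu_E * A1 + mf.mu_I * A2 - 1.0
    B3 = mf.mu_I * A3

    if B3 == 0.0:
        if B2 == 0.0:
            raise ArithmeticError("no steady state: degenerate linear system")
        r_E = -B1 / B2
    else:
        disc = B2 * B2 - 4.0 * B1 * B3
        if disc < 0:
            raise ArithmeticError("no steady state: negative discriminant")
        sq = float(np.sqrt(disc))
        denom = -B2 + sq
        roots = []
        if denom != 0.0:
            roots.append(2.0 * B1 / denom)  # canonical rationalized form
        roots.append((-B2 - sq) / (2.0 * B3))
        roots.append((-B2 + sq) / (2.0 * B3))
        r_E = next((r for r in roots if np.isfinite(r) and r >= 0), None)
        if r_E is None:
            raise ArithmeticError("no admissible rate: all roots negative")
        resid = B3 * r_E * r_E + B2 * r_E + B1
        scale = max(abs(B1), abs(B2 * r_E), abs(B3 * r_E * r_E), 1.0)
        if abs(resid) > 1e-8 * scale:
            raise ArithmeticError("fixed-point root verification failed")

    if r_E < 0 or not np.isfinite(r_E):
        raise ArithmeticError("no admissible rate")
    r_I = mf.mu_I / mf.mu_E * r_E
    g_E_bar = r_E * mf.w_E * mf.tau_E_s
    g_I_bar = r_I * mf.w_I * mf.tau_I_s
    J = _input_at(mf, r_E, r_I)

    sol = MeanFieldSolution(
        A1=A1, A2=A2, A3=A3, A4=A4, B1=B1, B2=B2, B3=B3,
        r_E_bar=float(r_E), r_I_bar=float(r_I),
        g_E_bar=float(g_E_bar), g_I_bar=float(g_I_bar), J_bar=float(J),
        lambda1=np.nan, lambda2=np.nan, stable=False,
    )
    lam1, lam2, stable = meanfield_stability(mf, sol)
    return replace(sol, lambda1=lam1, lambda2=lam2, stable=stable)


def _jacobian(mf: MeanFieldParams, g_E_bar: float, g_I_total: float) -> np.ndarray:
    """2x2 Jacobian of the conductance dynamics at the fixed point."""
    pNE, pNI = mf.p * mf.N_E, mf.p * mf.N_I
    kG = mf.kappa_G
    QE = 1.0 + kG * mf.d + kG * mf.c * g_I_total
    QI = 1.0 + kG * pNE * mf.b + kG * pNE * mf.a * g_E_bar
    return np.array(
        [
            [-1.0 + pNE * mf.w_E * mf.tau_E_s * mf.mu_E * mf.a * QE,
             pNI * mf.w_E * mf.tau_E_s * mf.mu_E * mf.c * QI],
            [pNE * mf.w_I * mf.tau_I_s * mf.mu_I * mf.a * QE,
             -1.0 + pNI * mf.c * mf.w_I * mf.tau_I_s * mf.mu_I * QI],
        ]
    )


def meanfield_stability(
    mf: MeanFieldParams, solution: MeanFieldSolution
) -> tuple[float, float, bool]:
    """Eigenvalues of the linearized rate dynamics at the fixed point.

    Returns (lambda1, lambda2, stable) from the closed forms (lambda1 = -1
    identically) and cross-checks them against a numerical
    eigen-decomposition of the Jacobian; a mismatch raises
    ``ArithmeticError``.
    """
    g_E_bar = solution.g_E_bar
    # total inhibitory conductance seen by one neuron: N_I*p afferents
    g_I_total = mf.N_I * mf.p * solution.g_I_bar
    pNE, pNI = mf.p * mf.N_E, mf.p * mf.N_I
    kG = mf.kappa_G
    lam1 = -1.0
    lam2 = (
        pNE * mf.w_E * mf.tau_E_s * mf.mu_E * mf.a
        * (1.0 + kG * mf.d + kG * mf.c * g_I_total)
        + pNI * mf.c * mf.w_I * mf.tau_I_s * mf.mu_I
        * (1.0 + kG * pNE * mf.b + kG * pNE * mf.a * g_E_bar)
        - 1.0
    )
    J = _jacobian(mf, g_E_bar, g_I_total)
    eig = np.sort(np.linalg.eigvals(J).real)
    closed = np.sort([lam1, lam2])
    scale = max(1.0, float(np.max(np.abs(closed))))
    if np.max(np.abs(eig - closed)) > 1e-9 * scale:
        raise ArithmeticError(
            f"closed-form eigenvalues {closed} disagree with numerical {eig}"
        )
    return lam1, float(lam2), bool(lam2 < 0)


def rate_sweep(mf: MeanFieldParams, w_E_values) -> pd.DataFrame:
    """Fixed-point rates and stability across a sweep of the excitatory weight.

    Rows where no admissible fixed point exists carry NaNs.
    """
    w_E_values = np.atleast_1d(np.asarray(w_E_values, dtype=float))
    if w_E_values.size == 0:
        raise ValueError("sweep must not be empty")
    rows = []
    for w in w_E_values:
        try:
            sol = meanfield_fixed_point(replace(mf, w_E=float(w)))
            rows.append((w, sol.r_E_bar, sol.r_I_bar, sol.lambda2, sol.stable))
        except ArithmeticError:
            rows.append((w, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["w_E", "r_E_bar", "r_I_bar", "lambda2", "stable"])
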