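"""Contrast-agent kinetics and dynamic DSC-MRI signal synthesis.

A gamma-variate arterial input function (with optional dispersed
recirculation) drives a two-compartment leakage model: contrast agent at
plasma concentration Cp(t) extravasates across the vessel wall with volume
transfer constant Ktrans (min⁻¹) into the extravascular extracellular space
(EES, volume fraction ve), where its concentration Ce obeys

    ve · dCe/dt = Ktrans · (Cp − Ce)      ⇒
    Ce(t) = (Ktrans/ve) ∫₀ᵗ Cp(τ) · exp(−(Ktrans/ve)(t−τ)) dτ.

Concentration maps to a susceptibility shift Δχ = χm·C (χm the molar
susceptibility of the agent) and to relaxation changes 1/T1 = 1/T10 + r1·C,
1/T2* = 1/T20* + r2·C.  At each imaging time point the agent is assumed
well-mixed within each compartment; the vessel-vs-EES susceptibility
difference is χm·(Cp − Ce) and the cell-vs-EES difference is −χm·Ce (cells
contain no agent).  The dynamic signal S/S0 is synthesized by computing the
superposed field, per-compartment steady-state spoiled-GE longitudinal
weighting w = (1 − E1)·sinα / (1 − E1·cosα), and one transverse evolution
over TE per time point with the finite-difference solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bloch_fdm import (
    SequenceParams,
    build_transition_matrix,
    evolve,
    phase_relax_vector,
)
from .fieldmap import CGS_TO_SI, FieldMap, compute_field, perturber_kernel
from .geometry import LABEL_CELL, LABEL_EES, LABEL_VASCULAR, TissueModel

__all__ = [
    "KineticParams",
    "ConcentrationCurves",
    "RelaxationParams",
    "generate_aif",
    "ees_concentration",
    "concentration_curves",
    "concentration_to_dchi",
    "relaxation_update",
    "spoiled_ge_weight",
    "dsc_signal_timeseries",
]

#: molar susceptibility of Gd-DTPA per mM, Gaussian-cgs volume units
#: (multiply by fieldmap.CGS_TO_SI when driving the SI dipole kernel)
CHI_M = 0.027e-6


@dataclass
class KineticParams:
    """Two-compartment leakage kinetics plus AIF shape parameters.

    The AIF first pass is a gamma-variate A·(t−t0)^α·exp(−(t−t0)/β) scaled so
    its peak equals ``peak_mM``; a recirculation term adds the first pass
    convolved with an exponential tail of time constant ``recirc_tau_s``,
    weighted by ``recirc_fraction``.  A slow equilibrium component
    (``steady_fraction`` of the peak, rising over ``steady_rise_s`` and
    decaying with the renal-clearance constant ``steady_decay_s``) keeps the
    plasma level at a few tenths of a mM for many minutes after the bolus,
    as measured single-dose curves do — without it the agent would vanish
    from the tissue within two minutes and no late leakage effects could
    exist.
    """

    Ktrans: float = 0.2  # min⁻¹
    ve: float = 0.2
    vp: float = 0.04
    arrival_s: float = 20.0
    alpha: float = 3.0
    beta_s: float = 4.0
    peak_mM: float = 6.0
    recirc_fraction: float = 0.25
    recirc_tau_s: float = 90.0
    steady_fraction: float = 0.095
    steady_rise_s: float = 60.0
    steady_decay_s: float = 3000.0
    duration_min: float = 9.0
    n_timepoints: int = 150

    def __post_init__(self):
        if self.Ktrans < 0:
            raise ValueError("Ktrans must be ≥ 0")
        if self.Ktrans > 0 and not 0 < self.ve <= 1:
            raise ValueError("ve must be in (0, 1] when Ktrans > 0")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if self.alpha <= 0 or self.beta_s <= 0:
            raise ValueError("gamma-variate shape parameters must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.linspace(0.0, self.duration_min * 60.0, self.n_timepoints)


@dataclass
class ConcentrationCurves:
    t: np.ndarray  # s
    Cp: np.ndarray  # mM, plasma
    Ce: np.ndarray  # mM, EES


@dataclass
class RelaxationParams:
    """Baseline relaxation times (ms) and contrast-agent relaxivities."""

    T10: float = 1000.0  # ms
    T20_star: float = 50.0  # ms
    r1: float = 3.9  # mM⁻¹ s⁻¹
    r2: float = 5.3  # mM⁻¹ s⁻¹
    chi_m: float = CHI_M  # mM⁻¹

    def __post_init__(self):
        if min(self.T10, self.T20_star, self.r1, self.r2, self.chi_m) <= 0:
            raise ValueError("relaxation parameters must be positive")


def generate_aif(params: KineticParams, times: np.ndarray | None = None) -> np.ndarray:
    """Plasma concentration curve Cp(t) in mM at the given times (s)."""
    t = params.times_s if times is None else np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("times must ascend from 0")
    tau = t - params.arrival_s
    first = np.zeros_like(t)
    pos = tau > 0
    first[pos] = tau[pos] ** params.alpha * np.exp(-tau[pos] / params.beta_s)
    peak = (params.alpha * params.beta_s) ** params.alpha * np.exp(-params.alpha)
    first *= params.peak_mM / peak
    if params.recirc_fraction > 0:
        # dispersed recirculation: first pass convolved with an exponential tail
        dt = np.gradient(t)
        kern = np.exp(-t / params.recirc_tau_s) / params.recirc_tau_s
        rc = np.convolve(first, kern)[: len(t)] * dt
        first = first + params.recirc_fraction * rc
    if params.steady_fraction > 0:
        steady = np.zeros_like(t)
        steady[pos] = (
            params.steady_fraction
            * params.peak_mM
            * (1.0 - np.exp(-tau[pos] / params.steady_rise_s))
            * np.exp(-tau[pos] / params.steady_decay_s)
        )
        first = first + steady
    return first


def ees_concentration(
    Cp: np.ndarray, Ktrans: float, ve: float, times: np.ndarray
) -> np.ndarray:
    """EES concentration Ce(t) from the two-compartment leakage model.

    Evaluates Ce(t) = kep·∫Cp(τ)e^{−kep(t−τ)}dτ (kep = Ktrans/ve, Ktrans
    converted from min⁻¹ to s⁻¹) with an exact recursion for piecewise-linear
    Cp, so the result matches adaptive ODE integration to high precision.
    """
    Cp = np.asarray(Cp, dtype=float)
    t = np.asarray(times, dtype=float)
    if Ktrans == 0:
        return np.zeros_like(Cp)
    if ve <= 0:
        raise ValueError("ve must be positive when Ktrans > 0")
    kep = (Ktrans / 60.0) / ve  # s⁻¹
    Ce = np.zeros_like(Cp)
    for i in range(len(t) - 1):
        h = t[i + 1] - t[i]
        E = np.exp(-kep * h)
        c0, m = Cp[i], (Cp[i + 1] - Cp[i]) / h
        # ∫₀ʰ (c0 + m·s)·e^{−kep(h−s)} ds, times kep
        I0 = (1.0 - E) / kep
        I1 = h / kep - (1.0 - E) / kep**2
        Ce[i + 1] = Ce[i] * E + kep * (c0 * I0 + m * I1)
    return Ce


def concentration_curves(params: KineticParams) -> ConcentrationCurves:
    """AIF and EES curves on the parameter object's time grid."""
    t = params.times_s
    Cp = generate_aif(params, t)
    Ce = ees_concentration(Cp, params.Ktrans, params.ve, t)
    return ConcentrationCurves(t, Cp, Ce)


def concentration_to_dchi(C: float | np.ndarray, chi_m: float = CHI_M):
    """Susceptibility shift Δχ = χm·C for agent concentration C (mM)."""
    return chi_m * np.asarray(C) if np.ndim(C) else chi_m * C


def relaxation_update(params: RelaxationParams, C: float) -> tuple[float, float]:
    """(T1, T2*) in ms for a compartment holding concentration C (mM)."""
    if C < 0:
        raise ValueError("concentration must be ≥ 0")
    R1 = 1.0 / params.T10 + params.r1 * C * 1e-3  # ms⁻¹
    R2 = 1.0 / params.T20_star + params.r2 * C * 1e-3
    return 1.0 / R1, 1.0 / R2


def spoiled_ge_weight(T1: float, TR: float, flip_angle_deg: float) -> float:
    """Steady-state longitudinal weighting of a spoiled gradient echo."""
    E1 = np.exp(-TR / T1)
    a = np.deg2rad(flip_angle_deg)
    return (1.0 - E1) * np.sin(a) / (1.0 - E1 * np.cos(a))


def dsc_signal_timeseries(
    model: TissueModel,
    curves: ConcentrationCurves,
    relax: RelaxationParams,
    seq: SequenceParams,
    B0: float = 3.0,
    D: float = 1.3,
    Pm: float = 0.0,
    pad_fraction: float = 0.1,
    B0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0),
    intravascular_r2: bool = True,
    return_field_std: bool = False,
):
    """Dynamic DSC-MRI signal ratio S(t)/S0 for a labeled tissue structure.

    Per time point: (1) vessel-vs-EES Δχ = χm·(Cp−Ce) and cell-vs-EES
    Δχ = −χm·Ce set the superposed field; (2) per-compartment T1 and T2* come
    from the local concentration (vessels see Cp, EES sees Ce, cells none);
    (3) the spoiled-GE steady-state weight is applied as initial per-voxel
    magnetization; (4) the magnetization evolves over one TE and the echo
    signal is normalized to the pre-contrast (C = 0) run.

    ``D`` in µm²/ms.  Returns the S/S0 array (and the field-shift standard
    deviation per time point when ``return_field_std``).
    """
    labels = model.labels
    n = model.grid_shape[0]
    kernel = perturber_kernel(n, model.voxel_size, B0_direction, pad_fraction)
    # unit-susceptibility fields; scaled per time point by linearity
    unit_vessel = compute_field(model, LABEL_VASCULAR, 1.0, B0, kernel).dB
    unit_cell = compute_field(model, LABEL_CELL, 1.0, B0, kernel).dB
    A = build_transition_matrix(model, D, Pm=Pm, dt=seq.dt)

    flat = labels.ravel()
    is_v = flat == LABEL_VASCULAR
    is_c = flat == LABEL_CELL
    is_e = flat == LABEL_EES

    # χm is quoted in cgs volume-susceptibility units; the kernel is SI
    chi_si = CGS_TO_SI * relax.chi_m

    def echo_signal(Cp_i: float, Ce_i: float) -> tuple[float, float]:
        dB = unit_vessel * (chi_si * (Cp_i - Ce_i)) + unit_cell * (-chi_si * Ce_i)
        T1_v, T2_v = relaxation_update(relax, Cp_i)
        if not intravascular_r2:
            T2_v = relax.T20_star
        T1_e, T2_e = relaxation_update(relax, Ce_i)
        T1_c, T2_c = relax.T10, relax.T20_star
        T2_map = np.empty(flat.size)
        T2_map[is_v] = T2_v
        T2_map[is_e] = T2_e
        T2_map[is_c] = T2_c
        M0 = np.empty(flat.size)
        M0[is_v] = spoiled_ge_weight(T1_v, seq.TR, seq.flip_angle)
        M0[is_e] = spoiled_ge_weight(T1_e, seq.TR, seq.flip_angle)
        M0[is_c] = spoiled_ge_weight(T1_c, seq.TR, seq.flip_angle)
        phi = phase_relax_vector(dB, T2_map, seq.dt)
        tc = evolve(A, phi, seq, M0=M0)
        # at_echo is normalized to Σ M0; undo to keep the T1 weighting in S
        return tc.at_echo * M0.sum(), float(dB.std())

    S0, _ = echo_signal(0.0, 0.0)
    ratios = np.empty(len(curves.t))
    stds = np.empty(len(curves.t))
    for i, (cp, ce) in enumerate(zip(curves.Cp, curves.Ce)):
        S, stds[i] = echo_signal(float(cp), float(ce))
        ratios[i] = S / S0
    if return_field_std:
        return ratios, stds
    return ratios
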