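"""Monte-Carlo random-walk reference solver.

Tracks an ensemble of spins performing Brownian motion through the periodic
tissue box, accumulating phase from the local field shift.  This is the
classical approach the matrix finite-difference solver replaces; it serves
here as an independent cross-validation oracle.

Each step a spin takes a Gaussian displacement with per-axis standard
deviation √(2·D·Δt).  With impermeable membranes (Pm = 0) a step that would
change compartment is rejected elastically (the spin keeps its previous
position).  Phase accrues as γ·ΔB(x)·Δt with nearest-voxel field lookup
(trilinear interpolation optional); spin echo negates all phases at TE/2.
The signal is |⟨exp(iφ)⟩|·exp(−TE/T2) for a uniform T2.
"""

from __future__ import annotations

import numpy as np

from .bloch_fdm import SequenceParams, delta_r2
from .fieldmap import GAMMA, FieldMap
from .geometry import TissueModel

__all__ = ["run_walk", "mc_delta_r2"]


def _lookup_nearest(values: np.ndarray, pos: np.ndarray, voxel_size: float) -> np.ndarray:
    n = values.shape[0]
    idx = np.floor(pos / voxel_size).astype(np.int64) % n
    return values[idx[:, 0], idx[:, 1], idx[:, 2]]


def _lookup_trilinear(values: np.ndarray, pos: np.ndarray, voxel_size: float) -> np.ndarray:
    n = values.shape[0]
    g = pos / voxel_size - 0.5  # voxel centers at (i + 0.5)·Δx
    i0 = np.floor(g).astype(np.int64)
    f = g - i0
    out = np.zeros(len(pos))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                out += w * values[
                    (i0[:, 0] + dx) % n, (i0[:, 1] + dy) % n, (i0[:, 2] + dz) % n
                ]
    return out


def run_walk(
    model: TissueModel,
    fieldmap: FieldMap,
    n_spins: int,
    D: float,
    seq: SequenceParams,
    Pm: float = np.inf,
    T2: float = np.inf,
    seed: int = 0,
    interpolation: str = "nearest",
    return_timecourse: bool = False,
):
    """Random-walk MR signal at the echo (optionally the full timecourse).

    Returns the scalar signal magnitude at TE, or ``(signal, timecourse)``
    when ``return_timecourse`` is set.  ``D`` in µm²/ms, ``Pm`` in µm/ms;
    only the limits are meaningful for the rejection scheme: Pm = 0 rejects
    every compartment change elastically (fully restricted) and Pm = np.inf
    lets walkers cross freely (perturbers as susceptibility sources only).
    """
    if n_spins < 1:
        raise ValueError("need at least one spin")
    if model.grid_shape != fieldmap.dB.shape:
        raise ValueError("tissue model and field map grids differ")
    rng = np.random.default_rng(seed)
    box = model.box_size
    vs = model.voxel_size
    lookup = _lookup_trilinear if interpolation == "trilinear" else _lookup_nearest
    labels = model.labels

    pos = rng.uniform(0, box, (n_spins, 3))
    comp = _lookup_nearest(labels, pos, vs)
    phase = np.zeros(n_spins)
    n_steps = seq.n_steps
    invert_at = n_steps // 2 if seq.echo_type == "SE" else -1
    sigma = np.sqrt(2.0 * D * seq.dt)
    impermeable = Pm == 0.0

    S = np.empty(n_steps + 1, dtype=complex) if return_timecourse else None
    if return_timecourse:
        S[0] = np.mean(np.exp(1j * phase))
    for step in range(1, n_steps + 1):
        if sigma > 0:
            trial = np.mod(pos + rng.normal(0.0, sigma, (n_spins, 3)), box)
            if impermeable:
                new_comp = _lookup_nearest(labels, trial, vs)
                crossed = new_comp != comp
                trial[crossed] = pos[crossed]  # elastic rejection
            else:
                comp = _lookup_nearest(labels, trial, vs)
            pos = trial
        phase += GAMMA * lookup(fieldmap.dB, pos, vs) * seq.dt
        if step == invert_at:
            phase = -phase
        if return_timecourse:
            S[step] = np.mean(np.exp(1j * phase))
    decay = np.exp(-seq.TE / T2) if np.isfinite(T2) else 1.0
    signal = float(np.abs(np.mean(np.exp(1j * phase))) * decay)
    if return_timecourse:
        t = np.arange(n_steps + 1) * seq.dt
        return signal, (t, S * decay)
    return signal


def mc_delta_r2(S_pre: float, S_post: float, TE: float) -> float:
    """ΔR2 in s⁻¹ from pre/post signals at the echo (same formula as the FDM)."""
    return delta_r2(S_pre, S_post, TE)
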