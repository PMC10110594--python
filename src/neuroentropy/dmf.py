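"""Neuromodulated dynamic mean-field model on a structural connectome.

Each region couples an excitatory (NMDA-mediated) and an inhibitory
(GABA-A-mediated) neural mass. Regions interact through their excitatory
populations only, weighted by the connectome and the global coupling ``G``.
Serotonin-2A receptor activation is modelled as a response-gain modulation of
the frequency-current (F-I) curve of both populations: region ``n`` gets gain

    g_nm_n = 1 + s_nm * density_n

Feedback inhibitory control (FIC) tunes the per-region inhibitory weight
``J_fic`` so that every excitatory population fires near the 3 Hz set-point
in the placebo condition; the 5HT2A condition then perturbs that calibrated
brain without re-calibrating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from ._kernels import run_dmf
from .params import (
    Connectome,
    InvalidParameterError,
    ModelParameters,
    ReceptorMap,
    validate_pair,
)

__all__ = [
    "Condition",
    "SimulationState",
    "FiringRateSeries",
    "CalibrationResult",
    "CalibrationError",
    "SimulationDivergedError",
    "neuromod_gain",
    "transfer_rate",
    "compute_currents",
    "em_step",
    "calibrate_fic",
    "simulate",
]

Condition = Literal["placebo", "5ht2a"]


class CalibrationError(RuntimeError):
    """FIC calibration failed to converge; carries the worst deviation (Hz)."""

    def __init__(self, message: str, worst_deviation: float):
        super().__init__(message)
        self.worst_deviation = worst_deviation


class SimulationDivergedError(RuntimeError):
    """The integrated state became non-finite; carries the offending step."""

    def __init__(self, step: int):
        super().__init__(f"simulation diverged (non-finite state) at step {step}")
        self.step = step


def _normalise_condition(condition: str) -> str:
    c = condition.lower()
    if c in ("placebo", "pla"):
        return "placebo"
    if c in ("5ht2a", "5-ht2a", "5ht2a-r"):
        return "5ht2a"
    raise InvalidParameterError(f"unknown condition: {condition!r}")


def neuromod_gain(s_nm: float, density: np.ndarray) -> np.ndarray:
    """Neuromodulatory response gain, ``1 + s_nm * density`` elementwise.

    ``s_nm`` scales regional receptor density into a multiplicative gain on
    the F-I curve; with ``s_nm = 0`` (placebo) every gain is exactly 1.
    """
    density = np.asarray(density, dtype=float)
    if s_nm < 0:
        raise InvalidParameterError("s_nm must be >= 0")
    if np.any(density < 0):
        raise InvalidParameterError("receptor densities must be >= 0")
    return 1.0 + s_nm * density


def transfer_rate(
    I: np.ndarray | float,
    population: Literal["E", "I"],
    g_nm: np.ndarray | float = 1.0,
    params: ModelParameters | None = None,
) -> np.ndarray | float:
    """F-I curve: firing rate (Hz) of a population given its input current.

    ``F(I) = y / (1 - exp(-d*y))`` with ``y = g_nm * g * (I - I_thr)``; the
    removable singularity at ``y = 0`` is filled with its limit ``1/d``.
    Strictly increasing in ``I`` and nonnegative.
    """
    p = params or ModelParameters()
    if population == "E":
        g, d, thr = p.g_E, p.d_E, p.I_thr_E
    elif population == "I":
        g, d, thr = p.g_I, p.d_I, p.I_thr_I
    else:
        raise InvalidParameterError(f"population must be 'E' or 'I', got {population!r}")
    y = np.asarray(g_nm, dtype=float) * g * (np.asarray(I, dtype=float) - thr)
    z = d * y
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(np.abs(z) < 1e-9, 1.0 / d + 0.5 * y, y / (1.0 - np.exp(-z)))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class SimulationState:
    """Instantaneous model state: gating variables, FIC weights, RNG state."""

    S_E: np.ndarray
    S_I: np.ndarray
    J_fic: np.ndarray
    rng_state: dict

    def __post_init__(self) -> None:
        for name in ("S_E", "S_I", "J_fic"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (np.all(self.S_E >= 0) and np.all(self.S_E <= 1)):
            raise InvalidParameterError("S_E must lie in [0, 1]")
        if not (np.all(self.S_I >= 0) and np.all(self.S_I <= 1)):
            raise InvalidParameterError("S_I must lie in [0, 1]")
        if np.any(self.J_fic <= 0):
            raise InvalidParameterError("J_fic must be > 0")

    @classmethod
    def initial(cls, J_fic: np.ndarray, seed: int, s0: float = 0.1) -> "SimulationState":
        n = len(J_fic)
        rng = np.random.default_rng(seed)
        return cls(
            S_E=np.full(n, s0),
            S_I=np.full(n, s0),
            J_fic=np.asarray(J_fic, dtype=float),
            rng_state=rng.bit_generator.state,
        )


@dataclass(frozen=True)
class FiringRateSeries:
    """Recorded excitatory firing rates: T x N matrix (Hz) for one condition."""

    rates: np.ndarray
    sampling_dt: float
    condition_tag: str

    @property
    def n_regions(self) -> int:
        return self.rates.shape[1]


def compute_currents(
    state: SimulationState,
    connectome: Connectome,
    params: ModelParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Input currents (nA) to the excitatory and inhibitory populations.

    The excitatory current combines the external drive, local recurrence,
    long-range excitation through the connectome, and feedback inhibition;
    the inhibitory current receives no long-range term.
    """
    S_E, S_I = state.S_E, state.S_I
    n = connectome.n_regions
    if len(S_E) != n or len(S_I) != n or len(state.J_fic) != n:
        raise InvalidParameterError("state dimension does not match connectome")
    p = params
    I_E = (
        p.W_E * p.I0
        + p.w_plus * p.J_NMDA * S_E
        + p.G * p.J_NMDA * (connectome.weights @ S_E)
        - state.J_fic * S_I
    )
    I_I = p.W_I * p.I0 + p.J_NMDA * S_E - S_I
    return I_E, I_I


def em_step(
    state: SimulationState,
    connectome: Connectome,
    receptor_map: ReceptorMap | None,
    params: ModelParameters,
    condition: str = "placebo",
) -> SimulationState:
    """Advance the gating variables one Euler-Maruyama step of ``dt`` ms.

    Drifts follow the gating equations (rates converted from Hz to spikes/ms);
    independent Gaussian increments are scaled by ``sigma*sqrt(dt)`` per
    gating variable, then both vectors are clipped to [0, 1].
    """
    p = params
    cond = _normalise_condition(condition)
    if cond == "5ht2a":
        if receptor_map is None:
            raise InvalidParameterError("5ht2a condition requires a receptor map")
        validate_pair(connectome, receptor_map)
        gain = neuromod_gain(p.s_nm, receptor_map.density)
    else:
        gain = np.ones(connectome.n_regions)

    I_E, I_I = compute_currents(state, connectome, params)
    r_E = transfer_rate(I_E, "E", gain, p)
    r_I = transfer_rate(I_I, "I", gain, p)

    rng = np.random.default_rng()
    rng.bit_generator.state = state.rng_state
    sq = p.sigma * np.sqrt(p.dt)
    dS_E = -state.S_E / p.tau_NMDA + (1.0 - state.S_E) * p.gamma_kin * r_E * 1e-3
    dS_I = -state.S_I / p.tau_GABA + r_I * 1e-3
    S_E = np.clip(state.S_E + p.dt * dS_E + sq * rng.standard_normal(len(r_E)), 0, 1)
    S_I = np.clip(state.S_I + p.dt * dS_I + sq * rng.standard_normal(len(r_I)), 0, 1)
    return SimulationState(
        S_E=S_E, S_I=S_I, J_fic=state.J_fic, rng_state=rng.bit_generator.state
    )


def _fixed_point_targets(params: ModelParameters) -> tuple[float, float, float]:
    """Uncoupled placebo fixed point at the FIC set-point.

    Returns (S_E*, S_I*, I_E*): the excitatory gating and current consistent
    with the target rate, and the inhibitory gating solving its own
    self-consistency at that excitatory level. Used to warm-start the FIC
    calibration.
    """
    p = params
    r = p.target_rate
    gr = p.gamma_kin * r * p.tau_NMDA * 1e-3
    s_e = gr / (1.0 + gr)

    # invert the excitatory F-I curve at the target rate
    def f_inv(y):
        return transfer_rate(p.I_thr_E + y / p.g_E, "E", 1.0, p) - r

    y = brentq(f_inv, -200.0, 200.0)
    i_e = p.I_thr_E + y / p.g_E

    def g(s_i):
        i_i = p.W_I * p.I0 + p.J_NMDA * s_e - s_i
        return transfer_rate(i_i, "I", 1.0, p) * p.tau_GABA * 1e-3 - s_i

    s_i = brentq(g, 0.0, 1.0)
    return s_e, s_i, i_e


def _run_kernel(
    connectome: Connectome,
    J_fic: np.ndarray,
    gain: np.ndarray,
    params: ModelParameters,
    t_total: float,
    seed: int,
    S_E0: np.ndarray | None = None,
    S_I0: np.ndarray | None = None,
):
    p = params
    n = connectome.n_regions
    n_steps = int(round(t_total * 1000.0 / p.dt))
    record_every = int(round(p.record_dt / p.dt))
    if S_E0 is None:
        S_E0 = np.full(n, 0.1)
    if S_I0 is None:
        S_I0 = np.full(n, 0.1)
    rates, S_E, S_I, bad = run_dmf(
        np.ascontiguousarray(connectome.weights, dtype=np.float64),
        np.asarray(J_fic, dtype=np.float64),
        np.asarray(gain, dtype=np.float64),
        np.asarray(gain, dtype=np.float64),
        np.asarray(S_E0, dtype=np.float64),
        np.asarray(S_I0, dtype=np.float64),
        p.I0, p.W_E, p.W_I, p.w_plus, p.J_NMDA, p.G,
        p.I_thr_E, p.I_thr_I, p.g_E, p.g_I, p.d_E, p.d_I,
        p.gamma_kin, p.sigma, p.tau_NMDA, p.tau_GABA,
        p.dt, n_steps, record_every, int(seed) % (2**31),
    )
    if bad >= 0:
        raise SimulationDivergedError(bad)
    return rates, S_E, S_I


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the FIC calibration: weights and achieved placebo rates."""

    J_fic: np.ndarray
    achieved_rates: np.ndarray
    n_iter: int
    tol: float


def _invert_fi_excitatory(rate: float, params: ModelParameters) -> float:
    """Inverse of the unit-gain excitatory F-I curve, in y = g_E*(I - I_thr)."""
    return brentq(
        lambda y: transfer_rate(params.I_thr_E + y / params.g_E, "E", 1.0, params)
        - rate,
        -500.0,
        500.0,
    )


def calibrate_fic(
    connectome: Connectome,
    receptor_map: ReceptorMap | None = None,
    params: ModelParameters | None = None,
    tol: float = 0.5,
    max_iter: int = 80,
    eta: float = 0.75,
    t_window: float = 10.0,
    t_window_burn: float = 2.0,
) -> CalibrationResult:
    """Tune per-region feedback inhibition to the placebo rate set-point.

    Iterative balancing: simulate a placebo calibration window, measure each
    region's time-averaged excitatory rate, and correct its inhibitory weight
    by the equivalent input-current error — the measured mean rate is mapped
    back through the inverse F-I curve and compared with the current that
    produces the target rate, a Newton-style step that stays well conditioned
    when rates saturate near zero. The per-region step size ``eta_n`` halves
    whenever a region's deviation changes sign. Convergence is declared when
    every deviation, re-measured on a doubled confirmation window, is within
    ``tol`` (Hz) of the target. Calibration always runs in the placebo
    condition: the receptor map (if given) only validates dimensions, and
    the calibrated weights are held fixed under 5HT2A activation.
    """
    p = params or ModelParameters()
    validate_pair(connectome, receptor_map)
    n = connectome.n_regions
    gain = np.ones(n)

    s_e, s_i, i_e = _fixed_point_targets(p)
    strength = connectome.strength()
    J = (
        p.W_E * p.I0
        + p.w_plus * p.J_NMDA * s_e
        + p.G * p.J_NMDA * strength * s_e
        - i_e
    ) / s_i
    J = np.maximum(J, 1e-3)

    y_target = _invert_fi_excitatory(p.target_rate, p)
    rate_floor = 0.02  # Hz; keeps the inverse F-I finite for silent regions
    eta_n = np.full(n, eta)
    prev_sign = np.zeros(n)
    burn_rec = int(round(t_window_burn * 1000.0 / p.record_dt))
    worst = np.inf
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None

    for it in range(1, max_iter + 1):
        confirm = worst <= 0.7 * tol  # candidate: re-measure on a longer window
        t_sim = t_window * (4.0 if confirm else 1.0)
        seed = (p.seed * 1000003 + it) % (2**31)
        rates, _, _ = _run_kernel(
            connectome, J, gain, p, t_sim + t_window_burn, seed,
            S_E0=np.full(n, s_e), S_I0=np.full(n, s_i),
        )
        rates_mean = rates[burn_rec:].mean(axis=0)
        delta = rates_mean - p.target_rate
        worst = float(np.max(np.abs(delta)))
        if confirm:
            if worst <= 0.5 * tol:
                return CalibrationResult(
                    J_fic=J, achieved_rates=rates_mean, n_iter=it, tol=tol
                )
            if best is None or worst < best[0]:
                best = (worst, J.copy(), rates_mean.copy(), it)
        y_measured = np.array(
            [_invert_fi_excitatory(max(r, rate_floor), p) for r in rates_mean]
        )
        current_error = (y_measured - y_target) / p.g_E  # nA
        sign = np.sign(delta)
        eta_n[(sign * prev_sign) < 0] *= 0.5
        np.maximum(eta_n, 0.02, out=eta_n)
        prev_sign = sign
        J = np.maximum(J + eta_n * current_error / s_i, 1e-3)

    # iterations exhausted: the best confirmed state may still honour the
    # documented tolerance even though the stricter early-exit gate did not
    if best is not None and best[0] <= tol:
        return CalibrationResult(
            J_fic=best[1], achieved_rates=best[2], n_iter=max_iter, tol=tol
        )
    raise CalibrationError(
        f"FIC calibration did not converge within {max_iter} iterations "
        f"(worst deviation {worst:.3f} Hz)",
        worst_deviation=(best[0] if best is not None else worst),
    )


def simulate(
    connectome: Connectome,
    receptor_map: ReceptorMap | None,
    params: ModelParameters,
    J_fic: np.ndarray,
    condition: str,
    seed: int | None = None,
) -> FiringRateSeries:
    """Simulate one condition and return burn-in-free excitatory rates.

    The placebo condition runs with unit gains; the 5HT2A condition applies
    the receptor-density-dependent gain to both populations. ``J_fic`` must
    come from a prior placebo calibration. Output has
    ``floor((t_total - t_burn)/record_dt)`` samples per region.
    """
    p = params
    cond = _normalise_condition(condition)
    if cond == "5ht2a":
        if receptor_map is None:
            raise InvalidParameterError("5ht2a condition requires a receptor map")
        validate_pair(connectome, receptor_map)
        gain = neuromod_gain(p.s_nm, receptor_map.density)
    else:
        gain = np.ones(connectome.n_regions)

    rates, _, _ = _run_kernel(
        connectome, J_fic, gain, p, p.t_total, seed if seed is not None else p.seed
    )
    n_burn = int(round(p.t_burn * 1000.0 / p.record_dt))
    kept = rates[n_burn : n_burn + p.n_samples]
    return FiringRateSeries(rates=kept, sampling_dt=p.record_dt, condition_tag=cond)
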