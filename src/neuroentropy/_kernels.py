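"""Numba-compiled integration kernel for the DMF equations.

The model is integrated with the Euler-Maruyama scheme at step ``dt`` (ms).
Rates from the F-I curve are in Hz while time constants are in ms, so the
rate terms in the gating drifts carry a factor 1e-3 (spikes per ms). Gaussian
increments are independent per gating variable and scaled by sigma*sqrt(dt);
gating variables are clipped to [0, 1] after every step.
"""

import numpy as np
from numba import njit

__all__ = ["run_dmf"]


@njit(cache=True)
def _fi(y, d):
    """F-I curve y / (1 - exp(-d*y)) with the removable singularity at y=0."""
    z = d * y
    if np.abs(z) < 1e-9:
        # limit 1/d, first-order correction y/2
        return 1.0 / d + 0.5 * y
    return y / (1.0 - np.exp(-z))


@njit(cache=True)
def run_dmf(
    C,            # (N, N) connectome weights
    J_fic,        # (N,) feedback inhibitory weights (nA)
    gain_E,       # (N,) neuromodulatory gain on excitatory F-I (>= 1)
    gain_I,       # (N,) neuromodulatory gain on inhibitory F-I (>= 1)
    S_E0, S_I0,   # (N,) initial gating variables
    I0, W_E, W_I, w_plus, J_NMDA, G,
    I_thr_E, I_thr_I, g_E, g_I, d_E, d_I,
    gamma_kin, sigma, tau_NMDA, tau_GABA,
    dt,           # integration step (ms)
    n_steps,      # total integration steps
    record_every, # record instantaneous excitatory rates every this many steps
    seed,
):
    """Integrate the DMF equations; return recorded excitatory rates.

    Returns
    -------
    rates : (n_steps // record_every, N) recorded excitatory rates (Hz)
    S_E, S_I : final gating vectors
    bad_step : -1 if the state stayed finite, else the step index at which a
        non-finite value was first recorded.
    """
    np.random.seed(seed)
    N = C.shape[0]
    n_rec = n_steps // record_every

    S_E = S_E0.copy()
    S_I = S_I0.copy()
    rates = np.empty((n_rec, N))
    sq = sigma * np.sqrt(dt)
    bad_step = -1

    rec = 0
    for step in range(1, n_steps + 1):
        CS = C @ S_E
        xi_E = np.random.standard_normal(N)
        xi_I = np.random.standard_normal(N)
        for n in range(N):
            I_E = (
                W_E * I0
                + w_plus * J_NMDA * S_E[n]
                + G * J_NMDA * CS[n]
                - J_fic[n] * S_I[n]
            )
            I_I = W_I * I0 + J_NMDA * S_E[n] - S_I[n]
            r_E = _fi(gain_E[n] * g_E * (I_E - I_thr_E), d_E)
            r_I = _fi(gain_I[n] * g_I * (I_I - I_thr_I), d_I)
            # drifts per ms; rates converted from Hz to spikes/ms
            dS_E = -S_E[n] / tau_NMDA + (1.0 - S_E[n]) * gamma_kin * r_E * 1e-3
            dS_I = -S_I[n] / tau_GABA + r_I * 1e-3
            S_E[n] = min(max(S_E[n] + dt * dS_E + sq * xi_E[n], 0.0), 1.0)
            S_I[n] = min(max(S_I[n] + dt * dS_I + sq * xi_I[n], 0.0), 1.0)
            if step % record_every == 0:
                rates[rec, n] = r_E
        if step % record_every == 0:
            for n in range(N):
                if not np.isfinite(rates[rec, n]):
                    bad_step = step
                    return rates[: rec + 1], S_E, S_I, bad_step
            rec += 1

    return rates, S_E, S_I, bad_step
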