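"""Model parameters and core domain containers.

The dynamic mean-field (DMF) model describes each brain region as a pair of
coupled excitatory/inhibitory neural-mass populations, linked across regions
through a weighted structural connectome. :class:`ModelParameters` collects
the biophysical constants of the neural masses (synaptic couplings, F-I curve
constants, time constants), the global coupling ``G``, the neuromodulatory
gain scaling ``s_nm`` that converts regional serotonin-2A receptor density
into a multiplicative response gain, and the integration settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "Connectome",
    "ReceptorMap",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """Raised when a model parameter or input violates its domain."""


@dataclass(frozen=True)
class ModelParameters:
    """Biophysical and numerical parameters of the neuromodulated DMF model.

    Defaults are the standard parameterisation of the model: currents in nA,
    rates in Hz, time constants and integration step in ms, durations in
    seconds. ``G`` (global coupling) and ``s_nm`` (neuromodulatory gain per
    unit receptor density) default to the values used for 5HT2A-R agonism
    studies, 2.4 and 0.025.
    """

    I0: float = 0.382          # external current (nA)
    W_E: float = 1.0           # excitatory scaling of I0
    W_I: float = 0.7           # inhibitory scaling of I0
    w_plus: float = 1.4        # local excitatory recurrence
    J_NMDA: float = 0.15       # excitatory synaptic coupling (nA)
    I_thr_E: float = 0.403     # excitatory F-I threshold (nA)
    I_thr_I: float = 0.288     # inhibitory F-I threshold (nA)
    g_E: float = 310.0         # excitatory gain (1/nC)
    g_I: float = 615.0         # inhibitory gain (1/nC)
    d_E: float = 0.16          # excitatory F-I shape constant (s)
    d_I: float = 0.087         # inhibitory F-I shape constant (s)
    gamma_kin: float = 0.641   # excitatory kinetic parameter
    sigma: float = 0.01        # noise amplitude (nA)
    tau_NMDA: float = 100.0    # NMDA time constant (ms)
    tau_GABA: float = 10.0     # GABA-A time constant (ms)
    G: float = 2.4             # global coupling
    s_nm: float = 0.025        # neuromodulatory gain scaling
    dt: float = 0.1            # integration step (ms)
    t_total: float = 120.0     # simulated duration (s)
    t_burn: float = 20.0       # discarded duration (s)
    record_dt: float = 1.0     # sampling interval of stored rates (ms)
    target_rate: float = 3.0   # FIC set-point (Hz)
    seed: int = 0              # RNG seed

    def __post_init__(self) -> None:
        positive = (
            "tau_NMDA", "tau_GABA", "dt", "t_total", "record_dt",
            "d_E", "d_I", "g_E", "g_I",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        nonnegative = ("sigma", "G", "s_nm", "t_burn")
        for name in nonnegative:
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.t_burn >= self.t_total:
            raise InvalidParameterError("t_burn must be smaller than t_total")
        if self.record_dt < self.dt:
            raise InvalidParameterError("record_dt must be >= dt")

    def with_updates(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def n_samples(self) -> int:
        """Number of recorded samples after the burn-in is discarded."""
        return int(np.floor((self.t_total - self.t_burn) * 1000.0 / self.record_dt))


@dataclass(frozen=True)
class Connectome:
    """Weighted, symmetric structural connectivity over ``N`` regions.

    ``weights`` is an N x N nonnegative matrix with zero diagonal; ``labels``
    are region identifiers in matrix order.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError("connectome weights must be a square matrix")
        if w.shape[0] < 2:
            raise InvalidParameterError("connectome needs at least 2 regions")
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("connectome weights must be finite")
        if np.any(w < 0):
            raise InvalidParameterError("connectome weights must be nonnegative")
        if not np.allclose(w, w.T, rtol=0, atol=1e-10):
            raise InvalidParameterError("connectome weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise InvalidParameterError("connectome diagonal must be zero")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"R{i:03d}" for i in range(w.shape[0]))
            )
        elif len(self.labels) != w.shape[0]:
            raise InvalidParameterError("label count must match matrix size")
        else:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def strength(self) -> np.ndarray:
        """Node strength: sum of incident edge weights per region."""
        return self.weights.sum(axis=1)


@dataclass(frozen=True)
class ReceptorMap:
    """Per-region receptor density vector (nonnegative, PET-like units)."""

    density: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float).ravel()
        object.__setattr__(self, "density", d)
        if not np.all(np.isfinite(d)):
            raise InvalidParameterError("receptor densities must be finite")
        if np.any(d < 0):
            raise InvalidParameterError("receptor densities must be nonnegative")

    def __len__(self) -> int:
        return self.density.shape[0]


def validate_pair(connectome: Connectome, receptors: ReceptorMap | None) -> None:
    """Check that a receptor map matches a connectome's region count."""
    if receptors is not None and len(receptors) != connectome.n_regions:
        raise InvalidParameterError(
            f"receptor map length {len(receptors)} != "
            f"connectome size {connectome.n_regions}"
        )
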