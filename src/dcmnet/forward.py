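"""Generative model: bilinear neural dynamics, Balloon hemodynamics, BOLD read-out.

Neural layer
    dx/dt = A_eff x + u (B x) + C u
with ``A_eff`` carrying the extrinsic couplings off the diagonal (Hz, prior
mean 0) and self-connections on the diagonal parameterized as
``-0.5 * exp(a_i)`` so they stay strictly negative (a log-scaling of a -0.5 Hz
prior). B is identically zero by default: no modulatory structure is modelled.

Hemodynamic layer (per region, the extended Balloon model)
    ds/dt = x - D s - gamma (f - 1)
    df/dt = s
    T dv/dt = f - v**(1/alpha)
    T dq/dt = f (1 - (1 - E0)**(1/f)) / E0 - v**(1/alpha) q / v
with vasodilatory signal s, normalized inflow f, venous volume v and
deoxyhemoglobin content q; resting fixed point s=0, f=v=q=1.

BOLD read-out (1.5 T revised coefficients)
    y = V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v))
    k1 = 4.3 theta0 E0 TE,  k2 = E r0 E0 TE,  k3 = 1 - E
where E is the region's intra/extravascular signal ratio.

Integration is fixed-step classical Runge-Kutta (RK4) on a microtime grid of
``TR / 16`` by default, with the first microtime sample of each TR bin as the
volume read-out. The integrator is batched over parameter sets so that
finite-difference sensitivities during model inversion cost a single sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model_space import ModelSpec, REGIONS

__all__ = [
    "StimulusDesign",
    "HemodynamicConstants",
    "HemodynamicParams",
    "DCMParameters",
    "NoiseSpec",
    "SessionData",
    "input_function",
    "neural_derivative",
    "hemodynamic_derivative",
    "bold_signal",
    "integrate_dcm",
    "is_stable",
]


@dataclass(frozen=True)
class StimulusDesign:
    """Block paradigm: alternating inactive/active blocks sampled every TR.

    The session starts with one inactive (rest) block of ``initial_rest``
    seconds, after which ``block_length``-second active and inactive blocks
    alternate until the session ends.
    """

    TR: float = 4.0
    n_volumes: int = 100
    block_length: float = 40.0
    initial_rest: float = 40.0
    microtime_dt: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.microtime_dt is None:
            object.__setattr__(self, "microtime_dt", self.TR / 16.0)
        n_micro = self.TR / self.microtime_dt
        if abs(n_micro - round(n_micro)) > 1e-9:
            raise ValueError("microtime_dt must divide TR")

    @property
    def duration(self) -> float:
        return self.TR * self.n_volumes

    @property
    def steps_per_tr(self) -> int:
        return int(round(self.TR / self.microtime_dt))


def input_function(design: StimulusDesign, t) -> np.ndarray:
    """Boxcar input: 1 inside active blocks, 0 at rest. Vectorized over *t*.

    The ~1 Hz passive-movement cycling is deliberately collapsed to a
    sustained unit boxcar: a 4 s TR cannot resolve it and block-design
    modelling conventionally treats the block as a constant drive.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > design.duration):
        raise ValueError("t outside the session")
    shifted = t - design.initial_rest
    phase = np.floor_divide(shifted, design.block_length).astype(int)
    u = np.where((shifted >= 0) & (phase % 2 == 0), 1.0, 0.0)
    return u if u.shape else float(u)


@dataclass(frozen=True)
class HemodynamicConstants:
    """Fixed Balloon/BOLD constants (1.5 T gradient-echo)."""

    gamma: float = 0.32   # flow-dependent elimination rate, 1/s
    alpha: float = 0.32   # vessel stiffness exponent
    E0: float = 0.4       # resting oxygen extraction fraction
    V0: float = 0.04      # resting venous volume fraction
    TE: float = 0.042     # echo time, s
    theta0: float = 40.3  # frequency offset of fully deoxygenated blood, 1/s
    r0: float = 25.0      # intravascular relaxation slope, 1/s

    def __post_init__(self) -> None:
        if min(self.gamma, self.alpha, self.E0, self.V0, self.TE, self.theta0, self.r0) <= 0:
            raise ValueError("hemodynamic constants must be positive")

    @property
    def k1(self) -> float:
        return 4.3 * self.theta0 * self.E0 * self.TE

    def k2(self, epsilon) -> np.ndarray:
        return np.asarray(epsilon) * self.r0 * self.E0 * self.TE

    def k3(self, epsilon) -> np.ndarray:
        return 1.0 - np.asarray(epsilon)


#: Prior (scale) values of the three free hemodynamic parameters.
HEMO_PRIOR_DECAY = 0.64    # D, 1/s
HEMO_PRIOR_TRANSIT = 2.0   # T, s
HEMO_PRIOR_EPSILON = 1.0   # E, dimensionless


@dataclass(frozen=True)
class HemodynamicParams:
    """Per-region free hemodynamic parameters: decay D, transit time T, ratio E."""

    decay: np.ndarray
    transit: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.decay, dtype=float))
        t = np.atleast_1d(np.asarray(self.transit, dtype=float))
        e = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        if not (d.shape == t.shape == e.shape):
            raise ValueError("decay, transit and epsilon must have equal length")
        if np.any(d <= 0) or np.any(t <= 0) or np.any(e <= 0):
            raise ValueError("hemodynamic parameters must be strictly positive")
        object.__setattr__(self, "decay", d)
        object.__setattr__(self, "transit", t)
        object.__setattr__(self, "epsilon", e)

    @classmethod
    def from_log_scales(cls, log_d, log_t, log_e) -> "HemodynamicParams":
        """Build from log-scalings of the fixed priors (0 -> prior value)."""
        return cls(
            decay=HEMO_PRIOR_DECAY * np.exp(np.asarray(log_d, dtype=float)),
            transit=HEMO_PRIOR_TRANSIT * np.exp(np.asarray(log_t, dtype=float)),
            epsilon=HEMO_PRIOR_EPSILON * np.exp(np.asarray(log_e, dtype=float)),
        )

    @classmethod
    def priors(cls, n_regions: int) -> "HemodynamicParams":
        z = np.zeros(n_regions)
        return cls.from_log_scales(z, z, z)

    @property
    def n_regions(self) -> int:
        return self.decay.shape[0]


@dataclass(frozen=True)
class DCMParameters:
    """Neural and hemodynamic parameters of one session's generative model.

    ``A`` holds the extrinsic couplings (Hz; diagonal ignored), while the
    effective self-connections are ``-0.5 * exp(self_log_scale)``.
    """

    A: np.ndarray
    self_log_scale: np.ndarray
    C: np.ndarray
    hemo: HemodynamicParams
    B: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        a = np.asarray(self.self_log_scale, dtype=float)
        C = np.asarray(self.C, dtype=float)
        n = A.shape[0]
        if A.shape != (n, n) or a.shape != (n,) or C.shape != (n,):
            raise ValueError("inconsistent parameter dimensions")
        if self.hemo.n_regions != n:
            raise ValueError("hemodynamic parameters must cover every region")
        B = np.zeros((n, n)) if self.B is None else np.asarray(self.B, dtype=float)
        if B.shape != (n, n):
            raise ValueError("B must match A's shape")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "self_log_scale", a)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "B", B)

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def a_eff(self) -> np.ndarray:
        """Coupling matrix with the strictly negative effective diagonal."""
        A = self.A.copy()
        np.fill_diagonal(A, -0.5 * np.exp(self.self_log_scale))
        return A

    def validate_against(self, spec: ModelSpec) -> None:
        """Reject nonzero couplings or inputs outside the model's masks."""
        off = ~np.asarray(spec.a_mask)
        np.fill_diagonal(off, False)
        if np.any(self.A[off] != 0):
            raise ValueError("A has nonzero entries outside the model's a_mask")
        if np.any(self.C[~np.asarray(spec.c_mask)] != 0):
            raise ValueError("C has nonzero entries outside the model's c_mask")

    @classmethod
    def from_prior_means(cls, spec: ModelSpec, c_gain: float = 0.5) -> "DCMParameters":
        """Prior-mean parameters under *spec*: A=0 off-diagonal, inputs at *c_gain*."""
        n = len(spec.region_labels)
        return cls(
            A=np.zeros((n, n)),
            self_log_scale=np.zeros(n),
            C=np.where(np.asarray(spec.c_mask), c_gain, 0.0),
            hemo=HemodynamicParams.priors(n),
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic perturbations for the simulator.

    ``state_sd`` scales white neural-state noise added on the microtime grid
    (as ``state_sd * sqrt(dt) * N(0,1)``, so the injected variance per unit
    time is grid-independent). ``obs_snr`` sets white observation noise with
    standard deviation ``std(noiseless series) / obs_snr``; ``obs_sd`` gives
    the standard deviation directly and overrides ``obs_snr``.
    """

    state_sd: float = 0.01
    obs_snr: Optional[float] = 10.0
    obs_sd: Optional[float] = None


@dataclass
class SessionData:
    """One subject-session: a volumes x regions BOLD table plus metadata."""

    data: pd.DataFrame
    TR: float
    condition: str = "unspecified"
    subject: str = "sim"
    seed: Optional[int] = None
    noise: Optional[dict] = None

    @property
    def region_labels(self):
        return tuple(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_volumes(self) -> int:
        return len(self.data)


def neural_derivative(x, u, params: DCMParameters, spec: Optional[ModelSpec] = None):
    """dx/dt of the neural layer; linear in x once B = 0."""
    if spec is not None:
        params.validate_against(spec)
    x = np.asarray(x, dtype=float)
    return (params.a_eff + u * params.B) @ x + params.C * u


def hemodynamic_derivative(
    h,
    x_r: float,
    p: Optional[HemodynamicParams] = None,
    c: HemodynamicConstants = HemodynamicConstants(),
    region: int = 0,
):
    """Balloon-model state derivative (s, f, v, q) for one region.

    *h* is the state tuple ``(s, f, v, q)``; *x_r* the region's neural
    activity. Defaults to prior hemodynamic parameters.
    """
    s, f, v, q = (float(z) for z in h)
    if v <= 0 or q <= 0:
        raise ValueError("venous volume and deoxyhemoglobin content must be positive")
    if p is None:
        p = HemodynamicParams.priors(1)
    D = float(p.decay[region])
    T = float(p.transit[region])
    fv = v ** (1.0 / c.alpha)
    ds = x_r - D * s - c.gamma * (f - 1.0)
    df = s
    dv = (f - fv) / T
    dq = (f * (1.0 - (1.0 - c.E0) ** (1.0 / f)) / c.E0 - fv * q / v) / T
    return np.array([ds, df, dv, dq])


def bold_signal(v, q, c: HemodynamicConstants = HemodynamicConstants(), epsilon=1.0):
    """BOLD signal change (fraction) from venous volume and deoxyhemoglobin."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be positive")
    return c.V0 * (c.k1 * (1.0 - q) + c.k2(epsilon) * (1.0 - q / v) + c.k3(epsilon) * (1.0 - v))


def is_stable(a_eff: np.ndarray) -> bool:
    """True when every eigenvalue of the coupling matrix has negative real part."""
    return bool(np.all(np.linalg.eigvals(a_eff).real < 0))


def _simulate_batch(
    a_eff: np.ndarray,
    C: np.ndarray,
    decay: np.ndarray,
    transit: np.ndarray,
    epsilon: np.ndarray,
    design: StimulusDesign,
    constants: HemodynamicConstants = HemodynamicConstants(),
    state_noise: Optional[np.ndarray] = None,
) -> np.ndarray:
    """RK4-integrate a batch of parameter sets; returns (B, n_volumes, n) BOLD.

    All parameter arrays carry a leading batch axis. ``state_noise``, when
    given, is a (B, n_steps, n) array of pre-drawn standard-normal deviates
    added to the neural states as ``state_sd`` is already folded in by the
    caller. Non-finite trajectories propagate as NaN in the output; the
    public wrapper turns them into a flagged error.
    """
    a_eff = np.asarray(a_eff, dtype=float)
    Bsz, n, _ = a_eff.shape
    C = np.asarray(C, dtype=float)
    dt = design.microtime_dt
    n_steps = design.n_volumes * design.steps_per_tr
    g, alpha, E0 = constants.gamma, constants.alpha, constants.E0
    ia = 1.0 / alpha

    # the input is held constant over each microstep (block edges align with
    # the grid), so every RK4 step integrates a smooth vector field
    t_grid = np.arange(n_steps) * dt
    u0 = input_function(design, t_grid)

    x = np.zeros((Bsz, n))
    s = np.zeros((Bsz, n))
    f = np.ones((Bsz, n))
    v = np.ones((Bsz, n))
    q = np.ones((Bsz, n))

    out = np.empty((Bsz, design.n_volumes, n))
    k1c = constants.k1
    k2c = constants.k2(epsilon)
    k3c = constants.k3(epsilon)
    V0 = constants.V0
    spt = design.steps_per_tr

    def deriv(state, u):
        x_, s_, f_, v_, q_ = state
        fv = v_ ** ia
        dx = np.einsum("bij,bj->bi", a_eff, x_) + C * u
        ds = x_ - decay * s_ - g * (f_ - 1.0)
        df = s_
        dv = (f_ - fv) / transit
        dq = (f_ * (1.0 - (1.0 - E0) ** (1.0 / f_)) / E0 - fv * q_ / v_) / transit
        return dx, ds, df, dv, dq

    vol = 0
    with np.errstate(all="ignore"):
        for k in range(n_steps):
            if k % spt == 0:
                out[:, vol] = V0 * (k1c * (1.0 - q) + k2c * (1.0 - q / v) + k3c * (1.0 - v))
                vol += 1
            state = (x, s, f, v, q)
            u = u0[k]
            d1 = deriv(state, u)
            s2 = tuple(y + 0.5 * dt * d for y, d in zip(state, d1))
            d2 = deriv(s2, u)
            s3 = tuple(y + 0.5 * dt * d for y, d in zip(state, d2))
            d3 = deriv(s3, u)
            s4 = tuple(y + dt * d for y, d in zip(state, d3))
            d4 = deriv(s4, u)
            x, s, f, v, q = (
                y + (dt / 6.0) * (a + 2.0 * b + 2.0 * cc + e)
                for y, a, b, cc, e in zip(state, d1, d2, d3, d4)
            )
            if state_noise is not None:
                x = x + state_noise[:, k]
    return out


def integrate_dcm(
    spec: Optional[ModelSpec],
    params: DCMParameters,
    design: StimulusDesign,
    noise: Optional[NoiseSpec] = None,
    seed: Optional[int] = None,
    constants: HemodynamicConstants = HemodynamicConstants(),
    condition: str = "unspecified",
    subject: str = "sim",
) -> SessionData:
    """Simulate one session's multi-region BOLD series.

    *spec* (when given) supplies the connectivity masks for validation and the
    region labels; pass ``None`` for reduced systems with custom dimension.
    Bit-reproducible for a fixed seed.
    """
    if spec is not None:
        params.validate_against(spec)
        labels = spec.region_labels
    else:
        labels = tuple(REGIONS[: params.n_regions]) if params.n_regions <= 8 else tuple(
            f"r{i}" for i in range(params.n_regions)
        )
    n = params.n_regions
    rng = np.random.default_rng(seed)

    state_noise = None
    if noise is not None and noise.state_sd and noise.state_sd > 0:
        n_steps = design.n_volumes * design.steps_per_tr
        state_noise = (
            noise.state_sd
            * np.sqrt(design.microtime_dt)
            * rng.standard_normal((1, n_steps, n))
        )

    y = _simulate_batch(
        params.a_eff[None],
        params.C[None],
        params.hemo.decay[None],
        params.hemo.transit[None],
        params.hemo.epsilon[None],
        design,
        constants=constants,
        state_noise=state_noise,
    )[0]

    bad = ~np.isfinite(y).all(axis=1)
    if bad.any():
        first = int(np.argmax(bad))
        raise FloatingPointError(
            f"unstable dynamics: non-finite BOLD first at volume index {first}"
        )

    noise_meta = None
    if noise is not None:
        obs_sd = noise.obs_sd
        if obs_sd is None and noise.obs_snr:
            obs_sd = float(np.std(y)) / noise.obs_snr
        if obs_sd:
            y = y + obs_sd * rng.standard_normal(y.shape)
        noise_meta = {
            "state_sd": noise.state_sd,
            "obs_snr": noise.obs_snr,
            "obs_sd": obs_sd,
        }

    df = pd.DataFrame(y, columns=list(labels))
    df.index.name = "volume"
    return SessionData(
        data=df, TR=design.TR, condition=condition, subject=subject, seed=seed, noise=noise_meta
    )
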