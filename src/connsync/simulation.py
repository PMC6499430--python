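"""Delayed, noisy Kuramoto dynamics on a weighted directed network.

Each region is a phase oscillator theta_i obeying

    dtheta_i/dt = omega_i
                  + k * sum_j A_ij * sin(theta_j(t - tau_ij) - theta_i(t))
                  + eta_i(t),

where A_ij is the (row = target) weight matrix, tau_ij = d_ij / v is the
conduction delay given a fixed conduction speed v, and eta_i is Gaussian
white noise with autocorrelation delta(t-t') * sigma_n^2 / T.  Natural
frequencies are drawn from a Gaussian of mean f0 and SD sigma_d (Hz) and
used in angular units, omega = 2*pi*f.

Integration is forward Euler with step dt; the noise increment per step is
sqrt(dt * sigma_n^2 / T) * xi with unit normal xi, and the delay term reads
phases out of a ring buffer whose depth is the largest delay in steps.  The
delay history before t=0 is the initial condition held constant.  The first
``burn_in_fraction`` of the run is discarded before any time averaging.

The stepping kernel is JIT-compiled with numba when available and falls
back to a vectorized numpy loop otherwise; zero-delay runs use a fast
matrix-product path in either case.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

try:  # optional acceleration
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]

__all__ = ["SimConfig", "PhaseTrajectory", "TimestepCheck",
           "sample_frequencies", "compute_delay_steps", "validate_timestep",
           "simulate"]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    k : global coupling coefficient (dimensionless).
    f0, sigma_d : mean and SD of the natural-frequency distribution, Hz.
    sigma_n : white-noise SD, radians; T_noise : noise timescale, s.
    conduction_speed : m/s, converts micrometre distances to delays.
    dt, n_steps : Euler step (s) and step count; burn_in_fraction of the run
        is discarded before averaging.
    sample_stride : keep every stride-th retained step in the trajectory.
    delays_enabled : if False all delays are zero regardless of distances.
    """

    k: float = 1.0
    f0: float = 40.0
    sigma_d: float = 0.0
    sigma_n: float = 2.0
    T_noise: float = 1.0
    conduction_speed: float = 3.5
    dt: float = 1e-4
    n_steps: int = 40_000
    burn_in_fraction: float = 0.5
    seed: int = 0
    delays_enabled: bool = True
    sample_stride: int = 10

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.conduction_speed <= 0:
            raise ValueError("conduction_speed must be > 0")
        if self.sigma_d < 0:
            raise ValueError("sigma_d must be >= 0")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")

    @property
    def burn_in_steps(self) -> int:
        return int(self.burn_in_fraction * self.n_steps)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhaseTrajectory:
    """Retained-window phase samples, wrapped to [0, 2*pi).

    ``phases`` has shape (n_samples, n_nodes); samples are every
    ``sample_stride``-th Euler step after burn-in.
    """

    phases: np.ndarray
    sample_stride: int
    config: SimConfig

    @property
    def n_samples(self) -> int:
        return self.phases.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[1]


@dataclass(frozen=True)
class TimestepCheck:
    """Result of the Euler stability heuristic for the phase model."""

    passed: bool
    bound: float
    binding_term: str
    dt: float

    @property
    def margin(self) -> float:
        return self.bound / self.dt


def sample_frequencies(config: SimConfig, n: int,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-node angular frequencies omega_i = 2*pi*f_i (rad/s) with
    f_i ~ Normal(f0, sigma_d^2)."""
    if n < 1:
        raise ValueError("need at least one node")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    f = config.f0 + config.sigma_d * rng.standard_normal(n)
    return TWO_PI * f


def compute_delay_steps(distances: np.ndarray, config: SimConfig) -> np.ndarray:
    """Conduction delays tau_ij = d_ij / v, rounded to whole Euler steps.

    Distances are in micrometres and the speed in m/s; with the default
    dt = 1e-4 s the rounding error is at most 0.05 ms.
    """
    d = np.asarray(distances, dtype=float)
    if not config.delays_enabled:
        return np.zeros(d.shape, dtype=np.int64)
    tau = d * 1e-6 / config.conduction_speed  # seconds
    return np.rint(tau / config.dt).astype(np.int64)


def validate_timestep(config: SimConfig, weights: np.ndarray) -> TimestepCheck:
    """Evaluate the Euler stability bound
    dt <= 0.01 / max(max(k*A_ij), 0.05*mu, sigma_n^2/(2T), 1)
    with mu the mean angular frequency 2*pi*f0, and report which term binds."""
    w = np.asarray(weights, dtype=float)
    terms = {
        "coupling": config.k * (w.max() if w.size else 0.0),
        "frequency": 0.05 * TWO_PI * config.f0,
        "noise": config.sigma_n ** 2 / (2.0 * config.T_noise),
        "unity": 1.0,
    }
    binding = max(terms, key=terms.get)  # type: ignore[arg-type]
    bound = 0.01 / terms[binding]
    return TimestepCheck(config.dt <= bound, bound, binding, config.dt)


# ---------------------------------------------------------------------------
# stepping kernels

@njit(cache=True, fastmath=True)
def _step_delayed_numba(theta0, omega, A, delay, k, dt, noise, burn, stride,
                        out):  # pragma: no cover - exercised via simulate()
    # sin(theta_j(t-tau) - theta_i(t)) = sin_d*cos_i - cos_d*sin_i, with
    # sin/cos of the phase history kept in ring buffers updated one row per
    # step; trig cost is O(n) per step instead of O(n^2)
    n = theta0.shape[0]
    n_steps = noise.shape[0]
    L = int(delay.max()) + 1
    buf_s = np.empty((L, n))
    buf_c = np.empty((L, n))
    for i in range(n):
        s0, c0 = np.sin(theta0[i]), np.cos(theta0[i])
        for r in range(L):
            buf_s[r, i] = s0
            buf_c[r, i] = c0
    theta = theta0.copy()
    m = 0
    for t in range(n_steps):
        new = np.empty(n)
        for i in range(n):
            si, ci = np.sin(theta[i]), np.cos(theta[i])
            c = 0.0
            for j in range(n):
                row = (t - delay[i, j]) % L
                c += A[i, j] * (buf_s[row, j] * ci - buf_c[row, j] * si)
            v = theta[i] + dt * (omega[i] + k * c) + noise[t, i]
            if not np.isfinite(v):
                return -(t + 1)
            new[i] = v
        theta = new
        row_new = (t + 1) % L
        for i in range(n):
            buf_s[row_new, i] = np.sin(theta[i])
            buf_c[row_new, i] = np.cos(theta[i])
        s = t + 1 - burn
        if s >= 1 and s % stride == 0:
            out[m] = theta
            m += 1
    return m


def _step_delayed_numpy(theta0, omega, A, delay, k, dt, noise, burn, stride,
                        out):
    n = theta0.shape[0]
    n_steps = noise.shape[0]
    L = int(delay.max()) + 1
    buf = np.tile(theta0, (L, 1))
    theta = theta0.copy()
    cols = np.arange(n)[None, :]
    m = 0
    for t in range(n_steps):
        rows = (t - delay) % L
        theta_d = buf[rows, cols]  # theta_j(t - tau_ij), shape (n, n)
        coupling = (A * np.sin(theta_d - theta[:, None])).sum(axis=1)
        theta = theta + dt * (omega + k * coupling) + noise[t]
        if not np.all(np.isfinite(theta)):
            return -(t + 1)
        buf[(t + 1) % L] = theta
        s = t + 1 - burn
        if s >= 1 and s % stride == 0:
            out[m] = theta
            m += 1
    return m


def _step_nodelay_numpy(theta0, omega, A, k, dt, noise, burn, stride, out):
    # sin(theta_j - theta_i) expands to matrix products with sin/cos(theta)
    theta = theta0.copy()
    n_steps = noise.shape[0]
    m = 0
    for t in range(n_steps):
        s_, c_ = np.sin(theta), np.cos(theta)
        coupling = c_ * (A @ s_) - s_ * (A @ c_)
        theta = theta + dt * (omega + k * coupling) + noise[t]
        if not np.all(np.isfinite(theta)):
            return -(t + 1)
        s = t + 1 - burn
        if s >= 1 and s % stride == 0:
            out[m] = theta
            m += 1
    return m


def simulate(weights: np.ndarray, distances: np.ndarray | None,
             config: SimConfig, *, omega: np.ndarray | None = None,
             initial_phases: np.ndarray | None = None) -> PhaseTrajectory:
    """Integrate the delayed noisy phase model and return the retained
    trajectory.

    Parameters
    ----------
    weights : (n, n) non-negative coupling matrix, rows = targets.
    distances : (n, n) distance matrix (micrometres); may be None when
        ``config.delays_enabled`` is False.
    omega : optional per-node angular frequencies (rad/s), overriding the
        Gaussian draw — useful for controlled fixtures.
    initial_phases : optional initial condition; default uniform on
        [0, 2*pi) from the config seed.
    """
    A = np.asarray(weights, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError(f"weights must be square, got {A.shape}")
    if config.delays_enabled and distances is None:
        raise ValueError("distances are required when delays are enabled")

    ss = np.random.SeedSequence([config.seed, 23])
    rng_init, rng_freq, rng_noise = [np.random.default_rng(s)
                                     for s in ss.spawn(3)]
    if omega is None:
        omega = sample_frequencies(config, n, rng_freq)
    else:
        omega = np.asarray(omega, dtype=float)
        if omega.shape != (n,):
            raise ValueError(f"omega must have shape ({n},)")
    if initial_phases is None:
        theta0 = rng_init.uniform(0.0, TWO_PI, size=n)
    else:
        theta0 = np.asarray(initial_phases, dtype=float).copy()
        if theta0.shape != (n,):
            raise ValueError(f"initial_phases must have shape ({n},)")

    noise_amp = np.sqrt(config.dt * config.sigma_n ** 2 / config.T_noise)
    if noise_amp > 0:
        noise = noise_amp * rng_noise.standard_normal((config.n_steps, n))
    else:
        noise = np.zeros((config.n_steps, n))

    burn = config.burn_in_steps
    stride = config.sample_stride
    n_samples = (config.n_steps - burn) // stride
    if n_samples < 1:
        raise ValueError("no retained samples: reduce burn-in or stride")
    out = np.empty((n_samples, n))

    delay = (compute_delay_steps(distances, config)
             if config.delays_enabled else np.zeros((n, n), dtype=np.int64))
    # overflow inside the step loop is caught by the finiteness check
    with np.errstate(over="ignore", invalid="ignore"):
        if not delay.any():
            m = _step_nodelay_numpy(theta0, omega, A, config.k, config.dt,
                                    noise, burn, stride, out)
        elif _HAVE_NUMBA:
            m = _step_delayed_numba(theta0, omega, A,
                                    np.ascontiguousarray(delay), config.k,
                                    config.dt, noise, burn, stride, out)
        else:
            m = _step_delayed_numpy(theta0, omega, A, delay, config.k,
                                    config.dt, noise, burn, stride, out)
    if m < 0:
        raise FloatingPointError(
            f"phases became non-finite at step {-m} "
            f"(dt={config.dt}, k={config.k}); see validate_timestep"
        )
    assert m == n_samples
    return PhaseTrajectory(np.mod(out, TWO_PI), stride, config)
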