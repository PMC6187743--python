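"""Four-field reaction–diffusion model of branching morphogenesis on a 3D grid.

The model couples an activator ``A``, an inhibitor ``H``, a substrate ``S``
and a non-diffusing cell-differentiation marker ``Y``:

.. math::

    \\partial_t A &= c A^2 S / H - \\mu A + D_A \\nabla^2 A + \\rho_A Y \\\\
    \\partial_t H &= c A^2 S - \\nu H + D_H \\nabla^2 H + \\rho_H Y \\\\
    \\partial_t S &= c_0 - \\gamma S - \\varepsilon Y S + D_S \\nabla^2 S \\\\
    \\partial_t Y &= d A - e Y + Y^2 / (1 + f Y^2)

The activator self-amplifies while consuming substrate, the faster-diffusing
inhibitor suppresses it laterally, and sustained high activator pushes the
bistable ``Y`` dynamics over its threshold, irreversibly committing a voxel
to differentiated tissue.  All quantities are dimensionless.

Time stepping is explicit Euler with a 7-point Laplacian; ``Y`` carries no
diffusion term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "SimulationDomain",
    "FieldState",
    "InitialConditionSpec",
    "StepperConfig",
    "RunLog",
    "RunResult",
    "reaction_rates",
    "laplacian",
    "step",
    "initialize",
    "run",
]

FIELD_NAMES = ("A", "H", "S", "Y")


class NonFiniteFieldError(RuntimeError):
    """Raised when a field develops a NaN/inf voxel during stepping."""

    def __init__(self, field_name: str, step_index: int, voxel: tuple[int, ...]):
        self.field_name = field_name
        self.step_index = step_index
        self.voxel = voxel
        super().__init__(
            f"non-finite value in field {field_name!r} at voxel {voxel} "
            f"after step {step_index}"
        )


@dataclass(frozen=True)
class ModelParameters:
    """The fourteen reaction/diffusion constants of the model.

    Defaults are the baseline side-branching parameter set.  ``mu``, ``nu``,
    ``gamma`` and ``e`` are first-order degradation rates of A, H, S and Y;
    ``rho_A``/``rho_H`` are secretion rates of A/H by differentiated cells;
    ``c`` is the autocatalysis rate, ``c0``/``gamma``/``epsilon`` govern
    substrate supply, decay and consumption by tissue; ``d`` converts
    activator into commitment, ``e``/``f`` shape the bistable Y kinetics.
    """

    c: float = 0.04
    mu: float = 0.3
    nu: float = 0.03
    rho_A: float = 0.03
    rho_H: float = 0.0001
    c0: float = 0.02
    gamma: float = 0.02
    epsilon: float = 0.042
    d: float = 0.008
    e: float = 0.1
    f: float = 10.0
    D_A: float = 0.1
    D_H: float = 0.26
    D_S: float = 0.06

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")
        if self.D_A >= self.D_H and (self.D_A > 0 or self.D_H > 0):
            # the inhibitor must outrun the activator for lateral inhibition
            warnings.warn(
                f"D_A={self.D_A} >= D_H={self.D_H}: the inhibitor should diffuse "
                "faster than the activator for Turing patterning",
                stacklevel=2,
            )

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class SimulationDomain:
    """Regular 3D grid: extents in voxels, spacing ``h``, boundary kind."""

    nx: int = 64
    ny: int = 64
    nz: int = 32
    h: float = 1.0
    boundary: str = "zero-flux"  # or "periodic"

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 3:
            raise ValueError("grid extents must be >= 3 voxels")
        if self.h <= 0:
            raise ValueError("grid spacing h must be positive")
        if self.boundary not in ("zero-flux", "periodic"):
            raise ValueError(f"unknown boundary kind {self.boundary!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def center(self) -> tuple[int, int, int]:
        return (self.nx // 2, self.ny // 2, self.nz // 2)

    def to_dict(self) -> dict:
        return {
            "nx": self.nx, "ny": self.ny, "nz": self.nz,
            "h": self.h, "boundary": self.boundary,
        }


@dataclass
class FieldState:
    """The four concentration fields plus step/time counters."""

    A: np.ndarray
    H: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    step: int = 0
    t: float = 0.0

    def __post_init__(self) -> None:
        shapes = {f.shape for f in (self.A, self.H, self.S, self.Y)}
        if len(shapes) != 1:
            raise ValueError(f"fields must share one grid shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.A.shape

    def copy(self) -> "FieldState":
        return FieldState(
            A=self.A.copy(), H=self.H.copy(), S=self.S.copy(), Y=self.Y.copy(),
            step=self.step, t=self.t,
        )

    def fields(self) -> dict[str, np.ndarray]:
        return {"A": self.A, "H": self.H, "S": self.S, "Y": self.Y}


@dataclass(frozen=True)
class InitialConditionSpec:
    """Initial seeding of the four fields.

    ``seeded`` places a small Y=1 sphere at the domain center (the initial
    bud); ``gradient`` leaves Y=0 everywhere and imposes an affine activator
    ramp along ``gradient_axis``; ``uniform`` is the no-seed, no-gradient
    control.  A and H receive i.i.d. multiplicative fluctuations of relative
    amplitude ``fluctuation`` drawn from the seeded RNG.

    The default morphogen background is a quiescent low state (A0 = H0 =
    1e-3, S0 at the supply/decay balance c0/gamma): activator autocatalysis
    cannot self-ignite there, so all pattern activity originates from the
    seeded bud (or the imposed gradient).  The homogeneous Y=0 steady state
    is available instead via ``A0="steady_state"`` (it is linearly unstable
    and nucleates patterns everywhere — the spillover-like regime).
    """

    mode: str = "seeded"  # seeded | gradient | uniform
    seed_center: tuple[int, int, int] | None = None  # None -> domain center
    seed_radius: float = 2.0
    seed_Y_value: float = 1.0
    A0: float | str = 1e-3  # number, or "steady_state"
    H0: float | str = 1e-3
    S0: float | None = None  # None -> c0/gamma
    # "fixed": H = H0 everywhere; "equilibrium": H tracks the imposed
    # activator via the H-equation balance c A^2 S0 / nu, floored at H0
    # (used by the gradient/uniform scenarios so that an imposed activator
    # profile carries a consistent inhibitor background)
    H_mode: str = "fixed"
    fluctuation: float = 0.05
    rng_seed: int = 0
    gradient_axis: str = "z"
    gradient_low: float = 0.001
    gradient_high: float = 2.9

    def __post_init__(self) -> None:
        if self.mode not in ("seeded", "gradient", "uniform"):
            raise ValueError(f"unknown init mode {self.mode!r}")
        if not (0 <= self.fluctuation < 1):
            raise ValueError("fluctuation must satisfy 0 <= fluctuation < 1")
        if self.gradient_low > self.gradient_high:
            raise ValueError("gradient_low must not exceed gradient_high")
        if self.gradient_axis not in ("x", "y", "z"):
            raise ValueError(f"gradient_axis must be x, y or z, got {self.gradient_axis!r}")
        if self.H_mode not in ("fixed", "equilibrium"):
            raise ValueError(f"H_mode must be 'fixed' or 'equilibrium', got {self.H_mode!r}")

    def replace(self, **kwargs) -> "InitialConditionSpec":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if d["seed_center"] is not None:
            d["seed_center"] = list(d["seed_center"])
        return d


def stability_dt_limit(params: ModelParameters, h: float = 1.0) -> float:
    """Explicit-Euler diffusion bound for the 7-point stencil: h^2 / (6 max D)."""
    dmax = max(params.D_A, params.D_H, params.D_S)
    if dmax == 0:
        return np.inf
    return h * h / (6.0 * dmax)


@dataclass(frozen=True)
class StepperConfig:
    """Explicit-Euler stepping controls.

    ``dt`` must respect the 3D diffusion stability bound ``h^2/(6 max D)``
    unless ``allow_unstable_dt`` is set.  ``H_floor`` clamps the denominator
    of the autocatalysis term.
    """

    dt: float = 0.5
    n_steps: int = 2000
    snapshot_every: int = 0  # 0 -> no intermediate snapshots
    H_floor: float = 1e-8
    allow_unstable_dt: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.H_floor <= 0:
            raise ValueError("H_floor must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    def validate_against(self, params: ModelParameters, domain: SimulationDomain) -> None:
        limit = stability_dt_limit(params, domain.h)
        if self.dt > limit and not self.allow_unstable_dt:
            raise ValueError(
                f"dt={self.dt} exceeds the explicit-Euler diffusion stability "
                f"bound h^2/(6 max D) = {limit:.6g}; set allow_unstable_dt=True "
                "to override"
            )

    def replace(self, **kwargs) -> "StepperConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# local kinetics


def reaction_rates(A, H, S, Y, params: ModelParameters, H_floor: float = 1e-8):
    """Local reaction terms (diffusion excluded), elementwise over arrays.

    ``H`` is clamped to ``H_floor`` in the autocatalysis denominator.
    Returns ``(dA, dH, dS, dY)``.
    """
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    S = np.asarray(S, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Hc = np.maximum(H, H_floor)
    auto = params.c * A * A * S
    dA = auto / Hc - params.mu * A + params.rho_A * Y
    dH = auto - params.nu * H + params.rho_H * Y
    dS = params.c0 - params.gamma * S - params.epsilon * Y * S
    Y2 = Y * Y
    dY = params.d * A - params.e * Y + Y2 / (1.0 + params.f * Y2)
    for name, arr in zip(("dA", "dH", "dS", "dY"), (dA, dH, dS, dY)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite reaction rate in term {name}")
    return dA, dH, dS, dY


def _laplacian_neumann(f: np.ndarray, h2: float) -> np.ndarray:
    g = np.pad(f, 1, mode="edge")  # mirror ghost = boundary value
    return (
        g[2:, 1:-1, 1:-1] + g[:-2, 1:-1, 1:-1]
        + g[1:-1, 2:, 1:-1] + g[1:-1, :-2, 1:-1]
        + g[1:-1, 1:-1, 2:] + g[1:-1, 1:-1, :-2]
        - 6.0 * f
    ) / h2


def _laplacian_periodic(f: np.ndarray, h2: float) -> np.ndarray:
    out = -6.0 * f
    for axis in range(3):
        out += np.roll(f, 1, axis=axis) + np.roll(f, -1, axis=axis)
    return out / h2


def laplacian(f: np.ndarray, domain: SimulationDomain) -> np.ndarray:
    """7-point discrete Laplacian of ``f`` under the domain's boundary rule."""
    f = np.asarray(f, dtype=float)
    if f.shape != domain.shape:
        raise ValueError(f"field shape {f.shape} does not match domain {domain.shape}")
    h2 = domain.h * domain.h
    if domain.boundary == "periodic":
        return _laplacian_periodic(f, h2)
    return _laplacian_neumann(f, h2)


def step(
    state: FieldState,
    params: ModelParameters,
    stepper: StepperConfig,
    domain: SimulationDomain,
    clamp_counter: list | None = None,
) -> FieldState:
    """Advance ``state`` in place by one explicit-Euler update; returns it.

    A, H and S receive reaction plus diffusion; Y is purely local.  Any
    non-finite voxel after the update aborts with a diagnostic naming the
    step, voxel and field.
    """
    dt = stepper.dt
    if clamp_counter is not None:
        clamp_counter[0] += int(np.count_nonzero(state.H < stepper.H_floor))
    dA, dH, dS, dY = reaction_rates(
        state.A, state.H, state.S, state.Y, params, H_floor=stepper.H_floor
    )
    state.A += dt * (dA + params.D_A * laplacian(state.A, domain))
    state.H += dt * (dH + params.D_H * laplacian(state.H, domain))
    state.S += dt * (dS + params.D_S * laplacian(state.S, domain))
    state.Y += dt * dY
    state.step += 1
    state.t += dt
    for name, arr in state.fields().items():
        if not np.all(np.isfinite(arr)):
            voxel = tuple(int(i) for i in np.argwhere(~np.isfinite(arr))[0])
            raise NonFiniteFieldError(name, state.step, voxel)
    return state


# ---------------------------------------------------------------------------
# initialization


def default_baselines(params: ModelParameters) -> tuple[float, float, float]:
    """Homogeneous Y=0 steady state (A0, H0, S0) = (nu/mu, c nu S0/mu^2, c0/gamma)."""
    if params.mu <= 0 or params.gamma <= 0:
        raise ValueError("mu and gamma must be positive for the Y=0 steady state")
    S0 = params.c0 / params.gamma
    A0 = params.nu / params.mu
    H0 = params.c * params.nu * S0 / params.mu**2
    return A0, H0, S0


def initialize(
    domain: SimulationDomain,
    ic: InitialConditionSpec,
    params: ModelParameters | None = None,
) -> FieldState:
    """Build the initial :class:`FieldState` from an initial-condition spec.

    ``S0=None`` resolves to the supply/decay balance ``c0/gamma``;
    ``A0``/``H0`` given as ``"steady_state"`` resolve to the homogeneous
    Y=0 fixed point of ``params``.
    """
    A0, H0, S0 = ic.A0, ic.H0, ic.S0
    if A0 == "steady_state" or H0 == "steady_state" or S0 is None:
        if params is None:
            raise ValueError("params required to resolve default baselines")
        a, h, s = default_baselines(params)
        A0 = a if A0 == "steady_state" else A0
        H0 = h if H0 == "steady_state" else H0
        S0 = s if S0 is None else S0

    rng = np.random.default_rng(ic.rng_seed)
    shape = domain.shape

    A = np.full(shape, float(A0))
    if ic.mode == "gradient":
        axis = "xyz".index(ic.gradient_axis)
        n = shape[axis]
        ramp = np.linspace(ic.gradient_low, ic.gradient_high, n)
        A = np.broadcast_to(
            ramp.reshape([-1 if i == axis else 1 for i in range(3)]), shape
        ).astype(float).copy()

    if ic.H_mode == "equilibrium":
        if params is None:
            raise ValueError("params required for H_mode='equilibrium'")
        if params.nu <= 0:
            raise ValueError("H_mode='equilibrium' requires nu > 0")
        H = np.maximum(params.c * A * A * S0 / params.nu, float(H0))
    else:
        H = np.full(shape, float(H0))
    if ic.fluctuation > 0:
        A *= 1.0 + rng.uniform(-ic.fluctuation, ic.fluctuation, shape)
        H = H * (1.0 + rng.uniform(-ic.fluctuation, ic.fluctuation, shape))
    S = np.full(shape, float(S0))
    Y = np.zeros(shape)

    if ic.mode == "seeded":
        center = ic.seed_center if ic.seed_center is not None else domain.center
        r = ic.seed_radius
        for c, n in zip(center, shape):
            if c - r < 0 or c + r > n - 1:
                raise ValueError(
                    f"seed sphere (center {center}, radius {r}) extends outside "
                    f"the {shape} domain"
                )
        ii, jj, kk = np.ogrid[: shape[0], : shape[1], : shape[2]]
        inside = (
            (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
        ) <= r * r
        Y[inside] = ic.seed_Y_value

    return FieldState(A=A, H=H, S=S, Y=Y)


# ---------------------------------------------------------------------------
# run driver


@dataclass
class RunLog:
    """Per-run diagnostics: H-floor clamp count and per-snapshot field ranges."""

    clamp_count: int = 0
    snapshots: list = field(default_factory=list)  # list of per-snapshot dicts

    def record(self, state: FieldState) -> None:
        entry: dict = {"step": state.step, "t": state.t}
        for name, arr in state.fields().items():
            entry[f"{name}_min"] = float(arr.min())
            entry[f"{name}_max"] = float(arr.max())
        self.snapshots.append(entry)

    def to_dict(self) -> dict:
        return {"clamp_count": self.clamp_count, "snapshots": self.snapshots}


@dataclass
class RunResult:
    final: FieldState
    trajectory: list  # [(step, FieldState copy), ...] at snapshot cadence
    log: RunLog


def run(
    params: ModelParameters,
    domain: SimulationDomain,
    ic: InitialConditionSpec,
    stepper: StepperConfig,
    observers: Sequence[Callable[[FieldState, SimulationDomain], None]] = (),
    keep_snapshots: bool = True,
) -> RunResult:
    """Integrate the model for ``stepper.n_steps`` Euler updates.

    Deterministic given the full configuration including ``ic.rng_seed``.
    Snapshots (deep copies) are stored every ``stepper.snapshot_every`` steps
    when that is positive; observers are called at the same cadence and at
    the final step.  On a stepping error the partial trajectory is attached
    to the raised exception for post-mortem inspection.
    """
    stepper.validate_against(params, domain)
    state = initialize(domain, ic, params)
    log = RunLog()
    trajectory: list = []
    clamp = [0]

    def observe(s: FieldState) -> None:
        log.record(s)
        if keep_snapshots and stepper.snapshot_every > 0:
            trajectory.append((s.step, s.copy()))
        for obs in observers:
            obs(s, domain)

    observe(state)
    try:
        for _ in range(stepper.n_steps):
            step(state, params, stepper, domain, clamp_counter=clamp)
            if stepper.snapshot_every > 0 and state.step % stepper.snapshot_every == 0:
                observe(state)
    except Exception as exc:
        exc.partial_trajectory = trajectory  # type: ignore[attr-defined]
        raise
    if not trajectory or trajectory[-1][0] != state.step:
        if stepper.snapshot_every > 0 or not trajectory:
            log.record(state)
            for obs in observers:
                obs(state, domain)
    log.clamp_count = clamp[0]
    return RunResult(final=state, trajectory=trajectory, log=log)
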