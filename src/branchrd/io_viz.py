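"""Snapshot I/O, synthetic geometric fixtures, config files and checkpoints.

Snapshots are legacy ASCII VTK STRUCTURED_POINTS files carrying the four
scalar arrays A, H, S, Y (voxel order x-fastest), readable by ParaView and
diffable in tests.  Fixtures are deterministic voxelizations of analytic
shapes (sphere, cylinder, Y-tube, double-Y) used to validate the
morphometry on volumes of known topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from branchrd.model_core import (
    FieldState,
    InitialConditionSpec,
    ModelParameters,
    SimulationDomain,
    StepperConfig,
)

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "sphere_fixture",
    "cylinder_fixture",
    "y_tube_fixture",
    "double_y_fixture",
    "save_checkpoint",
    "load_checkpoint",
    "load_config",
    "configs_from_dict",
]

_FIELD_ORDER = ("A", "H", "S", "Y")
_CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# VTK snapshots


def write_snapshot(state: FieldState, domain: SimulationDomain, path) -> Path:
    """Write the four fields as an ASCII VTK STRUCTURED_POINTS file."""
    path = Path(path)
    nx, ny, nz = domain.shape
    lines = [
        "# vtk DataFile Version 3.0",
        f"branchrd snapshot step={state.step} t={state.t!r}",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"SPACING {domain.h!r} {domain.h!r} {domain.h!r}",
        "ORIGIN 0 0 0",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name in _FIELD_ORDER:
        arr = getattr(state, name)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK structured points iterate x fastest; arrays are (x, y, z)
        flat = arr.transpose(2, 1, 0).ravel()
        lines.extend(f"{v:.17g}" for v in flat)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_snapshot(path) -> tuple[FieldState, SimulationDomain]:
    """Read a snapshot written by :func:`write_snapshot`."""
    path = Path(path)
    tokens = path.read_text().splitlines()
    dims = None
    spacing = 1.0
    step, t = 0, 0.0
    fields: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("branchrd snapshot"):
            for part in line.split():
                if part.startswith("step="):
                    step = int(part[5:])
                elif part.startswith("t="):
                    t = float(part[2:])
        elif line.startswith("DIMENSIONS"):
            dims = tuple(int(v) for v in line.split()[1:4])
        elif line.startswith("SPACING"):
            spacing = float(line.split()[1])
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            if dims is None:
                raise ValueError(f"{path}: SCALARS before DIMENSIONS (line {i + 1})")
            n = dims[0] * dims[1] * dims[2]
            if i + 1 >= len(tokens) or not tokens[i + 1].startswith("LOOKUP_TABLE"):
                raise ValueError(f"{path}: missing LOOKUP_TABLE after SCALARS "
                                 f"(line {i + 2})")
            vals = tokens[i + 2 : i + 2 + n]
            if len(vals) < n:
                raise ValueError(f"{path}: truncated data for array {name!r}")
            arr = np.array([float(v) for v in vals]).reshape(dims[2], dims[1], dims[0])
            fields[name] = arr.transpose(2, 1, 0)
            i += 1 + n
        i += 1
    if dims is None:
        raise ValueError(f"{path}: no DIMENSIONS line found")
    missing = [f for f in _FIELD_ORDER if f not in fields]
    if missing:
        raise ValueError(f"{path}: missing scalar arrays {missing}")
    domain = SimulationDomain(nx=dims[0], ny=dims[1], nz=dims[2], h=spacing)
    state = FieldState(A=fields["A"], H=fields["H"], S=fields["S"], Y=fields["Y"],
                       step=step, t=t)
    return state, domain


# ---------------------------------------------------------------------------
# geometric fixtures


def _check_fits(mask: np.ndarray, name: str) -> np.ndarray:
    border = np.concatenate([
        mask[0].ravel(), mask[-1].ravel(),
        mask[:, 0].ravel(), mask[:, -1].ravel(),
        mask[:, :, 0].ravel(), mask[:, :, -1].ravel(),
    ])
    if border.any():
        raise ValueError(f"{name} fixture touches the domain boundary; "
                         "enlarge the domain or shrink the geometry")
    return mask


def sphere_fixture(shape=(33, 33, 33), center=None, radius=8.0) -> np.ndarray:
    """Boolean solid sphere.

    Centers default to integer voxels: medial-axis thinning preserves a
    well-defined centerline only when the shape has a central voxel plane.
    """
    center = center if center is not None else tuple(s // 2 for s in shape)
    ii, jj, kk = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r2 = ((ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2)
    return _check_fits(r2 <= radius * radius, "sphere")


def _capsule_mask(shape, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0-p1 (cylinder with round caps)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    seg = p1 - p0
    L2 = float(seg @ seg)
    rel = grid - p0
    t = np.clip((rel @ seg) / max(L2, 1e-12), 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    d2 = ((grid - closest) ** 2).sum(axis=-1)
    return d2 <= radius * radius


def cylinder_fixture(shape=(17, 17, 48), radius=3.0, length=40, axis=2) -> np.ndarray:
    """Boolean straight tube of given radius and length along ``axis``."""
    center = [s // 2 for s in shape]
    p0 = list(center)
    p1 = list(center)
    p0[axis] = (shape[axis] - length) // 2
    p1[axis] = p0[axis] + length - 1
    return _check_fits(_capsule_mask(shape, p0, p1, radius), "cylinder")


def y_tube_fixture(shape=(49, 33, 49), radius=2.5, trunk=18, arm=14,
                   angle_deg=45.0) -> np.ndarray:
    """Trunk along z splitting into two symmetric arms in the x-z plane."""
    cx, cy = shape[0] // 2, shape[1] // 2
    z0 = 4.0
    fork = np.array([cx, cy, z0 + trunk])
    a = np.deg2rad(angle_deg)
    d1 = np.array([np.sin(a), 0.0, np.cos(a)])
    d2 = np.array([-np.sin(a), 0.0, np.cos(a)])
    m = _capsule_mask(shape, [cx, cy, z0], fork, radius)
    m |= _capsule_mask(shape, fork, fork + arm * d1, radius)
    m |= _capsule_mask(shape, fork, fork + arm * d2, radius)
    return _check_fits(m, "y_tube")


def double_y_fixture(shape=(65, 33, 65), radius=2.5, trunk=16, arm=12,
                     arm2=10, angle_deg=45.0) -> np.ndarray:
    """Y-tube whose two arms each split again (three branch points)."""
    cx, cy = shape[0] // 2, shape[1] // 2
    z0 = 4.0
    fork = np.array([cx, cy, z0 + trunk])
    a = np.deg2rad(angle_deg)
    dirs = [np.array([np.sin(s * a), 0.0, np.cos(s * a)]) for s in (+1, -1)]
    m = _capsule_mask(shape, [cx, cy, z0], fork, radius)
    for d in dirs:
        tip1 = fork + arm * d
        m |= _capsule_mask(shape, fork, tip1, radius)
        for s2 in (+1, -1):
            a2 = np.arctan2(d[0], d[2]) + s2 * a * 0.75
            d2 = np.array([np.sin(a2), 0.0, np.cos(a2)])
            m |= _capsule_mask(shape, tip1, tip1 + arm2 * d2, radius)
    return _check_fits(m, "double_y")


def side_branch_fixture(shape=(49, 33, 49), radius=2.5, trunk=36, arm=12,
                        n_arms=2) -> np.ndarray:
    """Straight trunk along z with perpendicular lateral arms at mid-trunk."""
    cx, cy = shape[0] // 2, shape[1] // 2
    z0 = 4
    m = _capsule_mask(shape, [cx, cy, z0], [cx, cy, z0 + trunk], radius)
    arm_z = [z0 + trunk // 3, z0 + 2 * trunk // 3, z0 + trunk // 2][:n_arms]
    for k, z in enumerate(arm_z):
        sgn = 1 if k % 2 == 0 else -1
        m |= _capsule_mask(shape, [cx, cy, z], [cx + sgn * arm, cy, z], radius)
    return _check_fits(m, "side_branch")


def make_fixture(spec: dict) -> np.ndarray:
    """Dispatch on ``spec['shape']``: sphere | cylinder | y_tube | double_y |
    side_branch."""
    kind = spec.get("shape")
    makers = {
        "sphere": sphere_fixture,
        "cylinder": cylinder_fixture,
        "y_tube": y_tube_fixture,
        "double_y": double_y_fixture,
        "side_branch": side_branch_fixture,
    }
    if kind not in makers:
        raise ValueError(f"unknown fixture shape {kind!r}")
    kwargs = {k: v for k, v in spec.items() if k != "shape"}
    if "domain" in kwargs:
        kwargs["shape"] = tuple(kwargs.pop("domain"))
    return makers[kind](**kwargs)


# ---------------------------------------------------------------------------
# checkpoint / restore


def save_checkpoint(state: FieldState, path, rng: np.random.Generator | None = None,
                    metadata: dict | None = None) -> Path:
    """Serialize full field state (+ optional RNG state) to one .npz container."""
    path = Path(path)
    header = {
        "version": _CHECKPOINT_VERSION,
        "step": state.step,
        "t": state.t,
        "metadata": metadata or {},
    }
    if rng is not None:
        header["rng_state"] = rng.bit_generator.state
    np.savez_compressed(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        A=state.A, H=state.H, S=state.S, Y=state.Y,
    )
    return path


def load_checkpoint(path) -> tuple[FieldState, np.random.Generator | None, dict]:
    """Restore a checkpoint; refuses version mismatches and corrupt files."""
    path = Path(path)
    try:
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            if header.get("version") != _CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint version {header.get('version')} not supported "
                    f"(expected {_CHECKPOINT_VERSION})"
                )
            state = FieldState(
                A=data["A"].copy(), H=data["H"].copy(),
                S=data["S"].copy(), Y=data["Y"].copy(),
                step=int(header["step"]), t=float(header["t"]),
            )
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"corrupt or unreadable checkpoint {path}: {exc}") from exc
    rng = None
    if "rng_state" in header:
        rng = np.random.default_rng()
        rng.bit_generator.state = header["rng_state"]
    return state, rng, header.get("metadata", {})


# ---------------------------------------------------------------------------
# config files


def configs_from_dict(cfg: dict):
    """Build (params, domain, ic, stepper) from a nested config mapping."""
    params = ModelParameters(**cfg.get("params", {}))
    domain = SimulationDomain(**cfg.get("domain", {}))
    init = dict(cfg.get("init", {}))
    if "seed_center" in init and init["seed_center"] is not None:
        init["seed_center"] = tuple(init["seed_center"])
    ic = InitialConditionSpec(**init)
    stepper = StepperConfig(**cfg.get("stepper", {}))
    return params, domain, ic, stepper


def load_config(path):
    """Load a YAML config file with [params]/[domain]/[init]/[stepper] keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return configs_from_dict(cfg)


def run_metadata(params, domain, ic, stepper, log=None, extra=None) -> dict:
    from branchrd import __version__

    md = {
        "software": {"name": "branchrd", "version": __version__},
        "params": params.to_dict(),
        "domain": domain.to_dict(),
        "init": ic.to_dict(),
        "stepper": stepper.to_dict(),
    }
    if log is not None:
        md["log"] = log.to_dict()
    if extra:
        md.update(extra)
    return md
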