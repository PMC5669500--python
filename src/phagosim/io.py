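"""Configuration, trajectory storage and reproducibility metadata.

A trajectory is a directory: ``meta.json`` (format version, seed, full
configuration + hash, units), numbered full-precision ASCII PLY frames,
optional per-frame chain tables, and a TSV observable table.  Coordinates
are written with 17 significant digits so the write/read round trip is
bit-identical for float64.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .mesh import TriMesh
from .proteins import DimerChain

__all__ = [
    "ConfigError",
    "TrajectoryError",
    "DEFAULT_CONFIG",
    "PRESETS",
    "load_config",
    "config_hash",
    "write_ply",
    "read_ply",
    "write_trajectory",
    "read_trajectory",
]

FORMAT_VERSION = 1

UNITS = {
    "length": "tether length scale l",
    "energy": "k_B T (branch energies also reported in 8*pi*kappa units)",
}


class ConfigError(ValueError):
    pass


class TrajectoryError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# defaults: free-vesicle runs (kappa = 20); protein presets override below
DEFAULT_CONFIG = {
    "preset": None,             # optional scenario name (see PRESETS)
    "kappa": 20.0,              # bending rigidity, k_B T
    "K_A": 1.0e6,               # area constraint stiffness, k_B T
    "K_V": 1.0e6,               # volume constraint stiffness, k_B T
    "K_da": 0.0,                # area-difference constraint stiffness
    "da_0": 1.0,                # area-difference target
    "u": 0.0,                   # reduced binding strength (8*pi*kappa units)
    "d0": 0.5,                  # adhesion well inner edge, l
    "d1": 1.0,                  # adhesion well outer edge, l
    "n_spheres": 1,             # fused-vesicle count of the start shape
    "n_dimers": 0,              # protein dimers to place
    "chain_shape": "s",         # "s" or "straight"
    "subdivision_level": 3,     # icosphere level for sphere starts
    "n_sweeps": 10000,          # production sweeps
    "sample_stride": 50,        # observable sampling stride, sweeps
    "frame_stride": 0,          # trajectory frame stride (0 = final only)
    "temperature": 1.0,         # k_B T
    "seed": 0,
}

_POSITIVE = ("kappa", "temperature")
_NON_NEGATIVE = ("K_A", "K_V", "K_da", "u", "d0", "d1", "n_sweeps",
                 "sample_stride", "frame_stride", "seed")
_INT_FIELDS = ("n_spheres", "n_dimers", "subdivision_level", "n_sweeps",
               "sample_stride", "frame_stride", "seed")

# protein-run presets (kappa = 10, softer area/volume constraints)
PRESETS = {
    "free_vesicle": {"n_spheres": 3, "K_da": 5e6},
    "fused3_s6": {"n_spheres": 3, "n_dimers": 6, "chain_shape": "s",
                  "kappa": 10.0, "K_A": 2e5, "K_V": 5e5, "u": 0.12},
    "fused4_s6": {"n_spheres": 4, "n_dimers": 6, "chain_shape": "s",
                  "kappa": 10.0, "K_A": 2e5, "K_V": 5e5, "u": 0.12},
    "fused3_straight6": {"n_spheres": 3, "n_dimers": 6,
                         "chain_shape": "straight", "kappa": 10.0,
                         "K_A": 2e5, "K_V": 5e5, "u": 0.1},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Validated run configuration from a YAML file (or dict overrides).

    Empty/missing file yields the full defaults.  Unknown keys and
    out-of-range values raise :class:`ConfigError` with the field name.  A
    ``preset`` key expands to the corresponding scenario parameters first;
    explicit keys in the same file override the preset.
    """
    raw: dict = {}
    if path is not None:
        import yaml

        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)

    cfg = dict(DEFAULT_CONFIG)
    preset = raw.get("preset")
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(
                f"preset: unknown preset {preset!r}; "
                f"choose from {sorted(PRESETS)}")
        cfg.update(PRESETS[preset])
        cfg["preset"] = preset
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, val in raw.items():
        if key == "preset":
            continue
        cfg[key] = val

    for key in _POSITIVE:
        if not cfg[key] > 0:
            raise ConfigError(f"{key}: must be positive, got {cfg[key]}")
    for key in _NON_NEGATIVE:
        if cfg[key] < 0:
            raise ConfigError(f"{key}: must be non-negative, got {cfg[key]}")
    for key in _INT_FIELDS:
        if int(cfg[key]) != cfg[key]:
            raise ConfigError(f"{key}: must be an integer, got {cfg[key]}")
        cfg[key] = int(cfg[key])
    if cfg["d1"] <= cfg["d0"]:
        raise ConfigError("d1: adhesion well must have d1 > d0")
    if cfg["chain_shape"] not in ("s", "straight"):
        raise ConfigError("chain_shape: must be 's' or 'straight'")
    if not 1 <= cfg["n_spheres"] <= 8:
        raise ConfigError("n_spheres: must be between 1 and 8")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration (canonical JSON, sha256)."""
    blob = json.dumps(cfg, sort_keys=True, separators=(",", ":"),
                      default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# full-precision ASCII PLY
# ---------------------------------------------------------------------------

def write_ply(mesh: TriMesh, path) -> None:
    """ASCII PLY with 17-significant-digit coordinates (lossless for
    float64 round trips)."""
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x", "property double y", "property double z",
        f"element face {mesh.n_triangles}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ply(path) -> TriMesh:
    """Read an ASCII PLY written by :func:`write_ply` (or compatible)."""
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise TrajectoryError(f"{path}: not a PLY file")
    nv = nf = None
    i = 0
    for i, line in enumerate(text):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            nv = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            nf = int(parts[2])
        elif parts[:1] == ["end_header"]:
            break
    else:
        raise TrajectoryError(f"{path}: missing end_header")
    if nv is None or nf is None:
        raise TrajectoryError(f"{path}: missing element declarations")
    body = text[i + 1:]
    if len(body) < nv + nf:
        raise TrajectoryError(
            f"{path}: truncated (expected {nv + nf} body lines, "
            f"got {len(body)})")
    verts = np.array([[float(x) for x in body[j].split()[:3]]
                      for j in range(nv)])
    tris = np.array([[int(x) for x in body[nv + j].split()[1:4]]
                     for j in range(nf)], dtype=np.int64)
    return TriMesh(verts, tris)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _write_chains(chains, path) -> None:
    rows = ["chain\tbead\tx\ty\tz\tshape"]
    for ci, c in enumerate(chains):
        for bi, p in enumerate(c.positions):
            rows.append(f"{ci}\t{bi}\t{p[0]:.17g}\t{p[1]:.17g}"
                        f"\t{p[2]:.17g}\t{c.shape}")
    Path(path).write_text("\n".join(rows) + "\n")


def _read_chains(path, templates=None):
    lines = Path(path).read_text().splitlines()[1:]
    groups: dict[int, list] = {}
    shapes: dict[int, str] = {}
    for line in lines:
        ci, bi, x, y, z, shape = line.split("\t")
        groups.setdefault(int(ci), []).append([float(x), float(y), float(z)])
        shapes[int(ci)] = shape
    chains = []
    for ci in sorted(groups):
        pos = np.asarray(groups[ci])
        if templates is not None and ci < len(templates):
            c = templates[ci].copy()
            c.positions = pos
        else:
            from .proteins import build_s_dimer, build_straight_chain

            build = (build_s_dimer if shapes[ci] == "s"
                     else build_straight_chain)
            c = build(n_beads=len(pos))
            c.positions = pos
        chains.append(c)
    return chains


def write_trajectory(path, frames, observables=None, obs_columns=None,
                     config: dict | None = None, seed: int | None = None,
                     frame_stride: int | None = None) -> None:
    """Write frames (meshes or (mesh, chains) pairs) plus observables.

    ``path`` becomes a directory with ``meta.json``, ``frame_NNNNN.ply``
    (+ ``chains_NNNNN.tsv`` when chains are present) and
    ``observables.tsv``; the seed, configuration and its hash are embedded
    for exact reproduction.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n = 0
    has_chains = False
    for n, frame in enumerate(frames, start=1):
        if isinstance(frame, TriMesh):
            mesh, chains = frame, None
        else:
            mesh, chains = frame
        write_ply(mesh, path / f"frame_{n - 1:05d}.ply")
        if chains:
            has_chains = True
            _write_chains(chains, path / f"chains_{n - 1:05d}.tsv")
    if observables is not None and len(observables):
        cols = obs_columns or [f"c{i}" for i in
                               range(np.shape(observables)[1])]
        header = "\t".join(cols)
        np.savetxt(path / "observables.tsv", np.asarray(observables),
                   delimiter="\t", header=header, comments="",
                   fmt="%.17g")
    cfg = dict(config) if config else {}
    meta = {
        "format_version": FORMAT_VERSION,
        "n_frames": n,
        "has_chains": has_chains,
        "has_observables": bool(observables is not None
                                and len(observables)),
        "seed": seed,
        "frame_stride": frame_stride,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "units": UNITS,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1,
                                               default=str))


def read_trajectory(path) -> dict:
    """Read a trajectory directory; raises :class:`TrajectoryError` on
    version mismatch, missing frames or truncated files."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise TrajectoryError(f"{path}: missing meta.json")
    try:
        meta = json.loads(meta_file.read_text())
    except json.JSONDecodeError as exc:
        raise TrajectoryError(f"{path}: corrupt meta.json: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise TrajectoryError(
            f"{path}: format version {meta.get('format_version')} "
            f"(expected {FORMAT_VERSION})")
    frames = []
    for i in range(int(meta["n_frames"])):
        fply = path / f"frame_{i:05d}.ply"
        if not fply.exists():
            raise TrajectoryError(f"{path}: missing frame {i}")
        mesh = read_ply(fply)
        fch = path / f"chains_{i:05d}.tsv"
        chains = _read_chains(fch) if fch.exists() else None
        frames.append((mesh, chains))
    obs = None
    fobs = path / "observables.tsv"
    obs_columns = None
    if meta.get("has_observables") and fobs.exists():
        with open(fobs) as fh:
            obs_columns = fh.readline().strip().split("\t")
        obs = np.loadtxt(fobs, delimiter="\t", skiprows=1, ndmin=2)
    return {"meta": meta, "frames": frames, "observables": obs,
            "obs_columns": obs_columns}
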