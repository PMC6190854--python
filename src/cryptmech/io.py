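"""Configuration parsing, fixture generation, and artifact writers.

File formats are deliberately plain: flat ``key = value`` configuration
text, headered CSV for contours / cell tables / trajectories, JSON for the
run manifest, and SVG for contour snapshots.  All writers are
locale-independent (``.`` decimal point, ``\\n`` newlines, UTF-8, fixed
column order) and serialize floats with 17 significant digits so written
artifacts round-trip bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crypt_simulator import SimConfig, SimConfigError, config_from_mapping
from .geometry import Contour

__all__ = [
    "read_config",
    "write_config",
    "read_contour_csv",
    "write_contour_csv",
    "make_fixture",
    "write_outputs",
    "contour_to_svg",
    "RunManifest",
]

FLOAT_FMT = "%.17g"

_BOOL_KEYS = {"emt_enabled"}
_INT_KEYS = {"n_divisions", "ring_size", "n_cross_sections", "seed"}
_TUPLE_KEYS = {"A_L_schedule"}


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key in _BOOL_KEYS:
        if raw.lower() in ("true", "1", "yes", "on"):
            return True
        if raw.lower() in ("false", "0", "no", "off"):
            return False
        raise SimConfigError(f"config key {key!r}: expected a boolean, got {raw!r}")
    if key in _INT_KEYS:
        try:
            return int(raw)
        except ValueError as exc:
            raise SimConfigError(f"config key {key!r}: expected an integer, got {raw!r}") from exc
    if key in _TUPLE_KEYS:
        if not raw:
            return ()
        try:
            return tuple(float(v) for v in raw.split(","))
        except ValueError as exc:
            raise SimConfigError(f"config key {key!r}: expected comma-separated numbers") from exc
    if raw.lower() in ("none", ""):
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise SimConfigError(f"config key {key!r}: expected a number, got {raw!r}") from exc


def read_config(path) -> SimConfig:
    """Parse a flat ``key = value`` configuration file into a SimConfig.

    Lines are ``key = value``; blank lines and ``#`` comments are ignored.
    Unknown keys, duplicate keys, and invariant violations raise
    :class:`SimConfigError` naming the offending key.  Omitted keys take the
    documented SimConfig defaults.
    """
    text = Path(path).read_text(encoding="utf-8")
    mapping: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise SimConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in stripped.split("=", 1))
        if key in mapping:
            raise SimConfigError(f"duplicate config key: {key!r}")
        mapping[key] = _parse_value(key, raw)
    return config_from_mapping(mapping)


def write_config(config: SimConfig, path) -> None:
    """Write a SimConfig back out in the flat key = value dialect."""
    lines = []
    for key, val in asdict(config).items():
        if val is None:
            val = "none"
        elif isinstance(val, bool):
            val = "true" if val else "false"
        elif isinstance(val, (tuple, list)):
            val = ",".join(FLOAT_FMT % v for v in val)
        elif isinstance(val, float):
            val = FLOAT_FMT % val
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# contour / table CSV


def write_contour_csv(contour: Contour, path) -> None:
    """Write a contour as ``x,y`` CSV (closed implicitly, header required)."""
    df = pd.DataFrame(contour.points, columns=["x", "y"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_contour_csv(path) -> Contour:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["x", "y"]:
        raise ValueError("contour CSV must have header columns x,y")
    return Contour(df[["x", "y"]].to_numpy(dtype=float))


def cells_to_frame(cells) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.id for c in cells],
            "x": [c.position[0] for c in cells],
            "y": [c.position[1] for c in cells],
            "role": [c.role.value for c in cells],
            "column_index": [c.column_index for c in cells],
        }
    )


def junctions_to_frame(junctions) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_a": [j.cell_a for j in junctions],
            "cell_b": [j.cell_b for j in junctions],
            "rest_length": [j.rest_length for j in junctions],
            "stiffness": [j.stiffness for j in junctions],
        }
    )


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Generate a deterministic test fixture.

    Kinds
    -----
    ``ring``
        Regular MCE ring; params ``n`` (default 24), ``radius`` (1.0),
        ``stiffness`` (1.0), ``jitter`` (0.0: radial position noise drawn
        from the seeded generator).  Returns ``(cells_frame, junctions_frame)``.
    ``chain``
        Open chain of ``n`` cells along x, spacing ``spacing``; same return.
    ``teardrop``
        Closed teardrop contour (params ``n``, ``scale``, ``pinch``);
        returns a :class:`Contour`.
    ``ellipse``
        Axis-aligned ellipse (params ``n``, ``a``, ``b``); returns a
        :class:`Contour`.
    """
    from .junction_mechanics import make_ring

    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "ring":
        n = int(params.pop("n", 24))
        radius = float(params.pop("radius", 1.0))
        stiffness = float(params.pop("stiffness", 1.0))
        jitter = float(params.pop("jitter", 0.0))
        _reject_unknown(kind, params)
        cells, junctions = make_ring(n, radius, stiffness)
        if jitter > 0:
            for c in cells:
                r = radius + jitter * rng.standard_normal()
                t = math.atan2(c.position[1], c.position[0])
                c.position = np.array([r * math.cos(t), r * math.sin(t)])
        return cells_to_frame(cells), junctions_to_frame(junctions)
    if kind == "chain":
        from .junction_mechanics import Cell, Junction, Role

        n = int(params.pop("n", 10))
        spacing = float(params.pop("spacing", 1.0))
        stiffness = float(params.pop("stiffness", 1.0))
        _reject_unknown(kind, params)
        cells = [
            Cell(id=i, position=np.array([i * spacing, 0.0]), radius=spacing / 2,
                 column_index=i, role=Role.EPITHELIAL)
            for i in range(n)
        ]
        junctions = [
            Junction(cell_a=i, cell_b=i + 1, rest_length=spacing, stiffness=stiffness)
            for i in range(n - 1)
        ]
        return cells_to_frame(cells), junctions_to_frame(junctions)
    if kind == "teardrop":
        n = int(params.pop("n", 256))
        scale = float(params.pop("scale", 1.0))
        pinch = float(params.pop("pinch", 2.0))
        _reject_unknown(kind, params)
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        x = scale * np.cos(t)
        y = scale * np.sin(t) * np.sin(t / 2.0) ** pinch
        return Contour(np.column_stack([x, y]))
    if kind == "ellipse":
        n = int(params.pop("n", 256))
        a = float(params.pop("a", 1.0))
        b = float(params.pop("b", 1.0))
        _reject_unknown(kind, params)
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        return Contour(np.column_stack([a * np.cos(t), b * np.sin(t)]))
    raise ValueError(f"unknown fixture kind: {kind!r}")


def _reject_unknown(kind: str, params: dict) -> None:
    if params:
        raise ValueError(f"unknown parameter(s) for {kind!r} fixture: {sorted(params)}")


# ---------------------------------------------------------------------------
# SVG


def contour_to_svg(contour: Contour, path, *, size: int = 400, margin: float = 0.05) -> None:
    """Render a closed contour as a standalone SVG polygon."""
    pts = contour.points
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = float(max((hi - lo).max(), 1e-12))
    pad = margin * span
    scale = size / (span + 2 * pad)

    def to_px(p):
        q = (p - lo + pad) * scale
        return q[0], size - q[1]  # flip y for screen coordinates

    coords = " ".join("%.3f,%.3f" % to_px(p) for p in pts)
    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">\n'
        f'  <polygon points="{coords}" fill="none" stroke="black" stroke-width="1.5"/>\n'
        "</svg>\n"
    )
    Path(path).write_text(svg, encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# run outputs + manifest


class RunManifest(dict):
    """JSON-serializable manifest: config snapshot, seed, artifacts, hash."""

    @property
    def provenance_hash(self) -> str:
        return self["provenance_hash"]


def _canonical_inputs_hash(config: SimConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def write_outputs(result, out_dir, *, svg: bool = False) -> RunManifest:
    """Write all artifacts of a simulation run and return the manifest.

    Artifacts: ``trajectory.csv`` (per-step record), ``depth.csv``
    (per-cross-section displacement), ``emt_events.csv``, ``ledger.csv``
    (per-division hysteresis record), ``manifest.json`` and, optionally,
    one SVG per checkpoint contour.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    traj = pd.DataFrame.from_records(
        result.records,
        columns=["step", "F_C_xz", "S_x", "label", "iso_ratio", "aspect_ratio",
                 "n_emt_events", "residual"],
    )
    traj_path = out / "trajectory.csv"
    traj.to_csv(traj_path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    files.append(traj_path.name)

    depth = pd.DataFrame(
        {
            "m": [s.m for s in result.depth_sections],
            "S_x_m": [s.S_x_m for s in result.depth_sections],
            "D_L": [s.D_L for s in result.depth_sections],
        }
    )
    depth_path = out / "depth.csv"
    depth.to_csv(depth_path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    files.append(depth_path.name)

    emt = pd.DataFrame(
        {
            "step": [e.step_index for e in result.emt_events],
            "cell_id": [e.cell_id for e in result.emt_events],
            "force_at_trigger": [e.force_at_trigger for e in result.emt_events],
            "y_p_before": [e.y_p_before for e in result.emt_events],
            "y_p_after": [e.y_p_after for e in result.emt_events],
        }
    )
    emt_path = out / "emt_events.csv"
    emt.to_csv(emt_path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    files.append(emt_path.name)

    cum = result.ledger.cumulative
    led = pd.DataFrame(
        {
            "n": [e.index for e in result.ledger.events],
            "F": [e.applied_force for e in result.ledger.events],
            "K_spring": [e.K_spring for e in result.ledger.events],
            "F_v": [e.F_v for e in result.ledger.events],
            "S_n": [e.S_n for e in result.ledger.events],
            "S0_n": [e.S0_n for e in result.ledger.events],
            "net": [e.net for e in result.ledger.events],
            "S_x_cumulative": cum,
        }
    )
    led_path = out / "ledger.csv"
    led.to_csv(led_path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    files.append(led_path.name)

    if svg:
        for idx, contour in sorted(result.checkpoint_contours.items()):
            p = out / f"contour_{idx:05d}.svg"
            contour_to_svg(contour, p)
            files.append(p.name)

    manifest = RunManifest(
        version=__version__,
        seed=result.config.seed,
        config=asdict(result.config),
        artifacts=files,
        provenance_hash=_canonical_inputs_hash(result.config),
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
        newline="\n",
    )
    return manifest
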