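"""Readers, writers and configuration glue.

Mesh interchange uses two small ASCII dialects common in FE work: VTK legacy
unstructured grids (tets as cell type 10, patch facets as triangle cells with
a ``patch_id`` cell-data array) and Gmsh MSH v2 (tets as element type 4,
patch facets as type-2 triangles carrying physical tags named in
``$PhysicalNames``).  Node indices are 0-based in memory regardless of the
on-disk dialect (MSH is 1-based on disk).  Landmarks travel in a JSON sidecar
``<file>.landmarks.json``; for VTK the patch-id-to-name map rides along in
the same sidecar.

The pipeline configuration is YAML with the published constants as defaults
(cortical bone E = 17000 MPa, menisci 120 MPa, cartilage 15 MPa, tendon
900 MPa; grounding springs 1e9 N/mm, stabilisation springs 1 N/mm; segment
masses 6.22 / 3.8 kg).  Unknown keys are rejected.  Reports are written as
canonical JSON (sorted keys) so re-serialisation is byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .synthetic_anatomy import (
    DEFAULT_GRF_MAGNITUDES,
    DEFAULT_KNEE_FLEXION,
    GaitConfig,
    LimbConfig,
    MaterialSpec,
    TetPartMesh,
)

__all__ = [
    "ParseError",
    "PipelineConfig",
    "read_mesh",
    "write_mesh",
    "read_config",
    "write_report",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "{:.17g}"


def _fmt(x: float) -> str:
    return _FLOAT_FMT.format(float(x))


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".landmarks.json")


def write_mesh(mesh: TetPartMesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a part mesh as VTK legacy (``.vtk``) or Gmsh MSH v2 (``.msh``)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "msh":
        _write_msh(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (use 'vtk' or 'msh')")
    sidecar = {
        "part": mesh.name,
        "landmarks": {k: [float(x) for x in v] for k, v in mesh.landmarks.items()},
    }
    if fmt == "vtk":
        sidecar["patch_ids"] = {name: i + 1 for i, name in enumerate(mesh.patches)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_mesh(path: str | Path, fmt: str | None = None) -> TetPartMesh:
    """Read a part mesh written by :func:`write_mesh` (or compatible files)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "vtk":
        mesh = _read_vtk(path)
    elif fmt == "msh":
        mesh = _read_msh(path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (use 'vtk' or 'msh')")
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        mesh.name = meta.get("part", mesh.name)
        mesh.landmarks = {
            k: np.asarray(v, float) for k, v in meta.get("landmarks", {}).items()
        }
        ids = meta.get("patch_ids")
        if ids and mesh.patches and set(mesh.patches) != set(ids):
            # VTK stores numeric ids; translate to names via the sidecar
            by_id = {v: k for k, v in ids.items()}
            mesh.patches = {
                by_id.get(int(k.split(":")[-1]), k): v for k, v in mesh.patches.items()
            }
    return mesh


def _write_vtk(mesh: TetPartMesh, path: Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        mesh.name,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(mesh.nodes)} double",
    ]
    for p in mesh.nodes:
        lines.append(" ".join(_fmt(x) for x in p))
    patch_items = list(mesh.patches.items())
    n_tris = sum(len(f) for _n, f in patch_items)
    n_cells = len(mesh.tets) + n_tris
    size = 5 * len(mesh.tets) + 4 * n_tris
    lines.append(f"CELLS {n_cells} {size}")
    for t in mesh.tets:
        lines.append("4 " + " ".join(str(i) for i in t))
    for _name, facets in patch_items:
        for f in facets:
            lines.append("3 " + " ".join(str(i) for i in f))
    lines.append(f"CELL_TYPES {n_cells}")
    lines.extend(["10"] * len(mesh.tets))
    for _name, facets in patch_items:
        lines.extend(["5"] * len(facets))
    lines.append(f"CELL_DATA {n_cells}")
    lines.append("SCALARS patch_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(["-1"] * len(mesh.tets))
    for pid, (_name, facets) in enumerate(patch_items, start=1):
        lines.extend([str(pid)] * len(facets))
    path.write_text("\n".join(lines) + "\n")


def _read_vtk(path: Path) -> TetPartMesh:
    lines = path.read_text().splitlines()
    try:
        return _parse_vtk(lines, path)
    except (IndexError, StopIteration) as exc:
        raise ParseError(f"{path}: unexpected end of file") from exc


def _parse_vtk(lines: list[str], path: Path) -> TetPartMesh:
    i = 0

    def tokens_from(start: int, count: int, what: str):
        nonlocal i
        toks: list[str] = []
        i = start
        while len(toks) < count:
            if i >= len(lines):
                raise ParseError(f"{path}:{i}: truncated {what}")
            toks.extend(lines[i].split())
            i += 1
        return toks

    name = lines[1].strip() if len(lines) > 1 else "mesh"
    while i < len(lines) and not lines[i].startswith("POINTS"):
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no POINTS section")
    try:
        npts = int(lines[i].split()[1])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}:{i + 1}: malformed POINTS header") from exc
    toks = tokens_from(i + 1, 3 * npts, "POINTS block")
    nodes = np.array(toks, dtype=float).reshape(npts, 3)

    while i < len(lines) and not lines[i].startswith("CELLS"):
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no CELLS section")
    header_line = i
    try:
        ncells, size = (int(x) for x in lines[i].split()[1:3])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}:{i + 1}: malformed CELLS header") from exc
    toks = tokens_from(i + 1, size, "CELLS block")
    cells = []
    k = 0
    for _ in range(ncells):
        cnt = int(toks[k])
        cells.append([int(x) for x in toks[k + 1 : k + 1 + cnt]])
        k += 1 + cnt

    while i < len(lines) and not lines[i].startswith("CELL_TYPES"):
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no CELL_TYPES section")
    toks = tokens_from(i + 1, ncells, "CELL_TYPES block")
    ctypes = [int(x) for x in toks]

    patch_ids = [-1] * ncells
    while i < len(lines) and not lines[i].startswith("SCALARS patch_id"):
        i += 1
    if i < len(lines):
        toks = tokens_from(i + 2, ncells, "patch_id block")
        patch_ids = [int(x) for x in toks]

    tets, patches = [], {}
    for ci, (cell, ct) in enumerate(zip(cells, ctypes)):
        if ct == 10:
            tets.append(cell)
        elif ct == 5:
            patches.setdefault(f"patch:{patch_ids[ci]}", []).append(cell)
        else:
            raise ParseError(
                f"{path}:{header_line + 1}: unsupported cell type {ct} "
                f"(only tetrahedra and patch triangles are allowed)"
            )
    return TetPartMesh(
        name=name,
        nodes=nodes,
        tets=np.asarray(tets, dtype=np.int64).reshape(-1, 4),
        patches={k: np.asarray(v, dtype=np.int64) for k, v in patches.items()},
    )


def _write_msh(mesh: TetPartMesh, path: Path) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    patch_items = list(mesh.patches.items())
    lines.append("$PhysicalNames")
    lines.append(str(len(patch_items)))
    for pid, (pname, _f) in enumerate(patch_items, start=1):
        lines.append(f'2 {pid} "{pname}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(len(mesh.nodes)))
    for k, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{k} " + " ".join(_fmt(x) for x in p))
    lines.append("$EndNodes")
    n_tris = sum(len(f) for _n, f in patch_items)
    lines.append("$Elements")
    lines.append(str(len(mesh.tets) + n_tris))
    eid = 1
    for t in mesh.tets:
        lines.append(f"{eid} 4 2 0 0 " + " ".join(str(i + 1) for i in t))
        eid += 1
    for pid, (_pname, facets) in enumerate(patch_items, start=1):
        for f in facets:
            lines.append(f"{eid} 2 2 {pid} {pid} " + " ".join(str(i + 1) for i in f))
            eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> TetPartMesh:
    lines = path.read_text().splitlines()
    sections: dict[str, tuple[int, list[str]]] = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            start = i + 1
            j = start
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                j += 1
            if j == len(lines):
                raise ParseError(f"{path}:{i + 1}: unterminated section ${name}")
            sections[name] = (start, lines[start:j])
            i = j + 1
        else:
            i += 1
    if "Nodes" not in sections or "Elements" not in sections:
        raise ParseError(f"{path}: missing $Nodes or $Elements section")

    start, body = sections["Nodes"]
    try:
        nn = int(body[0])
    except ValueError as exc:
        raise ParseError(f"{path}:{start + 1}: bad node count") from exc
    nodes = np.zeros((nn, 3))
    id_map: dict[int, int] = {}
    for k, line in enumerate(body[1 : 1 + nn]):
        toks = line.split()
        try:
            nid = int(toks[0])
            nodes[k] = [float(x) for x in toks[1:4]]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{start + 2 + k}: malformed node line") from exc
        id_map[nid] = k

    phys_names: dict[int, str] = {}
    if "PhysicalNames" in sections:
        _s, body_p = sections["PhysicalNames"]
        for line in body_p[1:]:
            toks = line.split(None, 2)
            if len(toks) == 3:
                phys_names[int(toks[1])] = toks[2].strip().strip('"')

    start, body = sections["Elements"]
    ne = int(body[0])
    tets, patches = [], {}
    for k, line in enumerate(body[1 : 1 + ne]):
        toks = [int(x) for x in line.split()]
        etype, ntags = toks[1], toks[2]
        conn = [id_map[t] for t in toks[3 + ntags :]]
        if etype == 4:
            tets.append(conn)
        elif etype == 2:
            pid = toks[3] if ntags >= 1 else 0
            patches.setdefault(phys_names.get(pid, f"patch:{pid}"), []).append(conn)
        else:
            raise ParseError(
                f"{path}:{start + 2 + k}: unsupported element type {etype} "
                f"(only tetrahedra and patch triangles are allowed)"
            )
    return TetPartMesh(
        name=path.stem,
        nodes=nodes,
        tets=np.asarray(tets, dtype=np.int64).reshape(-1, 4),
        patches={k: np.asarray(v, dtype=np.int64) for k, v in patches.items()},
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Thresholds:
    """Validation thresholds (percent)."""

    relative_difference_max_pct: float = 16.0
    spring_to_grf_max_pct: float = 5.0
    elastic_fraction_max_pct: float = 5.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0 < v <= 100):
                raise ValueError(f"threshold {f.name} must lie in (0, 100], got {v}")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the five-position pipeline needs, with published defaults."""

    body_mass: float = 62.0
    materials: dict = field(
        default_factory=lambda: {
            "bone": MaterialSpec(17000.0, 0.3),
            "menisci": MaterialSpec(120.0, 0.45),
            "cartilage": MaterialSpec(15.0, 0.45),
            "tendon": MaterialSpec(900.0, 0.3),
        }
    )
    grounding_k: float = 1e9  # N/mm, femoral-head fixation springs
    stabilisation_k: float = 1.0  # N/mm, weak springs at the distal tibia
    tie_k: float = 1e4  # N/mm, spring-tie surrogate for bonded non-conforming parts
    tendon_E: float = 900.0  # MPa
    tendon_A: float = 160.0  # mm^2
    tendon_L: float = 50.0  # mm
    tendon_n_springs: int = 3
    thresholds: Thresholds = field(default_factory=Thresholds)
    gait: GaitConfig = field(default_factory=GaitConfig)
    limb: LimbConfig = field(default_factory=LimbConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grounding_k", "stabilisation_k", "tie_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.tendon_E, self.tendon_A, self.tendon_L) <= 0:
            raise ValueError("tendon E, A and L must be positive")


_CONFIG_SECTIONS = {
    "body_mass",
    "materials",
    "springs",
    "tendon",
    "thresholds",
    "gait",
    "limb",
    "seed",
}


def read_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration, filling published defaults.

    Unknown keys (at the top level or inside a section) raise ``ParseError``
    naming the key; invalid values raise ``ValueError`` from the dataclass
    validators.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config root must be a mapping")
    unknown = set(raw) - _CONFIG_SECTIONS
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")

    kwargs: dict = {}
    if "body_mass" in raw:
        kwargs["body_mass"] = float(raw["body_mass"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "materials" in raw:
        mats = dict(PipelineConfig().materials)
        for name, spec in raw["materials"].items():
            extra = set(spec) - {"E", "nu"}
            if extra:
                raise ParseError(f"{path}: unknown material keys {sorted(extra)}")
            mats[name] = MaterialSpec(float(spec["E"]), float(spec["nu"]))
        kwargs["materials"] = mats
    if "springs" in raw:
        allowed = {"grounding_k", "stabilisation_k", "tie_k"}
        extra = set(raw["springs"]) - allowed
        if extra:
            raise ParseError(f"{path}: unknown spring keys {sorted(extra)}")
        for k, v in raw["springs"].items():
            kwargs[k] = float(v)
    if "tendon" in raw:
        allowed = {"E", "A", "L", "n_springs"}
        extra = set(raw["tendon"]) - allowed
        if extra:
            raise ParseError(f"{path}: unknown tendon keys {sorted(extra)}")
        mapping = {"E": "tendon_E", "A": "tendon_A", "L": "tendon_L",
                   "n_springs": "tendon_n_springs"}
        for k, v in raw["tendon"].items():
            kwargs[mapping[k]] = type(getattr(PipelineConfig(), mapping[k]))(v)
    if "thresholds" in raw:
        allowed = {f.name for f in fields(Thresholds)}
        extra = set(raw["thresholds"]) - allowed
        if extra:
            raise ParseError(f"{path}: unknown threshold keys {sorted(extra)}")
        kwargs["thresholds"] = Thresholds(**{k: float(v) for k, v in raw["thresholds"].items()})
    for section, cls in (("gait", GaitConfig), ("limb", LimbConfig)):
        if section in raw:
            allowed = {f.name for f in fields(cls)}
            extra = set(raw[section]) - allowed
            if extra:
                raise ParseError(f"{path}: unknown {section} keys {sorted(extra)}")
            vals = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw[section].items()
            }
            kwargs[section] = cls(**vals)
    return PipelineConfig(**kwargs)


def write_report(report: dict, path: str | Path) -> None:
    """Write a report dict as canonical JSON (sorted keys, byte-stable)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return [float(x) for x in np.asarray(o).ravel()]
        if isinstance(o, (np.floating, np.integer, np.bool_)):
            return o.item()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"cannot serialise {type(o).__name__}")

    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=default) + "\n"
    )
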