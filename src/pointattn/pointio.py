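"""Readers and writers for the point-cloud formats this tool consumes.

OFF meshes are parsed directly (the format is line-oriented; parse errors
name the offending line) with optional area-weighted surface resampling
through trimesh. PLY point clouds are handled by a small codec (ascii and
binary little-endian) that round-trips arbitrary per-vertex float scalars
such as attention weights. HDF5 uses the community layout: ``/data``
float32 (B, N, 3), ``/label`` int64 (B), optional ``/pid`` int64 (B, N).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .geometry import PointCloud

__all__ = [
    "read_pointcloud", "read_off", "write_off", "read_ply_points",
    "write_ply_points", "read_h5", "write_h5", "read_xyz", "write_xyz",
    "unit_normalize", "export_attention_csv", "export_attention_ply",
    "read_attention_csv",
]


def unit_normalize(coords: np.ndarray) -> np.ndarray:
    """Center on the centroid and scale into the unit sphere."""
    coords = np.asarray(coords, dtype=float)
    coords = coords - coords.mean(axis=0)
    scale = np.linalg.norm(coords, axis=1).max()
    return coords / scale if scale > 0 else coords


# ---------------------------------------------------------------------------
# OFF

def read_off(path) -> tuple[np.ndarray, np.ndarray]:
    """Vertices (V,3) and faces (F,3 or ragged list) from an OFF file."""
    lines = Path(path).read_text().splitlines()
    content = [(i + 1, ln.strip()) for i, ln in enumerate(lines)
               if ln.strip() and not ln.strip().startswith("#")]
    if not content:
        raise ValueError(f"{path}: empty OFF file")
    lineno, header = content[0]
    rest = content[1:]
    if header.startswith("OFF") and len(header) > 3:
        # ModelNet quirk: counts glued onto the OFF keyword line
        rest = [(lineno, header[3:].strip())] + rest
    elif header != "OFF":
        raise ValueError(f"{path}, line {lineno}: expected 'OFF' header")
    lineno, counts = rest[0]
    try:
        nv, nf, _ = (int(tok) for tok in counts.split()[:3])
    except Exception as exc:
        raise ValueError(f"{path}, line {lineno}: bad count line "
                         f"'{counts}'") from exc
    body = rest[1:]
    if len(body) < nv + nf:
        raise ValueError(f"{path}: expected {nv} vertices and {nf} faces, "
                         f"found {len(body)} data lines")
    verts = np.empty((nv, 3))
    for row, (lineno, ln) in enumerate(body[:nv]):
        toks = ln.split()
        if len(toks) < 3:
            raise ValueError(f"{path}, line {lineno}: bad vertex '{ln}'")
        verts[row] = [float(t) for t in toks[:3]]
    faces = []
    for lineno, ln in body[nv:nv + nf]:
        toks = ln.split()
        n = int(toks[0])
        if len(toks) < n + 1:
            raise ValueError(f"{path}, line {lineno}: bad face '{ln}'")
        faces.append([int(t) for t in toks[1:n + 1]])
    if nv == 0:
        raise ValueError(f"{path}: empty geometry")
    return verts, faces


def write_off(path, verts: np.ndarray, faces=None) -> None:
    verts = np.asarray(verts, dtype=float)
    faces = faces or []
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(verts)} {len(faces)} 0\n")
        for v in verts:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in faces:
            fh.write(" ".join([str(len(f)), *map(str, f)]) + "\n")


def _resample_mesh(verts: np.ndarray, faces, n_points: int,
                   seed: int = 0) -> np.ndarray:
    import trimesh

    tris = [f for f in faces if len(f) == 3]
    tris += [t for f in faces if len(f) == 4
             for t in ([f[0], f[1], f[2]], [f[0], f[2], f[3]])]
    if not tris:
        raise ValueError("mesh has no triangulable faces to resample")
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(tris),
                           process=False)
    pts, _ = trimesh.sample.sample_surface(mesh, n_points, seed=seed)
    return np.asarray(pts, dtype=float)


# ---------------------------------------------------------------------------
# PLY point clouds with scalar vertex properties

_PLY_DTYPES = {"float": "<f4", "float32": "<f4", "double": "<f8",
               "float64": "<f8"}


def write_ply_points(path, coords: np.ndarray,
                     scalars: dict[str, np.ndarray] | None = None,
                     binary: bool = False) -> None:
    coords = np.asarray(coords, dtype=np.float64)
    scalars = {k: np.asarray(v, dtype=np.float64).reshape(-1)
               for k, v in (scalars or {}).items()}
    n = len(coords)
    props = ["x", "y", "z", *scalars]
    header = ["ply",
              "format binary_little_endian 1.0" if binary
              else "format ascii 1.0",
              f"element vertex {n}",
              *[f"property double {p}" for p in props],
              "end_header"]
    cols = [coords[:, 0], coords[:, 1], coords[:, 2], *scalars.values()]
    table = np.column_stack(cols)
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(table.astype("<f8").tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for row in table:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_ply_points(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Coordinates plus any extra per-vertex scalar properties."""
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header")
    if end < 0:
        raise ValueError(f"{path}: missing end_header")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end:].split(b"\n", 1)[1]
    if not header or header[0].strip() != "ply":
        raise ValueError(f"{path}, line 1: not a PLY file")
    fmt = None
    n = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for lineno, ln in enumerate(header[1:], start=2):
        toks = ln.split()
        if not toks:
            continue
        if toks[0] == "format":
            fmt = toks[1]
        elif toks[0] == "element":
            in_vertex = toks[1] == "vertex"
            if in_vertex:
                n = int(toks[2])
        elif toks[0] == "property" and in_vertex:
            if toks[1] not in _PLY_DTYPES:
                raise ValueError(f"{path}, line {lineno}: unsupported "
                                 f"property type '{toks[1]}'")
            props.append((toks[2], _PLY_DTYPES[toks[1]]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"{path}: unsupported format '{fmt}'")
    if n is None or not props:
        raise ValueError(f"{path}: no vertex element declared")
    if fmt == "ascii":
        rows = body.decode("ascii").split()
        table = np.array([float(v) for v in rows],
                         dtype=float).reshape(n, len(props))
        data = {name: table[:, i] for i, (name, _) in enumerate(props)}
    else:
        dt = np.dtype([(name, d) for name, d in props])
        rec = np.frombuffer(body[:n * dt.itemsize], dtype=dt)
        data = {name: rec[name].astype(float) for name, _ in props}
    for axis in "xyz":
        if axis not in data:
            raise ValueError(f"{path}: vertex element lacks '{axis}'")
    coords = np.column_stack([data.pop("x"), data.pop("y"), data.pop("z")])
    return coords, data


# ---------------------------------------------------------------------------
# HDF5 stacks and whitespace XYZ

def write_h5(path, clouds: list[PointCloud]) -> None:
    data = np.stack([c.coords for c in clouds]).astype(np.float32)
    labels = np.array([-1 if c.cloud_label is None else c.cloud_label
                       for c in clouds], dtype=np.int64)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=data)
        fh.create_dataset("label", data=labels)
        if all(c.point_labels is not None for c in clouds):
            fh.create_dataset("pid", data=np.stack(
                [c.point_labels for c in clouds]).astype(np.int64))


def read_h5(path) -> list[PointCloud]:
    with h5py.File(path, "r") as fh:
        data = np.asarray(fh["data"], dtype=float)
        labels = np.asarray(fh["label"]) if "label" in fh else None
        pid = np.asarray(fh["pid"]) if "pid" in fh else None
    out = []
    for i in range(len(data)):
        out.append(PointCloud(
            data[i],
            point_labels=None if pid is None else pid[i],
            cloud_label=None if labels is None or labels[i] < 0
            else int(labels[i])))
    return out


def read_xyz(path) -> np.ndarray:
    pts = np.loadtxt(path, dtype=float)
    pts = np.atleast_2d(pts)
    if pts.shape[1] < 3:
        raise ValueError(f"{path}: need at least three columns")
    return pts[:, :3]


def write_xyz(path, coords: np.ndarray) -> None:
    np.savetxt(path, np.asarray(coords, dtype=float), fmt="%.17g")


# ---------------------------------------------------------------------------
# dispatch

def read_pointcloud(path, format: str | None = None,
                    n_points: int | None = None, normalize: bool = False,
                    seed: int = 0):
    """Read one cloud (OFF/PLY/XYZ) or a list of clouds (HDF5).

    Mesh formats yield vertices; with ``n_points`` the surface is resampled
    area-weighted to exactly that many points. ``normalize`` recenters and
    rescales into the unit sphere.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("h5", "hdf5"):
        clouds = read_h5(path)
        if normalize:
            for c in clouds:
                c.coords = unit_normalize(c.coords)
        return clouds
    if fmt == "off":
        verts, faces = read_off(path)
        coords = (_resample_mesh(verts, faces, n_points, seed)
                  if n_points and faces else verts)
    elif fmt == "ply":
        coords, _ = read_ply_points(path)
    elif fmt in ("xyz", "txt", "pts"):
        coords = read_xyz(path)
    else:
        raise ValueError(f"unknown point-cloud format '{fmt}'")
    if normalize:
        coords = unit_normalize(coords)
    return PointCloud(coords)


# ---------------------------------------------------------------------------
# attention-mask export

def export_attention_csv(path, cloud: PointCloud, weights: np.ndarray) -> None:
    weights = np.asarray(weights, dtype=float).reshape(-1)
    with open(path, "w") as fh:
        fh.write("index,x,y,z,weight\n")
        for i, (p, w) in enumerate(zip(cloud.coords, weights)):
            fh.write(f"{i},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g},{w:.17g}\n")


def read_attention_csv(path) -> tuple[np.ndarray, np.ndarray]:
    table = np.loadtxt(path, delimiter=",", skiprows=1)
    table = np.atleast_2d(table)
    return table[:, 1:4], table[:, 4]


def export_attention_ply(path, cloud: PointCloud, weights: np.ndarray,
                         binary: bool = False) -> None:
    write_ply_points(path, cloud.coords, {"weight": weights}, binary=binary)
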