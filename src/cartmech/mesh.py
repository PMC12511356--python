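"""Hexahedral meshes of a tibial-cartilage slab.

The generic medial-tibial cartilage compartment is represented as an
elliptic-planform slab (optionally thicker at the centre), discretised into
8-node trilinear hexahedra.  Coordinate convention, used consistently for
centre-of-pressure reporting:

* ``x``  anterior (+) / posterior (-), mm
* ``y``  medial  (+) / lateral  (-), mm
* ``z``  depth; the bone-side surface sits at ``z = 0`` and the articular
  surface at ``z = thickness``.

Node and element indices are 0-based internally; the Abaqus-INP dialect is
1-based on disk only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Mesh",
    "SurfaceField",
    "build_slab_mesh",
    "element_volume",
    "element_volumes",
    "face_area_centroid",
    "face_areas_centroids",
    "read_mesh",
    "write_mesh",
]

# Gauss points/weights for the reference cube [-1, 1]^3 (2x2x2 rule)
_G = 1.0 / np.sqrt(3.0)
_GP3 = np.array([[sx, sy, sz] for sz in (-_G, _G) for sy in (-_G, _G) for sx in (-_G, _G)])
_GP2 = np.array([[sx, sy] for sy in (-_G, _G) for sx in (-_G, _G)])

# Local node coordinates of the trilinear hex (VTK ordering: bottom 0-3, top 4-7)
_XI = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

# Outward-oriented local faces of a hex
_HEX_FACES = np.array(
    [
        [0, 3, 2, 1],  # bottom (-z)
        [4, 5, 6, 7],  # top (+z)
        [0, 1, 5, 4],
        [1, 2, 6, 5],
        [2, 3, 7, 6],
        [3, 0, 4, 7],
    ]
)


def hex_shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Gradients dN_a/dxi of the 8 trilinear shape functions at points ``xi``.

    Returns array of shape ``(npts, 8, 3)``.
    """
    xi = np.atleast_2d(xi)
    g = np.empty((xi.shape[0], 8, 3))
    for a in range(8):
        sx, sy, sz = _XI[a]
        g[:, a, 0] = 0.125 * sx * (1 + sy * xi[:, 1]) * (1 + sz * xi[:, 2])
        g[:, a, 1] = 0.125 * sy * (1 + sx * xi[:, 0]) * (1 + sz * xi[:, 2])
        g[:, a, 2] = 0.125 * sz * (1 + sx * xi[:, 0]) * (1 + sy * xi[:, 1])
    return g


def hex_shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a at points ``xi``; shape ``(npts, 8)``."""
    xi = np.atleast_2d(xi)
    n = np.empty((xi.shape[0], 8))
    for a in range(8):
        sx, sy, sz = _XI[a]
        n[:, a] = 0.125 * (1 + sx * xi[:, 0]) * (1 + sy * xi[:, 1]) * (1 + sz * xi[:, 2])
    return n


_DN_GP = hex_shape_gradients(_GP3)  # (8, 8, 3)
_N_GP = hex_shape_functions(_GP3)
_DN_CORNERS = hex_shape_gradients(_XI)


def quad_shape_functions(st: np.ndarray) -> np.ndarray:
    st = np.atleast_2d(st)
    n = np.empty((st.shape[0], 4))
    sgn = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    for a in range(4):
        n[:, a] = 0.25 * (1 + sgn[a, 0] * st[:, 0]) * (1 + sgn[a, 1] * st[:, 1])
    return n


def quad_shape_gradients(st: np.ndarray) -> np.ndarray:
    st = np.atleast_2d(st)
    g = np.empty((st.shape[0], 4, 2))
    sgn = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    for a in range(4):
        g[:, a, 0] = 0.25 * sgn[a, 0] * (1 + sgn[a, 1] * st[:, 1])
        g[:, a, 1] = 0.25 * sgn[a, 1] * (1 + sgn[a, 0] * st[:, 0])
    return g


_QN_GP = quad_shape_functions(_GP2)  # (4, 4)
_QDN_GP = quad_shape_gradients(_GP2)  # (4, 4, 2)


@dataclass
class Mesh:
    """Hexahedral mesh with labelled boundary faces.

    Attributes
    ----------
    nodes : (N, 3) float array, coordinates in mm.
    hexes : (E, 8) int array, trilinear hex connectivity (VTK node order).
    faces : (F, 4) int array of boundary quad faces, outward oriented.
    surface_sets : mapping name -> int array of face indices into ``faces``.
        Standard names are ``articular``, ``bone`` and ``rim``; the sets are
        disjoint and jointly cover the boundary.
    element_sets : optional named element groups.
    """

    nodes: np.ndarray
    hexes: np.ndarray
    faces: np.ndarray
    surface_sets: dict[str, np.ndarray]
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hexes.shape[0]

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        if self.hexes.min() < 0 or self.hexes.max() >= self.n_nodes:
            raise ValueError("hex connectivity references out-of-range nodes")
        dets = corner_jacobians(self)
        if dets.min() <= 0:
            bad = int(np.argwhere(dets.min(axis=1) <= 0)[0, 0])
            raise ValueError(f"non-positive corner Jacobian in element {bad}")
        all_faces = np.concatenate([np.asarray(ix) for ix in self.surface_sets.values()])
        if len(np.unique(all_faces)) != all_faces.size:
            raise ValueError("surface sets overlap")
        if sorted(all_faces.tolist()) != list(range(self.faces.shape[0])):
            raise ValueError("surface sets do not cover the boundary")

    def articular_faces(self) -> np.ndarray:
        return self.surface_sets["articular"]


@dataclass
class SurfaceField:
    """Scalar field (e.g. contact pressure, MPa) on articular faces at one frame."""

    face_ids: np.ndarray
    values: np.ndarray
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        self.face_ids = np.asarray(self.face_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.face_ids.shape != self.values.shape:
            raise ValueError("face_ids and values must have matching shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("surface field values must be finite")


def corner_jacobians(mesh: Mesh) -> np.ndarray:
    """det of the isoparametric map at the 8 corners of every hex; (E, 8)."""
    xe = mesh.nodes[mesh.hexes]  # (E, 8, 3)
    jac = np.einsum("eai,caj->ecji", xe, _DN_CORNERS)  # (E, 8corners, 3, 3)
    return np.linalg.det(jac)


def _square_to_ellipse(u: np.ndarray, v: np.ndarray, a: float, b: float):
    """Smooth bijection of the square [-1,1]^2 onto the (a, b) ellipse.

    Elliptic variant of the classic square-to-disc mapping; non-degenerate
    Jacobian everywhere (no polar singularity at the centre), boundary of the
    square maps onto the ellipse exactly.
    """
    x = a * u * np.sqrt(np.maximum(1.0 - 0.5 * v * v, 0.0))
    y = b * v * np.sqrt(np.maximum(1.0 - 0.5 * u * u, 0.0))
    return x, y


def build_slab_mesh(
    a: float,
    b: float,
    thickness: float,
    n_radial: int,
    n_circum: int,
    n_depth: int,
    thickness_profile: str = "constant",
    edge_thickness_fraction: float = 0.6,
) -> Mesh:
    """Structured hex mesh of an elliptic cartilage slab.

    Parameters
    ----------
    a, b : ellipse semi-axes in the anterior/posterior (x) and medial/lateral
        (y) directions, mm.
    thickness : slab thickness at the centre, mm.
    n_radial, n_circum, n_depth : cells along the two planform directions and
        through the depth; the element count is exactly their product.
    thickness_profile : ``"constant"`` or ``"center_thick"``.  The latter
        tapers quadratically to ``edge_thickness_fraction * thickness`` at the
        rim.
    """
    if a <= 0 or b <= 0 or thickness <= 0:
        raise ValueError("planform semi-axes and thickness must be positive")
    if min(n_radial, n_circum, n_depth) < 1:
        raise ValueError("all subdivision counts must be >= 1")
    if thickness_profile not in ("constant", "center_thick"):
        raise ValueError(f"unknown thickness profile {thickness_profile!r}")

    nu, nv, nw = n_radial, n_circum, n_depth
    u = np.linspace(-1.0, 1.0, nu + 1)
    v = np.linspace(-1.0, 1.0, nv + 1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x, y = _square_to_ellipse(uu, vv, a, b)

    if thickness_profile == "constant":
        t_map = np.full_like(x, thickness)
    else:
        rho2 = np.clip((x / a) ** 2 + (y / b) ** 2, 0.0, 1.0)
        f = edge_thickness_fraction
        t_map = thickness * (f + (1.0 - f) * (1.0 - rho2))

    # node id = (i * (nv+1) + j) * (nw+1) + k
    nodes = np.empty(((nu + 1) * (nv + 1) * (nw + 1), 3))
    zfrac = np.linspace(0.0, 1.0, nw + 1)
    nid = lambda i, j, k: (i * (nv + 1) + j) * (nw + 1) + k
    for i in range(nu + 1):
        for j in range(nv + 1):
            base = (i * (nv + 1) + j) * (nw + 1)
            nodes[base : base + nw + 1, 0] = x[i, j]
            nodes[base : base + nw + 1, 1] = y[i, j]
            nodes[base : base + nw + 1, 2] = zfrac * t_map[i, j]

    hexes = np.empty((nu * nv * nw, 8), dtype=int)
    e = 0
    for i in range(nu):
        for j in range(nv):
            for k in range(nw):
                hexes[e] = [
                    nid(i, j, k),
                    nid(i + 1, j, k),
                    nid(i + 1, j + 1, k),
                    nid(i, j + 1, k),
                    nid(i, j, k + 1),
                    nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1),
                    nid(i, j + 1, k + 1),
                ]
                e += 1

    faces: list[list[int]] = []
    sets: dict[str, list[int]] = {"articular": [], "bone": [], "rim": []}

    def add_face(nodes4: list[int], name: str) -> None:
        sets[name].append(len(faces))
        faces.append(nodes4)

    for i in range(nu):
        for j in range(nv):
            add_face([nid(i, j, 0), nid(i, j + 1, 0), nid(i + 1, j + 1, 0), nid(i + 1, j, 0)], "bone")
            k = nw
            add_face([nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k)], "articular")
    for i in range(nu):
        for k in range(nw):
            add_face([nid(i, 0, k), nid(i + 1, 0, k), nid(i + 1, 0, k + 1), nid(i, 0, k + 1)], "rim")
            add_face([nid(i, nv, k), nid(i, nv, k + 1), nid(i + 1, nv, k + 1), nid(i + 1, nv, k)], "rim")
    for j in range(nv):
        for k in range(nw):
            add_face([nid(0, j, k), nid(0, j, k + 1), nid(0, j + 1, k + 1), nid(0, j + 1, k)], "rim")
            add_face([nid(nu, j, k), nid(nu, j + 1, k), nid(nu, j + 1, k + 1), nid(nu, j, k + 1)], "rim")

    mesh = Mesh(
        nodes=nodes,
        hexes=hexes,
        faces=np.asarray(faces, dtype=int),
        surface_sets={k: np.asarray(ix, dtype=int) for k, ix in sets.items()},
    )
    # orientation guard: the structured scheme above is right-handed, but a
    # negative edge_thickness_fraction or exotic inputs must never slip through
    if corner_jacobians(mesh).min() <= 0:
        raise ValueError("slab construction produced inverted elements")
    return mesh


def build_box_mesh(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int) -> Mesh:
    """Structured box mesh (lx x ly x lz mm), labelled like the slab.

    Top face (z = lz) is ``articular``, bottom ``bone``, sides ``rim``.  Used
    for verification columns and single-element problems.
    """
    if min(lx, ly, lz) <= 0:
        raise ValueError("box dimensions must be positive")
    if min(nx, ny, nz) < 1:
        raise ValueError("subdivision counts must be >= 1")
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    zs = np.linspace(0.0, lz, nz + 1)
    nid = lambda i, j, k: (i * (ny + 1) + j) * (nz + 1) + k
    nodes = np.array([[xs[i], ys[j], zs[k]]
                      for i in range(nx + 1) for j in range(ny + 1) for k in range(nz + 1)])
    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append([
                    nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    faces: list[list[int]] = []
    sets: dict[str, list[int]] = {"articular": [], "bone": [], "rim": []}

    def add(nodes4, name):
        sets[name].append(len(faces))
        faces.append(nodes4)

    for i in range(nx):
        for j in range(ny):
            add([nid(i, j, 0), nid(i, j + 1, 0), nid(i + 1, j + 1, 0), nid(i + 1, j, 0)], "bone")
            add([nid(i, j, nz), nid(i + 1, j, nz), nid(i + 1, j + 1, nz), nid(i, j + 1, nz)], "articular")
    for i in range(nx):
        for k in range(nz):
            add([nid(i, 0, k), nid(i + 1, 0, k), nid(i + 1, 0, k + 1), nid(i, 0, k + 1)], "rim")
            add([nid(i, ny, k), nid(i, ny, k + 1), nid(i + 1, ny, k + 1), nid(i + 1, ny, k)], "rim")
    for j in range(ny):
        for k in range(nz):
            add([nid(0, j, k), nid(0, j, k + 1), nid(0, j + 1, k + 1), nid(0, j + 1, k)], "rim")
            add([nid(nx, j, k), nid(nx, j + 1, k), nid(nx, j + 1, k + 1), nid(nx, j, k + 1)], "rim")
    return Mesh(
        nodes=nodes,
        hexes=np.asarray(hexes, dtype=int),
        faces=np.asarray(faces, dtype=int),
        surface_sets={k: np.asarray(v, dtype=int) for k, v in sets.items()},
    )


def element_volumes(mesh: Mesh, node_coords: np.ndarray | None = None) -> np.ndarray:
    """Volumes of all elements by 8-point Gauss quadrature; (E,) in mm^3."""
    coords = mesh.nodes if node_coords is None else np.asarray(node_coords)
    xe = coords[mesh.hexes]
    jac = np.einsum("eai,gaj->egji", xe, _DN_GP)
    return np.linalg.det(jac).sum(axis=1)


def element_volume(mesh: Mesh, element_id: int, node_coords_override: np.ndarray | None = None) -> float:
    """Volume (mm^3) of one element, optionally in a deformed configuration."""
    if not 0 <= element_id < mesh.n_elements:
        raise IndexError(f"element {element_id} out of range")
    coords = mesh.nodes if node_coords_override is None else np.asarray(node_coords_override)
    xe = coords[mesh.hexes[element_id]]
    jac = np.einsum("ai,gaj->gji", xe, _DN_GP)
    vol = float(np.linalg.det(jac).sum())
    if vol <= 0:
        raise ValueError(f"element {element_id} has non-positive volume")
    return vol


def face_areas_centroids(mesh: Mesh, face_ids: np.ndarray | None = None, node_coords: np.ndarray | None = None):
    """Areas (mm^2) and area-weighted centroids (mm) of quad faces by 2x2 quadrature."""
    ids = np.arange(mesh.faces.shape[0]) if face_ids is None else np.asarray(face_ids, dtype=int)
    coords = mesh.nodes if node_coords is None else np.asarray(node_coords)
    xf = coords[mesh.faces[ids]]  # (F, 4, 3)
    tang = np.einsum("fai,gad->fgdi", xf, _QDN_GP)  # (F, 4gp, 2, 3)
    cross = np.cross(tang[:, :, 0, :], tang[:, :, 1, :])  # (F, 4gp, 3)
    da = np.linalg.norm(cross, axis=2)  # (F, 4gp)
    areas = da.sum(axis=1)
    pts = np.einsum("ga,fai->fgi", _QN_GP, xf)  # (F, 4gp, 3)
    centroids = np.einsum("fg,fgi->fi", da, pts) / areas[:, None]
    return areas, centroids


def face_area_centroid(mesh: Mesh, face_id: int) -> tuple[float, np.ndarray]:
    """Area (mm^2) and area-weighted centroid of one boundary quad face."""
    if not 0 <= face_id < mesh.faces.shape[0]:
        raise IndexError(f"face {face_id} out of range")
    areas, cents = face_areas_centroids(mesh, np.array([face_id]))
    return float(areas[0]), cents[0]


def total_volume(mesh: Mesh) -> float:
    return float(element_volumes(mesh).sum())


# ---------------------------------------------------------------------------
# I/O: legacy-ASCII VTK unstructured grid and a restricted Abaqus-INP dialect
# ---------------------------------------------------------------------------

_VTK_HEX = 12


def write_mesh(mesh: Mesh, path: str | Path, fmt: str = "vtk") -> None:
    path = Path(path)
    if fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "inp_subset":
        _write_inp(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def read_mesh(path: str | Path, fmt: str = "vtk") -> Mesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "vtk":
        return _read_vtk(path)
    if fmt == "inp_subset":
        return _read_inp(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


def _fmt_float(x: float) -> str:
    return format(x, ".17g")


def _write_vtk(mesh: Mesh, path: Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "cartmech mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for p in mesh.nodes:
        lines.append(" ".join(_fmt_float(c) for c in p))
    ne = mesh.n_elements
    lines.append(f"CELLS {ne} {ne * 9}")
    for h in mesh.hexes:
        lines.append("8 " + " ".join(str(i) for i in h))
    lines.append(f"CELL_TYPES {ne}")
    lines.extend([str(_VTK_HEX)] * ne)
    # face table and named sets carried in FIELD blocks (ignored by viewers)
    n_extra = 1 + len(mesh.surface_sets) + len(mesh.element_sets)
    lines.append(f"FIELD cartmech {n_extra}")
    lines.append(f"boundary_faces 4 {mesh.faces.shape[0]} int")
    for f in mesh.faces:
        lines.append(" ".join(str(i) for i in f))
    for name, ids in mesh.surface_sets.items():
        lines.append(f"surface_set_{name} 1 {len(ids)} int")
        lines.append(" ".join(str(i) for i in ids) if len(ids) else "")
    for name, ids in mesh.element_sets.items():
        lines.append(f"element_set_{name} 1 {len(ids)} int")
        lines.append(" ".join(str(i) for i in ids) if len(ids) else "")
    path.write_text("\n".join(lines) + "\n")


def _read_vtk(path: Path) -> Mesh:
    tokens_lines = path.read_text().splitlines()
    i = 0

    def expect(pred, msg):
        if not pred:
            raise ValueError(f"{path}:{i + 1}: {msg}")

    expect(tokens_lines[0].startswith("# vtk DataFile"), "not a legacy VTK file")
    while not tokens_lines[i].startswith("DATASET"):
        i += 1
    expect("UNSTRUCTURED_GRID" in tokens_lines[i], "only UNSTRUCTURED_GRID is supported")
    i += 1
    expect(tokens_lines[i].startswith("POINTS"), "POINTS block expected")
    n_pts = int(tokens_lines[i].split()[1])
    nodes = np.array([[float(t) for t in tokens_lines[i + 1 + j].split()] for j in range(n_pts)])
    i += 1 + n_pts
    expect(tokens_lines[i].startswith("CELLS"), "CELLS block expected")
    n_cells = int(tokens_lines[i].split()[1])
    hexes = np.empty((n_cells, 8), dtype=int)
    for j in range(n_cells):
        parts = tokens_lines[i + 1 + j].split()
        if parts[0] != "8":
            raise ValueError(f"{path}:{i + 2 + j}: only 8-node cells are supported")
        hexes[j] = [int(t) for t in parts[1:]]
    i += 1 + n_cells
    expect(tokens_lines[i].startswith("CELL_TYPES"), "CELL_TYPES block expected")
    for j in range(n_cells):
        if tokens_lines[i + 1 + j].strip() != str(_VTK_HEX):
            raise ValueError(f"{path}:{i + 2 + j}: unsupported cell type (need {_VTK_HEX}/hexahedron)")
    i += 1 + n_cells
    faces = np.empty((0, 4), dtype=int)
    surface_sets: dict[str, np.ndarray] = {}
    element_sets: dict[str, np.ndarray] = {}
    while i < len(tokens_lines):
        line = tokens_lines[i].strip()
        if line.startswith("FIELD"):
            i += 1
            continue
        if not line:
            i += 1
            continue
        name, ncomp, ntup, _dtype = line.split()
        ncomp, ntup = int(ncomp), int(ntup)
        vals: list[int] = []
        j = i + 1
        while len(vals) < ncomp * ntup:
            vals.extend(int(t) for t in tokens_lines[j].split())
            j += 1
        if ntup == 0:
            j = i + 2  # writer emits one (possibly empty) line
        arr = np.array(vals, dtype=int).reshape(ntup, ncomp)
        if name == "boundary_faces":
            faces = arr
        elif name.startswith("surface_set_"):
            surface_sets[name[len("surface_set_"):]] = arr.ravel()
        elif name.startswith("element_set_"):
            element_sets[name[len("element_set_"):]] = arr.ravel()
        i = j
    return Mesh(nodes=nodes, hexes=hexes, faces=faces, surface_sets=surface_sets, element_sets=element_sets)


def _write_inp(mesh: Mesh, path: Path) -> None:
    lines = ["*HEADING", "cartmech cartilage slab", "*NODE"]
    for n, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{n}, {_fmt_float(p[0])}, {_fmt_float(p[1])}, {_fmt_float(p[2])}")
    lines.append("*ELEMENT, TYPE=C3D8P, ELSET=CARTILAGE")
    for e, h in enumerate(mesh.hexes, start=1):
        lines.append(f"{e}, " + ", ".join(str(i + 1) for i in h))
    for name, ids in mesh.element_sets.items():
        lines.append(f"*ELSET, ELSET={name.upper()}")
        for chunk in np.array_split(np.asarray(ids) + 1, max(1, (len(ids) + 15) // 16)):
            if len(chunk):
                lines.append(", ".join(str(i) for i in chunk))
    for name, ids in mesh.surface_sets.items():
        node_ids = np.unique(mesh.faces[ids]) + 1 if len(ids) else np.empty(0, dtype=int)
        lines.append(f"*NSET, NSET=SURF_{name.upper()}")
        for chunk in np.array_split(node_ids, max(1, (len(node_ids) + 15) // 16)):
            if len(chunk):
                lines.append(", ".join(str(i) for i in chunk))
    path.write_text("\n".join(lines) + "\n")


_SUPPORTED_INP_TYPES = {"C3D8", "C3D8P", "C3D8PH", "C3D8R"}


def _read_inp(path: Path) -> Mesh:
    nodes: dict[int, list[float]] = {}
    elems: dict[int, list[int]] = {}
    nsets: dict[str, list[int]] = {}
    elsets: dict[str, list[int]] = {}
    mode = None
    current: list[int] | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            key = line.split(",")[0].strip().upper()
            opts = {
                kv.split("=")[0].strip().upper(): kv.split("=")[1].strip()
                for kv in line.split(",")[1:]
                if "=" in kv
            }
            if key == "*NODE":
                mode = "node"
            elif key == "*ELEMENT":
                etype = opts.get("TYPE", "").upper()
                if etype not in _SUPPORTED_INP_TYPES:
                    raise ValueError(
                        f"{path}:{lineno}: unsupported element type {etype!r} "
                        f"(supported: {sorted(_SUPPORTED_INP_TYPES)})"
                    )
                mode = "element"
                if "ELSET" in opts:
                    current = elsets.setdefault(opts["ELSET"].upper(), [])
                else:
                    current = None
            elif key == "*NSET":
                mode = "nset"
                current = nsets.setdefault(opts["NSET"].upper(), [])
            elif key == "*ELSET":
                mode = "elset"
                current = elsets.setdefault(opts["ELSET"].upper(), [])
            else:
                mode = None  # *HEADING and friends: ignore
            continue
        parts = [t for t in line.replace(",", " ").split() if t]
        if mode == "node":
            nodes[int(parts[0])] = [float(t) for t in parts[1:4]]
        elif mode == "element":
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: hex element needs 8 nodes")
            eid = int(parts[0])
            elems[eid] = [int(t) for t in parts[1:]]
            if current is not None:
                current.append(eid)
        elif mode in ("nset", "elset"):
            current.extend(int(t) for t in parts)

    if not nodes or not elems:
        raise ValueError(f"{path}: no nodes/elements found")
    node_ids = sorted(nodes)
    remap = {nid: i for i, nid in enumerate(node_ids)}
    node_arr = np.array([nodes[nid] for nid in node_ids])
    elem_ids = sorted(elems)
    eremap = {eid: i for i, eid in enumerate(elem_ids)}
    hex_arr = np.array([[remap[n] for n in elems[eid]] for eid in elem_ids], dtype=int)

    mesh = Mesh(nodes=node_arr, hexes=hex_arr, faces=np.empty((0, 4), dtype=int), surface_sets={})
    faces, owners = boundary_faces(hex_arr)
    mesh.faces = faces

    surface_sets: dict[str, np.ndarray] = {}
    for name, ids in nsets.items():
        if not name.startswith("SURF_"):
            continue
        nodeset = {remap[n] for n in ids if n in remap}
        hit = [fi for fi in range(faces.shape[0]) if set(faces[fi]) <= nodeset]
        surface_sets[name[len("SURF_"):].lower()] = np.array(hit, dtype=int)
    if surface_sets:
        claimed = np.concatenate(list(surface_sets.values())) if surface_sets else np.empty(0, int)
        rest = np.setdiff1d(np.arange(faces.shape[0]), claimed)
        if len(rest):
            surface_sets.setdefault("rim", np.empty(0, dtype=int))
            surface_sets["rim"] = np.union1d(surface_sets["rim"], rest)
    else:
        surface_sets = {"articular": np.arange(faces.shape[0])}
    mesh.surface_sets = surface_sets
    mesh.element_sets = {
        name.lower(): np.array(sorted(eremap[e] for e in ids if e in eremap), dtype=int)
        for name, ids in elsets.items()
        if name != "CARTILAGE"
    }
    return mesh


def boundary_faces(hexes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract outward-oriented boundary quads; returns (faces, owner elements)."""
    all_faces = hexes[:, _HEX_FACES]  # (E, 6, 4)
    flat = all_faces.reshape(-1, 4)
    key = np.sort(flat, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    owners = np.repeat(np.arange(hexes.shape[0]), 6)[on_boundary]
    return flat[on_boundary].copy(), owners
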