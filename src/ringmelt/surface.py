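"""Disc-topology minimal surfaces spanned on ring contours.

A triangulated surface with the ring contour as its fixed boundary is
evolved by steepest descent on total area ("overdamped surface-tension
evolution"), interleaved with mesh maintenance that preserves the disc
topology (Euler characteristic V - E + F = 1): area-decreasing edge flips,
refinement of long interior edges, and collapse of short ones.  The
boundary polyline never moves, so the surface is exactly bounded by the
simulated contour.  The result approximates the least-area disc; a global
minimum is not guaranteed (nor needed -- piercing analysis is robust to the
residual).
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

__all__ = ["TriangulatedSurface", "triangulate_ring", "minimize_area", "surface_area"]


class TriangulatedSurface:
    """Triangle mesh with a fixed boundary cycle.

    The first ``n_boundary`` vertices are the ring's contour in order and
    are immutable; the rest are free interior vertices.  Faces are index
    triples with consistent orientation.
    """

    def __init__(self, vertices, faces, n_boundary):
        self.vertices = np.asarray(vertices, dtype=float).copy()
        self.faces = np.asarray(faces, dtype=np.int64).copy()
        self.n_boundary = int(n_boundary)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (nv, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (nf, 3)")

    # -- basic quantities ---------------------------------------------------

    @property
    def n_vertices(self):
        return len(self.vertices)

    @property
    def n_faces(self):
        return len(self.faces)

    def edges(self):
        """Set of undirected edges as a (ne, 2) sorted-index array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self):
        return self.n_vertices - len(self.edges()) + self.n_faces

    def triangle_areas(self):
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def area(self):
        return float(self.triangle_areas().sum())

    def boundary_contour(self):
        return self.vertices[: self.n_boundary]

    def copy(self):
        return TriangulatedSurface(self.vertices, self.faces, self.n_boundary)

    def validate(self, min_area=1e-10):
        chi = self.euler_characteristic()
        if chi != 1:
            raise GeometryError(f"surface is not a disc (chi = {chi})")
        if np.any(self.triangle_areas() <= min_area):
            raise GeometryError("degenerate triangle in mesh")

    # -- export -------------------------------------------------------------

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def export(self, path, file_type=None):
        """Write the mesh in OFF or PLY (inferred from the extension)."""
        self.to_trimesh().export(path, file_type=file_type)


def triangulate_ring(contour, closure_tol=1e-6):
    """Initial fan triangulation of a closed contour from its centroid.

    The contour must be a closed unwrapped polyline: vertex k bonds to
    vertex (k+1) mod n.  (For contours handed over as an explicitly closed
    polyline -- last vertex repeating the first within ``closure_tol`` --
    the duplicate is dropped; a genuinely open polyline signals a bad
    unwrapping and is rejected.)
    """
    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise GeometryError("contour must be (n, 3)")
    if len(c) >= 4 and np.linalg.norm(c[0] - c[-1]) <= closure_tol:
        c = c[:-1]
    if len(c) < 3:
        raise GeometryError("contour needs at least 3 distinct vertices")
    seg = np.linalg.norm(np.diff(c, axis=0), axis=1)
    if np.any(seg <= closure_tol):
        raise GeometryError("repeated consecutive contour vertices")
    n = len(c)
    centroid = c.mean(axis=0)
    if n == 3:
        return TriangulatedSurface(c, np.array([[0, 1, 2]]), 3)
    vertices = np.vstack([c, centroid])
    faces = np.array([[i, (i + 1) % n, n] for i in range(n)])
    return TriangulatedSurface(vertices, faces, n)


def surface_area(surface: TriangulatedSurface) -> float:
    """Total triangle area (sigma^2)."""
    return surface.area()


# --------------------------------------------------------------------------
# area gradient and descent
# --------------------------------------------------------------------------


def _area_gradient(vertices, faces):
    """Gradient of total area with respect to every vertex."""
    g = np.zeros_like(vertices)
    p0, p1, p2 = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    nn = np.where(nn < 1e-300, 1.0, nn)
    nh = n / nn
    # dA/dp0 = 0.5 * nh x (p2 - p1), cyclically
    np.add.at(g, faces[:, 0], 0.5 * np.cross(nh, p2 - p1))
    np.add.at(g, faces[:, 1], 0.5 * np.cross(nh, p0 - p2))
    np.add.at(g, faces[:, 2], 0.5 * np.cross(nh, p1 - p0))
    return g


def _edge_face_map(faces):
    """Map sorted edge -> list of (face index, opposite vertex)."""
    m = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
            key = (u, v) if u < v else (v, u)
            m.setdefault(key, []).append((fi, w))
    return m


def _flip_edges(surface, min_gain=1e-12, max_rounds=200):
    """Replace interior-edge diagonals when the flip strictly reduces area.

    The adjacency is rebuilt after every applied flip (one flip per round),
    so later decisions never act on stale face data; meshes here are small
    enough that the quadratic worst case is irrelevant.
    """
    v = surface.vertices
    faces = surface.faces.copy()
    changed = False

    def tri_area(i, j, k):
        return 0.5 * np.linalg.norm(np.cross(v[j] - v[i], v[k] - v[i]))

    for _ in range(max_rounds):
        em = _edge_face_map(faces)
        edge_set = set(em.keys())
        applied = False
        for (a, b), adj in em.items():
            if len(adj) != 2:
                continue  # boundary edge
            (f1, c), (f2, d) = adj
            if c == d:
                continue
            cd = (c, d) if c < d else (d, c)
            if cd in edge_set:
                continue  # flip would create a duplicate edge (fold)
            old = tri_area(a, b, c) + tri_area(a, b, d)
            new = tri_area(c, d, a) + tri_area(c, d, b)
            if new < old - min_gain and new > 1e-12:
                t = list(faces[f1])
                a_next = t[(t.index(a) + 1) % 3]
                if a_next == b:  # f1 winds a->b
                    faces[f1] = [a, d, c]
                    faces[f2] = [b, c, d]
                else:
                    faces[f1] = [a, c, d]
                    faces[f2] = [b, d, c]
                applied = True
                changed = True
                break
        if not applied:
            break
    if changed:
        surface.faces = faces
    return changed


def _split_long_edges(surface, l_max):
    """Insert midpoints on interior edges longer than l_max (chi-preserving)."""
    v = list(surface.vertices)
    faces = surface.faces.copy()
    em = _edge_face_map(faces)
    new_faces = {i: None for i in range(len(faces))}
    appended = []
    replaced = {}
    for (a, b), adj in em.items():
        if len(adj) != 2:
            continue
        if np.linalg.norm(surface.vertices[a] - surface.vertices[b]) <= l_max:
            continue
        if any(f in replaced for f, _ in adj):
            continue  # one split per face per pass
        mid_idx = len(v)
        v.append(0.5 * (surface.vertices[a] + surface.vertices[b]))
        appended.append(mid_idx)
        for f, _ in adj:
            replaced[f] = ((a, b), mid_idx)
    if not appended:
        return False
    out = []
    for fi, tri in enumerate(faces):
        if fi not in replaced:
            out.append(tri)
            continue
        (a, b), m = replaced[fi]
        t = list(tri)
        ia, ib = t.index(a), t.index(b)
        for k in range(3):
            if t[k] == a:
                s = t.copy()
                s[k] = m
                out.append(s)
        for k in range(3):
            if t[k] == b:
                s = t.copy()
                s[k] = m
                out.append(s)
    surface.vertices = np.array(v)
    surface.faces = np.array(out, dtype=np.int64)
    return True


def _collapse_short_edges(surface, l_min):
    """Collapse short interior edges (interior vertex removed; boundary fixed)."""
    nb = surface.n_boundary
    changed = False
    while True:
        v = surface.vertices
        faces = surface.faces
        em = _edge_face_map(faces)
        target = None
        for (a, b), adj in em.items():
            if len(adj) != 2:
                continue
            if a < nb and b < nb:
                continue  # both boundary: never collapse
            if np.linalg.norm(v[a] - v[b]) >= l_min:
                continue
            # link condition: shared neighbors of a and b must be exactly the
            # two opposite vertices, else the collapse pinches the disc
            nbrs_a = set()
            nbrs_b = set()
            for (x, y) in em.keys():
                if x == a:
                    nbrs_a.add(y)
                if y == a:
                    nbrs_a.add(x)
                if x == b:
                    nbrs_b.add(y)
                if y == b:
                    nbrs_b.add(x)
            if len(nbrs_a & nbrs_b) != 2:
                continue
            target = (a, b)
            break
        if target is None:
            return changed
        a, b = target
        keep, drop = (a, b) if b >= nb else (b, a)  # drop the interior one
        faces = faces[
            ~(np.any(faces == drop, axis=1) & np.any(faces == keep, axis=1))
        ]
        faces = np.where(faces == drop, keep, faces)
        # remove now-degenerate faces (repeated vertices)
        ok = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 2] != faces[:, 0])
        )
        faces = faces[ok]
        # reindex to drop the removed vertex
        remap = np.arange(len(v))
        remap[drop:] -= 1
        surface.vertices = np.delete(v, drop, axis=0)
        surface.faces = remap[faces]
        changed = True


def minimize_area(
    surface: TriangulatedSurface,
    tol: float = 1e-4,
    max_iters: int = 400,
    *,
    l_max: float = 1.4,
    l_min: float = 0.2,
    maintenance_every: int = 5,
    step0: float = 0.25,
) -> TriangulatedSurface:
    """Evolve interior vertices by steepest descent on total area.

    One sweep moves all interior vertices along the negative area gradient
    with a backtracking line search (the step is halved until the area
    decreases), so the area is monotonically non-increasing across descent
    sweeps.  Every ``maintenance_every`` sweeps the mesh is maintained:
    area-decreasing edge flips, splitting of interior edges longer than
    ``l_max`` (keeping triangles at the bond-length scale so no threading
    bond can skip one), and collapse of interior edges shorter than
    ``l_min``.  Stops when the relative area decrease over a sweep falls
    below ``tol`` (checked after maintenance has quiesced) or after
    ``max_iters`` sweeps.  The boundary is never touched.
    """
    s = surface.copy()
    s.validate()
    nb = s.n_boundary
    step = step0
    area = s.area()
    for it in range(max_iters):
        if it % maintenance_every == 0:
            _flip_edges(s)
            _split_long_edges(s, l_max)
            _collapse_short_edges(s, l_min)
            area = s.area()
        g = _area_gradient(s.vertices, s.faces)
        g[:nb] = 0.0
        gnorm = np.linalg.norm(g)
        if gnorm < 1e-14:
            break
        trial_step = step
        improved = False
        for _ in range(30):
            trial = s.vertices - trial_step * g
            cand = TriangulatedSurface(trial, s.faces, nb)
            a_new = cand.area()
            if a_new < area:
                improved = True
                break
            trial_step *= 0.5
        if not improved:
            # gradient step cannot improve at any scale: converged
            break
        s.vertices = trial
        rel = (area - a_new) / max(area, 1e-300)
        area = a_new
        step = min(trial_step * 1.5, 4.0 * step0)
        if rel < tol and it > maintenance_every:
            break
    # final cleanup flips may still reduce area; keep only if they do
    _flip_edges(s)
    if np.any(s.triangle_areas() <= 1e-10):
        _collapse_short_edges(s, l_min)
    s.validate()
    return s
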