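"""Threading detection and threading kinetics.

A ring *i* threads a ring *j* when the contour of *i* pierces the minimal
surface spanned on the contour of *j*.  For nonconcatenated rings the
piercings come in pairs of opposite orientation (the signed crossing count
is the pairwise linking number, which is zero), so every directed threaded
pair has an even piercing count with signed sum 0 -- violations are flagged
as concatenation anomalies.

The threading depth is measured by the separation length

    L_sep = min( sum over even-index arcs, sum over odd-index arcs )

of the threading ring's contour arcs between consecutive piercings (in
monomers), and the ratio Q = L_sep / (N - L_sep) in (0, 1].  Kinetics are
tracked at the directed-pair level: gain/loss Delta n+-, the presence
correlation Phi(t, t0), and the first-unthreading survival distribution
pi(t, t0).
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .errors import ConcatenationAnomalyError, GeometryError
from .surface import TriangulatedSurface, minimize_area, triangulate_ring

__all__ = [
    "Piercing",
    "ThreadingEntry",
    "ThreadingTable",
    "find_piercings",
    "separation_length",
    "analyze_frame",
    "threading_clusters",
    "threading_gain_loss",
    "threading_correlation",
    "survival_distribution",
    "threaded_neighbor_count",
]


@dataclasses.dataclass
class Piercing:
    """One transversal intersection of a threading bond with a surface."""

    surface_ring: int
    threading_ring: int
    bond_index: int  # contour index of the piercing bond on the threading ring
    point: np.ndarray  # intersection coordinates (sigma)
    sign: int  # +-1: crossing orientation vs. the surface normal


@dataclasses.dataclass
class ThreadingEntry:
    """Directed threaded pair: ``threading_ring`` threads ``surface_ring``."""

    surface_ring: int
    threading_ring: int
    piercings: list
    L_sep: int
    Q: float


@dataclasses.dataclass
class ThreadingTable:
    """All directed threadings of one frame."""

    time: float
    M: int
    entries: list

    def pair_set(self) -> frozenset:
        """Directed pairs (threader, threaded) present in this frame."""
        return frozenset(
            (e.threading_ring, e.surface_ring) for e in self.entries
        )

    def to_tsv(self, path, mode="w", header=True):
        with open(path, mode) as fh:
            if header:
                fh.write("frame_time\ti_threads\tj_threaded\tn_piercings\tL_sep\tQ\n")
            for e in self.entries:
                fh.write(
                    f"{self.time:g}\t{e.threading_ring}\t{e.surface_ring}\t"
                    f"{len(e.piercings)}\t{e.L_sep}\t{e.Q:.6f}\n"
                )


# --------------------------------------------------------------------------
# geometric piercing detection
# --------------------------------------------------------------------------


def _segment_triangle_hits(p0, p1, tri_v, eps=1e-9):
    """Vectorized Moller--Trumbore over all (segment, triangle) pairs.

    Returns hit arrays (seg_idx, tri_idx, t_param, points, signs) and a
    boolean 'degenerate' marking any near-tangent or edge-grazing pair that
    requires a perturbation retry.
    """
    d = p1 - p0  # (ns, 3)
    v0 = tri_v[:, 0]
    e1 = tri_v[:, 1] - v0  # (nt, 3)
    e2 = tri_v[:, 2] - v0

    pvec = np.cross(d[:, None, :], e2[None, :, :])  # (ns, nt, 3)
    det = np.einsum("tj,stj->st", e1, pvec)
    tvec = p0[:, None, :] - v0[None, :, :]
    near_parallel = np.abs(det) < 1e-12

    inv = np.where(near_parallel, 1.0, 1.0 / np.where(near_parallel, 1.0, det))
    u = np.einsum("stj,stj->st", tvec, pvec) * inv
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("sj,stj->st", d, qvec) * inv
    t = np.einsum("tj,stj->st", e2, qvec) * inv

    inside = (
        (u > eps)
        & (v > eps)
        & (u + v < 1.0 - eps)
        & (t > eps)
        & (t < 1.0 - eps)
        & ~near_parallel
    )
    graze = (
        (~near_parallel)
        & (t > -eps)
        & (t < 1.0 + eps)
        & (u > -eps)
        & (v > -eps)
        & (u + v < 1.0 + eps)
        & ~inside
    )
    # a segment lying (near-)parallel inside a triangle's slab is only a
    # problem if it also overlaps the triangle region; flag conservatively
    degenerate = bool(np.any(graze))
    si, ti = np.nonzero(inside)
    tt = t[si, ti]
    pts = p0[si] + tt[:, None] * d[si]
    normals = np.cross(e1, e2)
    signs = np.sign(np.einsum("sj,sj->s", d[si], normals[ti])).astype(int)
    return si, ti, tt, pts, signs, degenerate


def find_piercings(
    surface: TriangulatedSurface,
    contour,
    *,
    surface_ring=-1,
    threading_ring=-1,
    box=None,
    eps=1e-9,
    max_retries=4,
    _rng_seed=1234,
):
    """All transversal piercings of ``surface`` by the closed ``contour``.

    ``contour`` is the threading ring's unwrapped (N, 3) polyline; bond k
    connects vertex k to (k+1) mod N.  With ``box`` given, the contour is
    rigidly translated to the minimum image relative to the surface's
    centroid first; contours wider than half the box are rejected with a
    diagnostics error (the analysis convention requires rings smaller than
    the box).

    Grazing or in-plane configurations trigger a deterministic tiny
    perturbation of the contour and a retry; persistent degeneracy raises
    :class:`GeometryError`.
    """
    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3 or len(c) < 3:
        raise GeometryError("contour must be (N>=3, 3)")
    if box is not None:
        box = np.asarray(box, dtype=float)
        ext_c = c.max(axis=0) - c.min(axis=0)
        sv = surface.vertices
        ext_s = sv.max(axis=0) - sv.min(axis=0)
        if np.any(ext_c >= box / 2) or np.any(ext_s >= box / 2):
            raise GeometryError(
                "ring extent exceeds half the box; minimum-image threading "
                f"analysis undefined (extents {ext_c}, {ext_s}, box {box})"
            )
        center = sv[: surface.n_boundary].mean(axis=0)
        shift = box * np.rint((c.mean(axis=0) - center) / box)
        c = c - shift

    tri_v = surface.vertices[surface.faces]  # (nt, 3, 3)
    rng = np.random.default_rng(_rng_seed)
    work = c
    for attempt in range(max_retries + 1):
        p0 = work
        p1 = np.roll(work, -1, axis=0)
        # prefilter with bounding boxes
        lo_s = np.minimum(p0, p1).min(axis=0)
        hi_s = np.maximum(p0, p1).max(axis=0)
        lo_t = tri_v.min(axis=(0, 1))
        hi_t = tri_v.max(axis=(0, 1))
        if np.any(lo_s > hi_t) or np.any(lo_t > hi_s):
            return []
        si, ti, tt, pts, signs, degenerate = _segment_triangle_hits(
            p0, p1, tri_v, eps
        )
        if not degenerate:
            order = np.lexsort((tt, si))
            return [
                Piercing(
                    surface_ring=surface_ring,
                    threading_ring=threading_ring,
                    bond_index=int(si[k]),
                    point=pts[k],
                    sign=int(signs[k]),
                )
                for k in order
            ]
        if attempt == max_retries:
            raise GeometryError(
                "persistent grazing segment--triangle configuration; "
                "piercing detection ill-conditioned"
            )
        work = c + rng.normal(scale=1e-7, size=c.shape)
    raise AssertionError("unreachable")


def separation_length(piercings, N):
    """(L_sep, Q) from an even list of piercings of one directed pair.

    Arc lengths (in monomers of the threading ring) between consecutive
    piercing bonds, cyclically; the two alternating-parity sums total N and
    the smaller one is L_sep.  Q = L_sep / (N - L_sep).
    """
    k = len(piercings)
    if k < 2 or k % 2 != 0:
        raise ConcatenationAnomalyError(
            f"piercing count {k} is not an even number >= 2; "
            "inconsistent with nonconcatenated rings"
        )
    idx = np.sort(np.array([p.bond_index for p in piercings]))
    arcs = np.diff(np.append(idx, idx[0] + N))
    even = int(arcs[0::2].sum())
    odd = int(arcs[1::2].sum())
    L_sep = min(even, odd)
    if L_sep < 1:
        # two piercings on the same bond: the threading is infinitesimally
        # shallow; count the minimal resolvable depth of one monomer
        L_sep = 1
    Q = L_sep / (N - L_sep)
    return L_sep, Q


# --------------------------------------------------------------------------
# frame-level analysis
# --------------------------------------------------------------------------


def analyze_frame(
    state,
    *,
    surface_tol=1e-4,
    max_iters=400,
    strict=True,
) -> ThreadingTable:
    """Build the ThreadingTable of one melt snapshot.

    Spans and minimizes a disc surface on every closed ring (independently,
    no warm start) and detects the piercings of every other closed ring's
    contour through it.  With ``strict`` (default) an odd piercing count or
    nonzero signed sum raises; otherwise such pairs are skipped.
    """
    M = state.M
    contours = [state.ring_positions(r) for r in range(M)]
    surfaces = {}
    for r in range(M):
        if state.closed[r]:
            surfaces[r] = minimize_area(
                triangulate_ring(contours[r]), tol=surface_tol, max_iters=max_iters
            )
    entries = []
    for j, surf in surfaces.items():
        for i in range(M):
            if i == j or not state.closed[i]:
                continue
            pierc = find_piercings(
                surf,
                contours[i],
                surface_ring=j,
                threading_ring=i,
                box=state.box,
            )
            if not pierc:
                continue
            signed = sum(p.sign for p in pierc)
            if len(pierc) % 2 != 0 or signed != 0:
                if strict:
                    raise ConcatenationAnomalyError(
                        f"pair ({i} threads {j}): {len(pierc)} piercings, "
                        f"signed sum {signed}"
                    )
                continue
            L_sep, Q = separation_length(pierc, state.N)
            entries.append(
                ThreadingEntry(
                    surface_ring=j,
                    threading_ring=i,
                    piercings=pierc,
                    L_sep=L_sep,
                    Q=Q,
                )
            )
    return ThreadingTable(time=state.time, M=M, entries=entries)


# --------------------------------------------------------------------------
# clusters
# --------------------------------------------------------------------------


def threading_clusters(table: ThreadingTable, L_cutoff, active_rings=None):
    """Partition rings into threading clusters at depth cutoff ``L_cutoff``.

    Two rings share a cluster if at least one threads the other with
    ``L_sep > L_cutoff``.  Returns a dict with per-ring labels, the biggest
    cluster size, and -- when ``active_rings`` (bool per ring) is given --
    the size of the biggest cluster composed of passive rings only.
    """
    g = nx.Graph()
    g.add_nodes_from(range(table.M))
    for e in table.entries:
        if e.L_sep > L_cutoff:
            g.add_edge(e.threading_ring, e.surface_ring)
    comps = list(nx.connected_components(g))
    labels = np.empty(table.M, dtype=int)
    for ci, comp in enumerate(sorted(comps, key=min)):
        for r in comp:
            labels[r] = ci
    biggest = max(len(c) for c in comps)
    out = {
        "labels": labels,
        "n_clusters": len(comps),
        "biggest_cluster_size": biggest,
    }
    if active_rings is not None:
        active_rings = np.asarray(active_rings, dtype=bool)
        passive_only = [
            len(c) for c in comps if not active_rings[list(c)].any()
        ]
        out["biggest_passive_cluster_size"] = max(passive_only) if passive_only else 0
    return out


# --------------------------------------------------------------------------
# kinetics over pair-set time series
# --------------------------------------------------------------------------


def _as_pair_set(obj):
    if isinstance(obj, ThreadingTable):
        return obj.pair_set()
    return frozenset(tuple(p) for p in obj)


def threading_gain_loss(table_t, table_next):
    """(Delta n+, Delta n-): threadings gained and lost between two frames."""
    a = _as_pair_set(table_t)
    b = _as_pair_set(table_next)
    return len(b - a), len(a - b)


def threading_correlation(series, t0_index=0):
    """Presence correlation Phi(t, t0) over a pair-set time series.

    Phi(t) = |T(t0) intersect T(t0 + t)| / |T(t0)|; re-formed threadings
    count (the correlation is presence-based, not survival-based).
    Returns an array over the available lags; None if no pairs at t0.
    """
    sets = [_as_pair_set(s) for s in series[t0_index:]]
    base = sets[0]
    if not base:
        return None
    return np.array([len(base & s) / len(base) for s in sets])


def survival_distribution(series, t0_index=0):
    """First-unthreading waiting times of the pairs threaded at t0.

    Returns ``(counts, n_pairs)`` where ``counts[k]`` (k = 1 .. n_lags-1)
    is the number of t0-threaded pairs first absent at lag k and the final
    bin ``counts[n_lags-1]`` additionally accumulates pairs still threaded
    at the end of the analyzed window (the late-time peak).  ``counts[0]``
    is unused (a pair present at t0 cannot unthread at lag 0).
    """
    sets = [_as_pair_set(s) for s in series[t0_index:]]
    base = sets[0]
    if not base:
        return None, 0
    n_lags = len(sets)
    counts = np.zeros(n_lags, dtype=int)
    for pair in base:
        for k in range(1, n_lags):
            if pair not in sets[k]:
                counts[k] += 1
                break
        else:
            counts[n_lags - 1] += 1  # survived the whole window
    return counts, len(base)


def threaded_neighbor_count(table: ThreadingTable) -> float:
    """Mean threaded neighbors n_tn = n_th / M with directed counting."""
    return len(table.entries) / table.M


# --------------------------------------------------------------------------
# compact pair-set series container
# --------------------------------------------------------------------------


def pair_series_to_bitmap(series, M, path):
    """Serialize a directed-pair-set time series as a packed bitmap.

    Layout: a one-line JSON header (``M``, ``n_frames``) terminated by a
    newline, followed by ``numpy.packbits`` of the boolean array of shape
    (n_frames, M, M) whose [f, i, j] entry flags 'i threads j' in frame f.
    """
    import json as _json

    sets = [_as_pair_set(s) for s in series]
    arr = np.zeros((len(sets), M, M), dtype=bool)
    for f, s in enumerate(sets):
        for i, j in s:
            arr[f, i, j] = True
    with open(path, "wb") as fh:
        fh.write(
            (_json.dumps({"M": M, "n_frames": len(sets)}) + "\n").encode()
        )
        fh.write(np.packbits(arr.ravel()).tobytes())


def pair_series_from_bitmap(path):
    """Inverse of :func:`pair_series_to_bitmap`; returns a list of frozensets."""
    import json as _json

    with open(path, "rb") as fh:
        header = _json.loads(fh.readline().decode())
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    M, F = header["M"], header["n_frames"]
    arr = np.unpackbits(raw, count=F * M * M).astype(bool).reshape(F, M, M)
    return [
        frozenset((int(i), int(j)) for i, j in zip(*np.nonzero(arr[f])))
        for f in range(F)
    ]
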