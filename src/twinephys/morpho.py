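"""SWC morphology I/O and morphometrics.

Metrics: Sholl intersection profile (3-D spheres, 10 um increments),
branch count, maximal branch length, total dendritic length, soma area.

A "branch" is a maximal unbranched path between junction nodes (the root or
a node with >= 2 children) and a tip or the next junction.  Sholl
intersections count crossings of parent-child line segments with the sphere
boundary at each radius; a segment crossing twice counts twice, tangency
counts once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import InvalidParameterError, TwinephysError

__all__ = [
    "Morphology", "ShollProfile", "SwcFormatError",
    "read_swc", "write_swc", "sholl", "branch_metrics", "soma_size",
]

SOMA_TYPE = 1


class SwcFormatError(TwinephysError, ValueError):
    """Structural defect in an SWC file (cycle, multiple roots, dangling
    parent); message carries the offending line number when known."""


@dataclass
class Morphology:
    """Node table of a reconstructed neuron (standard 7-column SWC)."""

    ids: np.ndarray        # int, 1-based as stored
    types: np.ndarray      # int type codes (1 = soma)
    xyz: np.ndarray        # (n, 3) um
    radii: np.ndarray      # um
    parents: np.ndarray    # int, -1 at root

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        self.validate()

    # index of each id into the arrays
    @property
    def _idx(self) -> dict[int, int]:
        return {int(i): k for k, i in enumerate(self.ids)}

    def validate(self) -> None:
        n = self.ids.size
        if n == 0:
            raise SwcFormatError("empty morphology")
        if len(set(self.ids.tolist())) != n:
            raise SwcFormatError("duplicate node ids")
        if np.any(self.radii < 0):
            raise SwcFormatError("negative radius")
        roots = np.flatnonzero(self.parents == -1)
        if roots.size != 1:
            raise SwcFormatError(f"expected exactly one root, found {roots.size}")
        idx = self._idx
        for k in range(n):
            p = int(self.parents[k])
            if p == -1:
                continue
            if p not in idx:
                raise SwcFormatError(
                    f"node {int(self.ids[k])}: dangling parent id {p}")
        # connectivity / acyclicity via walk to root
        for k in range(n):
            seen = set()
            cur = k
            while int(self.parents[cur]) != -1:
                if cur in seen:
                    raise SwcFormatError(
                        f"cycle involving node {int(self.ids[cur])}")
                seen.add(cur)
                cur = idx[int(self.parents[cur])]

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parents == -1)[0])

    @property
    def soma_center(self) -> np.ndarray:
        """Centroid of soma-type nodes, or the root position if none."""
        soma = self.types == SOMA_TYPE
        if np.any(soma):
            return self.xyz[soma].mean(axis=0)
        return self.xyz[self.root_index]

    def segments(self, exclude_soma_internal: bool = True
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Parent-child line segments as (p, c) coordinate pairs.

        Segments joining two soma-type nodes (soma contour edges) are
        excluded from neurite metrics by default.
        """
        idx = self._idx
        out = []
        for k in range(self.ids.size):
            p = int(self.parents[k])
            if p == -1:
                continue
            kp = idx[p]
            if (exclude_soma_internal and self.types[k] == SOMA_TYPE
                    and self.types[kp] == SOMA_TYPE):
                continue
            out.append((self.xyz[kp], self.xyz[k]))
        return out

    def children_map(self) -> dict[int, list[int]]:
        """Array-index children lists."""
        idx = self._idx
        ch: dict[int, list[int]] = {k: [] for k in range(self.ids.size)}
        for k in range(self.ids.size):
            p = int(self.parents[k])
            if p != -1:
                ch[idx[p]].append(k)
        return ch


@dataclass
class ShollProfile:
    """Intersections with concentric spheres at 10 um radial increments."""

    radii: np.ndarray
    intersections: np.ndarray
    step: float = 10.0

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=int)
        if self.radii.size != self.intersections.size:
            raise InvalidParameterError("radii and intersections must align")


# -- SWC I/O ---------------------------------------------------------------

def read_swc(path: str | Path) -> Morphology:
    """Parse a 7-column SWC file with full structural validation."""
    path = Path(path)
    ids, types, xyz, radii, parents = [], [], [], [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcFormatError(f"line {lineno}: expected 7 columns, "
                                 f"got {len(parts)}")
        try:
            ids.append(int(parts[0]))
            types.append(int(parts[1]))
            xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
        except ValueError as exc:
            raise SwcFormatError(f"line {lineno}: {exc}") from exc
    if not ids:
        raise SwcFormatError(f"{path}: no nodes")
    return Morphology(np.array(ids), np.array(types), np.array(xyz),
                      np.array(radii), np.array(parents))


def write_swc(morph: Morphology, path: str | Path) -> None:
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    for k in range(morph.ids.size):
        x, y, z = morph.xyz[k]
        lines.append(f"{int(morph.ids[k])} {int(morph.types[k])} "
                     f"{x:.6f} {y:.6f} {z:.6f} {morph.radii[k]:.6f} "
                     f"{int(morph.parents[k])}")
    path.write_text("\n".join(lines) + "\n")


# -- Sholl -----------------------------------------------------------------

def _segment_sphere_crossings(p: np.ndarray, c: np.ndarray,
                              center: np.ndarray, r: float,
                              eps: float = 1e-9) -> int:
    """Number of crossings of segment p->c with the sphere |x-center| = r.

    Roots of the quadratic |p + t(c-p) - center|^2 = r^2 counted on the
    half-open interval (0, 1]; a node sitting exactly on the sphere is thus
    attributed to the segment ending at it, never double counted.  Tangency
    (double root) counts once.
    """
    d = c - p
    f = p - center
    a = float(d @ d)
    if a == 0:
        return 0
    b = 2.0 * float(f @ d)
    c0 = float(f @ f) - r * r
    disc = b * b - 4 * a * c0
    if disc < -eps * max(1.0, b * b):
        return 0
    disc = max(disc, 0.0)
    sq = np.sqrt(disc)
    t1 = (-b - sq) / (2 * a)
    t2 = (-b + sq) / (2 * a)
    count = 0
    for t in ((t1,) if sq == 0 else (t1, t2)):
        if eps < t <= 1.0 + eps:
            count += 1
    return count


def sholl(morph: Morphology, step: float = 10.0,
          center: np.ndarray | None = None,
          project_2d: bool = False) -> ShollProfile:
    """Count segment crossings with concentric spheres every ``step`` um.

    ``project_2d`` drops the z coordinate first, reproducing a planar
    (concentric-circle) analysis of the xy projection.
    """
    if step <= 0:
        raise InvalidParameterError("step must be > 0")
    if center is None:
        center = morph.soma_center
    segs = morph.segments()
    if project_2d:
        center = center * np.array([1.0, 1.0, 0.0])
        segs = [(p * np.array([1.0, 1.0, 0.0]), c * np.array([1.0, 1.0, 0.0]))
                for p, c in segs]
    if not segs:
        return ShollProfile(np.array([step]), np.array([0]), step=step)
    rmax = max(float(np.linalg.norm(c - center)) for _, c in segs)
    n_rings = max(1, int(np.floor(rmax / step + 1e-9)) + 1)
    radii = step * np.arange(1, n_rings + 1)
    counts = np.zeros(n_rings, dtype=int)
    for p, c in segs:
        for i, r in enumerate(radii):
            counts[i] += _segment_sphere_crossings(p, c, center, float(r))
    # trim trailing zeros but keep at least one ring
    nz = np.flatnonzero(counts)
    last = int(nz[-1]) + 1 if nz.size else 1
    return ShollProfile(radii[:last], counts[:last], step=step)


# -- branch metrics --------------------------------------------------------

def branch_metrics(morph: Morphology) -> tuple[int, float, float]:
    """(n_branches, max_branch_length_um, total_length_um)."""
    ch = morph.children_map()
    root = morph.root_index

    def seglen(k: int) -> float:
        kp = morph._idx[int(morph.parents[k])]
        return float(np.linalg.norm(morph.xyz[k] - morph.xyz[kp]))

    soma_internal = {
        k for k in range(morph.ids.size)
        if int(morph.parents[k]) != -1
        and morph.types[k] == SOMA_TYPE
        and morph.types[morph._idx[int(morph.parents[k])]] == SOMA_TYPE
    }

    total = sum(seglen(k) for k in range(morph.ids.size)
                if int(morph.parents[k]) != -1 and k not in soma_internal)

    junctions = {root} | {k for k, cs in ch.items() if len(cs) >= 2}
    branch_lengths: list[float] = []
    for start_parent in junctions:
        for child in ch[start_parent]:
            if child in soma_internal:
                continue
            length = seglen(child)
            cur = child
            while cur not in junctions and len(ch[cur]) == 1:
                nxt = ch[cur][0]
                length += seglen(nxt)
                cur = nxt
            branch_lengths.append(length)
    n_branches = len(branch_lengths)
    max_len = max(branch_lengths) if branch_lengths else 0.0
    return n_branches, max_len, total


def soma_size(morph: Morphology) -> float:
    """Soma area in um^2: shoelace area of a traced soma contour (>= 3
    soma-type nodes), else pi * r^2 of the root radius."""
    soma_idx = np.flatnonzero(morph.types == SOMA_TYPE)
    if soma_idx.size >= 3:
        pts = morph.xyz[soma_idx][:, :2]
        x, y = pts[:, 0], pts[:, 1]
        return float(0.5 * np.abs(np.dot(x, np.roll(y, -1))
                                  - np.dot(y, np.roll(x, -1))))
    r = float(morph.radii[morph.root_index])
    return float(np.pi * r * r)
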