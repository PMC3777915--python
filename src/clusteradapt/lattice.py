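"""Hexagonal chemoreceptor lattice: dimers, MWC complexes, assistance neighborhoods.

Receptor dimers tile a triangular lattice (every interior dimer touches six
neighbors).  Groups of six dimers form one cooperative MWC signaling
complex; three complexes form the basic hexagonal unit of the lattice, so a
``(w, h)``-unit lattice holds ``18*w*h`` dimers and ``3*w*h`` complexes.
The assistance neighborhood of a dimer — the set of receptors reachable by
the tether of an enzyme bound there — is the dimer itself plus its
adjacent dimers (seven for interior dimers).

The simulator consumes only adjacency, complex membership and neighborhood
maps, so any fixed planar embedding with the right invariants serves.  Here
dimers live on an axial-coordinate triangular grid of ``6*h`` rows by
``3*w`` columns; a complex is a 2-row by 3-column block; a unit is a column
of three complexes.  Indices are 0-based, row-major, so traces are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatticeGeometry",
    "build_lattice",
    "assistance_neighborhood",
    "validate_geometry",
    "geometry_to_table",
    "geometry_from_table",
]


@dataclass
class LatticeGeometry:
    """Immutable description of a receptor lattice.

    Attributes
    ----------
    n_dimers:
        Total number of receptor dimers.
    neighbors:
        ``(n_dimers, 6)`` int32 array of adjacent dimer ids, padded with -1.
    n_neighbors:
        Number of valid entries per row of ``neighbors``.
    complex_of:
        Complex id of each dimer.
    complexes:
        ``(n_complexes, dimers_per_complex)`` array listing each complex.
    units:
        ``(width, height)`` in basic hexagonal units, or ``None`` for
        hand-built geometries.
    """

    n_dimers: int
    neighbors: np.ndarray
    n_neighbors: np.ndarray
    complex_of: np.ndarray
    complexes: np.ndarray
    units: tuple[int, int] | None = None

    @property
    def n_complexes(self) -> int:
        return self.complexes.shape[0]

    @property
    def dimers_per_complex(self) -> int:
        return self.complexes.shape[1]

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=np.int32)
        self.n_neighbors = np.asarray(self.n_neighbors, dtype=np.int32)
        self.complex_of = np.asarray(self.complex_of, dtype=np.int32)
        self.complexes = np.asarray(self.complexes, dtype=np.int32)


def build_lattice(width_units: int, height_units: int) -> LatticeGeometry:
    """Build an open-boundary triangular lattice of ``18*w*h`` dimers.

    Parameters are the lattice extent in basic hexagonal units (three
    6-dimer complexes each).  Raises ``ValueError`` for non-positive sizes.
    """
    if width_units < 1 or height_units < 1:
        raise ValueError("lattice dimensions must be >= 1 unit")
    rows = 6 * height_units
    cols = 3 * width_units
    n = rows * cols

    idx = np.arange(n, dtype=np.int32).reshape(rows, cols)
    neighbors = np.full((n, 6), -1, dtype=np.int32)
    n_neighbors = np.zeros(n, dtype=np.int32)
    # axial triangular-lattice adjacency
    offsets = ((0, 1), (0, -1), (1, 0), (-1, 0), (1, -1), (-1, 1))
    for i in range(rows):
        for j in range(cols):
            d = idx[i, j]
            k = 0
            for di, dj in offsets:
                ii, jj = i + di, j + dj
                if 0 <= ii < rows and 0 <= jj < cols:
                    neighbors[d, k] = idx[ii, jj]
                    k += 1
            n_neighbors[d] = k

    # complexes: 2-row x 3-column blocks of the grid
    comp_cols = cols // 3
    complex_of = np.empty(n, dtype=np.int32)
    for i in range(rows):
        for j in range(cols):
            complex_of[idx[i, j]] = (i // 2) * comp_cols + (j // 3)
    n_complexes = (rows // 2) * comp_cols
    complexes = np.empty((n_complexes, 6), dtype=np.int32)
    counts = np.zeros(n_complexes, dtype=np.int32)
    for d in range(n):
        c = complex_of[d]
        complexes[c, counts[c]] = d
        counts[c] += 1

    return LatticeGeometry(
        n_dimers=n,
        neighbors=neighbors,
        n_neighbors=n_neighbors,
        complex_of=complex_of,
        complexes=complexes,
        units=(width_units, height_units),
    )


def assistance_neighborhood(geometry: LatticeGeometry, dimer: int) -> np.ndarray:
    """The dimer itself plus its adjacent dimers (sorted ids).

    Size 7 for interior dimers of the standard lattice, smaller at the open
    boundary.
    """
    if not (0 <= dimer < geometry.n_dimers):
        raise ValueError(f"unknown dimer id {dimer}")
    k = geometry.n_neighbors[dimer]
    hood = np.concatenate(([dimer], geometry.neighbors[dimer, :k]))
    return np.sort(hood.astype(np.int32))


def validate_geometry(geometry: LatticeGeometry) -> dict:
    """Check all structural invariants; never silently passes.

    Returns a report dict with ``violations`` (list of strings, empty when
    valid) and interior/boundary dimer counts.
    """
    g = geometry
    violations: list[str] = []

    seen = np.zeros(g.n_dimers, dtype=bool)
    for c in range(g.n_complexes):
        for d in g.complexes[c]:
            if d < 0 or d >= g.n_dimers:
                violations.append(f"complex {c} references unknown dimer {d}")
                continue
            if seen[d]:
                violations.append(f"dimer {d} assigned to more than one complex")
            seen[d] = True
            if g.complex_of[d] != c:
                violations.append(f"complex_of[{d}] disagrees with complex {c} membership")
    if not seen.all():
        violations.append("complexes do not cover all dimers")

    max_deg = g.neighbors.shape[1]
    for d in range(g.n_dimers):
        k = g.n_neighbors[d]
        if k > max_deg:
            violations.append(f"dimer {d} claims {k} neighbors")
            continue
        row = g.neighbors[d, :k]
        if np.any(row < 0) or np.any(row >= g.n_dimers):
            violations.append(f"dimer {d} has out-of-range neighbor ids")
            continue
        if d in row:
            violations.append(f"adjacency is reflexive at dimer {d}")
        if len(set(row.tolist())) != k:
            violations.append(f"duplicate neighbors at dimer {d}")
        for e in row:
            ke = g.n_neighbors[e]
            if d not in g.neighbors[e, :ke]:
                violations.append(f"asymmetric adjacency: {e} in nbrs({d}) but not conversely")

    if g.units is not None:
        w, h = g.units
        if g.n_dimers != 18 * w * h:
            violations.append(f"dimer count {g.n_dimers} != 18*{w}*{h}")
    if g.n_dimers != g.n_complexes * g.dimers_per_complex:
        violations.append("complex partition does not account for every dimer")

    n_interior = int(np.sum(g.n_neighbors == 6))
    return {
        "violations": violations,
        "n_dimers": g.n_dimers,
        "n_complexes": g.n_complexes,
        "n_interior": n_interior,
        "n_boundary": g.n_dimers - n_interior,
    }


def geometry_to_table(geometry: LatticeGeometry) -> str:
    """Serialize geometry as a plain tab-separated text block.

    One ``dimer<TAB>complex<TAB>n1,n2,...`` line per dimer — a debugging and
    fixture format, not a performance path.
    """
    lines = [f"# units\t{geometry.units[0]}\t{geometry.units[1]}" if geometry.units else "# units\t-\t-"]
    for d in range(geometry.n_dimers):
        k = geometry.n_neighbors[d]
        nbrs = ",".join(str(int(x)) for x in geometry.neighbors[d, :k])
        lines.append(f"{d}\t{int(geometry.complex_of[d])}\t{nbrs}")
    return "\n".join(lines) + "\n"


def geometry_from_table(text: str) -> LatticeGeometry:
    """Inverse of :func:`geometry_to_table`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    units = None
    if header[0] == "# units" and header[1] != "-":
        units = (int(header[1]), int(header[2]))
    body = lines[1:]
    n = len(body)
    complex_of = np.empty(n, dtype=np.int32)
    neighbors = np.full((n, 6), -1, dtype=np.int32)
    n_neighbors = np.zeros(n, dtype=np.int32)
    for ln in body:
        d_s, c_s, nb_s = ln.split("\t")
        d = int(d_s)
        complex_of[d] = int(c_s)
        nbrs = [int(x) for x in nb_s.split(",")] if nb_s else []
        neighbors[d, : len(nbrs)] = nbrs
        n_neighbors[d] = len(nbrs)
    n_complexes = int(complex_of.max()) + 1
    per = n // n_complexes
    complexes = np.empty((n_complexes, per), dtype=np.int32)
    counts = np.zeros(n_complexes, dtype=np.int32)
    for d in range(n):
        c = complex_of[d]
        complexes[c, counts[c]] = d
        counts[c] += 1
    return LatticeGeometry(
        n_dimers=n,
        neighbors=neighbors,
        n_neighbors=n_neighbors,
        complex_of=complex_of,
        complexes=complexes,
        units=units,
    )
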