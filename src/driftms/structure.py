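"""Structure-side observables linking atomistic models to ion mobility.

Radius of gyration, projection-approximation (PA) collision cross
section, Kabsch-superposed RMSD, the linear Rg-CCS calibration, the
Rg-quartile secondary-structure statistic, and the uniform-cuboid Rg
used for protofilament dimension estimates.

The PA CCS is the orientation-averaged area of the projection of the
atom-sphere union (atom van der Waals radius plus a probe radius for the
buffer gas).  It systematically underestimates trajectory-method CCS
values for concave surfaces because it ignores multiple scattering; the
offset is a documented property of the approximation, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

__all__ = [
    "BONDI_RADII",
    "StructureModel",
    "PACCSResult",
    "RgCcsFit",
    "QuartileStat",
    "read_pdb",
    "radius_of_gyration",
    "pa_ccs",
    "kabsch_rmsd",
    "rg_ccs_regression",
    "quartile_response",
    "cuboid_rg",
    "synthetic_globule",
]

#: Bondi van der Waals radii, Angstrom
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70

_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
}


@dataclass
class StructureModel:
    """Atom-level structure: coordinates (Angstrom), masses (u), radii
    (Angstrom) and element symbols."""

    elements: list[str]
    masses: np.ndarray
    coords: np.ndarray   # (n, 3)
    radii: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.coords) == 0:
            raise ValueError("structure has no atoms")
        if np.any(self.masses <= 0) or np.any(self.radii <= 0):
            raise ValueError("masses and radii must be positive")

    @classmethod
    def from_coords(
        cls,
        coords,
        masses=None,
        radii=None,
        elements=None,
        label: str = "",
    ) -> "StructureModel":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(coords)
        if elements is None:
            elements = ["C"] * n
        if masses is None:
            masses = [_ATOMIC_MASS.get(e.upper(), 12.011) for e in elements]
        if radii is None:
            radii = [BONDI_RADII.get(e.upper(), _DEFAULT_RADIUS) for e in elements]
        return cls(
            elements=list(elements),
            masses=np.asarray(masses, dtype=float),
            coords=coords,
            radii=np.asarray(radii, dtype=float),
            label=label,
        )


def read_pdb(path, label: str | None = None) -> StructureModel:
    """Read an atomic structure from PDB: first model, altloc 'A' (or
    blank), hydrogens kept if present."""
    import gemmi

    st = gemmi.read_structure(str(path))
    model = st[0]
    elements, masses, coords, radii = [], [], [], []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                el = atom.element.name.upper()
                elements.append(el)
                masses.append(atom.element.weight)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(BONDI_RADII.get(el, _DEFAULT_RADIUS))
    return StructureModel(
        elements=elements,
        masses=np.array(masses),
        coords=np.array(coords),
        radii=np.array(radii),
        label=label or st.name,
    )


def radius_of_gyration(model: StructureModel) -> float:
    """Mass-weighted RMS distance of atoms from the centre of mass, Angstrom."""
    m = model.masses
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    com = (m[:, None] * model.coords).sum(axis=0) / total
    d2 = np.sum((model.coords - com) ** 2, axis=1)
    return math.sqrt(float((m * d2).sum() / total))


@dataclass(frozen=True)
class PACCSResult:
    ccs: float        # Angstrom^2
    stderr: float     # Monte-Carlo standard error over orientations
    n_orientations: int

    def __float__(self):
        return self.ccs


def _projected_area(xy: np.ndarray, radii: np.ndarray, grid: float) -> float:
    """Area of the union of disks by rasterisation on a square grid."""
    rmax = radii.max()
    lo = xy.min(axis=0) - rmax - grid
    hi = xy.max(axis=0) + rmax + grid
    nx = int(math.ceil((hi[0] - lo[0]) / grid)) + 1
    ny = int(math.ceil((hi[1] - lo[1]) / grid)) + 1
    mask = np.zeros((nx, ny), dtype=bool)
    xs = lo[0] + grid * np.arange(nx)
    ys = lo[1] + grid * np.arange(ny)
    for (cx, cy), r in zip(xy, radii):
        i0 = max(int((cx - r - lo[0]) / grid), 0)
        i1 = min(int((cx + r - lo[0]) / grid) + 2, nx)
        j0 = max(int((cy - r - lo[1]) / grid), 0)
        j1 = min(int((cy + r - lo[1]) / grid) + 2, ny)
        dx2 = (xs[i0:i1] - cx) ** 2
        dy2 = (ys[j0:j1] - cy) ** 2
        mask[i0:i1, j0:j1] |= dx2[:, None] + dy2[None, :] <= r * r
    return float(mask.sum()) * grid * grid


def pa_ccs(
    model: StructureModel,
    probe_radius: float = 1.0,
    n_orientations: int = 500,
    seed: int = 0,
    grid: float = 0.1,
) -> PACCSResult:
    """Projection-approximation CCS, Angstrom^2.

    Mean over uniformly random rigid rotations of the projected area of
    the union of disks of radius (atom radius + probe radius); the
    projection is rasterised on a square grid.  The Monte-Carlo standard
    error over orientations is reported alongside the mean.
    """
    if n_orientations < 100:
        raise ValueError("need at least 100 orientations")
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_orientations, random_state=rng)
    radii = model.radii + probe_radius
    centred = model.coords - model.coords.mean(axis=0)
    areas = np.empty(n_orientations)
    for i, rot in enumerate(rots):
        xy = rot.apply(centred)[:, :2]
        areas[i] = _projected_area(xy, radii, grid)
    return PACCSResult(
        ccs=float(areas.mean()),
        stderr=float(areas.std(ddof=1) / math.sqrt(n_orientations)),
        n_orientations=n_orientations,
    )


def kabsch_rmsd(
    a: StructureModel, b: StructureModel, subset: Sequence[int] | None = None
) -> float:
    """RMSD after optimal rigid superposition (translation + proper rotation)."""
    pa = a.coords if subset is None else a.coords[list(subset)]
    pb = b.coords if subset is None else b.coords[list(subset)]
    if pa.shape != pb.shape:
        raise ValueError("subsets must have equal size")
    if len(pa) < 3:
        raise ValueError("need at least 3 atoms")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    H = pb.T @ pa
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = pb @ R.T - pa
    return math.sqrt(float(np.mean(np.sum(diff**2, axis=1))))


@dataclass(frozen=True)
class RgCcsFit:
    """OLS calibration CCS = slope * Rg + intercept with Pearson r."""

    slope: float       # Angstrom^2 per Angstrom
    intercept: float   # Angstrom^2
    pearson_r: float
    n: int

    def predict(self, rg: float) -> float:
        return self.slope * rg + self.intercept


def rg_ccs_regression(pairs: Sequence[tuple[float, float]]) -> RgCcsFit:
    """Linear calibration between radius of gyration and CCS."""
    rg = np.array([p[0] for p in pairs], dtype=float)
    ccs = np.array([p[1] for p in pairs], dtype=float)
    if len(rg) < 2 or len(np.unique(rg)) < 2:
        raise ValueError("need >= 2 distinct Rg values")
    res = stats.linregress(rg, ccs)
    return RgCcsFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=len(rg),
    )


@dataclass(frozen=True)
class QuartileStat:
    """Mean response in four Rg-ascending (compact -> extended) bins."""

    means: tuple[float, float, float, float]
    edges: tuple[float, ...]  # 5 cut values on the Rg axis
    sizes: tuple[int, int, int, int]


def quartile_response(
    rg_series: Sequence[float], response_series: Sequence[float]
) -> QuartileStat:
    """Split samples into Rg quartiles and average the response per bin.

    Samples are sorted by ascending Rg and split into four near-equal
    bins (sizes differing by at most one), reported compact to extended.
    """
    rg = np.asarray(rg_series, dtype=float)
    resp = np.asarray(response_series, dtype=float)
    if rg.shape != resp.shape:
        raise ValueError("series must have equal length")
    if len(rg) < 4:
        raise ValueError("need at least 4 samples")
    order = np.argsort(rg, kind="stable")
    bins = np.array_split(order, 4)
    means = tuple(float(resp[b].mean()) for b in bins)
    edges = [float(rg[order[0]])]
    for b0, b1 in zip(bins, bins[1:]):
        edges.append(0.5 * (float(rg[b0[-1]]) + float(rg[b1[0]])))
    edges.append(float(rg[order[-1]]))
    return QuartileStat(means=means, edges=tuple(edges), sizes=tuple(len(b) for b in bins))


def cuboid_rg(a: float, b: float, c: float) -> float:
    """Radius of gyration of a uniform rectangular cuboid with edges a, b, c.

    Degenerate edges (zero) are allowed, giving the slab/rod limits.
    """
    if a < 0 or b < 0 or c < 0 or (a == 0 and b == 0 and c == 0):
        raise ValueError("edges must be non-negative with at least one positive")
    return math.sqrt((a * a + b * b + c * c) / 12.0)


def synthetic_globule(
    n_atoms: int, radius: float, seed: int = 0, element: str = "C"
) -> StructureModel:
    """Random compact cluster of atoms inside a sphere — a stand-in
    conformer for exercising the Rg-CCS calibration."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4 * n_atoms, 3))
    pts = pts[np.linalg.norm(pts, axis=1) > 1e-9][:n_atoms]
    u = rng.random(n_atoms) ** (1 / 3)
    coords = radius * u[:, None] * pts / np.linalg.norm(pts, axis=1)[:, None]
    return StructureModel.from_coords(coords, elements=[element] * n_atoms)
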