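"""Presence records: ingestion, spatial thinning, bias surface, background.

Presence-only modelling is acutely sensitive to two sampling artefacts:
clustered duplicate records (spatial autocorrelation) and geographically
uneven collection effort. This module addresses both — a nearest-neighbour
thinning rule that enforces a minimum pairwise great-circle distance while
retaining as many localities as possible, and a kernel-density bias surface
used to draw background points with the same spatial sampling intensity as
the presences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EARTH_RADIUS_KM, ClimateGrid, GridStack

log = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Presence coordinates for one species (lon, lat in decimal degrees)."""

    species: str
    points: np.ndarray  # (n, 2) columns lon, lat
    provenance: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lon(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def lat(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            pd.DataFrame({
                "species": self.species,
                "longitude": self.points[:, 0],
                "latitude": self.points[:, 1],
            }).to_csv(fh, index=False)


@dataclass
class BackgroundSet:
    """Background (pseudo-absence) sample drawn from the landscape."""

    points: np.ndarray          # (n, 2) lon, lat of cell centres
    cells: np.ndarray           # (n, 2) row, col of the sampled cells
    weights: np.ndarray         # per-point selection density used
    seed: int = 0

    def __len__(self) -> int:
        return len(self.points)


def load_occurrences(path: str, species: str, *,
                     species_col: str = "species",
                     lon_col: str = "longitude",
                     lat_col: str = "latitude") -> OccurrenceSet:
    """Parse one species' records from a CSV of presence points.

    Exact duplicate coordinates are collapsed (first occurrence kept) and
    rows with out-of-range or non-numeric coordinates are dropped; both
    counts are logged.
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        warnings.warn(f"{path}: no rows parsed; returning empty set")
        return OccurrenceSet(species=species, points=np.empty((0, 2)), provenance=path)
    for col in (species_col, lon_col, lat_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df[df[species_col].astype(str) == species]
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    ok = lon.between(-180, 180) & lat.between(-90, 90)
    n_bad = int((~ok).sum())
    if n_bad:
        log.info("%s: rejected %d out-of-range/non-numeric rows", path, n_bad)
    pts = np.column_stack([lon[ok].to_numpy(), lat[ok].to_numpy()])
    pts, n_dup = _dedup(pts)
    if n_dup:
        log.info("%s: collapsed %d duplicate coordinates", path, n_dup)
    if len(pts) == 0:
        warnings.warn(f"{path}: no valid records for species {species!r}")
    return OccurrenceSet(species=species, points=pts, provenance=path)


def _dedup(points: np.ndarray) -> tuple[np.ndarray, int]:
    if len(points) == 0:
        return points, 0
    _, idx = np.unique(points, axis=0, return_index=True)
    keep = np.sort(idx)
    return points[keep], len(points) - len(keep)


def haversine_km(p: tuple[float, float], q) -> float | np.ndarray:
    """Great-circle distance (km, spherical Earth R = 6371 km).

    ``q`` may be one (lon, lat) pair or an (n, 2) array; vectorised over q.
    """
    q = np.asarray(q, dtype=float)
    lon1, lat1 = np.radians(p[0]), np.radians(p[1])
    lon2 = np.radians(q[..., 0])
    lat2 = np.radians(q[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def pairwise_haversine_km(points: np.ndarray) -> np.ndarray:
    """Full symmetric distance matrix in km for an (n, 2) lon/lat array."""
    pts = np.asarray(points, dtype=float)
    lon = np.radians(pts[:, 0])[:, None]
    lat = np.radians(pts[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def thin(occ: OccurrenceSet, min_dist_km: float = 10.0, reps: int = 10,
         seed: int = 0) -> OccurrenceSet:
    """Spatially thin presences so every pair is strictly > ``min_dist_km`` apart.

    Per repetition the point with the most neighbours closer than the cutoff
    is deleted (ties broken uniformly at random) until no violating pair
    remains; the largest retained set over ``reps`` randomized repetitions is
    returned. This greedy most-neighbours-first rule keeps as many localities
    as possible. Deterministic for a fixed seed.
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be > 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = len(occ)
    if n <= 1:
        return occ
    dmat = pairwise_haversine_km(occ.points)
    conflict = (dmat <= min_dist_km)
    np.fill_diagonal(conflict, False)
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(reps):
        keep = np.ones(n, dtype=bool)
        counts = conflict.sum(axis=1).astype(int)
        while True:
            active = np.where(keep)[0]
            sub = counts[active]
            if sub.max(initial=0) == 0:
                break
            worst = active[sub == sub.max()]
            victim = int(rng.choice(worst))
            keep[victim] = False
            counts[conflict[victim]] -= 1
            counts[victim] = 0
        if best is None or keep.sum() > best.sum():
            best = keep
    assert best is not None
    out = OccurrenceSet(
        species=occ.species,
        points=occ.points[best],
        provenance=f"{occ.provenance} | thinned >{min_dist_km} km, reps={reps}, seed={seed}",
    )
    return out


def bias_surface(occ: OccurrenceSet, template: ClimateGrid,
                 bandwidth_km: float = 200.0) -> ClimateGrid:
    """Gaussian kernel density of presences over the template's unmasked cells.

    Densities are normalized to sum to 1 over unmasked cells and are strictly
    positive everywhere (the Gaussian kernel has unbounded support), so a
    weighted background draw can in principle reach any cell.
    """
    if len(occ) == 0:
        raise ValueError("bias_surface requires at least one occurrence")
    if bandwidth_km <= 0:
        raise ValueError("bandwidth_km must be > 0")
    lon, lat = template.cell_centers()
    keep = ~template.mask
    centers = np.column_stack([lon[keep], lat[keep]])
    dens = np.zeros(len(centers))
    for p in occ.points:
        d = haversine_km((p[0], p[1]), centers)
        dens += np.exp(-0.5 * (d / bandwidth_km) ** 2)
    # guard against total underflow when all points are extremely remote
    total = dens.sum()
    if total <= 0:
        dens[:] = 1.0
        total = dens.sum()
    dens /= total
    out = np.zeros(template.shape)
    out[keep] = dens
    return template.with_values(out, name="bias", units="density")


def sample_background(stack: GridStack, bias: ClimateGrid | None, n: int = 50_000,
                      seed: int = 0) -> BackgroundSet:
    """Draw ``n`` background cells with replacement, probability ∝ bias.

    ``bias=None`` draws uniformly over unmasked cells. Points are placed at
    cell centres. The study-faithful default is 50,000 points per species.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    template = stack.template
    if bias is not None and not template.same_georeference(bias):
        raise ValueError("bias surface is not aligned with the stack")
    keep = ~stack.mask
    if not keep.any():
        raise ValueError("all cells are masked; nothing to sample")
    rows, cols = np.where(keep)
    w = np.ones(keep.sum()) if bias is None else bias.values[keep].astype(float)
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("bias surface sums to zero over unmasked cells")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=True, p=p)
    rr, cc = rows[idx], cols[idx]
    pts = np.column_stack([
        np.asarray(template.lon_center(cc)),
        np.asarray(template.lat_center(rr)),
    ])
    return BackgroundSet(points=pts, cells=np.column_stack([rr, cc]),
                         weights=p[idx], seed=seed)
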