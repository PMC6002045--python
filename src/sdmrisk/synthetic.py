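"""Synthetic study systems with a known climatic niche.

The generator emulates the statistical structure the pipeline assumes:
smooth gridded climate fields (a temperature-like layer with a latitudinal
gradient, a precipitation-like layer, plus uninformative noise layers), a
known true suitability surface — unimodal (Gaussian) in temperature and
monotonically decreasing in precipitation — spatially biased presence
sampling from that truth, and a uniformly warmed / precipitation-scaled
"future" slice. Because the niche parameters are known, recovery of the
temperature optimum, importance rankings and the direction of projected
change are all falsifiable.

Defaults mirror the empirical niche of the study system this package was
built around: a pest whose occurrences centre on 23.8 °C annual mean
temperature (SD 3.8 °C), and a host centring on 20.1 °C.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import ClimateGrid, GridStack, align_stack
from .maxent import SuitabilityGrid
from .occurrences import OccurrenceSet

#: annual-mean-temperature optimum of the pest's occurrences, °C
PEST_TEMP_OPTIMUM = 23.8
#: occurrence-sample SD of annual mean temperature for the pest, °C
PEST_TEMP_SD = 3.8
#: same for the host crop
HOST_TEMP_OPTIMUM = 20.1
HOST_TEMP_SD = 4.3


@dataclass
class TruthParams:
    """Parameters of the known true suitability surface."""

    temp_optimum: float = PEST_TEMP_OPTIMUM   # °C
    temp_sd: float = PEST_TEMP_SD             # °C
    precip_halfsat: float = 150.0             # mm; suitability halves at this P
    bias_strength: float = 0.0                # 0 = unbiased sampling
    n_presence: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.temp_sd > 0:
            raise ValueError("temp_sd must be > 0")
        if self.n_presence < 1:
            raise ValueError("n_presence must be >= 1")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def make_climate(shape: tuple[int, int] = (40, 40), n_vars: int = 4, seed: int = 0,
                 origin: tuple[float, float] = (-30.0, 40.0),
                 cell_size: float = 1.0) -> GridStack:
    """Smooth synthetic climate fields on a lat/lon lattice.

    Layer 1 (``bio1``) is temperature-like: a linear latitudinal gradient
    spanning ≈ 2–26 °C from the poleward to the equatorward edge of the
    window, plus smoothed noise. The warm edge sits near a warm-adapted
    species' optimum, so uniform warming moves most of the window toward
    higher suitability — the regime the projection stages are meant to
    exercise. Layer 2 (``bio12``) is precipitation-like,
    longitudinal wet/dry bands in ≈ 0–3000 mm. Remaining layers are smoothed
    noise with no relation to the truth. Deterministic per seed.
    """
    nrows, ncols = shape
    if nrows < 10 or ncols < 10:
        raise ValueError("grid must be at least 10×10")
    if n_vars < 2:
        raise ValueError("need at least temperature and precipitation layers")
    rng = np.random.default_rng(seed)
    rows = np.arange(nrows)
    lat = origin[1] - (rows + 0.5) * cell_size

    def smooth_noise(scale: float) -> np.ndarray:
        return gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=3.0) * scale

    # latitudinal trend: warmest at the equatorward (low-|lat|) window edge
    frac = (np.abs(lat) - np.abs(lat).min()) / max(np.ptp(np.abs(lat)), 1e-9)
    lat_trend = 26.0 - 24.0 * frac
    temp = np.clip(lat_trend[:, None] + smooth_noise(8.0), 0.0, 30.0)
    precip = np.clip(1500.0 + 1500.0 * np.sin(np.linspace(0, 3 * np.pi, ncols))[None, :]
                     + smooth_noise(4000.0), 0.0, 3000.0)
    mask = np.zeros(shape, dtype=bool)
    grids = [
        ClimateGrid("bio1", temp, mask, origin, cell_size, units="°C"),
        ClimateGrid("bio12", precip, mask, origin, cell_size, units="mm"),
    ]
    for i in range(n_vars - 2):
        # rougher fields than the two real drivers, so they cannot mimic the
        # latitudinal trend by chance in a finite window
        noise = gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=1.0) * 10.0 + 50.0
        grids.append(ClimateGrid(f"noise{i + 1}", noise, mask, origin, cell_size,
                                 units="index"))
    return align_stack(grids, slice_label="current")


def make_future(stack: GridStack, delta_temp: float = 2.0,
                precip_scale: float = 0.9, slice_label: str = "future") -> GridStack:
    """Uniformly warmed / precipitation-scaled copy of a climate stack."""
    grids = []
    for name, g in stack.layers.items():
        if g.units == "°C":
            grids.append(g.with_values(g.values + delta_temp))
        elif g.units == "mm":
            grids.append(g.with_values(g.values * precip_scale))
        else:
            grids.append(g.with_values(g.values))
    return align_stack(grids, slice_label=slice_label)


def true_suitability(stack: GridStack, params: TruthParams,
                     temp_var: str = "bio1", precip_var: str = "bio12",
                     ) -> SuitabilityGrid:
    """The known truth: Gaussian in temperature × decreasing in precipitation.

    s(x) = exp(−(T − T_opt)² / (2σ²)) · h / (h + P), values in (0, 1].
    """
    for v in (temp_var, precip_var):
        if v not in stack.layers:
            raise ValueError(f"stack lacks required layer {v!r}")
    T = stack[temp_var].values
    P = stack[precip_var].values
    s = np.exp(-((T - params.temp_optimum) ** 2) / (2.0 * params.temp_sd ** 2))
    s = s * params.precip_halfsat / (params.precip_halfsat + P)
    s[stack.mask] = 0.0
    grid = stack.template.with_values(s, name="true_suitability", units="index")
    return SuitabilityGrid(grid=grid, transform="raw", clamp_mode="none",
                           clamp_counts=np.zeros(grid.shape, dtype=int))


def sample_presences(truth: SuitabilityGrid, bias: ClimateGrid | None,
                     n: int, seed: int = 0, species: str = "synthetic",
                     ) -> OccurrenceSet:
    """Draw presence cells ∝ truth × bias; points jittered inside their cell.

    The sub-cell jitter gives distinct coordinates even when a cell is drawn
    twice, which is what real coordinate noise looks like to the thinning
    step. Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    g = truth.grid
    w = truth.values.astype(float).copy()
    w[g.mask] = 0.0
    if bias is not None:
        if not g.same_georeference(bias):
            raise ValueError("bias surface is not aligned with the truth grid")
        w = w * np.clip(bias.values, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    p = (w / total).ravel()
    rng = np.random.default_rng(seed)
    flat = rng.choice(p.size, size=n, replace=True, p=p)
    rr, cc = np.unravel_index(flat, g.shape)
    jitter = rng.uniform(-0.499, 0.499, size=(n, 2))
    lon = g.origin[0] + (cc + 0.5 + jitter[:, 0]) * g.cell_size
    lat = g.origin[1] - (rr + 0.5 + jitter[:, 1]) * g.cell_size
    return OccurrenceSet(species=species, points=np.column_stack([lon, lat]),
                         provenance=f"synthetic truth sample, seed={seed}")
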