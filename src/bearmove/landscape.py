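"""Co-registered raster stacks and synthetic landscape generation.

All rasters live on a shared planar grid (meters, default 30 m pixels).
Row 0 is the northern edge; cell centers are offset half a pixel from the
grid origin (west/south corner).  Layers are either categorical (0/1) or
continuous (finite floats).  Interchange format is single-band ESRI ASCII
grid (.asc), one file per layer, which keeps everything plain text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

#: layers every generated landscape provides
DEFAULT_CATEGORICAL = (
    "deciduous_forest",
    "coniferous_forest",
    "mixed_forest",
    "forested_wetland",
    "agriculture",
    "low_density_residential",
)


class ConfigurationError(ValueError):
    """Raised when a landscape or study configuration is internally inconsistent."""


@dataclass
class LandscapeStack:
    """Named 2-D grids sharing one origin, resolution and extent.

    Parameters
    ----------
    layers
        Mapping layer name -> 2-D float array, all the same shape.
    kinds
        Mapping layer name -> ``"categorical"`` or ``"continuous"``.
    res
        Pixel size in meters.
    x0, y0
        Coordinates (m) of the west/south corner of the grid.
    """

    layers: dict[str, np.ndarray]
    kinds: dict[str, str]
    res: float = 30.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ConfigurationError(f"layers have mismatched shapes: {shapes}")
        for name, arr in self.layers.items():
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"layer {name!r} contains non-finite values")
            if self.kinds.get(name) == CATEGORICAL and not np.isin(arr, (0.0, 1.0)).all():
                raise ConfigurationError(f"categorical layer {name!r} is not 0/1")

    # --- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        nr, nc = self.shape
        return (self.x0, self.y0, self.x0 + nc * self.res, self.y0 + nr * self.res)

    def xy_to_rc(self, x, y):
        """Map coordinates to (row, col) indices (row 0 = north)."""
        nr, _ = self.shape
        col = np.floor((np.asarray(x) - self.x0) / self.res).astype(int)
        row = nr - 1 - np.floor((np.asarray(y) - self.y0) / self.res).astype(int)
        return row, col

    def rc_to_xy(self, row, col):
        """Cell-center coordinates of (row, col)."""
        nr, _ = self.shape
        x = self.x0 + (np.asarray(col) + 0.5) * self.res
        y = self.y0 + (nr - np.asarray(row) - 0.5) * self.res
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.shape
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        return self.rc_to_xy(rows, cols)

    def in_bounds(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        return (np.asarray(x) >= xmin) & (np.asarray(x) < xmax) & (np.asarray(y) >= ymin) & (np.asarray(y) < ymax)

    def value_at(self, name: str, x, y):
        row, col = self.xy_to_rc(x, y)
        return self.layers[name][row, col]

    # --- I/O ----------------------------------------------------------
    def write_ascii_grids(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nr, nc = self.shape
        for name, arr in self.layers.items():
            header = (
                f"ncols {nc}\nnrows {nr}\nxllcorner {self.x0}\nyllcorner {self.y0}\n"
                f"cellsize {self.res}\nNODATA_value -9999\n"
            )
            path = directory / f"{name}.asc"
            with open(path, "w") as fh:
                fh.write(header)
                np.savetxt(fh, arr, fmt="%.6g")
        kinds = "\n".join(f"{n}: {k}" for n, k in self.kinds.items())
        (directory / "layer_kinds.txt").write_text(kinds + "\n")

    @classmethod
    def read_ascii_grids(cls, directory: str | Path) -> "LandscapeStack":
        directory = Path(directory)
        kinds: dict[str, str] = {}
        kinds_file = directory / "layer_kinds.txt"
        if kinds_file.exists():
            for line in kinds_file.read_text().splitlines():
                if ":" in line:
                    n, k = line.split(":", 1)
                    kinds[n.strip()] = k.strip()
        layers, meta = {}, None
        for path in sorted(directory.glob("*.asc")):
            hdr = {}
            with open(path) as fh:
                for _ in range(6):
                    key, val = re.split(r"\s+", fh.readline().strip(), maxsplit=1)
                    hdr[key.lower()] = float(val)
                arr = np.loadtxt(fh)
            layers[path.stem] = np.atleast_2d(arr)
            meta = hdr
        if meta is None:
            raise FileNotFoundError(f"no .asc layers under {directory}")
        return cls(
            layers=layers,
            kinds={n: kinds.get(n, CONTINUOUS) for n in layers},
            res=meta["cellsize"],
            x0=meta["xllcorner"],
            y0=meta["yllcorner"],
        )


def _smooth_field(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white noise, unit-variance-ish, used to carve patches."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px, mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def make_landscape(
    proportions: dict[str, float] | None = None,
    shape: tuple[int, int] = (200, 200),
    res: float = 30.0,
    autocorr_range: float = 300.0,
    seed: int = 0,
    constant_layers: dict[str, float] | None = None,
) -> LandscapeStack:
    """Generate a synthetic land-cover stack with contiguous patches.

    Mutually exclusive cover classes are carved sequentially from
    independent smoothed-noise fields: each class claims its target share
    of the still-unassigned cells with the highest field values, which
    yields contiguous patches and *exact* class proportions.  Continuous
    companions (percent impervious, slope, housing density) are derived
    from further smoothed fields so they correlate spatially with cover.

    Parameters
    ----------
    proportions
        Target share per mutually exclusive categorical class.  Defaults
        to a forest-dominated mix typical of southern New England.
    autocorr_range
        Spatial autocorrelation range in meters (Gaussian smoothing SD of
        the noise fields).
    constant_layers
        Optional overrides: layer name -> constant value (useful for
        degenerate test configurations, e.g. impervious identically 0).
    """
    if proportions is None:
        proportions = {
            "deciduous_forest": 0.30,
            "coniferous_forest": 0.15,
            "mixed_forest": 0.15,
            "forested_wetland": 0.08,
            "agriculture": 0.08,
            "low_density_residential": 0.08,
        }
    for name, p in proportions.items():
        if not 0.0 < p < 1.0:
            raise ConfigurationError(f"proportion for {name!r} must be in (0,1), got {p}")
    if sum(proportions.values()) > 1.0:
        raise ConfigurationError("mutually exclusive class proportions sum to more than 1")
    if shape[0] < 64 or shape[1] < 64:
        raise ConfigurationError("grid must be at least 64x64")

    rng = np.random.default_rng(seed)
    sigma_px = autocorr_range / res
    n_cells = shape[0] * shape[1]

    layers: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    unassigned = np.ones(shape, bool)
    for name, p in proportions.items():
        fld = _smooth_field(shape, sigma_px, rng)
        target = int(round(p * n_cells))
        vals = np.where(unassigned, fld, -np.inf)
        take = min(target, int(unassigned.sum()))
        idx = np.argpartition(vals.ravel(), -take)[-take:] if take else np.empty(0, int)
        mask = np.zeros(n_cells, bool)
        mask[idx] = True
        mask = mask.reshape(shape)
        layers[name] = mask.astype(float)
        kinds[name] = CATEGORICAL
        unassigned &= ~mask

    # impervious surface: high inside residential patches, low elsewhere
    resid = layers.get("low_density_residential", np.zeros(shape))
    base = _smooth_field(shape, sigma_px, rng)
    imperv = 100.0 * np.clip(
        0.06 * (base - base.min()) / np.ptp(base) if np.ptp(base) > 0 else 0.0 * base,
        0,
        1,
    )
    imperv = imperv + 55.0 * ndimage.gaussian_filter(resid, sigma_px / 2, mode="nearest")
    layers["percent_impervious"] = np.clip(imperv, 0.0, 100.0)
    kinds["percent_impervious"] = CONTINUOUS

    # housing density (houses/km^2): proportional to impervious with local texture
    tex = _smooth_field(shape, sigma_px / 2, rng)
    housing = np.clip(3.0 * layers["percent_impervious"] + 8.0 * tex, 0.0, None)
    layers["housing_density"] = housing
    kinds["housing_density"] = CONTINUOUS

    # roads: narrow level-set bands of a smooth field, denser near development
    road_fld = _smooth_field(shape, sigma_px, rng)
    roads = (np.abs(road_fld) < 0.04).astype(float)
    layers["roads"] = roads
    kinds["roads"] = CATEGORICAL

    # slope (degrees) from a synthetic elevation field
    elev = 120.0 * _smooth_field(shape, 2 * sigma_px, rng)
    gy, gx = np.gradient(elev, res)
    layers["slope"] = np.degrees(np.arctan(np.hypot(gx, gy)))
    kinds["slope"] = CONTINUOUS

    if constant_layers:
        for name, val in constant_layers.items():
            layers[name] = np.full(shape, float(val))
            kinds.setdefault(name, CONTINUOUS)

    return LandscapeStack(layers=layers, kinds=kinds, res=res)
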