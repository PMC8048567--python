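"""Core data containers shared across the pipeline.

The pipeline passes around a small set of labelled containers: suitability
raster stacks, site tables, diploid genotype datasets, per-site score
vectors, pairwise distance matrices and prioritization series.  They are
thin dataclasses over numpy arrays and pandas objects, with the invariants
(symmetry, zero diagonals, label alignment) enforced at construction time
so downstream code never has to re-check them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0  # allele code for a missing call; real alleles are >= 1


class GensurrError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass(frozen=True)
class RasterStack:
    """Aligned suitability grids for one or more time periods.

    Grids follow the ESRI ASCII convention: row 0 is the northernmost row,
    ``xllcorner``/``yllcorner`` give the lower-left corner of the grid, and
    coordinates refer to cell centres.  Values are suitabilities in [0, 1];
    NODATA cells are stored as NaN and the NODATA mask is shared across
    periods.  Period 0 is the contemporary layer by convention.
    """

    periods: tuple[str, ...]
    values: np.ndarray  # (n_periods, nrows, ncols), float64, NaN = NODATA
    xllcorner: float
    yllcorner: float
    cellsize: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3 or vals.shape[0] != len(self.periods):
            raise GensurrError("values must be (n_periods, nrows, ncols)")
        if len(self.periods) < 1:
            raise GensurrError("a RasterStack needs at least one period")
        if self.cellsize <= 0:
            raise GensurrError("cellsize must be positive")
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise GensurrError("suitability values must lie in [0, 1]")
        masks = np.isnan(vals)
        if masks.any() and not (masks == masks[0]).all():
            raise GensurrError("NODATA mask must be shared across periods")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def contemporary(self) -> np.ndarray:
        return self.values[0]

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values[0])

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing map coordinates (x, y)."""
        nrows, ncols = self.shape
        col = int(np.floor((x - self.xllcorner) / self.cellsize))
        row = nrows - 1 - int(np.floor((y - self.yllcorner) / self.cellsize))
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise GensurrError(f"coordinates ({x}, {y}) fall outside the raster")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows, _ = self.shape
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (nrows - row - 0.5) * self.cellsize
        return x, y

    def value_at(self, period: int, x: float, y: float) -> float:
        row, col = self.cell_of(x, y)
        return float(self.values[period, row, col])


@dataclass(frozen=True)
class SiteTable:
    """Sampling sites with projected (metric) coordinates."""

    frame: pd.DataFrame  # columns: site_id, x, y

    def __post_init__(self) -> None:
        required = {"site_id", "x", "y"}
        if not required.issubset(self.frame.columns):
            raise GensurrError(f"site table needs columns {sorted(required)}")
        if self.frame["site_id"].duplicated().any():
            raise GensurrError("duplicate site IDs")
        if self.frame[["x", "y"]].isna().any().any():
            raise GensurrError("NaN coordinates in site table")
        object.__setattr__(self, "frame", self.frame.reset_index(drop=True))

    @property
    def ids(self) -> list[str]:
        return [str(s) for s in self.frame["site_id"]]

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class GenotypeDataset:
    """Codominant diploid genotypes grouped by sampling site.

    ``calls[site]`` is an int array of shape (n_individuals, n_loci, 2)
    holding allele IDs (positive integers); 0 marks a missing allele call.
    Allele pairs are unordered: all computations must be invariant to
    swapping the two calls of a genotype.
    """

    sites: list[str]
    loci: list[str]
    calls: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.sites) != set(self.calls):
            raise GensurrError("calls must cover exactly the listed sites")
        for site, arr in self.calls.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 3 or arr.shape[1] != len(self.loci) or arr.shape[2] != 2:
                raise GensurrError(
                    f"calls for site {site!r} must be (n_individuals, n_loci, 2)"
                )
            if (arr < 0).any():
                raise GensurrError("allele IDs must be >= 0 (0 = missing)")
            self.calls[site] = arr

    def n_individuals(self, site: str) -> int:
        return self.calls[site].shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class ScoreVector:
    """One real score per site, labelled by the metric it carries."""

    series: pd.Series  # index: site IDs, values: float
    metric: str

    def __post_init__(self) -> None:
        ser = self.series.astype(float)
        if not np.isfinite(ser.to_numpy()).all():
            raise GensurrError(f"non-finite scores in {self.metric!r}")
        if ser.index.duplicated().any():
            raise GensurrError("duplicate site IDs in score vector")
        object.__setattr__(self, "series", ser)

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.series.index]

    def to_csv(self, path) -> None:
        frame = self.series.rename(self.metric).rename_axis("site_id").reset_index()
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreVector":
        frame = pd.read_csv(path)
        metric = frame.columns[1]
        ser = pd.Series(frame[metric].to_numpy(), index=frame["site_id"].astype(str))
        return cls(ser, metric)


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric non-negative distance matrix over sites."""

    sites: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.sites)
        if vals.shape != (n, n):
            raise GensurrError("distance matrix shape must match site count")
        if not np.isfinite(vals).all():
            raise GensurrError("distance matrix has non-finite entries")
        if (vals < -1e-12).any():
            raise GensurrError("negative distances")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise GensurrError("distance matrix must be symmetric")
        vals = np.clip((vals + vals.T) / 2.0, 0.0, None)  # exact symmetry
        np.fill_diagonal(vals, 0.0)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sites", tuple(str(s) for s in self.sites))

    @property
    def n(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.sites)

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("site_id").to_csv(path)

    @classmethod
    def from_csv(cls, path, metric: str = "distance") -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls(tuple(frame.index), frame.to_numpy(dtype=float), metric)

    def submatrix(self, sites: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sites.index(s) for s in sites]
        return DistanceMatrix(
            tuple(self.sites[i] for i in idx),
            self.values[np.ix_(idx, idx)],
            self.metric,
        )


@dataclass(frozen=True)
class PrioritizationSeries:
    """Incremental site selections for k = 1..n under one method.

    Rank-based series are nested by construction; optimal distance-based
    (p-median) series need not be.  ``objectives`` holds the p-median
    objective where the generating method defines one.
    """

    species: str
    method: str
    selections: dict[int, frozenset[str]]
    objectives: dict[int, float] = field(default_factory=dict)
    replicate: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for k, sel in self.selections.items():
            if len(sel) != k:
                raise GensurrError(f"selection for k={k} has {len(sel)} sites")

    @property
    def ks(self) -> list[int]:
        return sorted(self.selections)

    def to_rows(self) -> pd.DataFrame:
        rows = []
        for k in self.ks:
            for site in sorted(self.selections[k]):
                rows.append(
                    {
                        "species": self.species,
                        "method": self.method,
                        "k": k,
                        "replicate": -1 if self.replicate is None else self.replicate,
                        "site_id": site,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MLPEFit:
    """Maximum-likelihood population-effects regression fit on pairwise data."""

    intercept: float
    slope: float
    sigma2_u: float  # site random-effect variance
    sigma2_e: float  # pair residual variance
    loglik: float
    r2_beta: float
    slope_se: float
    converged: bool
    n_sites: int
    n_pairs: int

    def __post_init__(self) -> None:
        if self.converged:
            if self.sigma2_u < 0 or self.sigma2_e < 0:
                raise GensurrError("variance components must be non-negative")
            if not (0.0 <= self.r2_beta <= 1.0):
                raise GensurrError("R2_beta must lie in [0, 1]")

    def wald_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats

        half = stats.norm.ppf(0.5 + level / 2.0) * self.slope_se
        return self.slope - half, self.slope + half
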