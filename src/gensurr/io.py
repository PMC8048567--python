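"""Readers and writers for the plain-text formats the pipeline exchanges.

GENEPOP files carry multi-locus codominant genotypes (one ``Pop`` block per
sampling site, fixed-width allele codes, ``0`` codes for a missing allele).
Suitability grids travel as ESRI ASCII rasters (.asc).  Everything else is
CSV: site coordinates, long-format genotypes, score vectors and square
distance matrices.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GensurrError, GenotypeDataset, RasterStack, SiteTable

# ---------------------------------------------------------------------------
# GENEPOP


def write_genepop(dataset: GenotypeDataset, path, title: str = "gensurr export") -> None:
    """Write a GENEPOP file with 3-digit allele codes, one Pop per site."""
    lines = [title]
    lines.extend(dataset.loci)
    for site in dataset.sites:
        lines.append("Pop")
        arr = dataset.calls[site]
        for ind in range(arr.shape[0]):
            geno = " ".join(
                f"{arr[ind, l, 0]:03d}{arr[ind, l, 1]:03d}"
                for l in range(len(dataset.loci))
            )
            lines.append(f"{site}_{ind + 1} ,  {geno}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path) -> GenotypeDataset:
    """Read a GENEPOP file (2- or 3-digit dialect; 0/00/000 = missing).

    The site label of each Pop block is taken from the individual
    identifiers, which conventionally repeat the site name before the comma;
    the label of the last individual in the block identifies the population,
    stripped of a trailing ``_<number>`` suffix if present.
    """
    raw = Path(path).read_text().splitlines()
    if len(raw) < 3:
        raise GensurrError("GENEPOP file too short")
    lines = [ln.rstrip() for ln in raw]
    # locus names: one per line, or a single comma-separated line
    loci: list[str] = []
    idx = 1
    while idx < len(lines) and lines[idx].strip().lower() != "pop":
        chunk = lines[idx].strip()
        if chunk:
            loci.extend(s.strip() for s in chunk.split(",") if s.strip())
        idx += 1
    if not loci:
        raise GensurrError("no loci found in GENEPOP header")

    pops: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for ln in lines[idx:]:
        if ln.strip().lower() == "pop":
            current = []
            pops.append(current)
            continue
        if not ln.strip():
            continue
        if current is None:
            raise GensurrError("genotype line before first Pop")
        if "," not in ln:
            raise GensurrError(f"malformed GENEPOP line (no comma): {ln!r}")
        name, genos = ln.split(",", 1)
        fields = genos.split()
        if len(fields) != len(loci):
            raise GensurrError(
                f"individual {name.strip()!r} has {len(fields)} genotypes, "
                f"expected {len(loci)}"
            )
        current.append((name.strip(), fields))
    if not pops:
        raise GensurrError("no Pop blocks found")

    sites: list[str] = []
    calls: dict[str, np.ndarray] = {}
    for p, block in enumerate(pops):
        if not block:
            raise GensurrError("empty Pop block")
        label = re.sub(r"_\d+$", "", block[-1][0]) or f"pop{p + 1}"
        if label in calls:
            label = f"{label}.{p + 1}"
        arr = np.zeros((len(block), len(loci), 2), dtype=np.int64)
        for i, (_, fields) in enumerate(block):
            for l, code in enumerate(fields):
                if len(code) not in (4, 6) or not code.isdigit():
                    raise GensurrError(f"bad allele code {code!r}")
                half = len(code) // 2
                arr[i, l, 0] = int(code[:half])
                arr[i, l, 1] = int(code[half:])
        sites.append(label)
        calls[label] = arr
    return GenotypeDataset(sites=sites, loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# long-format genotype CSV


def write_genotypes_csv(dataset: GenotypeDataset, path) -> None:
    rows = []
    for site in dataset.sites:
        arr = dataset.calls[site]
        for ind in range(arr.shape[0]):
            for l, locus in enumerate(dataset.loci):
                rows.append(
                    (site, f"{site}_{ind + 1}", locus, arr[ind, l, 0], arr[ind, l, 1])
                )
    pd.DataFrame(
        rows, columns=["site", "individual", "locus", "allele1", "allele2"]
    ).to_csv(path, index=False)


def read_genotypes_csv(path) -> GenotypeDataset:
    frame = pd.read_csv(path, dtype={"site": str, "individual": str, "locus": str})
    required = {"site", "individual", "locus", "allele1", "allele2"}
    if not required.issubset(frame.columns):
        raise GensurrError(f"long-format CSV needs columns {sorted(required)}")
    sites = list(dict.fromkeys(frame["site"]))
    loci = list(dict.fromkeys(frame["locus"]))
    locus_pos = {l: i for i, l in enumerate(loci)}
    calls: dict[str, np.ndarray] = {}
    for site, grp in frame.groupby("site", sort=False):
        inds = list(dict.fromkeys(grp["individual"]))
        ind_pos = {ind: i for i, ind in enumerate(inds)}
        arr = np.zeros((len(inds), len(loci), 2), dtype=np.int64)
        rows = grp["individual"].map(ind_pos).to_numpy()
        cols = grp["locus"].map(locus_pos).to_numpy()
        arr[rows, cols, 0] = grp["allele1"].fillna(MISSING).to_numpy(dtype=np.int64)
        arr[rows, cols, 1] = grp["allele2"].fillna(MISSING).to_numpy(dtype=np.int64)
        calls[str(site)] = arr
    return GenotypeDataset(sites=[str(s) for s in sites], loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# ESRI ASCII grid


def write_ascii_grid(
    grid: np.ndarray,
    path,
    xllcorner: float,
    yllcorner: float,
    cellsize: float,
    nodata: float = -9999.0,
) -> None:
    grid = np.asarray(grid, dtype=float)
    nrows, ncols = grid.shape
    out = np.where(np.isnan(grid), nodata, grid)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {xllcorner:.6f}\n"
        f"yllcorner {yllcorner:.6f}\n"
        f"cellsize {cellsize:.6f}\n"
        f"NODATA_value {nodata:.6f}\n"
    )
    body = "\n".join(" ".join(f"{v:.8g}" for v in row) for row in out)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, float, float, float]:
    """Return (grid with NaN NODATA, xllcorner, yllcorner, cellsize)."""
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, ln in enumerate(text):
        parts = ln.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GensurrError(f"ASCII grid header missing {key}")
    grid = np.loadtxt(text[body_start:], dtype=float)
    grid = np.atleast_2d(grid)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GensurrError("ASCII grid body does not match header dimensions")
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid = np.where(np.isclose(grid, nodata), np.nan, grid)
    return grid, header["xllcorner"], header["yllcorner"], header["cellsize"]


def write_raster_stack(stack: RasterStack, directory, prefix: str = "suitability") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for p, period in enumerate(stack.periods):
        path = directory / f"{prefix}_{period}.asc"
        write_ascii_grid(
            stack.values[p], path, stack.xllcorner, stack.yllcorner, stack.cellsize
        )
        paths.append(path)
    return paths


def read_raster_stack(paths, periods: list[str]) -> RasterStack:
    grids = []
    georef = None
    for path in paths:
        grid, xll, yll, cs = read_ascii_grid(path)
        if georef is None:
            georef = (xll, yll, cs)
        elif not np.allclose(georef, (xll, yll, cs)):
            raise GensurrError("raster stack layers have mismatched georeference")
        grids.append(grid)
    assert georef is not None
    return RasterStack(tuple(periods), np.stack(grids), *georef)


# ---------------------------------------------------------------------------
# sites


def write_sites_csv(sites: SiteTable, path) -> None:
    sites.frame[["site_id", "x", "y"]].to_csv(path, index=False)


def read_sites_csv(path) -> SiteTable:
    frame = pd.read_csv(path, dtype={"site_id": str})
    return SiteTable(frame)
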