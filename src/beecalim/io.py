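"""Readers and writers for every external format the pipeline touches.

Movies are multi-page TIFF stacks (one page per frame) with a JSON
metadata sidecar (``<stem>.json``) carrying frame rate, stimulus timing
and identifiers.  Masks are single-page 8-bit PNGs (0 = excluded,
255 = included).  Tables are long-format CSV; XLSX import is supported
with an explicit layout mapping.  Distance matrices are square labeled
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .types import (
    AmplitudeTable,
    DistanceMatrix,
    Mask,
    Movie,
    OdorPanel,
    ValidationError,
)


class FormatError(ValueError):
    """Raised when a file does not conform to its expected format."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a Movie as a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    pixels = movie.pixels
    if np.issubdtype(pixels.dtype, np.integer):
        data = pixels.astype(np.uint16)
    else:
        data = pixels.astype(np.float32)
    # one page per frame, explicitly, so degenerate spatial shapes
    # (e.g. 1 x 1 movies) still round-trip as multi-page stacks
    stack = np.moveaxis(data, 2, 0)
    with tifffile.TiffWriter(path) as writer:
        for frame in stack:
            writer.write(frame, photometric="minisblack", contiguous=True)
    _sidecar(path).write_text(json.dumps(movie.metadata(), indent=1))


def read_movie(path: str | Path, metadata: dict | None = None) -> Movie:
    """Read a multi-page TIFF stack as a Movie.

    ``metadata`` overrides fields from the JSON sidecar (if present);
    sidecar-less stacks get the default acquisition descriptor.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2-D pages")
    if np.any(pages < 0):
        raise FormatError(f"{path}: negative intensities in a raw movie")
    meta: dict = {}
    if _sidecar(path).exists():
        meta.update(json.loads(_sidecar(path).read_text()))
    if metadata:
        meta.update(metadata)
    return Movie(np.moveaxis(pages, 0, 2), **meta)


def write_mask(mask: Mask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (0 = excluded, 255 = included)."""
    img = Image.fromarray(np.where(mask.include, 255, 0).astype(np.uint8))
    img.save(Path(path), format="PNG")


def read_mask(path: str | Path, label: str = "") -> Mask:
    """Read a binary 8-bit PNG mask; intermediate gray values are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(Image.open(path).convert("L"))
    bad = ~np.isin(arr, (0, 255))
    if bad.any():
        raise FormatError(
            f"{path}: {int(bad.sum())} pixels are neither 0 nor 255"
        )
    return Mask(arr == 255, label=label or path.stem)


def write_amplitude_table(table: AmplitudeTable, path: str | Path) -> None:
    table.data.to_csv(Path(path), index=False)


def read_amplitude_table(
    path: str | Path,
    panel: OdorPanel | None = None,
    layout: dict | None = None,
) -> AmplitudeTable:
    """Read an amplitude table from canonical long CSV or from XLSX.

    XLSX files require a ``layout`` mapping because supplementary
    spreadsheets come in many shapes.  Two layouts are supported:

    * ``{"format": "long", "sheet": ..., "columns": {canonical: actual}}``
    * ``{"format": "wide", "sheet": ..., "bee_column": ..., "structure": ...}``
      with bees as rows and stimuli as columns.

    When ``panel`` is given, stimulus names are validated against it.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        if layout is None:
            raise ValidationError("XLSX import requires an explicit layout mapping")
        df = _read_xlsx(path, layout)
    else:
        df = pd.read_csv(path)
        rename = {
            "structure_label": "structure",
            "stimulus_id": "stimulus",
        }
        df = df.rename(columns=rename)
    missing = [c for c in AmplitudeTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[list(AmplitudeTable.REQUIRED)].copy()
    df["amplitude"] = df["amplitude"].astype(float)
    if panel is not None:
        unknown = set(df["stimulus"]) - set(panel.names)
        if unknown:
            raise ValidationError(
                f"{path}: stimulus names not in panel: {sorted(unknown)}"
            )
    return AmplitudeTable(df)


def _read_xlsx(path: Path, layout: dict) -> pd.DataFrame:
    fmt = layout.get("format", "long")
    sheet = layout.get("sheet", 0)
    raw = pd.read_excel(path, sheet_name=sheet)
    if fmt == "long":
        cols = layout.get("columns", {})
        df = raw.rename(columns={v: k for k, v in cols.items()})
        if "structure" not in df.columns and "structure" in layout:
            df["structure"] = layout["structure"]
        return df
    if fmt == "wide":
        bee_col = layout.get("bee_column", raw.columns[0])
        long = raw.melt(
            id_vars=[bee_col], var_name="stimulus", value_name="amplitude"
        ).rename(columns={bee_col: "bee_id"})
        long["structure"] = layout.get("structure", "AL")
        return long
    raise ValidationError(f"unknown XLSX layout format {fmt!r}")


def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(Path(path))


def read_distance_matrix(
    path: str | Path,
    provenance: str = "behavioral",
    asymmetry_tolerance: float = 1e-6,
) -> DistanceMatrix:
    """Read a square labeled CSV as a DistanceMatrix.

    Asymmetries up to ``asymmetry_tolerance`` (absolute) are symmetrized by
    averaging; larger asymmetries are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: matrix is not square {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T).max()
    if asym > asymmetry_tolerance:
        raise ValidationError(
            f"{path}: asymmetry {asym:.3g} exceeds tolerance {asymmetry_tolerance:.3g}"
        )
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, [str(c) for c in df.columns], provenance)
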