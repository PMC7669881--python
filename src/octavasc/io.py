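"""TIFF-stack and CSV input/output.

Volumes travel as multi-page TIFF stacks.  The mapping of TIFF pages to
volume axes is explicit and configurable (never inferred): by default
pages are y sections (sagittal stacks), so a stack of ``n`` pages of
shape ``(nz, nx)`` becomes a volume of dims ``(nx, n, nz)``.

Measurement tables are CSV with units in the header and a deterministic
column order; an optional summary row appends the mean and population
SD.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import DiameterResult, LineProbe, summarize
from .tortuosity import SkeletonBranch
from .volume import Volume, axis_index

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_probes",
    "write_measurements",
    "write_branches",
]

# TIFF pages run along this axis unless the caller says otherwise
DEFAULT_PAGE_AXIS = "y"


def _stack_to_volume_axes(stack: np.ndarray, page_axis: int) -> np.ndarray:
    # page layout: pages x rows x cols = page_axis x z x (the remaining lateral axis)
    if page_axis == 0:  # pages = x sections (y-z planes), rows = z, cols = y
        return np.transpose(stack, (0, 2, 1))  # -> (x, y, z)
    if page_axis == 1:  # pages = y sections (x-z planes), rows = z, cols = x
        return np.transpose(stack, (2, 0, 1))  # -> (x, y, z)
    # pages = z sections (x-y planes), rows = y, cols = x
    return np.transpose(stack, (2, 1, 0))  # -> (x, y, z)


def _volume_axes_to_stack(data: np.ndarray, page_axis: int) -> np.ndarray:
    if page_axis == 0:
        return np.transpose(data, (0, 2, 1))
    if page_axis == 1:
        return np.transpose(data, (1, 2, 0))
    return np.transpose(data, (2, 1, 0))


def read_volume(
    path: str | Path,
    spacing_um: tuple[float, float, float],
    page_axis: int | str = DEFAULT_PAGE_AXIS,
) -> Volume:
    """Read a multi-page TIFF stack into a :class:`Volume`.

    ``spacing_um`` must come from the acquisition geometry; a missing
    or non-positive spacing is rejected with a remediation hint.
    8-bit, 16-bit and floating-point stacks are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if spacing_um is None or len(spacing_um) != 3 or min(spacing_um) <= 0:
        raise ValueError(
            "volume spacing missing or invalid; supply spacing_um from the "
            "acquisition geometry (fov_mm / dims), e.g. via the config file"
        )
    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # truncated/corrupt file: error, not crash
        raise ValueError(f"could not read TIFF stack {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3:
        raise ValueError(f"expected a stack of 2D pages, got shape {stack.shape}")
    data = _stack_to_volume_axes(np.asarray(stack), axis_index(page_axis))
    return Volume(intensities=data, spacing_um=tuple(spacing_um))


def write_volume(
    volume: Volume,
    path: str | Path,
    page_axis: int | str = DEFAULT_PAGE_AXIS,
    dtype=None,
) -> None:
    """Write a volume as a multi-page TIFF stack (one page per section)."""
    data = volume.intensities
    if dtype is not None:
        if np.issubdtype(np.dtype(dtype), np.integer):
            info = np.iinfo(dtype)
            data = np.clip(np.rint(data), info.min, info.max)
        data = data.astype(dtype)
    stack = _volume_axes_to_stack(np.ascontiguousarray(data), axis_index(page_axis))
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 2D or multi-page 8-bit mask TIFF as a boolean array."""
    arr = tifffile.imread(Path(path))
    return np.asarray(arr) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_probes(path: str | Path) -> pd.DataFrame:
    """Read a probe definition CSV.

    Columns: ``plane`` (x|y|z, the axis perpendicular to the section),
    ``index`` (section index), ``r0, c0, r1, c1`` (0-indexed voxel
    endpoints, pixel-center convention), optional ``width`` (odd,
    default 7).
    """
    df = pd.read_csv(path)
    required = {"plane", "index", "r0", "c0", "r1", "c1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe file {path} missing columns: {sorted(missing)}")
    if "width" not in df.columns:
        df["width"] = 7
    return df


def probe_from_row(row) -> LineProbe:
    return LineProbe(
        p0=(float(row.r0), float(row.c0)),
        p1=(float(row.r1), float(row.c1)),
        width=int(row.width),
    )


def write_measurements(
    results: list[DiameterResult],
    path: str | Path,
    labels: list[str] | None = None,
    summary: bool = True,
) -> pd.DataFrame:
    """Write diameter results as CSV (µm columns), optionally with a summary row."""
    if not results:
        raise ValueError("no measurements to write")
    labels = labels if labels is not None else [f"m{i + 1}" for i in range(len(results))]
    df = pd.DataFrame(
        {
            "label": labels,
            "d_um": [r.d for r in results],
            "d_fwhm_um": [r.d_fwhm for r in results],
            "d_edge_um": [r.d_edge for r in results],
        }
    )
    if summary:
        row = {"label": "mean"}
        sd_row = {"label": "sd"}
        for col in ("d_um", "d_fwhm_um", "d_edge_um"):
            stats = summarize(df[col].tolist())
            row[col] = stats.mean
            sd_row[col] = stats.sd
        df = pd.concat([df, pd.DataFrame([row, sd_row])], ignore_index=True)
    df.to_csv(Path(path), index=False)
    return df


def write_branches(
    branches: list[SkeletonBranch], path: str | Path, summary: bool = True
) -> pd.DataFrame:
    """Write per-branch tortuosity CSV, optionally with a mean/SD summary."""
    if not branches:
        raise ValueError("no branches to write")
    df = pd.DataFrame(
        {
            "branch": [f"b{i + 1}" for i in range(len(branches))],
            "path_length_um": [b.path_length for b in branches],
            "chord_length_um": [b.chord_length for b in branches],
            "tortuosity": [b.tortuosity for b in branches],
        }
    )
    if summary:
        finite = df[np.isfinite(df["tortuosity"])]
        if len(finite):
            stats = summarize(finite["tortuosity"].tolist())
            df = pd.concat(
                [
                    df,
                    pd.DataFrame(
                        [
                            {"branch": "mean", "tortuosity": stats.mean},
                            {"branch": "sd", "tortuosity": stats.sd},
                        ]
                    ),
                ],
                ignore_index=True,
            )
    df.to_csv(Path(path), index=False)
    return df
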