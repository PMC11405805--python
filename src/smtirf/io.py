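"""File I/O helpers: TIFF stacks, dwell lists, fit tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

__all__ = ["write_movie", "read_movie", "read_dwell_csv", "write_dwell_csv"]


def write_movie(stack: np.ndarray, path) -> None:
    """Write an image stack as multi-page 16-bit TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_movie(path) -> np.ndarray:
    """Read a multi-page TIFF stack as (n_frames, H, W)."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def read_dwell_csv(path) -> np.ndarray:
    """Read a one-column CSV of dwell times in seconds."""
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(dtype=float)


def write_dwell_csv(dwells, path) -> None:
    pd.DataFrame({"dwell_s": np.asarray(dwells, dtype=float)}).to_csv(
        path, index=False
    )
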