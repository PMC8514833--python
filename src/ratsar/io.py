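"""File-format plumbing: frame sequences, CSV tables, key = value configs."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd


def write_frames(frames: Sequence[np.ndarray], out_dir: str | Path,
                 prefix: str = "frame") -> list[Path]:
    """Write frames as numbered PNGs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(frames):
        p = out / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, f)
        paths.append(p)
    return paths


def read_frames(path: str | Path) -> list[np.ndarray]:
    """Read a directory of numbered PNG/TIFF frames or a multi-page TIFF."""
    p = Path(path)
    if p.is_dir():
        files = sorted(q for q in p.iterdir()
                       if q.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {p}")
        return [np.asarray(iio.imread(q)) for q in files]
    if p.suffix.lower() in (".tif", ".tiff"):
        stack = np.asarray(iio.imread(p))
        return [stack[i] for i in range(stack.shape[0])]
    raise ValueError(f"unsupported frame source: {p}")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(p, index=False)
    return p


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_keyvalue(path: str | Path) -> dict[str, str]:
    """Parse a plain-text ``key = value`` config; '#' starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def dump_keyvalue(values: dict, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text("".join(f"{k} = {v}\n" for k, v in values.items()))
    return p
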