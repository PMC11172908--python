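"""Fixed-width genome tiling.

The whole pipeline works on a genome partitioned into fixed-width windows
(default 800 bp, the resolution of read-depth CNV detection). The
:class:`WindowedGenome` is the coordinate authority: depth matrices, copy
number matrices, CNV calls and CNVRs all reference its windows. Coordinates
are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError

DEFAULT_WINDOW_SIZE = 800

WINDOW_COLUMNS = ["chrom", "start", "end", "gc", "masked"]


@dataclass
class WindowedGenome:
    """An ordered tiling of one or more chromosomes into fixed-width windows.

    Attributes
    ----------
    windows:
        DataFrame with columns ``chrom, start, end, gc, masked``; windows tile
        each chromosome left to right without overlap. Only the final window of
        a chromosome may be shorter than ``window_size``.
    chrom_lengths:
        Mapping chromosome -> length in bp.
    window_size:
        Nominal window width in bp.
    """

    windows: pd.DataFrame
    chrom_lengths: dict[str, int]
    window_size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self) -> None:
        self.windows = self.windows.reset_index(drop=True)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def gc(self) -> np.ndarray:
        return self.windows["gc"].to_numpy(dtype=float)

    @property
    def masked(self) -> np.ndarray:
        return self.windows["masked"].to_numpy(dtype=bool)

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.masked

    def window_keys(self) -> list[str]:
        """Column keys of the form ``chrom:start-end`` (0-based half-open)."""
        w = self.windows
        return [f"{c}:{s}-{e}" for c, s, e in zip(w["chrom"], w["start"], w["end"])]

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous window-index range of one chromosome."""
        idx = np.flatnonzero((self.windows["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def window_range(self, chrom: str, start: int, end: int) -> slice:
        """Window indices whose span lies within [start, end) on ``chrom``.

        ``start``/``end`` must align to window boundaries (the final short
        window of a chromosome counts as a boundary).
        """
        sl = self.chrom_slice(chrom)
        starts = self.windows["start"].to_numpy()[sl]
        ends = self.windows["end"].to_numpy()[sl]
        inside = np.flatnonzero((starts >= start) & (ends <= end))
        if inside.size == 0:
            raise KeyError(f"{chrom}:{start}-{end} covers no window")
        return slice(sl.start + int(inside[0]), sl.start + int(inside[-1]) + 1)


def _smooth_gc(n: int, rng: np.random.Generator) -> np.ndarray:
    """A smooth spatial GC profile strictly inside (0.2, 0.8).

    White noise smoothed with a Gaussian kernel, rescaled and squashed with
    tanh so neighbouring windows share similar GC (as real isochores do).
    """
    z = rng.normal(size=n)
    if n > 1:
        z = gaussian_filter1d(z, sigma=max(2.0, n / 100.0), mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    return 0.5 + 0.29 * np.tanh(z)


def make_windowed_genome(
    chrom_lengths: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    gc_profile_seed: int = 0,
    mask_fraction: float = 0.0,
) -> WindowedGenome:
    """Tile chromosomes into fixed-width windows with a smooth GC profile.

    Parameters
    ----------
    chrom_lengths:
        Chromosome lengths in bp; every length must be >= ``window_size``.
    window_size:
        Window width in bp (default 800).
    gc_profile_seed:
        Seed for the GC spatial process and the window mask.
    mask_fraction:
        Fraction of windows flagged as low-complexity/unalignable; masked
        windows are carried through matrices but excluded from all statistics.
    """
    if window_size <= 0:
        raise ConfigurationError(f"window_size must be positive, got {window_size}")
    if not chrom_lengths:
        raise ConfigurationError("chrom_lengths is empty")
    if not 0.0 <= mask_fraction < 1.0:
        raise ConfigurationError(f"mask_fraction must be in [0, 1), got {mask_fraction}")
    for chrom, length in chrom_lengths.items():
        if length < window_size:
            raise ConfigurationError(
                f"chromosome {chrom} length {length} < window_size {window_size}"
            )

    rng = np.random.default_rng(gc_profile_seed)
    frames = []
    for chrom in chrom_lengths:
        length = int(chrom_lengths[chrom])
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        gc = _smooth_gc(len(starts), rng)
        masked = rng.random(len(starts)) < mask_fraction
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "gc": gc, "masked": masked}
            )
        )
    windows = pd.concat(frames, ignore_index=True)
    return WindowedGenome(
        windows=windows,
        chrom_lengths={c: int(v) for c, v in chrom_lengths.items()},
        window_size=int(window_size),
    )


def write_windows(genome: WindowedGenome, path) -> None:
    """Write windows as BED-like TSV: chrom, start, end, gc, masked."""
    out = genome.windows.copy()
    out["masked"] = out["masked"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_windows(path) -> WindowedGenome:
    """Read a windows TSV written by :func:`write_windows`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"windows file missing columns: {missing}")
    df["masked"] = df["masked"].astype(bool)
    chrom_lengths = df.groupby("chrom", sort=False)["end"].max().to_dict()
    sizes = (df["end"] - df["start"]).to_numpy()
    window_size = int(np.max(sizes))
    return WindowedGenome(windows=df, chrom_lengths=chrom_lengths, window_size=window_size)
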