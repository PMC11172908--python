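"""Samples x windows matrices: raw/corrected read depth and absolute copy number.

Both containers keep a reference to the :class:`~cnvpopscan.genome.WindowedGenome`
they are laid out on; masked windows are carried as columns but flagged, and all
downstream statistics ignore them. Copy number matrices hold NaN sentinels in
masked columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .genome import WindowedGenome, read_windows


@dataclass
class DepthMatrix:
    """Per-window read counts (or corrected depths) for a cohort."""

    samples: list[str]
    values: np.ndarray  # (n_samples, n_windows), nonnegative
    genome: WindowedGenome

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("depth values must be 2-D (samples x windows)")
        if self.values.shape != (len(self.samples), self.genome.n_windows):
            raise InputError(
                f"depth shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {self.genome.n_windows} windows"
            )
        if np.any(self.values < 0):
            raise InputError("depth values must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.samples, name="sample"),
            columns=self.genome.window_keys(),
        )


@dataclass
class CopyNumberMatrix:
    """Absolute copy numbers (diploid baseline 2); NaN in masked windows."""

    samples: list[str]
    cn: np.ndarray  # (n_samples, n_windows)
    genome: WindowedGenome

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=float)
        if self.cn.shape != (len(self.samples), self.genome.n_windows):
            raise InputError(
                f"cn shape {self.cn.shape} does not match "
                f"{len(self.samples)} samples x {self.genome.n_windows} windows"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise InputError(f"unknown sample {sample!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cn, index=pd.Index(self.samples, name="sample"),
            columns=self.genome.window_keys(),
        )


def write_depth(depth: DepthMatrix, path) -> None:
    """TSV with first column ``sample`` and one column per window (chrom:start-end)."""
    depth.to_frame().to_csv(path, sep="\t")


def read_depth(path, genome: WindowedGenome) -> DepthMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    expected = genome.window_keys()
    if list(df.columns) != expected:
        raise ConfigurationError("depth matrix columns do not match the windowed genome")
    return DepthMatrix(samples=[str(s) for s in df.index], values=df.to_numpy(), genome=genome)


def write_copy_number(cn: CopyNumberMatrix, path) -> None:
    cn.to_frame().to_csv(path, sep="\t")


def read_copy_number(path, genome: WindowedGenome) -> CopyNumberMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    if list(df.columns) != genome.window_keys():
        raise ConfigurationError("copy-number matrix columns do not match the windowed genome")
    return CopyNumberMatrix(samples=[str(s) for s in df.index], cn=df.to_numpy(), genome=genome)
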