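"""Read, validate, normalize, and write structural connectomes and PSD tables.

The anatomical substrate is a weighted structural connectivity matrix ``C``
(region-to-region fiber counts or densities, arbitrary units) plus a fiber
distance matrix ``D`` in millimetres, both over the same labelled
parcellation.  Regional power spectra are stored as regions x frequency
tables, either in raw power or in dB.

All file formats are plain delimited text (comma or tab, sniffed from the
first line); the design envelope is dense matrices up to a few hundred
regions (the reference atlas has 68 cortical regions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SYM_ATOL = 1e-8


def _sniff_delimiter(path: Path) -> str:
    first = path.open().readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _symmetrize(M: np.ndarray, name: str) -> np.ndarray:
    """(M + M^T)/2 with a warning if the asymmetry is non-trivial.

    Diffusion-MRI connectome pipelines emit nominally symmetric matrices with
    small numeric asymmetries; averaging is a projection onto the symmetric
    subspace (applying it twice equals applying it once).
    """
    if not np.allclose(M, M.T, atol=_SYM_ATOL, rtol=0.0):
        logger.warning("%s matrix is asymmetric; symmetrizing as (M + M^T)/2", name)
    return (M + M.T) / 2.0


@dataclass
class ConnectomeGraph:
    """Labelled structural connectome: weights ``C`` and distances ``D`` (mm)."""

    region_labels: list[str]
    C: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.region_labels)
        for name, M in (("C", self.C), ("D", self.D)):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square, got shape {M.shape}")
            if M.shape[0] != n:
                raise ValueError(
                    f"{name} has {M.shape[0]} rows but {n} region labels"
                )
            if not np.all(np.isfinite(M)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(M < 0):
                raise ValueError(f"{name} contains negative entries")
        self.C = _symmetrize(self.C, "C")
        self.D = _symmetrize(self.D, "D")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("D must have a zero diagonal")
        degrees = self.C.sum(axis=1)
        if np.any(degrees == 0):
            bad = [self.region_labels[i] for i in np.flatnonzero(degrees == 0)]
            raise ValueError(f"isolated node(s) with zero-sum C row: {bad}")
        off = self.D[~np.eye(self.n_regions, dtype=bool)]
        if np.any(off == 0):
            logger.warning(
                "D has %d zero off-diagonal entries (no measured fiber length); "
                "treated as zero conduction delay",
                int(np.sum(off == 0)) // 2,
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def degrees(self) -> np.ndarray:
        """Row sums of the real weight matrix."""
        return self.C.sum(axis=1)


@dataclass
class RegionalPSD:
    """Regions x frequency power table, in raw power or dB."""

    region_labels: list[str]
    frequencies_hz: np.ndarray
    values: np.ndarray
    scale: str = "raw_power"  # "raw_power" | "dB"

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("raw_power", "dB"):
            raise ValueError(f"unknown scale {self.scale!r}")
        f = self.frequencies_hz
        if f.ndim != 1 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies not increasing")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if self.values.shape != (len(self.region_labels), f.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.region_labels)} regions x {f.size} frequencies"
            )
        if np.any(np.isnan(self.values)):
            raise ValueError("PSD contains NaN entries")
        if self.scale == "raw_power" and np.any(self.values < 0):
            raise ValueError("raw power must be nonnegative")
        if self.scale == "dB" and not np.all(np.isfinite(self.values)):
            raise ValueError("dB PSD must be finite")


@dataclass
class SpatialProfile:
    """Per-region nonnegative scalar profile (e.g., alpha-band raw power, power*Hz)."""

    region_labels: list[str]
    values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_labels),):
            raise ValueError("profile length does not match labels")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile entries must be finite and >= 0")


def _read_matrix(path: Path) -> np.ndarray:
    M = pd.read_csv(path, sep=_sniff_delimiter(path), header=None).to_numpy(dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is not square, shape {M.shape}")
    return M


def read_connectome(
    weights_path: str | Path,
    distances_path: str | Path,
    labels_path: str | Path | None = None,
) -> ConnectomeGraph:
    """Read C and D matrices (delimited text) plus optional one-per-line labels.

    Missing labels are auto-generated as R001, R002, ...  Asymmetric inputs
    are symmetrized with a warning; validation errors raise ``ValueError``.
    """
    C = _read_matrix(Path(weights_path))
    D = _read_matrix(Path(distances_path))
    if C.shape != D.shape:
        raise ValueError(f"C shape {C.shape} != D shape {D.shape}")
    if labels_path is not None:
        labels = [
            line.strip()
            for line in Path(labels_path).read_text().splitlines()
            if line.strip()
        ]
    else:
        labels = [f"R{i + 1:03d}" for i in range(C.shape[0])]
    return ConnectomeGraph(region_labels=labels, C=C, D=D)


def write_connectome(
    graph: ConnectomeGraph,
    weights_path: str | Path,
    distances_path: str | Path,
    labels_path: str | Path | None = None,
    sep: str = ",",
) -> None:
    fmt = dict(sep=sep, header=False, index=False, float_format="%.17g")
    pd.DataFrame(graph.C).to_csv(weights_path, **fmt)
    pd.DataFrame(graph.D).to_csv(distances_path, **fmt)
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(graph.region_labels) + "\n")


def row_degree_normalize(C: np.ndarray) -> np.ndarray:
    """Divide each row of a nonnegative square matrix by its row sum.

    Every row of the output sums to 1; zero-sum rows are rejected.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(C < 0):
        raise ValueError("matrix must be nonnegative")
    sums = C.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError("zero-sum row; cannot row-normalize")
    return C / sums[:, None]


def read_psd(path: str | Path, scale: str = "dB") -> RegionalPSD:
    """Read a PSD table: first column region label, header row of Hz."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    labels = df.iloc[:, 0].astype(str).tolist()
    freqs = np.array([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return RegionalPSD(labels, freqs, values, scale=scale)


def write_psd(psd: RegionalPSD, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(psd.values, columns=[f"{f:.17g}" for f in psd.frequencies_hz])
    df.insert(0, "region", psd.region_labels)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_profile(path: str | Path) -> SpatialProfile:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    return SpatialProfile(
        df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1].to_numpy(dtype=float)
    )


def write_profile(profile: SpatialProfile, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(
        {"region": profile.region_labels, "band_power": profile.values}
    ).to_csv(path, sep=sep, index=False, float_format="%.17g")
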