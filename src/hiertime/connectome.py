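"""Connectome container and I/O.

Orientation convention used everywhere in this package: matrices are
target-row x source-column, i.e. ``fln[i, j]`` is the fraction of labeled
neurons (FLN) of the projection from source area ``j`` into target area
``i``.  This matches the network equations, where the long-range input to
area *i* is ``sum_j FLN_ij * rE_j``.

FLN matrices from retrograde tracing are conventionally normalized per
target (each row sums to 1 over all sources); the loader can apply or skip
that normalization and the container records which was done.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "load_connectome",
    "write_connectome",
    "shuffle_fln",
    "remove_feedback",
]


class ConnectomeError(ValueError):
    """Raised on invalid or inconsistent connectome data."""


@dataclass
class Connectome:
    """Weighted directed inter-areal connectome.

    Attributes
    ----------
    areas:
        Ordered area identifiers; all matrices share this order.
    fln:
        N x N nonnegative FLN matrix, target-row x source-column, zero
        diagonal.
    sln:
        N x N fraction of supragranular labeled neurons, in [0, 1]; SLN >= 0.5
        conventionally marks a feedforward projection, SLN < 0.5 feedback.
    dist:
        N x N symmetric inter-areal distances in mm, zero diagonal.
    hierarchy_exp:
        Optional per-area structural hierarchy value.
    spines:
        Optional per-area dendritic spine counts.
    subnet:
        Optional per-area subnetwork labels.
    positions:
        Optional per-area 3-D coordinates in mm.
    row_normalized:
        Whether fln rows were rescaled to sum to 1 at load/construction.
    zero_rows:
        Indices of areas whose fln row sums to zero (no inputs); allowed
        after manipulations such as feedback deletion, flagged not rejected.
    """

    areas: list[str]
    fln: np.ndarray
    sln: np.ndarray
    dist: np.ndarray
    hierarchy_exp: np.ndarray | None = None
    spines: np.ndarray | None = None
    subnet: list[str] | None = None
    positions: np.ndarray | None = None
    row_normalized: bool = False
    zero_rows: list[int] = field(default_factory=list)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def __post_init__(self) -> None:
        self.areas = list(self.areas)
        self.fln = np.asarray(self.fln, dtype=float)
        self.sln = np.asarray(self.sln, dtype=float)
        self.dist = np.asarray(self.dist, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.n_areas
        for name, mat in (("fln", self.fln), ("sln", self.sln), ("dist", self.dist)):
            if mat.shape != (n, n):
                raise ConnectomeError(
                    f"{name} has shape {mat.shape}, expected ({n}, {n})"
                )
            if not np.all(np.isfinite(mat)):
                raise ConnectomeError(f"{name} contains non-finite entries")
        if np.any(self.fln < 0):
            raise ConnectomeError("negative FLN entries")
        if np.any(np.abs(np.diag(self.fln)) > 0):
            raise ConnectomeError("nonzero FLN diagonal")
        if np.any(self.sln < -1e-12) or np.any(self.sln > 1 + 1e-12):
            raise ConnectomeError("SLN entries outside [0, 1]")
        if np.any(self.dist < 0):
            raise ConnectomeError("negative distance entries")
        if not np.allclose(self.dist, self.dist.T, atol=1e-9):
            raise ConnectomeError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.dist)) > 1e-12):
            raise ConnectomeError("distance diagonal is not zero")
        row_sums = self.fln.sum(axis=1)
        self.zero_rows = [int(i) for i in np.flatnonzero(row_sums == 0)]
        if self.row_normalized:
            nonzero = row_sums > 0
            if not np.allclose(row_sums[nonzero], 1.0, atol=1e-9):
                raise ConnectomeError(
                    "flagged row-normalized but fln rows do not sum to 1"
                )

    def copy(self) -> "Connectome":
        return replace(
            self,
            areas=list(self.areas),
            fln=self.fln.copy(),
            sln=self.sln.copy(),
            dist=self.dist.copy(),
            hierarchy_exp=None if self.hierarchy_exp is None else self.hierarchy_exp.copy(),
            spines=None if self.spines is None else self.spines.copy(),
            subnet=None if self.subnet is None else list(self.subnet),
            positions=None if self.positions is None else self.positions.copy(),
        )


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a delimited matrix with an area-name header row and first column.

    Delimiter (comma/tab/semicolon/whitespace) is sniffed from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    header = text.splitlines()[0] if text else ""
    if "\t" in header:
        sep: str = "\t"
    elif "," in header:
        sep = ","
    elif ";" in header:
        sep = ";"
    else:
        sep = r"\s+"
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def _aligned(df: pd.DataFrame, areas: list[str], what: str) -> np.ndarray:
    missing = [a for a in areas if a not in df.index or a not in df.columns]
    if missing:
        raise ConnectomeError(f"{what} file is missing areas: {missing}")
    extra = [a for a in df.index if a not in areas]
    if extra:
        raise ConnectomeError(f"{what} file has unknown areas: {extra}")
    return df.loc[areas, areas].to_numpy(dtype=float)


def load_connectome(
    fln_path: str | Path,
    sln_path: str | Path,
    dist_path: str | Path,
    annotations_path: str | Path | None = None,
    normalize_rows: bool = False,
    repair_diagonal: bool = False,
) -> Connectome:
    """Load FLN/SLN/distance matrices (plus optional annotations) from text.

    Area ordering is taken from the FLN file; the SLN and distance files may
    list the same areas in any order and are reindexed to match.  With
    ``normalize_rows`` each nonzero FLN row is rescaled to sum to 1.
    ``repair_diagonal`` zeroes a nonzero FLN diagonal instead of erroring.
    """
    fln_df = _read_matrix(fln_path)
    areas = [str(a) for a in fln_df.index]
    if list(fln_df.columns) != areas:
        # allow column order to be a permutation of the row order
        fln = _aligned(fln_df, areas, "FLN")
    else:
        fln = fln_df.to_numpy(dtype=float)
    sln = _aligned(_read_matrix(sln_path), areas, "SLN")
    dist = _aligned(_read_matrix(dist_path), areas, "distance")

    if np.any(fln < 0):
        raise ConnectomeError("negative FLN entry in input file")
    if np.any(dist < 0):
        raise ConnectomeError("negative distance entry in input file")
    if np.any(np.abs(np.diag(fln)) > 0):
        if repair_diagonal:
            np.fill_diagonal(fln, 0.0)
        else:
            raise ConnectomeError(
                "nonzero FLN diagonal (pass repair_diagonal=True to zero it)"
            )

    if normalize_rows:
        sums = fln.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        fln[nz] = fln[nz] / sums[nz]

    hierarchy = spines = positions = None
    subnet = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path)
        ann["area"] = ann["area"].astype(str).str.strip()
        missing = [a for a in areas if a not in set(ann["area"])]
        if missing:
            raise ConnectomeError(f"annotations file is missing areas: {missing}")
        ann = ann.set_index("area").loc[areas]
        if "hierarchy_exp" in ann:
            hierarchy = ann["hierarchy_exp"].to_numpy(dtype=float)
        if "spines" in ann:
            spines = ann["spines"].to_numpy(dtype=float)
        if "subnet" in ann:
            subnet = [str(s) for s in ann["subnet"]]
        if {"x", "y", "z"}.issubset(ann.columns):
            positions = ann[["x", "y", "z"]].to_numpy(dtype=float)

    return Connectome(
        areas=areas,
        fln=fln,
        sln=sln,
        dist=dist,
        hierarchy_exp=hierarchy,
        spines=spines,
        subnet=subnet,
        positions=positions,
        row_normalized=normalize_rows,
    )


def write_connectome(
    conn: Connectome, directory: str | Path, precision: int = 12
) -> dict[str, Path]:
    """Write a connectome back to CSV files (fln.csv, sln.csv, dist.csv,
    annotations.csv when present).  Returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fmt = f"%.{precision}g"
    paths: dict[str, Path] = {}
    for name, mat in (("fln", conn.fln), ("sln", conn.sln), ("dist", conn.dist)):
        df = pd.DataFrame(mat, index=conn.areas, columns=conn.areas)
        p = directory / f"{name}.csv"
        df.to_csv(p, float_format=fmt)
        paths[name] = p
    ann: dict[str, object] = {"area": conn.areas}
    if conn.hierarchy_exp is not None:
        ann["hierarchy_exp"] = conn.hierarchy_exp
    if conn.spines is not None:
        ann["spines"] = conn.spines
    if conn.subnet is not None:
        ann["subnet"] = conn.subnet
    if conn.positions is not None:
        ann["x"], ann["y"], ann["z"] = conn.positions.T
    if len(ann) > 1:
        p = directory / "annotations.csv"
        pd.DataFrame(ann).to_csv(p, index=False, float_format=fmt)
        paths["annotations"] = p
    return paths


def shuffle_fln(conn: Connectome, seed: int) -> Connectome:
    """Randomly permute the off-diagonal FLN entries among off-diagonal
    positions (the diagonal is structurally zero and stays zero).

    SLN and distances are untouched; rows are NOT renormalized, so row sums
    generally change.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    out = conn.copy()
    n = out.n_areas
    off = ~np.eye(n, dtype=bool)
    vals = out.fln[off]
    out.fln[off] = rng.permutation(vals)
    out.row_normalized = False
    out.validate()
    return out


def remove_feedback(conn: Connectome, threshold: float = 0.5) -> Connectome:
    """Delete feedback projections: set fln[i, j] = 0 wherever
    sln[i, j] < threshold.

    Remaining rows are deliberately not renormalized, so the total
    long-range drive decreases — deletion is a lesion, not a reweighting.
    """
    if conn.sln is None:
        raise ConnectomeError("SLN matrix required for feedback removal")
    out = conn.copy()
    out.fln[out.sln < threshold] = 0.0
    out.row_normalized = False
    out.validate()
    return out
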