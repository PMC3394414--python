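"""Covariate extraction from coordinate trajectories, and file I/O.

Raw MD output (topology + coordinate files) is reduced to a covariate
matrix of per-residue C-alpha positional fluctuations: each frame is
optionally superposed onto a reference by least-squares rigid-body fitting
(Kabsch), then the per-atom deviation from the reference is recorded either
as a scalar Euclidean displacement per atom (``magnitude`` mode, the
default — one variable per residue) or as signed x/y/z components (``xyz``
mode).  Trajectory parsing is delegated to MDAnalysis behind a narrow
adapter, so the modelling code never touches format internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import CovariateMatrix

__all__ = [
    "CoordinateTrajectory",
    "FluctuationSpec",
    "trajectory_adapter",
    "superpose",
    "extract_fluctuations",
    "load_covariates",
    "write_covariates",
]


@dataclass
class CoordinateTrajectory:
    """(t, m, 3) coordinates in Angstrom with per-atom labels."""

    coordinates: np.ndarray
    atom_labels: tuple[str, ...]
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if len(self.atom_labels) != self.coordinates.shape[1]:
            raise ValueError("atom label count must match atom count")
        self.atom_labels = tuple(self.atom_labels)

    @property
    def t(self) -> int:
        return self.coordinates.shape[0]

    @property
    def m(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class FluctuationSpec:
    """How to turn coordinates into covariates.

    reference: ``"first_frame"`` or an explicit (m, 3) array.
    superpose: remove rigid-body translation+rotation per frame (default
    True — without it global tumbling dominates the fluctuations).
    mode: ``"magnitude"`` (one variable per atom) or ``"xyz"`` (three).
    """

    reference: str | np.ndarray = "first_frame"
    superpose: bool = True
    mode: str = "magnitude"

    def __post_init__(self):
        if self.mode not in ("magnitude", "xyz"):
            raise ValueError("mode must be 'magnitude' or 'xyz'")


def trajectory_adapter(
    topology: str | Path,
    trajectory: str | Path | None = None,
    atom_selection: str = "name CA",
) -> CoordinateTrajectory:
    """Read a trajectory through MDAnalysis and return selected-atom coordinates.

    ``topology`` is a structure file (PDB, GRO, PSF, ...); ``trajectory``
    an optional coordinate file (DCD, XTC, multi-model PDB, ...).  The
    default selection keeps one C-alpha per residue.  Atom labels are
    ``<resname><resid>`` with 1-based residue ids from the topology.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError("trajectory reading requires MDAnalysis") from exc

    topology = Path(topology)
    if not topology.exists():
        raise FileNotFoundError(f"topology file not found: {topology}")
    args = [str(topology)]
    if trajectory is not None:
        trajectory = Path(trajectory)
        if not trajectory.exists():
            raise FileNotFoundError(f"trajectory file not found: {trajectory}")
        args.append(str(trajectory))
    try:
        universe = mda.Universe(*args)
    except (ValueError, OSError) as exc:
        raise ValueError(
            f"could not parse {args}; supported formats include PDB, GRO, DCD, XTC"
        ) from exc
    atoms = universe.select_atoms(atom_selection)
    if len(atoms) == 0:
        raise ValueError(f"atom selection {atom_selection!r} matched no atoms")
    frames, times = [], []
    import warnings

    with warnings.catch_warnings():
        # formats without time metadata (e.g. multi-model PDB) default to
        # 1 ps/frame; the covariates do not depend on absolute times
        warnings.filterwarnings("ignore", message=".*no dt information.*")
        for ts in universe.trajectory:
            frames.append(atoms.positions.copy())
            times.append(ts.time)
    coords = np.asarray(frames, dtype=float)
    labels = tuple(f"{a.resname}{a.resid}" for a in atoms)
    times = np.asarray(times, dtype=float)
    return CoordinateTrajectory(coordinates=coords, atom_labels=labels, frame_times=times)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body superposition (Kabsch) of one frame.

    Returns the mobile coordinates rotated/translated to best fit the
    reference; both are (m, 3).  No mass weighting.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = u @ d @ vt
    return mob_c @ rot + reference.mean(axis=0)


def extract_fluctuations(
    traj: CoordinateTrajectory, spec: FluctuationSpec | None = None
) -> CovariateMatrix:
    """Per-atom positional fluctuations relative to a reference frame.

    magnitude mode: covariate i of frame k is the Euclidean displacement of
    atom i from its reference position (Angstrom), n = m variables.
    xyz mode: signed deviations, n = 3m variables labelled ``<atom>:x`` etc.
    """
    spec = spec or FluctuationSpec()
    if traj.t < 2:
        raise ValueError("need at least 2 frames")
    if isinstance(spec.reference, str):
        if spec.reference != "first_frame":
            raise ValueError("reference must be 'first_frame' or an (m, 3) array")
        ref = traj.coordinates[0]
    else:
        ref = np.asarray(spec.reference, float)
        if ref.shape != (traj.m, 3):
            raise ValueError(
                f"reference shape {ref.shape} does not match atom count {traj.m}"
            )
    deviations = np.empty_like(traj.coordinates)
    for k in range(traj.t):
        frame = traj.coordinates[k]
        if spec.superpose:
            frame = superpose(frame, ref)
        deviations[k] = frame - ref
    if spec.mode == "magnitude":
        values = np.linalg.norm(deviations, axis=2)
        labels = traj.atom_labels
    else:
        values = deviations.reshape(traj.t, 3 * traj.m)
        labels = tuple(
            f"{lab}:{axis}" for lab in traj.atom_labels for axis in ("x", "y", "z")
        )
    return CovariateMatrix(values=values, labels=labels)


def load_covariates(path: str | Path, sep: str | None = None) -> CovariateMatrix:
    """Read a covariate matrix from delimited text.

    First row = covariate labels; one row per frame.  A first column named
    ``frame`` is treated as the frame index.  Raises a parse error naming
    the offending line for ragged or non-numeric rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited text ({exc})") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no frames (header-only file)")
    frame_index = None
    if df.columns[0].strip().lower() == "frame":
        frame_index = df.iloc[:, 0].to_numpy()
        df = df.iloc[:, 1:]
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        for col in bad:
            row = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = int(row[0]) + 2 if len(row) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r}, line {line}")
    return CovariateMatrix(
        values=df.to_numpy(dtype=float),
        labels=tuple(str(c) for c in df.columns),
        frame_index=frame_index,
    )


def write_covariates(data: CovariateMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a covariate matrix as delimited text (full precision round trip)."""
    df = pd.DataFrame(data.values, columns=list(data.labels))
    df.insert(0, "frame", data.frame_index)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
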