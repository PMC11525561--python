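"""Trajectory input/output: multi-model PDB files and precomputed distance tables.

The portable trajectory dialect is multi-model PDB (MODEL/ENDMDL blocks with a
constant atom roster), which any MD post-processing tool can emit.  Users who
compute residue-pair distances externally (e.g. with ``gmx mindist``) can
instead supply a two-column delimited table of (time, distance) via
:func:`read_distance_table`.

Coordinates are held in ångström internally (the PDB convention); distances
are converted to the configured reporting unit (nm by default) downstream.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomKey",
    "TrajectoryFrames",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_distance_table",
    "get_alpha_carbon",
]


@dataclass(frozen=True)
class AtomKey:
    """Identity of one atom in the roster: (chain, residue number, atom name).

    ``residue_name`` rides along for labelling but is not part of the
    identity used when checking roster consistency across frames.
    """

    chain_id: str
    residue_number: int
    atom_name: str
    residue_name: str = ""

    @property
    def identity(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class TrajectoryFrames:
    """An ordered stack of frames sharing one atom roster.

    Attributes
    ----------
    roster : list of AtomKey
        Atom identities, in file order; identical for every frame.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    times : ndarray, shape (n_frames,)
        Frame timestamps in ns, strictly increasing.
    source_label : str
        Free-form provenance label (file name, replicate id, ...).
    """

    roster: list[AtomKey]
    coords: np.ndarray
    times: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.roster):
            raise ValueError(
                f"roster has {len(self.roster)} atoms but coords carry "
                f"{self.coords.shape[1]} per frame"
            )
        if len(self.times) != self.n_frames:
            raise ValueError("times and frames differ in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinate encountered")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_multimodel_pdb(
    path: str | Path,
    dt: float = 1.0,
    times: np.ndarray | None = None,
    source_label: str | None = None,
) -> TrajectoryFrames:
    """Read a multi-model PDB file as a trajectory.

    Each MODEL/ENDMDL block becomes one frame; a file without MODEL records is
    a single frame.  Alternate locations other than blank or "A" are dropped.

    Parameters
    ----------
    path : path
        PDB file, optionally gzip-compressed (``.gz``).
    dt : float
        Frame spacing in ns used when ``times`` is not given; frame ``i`` is
        stamped ``i * dt``.
    times : array-like, optional
        Explicit per-frame timestamps in ns (e.g. from a sidecar file).

    Raises
    ------
    ValueError
        If the atom roster differs between models (names the first offending
        model), or an ATOM/HETATM line has unparseable coordinates (names the
        line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        text = fh.read()

    # Pre-validate coordinate fields so a malformed line is reported by
    # number rather than silently skipped by the lenient parser.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}: unparseable coordinates on line {lineno}: {line!r}"
                ) from None

    structure = gemmi.read_pdb_string(text)
    if len(structure) == 0:
        raise ValueError(f"{path}: no models found")

    rosters: list[list[AtomKey]] = []
    coords: list[np.ndarray] = []
    for model in structure:
        keys: list[AtomKey] = []
        xyz: list[tuple[float, float, float]] = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("\0", "", "A"):
                        continue
                    keys.append(
                        AtomKey(
                            chain_id=chain.name or " ",
                            residue_number=residue.seqid.num,
                            atom_name=atom.name,
                            residue_name=residue.name,
                        )
                    )
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        rosters.append(keys)
        coords.append(np.array(xyz, dtype=float).reshape(-1, 3))

    ref = [k.identity for k in rosters[0]]
    for i, roster in enumerate(rosters[1:], start=2):
        if [k.identity for k in roster] != ref:
            raise ValueError(
                f"{path}: atom roster of model {i} differs from model 1 "
                f"({len(roster)} vs {len(rosters[0])} atoms or mismatched identities)"
            )

    n = len(coords)
    if times is None:
        times = np.arange(n, dtype=float) * dt
    return TrajectoryFrames(
        roster=rosters[0],
        coords=np.stack(coords),
        times=np.asarray(times, dtype=float),
        source_label=source_label if source_label is not None else path.name,
    )


def write_multimodel_pdb(frames: TrajectoryFrames, path: str | Path) -> None:
    """Write frames as a multi-model PDB (fixed 8.3 coordinate columns)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for m in range(frames.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for serial, (key, (x, y, z)) in enumerate(
                zip(frames.roster, frames.coords[m]), start=1
            ):
                name = key.atom_name
                # PDB atom-name column convention: 1-3 char names start in col 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{key.residue_name:>3s} "
                    f"{key.chain_id:1s}{key.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_distance_table(path: str | Path) -> "pd.DataFrame":
    """Read a two-column delimited (time ns, distance) table.

    Returns a DataFrame with columns ``time_ns`` and ``distance`` sorted by
    time, plus a ``unit`` attribute in ``df.attrs`` ("nm" unless the header
    says otherwise, e.g. ``distance_angstrom``).

    A header row is optional; CSV and whitespace/tab delimiters are accepted,
    as is gzip compression.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, distance)")
    df = df.iloc[:, :2]

    unit = "nm"
    first = df.iloc[0]
    header_like = any(
        not _is_number(v) for v in first
    )
    if header_like:
        label = str(first.iloc[1]).lower()
        if "angstrom" in label or label.endswith("_a") or "(a)" in label:
            unit = "angstrom"
        elif "nm" in label:
            unit = "nm"
        df = df.iloc[1:].reset_index(drop=True)

    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 data rows, got {len(df)}")

    out = pd.DataFrame()
    for col, name in zip(df.columns, ("time_ns", "distance")):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + (2 if header_like else 1)
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in row {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + (2 if header_like else 1)
            raise ValueError(f"{path}: missing value in row {row}")
        out[name] = converted.astype(float)
    out = out.sort_values("time_ns", kind="stable").reset_index(drop=True)
    out.attrs["unit"] = unit
    return out


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def get_alpha_carbon(
    frames: TrajectoryFrames,
    residue_number: int,
    chain_id: str | None = None,
    expected_residue_name: str | None = None,
) -> np.ndarray:
    """Per-frame CA coordinates of one residue, shape (n_frames, 3), in Å.

    If ``chain_id`` is omitted the residue number must be unique across
    chains.  A residue-name mismatch against ``expected_residue_name`` is a
    warning only, so non-LCAT systems with different sequences still work.
    """
    hits = [
        i
        for i, key in enumerate(frames.roster)
        if key.atom_name == "CA"
        and key.residue_number == residue_number
        and (chain_id is None or key.chain_id == chain_id)
    ]
    if not hits:
        available = sorted(
            {k.residue_number for k in frames.roster if k.atom_name == "CA"}
        )
        raise KeyError(
            f"residue {residue_number} (CA) not found"
            + (f" in chain {chain_id}" if chain_id else "")
            + f"; CA residues present: {available}"
        )
    if len(hits) > 1:
        chains = sorted({frames.roster[i].chain_id for i in hits})
        raise KeyError(
            f"residue {residue_number} is ambiguous across chains {chains}; "
            "pass chain_id"
        )
    key = frames.roster[hits[0]]
    if expected_residue_name and key.residue_name != expected_residue_name:
        warnings.warn(
            f"residue {residue_number} is {key.residue_name}, "
            f"expected {expected_residue_name}",
            stacklevel=2,
        )
    return frames.coords[:, hits[0], :]
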