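"""Readers and writers for the on-disk formats the pipeline touches.

Supported dialects:

* XVG — GROMACS pull-force output: ``#``/``@`` metadata lines, then
  whitespace-separated numeric rows ``time_ps f1 [f2]`` in kJ/(mol·nm).
* PDB — fixed-column ATOM records (coordinates in Å).
* GRO — fixed-column GROMACS coordinate files (coordinates in nm).
* TSV — tab-separated tables with a header row, written to 6 significant
  digits so that a write/read round trip is value-identical at that precision.

Everything is converted to internal units (nm, ns, pN) on the way in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ANGSTROM_TO_NM, KJ_PER_MOL_NM_TO_PN, PS_TO_NS

__all__ = [
    "ForceTrace",
    "StructureModel",
    "ParseError",
    "read_force_xvg",
    "read_structure",
    "read_trajectory",
    "write_tsv",
    "read_tsv",
]


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


@dataclass
class ForceTrace:
    """Two-channel pull-force time series from one force-probe trajectory.

    ``f1``/``f2`` are the spring forces at the two pulled termini; they
    carry opposite signs for an antisymmetric pull.  Elongation is the
    inter-spring distance ``v_pull * time``.
    """

    time: np.ndarray  # ns, strictly increasing
    f1: np.ndarray  # pN
    f2: np.ndarray  # pN
    v_pull: float  # nm/ns
    k_spring: float  # pN/nm
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        if self.time.size == 0:
            raise ParseError("empty force trace")
        if len(self.f1) != len(self.time) or len(self.f2) != len(self.time):
            raise ValueError("f1/f2 length must match time")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.v_pull <= 0:
            raise ValueError("v_pull must be positive")
        if self.k_spring <= 0:
            raise ValueError("k_spring must be positive")

    @property
    def elongation(self) -> np.ndarray:
        """Inter-spring distance v·t in nm."""
        return self.v_pull * self.time

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class StructureModel:
    """A single structure frame: flat atom table with coordinates in nm."""

    names: list[str]
    elements: list[str]
    resids: np.ndarray
    resnames: list[str]
    chains: list[str]
    coords: np.ndarray  # (n_atoms, 3) nm
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.resids = np.asarray(self.resids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or (self.n_atoms and self.coords.shape[1] != 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if self.n_atoms and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def subset(self, indices: np.ndarray) -> "StructureModel":
        idx = np.asarray(indices, dtype=int)
        return StructureModel(
            names=[self.names[i] for i in idx],
            elements=[self.elements[i] for i in idx],
            resids=self.resids[idx],
            resnames=[self.resnames[i] for i in idx],
            chains=[self.chains[i] for i in idx],
            coords=self.coords[idx],
            frame_id=self.frame_id,
        )

    def residue_mask(self, chain: str, first: int, last: int) -> np.ndarray:
        """Boolean mask of atoms in ``chain`` with first ≤ resid ≤ last."""
        in_chain = np.array([c == chain for c in self.chains])
        return in_chain & (self.resids >= first) & (self.resids <= last)

    def ca_coord(self, chain: str, resid: int) -> np.ndarray:
        """Coordinate of the unique Cα of (chain, resid); error otherwise."""
        mask = self.residue_mask(chain, resid, resid) & np.array(
            [n.strip() == "CA" for n in self.names]
        )
        n = int(mask.sum())
        if n != 1:
            raise ValueError(
                f"frame {self.frame_id}: expected exactly one CA for "
                f"{chain}:{resid}, found {n}"
            )
        return self.coords[mask][0]


def read_force_xvg(
    path: str | Path,
    v_pull: float,
    k_spring: float,
    unit_mode: str = "gmx",
    label: str = "",
) -> ForceTrace:
    """Read a GROMACS-style pull-force XVG file.

    Parameters
    ----------
    path
        Text file; lines starting with ``#`` or ``@`` are metadata, the rest
        are 2- or 3-column numeric rows (time_ps, f1[, f2]).
    v_pull, k_spring
        Pull velocity (nm/ns) and spring stiffness (pN/nm) metadata attached
        to the trace.
    unit_mode
        ``"gmx"``: times in ps and forces in kJ/(mol·nm), converted to ns/pN.
        ``"pN"``: times in ns, forces in pN, passed through verbatim.

    Two-column files describe a single spring; the second channel is
    synthesized as the negative of the first, so the combined force
    ``(f1 − f2)/2`` reduces to ``f1``.
    """
    if unit_mode not in ("gmx", "pN"):
        raise ValueError(f"unknown unit_mode {unit_mode!r}")
    times, forces1, forces2 = [], [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#@":
                continue
            parts = stripped.split()
            if len(parts) not in (2, 3):
                raise ParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric line") from exc
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ParseError(f"{path}:{lineno}: inconsistent column count")
            times.append(values[0])
            forces1.append(values[1])
            forces2.append(values[2] if len(values) == 3 else -values[1])
    if not times:
        raise ParseError(f"{path}: no data rows (empty trace)")
    time = np.asarray(times)
    f1 = np.asarray(forces1)
    f2 = np.asarray(forces2)
    if unit_mode == "gmx":
        time = time * PS_TO_NS
        f1 = f1 * KJ_PER_MOL_NM_TO_PN
        f2 = f2 * KJ_PER_MOL_NM_TO_PN
    if np.any(np.diff(time) <= 0):
        raise ParseError(f"{path}: time column not strictly increasing")
    return ForceTrace(time=time, f1=f1, f2=f2, v_pull=v_pull, k_spring=k_spring,
                      label=label or str(path))


_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE"}


def _infer_element(name: str) -> str:
    """Guess an element symbol from a PDB/GRO atom name.

    Protein atom names start with the element letter (possibly preceded by a
    digit for hydrogens like ``1HB``).  Two-letter elements are only returned
    for unambiguous ion-style names; ``CA``/``CB``… are carbons.
    """
    stripped = name.strip()
    alpha = "".join(ch for ch in stripped if ch.isalpha()).upper()
    if not alpha:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    if alpha in _TWO_LETTER_ELEMENTS:
        return alpha.capitalize()
    return alpha[0]


def _read_pdb_models(path: Path) -> list[StructureModel]:
    frames: list[dict] = []
    current = _empty_atom_lists()
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                if saw_model and current["names"]:
                    frames.append(current)
                    current = _empty_atom_lists()
                saw_model = True
            elif record == "ENDMDL":
                frames.append(current)
                current = _empty_atom_lists()
            elif record == "ATOM":
                try:
                    name = line[12:16]
                    resname = line[17:20].strip()
                    chain = line[21].strip() or "A"
                    resid = int(line[22:26])
                    xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: bad ATOM record") from exc
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = _infer_element(name)
                current["names"].append(name.strip())
                current["elements"].append(element.capitalize())
                current["resids"].append(resid)
                current["resnames"].append(resname)
                current["chains"].append(chain)
                current["coords"].append([c * ANGSTROM_TO_NM for c in xyz])
    if current["names"] or not frames:
        frames.append(current)
    models = []
    for i, fr in enumerate(frames):
        coords = np.asarray(fr["coords"], dtype=float).reshape(-1, 3)
        models.append(
            StructureModel(fr["names"], fr["elements"], np.asarray(fr["resids"], int),
                           fr["resnames"], fr["chains"], coords, frame_id=i)
        )
    return models


def _empty_atom_lists() -> dict:
    return {"names": [], "elements": [], "resids": [], "resnames": [],
            "chains": [], "coords": []}


def _read_gro(path: Path) -> StructureModel:
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 2:
        raise ParseError(f"{path}: truncated GRO file")
    try:
        natoms = int(lines[1])
    except ValueError as exc:
        raise ParseError(f"{path}:2: bad atom count") from exc
    if len(lines) < 2 + natoms:
        raise ParseError(f"{path}: fewer atom lines than declared")
    data = _empty_atom_lists()
    for i in range(natoms):
        line = lines[2 + i]
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            xyz = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{3 + i}: bad GRO atom line") from exc
        data["names"].append(name)
        data["elements"].append(_infer_element(name).capitalize())
        data["resids"].append(resid)
        data["resnames"].append(resname)
        data["chains"].append("A")  # GRO carries no chain identifiers
        data["coords"].append(xyz)
    return StructureModel(data["names"], data["elements"],
                          np.asarray(data["resids"], int), data["resnames"],
                          data["chains"], np.asarray(data["coords"]))


def read_structure(path: str | Path) -> StructureModel:
    """Read a single structure frame from a PDB (Å) or GRO (nm) file.

    Coordinates are returned in nm.  Only ATOM records are read from PDB
    files; a file with no ATOM records yields an empty model with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        model = _read_pdb_models(path)[0]
    elif suffix == ".gro":
        model = _read_gro(path)
    else:
        raise ParseError(f"unknown structure extension {suffix!r} for {path}")
    if model.n_atoms == 0:
        warnings.warn(f"{path}: no ATOM records — empty model", stacklevel=2)
    return model


def read_trajectory(paths: Sequence[str | Path]) -> list[StructureModel]:
    """Read an ordered sequence of structure files as trajectory frames.

    Multi-MODEL PDB files contribute one frame per MODEL.  Frames are
    renumbered 0..n−1; a change in atom count between frames is an error.
    """
    frames: list[StructureModel] = []
    for path in paths:
        path = Path(path)
        if path.suffix.lower() in (".pdb", ".ent"):
            frames.extend(_read_pdb_models(path))
        else:
            frames.append(read_structure(path))
    if not frames:
        raise ParseError("no frames read")
    n0 = frames[0].n_atoms
    for i, frame in enumerate(frames):
        if frame.n_atoms != n0:
            raise ParseError(
                f"atom count mismatch: frame {i} has {frame.n_atoms}, expected {n0}"
            )
        frame.frame_id = i
    return frames


def write_tsv(table: pd.DataFrame, path: str | Path, allow_empty: bool = False) -> None:
    """Write a table as TSV with a header row, floats to 6 significant digits."""
    if len(table) == 0 and not allow_empty:
        raise ValueError("refusing to write empty table (pass allow_empty=True)")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV table written by :func:`write_tsv`."""
    return pd.read_csv(path, sep="\t")
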