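"""Coordinate sets, conformational ensembles, and PDB / weights text I/O.

PDB files are parsed with biotite (fixed-column dialect).  Altloc 'A' is kept
when alternates are present; insertion codes are rejected because the target
depositions are simple NMR-style multi-model files.  Role tags (belt /
lipid-head / lipid-tail / tag) are assigned from residue names through a
configurable map so that downstream contrast assignment and selections work on
roles, not raw residue names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

#: residue-name -> role map used when reading foreign coordinate files.
DEFAULT_ROLE_MAP = {
    "MSP": "belt",
    "BLT": "belt",
    "PHO": "lipid-head",
    "HEA": "lipid-head",
    "TAI": "lipid-tail",
    "TAG": "tag",
    "DMP": "lipid-tail",
}
#: roles a particle may carry.
ROLES = ("belt", "lipid-head", "lipid-tail", "tag", "other")


class ModelNotFoundError(ValueError):
    pass


class PDBDialectError(ValueError):
    pass


@dataclass
class CoordinateSet:
    """Labelled particles of one model: coordinates in A plus PDB-ish labels."""

    xyz: np.ndarray  # (n, 3) float
    atom_name: np.ndarray  # (n,) str
    res_name: np.ndarray  # (n,) str
    res_id: np.ndarray  # (n,) int
    chain_id: np.ndarray  # (n,) str
    role: np.ndarray  # (n,) str, one of ROLES
    model: int = 1

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    def select_role(self, *roles: str) -> np.ndarray:
        return np.isin(self.role, roles)


def _roles_from_res_names(res_names: np.ndarray, role_map: dict[str, str]) -> np.ndarray:
    return np.array([role_map.get(rn, "other") for rn in res_names])


def list_models(path) -> list[int]:
    pdb = PDBFile.read(str(path))
    n = pdb.get_model_count()
    return list(range(1, n + 1))


def read_coordinates(
    path, model: int = 1, role_map: dict[str, str] | None = None
) -> CoordinateSet:
    """Read one model of a PDB file into a CoordinateSet."""
    role_map = DEFAULT_ROLE_MAP if role_map is None else role_map
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if model < 1 or model > n_models:
        raise ModelNotFoundError(
            f"{path}: model {model} not present (available: 1..{n_models})"
        )
    for line in pdb.lines:
        if line.startswith(("ATOM", "HETATM")) and len(line) > 26 and line[26] != " ":
            raise PDBDialectError(f"{path}: insertion codes are not supported")
    atoms = pdb.get_structure(model=model, altloc="first")
    return CoordinateSet(
        xyz=atoms.coord.astype(float),
        atom_name=atoms.atom_name.astype("U5"),
        res_name=atoms.res_name.astype("U4"),
        res_id=atoms.res_id.astype(int),
        chain_id=atoms.chain_id.astype("U2"),
        role=_roles_from_res_names(atoms.res_name, role_map),
        model=model,
    )


def _to_atom_array(cs: CoordinateSet) -> bst.AtomArray:
    n = len(cs)
    arr = bst.AtomArray(n)
    arr.coord = cs.xyz.astype(np.float32)
    arr.atom_name = cs.atom_name
    arr.res_name = cs.res_name
    arr.res_id = cs.res_id
    arr.chain_id = cs.chain_id
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_coordinates(frames, path) -> None:
    """Write one CoordinateSet or a sequence of them as a (multi-model) PDB."""
    if isinstance(frames, CoordinateSet):
        frames = [frames]
    stack = bst.stack([_to_atom_array(f) for f in frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


@dataclass
class Ensemble:
    """Ordered conformations with reference (prior) weights.

    All frames must share the particle labelling; ``meta`` may carry generator
    bookkeeping (planted axes, angles, cluster ids).
    """

    frames: list[CoordinateSet]
    ref_weights: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ref_weights is None:
            n = len(self.frames)
            self.ref_weights = np.full(n, 1.0 / n) if n else np.array([])
        self.ref_weights = np.asarray(self.ref_weights, dtype=float)
        if len(self.ref_weights) != len(self.frames):
            raise ValueError("one reference weight per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    def coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_frames, n_sel, 3) coordinate block for a particle mask."""
        if mask is None:
            return np.stack([f.xyz for f in self.frames])
        return np.stack([f.xyz[mask] for f in self.frames])


class WeightValidationError(ValueError):
    pass


def write_weights(weights, path) -> None:
    """Write frame weights as a 2-column TSV (frame index, weight)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise WeightValidationError("weights must be non-negative")
    with open(path, "w") as fh:
        fh.write("# frame\tweight\n")
        for i, wi in enumerate(w):
            fh.write(f"{i}\t{wi:.12e}\n")


def read_weights(path) -> np.ndarray:
    """Read weights TSV; renormalizes to sum 1 (warns if off by > 1e-6)."""
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            _, _, w = line.partition("\t")
            vals.append(float(w))
    w = np.asarray(vals, dtype=float)
    if np.any(w < 0):
        raise WeightValidationError(f"{path}: negative weight")
    total = w.sum()
    if total <= 0:
        raise WeightValidationError(f"{path}: weights sum to zero")
    if abs(total - 1.0) > 1e-6:
        warnings.warn(f"{path}: weights sum to {total:.6g}; renormalizing")
    return w / total
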