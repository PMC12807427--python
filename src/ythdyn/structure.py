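"""Structure and trajectory handling for protein-RNA complexes.

This module holds the light-weight data model used throughout the package: a
:class:`Structure` (atoms with author residue numbering and a protein /
nucleotide classification per residue), a :class:`Trajectory` (frames x atoms
x 3 coordinates in Angstrom), atom selections, least-squares rigid-body
superposition, and RMSD time series with replica averaging.

PDB parsing and writing are delegated to :mod:`biotite`; everything user
facing keeps the author residue numbering found in the file (e.g. 347-502 for
the YTH domain construct), never a renumbered index.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "Selection",
    "SeriesSummary",
    "read_pdb",
    "write_pdb",
    "read_trajectory_table",
    "write_trajectory_table",
    "select",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "replica_summary",
]

#: Standard amino-acid residue names (plus common variants) -> protein class.
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN", "MSE",
}

#: Ribonucleotide residue names, including N6-methyladenosine aliases used by
#: different force fields / depositions.  The table is module level so callers
#: can extend it for exotic residue names.
NUCLEOTIDE_RESNAMES = {
    "A", "U", "G", "C",
    "RA", "RU", "RG", "RC",
    "A3", "U5", "G5", "C3",
    "6MA", "6MZ", "M6A", "MA6", "A2M", "6MP",
}


class PDBError(ValueError):
    """Raised for unreadable or out-of-range PDB input."""


@dataclass(frozen=True)
class Atom:
    """A single atom; positions are in Angstrom."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    is_heavy: bool

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if self.is_heavy != (self.element.upper() != "H"):
            raise ValueError("is_heavy inconsistent with element")


@dataclass(frozen=True)
class Residue:
    """One residue: author-numbered key plus the atom index range it owns."""

    key: tuple[str, int]          # (chain_id, author residue number)
    name: str
    molecule_class: str           # "protein" | "nucleotide" | "other"
    atom_indices: np.ndarray      # ordered indices into the structure


class Structure:
    """An ordered collection of atoms grouped into classified residues.

    Coordinates and per-atom annotations are stored as parallel numpy arrays
    for speed; :meth:`atoms` materialises :class:`Atom` records on demand.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        coords: np.ndarray,
        serials: Sequence[int] | None = None,
    ) -> None:
        n = len(names)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(
            [_infer_element(e, nm) for e, nm in zip(elements, names)], dtype=object
        )
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coords = coords
        self.serials = (
            np.asarray(serials, dtype=int)
            if serials is not None
            else np.arange(1, n + 1)
        )
        self.is_heavy = np.asarray([e.upper() != "H" for e in self.elements])
        self.residues = self._build_residue_table()

    # -- residue bookkeeping ------------------------------------------------

    def _build_residue_table(self) -> list[Residue]:
        residues: list[Residue] = []
        seen: dict[tuple[str, int], int] = {}
        start = 0
        n = len(self.names)
        for i in range(1, n + 1):
            boundary = i == n or (
                self.residue_indices[i] != self.residue_indices[start]
                or self.chain_ids[i] != self.chain_ids[start]
            )
            if boundary:
                key = (str(self.chain_ids[start]), int(self.residue_indices[start]))
                if key in seen:
                    raise ValueError(f"duplicate residue key {key}")
                seen[key] = len(residues)
                resname = str(self.residue_names[start])
                residues.append(
                    Residue(
                        key=key,
                        name=resname,
                        molecule_class=classify_residue(resname),
                        atom_indices=np.arange(start, i),
                    )
                )
                start = i
        return residues

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.n_atoms

    def residue(self, residue_index: int, chain_id: str | None = None) -> Residue:
        """Look up a residue by author number (and chain when ambiguous)."""
        hits = [
            r
            for r in self.residues
            if r.key[1] == residue_index and (chain_id is None or r.key[0] == chain_id)
        ]
        if not hits:
            raise KeyError(f"no residue {residue_index!r} (chain {chain_id!r})")
        if len(hits) > 1:
            raise KeyError(f"residue {residue_index} ambiguous across chains")
        return hits[0]

    def atoms(self) -> list[Atom]:
        return [
            Atom(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                element=str(self.elements[i]),
                residue_index=int(self.residue_indices[i]),
                residue_name=str(self.residue_names[i]),
                chain_id=str(self.chain_ids[i]),
                position=self.coords[i].copy(),
                is_heavy=bool(self.is_heavy[i]),
            )
            for i in range(self.n_atoms)
        ]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure carrying different coordinates."""
        return Structure(
            self.names,
            self.elements,
            self.residue_indices,
            self.residue_names,
            self.chain_ids,
            coords,
            serials=self.serials,
        )


def classify_residue(resname: str) -> str:
    name = resname.strip().upper()
    if name in PROTEIN_RESNAMES:
        return "protein"
    if name in NUCLEOTIDE_RESNAMES:
        return "nucleotide"
    return "other"


def _infer_element(element: str, atom_name: str) -> str:
    """Element from the PDB element column, else first non-digit of the name."""
    e = element.strip()
    if e:
        return e.capitalize()
    for ch in atom_name.strip():
        if not ch.isdigit():
            return ch.upper()
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


@dataclass
class Trajectory:
    """F x N x 3 coordinates (Angstrom) over a fixed atom template.

    ``frame_spacing`` is the time between stored frames; the default of 1.0
    (ns) mirrors trajectories subsampled to one conformation per nanosecond.
    """

    frames: np.ndarray
    atom_template: Structure
    frame_spacing: float = 1.0
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty F x N x 3 array")
        if self.frames.shape[1] != self.atom_template.n_atoms:
            raise ValueError(
                f"trajectory has {self.frames.shape[1]} atoms, template has "
                f"{self.atom_template.n_atoms}"
            )
        if self.frames.shape[2] != 3:
            raise ValueError("frames must have xyz coordinates")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_spacing


@dataclass(frozen=True)
class Selection:
    """Ordered atom indices plus a human-readable label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("selection indices must be one-dimensional")
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("selection indices must be strictly increasing")
        if len(idx) and idx[0] < 0:
            raise ValueError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class SeriesSummary:
    """Per-frame mean and sample standard deviation across replicas."""

    mean: np.ndarray
    std: np.ndarray
    n_replicas: int


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_pdb(path: str | os.PathLike, model_index: int = 1) -> Structure:
    """Read one MODEL of a (possibly multi-model) PDB file.

    Parameters
    ----------
    path:
        PDB file path.
    model_index:
        1-based model number, as printed on MODEL records.  NMR depositions
        typically carry many models; analyses here conventionally use the
        first.

    Only blank or 'A' alternate locations are kept, so each residue resolves
    to a single deterministic conformer.
    """
    import biotite.structure.io.pdb as pdb

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
    except Exception as exc:  # biotite raises several parse error types
        raise PDBError(f"cannot parse PDB file {path}: {exc}") from exc
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise PDBError(f"no atoms parsed from {path}")
    if not 1 <= model_index <= n_models:
        raise PDBError(
            f"model {model_index} out of range: {path} has {n_models} model(s)"
        )
    arr = pdb_file.get_structure(model=model_index, altloc="first")
    if arr.array_length() == 0:
        raise PDBError(f"no atoms parsed from {path}")
    return Structure(
        names=[str(n) for n in arr.atom_name],
        elements=[str(e) for e in arr.element],
        residue_indices=arr.res_id,
        residue_names=[str(n) for n in arr.res_name],
        chain_ids=[str(c) for c in arr.chain_id],
        coords=arr.coord,
    )


def write_pdb(
    structure: Structure,
    path: str | os.PathLike,
    coords: np.ndarray | None = None,
) -> None:
    """Write a structure, or a stack of conformations of it, as PDB.

    ``coords`` may be omitted (write the structure's own coordinates), a
    single N x 3 array, or an M x N x 3 stack, which produces M MODEL blocks.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if coords is None:
        coords = structure.coords[None]
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1:] != (structure.n_atoms, 3):
        raise ValueError("coords incompatible with structure atom count")

    n = structure.n_atoms
    template = struc.AtomArray(n)
    template.atom_name = np.array([str(x) for x in structure.names])
    template.element = np.array([str(x).upper() for x in structure.elements])
    template.res_id = structure.residue_indices.copy()
    template.res_name = np.array([str(x) for x in structure.residue_names])
    template.chain_id = np.array([str(x) for x in structure.chain_ids])
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([template] * len(coords))
    stack.coord = coords
    out = pdb.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


# ---------------------------------------------------------------------------
# Plain-text trajectory tables
# ---------------------------------------------------------------------------

def write_trajectory_table(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as a whitespace table: frame atom x y z (Angstrom)."""
    frames, n_atoms = traj.frames.shape[:2]
    frame_col = np.repeat(np.arange(frames), n_atoms)
    atom_col = np.tile(np.arange(n_atoms), frames)
    flat = traj.frames.reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(f"# frame atom x y z  (Angstrom; frame_spacing={traj.frame_spacing} "
                 f"replica={traj.replica_id})\n")
        for f, a, (x, y, z) in zip(frame_col, atom_col, flat):
            fh.write(f"{f} {a} {x:.4f} {y:.4f} {z:.4f}\n")


def read_trajectory_table(
    path: str | os.PathLike,
    template: Structure,
    frame_spacing: float = 1.0,
    replica_id: int = 0,
) -> Trajectory:
    """Read the whitespace trajectory table written by
    :func:`write_trajectory_table`."""
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    if data.shape[1] != 5:
        raise ValueError("trajectory table must have columns: frame atom x y z")
    n_atoms = template.n_atoms
    frame_ids = data[:, 0].astype(int)
    n_frames = frame_ids.max() + 1
    if len(data) != n_frames * n_atoms:
        raise ValueError(
            f"table rows ({len(data)}) != frames ({n_frames}) x atoms ({n_atoms})"
        )
    order = np.lexsort((data[:, 1], data[:, 0]))
    coords = data[order, 2:5].reshape(n_frames, n_atoms, 3)
    return Trajectory(coords, template, frame_spacing=frame_spacing,
                      replica_id=replica_id)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select(structure: Structure, rule: str, allow_empty: bool = False) -> Selection:
    """Select atoms by a small conjunctive expression.

    Terms, joined by ``and``:

    - ``name <ATOM>`` -- atom name equality (e.g. ``name CA``)
    - ``heavy`` -- element is not hydrogen
    - ``protein`` / ``nucleotide`` -- residue molecule class
    - ``residue <i>`` or ``residue <i>-<j>`` -- author residue number range

    Example: ``"name CA and protein"`` selects the protein Calpha trace.
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    res_class = np.empty(structure.n_atoms, dtype=object)
    for res in structure.residues:
        res_class[res.atom_indices] = res.molecule_class

    terms = [t.strip() for t in rule.split(" and ")]
    for term in terms:
        if not term:
            raise ValueError("empty selection term")
        parts = term.split()
        kw = parts[0].lower()
        if kw == "name" and len(parts) == 2:
            mask &= structure.names == parts[1]
        elif kw == "heavy" and len(parts) == 1:
            mask &= structure.is_heavy
        elif kw in ("protein", "nucleotide") and len(parts) == 1:
            mask &= res_class == kw
        elif kw in ("residue", "resid") and len(parts) == 2:
            token = parts[1]
            if "-" in token[1:]:  # range like 431-442 (first char may be a sign)
                split_at = token.index("-", 1)
                lo, hi = int(token[:split_at]), int(token[split_at + 1:])
            else:
                lo = hi = int(token)
            mask &= (structure.residue_indices >= lo) & (structure.residue_indices <= hi)
        else:
            raise ValueError(f"unrecognised selection term {term!r}")
    indices = np.flatnonzero(mask)
    if len(indices) == 0 and not allow_empty:
        raise ValueError(f"selection {rule!r} matched no atoms")
    return Selection(indices=indices, label=rule)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: Selection | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` minimises the least-squares deviation over
    the fit atoms; the rotation is always proper (det +1).  The RMSD is
    computed over the fit selection after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching N x 3 arrays")
    idx = fit_selection.indices if fit_selection is not None else np.arange(len(mobile))
    if len(idx) < 3:
        raise ValueError("need at least 3 fit atoms")
    mob = mobile[idx]
    ref = reference[idx]
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mob0 = mob - mob_c
    # Collinear or coincident fit atoms leave the rotation under-determined.
    sv = np.linalg.svd(mob0, compute_uv=False)
    if len(sv) < 2 or sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear or coincident) fit atoms")
    rot, _ = Rotation.align_vectors(ref - ref_c, mob0)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    fitted = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ np.asarray(rotation).T + np.asarray(translation)


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection: Selection,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) to a reference over one atom selection.

    Each frame is first rigid-fitted to the reference over the same selection
    (``fit=False`` skips the fit and measures raw deviations).
    """
    if reference.n_atoms != traj.frames.shape[1]:
        raise ValueError("reference and trajectory atom counts differ")
    idx = selection.indices
    ref = reference.coords[idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.frames[f, idx]
        if fit:
            _, _, out[f] = superpose(mob, ref)
        else:
            out[f] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out


def replica_summary(
    series_list: Iterable[np.ndarray],
    allow_single: bool = False,
) -> SeriesSummary:
    """Frame-wise mean and sample std of per-replica series of equal length."""
    series = [np.asarray(s, dtype=float) for s in series_list]
    if not series:
        raise ValueError("no series given")
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    if len(series) < 2 and not allow_single:
        raise ValueError("need >= 2 replicas for a standard deviation")
    stacked = np.stack(series)
    mean = stacked.mean(axis=0)
    if len(series) >= 2:
        std = stacked.std(axis=0, ddof=1)
    else:
        std = np.full_like(mean, np.nan)
    return SeriesSummary(mean=mean, std=std, n_replicas=len(series))
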