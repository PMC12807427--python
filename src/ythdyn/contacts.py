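"""Native-contact analysis between protein residues and RNA nucleotides.

A native contact is a (residue, nucleotide) pair whose minimum heavy-atom
distance in the reference structure is strictly below the cutoff (6.0 A by
default).  Per-frame minimum heavy-atom distances of those pairs feed the
contact PCA; per-nucleotide contact counts use an inclusive cutoff
("within"), at either residue or atom-pair granularity.  Hydrogens are never
counted on either side, and no periodic-image handling is applied (analysis
trajectories are solute-only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Residue, Selection, Structure, Trajectory

__all__ = [
    "ContactPair",
    "ContactSet",
    "ContactDistanceSeries",
    "ContactCounts",
    "native_contacts",
    "min_distance_series",
    "contact_count_series",
]


@dataclass(frozen=True)
class ContactPair:
    """One native residue-nucleotide pair with its reference distance."""

    residue_key: tuple[str, int]
    nucleotide_key: tuple[str, int]
    native_min_distance: float

    def __post_init__(self) -> None:
        if self.native_min_distance <= 0:
            raise ValueError("native distance must be positive")


@dataclass
class ContactSet:
    """Ordered native contacts found below a cutoff on a reference."""

    pairs: list[ContactPair]
    cutoff: float = 6.0
    reference_id: str = ""

    def __post_init__(self) -> None:
        keys = [(p.residue_key, p.nucleotide_key) for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("contact pairs must be unique")
        for p in self.pairs:
            if p.native_min_distance >= self.cutoff:
                raise ValueError(
                    f"pair {p.residue_key}/{p.nucleotide_key} at "
                    f"{p.native_min_distance:.2f} A is not below cutoff"
                )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ContactDistanceSeries:
    """F x P matrix of per-frame minimum heavy-atom distances (Angstrom)."""

    distances: np.ndarray
    contacts: ContactSet

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[1] != len(self.contacts):
            raise ValueError("distance matrix must be F x n_contacts")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("distances must be positive and finite")
        self.distances = d

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]


@dataclass
class ContactCounts:
    """Per-frame contact counts of one nucleotide against the protein."""

    counts: np.ndarray
    nucleotide_key: tuple[str, int]
    level: str
    cutoff: float

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def std(self) -> float:
        return float(self.counts.std(ddof=1)) if len(self.counts) > 1 else 0.0


def _heavy_indices(structure: Structure, residue: Residue) -> np.ndarray:
    idx = residue.atom_indices
    return idx[structure.is_heavy[idx]]


def _resolve_residues(structure: Structure, which, molecule_class: str) -> list[Residue]:
    """Residues of a class, optionally restricted to given keys/numbers or an
    atom Selection."""
    pool = [r for r in structure.residues if r.molecule_class == molecule_class]
    if which is None:
        chosen = pool
    elif isinstance(which, Selection):
        wanted = set(which.indices.tolist())
        chosen = [r for r in pool if wanted.intersection(r.atom_indices.tolist())]
    else:
        keys = set()
        for item in which:
            keys.add(item if isinstance(item, tuple) else int(item))
        chosen = [r for r in pool if r.key in keys or r.key[1] in keys]
    if not chosen:
        raise ValueError(f"no {molecule_class} residues selected")
    return chosen


def native_contacts(
    ref: Structure,
    protein_residues=None,
    rna_nucleotides=None,
    cutoff: float = 6.0,
) -> ContactSet:
    """Native residue-nucleotide contacts of a reference structure.

    A pair is native when the minimum over all heavy-atom pairs of the
    Euclidean distance is strictly below ``cutoff``.  Pairs are ordered by
    (residue number, nucleotide number).  Residue groups may be given as
    author numbers, (chain, number) keys, atom Selections, or left as None
    for "all of that class".
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot = _resolve_residues(ref, protein_residues, "protein")
    rna = _resolve_residues(ref, rna_nucleotides, "nucleotide")
    pairs = []
    for res in sorted(prot, key=lambda r: r.key):
        ri = _heavy_indices(ref, res)
        if not len(ri):
            continue
        for nt in sorted(rna, key=lambda r: r.key):
            ni = _heavy_indices(ref, nt)
            if not len(ni):
                continue
            dmin = cdist(ref.coords[ri], ref.coords[ni]).min()
            if dmin < cutoff:
                pairs.append(ContactPair(res.key, nt.key, float(dmin)))
    return ContactSet(pairs=pairs, cutoff=cutoff, reference_id="")


def min_distance_series(
    traj: Trajectory,
    contacts: ContactSet,
) -> ContactDistanceSeries:
    """Per-frame minimum heavy-atom distance for every native contact pair."""
    template = traj.atom_template
    res_cache: dict[tuple[str, int], np.ndarray] = {}

    def heavy(key: tuple[str, int]) -> np.ndarray:
        if key not in res_cache:
            hits = [r for r in template.residues if r.key == key]
            if not hits:
                raise ValueError(f"residue {key} not present in trajectory template")
            res_cache[key] = _heavy_indices(template, hits[0])
        return res_cache[key]

    F = traj.n_frames
    out = np.empty((F, len(contacts)))
    for p, pair in enumerate(contacts.pairs):
        ri = heavy(pair.residue_key)
        ni = heavy(pair.nucleotide_key)
        a = traj.frames[:, ri]           # F x na x 3
        b = traj.frames[:, ni]           # F x nb x 3
        diff = a[:, :, None, :] - b[:, None, :, :]
        out[:, p] = np.sqrt((diff ** 2).sum(axis=-1)).reshape(F, -1).min(axis=1)
    return ContactDistanceSeries(distances=out, contacts=contacts)


def contact_count_series(
    traj: Trajectory,
    nucleotide_key,
    protein_residues=None,
    cutoff: float = 6.0,
    level: str = "residue",
    inclusive: bool = True,
) -> ContactCounts:
    """Per-frame contact count of one nucleotide against the protein.

    ``level="residue"`` counts protein residues whose minimum heavy-atom
    distance to the nucleotide is within the cutoff; ``level="atom_pair"``
    counts individual heavy-atom pairs.  "Within" is inclusive (<=) by
    default; pass ``inclusive=False`` for the strict rule used in
    native-contact determination.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if level not in ("residue", "atom_pair"):
        raise ValueError("level must be 'residue' or 'atom_pair'")
    template = traj.atom_template
    if not isinstance(nucleotide_key, tuple):
        nt_hits = [
            r for r in template.residues
            if r.molecule_class == "nucleotide" and r.key[1] == int(nucleotide_key)
        ]
    else:
        nt_hits = [r for r in template.residues if r.key == nucleotide_key]
    if not nt_hits:
        raise ValueError(f"unknown nucleotide {nucleotide_key!r}")
    nt = nt_hits[0]
    ni = _heavy_indices(template, nt)
    try:
        prot = _resolve_residues(template, protein_residues, "protein")
    except ValueError:
        prot = []
    F = traj.n_frames
    counts = np.zeros(F)
    b = traj.frames[:, ni]
    for res in prot:
        ri = _heavy_indices(template, res)
        if not len(ri):
            continue
        a = traj.frames[:, ri]
        diff = a[:, :, None, :] - b[:, None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1)).reshape(F, -1)
        within = dist <= cutoff if inclusive else dist < cutoff
        if level == "residue":
            counts += within.any(axis=1)
        else:
            counts += within.sum(axis=1)
    return ContactCounts(counts=counts, nucleotide_key=nt.key, level=level,
                         cutoff=cutoff)
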