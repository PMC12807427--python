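"""Synthetic protein-RNA complex trajectories with a two-state loop motion.

The generator emulates the statistical structure of an m6A-reader complex: a
pseudo-protein whose "recognition loop" block sits over a binding pocket that
buries the third nucleotide of a 6-mer RNA.  In the closed state the loop and
pocket residues all have heavy atoms within the 6 A contact cutoff of
nucleotide 3; a two-state Markov chain switches the loop to an open state in
which the loop block is rigidly displaced along a fixed opening direction,
breaking exactly the loop contacts while the pocket contacts persist.
Isotropic Gaussian noise models thermal fluctuation.

Three modes mirror the qualitative behaviours of a methylated complex
(``closed_stable``: the loop never opens), an apo receptor (``two_state``:
full close-open transition) and a non-methylated complex
(``partial_opening``: reduced open occupancy).  Everything is deterministic
given the seeds; ground-truth state labels and the planted breaking-contact
list are returned for downstream validation.

This is a statistical stand-in, not a physical simulator: there are no
sterics, no bonded energetics, and the noise is uncorrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .contacts import ContactDistanceSeries, ContactPair, ContactSet, native_contacts
from .structure import Structure, Trajectory

__all__ = [
    "ComplexTemplate",
    "DynamicsSpec",
    "GroundTruth",
    "InfeasibleGeometryError",
    "build_template",
    "generate_trajectories",
    "breaking_block_series",
]

_MODES = ("closed_stable", "two_state", "partial_opening")
_RNA_SEQUENCE = ("U", "G", "6MA", "C", "A", "C")
_AA_CYCLE = ("ALA", "LEU", "VAL", "MET", "TRP", "PRO", "GLY", "SER")


class InfeasibleGeometryError(ValueError):
    """Template geometry cannot satisfy the contact/opening constraints."""


@dataclass(frozen=True)
class ComplexTemplate:
    """Layout of the pseudo-complex (author residue numbering).

    Defaults mirror a 156-residue reader domain numbered 347-502 bound to a
    6-nucleotide RNA, with the recognition loop at 431-442 and the pocket
    floor at 380-386.
    """

    n_protein_residues: int = 156
    n_nucleotides: int = 6
    first_residue: int = 347
    loop_range: tuple[int, int] = (431, 442)
    pocket_range: tuple[int, int] = (380, 386)
    seed: int = 0

    def __post_init__(self) -> None:
        last = self.first_residue + self.n_protein_residues - 1
        for lo, hi in (self.loop_range, self.pocket_range):
            if not (self.first_residue <= lo <= hi <= last):
                raise ValueError("loop/pocket ranges must lie inside the protein")
        lr, pr = self.loop_range, self.pocket_range
        if not (lr[1] < pr[0] or pr[1] < lr[0]):
            raise ValueError("loop and pocket ranges must be disjoint")
        if self.n_nucleotides < 3:
            raise ValueError("need at least 3 nucleotides (the third is buried)")

    @property
    def loop_residues(self) -> range:
        return range(self.loop_range[0], self.loop_range[1] + 1)

    @property
    def pocket_residues(self) -> range:
        return range(self.pocket_range[0], self.pocket_range[1] + 1)


@dataclass(frozen=True)
class DynamicsSpec:
    """Two-state loop dynamics parameters.

    ``open_amplitude`` (A) is the rigid loop displacement between states;
    ``transition_rate`` scales the per-frame Markov switching probabilities;
    ``state_occupancy_target`` is the stationary open fraction in two_state
    mode (``partial_occupancy`` replaces it in partial_opening mode);
    ``noise_sigma`` (A) is the isotropic thermal noise on every atom.
    """

    open_amplitude: float = 8.0
    transition_rate: float = 0.05
    state_occupancy_target: float = 0.5
    partial_occupancy: float = 0.15
    noise_sigma: float = 0.2
    n_frames: int = 1000
    n_replicas: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.open_amplitude <= 0:
            raise ValueError("open amplitude must be positive")
        if not 0 < self.transition_rate < 1:
            raise ValueError("transition rate must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not 0 < self.state_occupancy_target < 1:
            raise ValueError("occupancy target must be in (0, 1)")
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ValueError("need at least one frame and one replica")


@dataclass
class GroundTruth:
    """Per-frame state labels and the planted breaking-contact list."""

    labels: np.ndarray                       # 0 closed / 1 open, concatenated
    labels_per_replica: list[np.ndarray]
    breaking_contacts: list[tuple[tuple[str, int], tuple[str, int]]]
    open_direction: np.ndarray
    parameters: dict = field(default_factory=dict)


def _sphere_points(n: int, radius: float) -> np.ndarray:
    """Deterministic near-uniform points on a sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _cone_directions(n: int, polar_deg: float) -> np.ndarray:
    theta = np.radians(polar_deg)
    az = 2.0 * np.pi * np.arange(n) / n
    return np.stack(
        [np.sin(theta) * np.cos(az), np.sin(theta) * np.sin(az),
         np.full(n, np.cos(theta))],
        axis=1,
    )


def open_direction(spec: ComplexTemplate) -> np.ndarray:
    """The unit vector along which the loop block opens (seed-deterministic)."""
    rot = Rotation.random(random_state=np.random.default_rng(spec.seed))
    return rot.apply(np.array([0.0, 0.0, 1.0]))


def build_template(spec: ComplexTemplate = ComplexTemplate()) -> Structure:
    """Deterministic pseudo-structure of the complex in the closed state.

    Nucleotide 3 sits at the pocket centre; pocket residues point inward from
    below and loop residues from above, each with a heavy atom ~4.6 A from
    the nucleotide (planting the closed-state contact shell).  Nucleotides
    1-2 and 4+ trail away from the pocket, each touching one designated
    peripheral surface residue only.  The whole assembly is rotated by a
    seed-derived rotation, which also sets the opening direction.
    """
    loop = list(spec.loop_residues)
    pocket = list(spec.pocket_residues)
    last = spec.first_residue + spec.n_protein_residues - 1
    special = set(loop) | set(pocket)
    ordinary = [r for r in range(spec.first_residue, last + 1) if r not in special]
    # One peripheral anchor residue per non-central nucleotide.
    n_periph = spec.n_nucleotides - 1
    if len(ordinary) < n_periph + 1:
        raise InfeasibleGeometryError("protein too small for peripheral anchors")
    peripheral = ordinary[:n_periph]
    arc = ordinary[n_periph:]

    # Nucleotide centres: #3 at the origin, the rest trailing away in the
    # equatorial plane, clear of both the loop and pocket cones.
    nt_centers = {}
    others = [k for k in range(1, spec.n_nucleotides + 1) if k != 3]
    for k in range(1, spec.n_nucleotides + 1):
        if k == 3:
            nt_centers[k] = np.zeros(3)
        else:
            nt_centers[k] = np.array(
                [-(4.5 + 5.5 * abs(k - 3)), 4.0 * (k - 3), 0.0]
            )

    names: list[str] = []
    elements: list[str] = []
    res_ids: list[int] = []
    res_names: list[str] = []
    chains: list[str] = []
    coords: list[np.ndarray] = []

    def add_atom(name, element, rid, rname, chain, pos):
        names.append(name)
        elements.append(element)
        res_ids.append(rid)
        res_names.append(rname)
        chains.append(chain)
        coords.append(np.asarray(pos, dtype=float))

    def add_residue(rid, ca, cb, cg, h):
        rname = _AA_CYCLE[rid % len(_AA_CYCLE)]
        add_atom("CA", "C", rid, rname, "A", ca)
        add_atom("CB", "C", rid, rname, "A", cb)
        add_atom("CG", "C", rid, rname, "A", cg)
        add_atom("H1", "H", rid, rname, "A", h)

    pocket_dirs = _cone_directions(len(pocket), 135.0)
    loop_dirs = _cone_directions(len(loop), 45.0)
    periph_by_res = dict(zip(peripheral, others))

    # Residues are emitted in author order so the residue table stays sorted.
    arc_centre = np.array([45.0, 0.0, 0.0])
    arc_radius = 30.0
    arc_angles = np.linspace(0.25 * np.pi, 1.75 * np.pi, max(len(arc), 2))
    arc_pos = {
        r: arc_centre + arc_radius * np.array([np.cos(a), np.sin(a), 0.0])
        for r, a in zip(arc, arc_angles)
    }
    for rid in range(spec.first_residue, last + 1):
        if rid in pocket:
            d = pocket_dirs[pocket.index(rid)]
            add_residue(rid, 8.0 * d, 6.2 * d, 4.6 * d, 8.8 * d)
        elif rid in loop:
            d = loop_dirs[loop.index(rid)]
            add_residue(rid, 8.0 * d, 6.2 * d, 4.6 * d, 8.8 * d)
        elif rid in periph_by_res:
            c = nt_centers[periph_by_res[rid]]
            add_residue(rid, c + (0.0, 0.0, 6.5), c + (0.0, 0.0, 5.0),
                        c + (1.5, 0.0, 5.5), c + (0.0, 0.0, 7.3))
        else:
            p = arc_pos[rid]
            n_hat = (p - arc_centre) / arc_radius
            add_residue(rid, p, p + 1.5 * n_hat, p - (0.0, 0.0, 1.5),
                        p + (0.0, 0.0, 1.0))

    nt_atom_names = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4", "C1'"]
    nt_elements = ["N", "C", "N", "C", "C", "N", "C", "N", "C", "C"]
    shell = _sphere_points(9, 1.2)
    for k in range(1, spec.n_nucleotides + 1):
        rname = _RNA_SEQUENCE[(k - 1) % len(_RNA_SEQUENCE)]
        centre = nt_centers[k]
        add_atom(nt_atom_names[0], nt_elements[0], k, rname, "B", centre)
        for j in range(9):
            add_atom(nt_atom_names[j + 1], nt_elements[j + 1], k, rname, "B",
                     centre + shell[j])
        add_atom("H2", "H", k, rname, "B", centre + (0.0, 0.0, 1.6))

    xyz = np.asarray(coords)
    rot = Rotation.random(random_state=np.random.default_rng(spec.seed))
    xyz = rot.apply(xyz)
    structure = Structure(names, elements, res_ids, res_names, chains, xyz)

    planted = native_contacts(structure, rna_nucleotides=[("B", 3)], cutoff=6.0)
    in_shell = set(loop) | set(pocket)
    shell_keys = {p.residue_key[1] for p in planted.pairs}
    if len(planted) < 6 or not shell_keys <= in_shell:
        raise InfeasibleGeometryError(
            f"closed-state shell invalid: {len(planted)} contacts, residues "
            f"{sorted(shell_keys - in_shell)} outside loop/pocket"
        )
    return structure


def _loop_atom_indices(structure: Structure, spec: ComplexTemplate) -> np.ndarray:
    idx = [
        r.atom_indices
        for r in structure.residues
        if r.molecule_class == "protein" and r.key[1] in spec.loop_residues
    ]
    return np.concatenate(idx)


def _markov_states(rng: np.random.Generator, n: int, rate: float,
                   occupancy: float) -> np.ndarray:
    if occupancy <= 0:
        return np.zeros(n, dtype=int)
    p_open = rate * occupancy          # closed -> open
    p_close = rate * (1.0 - occupancy)  # open -> closed
    states = np.empty(n, dtype=int)
    states[0] = int(rng.random() < occupancy)
    u = rng.random(n - 1)
    for i in range(1, n):
        if states[i - 1] == 0:
            states[i] = int(u[i - 1] < p_open)
        else:
            states[i] = int(u[i - 1] >= p_close)
    return states


def generate_trajectories(
    template: Structure,
    spec: ComplexTemplate,
    dyn: DynamicsSpec = DynamicsSpec(),
    mode: str = "two_state",
) -> tuple[list[Trajectory], GroundTruth]:
    """Replica trajectories of the pseudo-complex plus ground truth.

    Per frame the loop atoms are rigidly displaced along the opening
    direction by ``open_amplitude x state`` and every atom receives isotropic
    Gaussian noise.  The state follows a stationary two-state Markov chain
    (``closed_stable`` pins it closed; ``partial_opening`` uses the reduced
    ``partial_occupancy``).  Replica r draws its randomness from
    ``dyn.seed + r``.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    occupancy = {
        "closed_stable": 0.0,
        "two_state": dyn.state_occupancy_target,
        "partial_opening": dyn.partial_occupancy,
    }[mode]

    u_open = open_direction(spec)
    loop_idx = _loop_atom_indices(template, spec)

    # Opening must carry every planted loop contact beyond the cutoff by a
    # comfortable noise margin, otherwise labels and contacts decouple.
    planted_set = native_contacts(template, rna_nucleotides=[("B", 3)], cutoff=6.0)
    open_coords = template.coords.copy()
    open_coords[loop_idx] += dyn.open_amplitude * u_open
    opened = template.with_coords(open_coords)
    breaking = []
    from scipy.spatial.distance import cdist

    for pair in planted_set.pairs:
        if pair.residue_key[1] not in spec.loop_residues:
            continue
        res = opened.residue(pair.residue_key[1], pair.residue_key[0])
        nt = opened.residue(pair.nucleotide_key[1], pair.nucleotide_key[0])
        ri = res.atom_indices[opened.is_heavy[res.atom_indices]]
        ni = nt.atom_indices[opened.is_heavy[nt.atom_indices]]
        d_open = cdist(opened.coords[ri], opened.coords[ni]).min()
        if d_open <= planted_set.cutoff + 2.0 * dyn.noise_sigma:
            raise InfeasibleGeometryError(
                f"open-state distance {d_open:.2f} A for contact "
                f"{pair.residue_key}/{pair.nucleotide_key} does not clear the "
                f"cutoff; increase open_amplitude or reduce noise_sigma"
            )
        breaking.append((pair.residue_key, pair.nucleotide_key))

    trajectories: list[Trajectory] = []
    labels_per_replica: list[np.ndarray] = []
    for r in range(dyn.n_replicas):
        rng = np.random.default_rng(dyn.seed + r)
        states = _markov_states(rng, dyn.n_frames, dyn.transition_rate, occupancy)
        frames = (
            template.coords[None]
            + rng.normal(0.0, dyn.noise_sigma,
                         size=(dyn.n_frames, template.n_atoms, 3))
        )
        frames[:, loop_idx] += (
            states[:, None, None] * dyn.open_amplitude * u_open[None, None]
        )
        trajectories.append(
            Trajectory(frames, template, frame_spacing=1.0, replica_id=r)
        )
        labels_per_replica.append(states)

    labels = np.concatenate(labels_per_replica)
    if occupancy > 0:
        achieved = float(labels.mean())
        if abs(achieved - occupancy) > 0.1:
            warnings.warn(
                f"achieved open occupancy {achieved:.2f} differs from target "
                f"{occupancy:.2f}; increase frames or transition_rate",
                stacklevel=2,
            )
    truth = GroundTruth(
        labels=labels,
        labels_per_replica=labels_per_replica,
        breaking_contacts=breaking,
        open_direction=u_open,
        parameters={
            "mode": mode,
            "occupancy": occupancy,
            "open_amplitude": dyn.open_amplitude,
            "transition_rate": dyn.transition_rate,
            "noise_sigma": dyn.noise_sigma,
            "n_frames": dyn.n_frames,
            "n_replicas": dyn.n_replicas,
            "seed": dyn.seed,
        },
    )
    return trajectories, truth


def breaking_block_series(
    n_frames: int = 200,
    n_breaking: int = 6,
    n_stable: int = 14,
    gap: float = 4.0,
    sigma: float = 0.2,
    occupancy: float = 0.5,
    transition_rate: float = 0.1,
    seed: int = 0,
) -> tuple[ContactDistanceSeries, np.ndarray, np.ndarray]:
    """Synthetic contact-distance series with a planted breaking block.

    ``n_breaking`` columns jump by ``gap`` Angstrom whenever the shared
    two-state trajectory is open; the remaining columns fluctuate around
    their native distances with noise ``sigma`` only.  Returns the series,
    the breaking column indices, and the per-frame state labels.
    """
    rng = np.random.default_rng(seed)
    P = n_breaking + n_stable
    base = rng.uniform(3.5, 5.5, size=P)
    states = _markov_states(rng, n_frames, transition_rate, occupancy)
    D = base[None] + rng.normal(0.0, sigma, size=(n_frames, P))
    block = np.arange(n_breaking)
    D[:, block] += states[:, None] * gap
    D = np.clip(D, 0.5, None)
    pairs = [
        ContactPair(("A", 400 + i), ("B", 3), float(base[i])) for i in range(P)
    ]
    contact_set = ContactSet(pairs=pairs, cutoff=6.0, reference_id="synthetic")
    return ContactDistanceSeries(D, contact_set), block, states
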