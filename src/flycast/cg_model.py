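"""One-bead-per-residue coarse-grained model with a Gō-style potential.

Each residue is represented by a bead at its Cα position carrying the
full residue mass.  The potential has three terms, all in reduced energy
units (k_BT = 1 at the reference temperature):

* chain connectivity — harmonic bonds between consecutive residues at
  the Cα–Cα distance observed in the source structure,
  E_b = ½ k_b (b − b₀)²;
* native-structure restraining — a 12-10 contact well for residue pairs
  (|i−j| ≥ 3 along the chain) whose Cα distance in the reference is
  below the contact cutoff, E_c = ε [5 (r₀/r)¹² − 6 (r₀/r)¹⁰] with its
  minimum −ε at r = r₀;
* excluded volume — a purely repulsive (σ/r)¹² term truncated (shifted
  to zero) at σ, applied to every non-bonded, non-contact pair.

Phosphorylation of a residue is modelled as a topology edit, not an
energetic constant: the phospho-residue's native contacts within a
configurable sequence window are removed (local disorder release), and
optionally attractive contacts toward configured "pocket" beads on the
partner chain are added.  Both knobs are explicit configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import BuildError
from .structure_io import Structure

__all__ = [
    "PotentialParams",
    "CGSystem",
    "build_cg_system",
    "merge_systems",
    "apply_phosphorylation",
    "potential_energy_forces",
]


@dataclass(frozen=True)
class PotentialParams:
    """Gō-model energy scales (reduced units; lengths in Å).

    Defaults are standard Gō-model scales: stiff bonds keep folds intact
    while 1 k_BT contacts allow fly-casting-like excursions of loosely
    contacted segments.
    """

    bond_k: float = 100.0      # k_BT / Å²
    contact_eps: float = 1.0   # k_BT
    ev_eps: float = 1.0        # k_BT
    ev_sigma: float = 4.0      # Å

    def __post_init__(self):
        if min(self.bond_k, self.contact_eps, self.ev_eps, self.ev_sigma) <= 0:
            raise ValueError("all potential parameters must be > 0")


@dataclass
class CGSystem:
    """Bead topology + reference geometry for the desk-scale engine."""

    chain_id: np.ndarray       # (n,) str per bead
    res_id: np.ndarray         # (n,) int
    res_name: np.ndarray       # (n,) str
    mass: np.ndarray           # (n,) Da
    ref_coord: np.ndarray      # (n, 3) Å
    bonds: np.ndarray          # (nb, 2) int
    bond_r0: np.ndarray        # (nb,) Å
    contacts: np.ndarray       # (nc, 2) int, i < j
    contact_r0: np.ndarray     # (nc,) Å
    params: PotentialParams = field(default_factory=PotentialParams)
    contact_depth: np.ndarray | None = None  # per-contact ε; None → scalar

    _nonnative_pairs: np.ndarray | None = None  # lazy (np, 2) cache

    def __post_init__(self):
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=int).reshape(-1, 2)
        self.contact_r0 = np.asarray(self.contact_r0, dtype=float)
        self.ref_coord = np.asarray(self.ref_coord, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.contact_depth is not None:
            self.contact_depth = np.asarray(self.contact_depth, dtype=float)
            if len(self.contact_depth) != len(self.contacts):
                raise BuildError("one well depth per contact required")
        if len(self.bonds) and not (2.5 <= self.bond_r0.min()
                                    and self.bond_r0.max() <= 4.5):
            raise BuildError("bond rest lengths must lie in [2.5, 4.5] Å")

    def contact_depths(self) -> np.ndarray:
        if self.contact_depth is not None:
            return self.contact_depth
        return np.full(len(self.contacts), self.params.contact_eps)

    @property
    def n_beads(self) -> int:
        return len(self.ref_coord)

    def bead_index(self, chain: str, res: int) -> int:
        hits = np.flatnonzero((self.chain_id == chain) & (self.res_id == res))
        if len(hits) != 1:
            raise BuildError(f"no unique bead for chain {chain} residue {res}")
        return int(hits[0])

    def resolve_group(self, chain: str, residues) -> np.ndarray:
        return np.array([self.bead_index(chain, r) for r in residues], dtype=int)

    def as_structure(self, coord: np.ndarray | None = None) -> Structure:
        """View the bead system as a Cα pseudo-atom Structure."""
        n = self.n_beads
        return Structure(
            chain_id=self.chain_id,
            res_id=self.res_id,
            ins_code=np.full(n, "", dtype="U1"),
            res_name=self.res_name,
            atom_name=np.full(n, "CA", dtype="U6"),
            element=np.full(n, "C", dtype="U2"),
            coord=self.ref_coord if coord is None else coord,
            mass=self.mass,
        )

    def nonnative_pairs(self) -> np.ndarray:
        """All i<j pairs that are neither bonded nor native contacts."""
        if self._nonnative_pairs is None:
            n = self.n_beads
            excl = np.zeros((n, n), dtype=bool)
            iu = np.triu_indices(n, k=1)
            for p in (self.bonds, self.contacts):
                if len(p):
                    excl[p[:, 0], p[:, 1]] = True
                    excl[p[:, 1], p[:, 0]] = True
            mask = ~excl[iu]
            self._nonnative_pairs = np.column_stack(
                (iu[0][mask], iu[1][mask]))
        return self._nonnative_pairs

    def replace_contacts(self, contacts: np.ndarray, contact_r0: np.ndarray,
                         contact_depth: np.ndarray | None = None
                         ) -> "CGSystem":
        return replace(self, contacts=contacts, contact_r0=contact_r0,
                       contact_depth=contact_depth, _nonnative_pairs=None)


def _residue_table(structure: Structure):
    """Per-residue (chain, res_id, res_name, mass, ca_coord) in file order."""
    keys = structure.residue_keys()
    rows = []
    for chain, res, ins in keys:
        mask = ((structure.chain_id == chain) & (structure.res_id == res)
                & (structure.ins_code == ins))
        ca = mask & (structure.atom_name == "CA")
        if not ca.any():
            raise BuildError(
                f"residue {chain}:{res}{ins} has no Cα atom")
        rows.append((
            chain, res, str(structure.res_name[np.flatnonzero(mask)[0]]),
            float(structure.mass[mask].sum()),
            structure.coord[np.flatnonzero(ca)[0]],
        ))
    return rows


def build_cg_system(structure: Structure,
                    params: PotentialParams | None = None,
                    contact_cutoff: float = 8.0,
                    complex_reference: bool = False) -> CGSystem:
    """Map a structure to beads and derive bonds and native contacts.

    Bonds connect consecutive residues within each chain at their observed
    Cα–Cα distance.  Native contacts are residue pairs with |i−j| ≥ 3
    within a chain whose Cα distance is below ``contact_cutoff``;
    inter-chain contacts are included only when ``complex_reference`` is
    set (the structure is a native complex defining the bound state).
    """
    params = params or PotentialParams()
    rows = _residue_table(structure)
    if len(rows) < 2:
        raise BuildError("need at least 2 residues with Cα atoms")
    chain = np.array([r[0] for r in rows])
    res = np.array([r[1] for r in rows], dtype=int)
    names = np.array([r[2] for r in rows])
    mass = np.array([r[3] for r in rows])
    coord = np.array([r[4] for r in rows])

    bonds, bond_r0 = [], []
    for i in range(len(rows) - 1):
        if chain[i] == chain[i + 1]:
            bonds.append((i, i + 1))
            bond_r0.append(np.linalg.norm(coord[i + 1] - coord[i]))

    # O(n²) distance scan; n is residue count, small by construction
    diff = coord[:, None, :] - coord[None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=-1))
    contacts, contact_r0 = [], []
    n = len(rows)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] >= contact_cutoff:
                continue
            same = chain[i] == chain[j]
            if same and j - i < 3:
                continue
            if not same and not complex_reference:
                continue
            contacts.append((i, j))
            contact_r0.append(dist[i, j])

    return CGSystem(
        chain_id=chain, res_id=res, res_name=names, mass=mass,
        ref_coord=coord,
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        bond_r0=np.array(bond_r0, dtype=float),
        contacts=np.array(contacts, dtype=int).reshape(-1, 2),
        contact_r0=np.array(contact_r0, dtype=float),
        params=params,
    )


def merge_systems(a: CGSystem, b: CGSystem,
                  coords_a: np.ndarray | None = None,
                  coords_b: np.ndarray | None = None) -> CGSystem:
    """Concatenate two CG systems into one (no inter-system contacts)."""
    if a.params != b.params:
        raise BuildError("cannot merge systems with different parameters")
    off = a.n_beads
    ca = a.ref_coord if coords_a is None else np.asarray(coords_a, dtype=float)
    cb = b.ref_coord if coords_b is None else np.asarray(coords_b, dtype=float)
    return CGSystem(
        chain_id=np.concatenate([a.chain_id, b.chain_id]),
        res_id=np.concatenate([a.res_id, b.res_id]),
        res_name=np.concatenate([a.res_name, b.res_name]),
        mass=np.concatenate([a.mass, b.mass]),
        ref_coord=np.vstack([ca, cb]),
        bonds=np.vstack([a.bonds, b.bonds + off]),
        bond_r0=np.concatenate([a.bond_r0, b.bond_r0]),
        contacts=np.vstack([a.contacts, b.contacts + off]),
        contact_r0=np.concatenate([a.contact_r0, b.contact_r0]),
        params=a.params,
        contact_depth=np.concatenate([a.contact_depths(),
                                      b.contact_depths()]),
    )


def add_interface_contacts(system: CGSystem, contacts,
                           depth: float = 2.0) -> CGSystem:
    """Add Gō-style attractive contacts between chains.

    ``contacts`` is an iterable of ((chain, res), (chain, res), r0 Å)
    triples, typically measured from a native reference complex — they
    define the bound state: without any inter-chain attraction a
    two-chain system has no metastable complex that survives the
    unrestrained exploration stage.  ``depth`` is the per-contact well
    depth (k_BT); the default 2 k_BT per interface contact puts the
    total binding strength in the 10–30 k_BT range typical of a
    micromolar-to-nanomolar protein–protein complex.
    """
    rows = [
        (*sorted((system.bead_index(ca, ra), system.bead_index(cb, rb))),
         float(r0))
        for (ca, ra), (cb, rb), r0 in contacts
    ]
    if not rows:
        return system
    extra = np.array([(i, j) for i, j, _ in rows], dtype=int)
    extra_r0 = np.array([r0 for _, _, r0 in rows])
    contacts_new = np.vstack([system.contacts, extra]) \
        if len(system.contacts) else extra
    r0_new = np.concatenate([system.contact_r0, extra_r0])
    depth_new = np.concatenate([system.contact_depths(),
                                np.full(len(extra), float(depth))])
    return system.replace_contacts(contacts_new, r0_new, depth_new)


def apply_phosphorylation(system: CGSystem, chain: str, residue: int,
                          window: int = 2,
                          pocket: list[tuple[str, int]] | None = None,
                          pocket_r0: float = 5.0,
                          pocket_eps_scale: float = 1.0) -> CGSystem:
    """Topology edit representing phosphorylation of one residue.

    Removes the phospho-residue's intra-chain native contacts within
    ``± window`` residues (local disorder release) and, when ``pocket``
    beads are given, adds attractive contacts from the phospho-bead to
    each pocket bead at rest distance ``pocket_r0``.
    """
    idx = system.bead_index(chain, residue)
    lo, hi = residue - window, residue + window
    in_window = ((system.chain_id == chain)
                 & (system.res_id >= lo) & (system.res_id <= hi))
    window_idx = set(np.flatnonzero(in_window))
    keep = np.array([
        not (i in window_idx or j in window_idx)
        for i, j in system.contacts
    ], dtype=bool) if len(system.contacts) else np.zeros(0, dtype=bool)
    contacts = system.contacts[keep]
    contact_r0 = system.contact_r0[keep]
    depth = system.contact_depths()[keep]
    if pocket:
        extra = np.array([
            sorted((idx, system.bead_index(pc, pr))) for pc, pr in pocket
        ], dtype=int)
        contacts = np.vstack([contacts, extra]) if len(contacts) else extra
        contact_r0 = np.concatenate(
            [contact_r0, np.full(len(extra), float(pocket_r0))])
        depth = np.concatenate([depth, np.full(
            len(extra), pocket_eps_scale * system.params.contact_eps)])
    return system.replace_contacts(contacts, contact_r0, depth)


def potential_energy_forces(system: CGSystem, coords: np.ndarray
                            ) -> tuple[float, np.ndarray]:
    """Total potential energy and forces (−gradient) at ``coords``.

    Terms: harmonic bonds, 12-10 native-contact wells, truncated r⁻¹²
    repulsion between all remaining pairs.  Reduced energy units.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_beads, 3):
        raise ValueError(
            f"coords shape {coords.shape} != ({system.n_beads}, 3)")
    p = system.params
    energy = 0.0
    forces = np.zeros_like(coords)

    def accumulate(pairs, de_dr_over_r, e_sum):
        # de_dr_over_r: (dE/dr)/r per pair; force on i is -dE/dr * rij/r
        nonlocal energy
        energy += e_sum
        f_pair = -de_dr_over_r[:, None] * rij
        np.add.at(forces, pairs[:, 0], f_pair)
        np.add.at(forces, pairs[:, 1], -f_pair)

    if len(system.bonds):
        rij = coords[system.bonds[:, 0]] - coords[system.bonds[:, 1]]
        r = np.linalg.norm(rij, axis=1)
        db = r - system.bond_r0
        accumulate(system.bonds, p.bond_k * db / r,
                   0.5 * p.bond_k * float(np.sum(db ** 2)))

    if len(system.contacts):
        rij = coords[system.contacts[:, 0]] - coords[system.contacts[:, 1]]
        r = np.linalg.norm(rij, axis=1)
        s = system.contact_r0 / r
        eps = system.contact_depths()
        e = eps * (5.0 * s ** 12 - 6.0 * s ** 10)
        de = eps * (-60.0 * s ** 12 + 60.0 * s ** 10) / r
        accumulate(system.contacts, de / r, float(np.sum(e)))

    pairs = system.nonnative_pairs()
    if len(pairs):
        rij = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        r = np.linalg.norm(rij, axis=1)
        inside = r < p.ev_sigma
        if inside.any():
            pairs = pairs[inside]
            rij = rij[inside]
            r = r[inside]
            s = p.ev_sigma / r
            e = p.ev_eps * (s ** 12 - 1.0)   # shifted to zero at σ
            de = -12.0 * p.ev_eps * s ** 12 / r
            accumulate(pairs, de / r, float(np.sum(e)))

    return energy, forces
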