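"""Synthetic fixtures: toy dimers with a known native pose, prescribed-
statistics trajectories, and an ideal breathing helix.

Everything the pipeline needs for testing is generated here from a seed —
no downloads.  The toy dimer emulates the study system's shape: two
compact Cα chains initially 60 Å apart, two anchor residues on the mobile
chain with approach conditions toward receptor groups, a native complex
that defines a six-pair COM-distance table (satisfied exactly by
construction), and a disordered N-terminal tail carrying a
phosphorylatable residue.  No attempt is made to mimic real protein
geometry, sequence or energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .errors import GenerationError
from .structure_io import Structure

__all__ = [
    "ToyDimerSpec",
    "make_toy_dimer",
    "make_jitter_trajectory",
    "make_breathing_helix",
    "make_synthetic_phospho_pocket",
]

BOND_LENGTH = 3.8      # Å, Cα virtual bond
EXCLUSION = 3.0        # Å, self-avoidance radius
CONTACT_GAP = 4.2      # Å, closest inter-chain approach in the native pose


@dataclass(frozen=True)
class ToyDimerSpec:
    """Parameters of the synthetic two-chain system.

    Chain A is the receptor, chain B the mobile partner whose first
    ``tail_length`` residues form a disordered tail carrying the
    phosphorylatable residue ``phospho_residue`` (emulating an IDR with
    a gating phospho-site).  ``anchors`` maps two B anchor residues to A
    residue groups (mirroring the two approach conditions of the staged
    protocol); ``None`` derives them from the docked interface — the
    anchors of the real system are interface residues by definition, and
    the toy pose must make its own approach conditions satisfiable.
    ``restraint_pairs`` (six (res_a, res_b) pairs, or None to auto-pick
    interface pairs) defines the native-pose distance table.
    """

    chain_lengths: tuple[int, int] = (14, 12)
    anchors: tuple | None = None
    restraint_pairs: tuple | None = None
    separation: float = 60.0
    tail_length: int = 4
    phospho_residue: int = 2
    wall_d0: float = 5.0
    seed: int = 1

    def __post_init__(self):
        n_a, n_b = self.chain_lengths
        for res_b, group in self.anchors or ():
            if not 1 <= res_b <= n_b:
                raise GenerationError(f"anchor residue {res_b} outside chain B")
            for r in group:
                if not 1 <= r <= n_a:
                    raise GenerationError(f"group residue {r} outside chain A")
        if self.restraint_pairs is not None:
            if len(self.restraint_pairs) != 6:
                raise GenerationError("restraint table needs six pairs")
            for ra, rb in self.restraint_pairs:
                if not (1 <= ra <= n_a and 1 <= rb <= n_b):
                    raise GenerationError("table residue outside chain bounds")
        if not 1 <= self.phospho_residue <= self.tail_length:
            raise GenerationError("phospho residue must lie in the tail")


def _ca_structure(coords: np.ndarray, chain: str, title: str = "",
                  first_res: int = 1) -> Structure:
    n = len(coords)
    return Structure(
        chain_id=np.full(n, chain, dtype="U4"),
        res_id=np.arange(first_res, first_res + n),
        ins_code=np.full(n, "", dtype="U1"),
        res_name=np.full(n, "ALA", dtype="U5"),
        atom_name=np.full(n, "CA", dtype="U6"),
        element=np.full(n, "C", dtype="U2"),
        coord=np.asarray(coords, dtype=float),
        mass=np.full(n, 12.011),
        title=title,
    )


def _grow_compact_chain(n: int, rng: np.random.Generator,
                        max_restarts: int = 40) -> np.ndarray:
    """Compact self-avoiding Cα trace: 3.8 Å steps confined to a sphere."""
    radius = 3.0 * n ** (1 / 3)
    for _ in range(max_restarts):
        coords = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(120):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                cand = coords[-1] + BOND_LENGTH * u
                centroid = np.mean(coords, axis=0)
                if np.linalg.norm(cand - centroid) > radius:
                    continue
                if len(coords) > 1:
                    d = np.linalg.norm(np.asarray(coords[:-1]) - cand, axis=1)
                    if d.min() < EXCLUSION:
                        continue
                coords.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            arr = np.asarray(coords)
            return arr - arr.mean(axis=0)
    raise GenerationError(f"could not grow a compact {n}-residue chain")


def _grow_tail(core: np.ndarray, length: int, rng: np.random.Generator
               ) -> np.ndarray:
    """Extended, persistence-biased tail grown off the first core bead,
    pointing away from the core.  Returned tail runs N-terminus first."""
    centroid = core.mean(axis=0)
    direction = core[0] - centroid
    direction /= np.linalg.norm(direction)
    beads = [core[0]]
    all_coords = list(core)
    for _ in range(length):
        for attempt in range(200):
            u = direction + 0.6 * rng.standard_normal(3)
            u /= np.linalg.norm(u)
            cand = beads[-1] + BOND_LENGTH * u
            d = np.linalg.norm(np.asarray(all_coords) - cand, axis=1)
            if d.min() >= EXCLUSION:
                beads.append(cand)
                all_coords.append(cand)
                direction = u
                break
        else:
            raise GenerationError("could not grow the disordered tail")
    return np.asarray(beads[1:])[::-1]  # N-terminal residue first


def _rotation_to(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector v_from onto v_to."""
    a = v_from / np.linalg.norm(v_from)
    b = v_to / np.linalg.norm(v_to)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _spin_about_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _dock(coords_a, coords_b):
    """Slide chain B along +x until the closest approach is CONTACT_GAP."""
    xs = np.arange(5.0, 120.0, 0.1)
    da = coords_a
    for dx in xs:
        placed = coords_b + np.array([dx, 0.0, 0.0])
        d = np.sqrt(np.sum(
            (da[:, None, :] - placed[None, :, :]) ** 2, axis=2))
        if d.min() >= CONTACT_GAP:
            return placed
    raise GenerationError("docking failed: chains never separate")


def _refine_dock(coords_a, coords_b, anchors, min_gap: float = 3.5):
    """Grid-search small translations of chain B that minimize the worst
    anchor-to-group COM distance without creating clashes."""
    grid = np.arange(-6.0, 6.01, 0.5)
    dx = np.arange(-3.0, 4.51, 0.5)
    shifts = np.array(np.meshgrid(dx, grid, grid)).reshape(3, -1).T
    shifts = np.vstack([[0.0, 0.0, 0.0], shifts])  # current pose first

    diff = coords_a[:, None, :] - coords_b[None, :, :]  # (na, nb, 3)
    diff = diff.reshape(-1, 3)
    # min inter-chain distance per shift, chunked to bound memory
    feasible = np.empty(len(shifts), dtype=bool)
    cost = np.full(len(shifts), np.inf)
    group_coms = [coords_a[[r - 1 for r in grp]].mean(axis=0)
                  for _, grp in anchors]
    anchor_pos = [coords_b[res_b - 1] for res_b, _ in anchors]
    for lo in range(0, len(shifts), 512):
        chunk = shifts[lo:lo + 512]
        d2 = np.sum((diff[None, :, :] - chunk[:, None, :]) ** 2, axis=2)
        feasible[lo:lo + 512] = d2.min(axis=1) >= min_gap ** 2
        c = np.zeros(len(chunk))
        for com, pos in zip(group_coms, anchor_pos):
            c = np.maximum(c, np.linalg.norm(
                (pos[None, :] + chunk) - com[None, :], axis=1))
        cost[lo:lo + 512] = c
    cost[~feasible] = np.inf
    best = int(np.argmin(cost))
    if not np.isfinite(cost[best]):
        return coords_b, _anchor_cost(coords_a, coords_b, anchors)
    return coords_b + shifts[best], float(cost[best])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _derive_anchors(coords_a, coords_b, spec: "ToyDimerSpec"):
    """Pick two anchor residues on B (outside the tail, two apart in
    sequence, like the study's anchor pair) and map each to a tight
    receptor cluster (sizes 4 and 3) around its contact bead.

    The group is chosen as the subset of nearby receptor beads whose COM
    lies closest to the anchor in the native pose — geometrically a ring
    of beads around the anchor's contact point, so the COM sits directly
    beneath the anchor at the surface.  Any pose with the anchor over
    that patch then satisfies the 5 Å approach condition (a wide capture
    basin, mirroring how the study's residue groups line one binding
    groove); a lopsided group would shift the COM deep into the chain
    and leave the wall condition satisfiable only at one exact pose."""
    from itertools import combinations

    n_b = len(coords_b)
    d = np.sqrt(np.sum(
        (coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=2))
    allowed = [
        j for j in range(spec.tail_length, n_b)
        if spec.tail_length <= j - 2 or j + 2 < n_b
    ]
    j1 = min(allowed, key=lambda j: d[:, j].min())
    j2 = j1 + 2 if j1 + 2 < n_b else j1 - 2
    anchors = []
    used: set[int] = set()
    for j, size in ((j1, 4), (j2, 3)):
        cand = [i for i in np.argsort(d[:, j]) if i not in used][:8]
        group = min(
            combinations(cand, size),
            key=lambda c: np.linalg.norm(
                coords_b[j] - coords_a[list(c)].mean(axis=0)))
        used.update(group)
        anchors.append((j + 1, tuple(int(i) + 1 for i in sorted(group))))
    return tuple(anchors)


def _anchor_cost(coords_a, coords_b, anchors) -> float:
    return max(
        float(np.linalg.norm(
            coords_b[res_b - 1]
            - coords_a[[r - 1 for r in group]].mean(axis=0)))
        for res_b, group in anchors
    )


def _auto_table(coords_a, coords_b, n_pairs: int = 6,
                band: tuple[float, float] = (4.8, 12.0)):
    """Greedy nearest inter-chain residue pairs, each residue used once.

    Pairs are drawn from a distance band chosen to mirror the character
    of a residue-COM distance table (several Å across the interface) and
    to keep the harmonic targets outside the excluded-volume radius, so
    the native pose is an unbiased minimum of restraints + potential.
    """
    d = np.sqrt(np.sum(
        (coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=2))
    pairs = []
    used_a, used_b = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if d[i, j] < band[0]:
            continue
        if d[i, j] > band[1]:
            break
        if i in used_a or j in used_b:
            continue
        pairs.append((int(i) + 1, int(j) + 1))  # residue numbering is 1-based
        used_a.add(i)
        used_b.add(j)
        if len(pairs) == n_pairs:
            return pairs
    raise GenerationError("not enough interface pairs for the table")


def make_toy_dimer(spec: ToyDimerSpec | None = None
                   ) -> tuple[Structure, Structure, Structure, RunConfig]:
    """Generate (apo A, apo B, native complex, run config).

    The native complex is built by facing the anchor residues of B toward
    the receptor groups of A and sliding to contact; the emitted config
    carries two 5 Å approach walls and six harmonic distances measured
    from that pose (so the native pose satisfies its own table exactly).
    Apo structures are the same chains randomly re-oriented with COMs
    separated by ``spec.separation`` along x.
    """
    spec = spec or ToyDimerSpec()
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.chain_lengths

    native_a = native_b = anchors = None
    for _ in range(6):  # outer loop: regrow the folds if docking stalls
        chain_a = _grow_compact_chain(n_a, rng)
        core_b = _grow_compact_chain(n_b - spec.tail_length, rng)
        tail = _grow_tail(core_b, spec.tail_length, rng)
        chain_b = np.vstack([tail, core_b])
        chain_b = chain_b - chain_b.mean(axis=0)
        native_a, native_b, anchors = _dock_until_feasible(
            chain_a, chain_b, spec, rng)
        if native_a is not None:
            break
    if native_a is None:
        raise GenerationError(
            "anchors could not be brought within the wall distance "
            "(anchors colliding or buried) — adjust the spec")

    pairs = list(spec.restraint_pairs) if spec.restraint_pairs else \
        _auto_table(native_a, native_b)
    distances = [
        float(np.linalg.norm(native_a[ra - 1] - native_b[rb - 1]))
        for ra, rb in pairs
    ]

    # Gō-style interface contacts: the bound state of the run topology is
    # defined by the native pose (inter-chain bead pairs within 8 Å)
    d_ab = np.sqrt(np.sum(
        (native_a[:, None, :] - native_b[None, :, :]) ** 2, axis=2))
    interface = [
        [["A", int(i) + 1], ["B", int(j) + 1], float(d_ab[i, j])]
        for i, j in np.argwhere(d_ab < 5.5)
    ]

    native = _merge_structures(
        _ca_structure(native_a, "A", "toy dimer native complex"),
        _ca_structure(native_b, "B"))

    # apo placement: random orientations, COMs 60 Å apart along x
    def orient(coords):
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        return (coords - coords.mean(axis=0)) @ rot.T

    apo_a_coords = orient(native_a) + np.array([-spec.separation / 2, 0, 0])
    apo_b_coords = orient(native_b) + np.array([+spec.separation / 2, 0, 0])
    apo_a = _ca_structure(apo_a_coords, "A", "toy dimer apo A")
    apo_b = _ca_structure(apo_b_coords, "B", "toy dimer apo B")

    cfg = RunConfig(
        anchors=[
            [["B", res_b], ["A", list(group)]] for res_b, group in anchors
        ],
        wall_d0=spec.wall_d0,
        native_pairs=[[["A", ra], ["B", rb]] for ra, rb in pairs],
        native_distances=distances,
        interface_contacts=interface,
        separation=spec.separation,
        phospho={
            "enabled": False,
            "chain": "B",
            "residue": spec.phospho_residue,
            "window": 2,
            "pocket": [["A", r] for r in anchors[0][1][:2]],
            "pocket_r0": 5.0,
        },
        seed=spec.seed,
    )
    return apo_a, apo_b, native, cfg


def _dock_until_feasible(chain_a, chain_b, spec: "ToyDimerSpec", rng):
    """Orient, dock and refine until the native pose satisfies its own
    approach conditions; returns (None, None, None) if 40 tries fail."""
    for _ in range(40):
        if spec.anchors is not None:
            # face the specified anchors/groups across the interface
            group_idx = sorted({r - 1 for _, grp in spec.anchors for r in grp})
            anchor_idx = [res - 1 for res, _ in spec.anchors]
            face_a = _rotation_to(
                chain_a[group_idx].mean(axis=0) - chain_a.mean(axis=0),
                np.array([1.0, 0.0, 0.0]))
            face_b = _rotation_to(
                chain_b[anchor_idx].mean(axis=0) - chain_b.mean(axis=0),
                np.array([-1.0, 0.0, 0.0]))
            ca = chain_a @ (_spin_about_x(rng.uniform(0, 2 * np.pi)) @ face_a).T
            cb = chain_b @ (_spin_about_x(rng.uniform(0, 2 * np.pi)) @ face_b).T
            cb = _dock(ca, cb)
            cb, cost = _refine_dock(ca, cb, spec.anchors)
            cand = spec.anchors
        else:
            ca = chain_a @ _random_rotation(rng).T
            cb = chain_b @ _random_rotation(rng).T
            cb = _dock(ca, cb)
            cand = _derive_anchors(ca, cb, spec)
            cb, cost = _refine_dock(ca, cb, cand)
        # the native pose must satisfy its own approach conditions
        if cost <= spec.wall_d0:
            return ca, cb, cand
        # retry with a fresh spin and a small random tilt of both chains
        chain_a = chain_a @ _random_small_tilt(rng).T
        chain_b = chain_b @ _random_small_tilt(rng).T
    return None, None, None


def _random_small_tilt(rng, max_angle: float = 0.6) -> np.ndarray:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.1, max_angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def _merge_structures(a: Structure, b: Structure) -> Structure:
    return Structure(
        chain_id=np.concatenate([a.chain_id, b.chain_id]),
        res_id=np.concatenate([a.res_id, b.res_id]),
        ins_code=np.concatenate([a.ins_code, b.ins_code]),
        res_name=np.concatenate([a.res_name, b.res_name]),
        atom_name=np.concatenate([a.atom_name, b.atom_name]),
        element=np.concatenate([a.element, b.element]),
        coord=np.vstack([a.coord, b.coord]),
        mass=np.concatenate([a.mass, b.mass]),
        title=a.title,
    )


def make_jitter_trajectory(base: Structure, sigma: float, frames: int,
                           seed: int = 0):
    """Frames = base coordinates + iid Gaussian noise σ per coordinate.

    Ground truth for fluctuation metrics: with no superposition the
    per-residue RMSF converges to σ√3.
    """
    from .dynamics import Trajectory

    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    coords = base.coord[None, :, :] + sigma * rng.standard_normal(
        (frames, base.n_atoms, 3))
    return Trajectory(
        template=base,
        step_index=np.arange(1, frames + 1),
        region=np.full(frames, "II"),
        coords=coords,
        bias_energy=np.zeros(frames),
        potential_energy=np.zeros(frames),
        provenance={"generator": "jitter", "sigma": sigma, "seed": seed},
    )


def make_breathing_helix(residues: int, amplitude: float, period: int,
                         seed: int = 0, n_periods: int = 2):
    """Ideal Cα helix (rise 1.5 Å, 100°/residue, radius 2.3 Å) breathing
    uniformly: all coordinates scale by (r0 + a·sin(2πt/period))/r0, so
    the helix radius oscillates sinusoidally with amplitude ``a`` and the
    capture-radius series is exactly proportional to the scale factor.
    """
    from .dynamics import Trajectory

    if residues < 4:
        raise ValueError("need at least 4 residues for a helix")
    r0, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    i = np.arange(residues)
    base = np.column_stack([
        r0 * np.cos(twist * i),
        r0 * np.sin(twist * i),
        rise * i,
    ])
    base -= base.mean(axis=0)
    template = _ca_structure(base, "A", "breathing helix")
    n_frames = n_periods * period
    t = np.arange(n_frames)
    scale = (r0 + amplitude * np.sin(2 * np.pi * t / period)) / r0
    coords = scale[:, None, None] * base[None, :, :]
    return Trajectory(
        template=template,
        step_index=t + 1,
        region=np.full(n_frames, "II"),
        coords=coords,
        bias_energy=np.zeros(n_frames),
        potential_energy=np.zeros(n_frames),
        provenance={"generator": "breathing_helix", "amplitude": amplitude,
                    "period": period, "seed": seed},
    )


def make_synthetic_phospho_pocket() -> Structure:
    """SYNTHETIC stand-in for a phosphate-recognition site.

    A hand-placed all-atom fragment — not derived from any crystal
    structure — with a phosphothreonine (TPO 31, chain B) whose three
    phosphate oxygens each sit 2.8–3.0 Å from a basic side-chain
    nitrogen of chain A (Lys49 NZ, Arg56 NH1, Arg127 NH1), plus a decoy
    polar residue (Asn173) beyond the 3.5 Å cutoff.  By construction the
    residue-level phosphate-contact count against {Lys49, Arg56, Arg127}
    is 3.
    """
    rows = [
        # chain, res, res_name, atom, element, x, y, z
        ("B", 31, "TPO", "CA", "C", 0.0, 0.0, 0.0),
        ("B", 31, "TPO", "CB", "C", 1.5, 0.0, 0.0),
        ("B", 31, "TPO", "OG1", "O", 2.2, 1.2, 0.0),
        ("B", 31, "TPO", "P", "P", 3.7, 1.4, 0.0),
        ("B", 31, "TPO", "O1P", "O", 4.4, 0.4, 0.9),
        ("B", 31, "TPO", "O2P", "O", 4.2, 2.8, 0.3),
        ("B", 31, "TPO", "O3P", "O", 3.9, 1.1, -1.5),
        ("A", 49, "LYS", "NZ", "N", 6.9, -0.3, 1.5),   # 2.75 Å from O1P
        ("A", 56, "ARG", "NH1", "N", 5.8, 4.5, 0.5),   # 2.36 Å from O2P
        ("A", 127, "ARG", "NH1", "N", 4.5, 0.5, -4.2), # 2.83 Å from O3P
        ("A", 173, "ASN", "ND2", "N", 9.0, 6.0, 3.0),  # decoy, > cutoff
        ("A", 173, "ASN", "OD1", "O", 9.8, 6.8, 3.4),
    ]
    return Structure(
        chain_id=np.array([r[0] for r in rows], dtype="U4"),
        res_id=np.array([r[1] for r in rows], dtype=int),
        ins_code=np.full(len(rows), "", dtype="U1"),
        res_name=np.array([r[2] for r in rows], dtype="U5"),
        atom_name=np.array([r[3] for r in rows], dtype="U6"),
        element=np.array([r[4] for r in rows], dtype="U2"),
        coord=np.array([r[5:] for r in rows], dtype=float),
        mass=np.array([
            {"C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}[r[4]]
            for r in rows
        ]),
        title="synthetic phospho pocket (not from any crystal structure)",
    )
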