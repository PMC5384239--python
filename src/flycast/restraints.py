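"""COM-distance collective variables, bias potentials and the staged
protocol schedule.

The collective variable is the distance between the mass-weighted
centers of mass of two residue groups.  Two bias modes act on it:

* ``harmonic`` — two-sided, E = ½ k (d − d₀)², used to converge the
  complex onto reference (crystal-derived) distances;
* ``upper_wall`` — one-sided, E = ½ k (d − d₀)² only for d > d₀, used as
  an approach condition ("bring these groups within d₀") that leaves the
  groups free once inside.

Bias forces are distributed to the member atoms by mass fraction within
each group (the chain rule through the COM), so the total force on group
A is exactly minus the total force on group B.

The default protocol has three regions: Region I drives two anchor CVs
below 5 Å with upper walls (pseudo-native capture), Region II is
unrestrained exploration, Region III applies six simultaneous two-sided
harmonics at distances measured from the native reference complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, SelectionError
from .geometry import com_distance
from .structure_io import Selection, Structure

__all__ = [
    "RestraintSpec",
    "ResolvedRestraint",
    "Region",
    "ProtocolSchedule",
    "bias_energy_forces",
    "pseudo_native_restraints",
    "native_complex_restraints",
]

DEFAULT_WALL_DISTANCE = 5.0   # Å, pseudo-native approach condition
DEFAULT_FORCE_CONSTANT = 10.0  # k_BT / Å²


@dataclass(frozen=True)
class RestraintSpec:
    """A COM-distance bias between two residue groups."""

    group_a: Selection
    group_b: Selection
    d0: float
    k: float = DEFAULT_FORCE_CONSTANT
    mode: str = "harmonic"  # "harmonic" | "upper_wall"
    label: str = ""

    def __post_init__(self):
        if self.d0 <= 0 or self.k <= 0:
            raise ConfigError("restraint requires d0 > 0 and k > 0")
        if self.mode not in ("harmonic", "upper_wall"):
            raise ConfigError(f"unknown restraint mode {self.mode!r}")


@dataclass
class ResolvedRestraint:
    """A RestraintSpec bound to atom/bead indices and mass fractions."""

    spec: RestraintSpec
    idx_a: np.ndarray
    idx_b: np.ndarray
    frac_a: np.ndarray  # mass fractions within group A, sum 1
    frac_b: np.ndarray

    @classmethod
    def resolve(cls, spec: RestraintSpec, idx_a, idx_b, masses
                ) -> "ResolvedRestraint":
        idx_a = np.asarray(idx_a, dtype=int)
        idx_b = np.asarray(idx_b, dtype=int)
        for name, idx in (("A", idx_a), ("B", idx_b)):
            if len(idx) == 0:
                raise SelectionError(f"restraint group {name} is empty")
        ma, mb = masses[idx_a], masses[idx_b]
        return cls(spec, idx_a, idx_b, ma / ma.sum(), mb / mb.sum())

    def cv(self, coords: np.ndarray) -> float:
        com_a = self.frac_a @ coords[self.idx_a]
        com_b = self.frac_b @ coords[self.idx_b]
        return float(np.linalg.norm(com_a - com_b))

    def energy_forces(self, coords: np.ndarray
                      ) -> tuple[float, float, np.ndarray]:
        """Return (cv value, bias energy, dense force array)."""
        com_a = self.frac_a @ coords[self.idx_a]
        com_b = self.frac_b @ coords[self.idx_b]
        sep = com_a - com_b
        d = float(np.linalg.norm(sep))
        forces = np.zeros_like(coords)
        dev = d - self.spec.d0
        if self.spec.mode == "upper_wall" and dev <= 0:
            return d, 0.0, forces
        energy = 0.5 * self.spec.k * dev * dev
        # dE/d(com_a) = k * dev * unit(sep); distributed by mass fraction
        if d > 0:
            grad_com = self.spec.k * dev * sep / d
            forces[self.idx_a] -= self.frac_a[:, None] * grad_com
            forces[self.idx_b] += self.frac_b[:, None] * grad_com
        return d, energy, forces


def bias_energy_forces(spec: RestraintSpec, structure: Structure,
                       coords: np.ndarray | None = None
                       ) -> tuple[float, float, np.ndarray]:
    """Evaluate one restraint against a Structure.

    Returns (cv distance Å, bias energy, per-atom dense forces).  Forces
    land only on atoms of the two groups; Newton's third law holds by
    construction of the COM chain rule.
    """
    from .structure_io import resolve_selection

    coords = structure.coord if coords is None else np.asarray(coords, float)
    idx_a = resolve_selection(structure, spec.group_a)
    idx_b = resolve_selection(structure, spec.group_b)
    rr = ResolvedRestraint.resolve(spec, idx_a, idx_b, structure.mass)
    return rr.energy_forces(coords)


@dataclass(frozen=True)
class Region:
    label: str            # "I" | "II" | "III"
    start: int            # inclusive step
    end: int              # exclusive step
    restraints: tuple[RestraintSpec, ...] = ()


@dataclass
class ProtocolSchedule:
    """Ordered, contiguous protocol regions over [0, total_steps)."""

    regions: list[Region]

    def __post_init__(self):
        if not self.regions:
            raise ConfigError("schedule needs at least one region")
        prev_end = self.regions[0].start
        for reg in self.regions:
            if reg.start != prev_end or reg.end <= reg.start:
                raise ConfigError(
                    "region intervals must be contiguous and increasing")
            if reg.label == "II" and reg.restraints:
                raise ConfigError("Region II must be unrestrained")
            prev_end = reg.end
        if self.regions[0].start != 0:
            raise ConfigError("schedule must start at step 0")

    @property
    def total_steps(self) -> int:
        return self.regions[-1].end

    def region_at(self, step: int) -> Region:
        for reg in self.regions:
            if reg.start <= step < reg.end:
                return reg
        raise ConfigError(f"step {step} outside schedule")

    @classmethod
    def three_region(cls, steps: tuple[int, int, int],
                     region1: list[RestraintSpec],
                     region3: list[RestraintSpec]) -> "ProtocolSchedule":
        n1, n2, n3 = steps
        return cls([
            Region("I", 0, n1, tuple(region1)),
            Region("II", n1, n1 + n2, ()),
            Region("III", n1 + n2, n1 + n2 + n3, tuple(region3)),
        ])


def _as_selection(entry, default_atoms="all") -> Selection:
    """Accept Selection | (chain, residue) | (chain, [residues])."""
    if isinstance(entry, Selection):
        return entry
    chain, res = entry
    residues = frozenset([res]) if isinstance(res, int) else frozenset(res)
    return Selection(str(chain), residues, default_atoms)


def pseudo_native_restraints(anchors, d0: float = DEFAULT_WALL_DISTANCE,
                             k: float = DEFAULT_FORCE_CONSTANT
                             ) -> list[RestraintSpec]:
    """Build the Region-I approach walls.

    ``anchors`` maps each anchor residue on the mobile partner to its
    target residue group on the receptor:
    ``[ (anchor: (chain, res), group: (chain, [residues])), ... ]``.
    Every entry becomes an upper wall at ``d0`` (default 5 Å) on the
    COM distance between the anchor residue and the group.
    """
    if not anchors:
        raise ConfigError("at least one anchor mapping is required")
    specs = []
    for i, (anchor, group) in enumerate(anchors, start=1):
        specs.append(RestraintSpec(
            group_a=_as_selection(anchor),
            group_b=_as_selection(group),
            d0=float(d0), k=float(k), mode="upper_wall",
            label=f"wall{i}",
        ))
    return specs


def native_complex_restraints(pairs,
                              reference: Structure | None = None,
                              distances=None,
                              k: float = DEFAULT_FORCE_CONSTANT
                              ) -> list[RestraintSpec]:
    """Build the Region-III two-sided harmonics.

    ``pairs`` is a list of (receptor residue, partner residue) entries,
    each ``(chain, res)`` or a Selection.  Target distances come either
    verbatim from ``distances`` or are measured from the ``reference``
    native complex via the group-COM distance (exactly one source must
    be given).
    """
    pairs = list(pairs)
    if (reference is None) == (distances is None):
        raise ConfigError(
            "give exactly one of reference complex or explicit distances")
    if distances is not None and len(distances) != len(pairs):
        raise ConfigError("one distance per residue pair required")
    specs = []
    for i, (res_a, res_b) in enumerate(pairs):
        sel_a = _as_selection(res_a)
        sel_b = _as_selection(res_b)
        if distances is not None:
            d0 = float(distances[i])
        else:
            d0 = com_distance(reference, sel_a, sel_b)
        specs.append(RestraintSpec(
            group_a=sel_a, group_b=sel_b, d0=d0, k=float(k),
            mode="harmonic", label=f"native{i + 1}",
        ))
    return specs
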