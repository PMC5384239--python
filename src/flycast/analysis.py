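"""Trajectory and structure analysis: RMSD/RMSF after least-squares
superposition, per-segment RMSD, Shrake–Rupley solvent-accessible
surface area, normalized complex SASA, polar-contact counting and the
capture-radius (radius of gyration) series.

Conventions
-----------
* RMSD/RMSF follow the Cα least-squares convention: each frame is
  superposed (mass-unweighted Kabsch) on the fit selection before the
  deviation is measured.
* Normalized complex SASA is the monomer-sum convention:
  100 × SASA(complex) / (SASA(chain 1 alone) + SASA(chain 2 alone)),
  ≤ 100 by construction since burial only removes area.
* The polar-contact criterion is a heavy-atom N/O–N/O distance cutoff
  (default 3.5 Å) with no angular term, so crystal structures without
  hydrogens work unchanged.
* SASA on coarse-grained bead trajectories uses a uniform bead radius
  (default 3.0 Å) — a stand-in not comparable to all-atom percentages;
  metadata on the series says which mode produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fnmatch import fnmatch

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import FlycastError, SelectionError
from .geometry import kabsch_superpose, radius_of_gyration
from .structure_io import Selection, Structure, resolve_selection

__all__ = [
    "VDW_RADII",
    "MetricSeries",
    "ContactCriterion",
    "rmsd_series",
    "rmsd_by_segments",
    "rmsf",
    "sasa",
    "normalized_complex_sasa",
    "contact_count",
    "capture_radius_series",
]

# Fixed published element radii (Å): Bondi-style values for protein atoms.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

CG_BEAD_RADIUS = 3.0  # Å, uniform sphere for one-bead-per-residue systems


@dataclass
class MetricSeries:
    """A time- or residue-indexed metric with units and provenance."""

    index: np.ndarray
    values: np.ndarray
    name: str
    units: str
    selection: str = ""
    regions: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.index = np.asarray(self.index)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.index) != len(self.values):
            raise ValueError("index/values length mismatch")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "index": self.index,
            "value": self.values,
            "units": self.units,
            "metric": self.name,
            "selection": self.selection,
        })
        df["region"] = self.regions if self.regions is not None else ""
        return df

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, index=False)


def _paired_indices(trajectory, reference: Structure, sel: Selection):
    idx_t = resolve_selection(trajectory.template, sel)
    idx_r = resolve_selection(reference, sel)
    if len(idx_t) == 0 or len(idx_t) != len(idx_r):
        raise SelectionError(
            f"selection {sel.describe()} resolves to {len(idx_t)} frame atoms"
            f" vs {len(idx_r)} reference atoms (must match 1:1, non-empty)")
    return idx_t, idx_r


def rmsd_series(trajectory, reference: Structure, fit_sel: Selection,
                measure_sel: Selection) -> MetricSeries:
    """Per-frame RMSD (Å) over ``measure_sel`` after superposing each
    frame onto the reference over ``fit_sel``."""
    fit_t, fit_r = _paired_indices(trajectory, reference, fit_sel)
    mes_t, mes_r = _paired_indices(trajectory, reference, measure_sel)
    ref_fit = reference.coord[fit_r]
    ref_mes = reference.coord[mes_r]
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f]
        transform, _ = kabsch_superpose(frame[fit_t], ref_fit)
        moved = transform.apply(frame[mes_t])
        out[f] = np.sqrt(np.mean(np.sum((moved - ref_mes) ** 2, axis=1)))
    return MetricSeries(trajectory.step_index, out, "rmsd", "Å",
                        measure_sel.describe(), trajectory.region)


def rmsd_by_segments(trajectory, reference: Structure, fit_sel: Selection,
                     segments: list[tuple[int, int]], chain: str,
                     atoms: str = "calpha") -> dict[str, MetricSeries]:
    """Per-segment RMSD series, all measured after the same global fit.

    ``segments`` are inclusive residue ranges on ``chain`` (author
    numbering); ranges must not overlap.
    """
    for i, (a0, a1) in enumerate(segments):
        if a1 < a0:
            raise ValueError(f"segment {i} is reversed")
        for b0, b1 in segments[i + 1:]:
            if a0 <= b1 and b0 <= a1:
                raise ValueError("segments must not overlap")
    fit_t, fit_r = _paired_indices(trajectory, reference, fit_sel)
    ref_fit = reference.coord[fit_r]

    seg_idx = []
    for start, stop in segments:
        sel = Selection.residue_range(chain, start, stop, atoms)
        idx_t, idx_r = _paired_indices(trajectory, reference, sel)
        seg_idx.append((sel, idx_t, reference.coord[idx_r]))

    out = {f"{s}-{e}": np.empty(trajectory.n_frames) for s, e in segments}
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f]
        transform, _ = kabsch_superpose(frame[fit_t], ref_fit)
        for (sel, idx_t, ref_mes), key in zip(seg_idx, out):
            moved = transform.apply(frame[idx_t])
            out[key][f] = np.sqrt(np.mean(
                np.sum((moved - ref_mes) ** 2, axis=1)))
    return {
        key: MetricSeries(trajectory.step_index, vals, f"rmsd[{key}]", "Å",
                          f"chain {chain} res {key} atoms {atoms}",
                          trajectory.region)
        for key, vals in out.items()
    }


def rmsf(trajectory, fit_sel: Selection | None, measure_sel: Selection,
         window: tuple[int, int] | None = None,
         reference: Structure | None = None) -> MetricSeries:
    """Per-residue root-mean-square fluctuation (Å) about the time-mean
    position, after per-frame superposition on ``fit_sel``.

    ``fit_sel=None`` skips superposition (identity fit).  ``window``
    restricts to frames with start ≤ step < end.  The fit reference is
    the trajectory template unless given explicitly.
    """
    reference = reference or trajectory.template
    if window is None:
        frame_ids = np.arange(trajectory.n_frames)
    else:
        start, end = window
        frame_ids = np.flatnonzero(
            (trajectory.step_index >= start) & (trajectory.step_index < end))
    if len(frame_ids) == 0:
        raise FlycastError("RMSF window contains no frames")

    mes_t = resolve_selection(trajectory.template, measure_sel)
    if len(mes_t) == 0:
        raise SelectionError("measure selection is empty")
    if fit_sel is not None:
        fit_t, fit_r = _paired_indices(trajectory, reference, fit_sel)
        ref_fit = reference.coord[fit_r]

    fitted = np.empty((len(frame_ids), len(mes_t), 3))
    for k, f in enumerate(frame_ids):
        frame = trajectory.coords[f]
        if fit_sel is not None:
            transform, _ = kabsch_superpose(frame[fit_t], ref_fit)
            fitted[k] = transform.apply(frame[mes_t])
        else:
            fitted[k] = frame[mes_t]
    mean_pos = fitted.mean(axis=0)
    msf_atom = np.mean(np.sum((fitted - mean_pos) ** 2, axis=2), axis=0)

    # aggregate per residue (mass-weighted mean of squared fluctuation)
    t = trajectory.template
    res_keys = [(str(t.chain_id[i]), int(t.res_id[i])) for i in mes_t]
    order: dict[tuple, int] = {}
    for key in res_keys:
        order.setdefault(key, len(order))
    sums = np.zeros(len(order))
    wsum = np.zeros(len(order))
    for a, key in enumerate(res_keys):
        j = order[key]
        m = t.mass[mes_t[a]]
        sums[j] += m * msf_atom[a]
        wsum[j] += m
    values = np.sqrt(sums / wsum)
    index = np.array([res for (_, res) in order])
    return MetricSeries(index, values, "rmsf", "Å", measure_sel.describe(),
                        meta={"n_frames": len(frame_ids)})


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _atom_radii(structure: Structure, radius_override: float | None
                ) -> np.ndarray:
    if radius_override is not None:
        return np.full(structure.n_atoms, float(radius_override))
    unknown = [
        f"{structure.atom_name[i]} ({structure.element[i]!r})"
        for i in range(structure.n_atoms)
        if str(structure.element[i]).upper() not in VDW_RADII
    ]
    if unknown:
        raise FlycastError(
            "no vdW radius for atoms: " + ", ".join(unknown[:5]))
    return np.array([VDW_RADII[str(e).upper()] for e in structure.element])


def sasa(structure: Structure, probe_radius: float = 1.4,
         sphere_points: int = 960,
         radius_override: float | None = None
         ) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area (Ų).

    Each atom's accessible sphere (radius r_vdW + probe) is sampled with
    a deterministic golden-spiral point set; a test point is exposed if
    no other atom's accessible sphere contains it.  Returns
    (total, per-atom) areas.  ``radius_override`` replaces the element
    radii with one uniform radius (coarse-grained bead mode).
    """
    radii = _atom_radii(structure, radius_override) + probe_radius
    coords = structure.coord
    n = structure.n_atoms
    unit = _fibonacci_sphere(sphere_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    per_atom = np.empty(n)
    # each atom gets a deterministic random re-orientation of the point
    # set: per-atom discretization errors then decorrelate instead of
    # adding coherently, tightening rigid-motion invariance of the total
    spin_rng = np.random.default_rng(1905)
    for i in range(n):
        q = spin_rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        neighbors = tree.query_ball_point(coords[i], radii[i] + rmax)
        neighbors = [j for j in neighbors if j != i]
        points = coords[i] + radii[i] * (unit @ rot.T)
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            d2 = np.sum(
                (points[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (radii[nb] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return float(per_atom.sum()), per_atom


def normalized_complex_sasa(complex_structure: Structure,
                            partition: tuple[Selection, Selection],
                            probe_radius: float = 1.4,
                            sphere_points: int = 960,
                            radius_override: float | None = None) -> float:
    """Complex SASA as a percentage of the separated-monomer sum.

    100 × SASA(complex) / (SASA(part 1 alone) + SASA(part 2 alone)).
    The two selections must cover every atom exactly once.
    """
    sel_a, sel_b = partition
    idx_a = resolve_selection(complex_structure, sel_a)
    idx_b = resolve_selection(complex_structure, sel_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise FlycastError("partition selections overlap")
    if len(idx_a) + len(idx_b) != complex_structure.n_atoms:
        raise FlycastError("partition must cover all atoms")
    total, _ = sasa(complex_structure, probe_radius, sphere_points,
                    radius_override)
    parts = 0.0
    for idx in (idx_a, idx_b):
        sub_total, _ = sasa(complex_structure.subset(idx), probe_radius,
                            sphere_points, radius_override)
        parts += sub_total
    return 100.0 * total / parts


@dataclass(frozen=True)
class ContactCriterion:
    """Heavy-atom polar contact criterion (distance only, no angle)."""

    cutoff: float = 3.5  # Å
    donor_patterns: tuple[str, ...] | None = None     # atom-name globs
    acceptor_patterns: tuple[str, ...] | None = None
    level: str = "atom"  # "atom" (pair count) | "residue" (distinct B res)

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.level not in ("atom", "residue"):
            raise ValueError("level must be 'atom' or 'residue'")

    def _matches(self, structure: Structure, idx: np.ndarray,
                 patterns) -> np.ndarray:
        if patterns is None:  # default: any polar heavy atom (N or O)
            return np.isin(structure.element[idx], ["N", "O"])
        names = structure.atom_name[idx]
        return np.array([
            any(fnmatch(str(n), p) for p in patterns) for n in names])


def contact_count(structure: Structure, sel_a: Selection, sel_b: Selection,
                  criterion: ContactCriterion | None = None) -> int:
    """Count donor–acceptor pairs (or contacted B residues) within cutoff.

    A pair qualifies if (donor-pattern atom in A, acceptor-pattern atom
    in B) or vice versa are within the cutoff.  ``level="residue"``
    counts distinct B residues with ≥ 1 qualifying pair.
    """
    criterion = criterion or ContactCriterion()
    idx_a = resolve_selection(structure, sel_a)
    idx_b = resolve_selection(structure, sel_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise FlycastError("contact selections must be disjoint")
    if len(idx_a) == 0 or len(idx_b) == 0:
        return 0
    don_a = criterion._matches(structure, idx_a, criterion.donor_patterns)
    acc_a = criterion._matches(structure, idx_a, criterion.acceptor_patterns)
    don_b = criterion._matches(structure, idx_b, criterion.donor_patterns)
    acc_b = criterion._matches(structure, idx_b, criterion.acceptor_patterns)
    d2 = np.sum(
        (structure.coord[idx_a][:, None, :]
         - structure.coord[idx_b][None, :, :]) ** 2, axis=2)
    close = d2 <= criterion.cutoff ** 2
    qualifies = close & (
        (don_a[:, None] & acc_b[None, :]) | (acc_a[:, None] & don_b[None, :]))
    if criterion.level == "atom":
        return int(qualifies.sum())
    b_res = [
        (str(structure.chain_id[j]), int(structure.res_id[j]))
        for j in idx_b
    ]
    contacted = {
        b_res[jj] for jj in np.flatnonzero(qualifies.any(axis=0))
    }
    return len(contacted)


def capture_radius_series(trajectory, selection: Selection) -> MetricSeries:
    """Per-frame radius of gyration (Å) of the selection.

    The capture radius measures the conformational reach of a segment;
    a single-point selection is rejected (its Rg is identically zero) —
    widen the selection to a residue window instead.
    """
    idx = resolve_selection(trajectory.template, selection)
    if len(idx) < 2:
        raise SelectionError(
            "capture radius needs ≥ 2 atoms/beads; single-residue bead "
            "selections are degenerate — use a window (e.g. residue ± 2)")
    masses = trajectory.template.mass[idx]
    values = np.array([
        radius_of_gyration(trajectory.coords[f][idx], masses)
        for f in range(trajectory.n_frames)
    ])
    return MetricSeries(trajectory.step_index, values, "capture_radius", "Å",
                        selection.describe(), trajectory.region)
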