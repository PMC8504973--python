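"""Geometry metrics for multi-frame pentamer coordinate files.

Implements the quantities used to interpret conformational-sensor data on
gating trajectories: per-subunit ECD/TMD twist angle, inter- and
intra-subunit distances (Calpha, Cbeta, side-chain centroid or a named
atom), pore ring radius at a chosen residue, RMSD to a reference after
optimal superposition, and per-frame asymmetry summaries.

Frames come from standard multi-MODEL PDB files (parsed with gemmi) or
from the synthetic C5 pentamer builder used in tests, where every metric
equals its construction parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Frame",
    "Trajectory",
    "RegionSpec",
    "MetricSeries",
    "load_trajectory",
    "twist_angle",
    "pair_distance",
    "ring_radius",
    "rmsd_to_reference",
    "asymmetry_stats",
    "build_synthetic_pentamer",
    "synthetic_region_spec",
]

ATOM_COLUMNS = ["chain", "resnum", "resname", "atom", "element", "x", "y", "z", "occupancy", "altloc"]

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_BACKBONE_AND_CB = {"N", "CA", "C", "O", "OXT", "CB"}


@dataclass
class Frame:
    """Atom records of one model, at most one atom per (chain, residue, atom)."""

    atoms: pd.DataFrame
    model_index: int = 1

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing column(s): {missing}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")
        dup = self.atoms.duplicated(subset=["chain", "resnum", "atom"])
        if dup.any():
            raise ValueError("duplicate (chain, residue, atom) after altloc resolution")

    @property
    def chains(self) -> list[str]:
        # preserve file order
        return list(dict.fromkeys(self.atoms["chain"]))

    def coords(self, mask=None) -> np.ndarray:
        df = self.atoms if mask is None else self.atoms[mask]
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def atom_xyz(self, chain: str, resnum: int, atom: str) -> np.ndarray:
        sel = self.atoms[
            (self.atoms["chain"] == chain)
            & (self.atoms["resnum"] == resnum)
            & (self.atoms["atom"] == atom)
        ]
        if len(sel) == 0:
            raise KeyError(
                f"model {self.model_index}: atom {atom} of residue {resnum} "
                f"in chain {chain} not found"
            )
        return sel[["x", "y", "z"]].to_numpy(dtype=float)[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        out = self.atoms.copy()
        xyz = out[["x", "y", "z"]].to_numpy(dtype=float) @ np.asarray(rotation).T + translation
        out[["x", "y", "z"]] = xyz
        return Frame(atoms=out, model_index=self.model_index)


@dataclass
class Trajectory:
    frames: list[Frame]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory holds no frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]


@dataclass(frozen=True)
class RegionSpec:
    """Residue ranges (inclusive) of the two domain layers, plus chain order."""

    ecd_range: tuple[int, int]
    tmd_range: tuple[int, int]
    chains: tuple[str, ...]

    def __post_init__(self) -> None:
        e0, e1 = self.ecd_range
        t0, t1 = self.tmd_range
        if e0 > e1 or t0 > t1:
            raise ValueError("residue ranges must be (low, high)")
        if not (e1 < t0 or t1 < e0):
            raise ValueError("ECD and TMD residue ranges must be disjoint")
        if len(self.chains) < 3:
            raise ValueError("need at least 3 chains for axis fitting")


@dataclass
class MetricSeries:
    """Per-frame, per-subunit (or per-interface) values of one metric."""

    name: str
    unit: str  # "angstrom" | "degree"
    values: pd.DataFrame  # columns: frame, label, value

    def summary(self) -> pd.DataFrame:
        """Per-frame mean and sample SD."""
        g = self.values.groupby("frame")["value"]
        return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "metric", self.name)
        out["unit"] = self.unit
        with open(path, "w") as fh:
            fh.write(f"# metric: {self.name} [{self.unit}]\n")
            out.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _frame_from_gemmi_model(model, index: int) -> Frame:
    rows = []
    for chain in model:
        for residue in chain:
            # altloc resolution: highest occupancy, ties alphabetical
            by_name: dict[str, tuple] = {}
            for atom in residue:
                key = atom.name
                cand = (-(atom.occ if atom.occ else 1.0), atom.altloc or "")
                if key not in by_name or cand < by_name[key][0]:
                    by_name[key] = (cand, atom)
            for _, atom in by_name.values():
                rows.append(
                    (
                        chain.name,
                        residue.seqid.num,
                        residue.name,
                        atom.name,
                        atom.element.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.occ if atom.occ else 1.0,
                        atom.altloc or "",
                    )
                )
    if not rows:
        raise ValueError("model contains no atoms")
    return Frame(atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS), model_index=index)


def load_trajectory(path_or_paths) -> Trajectory:
    """Read a multi-MODEL PDB file, or a list of single-model files.

    Frames keep file order; altlocs are resolved to a single atom per
    (chain, residue, atom) by highest occupancy then alphabetical altloc.
    """
    import gemmi

    paths = [path_or_paths] if isinstance(path_or_paths, (str, Path)) else list(path_or_paths)
    frames: list[Frame] = []
    for path in paths:
        st = gemmi.read_structure(str(path))
        if len(st) == 0:
            raise ValueError(f"{path}: no models found")
        for model in st:
            frames.append(_frame_from_gemmi_model(model, index=len(frames) + 1))
    return Trajectory(frames=frames, source=", ".join(str(p) for p in paths))


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _region_mask(frame: Frame, chain: str, lo: int, hi: int) -> pd.Series:
    a = frame.atoms
    return (a["chain"] == chain) & (a["resnum"] >= lo) & (a["resnum"] <= hi)


def _centroid(frame: Frame, mask) -> np.ndarray:
    pts = frame.coords(mask)
    if pts.shape[0] == 0:
        raise ValueError("empty region selection")
    return pts.mean(axis=0)


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def twist_angle(frame: Frame, regions: RegionSpec) -> pd.Series:
    """Per-subunit ECD/TMD twist, degrees.

    The pseudo-dihedral of (subunit ECD centroid, whole-pentamer ECD
    centroid, whole-pentamer TMD centroid, subunit TMD centroid); positive
    when the ECD is rotated counterclockwise relative to the TMD viewed
    from the extracellular side.  Rigid-body invariant by construction.
    """
    e_lo, e_hi = regions.ecd_range
    t_lo, t_hi = regions.tmd_range
    ecd_per_chain = {
        c: _centroid(frame, _region_mask(frame, c, e_lo, e_hi)) for c in regions.chains
    }
    tmd_per_chain = {
        c: _centroid(frame, _region_mask(frame, c, t_lo, t_hi)) for c in regions.chains
    }
    ecd_all = np.mean(list(ecd_per_chain.values()), axis=0)
    tmd_all = np.mean(list(tmd_per_chain.values()), axis=0)
    # the dihedral axis runs ECD -> TMD (extracellular -> intracellular), so
    # its positive sense is clockwise when viewed from the extracellular side;
    # negate to report counterclockwise-positive as documented
    out = {
        c: -_dihedral(ecd_per_chain[c], ecd_all, tmd_all, tmd_per_chain[c])
        for c in regions.chains
    }
    return pd.Series(out, name="twist_deg")


def _pair_point(frame: Frame, chain: str, resnum: int, mode: str, atom: str | None) -> np.ndarray:
    if mode == "CA":
        return frame.atom_xyz(chain, resnum, "CA")
    if mode == "CB":
        return frame.atom_xyz(chain, resnum, "CB")
    if mode == "named_atom":
        if atom is None:
            raise ValueError("named_atom mode requires an atom name")
        return frame.atom_xyz(chain, resnum, atom)
    if mode == "sidechain_centroid":
        a = frame.atoms
        res = a[(a["chain"] == chain) & (a["resnum"] == resnum)]
        if len(res) == 0:
            raise KeyError(
                f"model {frame.model_index}: residue {resnum} in chain {chain} not found"
            )
        resname = res["resname"].iloc[0]
        heavy = res[res["element"].str.upper() != "H"]
        if resname in _STANDARD_RESIDUES:
            heavy = heavy[~heavy["atom"].isin(_BACKBONE_AND_CB)]
        if len(heavy) == 0:
            raise KeyError(
                f"model {frame.model_index}: residue {resnum} in chain {chain} "
                "has no side-chain heavy atoms beyond Cbeta"
            )
        return heavy[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def pair_distance(
    trajectory: Trajectory,
    res_a: int,
    res_b: int,
    mode: str = "CA",
    topology: str = "inter",
    chains: tuple[str, ...] | None = None,
    atom_a: str | None = None,
    atom_b: str | None = None,
) -> MetricSeries:
    """Distances between two residue sites across the pentamer, in angstrom.

    ``topology='intra'`` pairs the sites within each subunit;
    ``topology='inter'`` pairs residue a of subunit i with residue b of
    subunit i+1 for all five ordered interfaces (chain order from the file
    unless overridden).  Site positions follow ``mode``: Calpha, Cbeta, the
    unweighted side-chain heavy-atom centroid (all heavy atoms for
    non-standard residues such as a placed bimane), or a named atom.
    """
    if topology not in ("intra", "inter"):
        raise ValueError(f"unknown topology {topology!r}")
    rows = []
    for fi, frame in enumerate(trajectory, start=1):
        order = list(chains) if chains is not None else frame.chains
        for i, chain in enumerate(order):
            partner = chain if topology == "intra" else order[(i + 1) % len(order)]
            pa = _pair_point(frame, chain, res_a, mode, atom_a)
            pb = _pair_point(frame, partner, res_b, mode, atom_b)
            label = chain if topology == "intra" else f"{chain}-{partner}"
            rows.append({"frame": fi, "label": label, "value": float(np.linalg.norm(pa - pb))})
    name = f"{topology}_{res_a}_{res_b}_{mode}"
    return MetricSeries(name=name, unit="angstrom", values=pd.DataFrame(rows))


def _fit_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points: (point on line, unit direction)."""
    center = points.mean(axis=0)
    u, s, vt = np.linalg.svd(points - center)
    if s[0] < 1e-9 or (len(s) > 1 and s[1] / s[0] > 0.999):
        raise ValueError("axis fit degenerate: centroids do not define a line")
    return center, vt[0]


def ring_radius(
    frame: Frame,
    residue_number: int,
    regions: RegionSpec,
    atom_name: str = "CA",
    subtract_vdw: bool = False,
) -> float:
    """Open-pore ring radius at one residue level, in angstrom.

    The pore axis is the total-least-squares line through the per-chain
    ECD and TMD centroids; the radius is the mean perpendicular distance
    of the ring atoms to that axis, optionally minus a 1.7 A carbon van
    der Waals radius.  A geometric stand-in for channel-tracing free
    radii; no numeric equivalence with those is implied.
    """
    e_lo, e_hi = regions.ecd_range
    t_lo, t_hi = regions.tmd_range
    centroids = []
    for c in regions.chains:
        centroids.append(_centroid(frame, _region_mask(frame, c, e_lo, e_hi)))
        centroids.append(_centroid(frame, _region_mask(frame, c, t_lo, t_hi)))
    center, direction = _fit_axis(np.asarray(centroids))

    ring = []
    for c in regions.chains:
        try:
            ring.append(frame.atom_xyz(c, residue_number, atom_name))
        except KeyError:
            continue
    if len(ring) < 3:
        raise ValueError(
            f"ring atom {atom_name} of residue {residue_number} present in "
            f"{len(ring)} chains; need >= 3"
        )
    ring_pts = np.asarray(ring)
    sv = np.linalg.svd(ring_pts - ring_pts.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("ring atoms are collinear; ring/axis geometry degenerate")
    ring_arr = ring_pts - center
    perp = ring_arr - np.outer(ring_arr @ direction, direction)
    radius = float(np.mean(np.linalg.norm(perp, axis=1)))
    return radius - 1.7 if subtract_vdw else radius


def _correspondence(frame: Frame, selection: dict | None) -> pd.DataFrame:
    a = frame.atoms
    if selection:
        for col, val in selection.items():
            a = a[a[col] == val] if np.isscalar(val) else a[a[col].isin(val)]
    return a.sort_values(["chain", "resnum", "atom"])


def rmsd_to_reference(
    trajectory: Trajectory,
    reference: Frame,
    selection: dict | None = None,
    superpose: bool = True,
) -> MetricSeries:
    """Per-frame RMSD to a reference frame, in angstrom.

    Atoms correspond by (chain, residue, atom); with ``superpose`` the
    optimal proper rotation (Kabsch) and translation are removed first.
    ``selection`` filters atom-table columns, e.g. ``{"atom": "CA"}``.
    """
    ref = _correspondence(reference, selection)
    ref_keys = list(zip(ref["chain"], ref["resnum"], ref["atom"]))
    ref_xyz = ref[["x", "y", "z"]].to_numpy(dtype=float)
    rows = []
    for fi, frame in enumerate(trajectory, start=1):
        mob = _correspondence(frame, selection)
        mob_keys = list(zip(mob["chain"], mob["resnum"], mob["atom"]))
        if mob_keys != ref_keys:
            raise ValueError(
                f"frame {fi}: atom correspondence mismatch with reference "
                f"({len(mob_keys)} vs {len(ref_keys)} atoms)"
            )
        xyz = mob[["x", "y", "z"]].to_numpy(dtype=float)
        if superpose:
            mu_a, mu_b = xyz.mean(axis=0), ref_xyz.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_xyz - mu_b, xyz - mu_a)
            moved = (xyz - mu_a) @ rot.as_matrix().T + mu_b
        else:
            moved = xyz
        rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_xyz) ** 2, axis=1))))
        rows.append({"frame": fi, "label": "all", "value": rmsd})
    return MetricSeries(name="rmsd", unit="angstrom", values=pd.DataFrame(rows))


def asymmetry_stats(metric: MetricSeries) -> pd.DataFrame:
    """Per-frame mean, sample SD and range of a per-interface metric.

    Quantifies how asymmetric the five interfaces are in each frame; a
    shrinking SD along a trajectory signals symmetrization.
    """
    per_frame = metric.values.groupby("frame")["value"]
    counts = per_frame.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"frames {bad}: need >= 2 values per frame for asymmetry stats")
    out = pd.DataFrame(
        {
            "mean": per_frame.mean(),
            "sd": per_frame.std(ddof=1),
            "range": per_frame.max() - per_frame.min(),
        }
    )
    return out


def variability_declines(metric: MetricSeries) -> bool:
    """True when the per-frame SD at the last frame is below the first's."""
    stats = asymmetry_stats(metric)
    return bool(stats["sd"].iloc[-1] < stats["sd"].iloc[0])


# ---------------------------------------------------------------------------
# synthetic pentamer
# ---------------------------------------------------------------------------

def synthetic_region_spec(n_chains: int = 5, n_ecd: int = 5, n_tmd: int = 5) -> RegionSpec:
    chains = tuple("ABCDEFGHIJ"[:n_chains])
    return RegionSpec(ecd_range=(1, n_ecd), tmd_range=(101, 100 + n_tmd), chains=chains)


def build_synthetic_pentamer(
    radius: float = 20.0,
    layer_separation: float = 40.0,
    twist_deg: float = 0.0,
    compaction_scale: float = 1.0,
    n_chains: int = 5,
    n_ecd: int = 5,
    n_tmd: int = 5,
    model_index: int = 1,
) -> Frame:
    """Ideal Cn pseudo-Calpha pentamer with controllable twist and compaction.

    Each chain carries an ECD arc (residues 1..n_ecd, upper layer, radius
    scaled by ``compaction_scale`` and rotated by ``twist_deg`` about the
    symmetry axis) and a TMD arc (residues 101.., lower layer).  By
    construction every geometry metric equals its input parameter: twist
    angles equal ``twist_deg``, TMD ring radii equal ``radius``, and ECD
    inter-subunit distances scale exactly with ``compaction_scale``.
    """
    if n_chains < 3:
        raise ValueError("need at least 3 chains")
    rows = []
    arc_step = 4.0  # degrees between consecutive pseudo-residues of an arc
    for i in range(n_chains):
        chain = "ABCDEFGHIJ"[i]
        base = 360.0 * i / n_chains
        for j in range(n_ecd):
            ang = math.radians(base + twist_deg + j * arc_step)
            r = radius * compaction_scale
            rows.append(
                (chain, 1 + j, "GLY", "CA", "C",
                 r * math.cos(ang), r * math.sin(ang), layer_separation / 2.0, 1.0, "")
            )
        for j in range(n_tmd):
            ang = math.radians(base + j * arc_step)
            rows.append(
                (chain, 101 + j, "GLY", "CA", "C",
                 radius * math.cos(ang), radius * math.sin(ang), -layer_separation / 2.0, 1.0, "")
            )
    return Frame(atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS), model_index=model_index)
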