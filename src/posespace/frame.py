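"""Binding-site-anchored coordinate system.

Docked complexes from different poses (and different receptor models) are
made comparable not by structural superposition but by expressing ligand
core atoms in a local frame anchored to four receptor Cα atoms: one origin
residue and three axis residues.  The frame is rebuilt from each pose's own
complex, so receptor-side flexibility is absorbed into the anchors rather
than propagated into the features.

The basis is built by modified Gram–Schmidt over the three axis directions
(anchor Cα minus origin Cα) in their listed order, with the third axis
replaced by x̂ × ŷ, signed to point along the orthogonalized third direction.
The result is always orthonormal and right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import yaml

if TYPE_CHECKING:  # avoid circular import; io imports AnchorSpec from here
    import biotite.structure as struc
    from .io import EnsembleTable


class FrameError(ValueError):
    """Raised for unresolvable or degenerate anchor geometry."""


@dataclass(frozen=True)
class ResidueSelector:
    """One anchor atom: chain id, residue number, atom name (Cα by default)."""

    chain: str
    res_id: int
    atom_name: str = "CA"

    def __str__(self) -> str:
        return f"{self.chain}/{self.res_id}/{self.atom_name}"


@dataclass(frozen=True)
class AnchorSpec:
    """Four Cα anchors: an origin residue plus three axis residues."""

    origin: ResidueSelector
    axis1: ResidueSelector
    axis2: ResidueSelector
    axis3: ResidueSelector

    @property
    def selectors(self) -> tuple[ResidueSelector, ...]:
        return (self.origin, self.axis1, self.axis2, self.axis3)

    @classmethod
    def from_yaml(cls, path) -> "AnchorSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        def sel(d):
            return ResidueSelector(
                chain=str(d["chain"]),
                res_id=int(d["res_id"]),
                atom_name=str(d.get("atom_name", "CA")),
            )
        return cls(origin=sel(raw["origin"]), axis1=sel(raw["axis1"]),
                   axis2=sel(raw["axis2"]), axis3=sel(raw["axis3"]))

    def to_yaml(self, path) -> None:
        names = ("origin", "axis1", "axis2", "axis3")
        payload = {
            name: {"chain": s.chain, "res_id": s.res_id, "atom_name": s.atom_name}
            for name, s in zip(names, self.selectors)
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class AnchorFrame:
    """Origin (Å) plus a right-handed orthonormal basis (columns = axes)."""

    origin: np.ndarray  # (3,)
    basis: np.ndarray   # (3, 3), columns are unit axes

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise FrameError("basis is not orthonormal to 1e-9")
        if np.linalg.det(self.basis) < 0:
            raise FrameError("basis is left-handed")

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World coordinates → frame coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.basis

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.basis.T + self.origin


def resolve_anchor_coords(receptor: "struc.AtomArray", spec: AnchorSpec) -> np.ndarray:
    """Resolve the four anchor selectors to Cα coordinates, shape (4, 3).

    Each selector must match exactly one atom in the receptor.
    """
    out = np.empty((4, 3), dtype=float)
    for i, sel in enumerate(spec.selectors):
        mask = (
            (receptor.chain_id == sel.chain)
            & (receptor.res_id == sel.res_id)
            & (receptor.atom_name == sel.atom_name)
        )
        n = int(mask.sum())
        if n != 1:
            raise FrameError(
                f"anchor {sel} matched {n} atoms; expected exactly 1"
            )
        out[i] = receptor.coord[mask][0]
    return out


def build_frame_from_coords(anchor_coords: np.ndarray) -> AnchorFrame:
    """Build the anchored frame from resolved anchor positions (4×3 Å):
    row 0 is the origin Cα, rows 1–3 the axis Cαs in listed order."""
    anchor_coords = np.asarray(anchor_coords, dtype=float)
    if anchor_coords.shape != (4, 3):
        raise FrameError(f"expected (4, 3) anchor coordinates, got {anchor_coords.shape}")
    origin = anchor_coords[0]
    d = anchor_coords[1:] - origin  # rows: axis direction vectors
    if np.linalg.cond(d) > 1e6:
        raise FrameError("anchor axis vectors are (nearly) linearly dependent")
    # modified Gram-Schmidt over the listed order
    x = d[0] / np.linalg.norm(d[0])
    y = d[1] - (d[1] @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise FrameError("axis2 is collinear with axis1")
    y = y / ny
    z3 = d[2] - (d[2] @ x) * x - (d[2] @ y) * y
    z = np.cross(x, y)  # right-handed completion
    if z3 @ z < 0:
        raise FrameError(
            "anchor geometry is left-handed: third axis opposes x̂ × ŷ"
        )
    return AnchorFrame(origin=origin, basis=np.column_stack([x, y, z]))


def build_frame(receptor: "struc.AtomArray", spec: AnchorSpec) -> AnchorFrame:
    """Resolve anchors in the receptor and build the frame."""
    return build_frame_from_coords(resolve_anchor_coords(receptor, spec))


def to_spherical(points: np.ndarray) -> np.ndarray:
    """Cartesian frame coordinates → (r, θ, φ).

    r = |p|; θ = arccos(z/r) ∈ [0, π], polar angle from +z (θ := 0 at the
    origin); φ = atan2(y, x) ∈ [−π, π), azimuth from +x toward +y (φ := 0 on
    the z-axis).  Total function: works on a single point or an (n, 3) array.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    r = np.linalg.norm(p, axis=1)
    safe_r = np.where(r > 0, r, 1.0)
    theta = np.arccos(np.clip(p[:, 2] / safe_r, -1.0, 1.0))
    theta[r == 0] = 0.0
    phi = np.arctan2(p[:, 1], p[:, 0])
    phi[phi == np.pi] = -np.pi  # half-open convention [-π, π)
    out = np.column_stack([r, theta, phi])
    return out[0] if single else out


def spherical_to_cartesian(sph: np.ndarray) -> np.ndarray:
    """(r, θ, φ) → Cartesian; inverse of :func:`to_spherical`."""
    s = np.atleast_2d(np.asarray(sph, dtype=float))
    r, theta, phi = s[:, 0], s[:, 1], s[:, 2]
    out = np.column_stack([
        r * np.sin(theta) * np.cos(phi),
        r * np.sin(theta) * np.sin(phi),
        r * np.cos(theta),
    ])
    return out[0] if np.asarray(sph).ndim == 1 else out


@dataclass
class FeatureMatrix:
    """Per-pose core-atom coordinates in the anchored frame.

    ``cartesian`` is N×3m (x, y, z per core label); ``spherical`` is N×3m
    (r, θ, φ per core label).  Rows are sorted by pose key, so the layout is
    deterministic for a given ensemble.
    """

    keys: list[tuple[str, str, int]]
    cartesian: np.ndarray
    spherical: np.ndarray
    core_labels: list[str]
    compound_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        n, m3 = self.cartesian.shape
        if self.spherical.shape != (n, m3) or m3 != 3 * len(self.core_labels):
            raise FrameError("feature matrix shape mismatch")
        if len(self.keys) != n:
            raise FrameError("feature matrix key count mismatch")
        self.compound_ids = [k[0] for k in self.keys]

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def n_core_atoms(self) -> int:
        return len(self.core_labels)

    def cartesian_points(self) -> np.ndarray:
        """Cartesian features reshaped to (N, m, 3)."""
        return self.cartesian.reshape(len(self), self.n_core_atoms, 3)


def extract_features(ensemble: "EnsembleTable") -> FeatureMatrix:
    """Express each pose's core atoms in that pose's anchored frame.

    For every pose, the frame is rebuilt from the anchors resolved in that
    pose's own complex; the compound's core atoms (in canonical label order)
    are transformed into it and returned both as Cartesian and as spherical
    coordinates.  The output is invariant to any rigid transform applied
    jointly to receptor and ligand.
    """
    poses = ensemble.sorted_poses()
    if not poses:
        raise FrameError("empty ensemble")
    m = ensemble.core_map.n_core_atoms
    cart = np.empty((len(poses), 3 * m), dtype=float)
    sph = np.empty_like(cart)
    keys = []
    for i, pose in enumerate(poses):
        frame = build_frame_from_coords(ensemble.anchor_coords[pose.key])
        core_names = ensemble.core_map.atoms_for(pose.compound_id)
        local = frame.to_frame(pose.atom_coords(core_names))
        cart[i] = local.ravel()
        sph[i] = to_spherical(local).ravel()
        keys.append(pose.key)
    return FeatureMatrix(
        keys=keys, cartesian=cart, spherical=sph,
        core_labels=list(ensemble.core_map.core_labels),
    )
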