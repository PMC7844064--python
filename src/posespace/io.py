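"""Reading, validation and writing of pose ensembles.

A pose ensemble consists of one PDB complex per docked pose (ligand plus the
receptor chains needed for anchor lookup), a CSV score table keyed by
(compound_id, site_id, pose_index), and a core-atom map naming, per compound,
the atoms of the shared scaffold core in a canonical label order.  This module
joins and validates those pieces into an :class:`EnsembleTable`, the input to
the downstream frame/cluster/embedding stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .frame import AnchorSpec, resolve_anchor_coords

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("compound_id", "site_id", "pose_index", "chemscore")


class EnsembleError(ValueError):
    """Raised when an ensemble's pieces are inconsistent or malformed."""


@dataclass(frozen=True)
class LigandSelector:
    """Identifies the ligand inside a pose complex by residue name and,
    optionally, chain.  Docking exporters vary; the default residue name
    is ``LIG``."""

    res_name: str = "LIG"
    chain: str | None = None

    def __str__(self) -> str:  # used in error messages
        chain = self.chain if self.chain is not None else "*"
        return f"(res_name={self.res_name!r}, chain={chain})"


@dataclass
class PoseRecord:
    """One docked pose: identity, score and ordered ligand atoms (Å)."""

    compound_id: str
    site_id: str
    pose_index: int
    chemscore: float
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    source_path: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise EnsembleError(
                f"pose {self.key}: coords must be (n, 3), got {self.coords.shape}"
            )
        if not (len(self.atom_names) == len(self.elements) == len(self.coords)):
            raise EnsembleError(f"pose {self.key}: atom fields have unequal lengths")
        if len(set(self.atom_names)) != len(self.atom_names):
            raise EnsembleError(f"pose {self.key}: duplicate atom names")
        if not np.all(np.isfinite(self.coords)):
            raise EnsembleError(f"pose {self.key}: non-finite coordinates")
        if self.pose_index < 1:
            raise EnsembleError(f"pose {self.key}: pose_index must be >= 1")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.compound_id, self.site_id, self.pose_index)

    def atom_coords(self, names: Sequence[str]) -> np.ndarray:
        """Coordinates of the named atoms, in the given order."""
        index = {n: i for i, n in enumerate(self.atom_names)}
        try:
            rows = [index[n] for n in names]
        except KeyError as exc:
            raise EnsembleError(
                f"pose {self.key}: core atom {exc.args[0]!r} not present"
            ) from None
        return self.coords[rows]


@dataclass
class CoreAtomMap:
    """Canonical core labels plus, per compound, the matching atom names."""

    core_labels: list[str]
    per_compound: dict[str, list[str]]

    def __post_init__(self) -> None:
        m = len(self.core_labels)
        if m < 3:
            raise EnsembleError(f"core map needs >= 3 labels, got {m}")
        for cid, names in self.per_compound.items():
            if len(names) != m:
                raise EnsembleError(
                    f"core map for compound {cid!r} has {len(names)} atoms, expected {m}"
                )

    @property
    def n_core_atoms(self) -> int:
        return len(self.core_labels)

    def atoms_for(self, compound_id: str) -> list[str]:
        try:
            return self.per_compound[compound_id]
        except KeyError:
            raise EnsembleError(
                f"compound {compound_id!r} missing from core-atom map"
            ) from None


@dataclass
class EnsembleTable:
    """Validated, joined pose ensemble for one binding site.

    ``anchor_coords`` holds, per pose key, the resolved Cα positions of the
    four frame anchors (origin, axis1..axis3; shape (4, 3)) taken from that
    pose's own complex, so the anchored frame can be rebuilt per pose without
    keeping receptor structures in memory.
    """

    poses: list[PoseRecord]
    core_map: CoreAtomMap
    anchors: AnchorSpec
    anchor_coords: dict[tuple[str, str, int], np.ndarray]
    site_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [p.key for p in self.poses]
        if len(set(keys)) != len(keys):
            raise EnsembleError("duplicate (compound, site, pose) keys in ensemble")
        sites = {p.site_id for p in self.poses}
        if sites and sites != {self.site_id}:
            raise EnsembleError(f"poses span sites {sorted(sites)}, expected {self.site_id!r}")
        missing = sorted({p.compound_id for p in self.poses} - set(self.core_map.per_compound))
        if missing:
            raise EnsembleError(f"compounds missing from core map: {missing}")

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def compound_ids(self) -> list[str]:
        return sorted({p.compound_id for p in self.poses})

    def sorted_poses(self) -> list[PoseRecord]:
        return sorted(self.poses, key=lambda p: p.key)


def _infer_element(atom_name: str, element_field: str) -> str:
    """PDB element column when present, else leading letters of the atom name."""
    el = element_field.strip()
    if el:
        return el.capitalize()
    stripped = atom_name.strip().lstrip("0123456789")
    letters = "".join(c for c in stripped if c.isalpha())
    if not letters:
        raise EnsembleError(f"cannot infer element from atom name {atom_name!r}")
    # two-letter elements in ligands are rare; PDB convention right-justifies
    # single-letter elements, so the first letter is the element symbol
    return letters[0].capitalize()


def parse_pose_complex(
    path: str | Path,
    selector: LigandSelector = LigandSelector(),
) -> tuple[dict, struc.AtomArray]:
    """Parse one pose-complex PDB into a ligand block and the receptor.

    Returns ``(ligand, receptor)`` where ``ligand`` is a dict with keys
    ``atom_names``, ``elements``, ``coords`` (file atom order preserved) and
    ``receptor`` is a biotite :class:`AtomArray` of every non-ligand atom.

    Raises :class:`EnsembleError` if no residue, or more than one residue,
    matches the selector.
    """
    path = Path(path)
    try:
        structure = PDBFile.read(str(path)).get_structure(model=1)
    except Exception as exc:
        raise EnsembleError(f"{path}: unparseable PDB ({exc})") from exc

    mask = structure.res_name == selector.res_name
    if selector.chain is not None:
        mask &= structure.chain_id == selector.chain
    ligand = structure[mask]
    if ligand.array_length() == 0:
        raise EnsembleError(f"{path}: no ligand matches selector {selector}")
    residues = set(zip(ligand.chain_id, ligand.res_id))
    if len(residues) > 1:
        raise EnsembleError(
            f"{path}: {len(residues)} ligand residues match selector {selector}; "
            "expected exactly one"
        )
    elements = [
        _infer_element(name, el)
        for name, el in zip(ligand.atom_name, ligand.element)
    ]
    block = {
        "atom_names": [str(n) for n in ligand.atom_name],
        "elements": elements,
        "coords": np.array(ligand.coord, dtype=float),
    }
    return block, structure[~mask]


def write_pose_complex(
    path: str | Path,
    pose: PoseRecord,
    receptor: struc.AtomArray,
    ligand_res_name: str = "LIG",
    ligand_chain: str = "L",
) -> None:
    """Write receptor atoms plus the pose's ligand as a single-model PDB."""
    n = len(pose.atom_names)
    lig = struc.AtomArray(n)
    lig.coord = np.asarray(pose.coords, dtype=np.float32)
    lig.chain_id = np.full(n, ligand_chain)
    lig.res_id = np.ones(n, dtype=int)
    lig.res_name = np.full(n, ligand_res_name)
    lig.atom_name = np.array(pose.atom_names)
    lig.element = np.array([e.upper() for e in pose.elements])
    lig.hetero = np.ones(n, dtype=bool)
    combined = receptor + lig
    pdb = PDBFile()
    pdb.set_structure(combined)
    pdb.write(str(path))


def load_scores(path: str | Path) -> pd.DataFrame:
    """Load the pose score table.

    CSV, UTF-8, header required with columns
    ``compound_id,site_id,pose_index,chemscore``.  One row per pose; duplicate
    (compound, site, pose) keys are rejected with the offending rows listed.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str, "site_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise EnsembleError(f"{path}: score table missing columns {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: score table is empty (header only)", stacklevel=2)
        return df[list(SCORE_COLUMNS)]
    for col, kind in (("pose_index", "integer"), ("chemscore", "numeric")):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()].tolist()
        if bad:
            raise EnsembleError(
                f"{path}: non-{kind} {col!r} in rows {bad} "
                f"(values {df.loc[bad, col].tolist()})"
            )
        df[col] = coerced
    df["pose_index"] = df["pose_index"].astype(int)
    dup = df.duplicated(subset=["compound_id", "site_id", "pose_index"], keep=False)
    if dup.any():
        raise EnsembleError(
            f"{path}: duplicate (compound, site, pose) keys in rows "
            f"{df.index[dup].tolist()}"
        )
    return df[list(SCORE_COLUMNS)]


def load_core_map(path: str | Path) -> CoreAtomMap:
    """Core-atom map CSV: header ``compound_id,<label>,...``; one row per
    compound giving its atom name for each canonical core label."""
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "compound_id":
        raise EnsembleError(f"{path}: first column must be 'compound_id'")
    labels = list(df.columns[1:])
    per_compound = {
        row["compound_id"]: [row[lab] for lab in labels] for _, row in df.iterrows()
    }
    return CoreAtomMap(core_labels=labels, per_compound=per_compound)


def assemble_ensemble(
    pose_files: Mapping[tuple[str, str, int], str | Path],
    scores: pd.DataFrame,
    core_map: CoreAtomMap,
    anchors: AnchorSpec,
    selector: LigandSelector = LigandSelector(),
    provenance: dict | None = None,
) -> EnsembleTable:
    """Join pose files and the score table into a validated ensemble.

    ``pose_files`` maps (compound_id, site_id, pose_index) to the complex PDB
    path.  Every score row must have a pose file and vice versa; the core map
    must cover every compound; every core atom must exist in every pose.
    """
    score_keys = {
        (r.compound_id, r.site_id, int(r.pose_index)): float(r.chemscore)
        for r in scores.itertuples()
    }
    orphan_scores = sorted(set(score_keys) - set(pose_files))
    orphan_files = sorted(set(pose_files) - set(score_keys))
    if orphan_scores or orphan_files:
        raise EnsembleError(
            f"score/pose-file mismatch: {len(orphan_scores)} score rows without "
            f"files {orphan_scores[:5]}, {len(orphan_files)} files without "
            f"scores {orphan_files[:5]}"
        )
    if not score_keys:
        raise EnsembleError("empty ensemble: no score rows")
    sites = {k[1] for k in score_keys}
    if len(sites) != 1:
        raise EnsembleError(f"ensemble spans multiple sites: {sorted(sites)}")
    (site_id,) = sites

    poses: list[PoseRecord] = []
    anchor_coords: dict[tuple[str, str, int], np.ndarray] = {}
    for key in sorted(score_keys):
        compound_id, site, pose_index = key
        path = pose_files[key]
        ligand, receptor = parse_pose_complex(path, selector)
        pose = PoseRecord(
            compound_id=compound_id,
            site_id=site,
            pose_index=pose_index,
            chemscore=score_keys[key],
            atom_names=ligand["atom_names"],
            elements=ligand["elements"],
            coords=ligand["coords"],
            source_path=str(path),
        )
        pose.atom_coords(core_map.atoms_for(compound_id))  # validates presence
        anchor_coords[key] = resolve_anchor_coords(receptor, anchors)
        poses.append(pose)

    counts = pd.Series([p.compound_id for p in poses]).value_counts()
    logger.info("assembled ensemble: %d poses, per-compound counts:\n%s",
                len(poses), counts.to_string())
    return EnsembleTable(
        poses=poses,
        core_map=core_map,
        anchors=anchors,
        anchor_coords=anchor_coords,
        site_id=site_id,
        provenance=provenance or {},
    )


def write_ensemble(
    ensemble: EnsembleTable,
    out_dir: str | Path,
    receptor_for: Mapping[tuple[str, str, int], struc.AtomArray],
) -> dict[tuple[str, str, int], Path]:
    """Write one PDB per pose plus the score CSV; returns key → file path."""
    out_dir = Path(out_dir)
    pose_dir = out_dir / "poses"
    pose_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[tuple[str, str, int], Path] = {}
    rows = []
    for pose in ensemble.sorted_poses():
        fname = f"{pose.compound_id}_{pose.site_id}_{pose.pose_index:04d}.pdb"
        fpath = pose_dir / fname
        write_pose_complex(fpath, pose, receptor_for[pose.key])
        paths[pose.key] = fpath
        rows.append((pose.compound_id, pose.site_id, pose.pose_index, pose.chemscore))
    scores = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    scores.to_csv(out_dir / "scores.csv", index=False)
    return paths
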