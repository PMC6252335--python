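"""Reading, writing and validation of landmark-configuration data.

A cohort is a set of spatially dense quasi-landmark configurations (one
K x 3 coordinate table per subject) sharing a single template: a
triangulated mesh whose vertices define the landmark topology, a
bilateral left-right pair map, and a list of midline landmarks on the
sagittal plane.  Fathers and offspring are linked by a pairing table and
carry age / sex / BMI covariates.

File conventions (all indices 0-based, documented in file headers):

* template:   ``template.ply`` (or ``.obj``) + ``bilateral_pairs.csv``
  (columns ``left,right``) + ``midline.csv`` (column ``index``)
* configurations: per-subject ``<subject_id>.xyz`` text files (K rows,
  3 whitespace-separated columns) under ``configs/``, or a single
  ``configs.npz`` archive keyed by subject id
* pairing:    ``pairing.csv`` with columns ``offspring_id,father_id``
* covariates: ``covariates.csv`` with columns ``subject_id,age,sex,bmi``
  (sex as ``M``/``F`` strings)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "sex", "bmi")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TemplateMesh:
    """Shared landmark topology: mesh + bilateral pair map + midline set.

    Every landmark index appears exactly once, either on one side of a
    bilateral pair or in the midline list; the pair map is an involution.
    The left-right axis is x, and after alignment the sagittal plane is
    x = 0 (reflection negates the x coordinate).
    """

    vertices: np.ndarray  # (K, 3)
    faces: np.ndarray  # (F, 3) int
    bilateral_pairs: np.ndarray  # (P, 2) int, columns (left, right)
    midline: np.ndarray  # (M,) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        self.bilateral_pairs = np.asarray(self.bilateral_pairs, dtype=int).reshape(-1, 2)
        self.midline = np.asarray(self.midline, dtype=int).reshape(-1)
        self.validate()

    @property
    def vertex_count(self) -> int:
        return self.vertices.shape[0]

    @property
    def reflection_permutation(self) -> np.ndarray:
        """Index permutation that relabels each landmark with its mirror."""
        perm = np.arange(self.vertex_count)
        left, right = self.bilateral_pairs[:, 0], self.bilateral_pairs[:, 1]
        perm[left] = right
        perm[right] = left
        return perm

    def validate(self) -> None:
        k = self.vertex_count
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= k):
            raise ValueError("face indices out of range")
        paired = self.bilateral_pairs.reshape(-1)
        seen = np.concatenate([paired, self.midline])
        if len(seen) != k or len(np.unique(seen)) != k:
            raise ValueError(
                "every landmark must appear exactly once in bilateral_pairs or midline"
            )
        perm = self.reflection_permutation
        if not np.array_equal(perm[perm], np.arange(k)):
            raise ValueError("bilateral pair map is not an involution")
        if np.any(perm[self.midline] != self.midline):
            raise ValueError("midline landmarks must be fixed points of the pair map")


@dataclass
class LandmarkConfiguration:
    """One subject's K x 3 quasi-landmark coordinates."""

    subject_id: str
    coords: np.ndarray
    template_ref: str = "template"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"{self.subject_id}: coords must be K x 3")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.subject_id}: non-finite coordinates")


@dataclass
class PairedCohort:
    """Father and offspring configurations linked one-to-one.

    ``pairing`` maps offspring_id -> father_id; each father appears at
    most once (one child per family).  ``covariates`` is indexed by
    subject_id with columns age (years), sex (M/F) and bmi (kg/m2).
    """

    fathers: list[LandmarkConfiguration]
    offspring: list[LandmarkConfiguration]
    pairing: dict[str, str]
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    @property
    def offspring_ids(self) -> list[str]:
        return [c.subject_id for c in self.offspring]

    def father_of(self, offspring_id: str) -> str:
        return self.pairing[offspring_id]

    def father_array(self) -> np.ndarray:
        """(n, K, 3) father coordinates in pairing order of the offspring list."""
        by_id = {c.subject_id: c.coords for c in self.fathers}
        return np.stack([by_id[self.pairing[o]] for o in self.offspring_ids])

    def offspring_array(self) -> np.ndarray:
        return np.stack([c.coords for c in self.offspring])

    def offspring_sex(self) -> np.ndarray:
        """Array of 'M'/'F' per offspring, in offspring order."""
        return self.covariates.loc[self.offspring_ids, "sex"].to_numpy()

    def covariate_matrix(self, subject_ids: list[str]) -> pd.DataFrame:
        """Numeric covariate block (sex mapped M->0, F->1) for given subjects."""
        block = self.covariates.loc[subject_ids, list(COVARIATE_COLUMNS)].copy()
        block["sex"] = block["sex"].map({"M": 0.0, "F": 1.0})
        return block.astype(float)

    def validate(self) -> None:
        off_ids = self.offspring_ids
        fat_ids = [c.subject_id for c in self.fathers]
        if len(set(off_ids)) != len(off_ids) or len(set(fat_ids)) != len(fat_ids):
            raise ValueError("duplicate subject_id")
        if set(self.pairing) != set(off_ids):
            raise ValueError("pairing keys must equal offspring ids")
        mapped = list(self.pairing.values())
        if len(set(mapped)) != len(mapped):
            raise ValueError("pairing is not one-to-one (a father appears twice)")
        if set(mapped) != set(fat_ids):
            raise ValueError("pairing values must equal father ids")
        all_ids = off_ids + fat_ids
        missing = set(all_ids) - set(self.covariates.index)
        if missing:
            raise ValueError(f"missing covariates for {sorted(missing)[:5]}")
        block = self.covariates.loc[all_ids, list(COVARIATE_COLUMNS)]
        if block.isna().any().any():
            raise ValueError("paired subject with incomplete covariates")
        ks = {c.coords.shape[0] for c in self.fathers + self.offspring}
        if len(ks) > 1:
            raise ValueError("configurations disagree on landmark count")


@dataclass
class ScalarField:
    """Per-landmark scalar (e.g. h2 per landmark, as a fraction)."""

    values: np.ndarray
    name: str = "value"
    template_ref: str = "template"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar field contains non-finite values")


# ---------------------------------------------------------------------------
# Template IO
# ---------------------------------------------------------------------------


def write_template(template: TemplateMesh, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mesh_path = out_dir / "template.ply"
    trimesh.Trimesh(
        vertices=template.vertices, faces=template.faces, process=False
    ).export(mesh_path, encoding="ascii")
    pairs_path = out_dir / "bilateral_pairs.csv"
    pd.DataFrame(template.bilateral_pairs, columns=["left", "right"]).to_csv(
        pairs_path, index=False
    )
    midline_path = out_dir / "midline.csv"
    pd.DataFrame({"index": template.midline}).to_csv(midline_path, index=False)
    return {"mesh": mesh_path, "pairs": pairs_path, "midline": midline_path}


def read_template(template_dir: str | Path) -> TemplateMesh:
    template_dir = Path(template_dir)
    mesh_path = None
    for ext in ("ply", "obj"):
        cand = template_dir / f"template.{ext}"
        if cand.exists():
            mesh_path = cand
            break
    if mesh_path is None:
        raise FileNotFoundError(f"no template.ply/obj in {template_dir}")
    mesh = trimesh.load_mesh(mesh_path, process=False)
    pairs = pd.read_csv(template_dir / "bilateral_pairs.csv")[["left", "right"]]
    midline = pd.read_csv(template_dir / "midline.csv")["index"]
    return TemplateMesh(
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.faces),
        bilateral_pairs=pairs.to_numpy(),
        midline=midline.to_numpy(),
    )


# ---------------------------------------------------------------------------
# Cohort IO
# ---------------------------------------------------------------------------


def write_cohort(cohort: PairedCohort, out_dir: str | Path, archive: bool = False) -> Path:
    """Write a cohort as pairing.csv + covariates.csv + configurations.

    ``archive=True`` stores all configurations in one ``configs.npz``
    keyed by subject_id; otherwise one ``configs/<id>.xyz`` text file
    per subject.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"offspring_id": list(cohort.pairing), "father_id": list(cohort.pairing.values())}
    ).to_csv(out_dir / "pairing.csv", index=False)
    cov = cohort.covariates.copy()
    cov.index.name = "subject_id"
    cov.to_csv(out_dir / "covariates.csv")
    configs = cohort.fathers + cohort.offspring
    if archive:
        np.savez_compressed(
            out_dir / "configs.npz", **{c.subject_id: c.coords for c in configs}
        )
    else:
        cfg_dir = out_dir / "configs"
        cfg_dir.mkdir(exist_ok=True)
        for c in configs:
            np.savetxt(cfg_dir / f"{c.subject_id}.xyz", c.coords, fmt="%.17g")
    return out_dir


def _load_configs(config_dir: Path) -> dict[str, np.ndarray]:
    archive = config_dir / "configs.npz"
    if archive.exists():
        with np.load(archive) as data:
            return {key: np.array(data[key]) for key in data.files}
    cfg_dir = config_dir / "configs"
    out: dict[str, np.ndarray] = {}
    for path in sorted(cfg_dir.glob("*.xyz")):
        out[path.stem] = np.loadtxt(path, ndmin=2)
    return out


def read_cohort(config_dir: str | Path, template: TemplateMesh) -> PairedCohort:
    """Read and validate a cohort directory.

    Pairs in which either subject lacks a configuration or any covariate
    are excluded (with a logged count); structural violations (landmark
    count mismatch, duplicate ids, empty pairing) are hard errors.
    """
    config_dir = Path(config_dir)
    pairing_df = pd.read_csv(config_dir / "pairing.csv", dtype=str)
    if pairing_df.empty:
        raise ValueError("no pairs")
    if pairing_df["offspring_id"].duplicated().any():
        raise ValueError("duplicate subject_id in pairing table")
    cov = pd.read_csv(config_dir / "covariates.csv", dtype={"subject_id": str})
    if cov["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in covariate table")
    cov = cov.set_index("subject_id")
    coords = _load_configs(config_dir)
    for sid, arr in coords.items():
        if arr.shape != (template.vertex_count, 3):
            raise ValueError(
                f"{sid}: configuration shape {arr.shape} does not match template "
                f"({template.vertex_count}, 3)"
            )

    kept, excluded = [], 0
    for off_id, fat_id in pairing_df.itertuples(index=False):
        ok = all(
            sid in coords
            and sid in cov.index
            and not cov.loc[sid, list(COVARIATE_COLUMNS)].isna().any()
            for sid in (off_id, fat_id)
        )
        if ok:
            kept.append((off_id, fat_id))
        else:
            excluded += 1
    if excluded:
        logger.info("excluded %d pair(s) with missing configuration or covariates", excluded)
    if not kept:
        raise ValueError("no pairs")

    offspring = [LandmarkConfiguration(o, coords[o]) for o, _ in kept]
    fathers = [LandmarkConfiguration(f, coords[f]) for _, f in kept]
    keep_ids = [o for o, _ in kept] + [f for _, f in kept]
    return PairedCohort(
        fathers=fathers,
        offspring=offspring,
        pairing=dict(kept),
        covariates=cov.loc[keep_ids],
    )


# ---------------------------------------------------------------------------
# Scalar fields and matrices
# ---------------------------------------------------------------------------


def write_scalar_field(
    field: ScalarField, template: TemplateMesh, path_stem: str | Path
) -> dict[str, Path]:
    """Emit a per-landmark scalar as CSV and as a PLY with a vertex property."""
    if field.values.shape[0] != template.vertex_count:
        raise ValueError("scalar field length does not match template")
    path_stem = Path(path_stem)
    path_stem.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path_stem.with_suffix(".csv")
    pd.DataFrame({"index": np.arange(len(field.values)), field.name: field.values}).to_csv(
        csv_path, index=False
    )
    ply_path = path_stem.with_suffix(".ply")
    _write_scalar_ply(ply_path, template, field)
    return {"csv": csv_path, "ply": ply_path}


def _write_scalar_ply(path: Path, template: TemplateMesh, field: ScalarField) -> None:
    # ASCII PLY with the scalar as a per-vertex float property.
    k, f = template.vertex_count, template.faces.shape[0]
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {k}",
        "property float x",
        "property float y",
        "property float z",
        f"property float {field.name}",
        f"element face {f}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, s in zip(template.vertices, field.values):
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {s:.9g}")
    for tri in template.faces:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    path.write_text("\n".join(lines) + "\n")


def read_scalar_field(csv_path: str | Path) -> ScalarField:
    df = pd.read_csv(csv_path)
    name = [c for c in df.columns if c != "index"][0]
    return ScalarField(values=df[name].to_numpy(), name=name)


def save_matrix(values: np.ndarray, path_stem: str | Path, csv_export: bool = False) -> Path:
    """Save a matrix as an .npz archive (optionally also CSV)."""
    path_stem = Path(path_stem)
    path_stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path_stem.with_suffix(".npz"), values=values)
    if csv_export:
        np.savetxt(path_stem.with_suffix(".csv"), values, delimiter=",")
    return path_stem.with_suffix(".npz")


def load_matrix(path: str | Path) -> np.ndarray:
    with np.load(path) as data:
        return np.array(data["values"])
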