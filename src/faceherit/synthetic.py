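"""Synthetic father-offspring cohorts with known modular heritability.

The generator emulates corresponded, bilaterally symmetric quasi-landmark
configurations under a purely additive one-parent one-offspring model:
for each planted module and latent factor, a father draws a genetic
score g_f ~ N(0, Va) and the offspring score is g_o = g_f/2 +
sqrt(3 Va / 4) * xi, so cov(g_f, g_o) = Va/2 and var(g_o) = Va.
Independent environmental scores e ~ N(0, Ve) are added per individual.
Each score displaces the module's landmarks along a smooth, bilaterally
symmetric loading field (Gaussian bumps along the surface normal,
orthonormalized within module).  Linear covariate effects (age, sex,
BMI), iid coordinate noise, and a nuisance rigid motion + scale per
subject complete the observation model.

The planted truth for a module is h2 = Va / (Va + Ve + Vn) with Vn the
noise variance along a (unit-norm) loading direction, i.e. noise_sd**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_shapes import LandmarkConfiguration, PairedCohort, TemplateMesh
from .procrustes import similarity_tangent

# population parameters used to standardize covariates before applying loadings
_COV_DIST = {
    "offspring": {"age": (15.5, 0.5), "bmi": (21.0, 2.5)},
    "father": {"age": (45.0, 5.0), "bmi": (26.0, 3.0)},
}


@dataclass
class ModuleGenetics:
    """Per-module variance components of the generating model."""

    va: float  # additive genetic variance
    ve: float  # environmental variance
    n_factors: int = 2

    def __post_init__(self) -> None:
        if self.va < 0 or self.ve < 0 or self.n_factors < 1:
            raise ValueError("variances must be >= 0 and n_factors >= 1")


@dataclass
class SimulationDesign:
    """Full specification of a synthetic cohort (deterministic given seed)."""

    grid_shape: tuple[int, int] = (22, 11)
    n_pairs: int = 300
    modules: dict[int, ModuleGenetics] = field(
        default_factory=lambda: {
            0: ModuleGenetics(0.08, 0.02),
            1: ModuleGenetics(0.06, 0.04),
            2: ModuleGenetics(0.04, 0.06),
            3: ModuleGenetics(0.02, 0.08),
        }
    )
    partition: np.ndarray | None = None  # landmark -> module label; default quadrants
    # shared factors spanning several modules make co-inheritance nested
    # (module < supergroup < face), the structure the hierarchical
    # segmentation assumes; keys are tuples of module labels
    shared_factors: dict[tuple[int, ...], ModuleGenetics] = field(default_factory=dict)
    loading_smoothness: float = 0.35
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.03, "sex": 0.05, "bmi": 0.08}
    )
    noise_sd: float = 0.01
    rigid_rotation_deg: float = 10.0
    rigid_translation: float = 0.1
    log_scale_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise ValueError("n_pairs must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_design(
    grid_shape: tuple[int, int] = (22, 11),
    n_pairs: int = 300,
    seed: int = 0,
    h2: tuple[float, ...] = (0.8, 0.6, 0.4, 0.2),
    total_var: float = 0.1,
    n_factors: int = 2,
    noise_sd: float = 0.01,
    hierarchical: bool = False,
    **kwargs,
) -> SimulationDesign:
    """Convenience builder: one module per requested h2, Va + Ve = total_var.

    With ``hierarchical`` a shared factor is added per module pair
    ({0,1} and {2,3}) at the module factor variance and the mean h2
    ratio, so co-inheritance is nested without changing per-module h2
    when the module h2 values are equal.
    """
    modules = {
        m: ModuleGenetics(va=h * total_var, ve=(1.0 - h) * total_var, n_factors=n_factors)
        for m, h in enumerate(h2)
    }
    shared: dict[tuple[int, ...], ModuleGenetics] = {}
    if hierarchical:
        for pair in [(0, 1), (2, 3)]:
            mean_h2 = float(np.mean([h2[m] for m in pair]))
            shared[pair] = ModuleGenetics(
                va=mean_h2 * total_var, ve=(1.0 - mean_h2) * total_var, n_factors=1
            )
    return SimulationDesign(
        grid_shape=grid_shape,
        n_pairs=n_pairs,
        modules=modules,
        shared_factors=shared,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------


def make_template(grid_shape: tuple[int, int]) -> TemplateMesh:
    """Bilaterally symmetric paraboloid "face" sampled on a mirrored grid.

    z = -(x^2 + y^2)/2 on a rows x cols grid with x in [-1, 1] mirrored
    around 0; columns left/right of center form the bilateral pairs and,
    for odd column counts, the center column is the midline.
    """
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise ValueError("grid_shape must be at least 2 x 2")
    xs = np.linspace(-1.0, 1.0, cols)
    ys = np.linspace(-1.0, 1.0, rows)
    xx, yy = np.meshgrid(xs, ys)  # shape (rows, cols)
    zz = -(xx**2 + yy**2) / 2.0
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    pairs = [
        (i * cols + j, i * cols + (cols - 1 - j))
        for i in range(rows)
        for j in range(cols // 2)
    ]
    midline = (
        [i * cols + (cols - 1) // 2 for i in range(rows)] if cols % 2 == 1 else []
    )
    faces = []
    for i in range(rows - 1):
        for j in range(cols - 1):
            a = i * cols + j
            faces.append((a, a + 1, a + cols))
            faces.append((a + 1, a + cols + 1, a + cols))
    return TemplateMesh(
        vertices=vertices,
        faces=np.array(faces, dtype=int),
        bilateral_pairs=np.array(pairs, dtype=int),
        midline=np.array(midline, dtype=int),
    )


def default_partition(template: TemplateMesh, n_modules: int = 4) -> np.ndarray:
    """Bilaterally symmetric spatial partition (upper/lower x inner/outer)."""
    if n_modules != 4:
        raise ValueError("the default partition plants 4 modules")
    x, y = template.vertices[:, 0], template.vertices[:, 1]
    ax = np.round(np.abs(x), 9)  # exact mirror symmetry despite float noise
    upper = y > np.median(y)
    outer = ax > np.median(ax)
    return (2 * upper + outer).astype(int)


def _surface_normals(vertices: np.ndarray) -> np.ndarray:
    # analytic unit normals of z = -(x^2 + y^2)/2: (x, y, 1)/norm
    n = np.column_stack([vertices[:, 0], vertices[:, 1], np.ones(len(vertices))])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _loading_fields(
    template: TemplateMesh, idx: np.ndarray, n_factors: int, smoothness: float
) -> np.ndarray:
    """Orthonormal, bilaterally symmetric loading fields on landmark set idx.

    Each factor is a Gaussian bump (in (|x|, y)) centered on one of the
    set's landmarks, displacing along the surface normal; depending on
    |x| only, the bump weight is mirror-symmetric, and the normal field
    makes the displacement a symmetric vector field.  Each factor is
    projected off the set's similarity tangent space (translations,
    rotations, scaling) so planted variance is genuine shape variation
    that survives Procrustes alignment, then the factors are
    orthonormalized (QR); both steps keep symmetry.
    """
    verts = template.vertices
    normals = _surface_normals(verts)
    k = template.vertex_count
    # candidate centers on the non-negative-x side, spread over the set
    cand = idx[verts[idx, 0] >= -1e-12]
    if cand.size == 0:
        cand = idx
    order = np.argsort(verts[cand, 1] + 0.13 * np.abs(verts[cand, 0]))
    picks = cand[order[np.linspace(0, cand.size - 1, n_factors).astype(int)]]
    fields = np.zeros((n_factors, k, 3))
    sim_basis = similarity_tangent(verts[idx]) if idx.size >= 3 else None
    for f, center in enumerate(picks):
        cx, cy = np.abs(verts[center, 0]), verts[center, 1]
        d2 = (np.abs(verts[idx, 0]) - cx) ** 2 + (verts[idx, 1] - cy) ** 2
        bump = np.exp(-d2 / (2.0 * smoothness**2))
        local = bump[:, None] * normals[idx]
        if sim_basis is not None:
            vec = local.reshape(-1)
            local = (vec - sim_basis @ (sim_basis.T @ vec)).reshape(-1, 3)
        fields[f, idx] = local
    flat = fields.reshape(n_factors, -1).T  # (3K, F)
    q, r = np.linalg.qr(flat)
    q = q * np.sign(np.diag(r))[None, :]  # deterministic orientation
    return q.T.reshape(n_factors, k, 3)


def _module_loadings(
    template: TemplateMesh,
    partition: np.ndarray,
    modules: dict[int, ModuleGenetics],
    smoothness: float,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Per-module orthonormal loading fields (see _loading_fields)."""
    out: dict[int, np.ndarray] = {}
    for label, genetics in modules.items():
        idx = np.flatnonzero(partition == label)
        if idx.size == 0:
            raise ValueError(f"module {label} has no landmarks")
        out[label] = _loading_fields(template, idx, genetics.n_factors, smoothness)
    return out


def _covariate_loadings(template: TemplateMesh, smoothness: float) -> dict[str, np.ndarray]:
    """Unit-norm symmetric fields through which covariates deform the face."""
    verts = template.vertices
    normals = _surface_normals(verts)
    centers = {"age": (0.0, 0.6), "sex": (0.0, -0.6), "bmi": (0.55, 0.0)}
    out = {}
    for name, (cx, cy) in centers.items():
        d2 = (np.abs(verts[:, 0]) - cx) ** 2 + (verts[:, 1] - cy) ** 2
        bump = np.exp(-d2 / (2.0 * (1.6 * smoothness) ** 2))
        fld = bump[:, None] * normals
        out[name] = fld / np.linalg.norm(fld)
    return out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_deg, max_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def simulate_cohort(
    design: SimulationDesign, template: TemplateMesh | None = None
) -> PairedCohort:
    """Generate a PairedCohort realizing the design (bit-identical per seed).

    One master RNG (the design seed) draws scores and covariates in a
    fixed order; per-subject nuisance terms (noise, rigid motion) come
    from counter-split streams ``[seed, tag, subject_index]`` so results
    do not depend on iteration order.
    """
    if template is None:
        template = make_template(design.grid_shape)
    partition = (
        default_partition(template)
        if design.partition is None
        else np.asarray(design.partition, dtype=int)
    )
    if partition.shape[0] != template.vertex_count:
        raise ValueError("partition length must equal landmark count")
    perm = template.reflection_permutation
    if not np.array_equal(partition, partition[perm]):
        raise ValueError("planted partition must be bilaterally symmetric")

    rng = np.random.default_rng(design.seed)
    n = design.n_pairs
    loadings = _module_loadings(
        template, partition, design.modules, design.loading_smoothness, rng
    )
    cov_fields = _covariate_loadings(template, design.loading_smoothness)

    # covariates
    f_age = rng.normal(*_COV_DIST["father"]["age"], size=n)
    f_bmi = rng.normal(*_COV_DIST["father"]["bmi"], size=n)
    o_age = rng.normal(*_COV_DIST["offspring"]["age"], size=n)
    o_bmi = rng.normal(*_COV_DIST["offspring"]["bmi"], size=n)
    o_sex = rng.choice(np.array(["M", "F"]), size=n)

    base = template.vertices
    fathers = np.tile(base, (n, 1, 1))
    offspring = np.tile(base, (n, 1, 1))

    # genetic + environmental factor scores
    def _add_factor(fields_f: np.ndarray, genetics: ModuleGenetics) -> None:
        g_f = rng.normal(0.0, np.sqrt(genetics.va), size=n)
        g_o = 0.5 * g_f + np.sqrt(0.75 * genetics.va) * rng.normal(size=n)
        e_f = rng.normal(0.0, np.sqrt(genetics.ve), size=n)
        e_o = rng.normal(0.0, np.sqrt(genetics.ve), size=n)
        nonlocal fathers, offspring
        fathers += (g_f + e_f)[:, None, None] * fields_f
        offspring += (g_o + e_o)[:, None, None] * fields_f

    for label, genetics in design.modules.items():
        for f in range(genetics.n_factors):
            _add_factor(loadings[label][f], genetics)

    # supergroup factors spanning several modules (nested co-inheritance)
    for labels, genetics in design.shared_factors.items():
        idx = np.flatnonzero(np.isin(partition, labels))
        if idx.size == 0:
            raise ValueError(f"shared factor over empty module set {labels!r}")
        fields = _loading_fields(
            template, idx, genetics.n_factors, 1.5 * design.loading_smoothness
        )
        for f in range(genetics.n_factors):
            _add_factor(fields[f], genetics)

    # covariate effects on standardized covariate values
    def _z(values, cohort, name):
        mu, sd = _COV_DIST[cohort][name]
        return (values - mu) / sd

    eff = design.covariate_effects
    fathers += (eff.get("age", 0.0) * _z(f_age, "father", "age"))[:, None, None] * cov_fields["age"]
    fathers += (eff.get("bmi", 0.0) * _z(f_bmi, "father", "bmi"))[:, None, None] * cov_fields["bmi"]
    offspring += (eff.get("age", 0.0) * _z(o_age, "offspring", "age"))[:, None, None] * cov_fields["age"]
    offspring += (eff.get("bmi", 0.0) * _z(o_bmi, "offspring", "bmi"))[:, None, None] * cov_fields["bmi"]
    offspring += (eff.get("sex", 0.0) * (o_sex == "F").astype(float))[:, None, None] * cov_fields["sex"]

    # per-subject nuisance: measurement noise, then rigid motion + scale
    def _nuisance(coords, tag, i):
        sub_rng = np.random.default_rng([design.seed, tag, i])
        noisy = coords + sub_rng.normal(0.0, design.noise_sd, size=coords.shape)
        rot = _random_rotation(sub_rng, design.rigid_rotation_deg)
        scale = np.exp(sub_rng.normal(0.0, design.log_scale_sd))
        trans = sub_rng.uniform(-design.rigid_translation, design.rigid_translation, size=3)
        return scale * (noisy @ rot.T) + trans

    father_cfgs, offspring_cfgs, pairing = [], [], {}
    rows = []
    for i in range(n):
        fid, oid = f"F{i:05d}", f"O{i:05d}"
        father_cfgs.append(LandmarkConfiguration(fid, _nuisance(fathers[i], 7, i)))
        offspring_cfgs.append(LandmarkConfiguration(oid, _nuisance(offspring[i], 11, i)))
        pairing[oid] = fid
        rows.append((fid, f_age[i], "M", f_bmi[i]))
        rows.append((oid, o_age[i], o_sex[i], o_bmi[i]))

    covariates = pd.DataFrame(
        rows, columns=["subject_id", "age", "sex", "bmi"]
    ).set_index("subject_id")
    return PairedCohort(
        fathers=father_cfgs,
        offspring=offspring_cfgs,
        pairing=pairing,
        covariates=covariates,
    )


def true_heritability(design: SimulationDesign, module_label: int) -> float:
    """Planted h2 = Va / (Va + Ve + Vn) for a module.

    Vn is the noise variance along a generating loading direction; the
    loadings are unit-norm in the 3K coordinate space, so iid coordinate
    noise with sd ``noise_sd`` contributes Vn = noise_sd**2.
    """
    if module_label not in design.modules:
        raise KeyError(f"unknown module label {module_label!r}")
    g = design.modules[module_label]
    denom = g.va + g.ve + design.noise_sd**2
    return 0.0 if denom == 0 else g.va / denom
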