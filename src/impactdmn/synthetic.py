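"""Synthetic inputs for the whole pipeline, generated with seeded RNGs.

Four generators stand in for data that cannot ship with the package: a toy
two-shell tetrahedral head mesh (white core with radial axonal fibers,
cortical gray rind, thin CSF gap, outer skull shell); Gaussian-blob DMN
template z-maps on a voxel grid; a parametric surrogate for the
explicit-dynamics impact-simulation library, producing per-element peak
shear energy rate (gray matter) and peak von Mises stress (skull) with a
known monotone structure in velocity and impact distance; and AR(1)
network-mixture rsfMRI cohorts with a planted patient connectivity
deficit.  Every generator is bit-reproducible for a fixed (spec, seed).

The surrogate replaces a finite-element head model with the closed form

    e_j = A (v/v_ref)^alpha exp(-d_j/lambda) (1 + beta cos(theta))
            (R_ref/R)^gamma_R (1 + eta_j)

for gray elements (eta_j truncated Gaussian noise) and an analogous linear
law ``B v (R_ref/R)^gamma_R exp(-d_j/lambda)`` for skull von Mises stress.
It is a desk-scale stand-in with the qualitative structure the learning
layer needs (monotone in velocity, decaying with distance from impact,
sharper impactors more damaging), not a mechanical simulation.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.spatial import Delaunay

from .damage import PeakFieldSet, dmn_damage_percent, skull_fractured
from .ml import ImpactScenario, FeatureVector, extract_features, make_scenario

__all__ = [
    "HEAD_OUTER_RADIUS",
    "REGION_BANDS",
    "HeadMesh",
    "NetworkTemplate",
    "SurrogateParams",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "SimulationRecord",
    "build_toy_head_mesh",
    "build_dmn_template",
    "default_dmn_template",
    "surrogate_peak_fields",
    "build_scenario_library",
    "default_library_grid",
    "library_to_frame",
    "synth_rsfmri_cohort",
    "write_vtk",
    "read_vtk",
]

#: Outer skull radius of the toy head (m), roughly half a head's diameter.
HEAD_OUTER_RADIUS = 0.09

#: Tissue bands of the toy head as fractions of the outer radius:
#: label -> (inner, outer).
REGION_BANDS = {
    "white": (0.0, 0.45),
    "gray": (0.45, 0.70),
    "csf": (0.70, 0.77),
    "skull": (0.77, 10.0),
}

_REGION_CODES = {"gray": 0, "white": 1, "skull": 2, "csf": 3}
_CODE_REGIONS = {v: k for k, v in _REGION_CODES.items()}


@dataclass(frozen=True)
class HeadMesh:
    """Tetrahedral head mesh with tissue labels and white-matter fibers.

    ``nodes`` (N, 3) in m; ``tets`` (M, 4) node indices; ``region_label``
    (M,) strings from {gray, white, skull, csf}; ``fiber_direction`` (M, 3)
    unit vectors for white elements, NaN elsewhere.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_label: np.ndarray
    fiber_direction: np.ndarray

    def __post_init__(self) -> None:
        if self.tets.min() < 0 or self.tets.max() >= len(self.nodes):
            raise ValueError("tets reference invalid node indices")
        white = self.region_label == "white"
        norms = np.linalg.norm(self.fiber_direction[white], axis=1)
        if white.any() and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("white-matter fiber directions must be unit vectors")
        if not np.all(np.isnan(self.fiber_direction[~white])):
            raise ValueError("fiber directions exist only on white elements")

    @property
    def element_centroid(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    @property
    def element_volume(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.abs(np.einsum(
            "ij,ij->i", p[:, 0] - p[:, 3],
            np.cross(p[:, 1] - p[:, 3], p[:, 2] - p[:, 3]))) / 6.0

    def elements_of(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region_label == region)


def _region_of(radii: np.ndarray) -> np.ndarray:
    frac = radii / HEAD_OUTER_RADIUS
    out = np.empty(len(radii), dtype=object)
    for name, (lo, hi) in REGION_BANDS.items():
        out[(frac >= lo) & (frac < hi)] = name
    return out.astype(str)


def build_toy_head_mesh(resolution: int, seed: int = 0) -> HeadMesh:
    """Tetrahedralized two-shell ball standing in for a head.

    A cubic lattice of ``2*resolution + 1`` points per axis is clipped to
    the outer skull radius, jittered by a seeded perturbation (to avoid
    degenerate co-spherical Delaunay configurations) and tetrahedralized.
    Elements are labeled by centroid radius into white core / gray rind /
    CSF gap / skull shell; white elements get radial fiber directions.
    Deterministic for fixed (resolution, seed).
    """
    if resolution < 2:
        raise ValueError(f"resolution must be >= 2, got {resolution}")
    n = 2 * resolution + 1
    ax = np.linspace(-HEAD_OUTER_RADIUS, HEAD_OUTER_RADIUS, n)
    pts = np.array(np.meshgrid(ax, ax, ax, indexing="ij")).reshape(3, -1).T
    pts = pts[np.linalg.norm(pts, axis=1) <= HEAD_OUTER_RADIUS * 1.0001]
    # project the outermost lattice points onto the skull surface so the
    # shell is closed
    r = np.linalg.norm(pts, axis=1)
    spacing = ax[1] - ax[0]
    on_surf = r > HEAD_OUTER_RADIUS - 0.5 * spacing
    with np.errstate(invalid="ignore"):
        pts[on_surf] = pts[on_surf] * (HEAD_OUTER_RADIUS / r[on_surf])[:, None]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D657368]))
    interior = ~on_surf & (r > 1e-12)
    pts[interior] += rng.uniform(-0.02, 0.02, size=pts[interior].shape) * spacing

    tri = Delaunay(pts)
    tets = tri.simplices
    p = pts[tets]
    vol6 = np.einsum("ij,ij->i", p[:, 0] - p[:, 3],
                     np.cross(p[:, 1] - p[:, 3], p[:, 2] - p[:, 3]))
    # orient positively and drop slivers
    flip = vol6 < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    keep = np.abs(vol6) / 6.0 > 1e-9 * spacing ** 3
    tets = tets[keep]

    cents = pts[tets].mean(axis=1)
    radii = np.linalg.norm(cents, axis=1)
    region = _region_of(radii)

    fibers = np.full((len(tets), 3), np.nan)
    white = region == "white"
    wc = cents[white]
    wr = np.linalg.norm(wc, axis=1)
    fw = np.where(wr[:, None] > 1e-12, wc / np.maximum(wr, 1e-12)[:, None],
                  np.array([0.0, 0.0, 1.0]))
    fw /= np.linalg.norm(fw, axis=1)[:, None]
    fibers[white] = fw
    return HeadMesh(nodes=pts, tets=tets, region_label=region,
                    fiber_direction=fibers)


# ---------------------------------------------------------------------------
# Network templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkTemplate:
    """A resting-state network template: voxel z-map + affine + name."""

    z_map: np.ndarray
    affine: np.ndarray
    name: str = "DMN"

    def __post_init__(self) -> None:
        if self.z_map.ndim != 3 or min(self.z_map.shape) < 4:
            raise ValueError("z_map must be a 3-D grid of shape >= (4, 4, 4)")
        if abs(np.linalg.det(np.asarray(self.affine))) < 1e-15:
            raise ValueError("affine must be invertible")

    def binarize(self, z_threshold: float = 3.1) -> np.ndarray:
        """Binary network mask, ``z_map > z_threshold`` (strict)."""
        return self.z_map > z_threshold

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.z_map.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img_or_path, name: str = "DMN") -> "NetworkTemplate":
        img = (img_or_path if isinstance(img_or_path, nib.Nifti1Image)
               else nib.load(str(img_or_path)))
        return cls(z_map=np.asarray(img.get_fdata(), dtype=float),
                   affine=np.asarray(img.affine, dtype=float), name=name)


def build_dmn_template(grid_shape, affine, blob_centers, blob_sd: float,
                       peak_z: float, name: str = "DMN") -> NetworkTemplate:
    """Sum-of-Gaussian-blobs template z-map, rescaled so its max is peak_z.

    Blob centers are world coordinates (m); *blob_sd* the isotropic spatial
    standard deviation (m).
    """
    if peak_z <= 0:
        raise ValueError("peak_z must be positive")
    centers = np.atleast_2d(np.asarray(blob_centers, dtype=float))
    if centers.size == 0:
        raise ValueError("at least one blob center is required")
    affine = np.asarray(affine, dtype=float)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    world = (vox @ affine.T)[:, :3]
    z = np.zeros(len(world))
    for c in centers:
        d2 = np.sum((world - c) ** 2, axis=1)
        z += np.exp(-d2 / (2.0 * blob_sd ** 2))
    z = z.reshape(grid_shape)
    return NetworkTemplate(z_map=z * (peak_z / z.max()), affine=affine, name=name)


def default_dmn_template(grid_shape=(16, 16, 16), peak_z: float = 6.0) -> NetworkTemplate:
    """The package's default DMN template on a grid covering the toy head.

    Two midline blobs (a posterior and an anterior node) inside the gray
    rind, echoing the posterior-cingulate / medial-prefrontal core of the
    default-mode network.
    """
    R = HEAD_OUTER_RADIUS
    span = 2.2 * R
    voxel = span / np.asarray(grid_shape)
    affine = np.diag([*voxel, 1.0])
    affine[:3, 3] = -span / 2 + voxel / 2
    rind = 0.63 * R
    centers = [(-rind * 0.95, 0.0, 0.25 * R), (rind * 0.95, 0.0, 0.25 * R)]
    return build_dmn_template(grid_shape, affine, centers,
                              blob_sd=0.30 * R, peak_z=peak_z)


# ---------------------------------------------------------------------------
# Surrogate impact-simulation library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the parametric impact surrogate.

    amplitude (MJ/m^3/s) sets the gray-matter shear-energy-rate scale at
    the reference velocity; velocity_exponent the power law in
    v/reference_velocity; decay_length (m) the exponential decay with
    distance from the impact point; angle_gain the perpendicularity bonus
    ``1 + beta cos(theta)``; sharpness_exponent/reference_radius the
    impactor-curvature power law; skull_gain (MPa s/m) the linear skull
    von Mises law; noise_cv the coefficient of variation of the
    multiplicative truncated-Gaussian noise.
    """

    amplitude: float = 2.0
    reference_velocity: float = 8.0
    velocity_exponent: float = 2.0
    decay_length: float = 0.06
    angle_gain: float = 0.5
    sharpness_exponent: float = 0.25
    reference_radius: float = 0.036
    skull_gain: float = 9.0
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.amplitude, self.reference_velocity, self.decay_length,
               self.reference_radius) <= 0:
            raise ValueError("amplitude, reference_velocity, decay_length and "
                             "reference_radius must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _scenario_rng(params: SurrogateParams, scenario: ImpactScenario):
    tag = zlib.crc32(repr(scenario.key()).encode())
    return np.random.default_rng(np.random.SeedSequence([params.seed, tag]))


def surrogate_peak_fields(scenario: ImpactScenario, mesh: HeadMesh,
                          params: SurrogateParams) -> PeakFieldSet:
    """Per-element peak fields of one impact under the parametric surrogate.

    Deterministic given (scenario, params.seed); with ``noise_cv = 0`` the
    gray-element field is strictly increasing in velocity and strictly
    decreasing in distance from the impact point.
    """
    v = scenario.velocity
    if not 0.0 < v <= 16.0:
        raise ValueError(f"velocity must be in (0, 16] m/s, got {v}")
    rng = _scenario_rng(params, scenario)
    cents = mesh.element_centroid
    d = np.linalg.norm(cents - scenario.impact_point[None, :], axis=1)
    curvature = (params.reference_radius / scenario.radius_of_curvature
                 ) ** params.sharpness_exponent
    angle_term = 1.0 + params.angle_gain * np.cos(np.deg2rad(scenario.angle))

    gray_ids = mesh.elements_of("gray")
    base = (params.amplitude
            * (v / params.reference_velocity) ** params.velocity_exponent
            * np.exp(-d[gray_ids] / params.decay_length)
            * angle_term * curvature)
    eta = np.maximum(rng.normal(0.0, params.noise_cv, size=len(gray_ids)), -0.9)
    gray_peak = base * (1.0 + eta)

    skull_ids = mesh.elements_of("skull")
    sbase = (params.skull_gain * v * curvature
             * np.exp(-d[skull_ids] / params.decay_length))
    seta = np.maximum(rng.normal(0.0, params.noise_cv, size=len(skull_ids)), -0.9)
    skull_peak = sbase * (1.0 + seta)
    return PeakFieldSet(gray_ids=gray_ids, gray_peak=gray_peak,
                        skull_ids=skull_ids, skull_peak=skull_peak)


@dataclass(frozen=True)
class SimulationRecord:
    """One scenario of the library with its damage summary and features."""

    scenario: ImpactScenario
    fractured: bool
    damage_percent: float
    features: FeatureVector
    peaks: PeakFieldSet | None = field(default=None, repr=False, compare=False)


def default_library_grid() -> dict:
    """The default boundary-condition grid of the scenario library.

    5 locations x 4 impactors x 7 velocities (2..14 m/s step 2) x 3 angles
    ({-45, 0, 45} deg) = 420 scenarios, the order of magnitude of a
    realistic pre-computed simulation campaign.
    """
    from .ml import IMPACTORS, LOCATIONS
    return {
        "locations": list(LOCATIONS),
        "impactors": list(IMPACTORS),
        "velocities": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0],
        "angles": [-45.0, 0.0, 45.0],
    }


def build_scenario_library(mesh: HeadMesh, params: SurrogateParams,
                           dmn_ids, grid: dict | None = None,
                           damage_threshold: float = 1.0,
                           keep_fields: bool = False) -> list[SimulationRecord]:
    """One record per grid combination, with fracture flag and DMN damage %.

    *grid* maps the four boundary-condition dimensions to their value
    lists (see :func:`default_library_grid`); *dmn_ids* is the DMN
    gray-element set the damage percentage is computed over.  Fractured
    records are kept in the returned list (flagged) so the caller can
    filter and count them.
    """
    grid = dict(default_library_grid() if grid is None else grid)
    for k in ("locations", "impactors", "velocities", "angles"):
        if not grid.get(k):
            raise ValueError(f"grid dimension {k!r} is empty")
    records = []
    for loc, imp, v, ang in itertools.product(
            grid["locations"], grid["impactors"], grid["velocities"],
            grid["angles"]):
        sc = make_scenario(v, loc, angle=ang, impactor=imp)
        peaks = surrogate_peak_fields(sc, mesh, params)
        fractured = skull_fractured(peaks.skull_peak)
        res = dmn_damage_percent(peaks, dmn_ids, threshold=damage_threshold,
                                 fractured=fractured)
        feats = extract_features(sc, mesh, dmn_ids)
        records.append(SimulationRecord(
            scenario=sc, fractured=fractured,
            damage_percent=res.damage_percent, features=feats,
            peaks=peaks if keep_fields else None))
    return records


def library_to_frame(records) -> "pd.DataFrame":
    """Flatten a record list to a table (one row per scenario)."""
    import pandas as pd
    rows = []
    for r in records:
        row = {"velocity": r.scenario.velocity, "location": r.scenario.location,
               "angle": r.scenario.angle, "impactor": r.scenario.impactor,
               "radius_of_curvature": r.scenario.radius_of_curvature,
               "fractured": r.fractured, "damage_percent": r.damage_percent,
               "dist_to_dmn": r.features.dist_to_dmn,
               "angle_to_dmn": r.features.angle_to_dmn}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic rsfMRI cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions of a synthetic resting-state cohort.

    One patient plus *n_controls* controls; each subject's 4-D series is a
    mixture of *n_networks* template maps driven by AR(1) time courses
    plus Gaussian noise.  The patient's DMN loading is multiplied by
    ``1 - deficit_effect`` inside a contiguous region covering
    *deficit_fraction* of the binarized DMN mask.
    """

    grid_shape: tuple = (16, 16, 16)
    n_timepoints: int = 120
    n_controls: int = 18
    n_networks: int = 2
    ar1_coefficient: float = 0.4
    noise_sd: float = 1.0
    deficit_fraction: float = 0.15
    deficit_effect: float = 0.8
    z_threshold: float = 3.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls")
        if not 0.0 <= self.deficit_fraction <= 1.0:
            raise ValueError("deficit_fraction must be in [0, 1]")
        if not 0.0 <= self.deficit_effect <= 1.0:
            raise ValueError("deficit_effect must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort: 4-D series (x, y, z, t) per subject."""

    patient: np.ndarray
    controls: list
    affine: np.ndarray
    deficit_mask: np.ndarray
    spec: SyntheticCohortSpec


def _ar1_courses(rng, n_networks: int, n_t: int, phi: float) -> np.ndarray:
    eps = rng.standard_normal((n_networks, n_t))
    s = np.empty_like(eps)
    s[:, 0] = eps[:, 0]
    innov = np.sqrt(max(1.0 - phi * phi, 0.0))
    for t in range(1, n_t):
        s[:, t] = phi * s[:, t - 1] + innov * eps[:, t]
    return s


def _contiguous_region(mask: np.ndarray, n_target: int, start) -> np.ndarray:
    """Grow a contiguous (6-connected) region of n_target voxels inside mask
    by breadth-first search from *start*."""
    from collections import deque

    region = np.zeros_like(mask, dtype=bool)
    if n_target <= 0:
        return region
    q = deque([tuple(start)])
    seen = {tuple(start)}
    count = 0
    while q and count < n_target:
        v = q.popleft()
        if not mask[v]:
            continue
        region[v] = True
        count += 1
        for dim in range(3):
            for step in (-1, 1):
                w = list(v)
                w[dim] += step
                w = tuple(w)
                if (0 <= w[dim] < mask.shape[dim]) and w not in seen:
                    seen.add(w)
                    q.append(w)
    return region


def _subject_series(rng, maps: np.ndarray, spec: SyntheticCohortSpec) -> np.ndarray:
    s = _ar1_courses(rng, spec.n_networks, spec.n_timepoints,
                     spec.ar1_coefficient)
    series = np.tensordot(maps, s, axes=([0], [0]))
    if spec.noise_sd > 0:
        series = series + rng.normal(0.0, spec.noise_sd, size=series.shape)
    return series


def synth_rsfmri_cohort(spec: SyntheticCohortSpec, templates) -> SyntheticCohort:
    """Generate the patient + control 4-D series of a synthetic cohort.

    ``templates[0]`` is the DMN by convention; the patient's planted
    deficit region is grown from the template's peak voxel inside the
    mask binarized at ``spec.z_threshold``.  With ``deficit_effect = 0``
    the patient series is bit-identical to a control drawn from the same
    RNG stream.
    """
    templates = list(templates)
    if len(templates) != spec.n_networks:
        raise ValueError(f"expected {spec.n_networks} templates, got {len(templates)}")
    if spec.n_timepoints < spec.n_networks + 2:
        raise ValueError("n_timepoints must be >= n_networks + 2 "
                         "(temporal regression would be underdetermined)")
    for t in templates:
        if tuple(t.z_map.shape) != tuple(spec.grid_shape):
            raise ValueError("template grid does not match spec.grid_shape")

    maps = np.stack([t.z_map for t in templates])
    dmn_mask = templates[0].binarize(spec.z_threshold)
    n_target = int(round(spec.deficit_fraction * dmn_mask.sum()))
    start = np.unravel_index(np.argmax(np.where(dmn_mask, templates[0].z_map,
                                                -np.inf)), dmn_mask.shape)
    deficit = _contiguous_region(dmn_mask, n_target, start)

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_controls + 1)
    controls = [
        _subject_series(np.random.default_rng(ss), maps, spec)
        for ss in streams[:spec.n_controls]
    ]
    patient_maps = maps.copy()
    patient_maps[0] = np.where(deficit,
                               maps[0] * (1.0 - spec.deficit_effect), maps[0])
    patient = _subject_series(np.random.default_rng(streams[-1]),
                              patient_maps, spec)
    return SyntheticCohort(patient=patient, controls=controls,
                           affine=np.asarray(templates[0].affine),
                           deficit_mask=deficit, spec=spec)


# ---------------------------------------------------------------------------
# Legacy ASCII VTK I/O for the toy mesh
# ---------------------------------------------------------------------------

def write_vtk(mesh: HeadMesh, path) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid.

    Region labels are written as an integer cell field (gray=0, white=1,
    skull=2, csf=3) and fiber directions as a cell vector field (zeros on
    non-white elements).
    """
    n_pts, n_cells = len(mesh.nodes), len(mesh.tets)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntoy head mesh\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n_pts} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        fh.write(f"CELLS {n_cells} {5 * n_cells}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {n_cells}\n")
        fh.write("10\n" * n_cells)  # VTK_TETRA
        fh.write(f"CELL_DATA {n_cells}\nSCALARS region int 1\n"
                 "LOOKUP_TABLE default\n")
        for lab in mesh.region_label:
            fh.write(f"{_REGION_CODES[lab]}\n")
        fh.write("VECTORS fiber double\n")
        for f in np.nan_to_num(mesh.fiber_direction):
            fh.write(f"{f[0]:.9e} {f[1]:.9e} {f[2]:.9e}\n")


def read_vtk(path) -> HeadMesh:
    """Read a mesh written by :func:`write_vtk`."""
    with open(path) as fh:
        tokens = fh.read().split()

    def _find(word):
        return tokens.index(word)

    i = _find("POINTS")
    n_pts = int(tokens[i + 1])
    pts = np.array(tokens[i + 3:i + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)
    i = _find("CELLS")
    n_cells = int(tokens[i + 1])
    raw = np.array(tokens[i + 3:i + 3 + 5 * n_cells], dtype=int).reshape(-1, 5)
    tets = raw[:, 1:]
    i = _find("LOOKUP_TABLE")
    codes = np.array(tokens[i + 2:i + 2 + n_cells], dtype=int)
    region = np.array([_CODE_REGIONS[c] for c in codes])
    i = _find("VECTORS")
    fib = np.array(tokens[i + 3:i + 3 + 3 * n_cells], dtype=float).reshape(-1, 3)
    fibers = np.where((region == "white")[:, None], fib, np.nan)
    return HeadMesh(nodes=pts, tets=tets, region_label=region,
                    fiber_direction=fibers)
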