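"""Functional (rsfMRI) DMN damage: dual regression, single-case inference.

The functional damage criterion compares one patient's DMN connectivity
map against a control cohort: (1) dual regression projects a set of
template network maps onto each subject's 4-D series, yielding
z-normalized per-voxel connectivity maps; (2) the patient map is tested
voxel-wise against the controls with a single-case t statistic whose null
distribution is generated by sign flipping of the mean-centered maps,
with threshold-free cluster enhancement (TFCE) applied to the observed
and every permuted statistic map; (3) the "damage load" is the percentage
of DMN-mask voxels significantly less connected in the patient
(controls > patient contrast) at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SubjectNetworkMap",
    "CaseControlResult",
    "DamageLoad",
    "dual_regression",
    "crawford_howell_t",
    "tfce_enhance",
    "single_case_permutation",
    "binarize_dmn_template",
    "damage_load",
]


@dataclass(frozen=True)
class SubjectNetworkMap:
    """Per-voxel connectivity map for one network.

    ``z_map`` is the z-normalized map (stage-2 beta divided by its
    regression standard error), the quantity carried into the case-control
    statistics; ``beta_map`` the raw stage-2 regression coefficient, the
    natural scale for recovery checks on noiseless data where the standard
    error degenerates to zero.
    """

    z_map: np.ndarray
    affine: np.ndarray
    name: str = ""
    beta_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.z_map)):
            raise ValueError("network map contains non-finite values")


@dataclass(frozen=True)
class CaseControlResult:
    """Single-case permutation inference output (maps share one grid)."""

    t_map: np.ndarray
    tfce_map: np.ndarray
    p_map: np.ndarray
    n_permutations: int
    seed: int
    zero_variance_mask: np.ndarray


@dataclass(frozen=True)
class DamageLoad:
    n_disconnected: int
    dmn_mask_volume: int
    damage_load_percent: float


# ---------------------------------------------------------------------------
# Dual regression
# ---------------------------------------------------------------------------

def dual_regression(series_4d, templates, max_condition: float = 1e8):
    """Two-stage (temporal then spatial) regression of template networks.

    Stage 1 regresses each timepoint's volume on the template spatial maps
    (multiple regression across voxels), giving one time course per
    network.  Stage 2 regresses each voxel's time series on the
    variance-normalized time courses, giving per-network beta maps that
    are z-normalized by their voxel-wise regression standard error
    (beta / SE).  Returns one :class:`SubjectNetworkMap` per template;
    the caller selects the network of interest.
    """
    series = np.asarray(series_4d, dtype=float)
    templates = list(templates)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, z, t)")
    K = len(templates)
    n_t = series.shape[-1]
    if n_t <= K + 1:
        raise ValueError("need more timepoints than networks + 1")
    grid = series.shape[:3]
    for t in templates:
        if t.z_map.shape != grid:
            raise ValueError("template grid does not match the series grid")

    # stage 1: voxels x networks design
    X = np.stack([t.z_map.reshape(-1) for t in templates], axis=1)
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(f"template design is rank deficient or ill-conditioned "
                         f"(condition number {cond:.3g})")
    Y = series.reshape(-1, n_t)  # voxels x time
    courses, *_ = np.linalg.lstsq(X, Y, rcond=None)  # networks x time
    if not courses.any():  # degenerate all-zero series: all-zero maps
        zero = np.zeros(grid)
        return [SubjectNetworkMap(z_map=zero.copy(),
                                  affine=np.asarray(t.affine), name=t.name,
                                  beta_map=zero.copy()) for t in templates]

    # variance-normalize the time courses before the spatial stage
    sd = courses.std(axis=1, ddof=1)
    courses_n = np.where(sd[:, None] > 0, courses / np.where(sd == 0, 1, sd)[:, None],
                         courses)

    D = courses_n.T  # time x networks
    cond = np.linalg.cond(D)
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(f"time-course design is rank deficient "
                         f"(condition number {cond:.3g})")
    pinv = np.linalg.pinv(D)
    betas = pinv @ Y.T  # networks x voxels
    resid = Y.T - D @ betas
    dof = n_t - K
    sigma2 = (resid ** 2).sum(axis=0) / dof  # per voxel
    var_scale = np.diag(pinv @ pinv.T)  # (D'D)^-1 diagonal
    se = np.sqrt(var_scale[:, None] * sigma2[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, betas / se, 0.0)
    return [SubjectNetworkMap(z_map=z[k].reshape(grid),
                              affine=np.asarray(templates[k].affine),
                              name=templates[k].name,
                              beta_map=betas[k].reshape(grid))
            for k in range(K)]


# ---------------------------------------------------------------------------
# Single-case statistic, TFCE, permutation inference
# ---------------------------------------------------------------------------

def crawford_howell_t(patient: np.ndarray, controls: np.ndarray):
    """Single-case t statistic per voxel (controls > patient contrast).

    ``t = (mean_controls - patient) / (sd_controls * sqrt(1 + 1/N))`` with
    the control sd computed with N-1 degrees of freedom.  Voxels with zero
    control variance get t = 0 and are flagged.
    """
    mean_c = controls.mean(axis=0)
    sd_c = controls.std(axis=0, ddof=1)
    N = controls.shape[0]
    zero = sd_c == 0
    denom = np.where(zero, 1.0, sd_c) * np.sqrt(1.0 + 1.0 / N)
    t = np.where(zero, 0.0, (mean_c - patient) / denom)
    return t, zero


def tfce_enhance(stat_map, E: float = 0.5, H: float = 2.0,
                 dh: float | None = None, connectivity: int = 6) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map.

    For each voxel, cluster extent and height are integrated over all
    thresholds: ``TFCE(v) = sum_{h = dh, 2dh, ... <= stat(v)}
    e(h, v)^E h^H dh`` where ``e(h, v)`` is the voxel count of the
    connected component containing v at threshold h (voxels with
    ``stat >= h``).  Negative statistic values contribute nothing.  When
    *dh* is None the step adapts to the map, ``0.1 * max(stat)``.
    """
    stat = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map contains non-finite values")
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    peak = float(stat.max(initial=0.0))
    if peak <= 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = 0.1 * peak
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(stat.ndim, 1)
    elif connectivity in (18, 26) and stat.ndim == 3:
        structure = ndimage.generate_binary_structure(3, 2 if connectivity == 18 else 3)
    else:
        raise ValueError(f"unsupported connectivity {connectivity}")

    out = np.zeros_like(stat)
    h = dh
    # include h == peak despite float accumulation error
    while h <= peak * (1 + 1e-12):
        above = stat >= h * (1 - 1e-12)
        labels, n_lab = ndimage.label(above, structure=structure)
        if n_lab == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out += np.where(above, sizes[labels] ** E * h ** H * dh, 0.0)
        h += dh
    return out


def single_case_permutation(patient_map, control_maps, n_perm: int = 5000,
                            seed: int = 0, use_tfce: bool = True,
                            E: float = 0.5, H: float = 2.0,
                            dh: float | None = None,
                            connectivity: int = 6) -> CaseControlResult:
    """Voxel-wise permutation p-values for the controls > patient contrast.

    The observed statistic is the single-case t map (TFCE-enhanced when
    *use_tfce*); the null is generated by sign flipping: all subject maps
    are centered on the pooled mean, a random ±1 per subject per
    permutation multiplies each centered map, and the statistic (and its
    enhancement) is recomputed.  Voxel-wise
    ``p = (1 + #{perm >= observed}) / (n_perm + 1)``, uncorrected.
    """
    patient = (patient_map.z_map if isinstance(patient_map, SubjectNetworkMap)
               else np.asarray(patient_map, dtype=float))
    controls = np.stack([
        (m.z_map if isinstance(m, SubjectNetworkMap) else np.asarray(m, dtype=float))
        for m in control_maps])
    if controls.shape[0] < 2:
        raise ValueError("need at least 2 control maps")
    if controls.shape[1:] != patient.shape:
        raise ValueError("control and patient maps share one grid")

    t_obs, zero = crawford_howell_t(patient, controls)
    enhance = (lambda m: tfce_enhance(m, E=E, H=H, dh=dh,
                                      connectivity=connectivity)
               ) if use_tfce else (lambda m: np.maximum(m, 0.0))
    s_obs = enhance(t_obs)

    data = np.concatenate([controls, patient[None]], axis=0)
    centered = data - data.mean(axis=0)
    pooled_mean = data.mean(axis=0)
    rng = np.random.default_rng(seed)
    count = np.zeros(patient.shape, dtype=np.int64)
    n_sub = data.shape[0]
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        flipped = centered * signs.reshape((-1,) + (1,) * patient.ndim) + pooled_mean
        t_perm, _ = crawford_howell_t(flipped[-1], flipped[:-1])
        count += enhance(t_perm) >= s_obs
    p_map = (1.0 + count) / (n_perm + 1.0)
    return CaseControlResult(t_map=t_obs, tfce_map=s_obs, p_map=p_map,
                             n_permutations=n_perm, seed=seed,
                             zero_variance_mask=zero)


# ---------------------------------------------------------------------------
# Damage load
# ---------------------------------------------------------------------------

def binarize_dmn_template(template, z_threshold: float = 3.1) -> np.ndarray:
    """Binary DMN mask: template z-map strictly above *z_threshold*."""
    z = template.z_map if hasattr(template, "z_map") else np.asarray(template)
    if not np.all(np.isfinite(z)):
        raise ValueError("template z-map contains non-finite values")
    return z > z_threshold


def damage_load(p_map, dmn_binary_mask, alpha: float = 0.05,
                gray_mask=None) -> DamageLoad:
    """Percentage of DMN-mask voxels statistically disconnected (p < alpha).

    The count is restricted to *gray_mask* when given; the denominator is
    always the full DMN mask volume.
    """
    p = np.asarray(p_map, dtype=float)
    mask = np.asarray(dmn_binary_mask).astype(bool)
    if p.shape != mask.shape:
        raise ValueError("p map and DMN mask share one grid")
    volume = int(mask.sum())
    if volume == 0:
        raise ValueError("DMN mask is empty")
    region = mask if gray_mask is None else mask & np.asarray(gray_mask).astype(bool)
    n_disc = int(np.count_nonzero((p < alpha) & region))
    return DamageLoad(n_disconnected=n_disc, dmn_mask_volume=volume,
                      damage_load_percent=100.0 * n_disc / volume)
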