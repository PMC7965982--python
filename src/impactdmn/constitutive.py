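"""Brain-tissue constitutive model evaluated at a material point.

The stress response of gray and white matter is split into a volumetric part
(a power-law equation of state in the density ratio) and an isochoric part
(a Gent hyperelastic matrix, plus for white matter an exponential fiber
reinforcement along the local axonal direction).  The module also provides
the two scalar measures driving the damage criteria downstream: von Mises
stress (skull fracture indicator) and shear energy rate, the deviatoric
stress power density used as the gray-matter tissue damage criterion.

Units are SI throughout (Pa, m, s); ``shear_energy_rate`` alone converts its
output to MJ/m^3/s, the scale on which the damage threshold (~1 MJ/m^3/s)
is expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "BrainMaterialParams",
    "DeformationState",
    "StressTensor",
    "GentLimitError",
    "InvalidDeformationError",
    "WHITE_MATTER",
    "GRAY_MATTER",
    "load_material_params",
    "decompose_deformation",
    "cauchy_stress",
    "von_mises",
    "shear_energy_rate",
]

_I3 = np.eye(3)


class InvalidDeformationError(ValueError):
    """Deformation gradient with non-positive Jacobian."""


class GentLimitError(ValueError):
    """First distortional invariant reached the Gent locking limit j_m."""


@dataclass(frozen=True)
class BrainMaterialParams:
    """Constitutive parameters of one tissue.

    Parameters
    ----------
    mu_m : shear modulus of the Gent matrix (Pa).
    j_m : Gent limiting parameter (dimensionless); the stress diverges as
        ``I1* - 3`` approaches ``j_m``.
    k1 : fiber stiffness (Pa), ``None`` for isotropic tissue (gray matter).
    k2 : fiber exponent coefficient (dimensionless inside the exponential;
        the source tables list it in kPa but it multiplies the square of a
        dimensionless invariant), ``None`` for isotropic tissue.
    K_o : bulk modulus (Pa).
    Lambda_o : volumetric exponent (dimensionless).
    rho_o : reference density (kg/m^3).
    """

    mu_m: float
    j_m: float
    K_o: float
    Lambda_o: float
    rho_o: float
    k1: float | None = None
    k2: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.mu_m <= 0 or self.K_o <= 0 or self.rho_o <= 0:
            raise ValueError("mu_m, K_o and rho_o must be positive")
        if self.j_m <= 0:
            raise ValueError("j_m must be positive")
        if (self.k1 is None) != (self.k2 is None):
            raise ValueError("k1 and k2 must be supplied together")

    @property
    def is_isotropic(self) -> bool:
        return self.k1 is None


def load_material_params(path=None) -> dict[str, BrainMaterialParams]:
    """Load tissue parameter sets from the packaged YAML config.

    Returns a mapping ``{"white_matter": ..., "gray_matter": ...}``.  An
    explicit *path* overrides the packaged file.
    """
    if path is None:
        text = resources.files("impactdmn.data").joinpath("materials.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, BrainMaterialParams] = {}
    for name, p in raw["materials"].items():
        out[name] = BrainMaterialParams(
            mu_m=float(p["mu_m_kPa"]) * 1e3,
            j_m=float(p["j_m"]),
            K_o=float(p["K_o_GPa"]) * 1e9,
            Lambda_o=float(p["Lambda_o"]),
            rho_o=float(p["rho_o_kg_m3"]),
            k1=None if p.get("k1_kPa") is None else float(p["k1_kPa"]) * 1e3,
            k2=None if p.get("k1_kPa") is None else float(p.get("k2_kPa") or 0.0),
            name=name,
        )
    return out


_params = load_material_params()
WHITE_MATTER: BrainMaterialParams = _params["white_matter"]
GRAY_MATTER: BrainMaterialParams = _params["gray_matter"]
del _params


@dataclass(frozen=True)
class DeformationState:
    """Kinematic quantities derived from a deformation gradient F.

    ``J = det(F)``; ``F_star = J**(-1/3) F`` is the distortional
    (volume-preserving) part; ``B_star = F* F*^T``; ``I1_star = tr(F*^T F*)``
    and, when a fiber direction a is supplied, ``I4_star = a . C* a`` with
    ``C* = F*^T F*`` (equivalently ``tr(A_o C*)`` for ``A_o = a (x) a``).
    """

    F: np.ndarray
    J: float
    F_star: np.ndarray
    B_star: np.ndarray
    I1_star: float
    I4_star: float | None = None
    fiber: np.ndarray | None = None


def decompose_deformation(F, fiber=None) -> DeformationState:
    """Split F into volumetric and distortional parts and compute invariants.

    Parameters
    ----------
    F : (3, 3) array_like with ``det(F) > 0``.
    fiber : optional unit 3-vector, the reference axonal direction; when
        given, the anisotropic invariant ``I4*`` is computed.

    Raises
    ------
    InvalidDeformationError
        If ``det(F) <= 0``.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError(f"F must be 3x3, got {F.shape}")
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidDeformationError(f"det(F) = {J:g} <= 0")
    F_star = J ** (-1.0 / 3.0) * F
    B_star = F_star @ F_star.T
    I1_star = float(np.trace(B_star))
    I4_star = None
    a = None
    if fiber is not None:
        a = np.asarray(fiber, dtype=float)
        n = np.linalg.norm(a)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"fiber direction must be a unit vector (|a| = {n:g})")
        # I4* = a . C* a with C* = F*^T F*
        I4_star = float(a @ (F_star.T @ F_star) @ a)
    return DeformationState(F=F, J=J, F_star=F_star, B_star=B_star,
                            I1_star=I1_star, I4_star=I4_star, fiber=a)


@dataclass(frozen=True)
class StressTensor:
    """Cauchy stress split into volumetric and isochoric parts (Pa)."""

    sigma: np.ndarray
    sigma_vol: np.ndarray
    sigma_iso: np.ndarray


def _dev(T: np.ndarray) -> np.ndarray:
    return T - (np.trace(T) / 3.0) * _I3


def cauchy_stress(state: DeformationState, params: BrainMaterialParams,
                  fiber=None) -> StressTensor:
    """Total Cauchy stress at a material point.

    Isochoric part: Gent matrix term
    ``(mu_m / J) * [1 / (1 - (I1* - 3)/j_m)] * dev(B*)`` plus, for fibrous
    tissue, ``(2 k1 / J) (I4* - 1) exp[k2 (I4* - 1)^2] dev(F* A_o F*^T)``.
    Volumetric part: ``-[K_o/(Lambda_o + 1)] [(rho/rho_o)^(Lambda_o+1) - 1] I``
    with the density ratio obtained from mass conservation,
    ``rho/rho_o = 1/J``.

    The fiber direction may be carried by *state* (from
    :func:`decompose_deformation`) or passed here; it must be present exactly
    when the material has a fiber term.

    Raises
    ------
    GentLimitError
        If ``I1* - 3 >= j_m`` (the Gent matrix locks; stress is unbounded).
    ValueError
        On a fiber/material mismatch.
    """
    a = state.fiber if fiber is None else np.asarray(fiber, dtype=float)
    if params.is_isotropic:
        pass  # fiber, if supplied, is ignored for the matrix-only response
    elif a is None:
        raise ValueError(f"material {params.name or 'white'} has a fiber term; "
                         "a fiber direction is required")

    J = state.J
    stretch = state.I1_star - 3.0
    if stretch >= params.j_m:
        raise GentLimitError(
            f"I1* - 3 = {stretch:g} >= j_m = {params.j_m:g}: Gent limit reached")

    gent = (params.mu_m / J) / (1.0 - stretch / params.j_m)
    sigma_iso = gent * _dev(state.B_star)

    if not params.is_isotropic:
        if state.I4_star is not None and fiber is None:
            I4 = state.I4_star
        else:
            I4 = float(a @ (state.F_star.T @ state.F_star) @ a)
        A_o = np.outer(a, a)
        fib = (2.0 * params.k1 / J) * (I4 - 1.0) * np.exp(params.k2 * (I4 - 1.0) ** 2)
        sigma_iso = sigma_iso + fib * _dev(state.F_star @ A_o @ state.F_star.T)

    rho_ratio = 1.0 / J
    p = -(params.K_o / (params.Lambda_o + 1.0)) * (
        rho_ratio ** (params.Lambda_o + 1.0) - 1.0)
    sigma_vol = p * _I3
    return StressTensor(sigma=sigma_vol + sigma_iso, sigma_vol=sigma_vol,
                        sigma_iso=sigma_iso)


def von_mises(sigma) -> float:
    """Von Mises equivalent stress, ``sqrt(3/2 dev(s):dev(s))`` (Pa)."""
    s = sigma.sigma if isinstance(sigma, StressTensor) else np.asarray(sigma, dtype=float)
    d = _dev(s)
    return float(np.sqrt(1.5 * np.sum(d * d)))


def shear_energy_rate(sigma, D) -> float:
    """Deviatoric stress power density, in MJ/m^3/s.

    ``dev(sigma) : dev(D)`` with sigma in Pa and the rate-of-deformation
    tensor D in 1/s gives W/m^3; the result is returned in MJ/m^3/s, the
    scale of the gray-matter damage threshold.
    """
    s = sigma.sigma if isinstance(sigma, StressTensor) else np.asarray(sigma, dtype=float)
    D = np.asarray(D, dtype=float)
    return float(np.sum(_dev(s) * _dev(D))) * 1e-6
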