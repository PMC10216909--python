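"""Hyperelastic and linear-elastic material models for the glenohumeral capsule.

The capsule regions are modelled as incompressible, isotropic hyperelastic
membranes.  Two strain-energy families are provided:

* third-order Yeoh, ``W = c1 (I1-3) + c2 (I1-3)^2 + c3 (I1-3)^3``, the working
  model for the five capsule regions;
* Veronda-Westmann, ``W = c1 (exp(c2 (I1-3)) - 1) - c1 c2 / 2 (I2 - 3)``, the
  exponential form commonly used for ligamentous soft tissue, retained here as
  the source model from which Yeoh constants are calibrated by least squares.

The labrum is a stiff fibrocartilage band and is described by a plane-stress
Saint Venant-Kirchhoff (linear elastic) model.

Units are millimetres and megapascals throughout; thicknesses are stored with
the materials because each capsule region has its own wall thickness.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import least_squares

__all__ = [
    "CAPSULE_REGIONS",
    "LABRUM",
    "YeohMaterial",
    "VerondaWestmannMaterial",
    "LinearElasticMaterial",
    "UniaxialCurve",
    "FitResult",
    "RegionMaterial",
    "yeoh_energy",
    "uniaxial_invariants",
    "uniaxial_cauchy_stress",
    "equibiaxial_cauchy_stress",
    "uniaxial_curve",
    "fit_yeoh_to_curve",
    "region_materials",
    "load_material_table",
    "default_material_table",
    "calibration_report",
]

#: Canonical order of the five capsule regions (used for stable serialization).
CAPSULE_REGIONS: tuple[str, ...] = (
    "antero_superior",
    "posterior",
    "ab_ighl",
    "pb_ighl",
    "axillary_pouch",
)
LABRUM = "labrum"


# ---------------------------------------------------------------------------
# Material types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class YeohMaterial:
    """Third-order reduced-polynomial (Yeoh) incompressible material.

    ``c1`` is half the small-strain shear modulus and must be positive;
    ``c2`` is typically negative (initial softening) and ``c3`` positive
    (collagen-recruitment stiffening) for capsular tissue.
    """

    c1: float
    c2: float = 0.0
    c3: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.c1 <= 0.0:
            raise ValueError(
                f"c1 must be positive (shear modulus 2*c1 > 0), got {self.c1}"
            )

    def energy(self, i1):
        x = np.asarray(i1, dtype=float) - 3.0
        return self.c1 * x + self.c2 * x**2 + self.c3 * x**3

    def dW_dI1(self, i1):
        x = np.asarray(i1, dtype=float) - 3.0
        return self.c1 + 2.0 * self.c2 * x + 3.0 * self.c3 * x**2

    def dW_dI2(self, i1):
        return np.zeros_like(np.asarray(i1, dtype=float))


@dataclass(frozen=True)
class VerondaWestmannMaterial:
    """Veronda-Westmann exponential incompressible material.

    W = c1 (exp(c2 (I1 - 3)) - 1) - c1 c2 / 2 (I2 - 3).  The I2 term makes the
    energy and the uniaxial stress vanish identically in the reference state.
    """

    c1: float
    c2: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c1) and np.isfinite(self.c2)):
            raise ValueError("Veronda-Westmann constants must be finite")
        if self.c1 <= 0.0:
            raise ValueError(f"c1 must be positive, got {self.c1}")

    def energy(self, i1, i2):
        x = np.asarray(i1, dtype=float) - 3.0
        y = np.asarray(i2, dtype=float) - 3.0
        return self.c1 * (np.exp(self.c2 * x) - 1.0) - 0.5 * self.c1 * self.c2 * y

    def dW_dI1(self, i1):
        x = np.asarray(i1, dtype=float) - 3.0
        return self.c1 * self.c2 * np.exp(self.c2 * x)

    def dW_dI2(self, i1):
        return np.full_like(np.asarray(i1, dtype=float), -0.5 * self.c1 * self.c2)


@dataclass(frozen=True)
class LinearElasticMaterial:
    """Isotropic linear-elastic constants (labrum), used in plane stress."""

    tensile_modulus: float  # MPa
    poisson_ratio: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.tensile_modulus <= 0.0:
            raise ValueError("tensile modulus must be positive")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError(
                f"Poisson ratio must lie in (0, 0.5), got {self.poisson_ratio}"
            )

    @property
    def shear_modulus(self) -> float:
        return self.tensile_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def plane_stress_lambda(self) -> float:
        """First Lame parameter condensed for plane stress: E nu / (1 - nu^2)."""
        e, nu = self.tensile_modulus, self.poisson_ratio
        return e * nu / (1.0 - nu * nu)


@dataclass(frozen=True)
class UniaxialCurve:
    """A sampled uniaxial Cauchy stress-stretch response."""

    stretches: np.ndarray
    stresses: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretches, dtype=float)
        sig = np.asarray(self.stresses, dtype=float)
        if lam.shape != sig.shape or lam.ndim != 1:
            raise ValueError("stretches and stresses must be 1-d and equal length")
        if np.any(np.diff(lam) <= 0.0):
            raise ValueError("stretches must be strictly increasing")
        if np.any(lam <= 0.0):
            raise ValueError("stretches must be positive")
        object.__setattr__(self, "stretches", lam)
        object.__setattr__(self, "stresses", sig)

    def __len__(self) -> int:
        return len(self.stretches)


@dataclass(frozen=True)
class FitResult:
    fitted_material: YeohMaterial
    r_squared: float
    residual_norm: float
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


@dataclass(frozen=True)
class RegionMaterial:
    """Material plus wall thickness for one capsule region."""

    material: YeohMaterial | LinearElasticMaterial
    thickness: float  # mm

    def __post_init__(self) -> None:
        if self.thickness <= 0.0:
            raise ValueError("thickness must be positive")


# ---------------------------------------------------------------------------
# Constitutive responses in homogeneous deformation modes
# ---------------------------------------------------------------------------


def yeoh_energy(material: YeohMaterial, i1) -> np.ndarray | float:
    """Yeoh strain-energy density at first invariant ``i1`` (MPa)."""
    i1 = np.asarray(i1, dtype=float)
    if not np.all(np.isfinite(i1)):
        raise ValueError("i1 must be finite")
    if np.any(i1 < 3.0 - 1e-9):
        raise ValueError("i1 < 3 is impossible for an incompressible deformation")
    out = material.energy(i1)
    return float(out) if out.ndim == 0 else out


def uniaxial_invariants(stretch) -> tuple:
    """Invariants (I1, I2, I3) of incompressible uniaxial stretch ``lambda``.

    I1 = l^2 + 2/l, I2 = 2 l + 1/l^2, I3 = 1 (isochoric: the lateral
    stretches are 1/sqrt(l)).
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0) or not np.all(np.isfinite(lam)):
        raise ValueError("stretch must be positive and finite")
    i1 = lam**2 + 2.0 / lam
    i2 = 2.0 * lam + 1.0 / lam**2
    i3 = np.ones_like(lam)
    if lam.ndim == 0:
        return float(i1), float(i2), float(i3)
    return i1, i2, i3


def uniaxial_cauchy_stress(material, stretch):
    """Principal Cauchy stress under incompressible uniaxial tension.

    sigma = 2 (l^2 - 1/l) (dW/dI1 + (1/l) dW/dI2); the transverse stresses
    vanish.  For an I1-only model (Yeoh) the second term is zero.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0) or not np.all(np.isfinite(lam)):
        raise ValueError("stretch must be positive and finite")
    i1 = lam**2 + 2.0 / lam
    sig = 2.0 * (lam**2 - 1.0 / lam) * (
        material.dW_dI1(i1) + material.dW_dI2(i1) / lam
    )
    return float(sig) if sig.ndim == 0 else sig


def equibiaxial_cauchy_stress(material, stretch):
    """In-plane Cauchy stress under incompressible equibiaxial tension.

    sigma = 2 (l^2 - 1/l^4) (dW/dI1 + l^2 dW/dI2) with I1 = 2 l^2 + 1/l^4.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0) or not np.all(np.isfinite(lam)):
        raise ValueError("stretch must be positive and finite")
    i1 = 2.0 * lam**2 + 1.0 / lam**4
    sig = 2.0 * (lam**2 - 1.0 / lam**4) * (
        material.dW_dI1(i1) + lam**2 * material.dW_dI2(i1)
    )
    return float(sig) if sig.ndim == 0 else sig


def uniaxial_curve(material, lam_min=1.0, lam_max=1.3, n=50) -> UniaxialCurve:
    """Sample the uniaxial Cauchy response on a uniform stretch grid."""
    lam = np.linspace(lam_min, lam_max, n)
    return UniaxialCurve(lam, uniaxial_cauchy_stress(material, lam))


# ---------------------------------------------------------------------------
# Least-squares calibration
# ---------------------------------------------------------------------------


def fit_yeoh_to_curve(
    curve: UniaxialCurve,
    initial_guess: YeohMaterial | None = None,
    max_iter: int = 500,
    label: str = "",
) -> FitResult:
    """Fit third-order Yeoh constants to a uniaxial Cauchy stress curve.

    Damped (Levenberg-Marquardt) least squares on (c1, c2, c3); deterministic
    for a fixed curve and initial guess.  Raises ``RuntimeError`` with solver
    diagnostics on non-convergence.
    """
    if len(curve) < 4 or not np.any(curve.stretches > 1.0):
        raise ValueError("need at least 4 points spanning stretches > 1")
    x0 = (
        np.array([1.0, 0.0, 0.0])
        if initial_guess is None
        else np.array([initial_guess.c1, initial_guess.c2, initial_guess.c3])
    )
    lam = curve.stretches
    i1 = lam**2 + 2.0 / lam
    x = i1 - 3.0
    pref = 2.0 * (lam**2 - 1.0 / lam)

    def resid(c):
        return pref * (c[0] + 2.0 * c[1] * x + 3.0 * c[2] * x**2) - curve.stresses

    sol = least_squares(
        resid, x0, method="lm", max_nfev=max_iter, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if not sol.success:
        raise RuntimeError(
            f"Yeoh fit did not converge: status={sol.status}, nfev={sol.nfev}, "
            f"cost={sol.cost:.3e}, message={sol.message}"
        )
    c1, c2, c3 = sol.x
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((curve.stresses - curve.stresses.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0.0 else (1.0 if ss_res == 0.0 else 0.0)
    return FitResult(
        fitted_material=YeohMaterial(c1, c2, c3, label=label),
        r_squared=min(r2, 1.0),
        residual_norm=float(np.sqrt(ss_res)),
        n_iterations=int(sol.nfev),
    )


# ---------------------------------------------------------------------------
# Regional material table
# ---------------------------------------------------------------------------


def _table_path():
    return importlib.resources.files("capsfem") / "data" / "capsule_materials.yaml"


def default_material_table() -> dict:
    """The bundled regional constant table as a plain dict."""
    with importlib.resources.as_file(_table_path()) as p:
        with open(p, "r") as fh:
            return yaml.safe_load(fh)


def load_material_table(path) -> dict:
    with open(path, "r") as fh:
        table = yaml.safe_load(fh)
    if not isinstance(table, dict):
        raise ValueError(f"material table {path} is not a mapping")
    return table


def region_materials(table: Mapping | None = None) -> dict[str, RegionMaterial]:
    """Build the region -> (material, thickness) mapping from a constant table.

    ``table`` defaults to the bundled regional constants.  All five capsule
    regions must be present; the labrum entry supplies linear-elastic
    constants and the 4 mm band thickness.
    """
    if table is None:
        table = default_material_table()
    regions = table.get("regions", {})
    missing = [r for r in CAPSULE_REGIONS if r not in regions]
    if missing:
        raise ValueError(f"material table is missing capsule regions: {missing}")
    out: dict[str, RegionMaterial] = {}
    for name in CAPSULE_REGIONS:
        row = regions[name]
        mat = YeohMaterial(
            float(row["c1"]), float(row["c2"]), float(row["c3"]), label=name
        )
        out[name] = RegionMaterial(material=mat, thickness=float(row["thickness"]))
    lab = table.get("labrum")
    if lab is None:
        raise ValueError("material table is missing the labrum entry")
    out[LABRUM] = RegionMaterial(
        material=LinearElasticMaterial(
            float(lab["tensile_modulus"]), float(lab["poisson_ratio"]), label=LABRUM
        ),
        thickness=float(lab["thickness"]),
    )
    return out


def calibration_report(table: Mapping | None = None, n: int = 50) -> "pandas.DataFrame":
    """Round-trip calibration: regenerate each region's uniaxial curve and refit.

    Returns a table (region, c1, c2, c3, r_squared) of the recovered
    constants — the self-consistency check available when the source
    experimental data behind the regional constants is not published.
    """
    import pandas as pd

    mats = region_materials(table)
    rows = []
    for name in CAPSULE_REGIONS:
        mat = mats[name].material
        fit = fit_yeoh_to_curve(uniaxial_curve(mat, 1.0, 1.3, n), label=name)
        f = fit.fitted_material
        rows.append(
            {
                "region": name,
                "c1": f.c1,
                "c2": f.c2,
                "c3": f.c3,
                "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(rows)
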