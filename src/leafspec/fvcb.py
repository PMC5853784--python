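"""Farquhar-von Caemmerer-Berry (FvCB) C3 photosynthesis model: forward
assimilation, inversion of A-Ci curves for (Vcmax, J, Rd), and Arrhenius
normalization of Vcmax to 25 degC.

Model
-----
Net assimilation is the minimum of the Rubisco-limited and the
RuBP-regeneration-limited rate, minus day respiration::

    Ac = Vcmax * (Ci - GammaStar) / (Ci + Kc * (1 + O/Ko))
    Aj = J     * (Ci - GammaStar) / (4*Ci + 8*GammaStar)
    A  = min(Ac, Aj) - Rd

The analysis is on a Ci basis (infinite mesophyll conductance).  The hard
minimum is used by default; a hyperbolic-minimum smoothing factor is
available but off by default.  Triose-phosphate limitation is not modelled.

Kinetics
--------
Michaelis constants and the CO2 compensation point follow Arrhenius
temperature responses referenced to 25 degC.  The package ships a clearly
labelled generic C3 (tobacco-derived) constant set; species-specific sets
(e.g. Rubisco kinetics measured in vivo for wheat) should be supplied by the
user as an :class:`FvCBKinetics` instance, since those constants are not
bundled here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

R_GAS = 8.314  # J mol-1 K-1
T_REF_K = 298.15


class FvCBError(ValueError):
    pass


class FitWarning(UserWarning):
    pass


def arrhenius_factor(tleaf_c: float | np.ndarray, e_kj_mol: float) -> float | np.ndarray:
    """Arrhenius scaling referenced to 25 degC:
    exp[E * (T - 25) / (R * 298.15 * (T + 273.15))] with E in kJ mol-1.
    Equals 1 exactly at 25 degC."""
    t = np.asarray(tleaf_c, dtype=float)
    f = np.exp(e_kj_mol * 1e3 * (t - 25.0) / (R_GAS * T_REF_K * (t + 273.15)))
    return float(f) if np.isscalar(tleaf_c) else f


@dataclass(frozen=True)
class FvCBKinetics:
    """Rubisco kinetic constants at 25 degC plus activation energies.

    Units: Kc25 umol mol-1, Ko25 mmol mol-1, GammaStar25 umol mol-1,
    activation energies kJ mol-1.  Temperature functions evaluate to the
    25 degC value at 25 degC exactly.
    """

    Kc25: float = 404.9
    Ko25: float = 278.4
    GammaStar25: float = 42.75
    E_Kc: float = 79.43
    E_Ko: float = 36.38
    E_GammaStar: float = 37.83
    E_Vcmax: float = 65.33
    source_label: str = "generic C3 (tobacco-derived in vivo constants)"

    def __post_init__(self) -> None:
        for name in ("Kc25", "Ko25", "GammaStar25", "E_Kc", "E_Ko", "E_GammaStar", "E_Vcmax"):
            if getattr(self, name) <= 0:
                raise FvCBError(f"kinetic constant {name} must be positive")

    def Kc(self, tleaf_c: float) -> float:
        return self.Kc25 * arrhenius_factor(tleaf_c, self.E_Kc)

    def Ko(self, tleaf_c: float) -> float:
        return self.Ko25 * arrhenius_factor(tleaf_c, self.E_Ko)

    def GammaStar(self, tleaf_c: float) -> float:
        return self.GammaStar25 * arrhenius_factor(tleaf_c, self.E_GammaStar)


GENERIC_C3_KINETICS = FvCBKinetics()

#: Placeholder for wheat in vivo Rubisco kinetics: the constants belong to an
#: external reference and are deliberately not bundled; populate via
#: ``FvCBKinetics(..., source_label="wheat")`` before use.
WHEAT_KINETICS_PLACEHOLDER = None


@dataclass(frozen=True)
class ACiCurve:
    """Ordered gas-exchange points of a CO2 response curve.

    Ci in umol CO2 mol-1, A in umol CO2 m-2 s-1; Tleaf degC (curve mean);
    irradiance umol quanta m-2 s-1; O in mmol O2 mol-1 (ambient 210).
    A valid curve samples both limitation regimes: at least one point with
    Ci < 300 and one with Ci > 600.
    """

    ci: np.ndarray
    a: np.ndarray
    tleaf_c: float = 25.0
    irradiance: float = 1800.0
    o_mmol_mol: float = 210.0
    record_id: str = ""

    def __post_init__(self) -> None:
        ci = np.asarray(self.ci, dtype=float)
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "ci", ci)
        object.__setattr__(self, "a", a)
        if ci.size != a.size:
            raise FvCBError("Ci and A must have equal length")
        if ci.size < 5:
            raise FvCBError(f"A-Ci curve needs >=5 points, got {ci.size}")
        if np.any(ci <= 0):
            raise FvCBError("Ci values must be positive")
        if np.unique(ci).size != ci.size:
            raise FvCBError("Ci values must be distinct")

    @property
    def covers_rubisco_regime(self) -> bool:
        return bool(np.any(self.ci < 300.0))

    @property
    def covers_rubp_regime(self) -> bool:
        return bool(np.any(self.ci > 600.0))


@dataclass(frozen=True)
class PhotoTraits:
    """Fitted photosynthetic parameters for one curve (umol m-2 s-1)."""

    Vcmax: float
    J: float
    Rd: float
    Tleaf: float
    Vcmax25: float = field(default=np.nan)
    limitation: tuple[str, ...] = ()
    residual_ss: float = np.nan
    n_rubisco: int = 0
    n_rubp: int = 0
    converged: bool = True


def _limited_rates(ci, vcmax, j, tleaf_c, kinetics, o_mmol_mol=210.0):
    gs = kinetics.GammaStar(tleaf_c)
    km = kinetics.Kc(tleaf_c) * (1.0 + o_mmol_mol / kinetics.Ko(tleaf_c))
    ac = vcmax * (ci - gs) / (ci + km)
    aj = j * (ci - gs) / (4.0 * ci + 8.0 * gs)
    return ac, aj


def fvcb_assimilation(
    ci: float | np.ndarray,
    vcmax: float,
    j: float,
    rd: float,
    tleaf_c: float = 25.0,
    kinetics: FvCBKinetics = GENERIC_C3_KINETICS,
    o_mmol_mol: float = 210.0,
    smoothing_theta: float | None = None,
) -> float | np.ndarray:
    """Net CO2 assimilation rate at intercellular CO2 ``ci``.

    With the default hard minimum, A = min(Ac, Aj) - Rd; passing
    ``smoothing_theta`` in (0, 1) replaces the minimum with the lower root of
    the hyperbolic minimum  theta*x^2 - (Ac+Aj)*x + Ac*Aj = 0.
    At Ci = GammaStar(Tleaf), A = -Rd by construction.
    """
    ci_arr = np.asarray(ci, dtype=float)
    if np.any(ci_arr <= 0):
        raise FvCBError("Ci must be positive")
    if vcmax <= 0 or j <= 0 or rd < 0:
        raise FvCBError("require Vcmax > 0, J > 0, Rd >= 0")
    ac, aj = _limited_rates(ci_arr, vcmax, j, tleaf_c, kinetics, o_mmol_mol)
    if smoothing_theta is None:
        gross = np.minimum(ac, aj)
    else:
        th = float(smoothing_theta)
        if not 0 < th < 1:
            raise FvCBError("smoothing_theta must lie in (0, 1)")
        s = ac + aj
        gross = (s - np.sqrt(s * s - 4.0 * th * ac * aj)) / (2.0 * th)
    a = gross - rd
    return float(a) if np.isscalar(ci) else a


def normalize_vcmax25(vcmax: float, tleaf_c: float, e_vcmax_kj_mol: float = GENERIC_C3_KINETICS.E_Vcmax) -> float:
    """Normalize Vcmax measured at Tleaf to the 25 degC reference by dividing
    out the Arrhenius factor; identity at Tleaf = 25."""
    if not 0.0 <= tleaf_c <= 50.0:
        raise FvCBError(f"Tleaf {tleaf_c} degC outside supported range [0, 50]")
    return float(vcmax) / arrhenius_factor(tleaf_c, e_vcmax_kj_mol)


def vcmax_at_temperature(vcmax25: float, tleaf_c: float, e_vcmax_kj_mol: float = GENERIC_C3_KINETICS.E_Vcmax) -> float:
    """Forward Arrhenius map: Vcmax at Tleaf from Vcmax25 (inverse of
    :func:`normalize_vcmax25`)."""
    if not 0.0 <= tleaf_c <= 50.0:
        raise FvCBError(f"Tleaf {tleaf_c} degC outside supported range [0, 50]")
    return float(vcmax25) * arrhenius_factor(tleaf_c, e_vcmax_kj_mol)


RD_BOUNDS = (0.0, 5.0)  # umol m-2 s-1; treatment of Rd is a fitting choice


def _initial_guess(curve: ACiCurve, kinetics: FvCBKinetics) -> tuple[float, float, float]:
    """Vcmax0 from the Rubisco-limited equation on the 3 lowest-Ci points,
    J0 from the high-Ci plateau mean."""
    order = np.argsort(curve.ci)
    ci, a = curve.ci[order], curve.a[order]
    t = curve.tleaf_c
    gs = kinetics.GammaStar(t)
    km = kinetics.Kc(t) * (1.0 + curve.o_mmol_mol / kinetics.Ko(t))
    rd0 = 1.0
    lo = slice(0, 3)
    denom = (ci[lo] - gs) / (ci[lo] + km)
    vc0 = float(np.median((a[lo] + rd0) / np.where(np.abs(denom) > 1e-9, denom, np.nan)))
    if not np.isfinite(vc0) or vc0 <= 0:
        vc0 = 80.0
    hi = a[ci > 600.0] if np.any(ci > 600.0) else a[-3:]
    j0 = float(4.0 * (np.mean(hi) + rd0))
    if not np.isfinite(j0) or j0 <= 0:
        j0 = 1.5 * vc0
    return vc0, j0, rd0


def fit_aci(
    curve: ACiCurve,
    kinetics: FvCBKinetics = GENERIC_C3_KINETICS,
    n_restarts: int = 5,
    seed: int = 13,
    fix_rd: float | None = None,
) -> PhotoTraits:
    """Estimate (Vcmax, J, Rd) by least squares on the min-of-limitations
    model, with multistart around a slope/plateau initial guess.

    Rd is fitted within [0, 5] umol m-2 s-1 by default or fixed via
    ``fix_rd``.  Each point is labelled by its limiting process at the
    optimum.  If the curve misses one regime a :class:`FitWarning` is issued
    and the corresponding parameter (J for missing high-Ci, Vcmax for missing
    low-Ci) is poorly constrained; the fit proceeds on the available regime.
    """
    rng = np.random.default_rng(seed)
    vc0, j0, rd0 = _initial_guess(curve, kinetics)
    if not curve.covers_rubp_regime:
        warnings.warn(
            f"curve {curve.record_id or '<unnamed>'}: no points with Ci > 600; "
            "J is not estimable from the Rubisco-limited region",
            FitWarning,
            stacklevel=2,
        )
    if not curve.covers_rubisco_regime:
        warnings.warn(
            f"curve {curve.record_id or '<unnamed>'}: no points with Ci < 300; "
            "Vcmax is poorly constrained",
            FitWarning,
            stacklevel=2,
        )

    def residuals(theta):
        vc, j, rd = theta if fix_rd is None else (*theta, fix_rd)
        return fvcb_assimilation(curve.ci, vc, j, rd, curve.tleaf_c, kinetics, curve.o_mmol_mol) - curve.a

    if fix_rd is None:
        x0 = np.array([vc0, j0, rd0])
        lb = np.array([1e-3, 1e-3, RD_BOUNDS[0]])
        ub = np.array([2000.0, 3000.0, RD_BOUNDS[1]])
    else:
        x0 = np.array([vc0, j0])
        lb, ub = np.array([1e-3, 1e-3]), np.array([2000.0, 3000.0])

    best = None
    starts = [x0] + [x0 * rng.uniform(0.6, 1.4, size=x0.size) for _ in range(n_restarts - 1)]
    for s in starts:
        try:
            sol = least_squares(residuals, np.clip(s, lb + 1e-6, ub - 1e-6), bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FvCBError(
            f"A-Ci fit failed to converge after {n_restarts} starts "
            f"(curve {curve.record_id or '<unnamed>'}, n={curve.ci.size})"
        )
    vc, j = float(best.x[0]), float(best.x[1])
    rd = float(fix_rd) if fix_rd is not None else float(best.x[2])
    ac, aj = _limited_rates(curve.ci, vc, j, curve.tleaf_c, kinetics, curve.o_mmol_mol)
    labels = tuple("Rubisco" if a_ <= b_ else "RuBP" for a_, b_ in zip(ac, aj))
    return PhotoTraits(
        Vcmax=vc,
        J=j,
        Rd=rd,
        Tleaf=curve.tleaf_c,
        Vcmax25=normalize_vcmax25(vc, curve.tleaf_c, kinetics.E_Vcmax),
        limitation=labels,
        residual_ss=float(2.0 * best.cost),
        n_rubisco=sum(1 for L in labels if L == "Rubisco"),
        n_rubp=sum(1 for L in labels if L == "RuBP"),
        converged=True,
    )


def simulate_aci(
    photo: PhotoTraits,
    ci_levels: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    kinetics: FvCBKinetics = GENERIC_C3_KINETICS,
    o_mmol_mol: float = 210.0,
) -> ACiCurve:
    """Forward-simulate an A-Ci curve with i.i.d. Gaussian noise on A;
    reproducible per seed."""
    ci = np.asarray(ci_levels, dtype=float)
    a = fvcb_assimilation(ci, photo.Vcmax, photo.J, photo.Rd, photo.Tleaf, kinetics, o_mmol_mol)
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=ci.size)
    return ACiCurve(ci=ci, a=a, tleaf_c=photo.Tleaf, o_mmol_mol=o_mmol_mol)


#: A representative inlet-CO2 ladder expressed as Ci levels spanning both
#: limitation regimes (umol mol-1), used by the synthetic generator.
DEFAULT_CI_LEVELS = np.array([50.0, 100.0, 150.0, 225.0, 300.0, 450.0, 650.0, 900.0, 1200.0, 1500.0])
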