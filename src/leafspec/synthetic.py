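"""Synthetic spectra-trait datasets and gas-exchange curves.

The generator is statistical, not radiative-transfer based: it emulates the
features of real leaf-clip data that the pipeline depends on, so that every
stage is testable without external data.

* A smooth leaf-like baseline: low visible reflectance with a green bump
  near 550 nm, a red edge rising to an NIR plateau of ~0.47 (inside the
  [0.35, 0.6] plausibility window at 800 nm), water-absorption troughs near
  1450 and 1940 nm, and a declining SWIR2 tail.
* Four smooth, mutually non-collinear trait-linked signatures (a
  visible/chlorophyll signature, an NIR structural signature, two SWIR
  signatures).
* Traits drawn per genotype within configured ranges (genotype effect plus
  repetition noise, moderate positive inter-trait correlation), mapped
  linearly into the spectrum through the signatures -- the structure PLSR
  assumes -- plus band-correlated smooth noise and optional additive
  detector-jump artifacts at the instrument junctions.
* A-Ci curve sets with Vcmax25 drawn in the observed wheat range
  ([23, 280] umol m-2 s-1), leaf temperatures in 15-35 degC (field
  conditions do not hold Tleaf constant), Vcmax at temperature via the
  Arrhenius map and J proportional to Vcmax25.

The ``truth`` object returned with each dataset stores the noiseless traits
and the exact linear map, for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import fvcb
from .spectra import Spectrum, SpectralRecord, TraitTable, FULL_RANGE_NM

#: Default traits with (low, high) generator ranges.  Vcmax25 follows the
#: observed wheat range; the others span typical field-survey axes.
DEFAULT_TRAIT_RANGES = {
    "SPAD": (10.0, 60.0),
    "LMA": (25.0, 80.0),
    "Narea": (0.5, 3.0),
    "Vcmax25": (23.0, 280.0),
}

VCMAX_RANGE = (25.0, 400.0)  # at-temperature range implied by Tleaf variation


@dataclass
class GeneratorConfig:
    """Stated world for the synthetic datasets."""

    n_genotypes: int = 60
    repetitions: int = 4
    trait_ranges: dict = dc_field(default_factory=lambda: dict(DEFAULT_TRAIT_RANGES))
    trait_noise_frac: float = 0.02      # sd of trait noise as fraction of range
    spectral_noise_sd: float = 0.002    # sd of smooth spectral noise
    smooth_noise: bool = True           # band-correlated (moving-average) noise
    trait_correlation: float = 0.5      # off-diagonal inter-trait correlation
    genotype_variance_frac: float = 0.8 # share of trait variance between genotypes
    add_jumps: bool = False
    junctions: tuple[int, ...] = (1000, 1800)
    jump_magnitudes: tuple[float, ...] = (0.02, -0.015)
    signature_amplitude: float = 0.03   # reflectance units per trait z-score
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.trait_ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"trait range for {name} must be positive and ordered")


def _gauss(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / width) ** 2)


def _sigmoid(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(w - center) / width))


def default_grid() -> np.ndarray:
    return np.arange(FULL_RANGE_NM[0], FULL_RANGE_NM[1] + 1, dtype=np.int64)


def generate_basis(grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Leaf-like baseline plus four smooth signature vectors on ``grid``.

    Returns ``(baseline, signatures)`` with signatures of shape (4, p), each
    scaled to unit maximum magnitude.  The baseline passes the 800 nm
    plausibility filter and all values lie in [0, 1]; signatures are pairwise
    correlated below 0.95.
    """
    w = default_grid() if grid is None else np.asarray(grid, dtype=np.int64)
    wf = w.astype(float)
    baseline = (
        0.05
        + 0.42 * _sigmoid(wf, 715.0, 15.0)          # red edge to NIR plateau
        + 0.06 * _gauss(wf, 550.0, 30.0)            # green bump
        - 0.05 * _gauss(wf, 1200.0, 35.0)           # minor water feature
        - 0.16 * _gauss(wf, 1450.0, 40.0)           # water trough
        - 0.26 * _gauss(wf, 1940.0, 55.0)           # deep water trough
        - 0.12 * _sigmoid(wf, 2150.0, 120.0)        # SWIR2 decline
    )
    baseline = np.clip(baseline, 0.01, 0.99)
    sigs = np.vstack(
        [
            -(_gauss(wf, 680.0, 40.0) + 0.6 * _gauss(wf, 550.0, 35.0)),  # chlorophyll
            _sigmoid(wf, 760.0, 20.0) * (1.0 - _sigmoid(wf, 1350.0, 60.0)),  # NIR structure
            -_gauss(wf, 1650.0, 110.0),                                   # SWIR1
            -_gauss(wf, 2150.0, 110.0),                                   # SWIR2
        ]
    )
    sigs /= np.max(np.abs(sigs), axis=1, keepdims=True)
    return baseline, sigs


@dataclass
class DatasetTruth:
    """Exact generative map, for oracle checks against fitted models."""

    grid: np.ndarray
    baseline: np.ndarray
    signatures: np.ndarray         # (4, p)
    mixing: np.ndarray             # (4, 4): signature weights = mixing @ z
    amplitude: float
    trait_names: list[str]
    trait_mid: np.ndarray
    trait_scale: np.ndarray        # trait = mid + scale * z
    z: np.ndarray                  # (n, 4) latent trait z-scores per record
    noiseless_traits: pd.DataFrame
    clean_reflectance: np.ndarray  # (n, p) before noise/jumps

    def spectral_map(self, trait: str) -> np.ndarray:
        """The true linear functional giving the trait (up to constant) from a
        clean spectrum: trait - mid = scale * e_t' (amp * mixing)^-1 S^+ (r - baseline)."""
        t = self.trait_names.index(trait)
        pinv = np.linalg.pinv(self.signatures)          # (p, 4)
        inv_mix = np.linalg.inv(self.amplitude * self.mixing)
        return self.trait_scale[t] * (pinv @ inv_mix.T[:, t])


def _correlated_z(rng: np.random.Generator, n: int, t: int, rho: float) -> np.ndarray:
    """n draws of t-dim standard normals with common correlation rho,
    truncated at +-3 sd so linearly mapped traits stay inside their ranges."""
    corr = np.full((t, t), rho) + (1.0 - rho) * np.eye(t)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, t)) @ chol.T
    return np.clip(z, -3.0, 3.0)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, window: int = 41) -> np.ndarray:
    white = rng.standard_normal(shape)
    kernel = np.ones(window) / window
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, white)
    sm /= sm.std() if sm.std() > 0 else 1.0
    return sd * sm


def generate_dataset(config: GeneratorConfig | None = None):
    """Draw a spectra + trait dataset from the stated world.

    Returns ``(records, trait_table, truth)``.  Per record, the latent trait
    z-scores combine a genotype effect with repetition noise; traits are an
    exact linear function of the latents plus measurement noise, and the
    spectrum embeds the latents through the four signatures.  The whole
    dataset is a pure function of ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    grid = default_grid()
    baseline, sigs = generate_basis(grid)
    names = list(cfg.trait_ranges)
    n_traits = len(names)
    if n_traits != sigs.shape[0]:
        # mixing maps trait latents into the 4 signature channels; require a
        # square invertible map so every trait stays spectrally recoverable
        raise ValueError(
            f"generator supports exactly {sigs.shape[0]} traits (got {n_traits}); "
            "adjust trait_ranges"
        )
    ranges = np.array([cfg.trait_ranges[t] for t in names])
    mid = ranges.mean(axis=1)
    scale = (ranges[:, 1] - ranges[:, 0]) / 6.0  # +-3 sd spans the range

    n = cfg.n_genotypes * cfg.repetitions
    zg = _correlated_z(rng, cfg.n_genotypes, n_traits, cfg.trait_correlation)
    a = np.sqrt(cfg.genotype_variance_frac)
    b = np.sqrt(1.0 - cfg.genotype_variance_frac)
    z = np.clip(a * np.repeat(zg, cfg.repetitions, axis=0) + b * rng.standard_normal((n, n_traits)), -3.0, 3.0)

    # well-conditioned random mixing of trait latents into signature channels
    q, _ = np.linalg.qr(rng.standard_normal((n_traits, n_traits)))
    mixing = q + 0.2 * np.eye(n_traits)

    weights = z @ mixing.T                             # (n, 4) signature weights
    clean = baseline + cfg.signature_amplitude * weights @ sigs
    spectra = clean.copy()
    if cfg.spectral_noise_sd > 0:
        if cfg.smooth_noise:
            spectra = spectra + _smooth_noise(rng, clean.shape, cfg.spectral_noise_sd)
        else:
            spectra = spectra + rng.normal(0.0, cfg.spectral_noise_sd, clean.shape)
    if cfg.add_jumps:
        for j, mag in zip(cfg.junctions, cfg.jump_magnitudes):
            spectra[:, grid > j] += mag
    spectra = np.clip(spectra, 0.0, 1.5)

    noiseless = mid + z * scale
    traits = noiseless + rng.normal(0.0, 1.0, noiseless.shape) * (
        cfg.trait_noise_frac * (ranges[:, 1] - ranges[:, 0])
    )
    traits = np.maximum(traits, 1e-3)  # trait tables require positive values

    records = []
    ids = []
    for g in range(cfg.n_genotypes):
        for r in range(cfg.repetitions):
            i = g * cfg.repetitions + r
            rec = SpectralRecord(
                spectrum=Spectrum(
                    wavelengths_nm=grid,
                    reflectance=spectra[i],
                    instrument_id="synthetic",
                    junction_wavelengths_nm=cfg.junctions,
                ),
                genotype=f"G{g:03d}",
                experiment="sim",
                repetition=r + 1,
                leaf_replicate=1,
            )
            records.append(rec)
            ids.append(rec.record_id)

    trait_df = pd.DataFrame(traits, columns=names, index=pd.Index(ids, name="record_id"))
    truth = DatasetTruth(
        grid=grid,
        baseline=baseline,
        signatures=sigs,
        mixing=mixing,
        amplitude=cfg.signature_amplitude,
        trait_names=names,
        trait_mid=mid,
        trait_scale=scale,
        z=z,
        noiseless_traits=pd.DataFrame(noiseless, columns=names, index=trait_df.index),
        clean_reflectance=clean,
    )
    return records, TraitTable(data=trait_df), truth


# ---------------------------------------------------------------------------
# Gas-exchange curve sets
# ---------------------------------------------------------------------------

@dataclass
class ACiSetConfig:
    n_curves: int = 50
    vcmax25_range: tuple[float, float] = (23.0, 280.0)
    tleaf_range: tuple[float, float] = (15.0, 35.0)
    j_ratio_range: tuple[float, float] = (1.3, 2.0)   # J = ratio * Vcmax25
    rd_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.5   # umol m-2 s-1 on A
    ci_levels: np.ndarray = dc_field(default_factory=lambda: fvcb.DEFAULT_CI_LEVELS.copy())
    kinetics: fvcb.FvCBKinetics = dc_field(default_factory=lambda: fvcb.GENERIC_C3_KINETICS)
    seed: int = 0


def generate_aci_set(config: ACiSetConfig | None = None):
    """Draw A-Ci curves with known parameters; returns
    ``(curves, true_photo_traits)``."""
    cfg = config or ACiSetConfig()
    rng = np.random.default_rng(cfg.seed)
    curves, truths = [], []
    for i in range(cfg.n_curves):
        v25 = rng.uniform(*cfg.vcmax25_range)
        tleaf = rng.uniform(*cfg.tleaf_range)
        vc = fvcb.vcmax_at_temperature(v25, tleaf, cfg.kinetics.E_Vcmax)
        j = rng.uniform(*cfg.j_ratio_range) * v25
        rd = rng.uniform(*cfg.rd_range)
        photo = fvcb.PhotoTraits(Vcmax=vc, J=j, Rd=rd, Tleaf=tleaf, Vcmax25=v25)
        curve = fvcb.simulate_aci(
            photo,
            cfg.ci_levels,
            noise_sd=cfg.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            kinetics=cfg.kinetics,
        )
        curves.append(
            fvcb.ACiCurve(
                ci=curve.ci, a=curve.a, tleaf_c=curve.tleaf_c,
                o_mmol_mol=curve.o_mmol_mol, record_id=f"curve{i:04d}",
            )
        )
        truths.append(photo)
    return curves, truths


# ---------------------------------------------------------------------------
# Ratio-linked world for the direct-vs-components comparison
# ---------------------------------------------------------------------------

def generate_ratio_dataset(
    n: int = 240,
    seed: int = 0,
    component_noise_frac: float = 0.25,
    spectral_noise_sd: float = 0.002,
):
    """World where the ratio of two traits is the spectrally encoded quantity.

    The spectrum carries the ratio signal (chlorophyll-like signature); the
    denominator has large spectrum-independent variation, which the numerator
    inherits multiplicatively.  A model trained on the ratio directly sees a
    clean target, while models for numerator and denominator each carry the
    non-spectral noise, degrading the ratio-of-predictions route.

    Returns ``(X, grid, y_num, y_den)``.
    """
    rng = np.random.default_rng(seed)
    grid = default_grid()
    baseline, sigs = generate_basis(grid)
    z_ratio = np.clip(rng.standard_normal(n), -3, 3)
    z_other = np.clip(rng.standard_normal((n, 3)), -3, 3)
    weights = np.column_stack([z_ratio, z_other])
    X = baseline + 0.03 * weights @ sigs + _smooth_noise(rng, (n, grid.size), spectral_noise_sd)
    ratio = 100.0 + 15.0 * z_ratio                      # e.g. umol CO2 g-1 N s-1
    den = 1.75 + component_noise_frac * 1.75 * np.clip(rng.standard_normal(n), -2.5, 2.5)
    num = ratio * den
    return np.clip(X, 0.0, 1.5), grid, num, den
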