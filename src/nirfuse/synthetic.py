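"""Synthetic apricot-plum NIR spectra and quality traits.

Real diffuse-transmission spectra of stone fruit share a handful of robust
features on the 970–1700 nm grid: absorption troughs near 1180 nm (cell-wall
C–H, linked to firmness) and 1445 nm (O–H of water), a peak near 1285 nm
(C–H combinations of soluble sugars), baseline drift at the grid edges, and a
strong per-sample multiplicative scatter component.  The generator emulates
exactly these features, plus the tight empirical correlation structure of the
three quality traits — soluble solids content (SSC, °Brix), moisture content
(MC, mass fraction) and fruit firmness (FF, N) — so that every downstream
stage (preprocessing, splitting, PLSR, wavelength selection, Shapley
screening) can be exercised and tested without access to proprietary fruit
data.

The trait sampler is a Gaussian copula: standard-normal draws are coloured by
a Cholesky (or, for semi-definite matrices, eigenvalue) factor of the target
correlation matrix and then rescaled to the trait means/SDs.  Spectra are a
smooth base curve plus per-peak Gaussian bands whose amplitudes are affine in
the traits, a per-sample affine scatter term, an edge-localised drift ramp and
i.i.d. noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import SpectraBlock

TRAIT_NAMES = ("ssc_brix", "mc_fraction", "ff_newton")

#: Pairwise trait correlations observed on 120 commercial-maturity fruit:
#: SSC–MC = −0.96, SSC–FF = +0.81, MC–FF = −0.79.
DEFAULT_TRAIT_CORR = np.array([
    [1.00, -0.96, 0.81],
    [-0.96, 1.00, -0.79],
    [0.81, -0.79, 1.00],
])


class SyntheticConfigError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic spectra/trait generator.

    peak_trait_loadings is a (n_peaks, 3) matrix: row k gives the amplitude
    added to the Gaussian band at peak_centers[k] per unit of each trait
    (columns ordered SSC, MC, FF).  Negative loadings deepen a trough.
    """

    n_samples: int = 120
    grid: np.ndarray = field(
        default_factory=lambda: 970.0 + 5.6 * np.arange(129))
    trait_means: np.ndarray = field(
        default_factory=lambda: np.array([15.0, 0.85, 12.0]))
    trait_sds: np.ndarray = field(
        default_factory=lambda: np.array([2.0, 0.03, 3.0]))
    trait_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRAIT_CORR.copy())
    peak_centers: np.ndarray = field(
        default_factory=lambda: np.array([1180.0, 1285.0, 1445.0]))
    peak_widths: np.ndarray = field(
        default_factory=lambda: np.array([45.0, 40.0, 55.0]))
    peak_trait_loadings: np.ndarray = field(
        default_factory=lambda: np.array([
            #  SSC(/°Brix)  MC(/fraction)  FF(/N)
            [0.0,          0.0,          -0.008],   # 1180 nm trough: firmness
            [0.012,        0.0,           0.0],     # 1285 nm peak: sugars
            [0.0,         -1.0,           0.0],     # 1445 nm trough: water
        ]))
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    baseline_edge_amp: float = 0.002
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float).ravel()
        self.trait_means = np.asarray(self.trait_means, float).ravel()
        self.trait_sds = np.asarray(self.trait_sds, float).ravel()
        self.trait_corr = np.asarray(self.trait_corr, float)
        self.peak_centers = np.asarray(self.peak_centers, float).ravel()
        self.peak_widths = np.broadcast_to(
            np.asarray(self.peak_widths, float), self.peak_centers.shape).copy()
        self.peak_trait_loadings = np.atleast_2d(
            np.asarray(self.peak_trait_loadings, float))
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise SyntheticConfigError("n_samples must be >= 1")
        if self.grid.size > 1 and np.any(np.diff(self.grid) <= 0):
            raise SyntheticConfigError("grid must be strictly increasing")
        C = self.trait_corr
        if C.shape != (3, 3):
            raise SyntheticConfigError("trait_corr must be 3×3")
        if not np.allclose(C, C.T, atol=1e-12):
            raise SyntheticConfigError("trait_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise SyntheticConfigError("trait_corr must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise SyntheticConfigError("trait_corr is not positive semi-definite")
        if np.any(self.trait_sds < 0) or np.any(self.peak_widths <= 0):
            raise SyntheticConfigError("trait_sds must be >= 0, peak_widths > 0")
        if self.noise_sd < 0:
            raise SyntheticConfigError("noise_sd must be >= 0")
        lo, hi = self.grid.min(), self.grid.max()
        if np.any((self.peak_centers < lo) | (self.peak_centers > hi)):
            raise SyntheticConfigError("all peak_centers must lie within the grid range")
        if self.peak_trait_loadings.shape != (self.peak_centers.size, 3):
            raise SyntheticConfigError("peak_trait_loadings must be (n_peaks, 3)")


@dataclass
class TraitTable:
    """Per-sample quality traits: SSC (°Brix), MC (fraction), FF (N)."""

    values: np.ndarray          # (n, 3), columns ordered as TRAIT_NAMES
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[1] != 3:
            raise ValueError("TraitTable needs exactly 3 columns (SSC, MC, FF)")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, TRAIT_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(TRAIT_NAMES),
                            index=pd.Index(self.sample_ids, name="sample_id"))


def default_config(**overrides) -> SyntheticConfig:
    """The study conditions: 120 samples on a 129-point grid starting at
    970 nm with a 5.6 nm step, the observed trait correlations, and bands at
    1180/1285/1445 nm.  Keyword overrides replace individual fields."""
    cfg = SyntheticConfig()
    return replace(cfg, **overrides) if overrides else cfg


def _corr_factor(C: np.ndarray) -> np.ndarray:
    """Square root of a correlation matrix: Cholesky when PD, eigen otherwise."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        if w.min() < -1e-10:
            raise SyntheticConfigError("trait_corr is not positive semi-definite")
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def sample_traits(config: SyntheticConfig,
                  rng: np.random.Generator | None = None) -> TraitTable:
    """Draw correlated traits via a Gaussian copula.

    MC is clipped into [0, 1] after generation since it is a mass fraction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = _corr_factor(config.trait_corr)
    z = rng.standard_normal((config.n_samples, 3)) @ L.T
    vals = config.trait_means + z * config.trait_sds
    vals[:, 1] = np.clip(vals[:, 1], 0.0, 1.0)
    return TraitTable(vals)


def _gaussian_bands(grid: np.ndarray, centers: np.ndarray,
                    widths: np.ndarray) -> np.ndarray:
    """(n_peaks, p) unit-height Gaussians on the grid."""
    return np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / widths[:, None]) ** 2)


def base_curve(grid: np.ndarray) -> np.ndarray:
    """Smooth trait-independent transmittance-like base spectrum with the
    characteristic troughs at 1180/1445 nm and peak at 1285 nm."""
    shapes = _gaussian_bands(grid, np.array([1180.0, 1285.0, 1445.0]),
                             np.array([45.0, 40.0, 55.0]))
    return 0.7 - 0.12 * shapes[0] + 0.08 * shapes[1] - 0.22 * shapes[2]


def edge_drift(grid: np.ndarray, amp: float,
               lo: float = 1040.0, hi: float = 1625.0) -> np.ndarray:
    """Additive baseline drift proportional to the distance outside
    [lo, hi] nm and exactly zero inside — the reason those edges get trimmed."""
    below = np.clip(lo - grid, 0.0, None)
    above = np.clip(grid - hi, 0.0, None)
    return amp * (below + above)


def render_spectra(traits: TraitTable, config: SyntheticConfig,
                   rng: np.random.Generator | None = None) -> SpectraBlock:
    """Render one spectrum per trait row.

    spectrum_i = (1 + slope_i) · clean_i + offset_i + noise, where
    clean_i = base + Σ_k (loadings_k · traits_i) · Gaussian_k + edge drift.
    The scatter stream is derived from seed+1 and the noise stream from
    seed+2 so that traits, scatter and noise are independent.
    """
    config.validate()
    if traits.n_samples != config.n_samples:
        raise SyntheticConfigError(
            f"traits row count {traits.n_samples} != n_samples {config.n_samples}")
    n, p = config.n_samples, config.grid.size
    bands = _gaussian_bands(config.grid, config.peak_centers, config.peak_widths)
    amplitudes = traits.values @ config.peak_trait_loadings.T        # (n, n_peaks)
    clean = base_curve(config.grid)[None, :] + amplitudes @ bands
    clean = clean + edge_drift(config.grid, config.baseline_edge_amp)[None, :]

    scatter_rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    slopes = scatter_rng.standard_normal(n) * config.scatter_slope_sd
    offsets = scatter_rng.standard_normal(n) * config.scatter_offset_sd
    noise_rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    noise = noise_rng.standard_normal((n, p)) * config.noise_sd

    values = (1.0 + slopes)[:, None] * clean + offsets[:, None] + noise
    return SpectraBlock(config.grid.copy(), values, list(traits.sample_ids))


def generate(config: SyntheticConfig | None = None) -> tuple[SpectraBlock, TraitTable]:
    """Convenience wrapper: traits then spectra, all driven by config.seed."""
    config = default_config() if config is None else config
    traits = sample_traits(config)
    return render_spectra(traits, config), traits


def planted_band_data(n_samples: int = 120, n_bands: int = 99,
                      planted: tuple[int, ...] = (20, 50, 80),
                      signal_scale: float = 1.0, noise_sd: float = 0.05,
                      trait: str = "ssc_brix", seed: int = 0,
                      config: SyntheticConfig | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Feature matrix with a handful of informative columns for selector tests.

    The response is one trait drawn from the correlated trait model; the
    planted columns carry the standardised response at ``signal_scale`` on top
    of band noise, every other column is pure noise.  Returns (X, y, planted).
    """
    cfg = default_config(n_samples=n_samples, seed=seed) if config is None else config
    rng = np.random.default_rng(seed)
    traits = sample_traits(cfg, rng=rng)
    y = traits.column(trait)
    z = (y - y.mean()) / y.std()
    X = rng.standard_normal((n_samples, n_bands)) * noise_sd
    for j in planted:
        X[:, j] += signal_scale * z
    return X, y, tuple(planted)


def write_traits(traits: TraitTable, path) -> None:
    traits.to_frame().to_csv(path)


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in TRAIT_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"traits file {path} missing columns {missing}")
    return TraitTable(df[list(TRAIT_NAMES)].to_numpy(float),
                      [str(i) for i in df.index])
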