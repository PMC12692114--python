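"""Cross-parameter band fusion, Shapley attribution and multi-stage screening.

The fusion step pools the characteristic wavelengths selected independently
for each quality trait into one de-duplicated band set, exploiting the strong
physiological coupling of the traits (sugar accumulation, water loss and
cell-wall softening move together).  Each band in the fused model is then
attributed a Shapley value

    φ_i = Σ_{S ⊆ N\\{i}}  |S|! (|N|−|S|−1)! / |N|!  · [ f(S ∪ {i}) − f(S) ]

where f(S) evaluates the model with out-of-subset wavelengths frozen at
background (calibration-mean) values.  Because PLSR prediction is affine in
the features, the exact enumeration collapses to the closed form
φ_ij = B_j (x_ij − m_j); both routes are implemented, the enumeration serving
as the oracle for the closed form.  Multi-stage screening repeatedly drops
bands whose mean |φ| over the calibration samples falls below a threshold and
refits, producing a nested sequence of simpler models with an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np

from .model import (DatasetSplit, Metrics, PLSRModel, compute_metrics,
                    fit_plsr, predict)
from .synthetic import TraitTable

EXACT_ENUMERATION_GUARD = 20


class FusionError(ValueError):
    """Raised on contract violations in fusion or screening."""


# ---------------------------------------------------------------------------
# Band fusion
# ---------------------------------------------------------------------------

@dataclass
class BandSet:
    wavelengths: list[float]                 # sorted, unique, nm
    provenance: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, float)
        if w.size > 1 and np.any(np.diff(w) <= 0):
            raise FusionError("BandSet wavelengths must be sorted strictly increasing")
        if not self.provenance:
            self.provenance = [[] for _ in self.wavelengths]
        if len(self.provenance) != len(self.wavelengths):
            raise FusionError("provenance length mismatch")

    def __len__(self) -> int:
        return len(self.wavelengths)


def fuse_bands(band_lists: list[list[float]],
               sources: list[str] | None = None) -> BandSet:
    """Sorted, de-duplicated union of per-trait wavelength lists.

    Wavelengths are matched exactly after rounding to 3 decimals (the
    precision at which instrument grids are reported); provenance records
    which source list(s) contributed each retained band.
    """
    if not band_lists or any(len(b) == 0 for b in band_lists):
        raise FusionError("each band list must be non-empty")
    sources = sources or [f"list{i}" for i in range(len(band_lists))]
    seen: dict[float, list[str]] = {}
    for src, bands in zip(sources, band_lists):
        for w in bands:
            key = round(float(w), 3)
            tags = seen.setdefault(key, [])
            if src not in tags:
                tags.append(src)
    wavelengths = sorted(seen)
    return BandSet(wavelengths, [seen[w] for w in wavelengths])


def percent_reduction(n_before: int, n_after: int) -> float:
    """Band-count reduction in percent, e.g. 38 → 17 gives 55.26."""
    if n_before <= 0:
        raise FusionError("n_before must be positive")
    return 100.0 * (n_before - n_after) / n_before


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

@dataclass
class ShapMatrix:
    values: np.ndarray          # (n_samples, n_bands), trait units
    base_value: float           # model output at the background point
    band_ids: list


def value_function(model: PLSRModel, x: np.ndarray, subset,
                   background_means: np.ndarray) -> float:
    """f(S): model output with in-subset features at x, the rest frozen at
    the background means (interventional, independence-assuming)."""
    x = np.asarray(x, float).ravel()
    bg = np.asarray(background_means, float).ravel()
    p = model.coefficients.size
    if x.size != p or bg.size != p:
        raise FusionError("x/background length does not match model band count")
    subset = list(subset)
    if any(not 0 <= j < p for j in subset):
        raise FusionError(f"subset index out of range 0..{p - 1}")
    z = bg.copy()
    z[subset] = x[subset]
    return float(predict(model, z[None, :])[0])


def shap_exact(model: PLSRModel, X: np.ndarray,
               background_means: np.ndarray) -> ShapMatrix:
    """Shapley values by full subset enumeration (guarded at 20 bands)."""
    X = np.atleast_2d(np.asarray(X, float))
    p = model.coefficients.size
    if p > EXACT_ENUMERATION_GUARD:
        raise FusionError(
            f"{p} bands exceed the enumeration guard of {EXACT_ENUMERATION_GUARD}; "
            "use shap_linear for affine models")
    bg = np.asarray(background_means, float).ravel()
    base = value_function(model, bg, [], bg)
    others = list(range(p))
    phi = np.zeros((X.shape[0], p))
    for s, x in enumerate(X):
        # cache f(S) over all subsets once per sample
        fcache = {frozenset(): base}
        for r in range(1, p + 1):
            for sub in combinations(others, r):
                fcache[frozenset(sub)] = value_function(model, x, sub, bg)
        for i in range(p):
            rest = [j for j in others if j != i]
            total = 0.0
            for r in range(p):
                wgt = factorial(r) * factorial(p - r - 1) / factorial(p)
                for sub in combinations(rest, r):
                    S = frozenset(sub)
                    total += wgt * (fcache[S | {i}] - fcache[S])
            phi[s, i] = total
    return ShapMatrix(phi, base, list(model.wavelength_ids))


def shap_linear(model: PLSRModel, X: np.ndarray,
                background_means: np.ndarray) -> ShapMatrix:
    """Closed-form Shapley values for the affine PLSR predictor:
    φ_ij = B_j (x_ij − m_j), base value = prediction at the background."""
    X = np.atleast_2d(np.asarray(X, float))
    bg = np.asarray(background_means, float).ravel()
    if X.shape[1] != model.coefficients.size or bg.size != model.coefficients.size:
        raise FusionError("X/background width does not match model band count")
    base = float(predict(model, bg[None, :])[0])
    phi = (X - bg) * model.coefficients[None, :]
    return ShapMatrix(phi, base, list(model.wavelength_ids))


def band_importance(shap: ShapMatrix) -> np.ndarray:
    """Per-band importance: mean over samples of |φ|, in trait units."""
    if shap.values.shape[0] < 1:
        raise FusionError("need at least one sample")
    return np.abs(shap.values).mean(axis=0)


# ---------------------------------------------------------------------------
# Multi-stage screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningStage:
    threshold: float | None           # None for the incipient stage
    retained: BandSet
    retained_indices: list[int]       # indices into the stage-0 feature matrix
    model: PLSRModel | None
    cal_metrics: Metrics | None
    val_metrics: Metrics | None
    importances: np.ndarray | None    # per retained band, from this stage's model
    degenerate: bool = False


def screen_stages(X: np.ndarray, y: np.ndarray, split: DatasetSplit,
                  initial: BandSet, thresholds: list[float],
                  n_components: int = 5, one_shot: bool = False
                  ) -> list[ScreeningStage]:
    """Iterative Shapley-threshold band screening.

    Stage 0 fits on the full initial band set (columns of X, calibration rows
    only) and records metrics and mean-|φ| importances over the calibration
    samples.  Each subsequent stage drops bands whose importance — from the
    previous stage's model (or stage 0's when ``one_shot``) — is below that
    stage's threshold, refits and re-evaluates.  Retained sets are nested by
    construction; a stage that would retain nothing is marked degenerate, as
    are all later stages.
    """
    thr = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thr, thr[1:])):
        raise FusionError("thresholds must be strictly increasing")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[1] != len(initial):
        raise FusionError("X column count does not match the initial band set")
    cal, val = split.calibration_ids, split.validation_ids

    def fit_stage(indices: list[int], threshold: float | None) -> ScreeningStage:
        Xi = X[:, indices]
        a = max(1, min(n_components, len(cal) - 1, len(indices)))
        m = fit_plsr(Xi[cal], y[cal], a)
        bg = Xi[cal].mean(axis=0)
        shap = shap_linear(m, Xi[cal], bg)
        bands = BandSet([initial.wavelengths[j] for j in indices],
                        [list(initial.provenance[j]) for j in indices])
        return ScreeningStage(
            threshold=threshold, retained=bands, retained_indices=list(indices),
            model=m,
            cal_metrics=compute_metrics(y[cal], predict(m, Xi[cal])),
            val_metrics=compute_metrics(y[val], predict(m, Xi[val])),
            importances=band_importance(shap))

    stages = [fit_stage(list(range(X.shape[1])), None)]
    for t in thr:
        prev = stages[-1]
        if prev.degenerate:
            stages.append(ScreeningStage(t, prev.retained, prev.retained_indices,
                                         None, None, None, None, degenerate=True))
            continue
        ref = stages[0] if one_shot else prev
        keep_local = np.nonzero(np.asarray(ref.importances) >= t)[0]
        keep = [ref.retained_indices[j] for j in keep_local
                if ref.retained_indices[j] in set(prev.retained_indices)]
        if not keep:
            empty = BandSet([], [])
            stages.append(ScreeningStage(t, empty, [], None, None, None, None,
                                         degenerate=True))
            continue
        stages.append(fit_stage(keep, t))
    return stages


# ---------------------------------------------------------------------------
# Trait correlation
# ---------------------------------------------------------------------------

def pearson_matrix(traits: TraitTable | np.ndarray) -> np.ndarray:
    """3×3 Pearson product-moment correlation matrix of SSC, MC and FF."""
    vals = traits.values if isinstance(traits, TraitTable) else np.asarray(traits, float)
    if vals.shape[0] < 3:
        raise FusionError("need at least 3 samples for a correlation matrix")
    if np.any(vals.std(axis=0) == 0):
        raise FusionError("constant trait column: correlation undefined")
    return np.corrcoef(vals, rowvar=False)
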