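"""Spectral containers, CSV I/O, grid trimming and the standard NIR pretreatments.

The transforms implemented here are the classical per-spectrum corrections used
in diffuse-transmission fruit spectroscopy: min–max scaling, standard normal
variate (SNV), multiplicative scatter correction (MSC) and Savitzky–Golay
smoothing/derivatives.  All of them operate row-wise (one row = one sample
spectrum) and preserve sample count and order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


class SpectraError(ValueError):
    """Raised when a spectra block violates its contract."""


@dataclass
class SpectraBlock:
    """A samples × wavelengths matrix on a strictly increasing nm grid.

    Attributes
    ----------
    wavelengths : (p,) float array, strictly increasing, in nm.
    values : (n, p) float array; row i is the spectrum of sample i.
    sample_ids : list of n identifiers (strings).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]
        if self.values.shape[1] != self.wavelengths.size:
            raise SpectraError(
                f"column count {self.values.shape[1]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise SpectraError("sample_ids length does not match row count")
        if np.any(~np.isfinite(self.values)):
            raise SpectraError("spectra contain non-finite values")
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraError("wavelength grid must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray | None = None,
                  wavelengths: np.ndarray | None = None) -> "SpectraBlock":
        return SpectraBlock(
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            values=self.values if values is None else values,
            sample_ids=list(self.sample_ids),
        )


def read_spectra(path) -> SpectraBlock:
    """Read a spectra CSV: row 1 = wavelengths (nm), then one sample per row,
    first column = sample id."""
    df = pd.read_csv(path, header=0, index_col=0)
    try:
        wavelengths = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise SpectraError(f"non-numeric wavelength header in {path}: {exc}") from exc
    if wavelengths.size > 1 and np.any(np.diff(wavelengths) <= 0):
        raise SpectraError(f"wavelength header in {path} is not strictly increasing")
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise SpectraError(
            f"non-numeric or missing cell at row {bad[0] + 2}, column {bad[1] + 2} in {path}"
        )
    return SpectraBlock(wavelengths, values, [str(i) for i in df.index])


def write_spectra(block: SpectraBlock, path) -> None:
    df = pd.DataFrame(block.values,
                      index=pd.Index(block.sample_ids, name="sample_id"),
                      columns=[repr(float(w)) for w in block.wavelengths])
    df.to_csv(path)


def trim_head_tail(block: SpectraBlock, n_head: int, n_tail: int) -> SpectraBlock:
    """Drop the first `n_head` and last `n_tail` wavelength points.

    The head/tail regions of the instrument's range carry detector noise and
    background, so they are removed before any modelling.
    """
    if n_head < 0 or n_tail < 0:
        raise SpectraError("trim counts must be non-negative")
    p = block.n_wavelengths
    if n_head + n_tail >= p:
        raise SpectraError(
            f"cannot trim {n_head}+{n_tail} points from a {p}-point grid"
        )
    sl = slice(n_head, p - n_tail)
    return block.copy_with(values=block.values[:, sl],
                           wavelengths=block.wavelengths[sl])


def restrict_range(block: SpectraBlock, lo_nm: float, hi_nm: float) -> SpectraBlock:
    """Keep columns with lo_nm <= wavelength <= hi_nm (closed interval)."""
    if not lo_nm < hi_nm:
        raise SpectraError("lo_nm must be < hi_nm")
    mask = (block.wavelengths >= lo_nm) & (block.wavelengths <= hi_nm)
    if not mask.any():
        raise SpectraError(f"no wavelengths in [{lo_nm}, {hi_nm}] nm")
    return block.copy_with(values=block.values[:, mask],
                           wavelengths=block.wavelengths[mask])


def _check_nonconstant_rows(values: np.ndarray, ids, what: str) -> None:
    spans = values.max(axis=1) - values.min(axis=1)
    bad = np.nonzero(spans == 0)[0]
    if bad.size:
        raise SpectraError(f"{what}: constant spectrum for sample {ids[bad[0]]}")


def minmax_rows(block: SpectraBlock) -> SpectraBlock:
    """Affinely map each spectrum onto [0, 1] (row min -> 0, row max -> 1)."""
    _check_nonconstant_rows(block.values, block.sample_ids, "min–max")
    lo = block.values.min(axis=1, keepdims=True)
    hi = block.values.max(axis=1, keepdims=True)
    return block.copy_with(values=(block.values - lo) / (hi - lo))


def snv(block: SpectraBlock) -> SpectraBlock:
    """Standard normal variate: centre each spectrum and scale to unit sample
    standard deviation (n−1 divisor)."""
    _check_nonconstant_rows(block.values, block.sample_ids, "SNV")
    mean = block.values.mean(axis=1, keepdims=True)
    sd = block.values.std(axis=1, ddof=1, keepdims=True)
    return block.copy_with(values=(block.values - mean) / sd)


def msc(block: SpectraBlock, reference: np.ndarray | None = None) -> SpectraBlock:
    """Multiplicative scatter correction.

    Each spectrum x is regressed on the reference (default: the column-mean
    spectrum of the block) as x ≈ a + b·ref; the corrected spectrum is
    (x − a) / b, undoing per-sample additive offset and multiplicative gain.
    """
    if block.n_wavelengths < 2:
        raise SpectraError("MSC needs at least 2 wavelengths")
    ref = block.values.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.size != block.n_wavelengths:
        raise SpectraError("MSC reference length does not match wavelength count")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom < 1e-24:
        raise SpectraError("MSC reference spectrum is constant")
    X = block.values
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    small = np.nonzero(np.abs(b) < 1e-12)[0]
    if small.size:
        raise SpectraError(
            f"MSC: slope below tolerance for sample {block.sample_ids[small[0]]}"
        )
    a = X.mean(axis=1) - b * ref.mean()
    return block.copy_with(values=(X - a[:, None]) / b[:, None])


def savitzky_golay(block: SpectraBlock, window: int, polyorder: int,
                   deriv: int = 0, delta: float = 1.0) -> SpectraBlock:
    """Per-row Savitzky–Golay smoothing / derivative.

    Edges are handled by evaluating the polynomial fitted to the terminal
    windows (scipy's ``mode="interp"``).  ``delta`` is the grid spacing used to
    scale derivatives; the filter assumes a uniform grid.
    """
    if window % 2 == 0:
        raise SpectraError("Savitzky–Golay window must be odd")
    if polyorder >= window:
        raise SpectraError("polyorder must be < window")
    if window > block.n_wavelengths:
        raise SpectraError("window exceeds wavelength count")
    out = savgol_filter(block.values, window_length=window, polyorder=polyorder,
                        deriv=deriv, delta=delta, axis=1, mode="interp")
    return block.copy_with(values=out)
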