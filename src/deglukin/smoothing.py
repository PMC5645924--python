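"""Trajectory smoothing: the seven methods offered for landmark series.

All methods act on a scalar series sampled on a uniform grid and return a
series of the same length.  NaN samples are excluded from fitting and
re-inserted in the output, so missing frames never leak into neighbouring
estimates.  Smoothing is applied to anatomical-frame component series before
differentiation.

Methods
-------
``moving_average``
    Centered mean; near the edges the window shrinks symmetrically to the
    largest odd width that fits, so the endpoints pass through unchanged.
``savitzky_golay``
    Local least-squares polynomial (scipy); at the edges the polynomial is
    fitted on the one-sided window and evaluated at the edge sample.
``lowess`` / ``loess`` / ``robust_lowess`` / ``robust_loess``
    k-nearest-neighbour locally weighted regression with tricube weights;
    local degree 1 (lowess) or 2 (loess); robust variants run five bisquare
    re-weighting iterations.
``polynomial``
    One global least-squares polynomial in time.
``none``
    Identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter as _scipy_savgol

__all__ = [
    "SmoothingSpec",
    "smooth_series",
    "moving_average",
    "savitzky_golay",
    "lowess_family",
    "polynomial_fit",
    "METHODS",
    "DEFAULT_SPEC",
]

METHODS = (
    "none",
    "moving_average",
    "polynomial",
    "lowess",
    "loess",
    "savitzky_golay",
    "robust_lowess",
    "robust_loess",
)

ROBUST_ITERATIONS = 5


@dataclass(frozen=True)
class SmoothingSpec:
    """Method choice plus its span/degree parameters.

    span: odd window length in samples (moving_average, savitzky_golay),
    neighbour count k or fraction of the series length in (0, 1] (the lowess
    family).  degree: polynomial degree (polynomial, savitzky_golay).
    """

    method: str = "moving_average"
    span: float = 5
    degree: int = 2

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown smoothing method {self.method!r}; one of {METHODS}")
        if self.method in ("moving_average", "savitzky_golay"):
            span = self.span
            if span != int(span) or int(span) < 3 or int(span) % 2 == 0:
                raise ValueError(
                    f"{self.method} span must be an odd integer >= 3, got {self.span}"
                )
        if self.method == "savitzky_golay" and self.degree >= int(self.span):
            raise ValueError(
                f"savitzky_golay degree ({self.degree}) must be < span ({int(self.span)})"
            )
        if self.method in ("lowess", "loess", "robust_lowess", "robust_loess"):
            if self.span <= 0:
                raise ValueError("lowess-family span must be positive")
            if self.span > 1 and (self.span != int(self.span) or int(self.span) < 3):
                raise ValueError("lowess-family absolute span must be an integer >= 3")
        if self.method == "polynomial" and (self.degree < 0 or self.degree != int(self.degree)):
            raise ValueError("polynomial degree must be a non-negative integer")


#: Default smoothing: moving average with span 5.
DEFAULT_SPEC = SmoothingSpec(method="moving_average", span=5)


def moving_average(y: np.ndarray, span: int) -> np.ndarray:
    """Centered moving mean with symmetric shrinking edge windows.

    At sample i the half-width is min((span-1)//2, i, n-1-i): the window is
    always odd and centered, reaching width 1 at the endpoints (endpoints are
    returned unchanged).
    """
    y = np.asarray(y, dtype=float)
    if span != int(span) or int(span) < 3 or int(span) % 2 == 0:
        raise ValueError(f"span must be an odd integer >= 3, got {span}")
    span = int(span)
    n = y.size
    h = (span - 1) // 2
    out = np.empty(n)
    for i in range(n):
        hi = min(h, i, n - 1 - i)
        out[i] = y[i - hi : i + hi + 1].mean()
    return out


def savitzky_golay(y: np.ndarray, span: int, degree: int) -> np.ndarray:
    """Savitzky-Golay local polynomial filter.

    Interior samples use the standard centered convolution; the first/last
    half-windows are the fitted one-sided window polynomial evaluated at those
    samples (scipy's ``mode="interp"``).
    """
    y = np.asarray(y, dtype=float)
    if span != int(span) or int(span) < 3 or int(span) % 2 == 0:
        raise ValueError(f"span must be an odd integer >= 3, got {span}")
    span = int(span)
    if degree >= span:
        raise ValueError(f"degree ({degree}) must be < span ({span})")
    if y.size < span:
        raise ValueError(f"series length {y.size} shorter than span {span}")
    return _scipy_savgol(y, window_length=span, polyorder=degree, mode="interp")


def _resolve_k(span: float, n: int) -> int:
    if 0 < span <= 1:
        k = int(np.ceil(span * n))
        k = max(k, 3)
    else:
        k = int(span)
    if k < 3:
        raise ValueError(f"lowess-family span resolves to k={k} < 3")
    if k > n:
        raise ValueError(f"lowess-family span k={k} exceeds series length {n}")
    return k


def _tricube(d: np.ndarray, dmax: float) -> np.ndarray:
    if dmax == 0:
        return np.ones_like(d)
    w = 1.0 - (np.abs(d) / dmax) ** 3
    return np.clip(w, 0.0, None) ** 3


def lowess_family(
    y: np.ndarray,
    span: float,
    variant: str = "lowess",
    t: np.ndarray | None = None,
) -> np.ndarray:
    """Locally weighted regression at each sample over its k nearest neighbours.

    variant: lowess (local degree 1), loess (degree 2), robust_lowess,
    robust_loess.  Robust variants run :data:`ROBUST_ITERATIONS` bisquare
    re-weighting passes with scale 6 * median |residual|.
    """
    variants = {"lowess": 1, "loess": 2, "robust_lowess": 1, "robust_loess": 2}
    if variant not in variants:
        raise ValueError(f"unknown variant {variant!r}; one of {sorted(variants)}")
    local_degree = variants[variant]
    robust = variant.startswith("robust_")
    y = np.asarray(y, dtype=float)
    n = y.size
    t = np.arange(n, dtype=float) if t is None else np.asarray(t, dtype=float)
    k = _resolve_k(span, n)

    delta = np.ones(n)  # robustness weights
    fitted = y.copy()
    n_pass = ROBUST_ITERATIONS + 1 if robust else 1
    for _ in range(n_pass):
        for i in range(n):
            d = np.abs(t - t[i])
            nbr = np.argsort(d, kind="stable")[:k]
            w = _tricube(d[nbr], d[nbr].max()) * delta[nbr]
            if w.sum() == 0:
                w = delta[nbr] if delta[nbr].sum() > 0 else np.ones(k)
            # weighted polynomial fit of the local degree, evaluated at t[i]
            X = np.vander(t[nbr] - t[i], local_degree + 1, increasing=True)
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y[nbr] * sw, rcond=None)
            fitted[i] = coef[0]
        if not robust:
            break
        r = y - fitted
        s = np.median(np.abs(r))
        if s == 0:
            break
        delta = np.clip(1.0 - (r / (6.0 * s)) ** 2, 0.0, None) ** 2
    return fitted


def polynomial_fit(y: np.ndarray, degree: int, t: np.ndarray | None = None) -> np.ndarray:
    """Single global least-squares polynomial in time, evaluated at all samples."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if degree >= n:
        raise ValueError(f"degree ({degree}) must be < series length ({n})")
    t = np.arange(n, dtype=float) if t is None else np.asarray(t, dtype=float)
    if np.unique(t).size != t.size:
        raise ValueError("duplicate sample times: rank-deficient design")
    poly = np.polynomial.Polynomial.fit(t, y, degree)
    return poly(t)


def smooth_series(y: np.ndarray, spec: SmoothingSpec, t: np.ndarray | None = None) -> np.ndarray:
    """Dispatch smoothing per *spec*; NaNs are excluded from the fit and restored.

    Same length and time base as the input; ``method="none"`` is the identity.
    """
    if not isinstance(spec, SmoothingSpec):
        raise TypeError("spec must be a SmoothingSpec")
    y = np.asarray(y, dtype=float)
    if spec.method == "none":
        return y.copy()
    mask = ~np.isnan(y)
    n_valid = int(mask.sum())
    if n_valid < 2:
        raise ValueError(f"series has {n_valid} non-NA samples; need >= 2")
    t_all = np.arange(y.size, dtype=float) if t is None else np.asarray(t, dtype=float)
    yv, tv = y[mask], t_all[mask]
    if spec.method == "moving_average":
        sm = moving_average(yv, int(spec.span))
    elif spec.method == "savitzky_golay":
        sm = savitzky_golay(yv, int(spec.span), spec.degree)
    elif spec.method == "polynomial":
        deg = min(int(spec.degree), yv.size - 1)
        sm = polynomial_fit(yv, deg, t=tv)
    else:
        span = spec.span if spec.span <= 1 else min(int(spec.span), yv.size)
        sm = lowess_family(yv, span, variant=spec.method, t=tv)
    out = np.full_like(y, np.nan)
    out[mask] = sm
    return out
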