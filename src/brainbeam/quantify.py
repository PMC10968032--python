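"""Quantification of the simulated light distribution.

Four measures are computed from an energy volume (fluence F or
absorption density A):

* a 0-100 min-max normalization of the whole volume,
* per-layer energy percentages P_i = E_i / sum_i E_i * 100 (the fluence
  percentage FP and absorption percentage AP of the four tissue layers),
* the axial profile along the center column (through x = y = 7 mm),
  min-max normalized to [0, 1], with maximum-propagation-depth extraction
  at a fractional level of the column maximum (1%, 0.1%, 0.01%),
* full width at half maximum (FWHM) of lateral cuts through the center
  column at chosen depths, the proxy for optical field width.

Depths are reported as (k + 1) * voxel for voxel index k, so the deepest
voxel of the 140-slab grid reads 14.0 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tissue_model import LabeledVolume, layer_masks
from .transport import EnergyVolume

#: default relative-standard-error ceiling for trusting a threshold depth
NOISE_GUARD_MAX_RSE = 0.3


@dataclass
class NormalizedVolume:
    E_N: np.ndarray
    source_kind: str  # "fluence" or "absorption"


@dataclass
class LayerEnergySummary:
    """Per-layer energy percentages; ``percentages[i]`` is layer i+1."""

    percentages: np.ndarray
    source_kind: str

    def __getitem__(self, layer: int) -> float:
        """Percentage of layer 1..4."""
        return float(self.percentages[layer - 1])


@dataclass
class AxialProfile:
    """Center-column profile, min-max normalized to [0, 1].

    ``z_mm[k] = (k + 1) * voxel`` is the reported depth of voxel k;
    ``raw`` keeps the unnormalized column; ``rel_se`` the per-voxel
    relative standard error of the column (NaN when unavailable).
    """

    E_NZ: np.ndarray
    z_mm: np.ndarray
    raw: np.ndarray
    source_kind: str
    rel_se: np.ndarray | None = None


@dataclass
class DepthResult:
    depth_mm: float
    reached: bool
    level: float
    noise_guard_ok: bool = True
    rel_se_at_depth: float = float("nan")


@dataclass
class WidthProfile:
    """FWHM (mm) per depth, for X- and Y-axis cuts; NaN where undefined."""

    depths_mm: np.ndarray
    fwhm_x_mm: np.ndarray
    fwhm_y_mm: np.ndarray
    source_kind: str


def _component(E, kind):
    if isinstance(E, EnergyVolume):
        return E.F if kind == "fluence" else E.A
    return np.asarray(E)


def normalize_volume(E, kind: str = "fluence") -> NormalizedVolume:
    """Min-max rescale the energy volume to [0, 100]."""
    arr = _component(E, kind).astype(float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ValueError("constant volume: normalization undefined")
    return NormalizedVolume(E_N=(arr - lo) / (hi - lo) * 100.0, source_kind=kind)


def layer_percentages(E, labels: LabeledVolume, kind: str = "fluence") -> LayerEnergySummary:
    """Energy percentage per tissue layer (sums to 100 over the four layers)."""
    arr = _component(E, kind)
    if arr.shape != labels.labels.shape:
        raise ValueError("energy volume and label volume are not congruent")
    sums = np.array([float(arr[m].sum()) for m in layer_masks(labels)])
    total = sums.sum()
    if total <= 0:
        raise ValueError("zero total energy in the tissue layers")
    return LayerEnergySummary(percentages=sums / total * 100.0, source_kind=kind)


def axial_profile(E, labels: LabeledVolume | None = None, kind: str = "fluence") -> AxialProfile:
    """Center-column profile through (x, y) = (7, 7) mm, normalized to [0, 1]."""
    if isinstance(E, EnergyVolume):
        arr = _component(E, kind)
        ic, jc = E.column_index
        dx = E.voxel_size_mm
        rel_se = E.column_standard_error()
        if kind == "absorption":
            # A = mu_a F along the column: same relative noise as F
            rel_se = rel_se.copy()
    else:
        arr = np.asarray(E)
        ic, jc = arr.shape[0] // 2, arr.shape[1] // 2
        dx = labels.voxel_size_mm if labels is not None else 0.1
        rel_se = None
    col = arr[ic, jc, :].astype(float)
    lo, hi = float(col.min()), float(col.max())
    if hi == lo:
        raise ValueError("constant center column: normalization undefined")
    z = (np.arange(col.size) + 1) * dx
    return AxialProfile(
        E_NZ=(col - lo) / (hi - lo), z_mm=z, raw=col, source_kind=kind, rel_se=rel_se
    )


def depth_at_level(
    profile: AxialProfile, level: float, noise_guard_max_rse: float = NOISE_GUARD_MAX_RSE
) -> DepthResult:
    """Deepest depth whose normalized value is still at or above ``level``.

    ``level`` is a fraction of the column maximum (e.g. 0.01 for the 1%
    level).  The reported depth is (k + 1) * voxel for the deepest
    qualifying voxel index k.  A noise guard flags depths where the
    per-voxel Monte Carlo relative standard error exceeds the ceiling, so
    threshold depths close to the noise floor are not over-trusted.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    above = np.nonzero(profile.E_NZ >= level)[0]
    if above.size == 0:
        return DepthResult(depth_mm=0.0, reached=False, level=level)
    k = int(above[-1])
    rse = float("nan")
    guard_ok = True
    if profile.rel_se is not None and np.isfinite(profile.rel_se[k]):
        rse = float(profile.rel_se[k])
        guard_ok = rse <= noise_guard_max_rse
    return DepthResult(
        depth_mm=float(profile.z_mm[k]),
        reached=True,
        level=level,
        noise_guard_ok=guard_ok,
        rel_se_at_depth=rse,
    )


def fwhm(coords_mm, values) -> float:
    """Full width at half maximum of a 1D profile.

    The half-max crossings are located by linear interpolation between the
    bracketing samples; the width spans the leftmost and rightmost
    crossings.  Returns NaN when the profile never drops below half max on
    one side (no crossing inside the window).
    """
    x = np.asarray(coords_mm, float)
    y = np.asarray(values, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need matching 1D coordinate/value arrays")
    peak = float(y.max())
    if not np.isfinite(peak) or peak <= 0:
        return float("nan")
    half = peak / 2.0
    imax_first = int(np.argmax(y))
    imax_last = int(y.size - 1 - np.argmax(y[::-1]))

    def cross_left():
        for i in range(imax_first, 0, -1):
            if y[i - 1] < half <= y[i]:
                f = (half - y[i - 1]) / (y[i] - y[i - 1])
                return x[i - 1] + f * (x[i] - x[i - 1])
        return None

    def cross_right():
        for i in range(imax_last, y.size - 1):
            if y[i] >= half > y[i + 1]:
                f = (y[i] - half) / (y[i] - y[i + 1])
                return x[i] + f * (x[i + 1] - x[i])
        return None

    left = cross_left()
    right = cross_right()
    if left is None or right is None:
        return float("nan")
    return float(right - left)


def width_profiles(E: EnergyVolume, depths_mm, kind: str = "fluence") -> WidthProfile:
    """FWHM of the lateral X and Y cuts through the center column per depth."""
    arr = _component(E, kind)
    ic, jc = E.column_index
    dx = E.voxel_size_mm
    nx, ny, nz = arr.shape
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dx
    depths_mm = np.asarray(depths_mm, float)
    wx = np.empty(depths_mm.size)
    wy = np.empty(depths_mm.size)
    for d_idx, depth in enumerate(depths_mm):
        k = int(round(depth / dx)) - 1
        if not 0 <= k < nz:
            raise ValueError(f"depth {depth} mm outside the volume")
        wx[d_idx] = fwhm(xc, arr[:, jc, k])
        wy[d_idx] = fwhm(yc, arr[ic, :, k])
    return WidthProfile(depths_mm=depths_mm, fwhm_x_mm=wx, fwhm_y_mm=wy, source_kind=kind)
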