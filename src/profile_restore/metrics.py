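"""Profile-agreement metrics: MSE, 20-80% penumbra widths and PWD, 1-D gamma.

Conventions: profiles are normalized to 1.0 on the central axis; penumbra
thresholds (20% / 80%) refer to that central-axis value; the profile is
re-centered at the midpoint of its two 50% crossings before any crossing is
located, which makes the metrics robust to small setup offsets.  The gamma
index uses global dose normalization (percent of the reference maximum) with
a low-dose threshold, the prevailing convention for profile QA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Profile

__all__ = ["PenumbraReport", "GammaReport", "mse", "penumbra", "pwd", "pwd_summary", "gamma_1d"]


def mse(predicted, reference) -> float:
    """Mean squared error between two equal-length value sequences."""
    o = np.asarray(predicted, dtype=float)
    p = np.asarray(reference, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size < 1:
        raise ValueError("need at least one sample")
    return float(np.mean((o - p) ** 2))


@dataclass(frozen=True)
class PenumbraReport:
    """20-80% penumbra widths of both field edges (positions re-centered)."""

    left_width_mm: float
    right_width_mm: float
    crossings: dict[str, float]  # e.g. "left_20", "right_80", "left_50"

    @property
    def mean_width_mm(self) -> float:
        return 0.5 * (self.left_width_mm + self.right_width_mm)


def _crossing_outward(x: np.ndarray, v: np.ndarray, level: float, side: str) -> float:
    """Position where the profile falls through ``level`` searching outward
    from the center (x = 0), by linear interpolation between grid points."""
    if side == "right":
        sel = x >= 0
        xs, vs = x[sel], v[sel]
    else:
        sel = x <= 0
        xs, vs = x[sel][::-1], v[sel][::-1]  # walk outward: center -> edge
    below = np.nonzero(vs < level)[0]
    if below.size == 0 or below[0] == 0:
        raise ValueError(f"profile never crosses {level:.3g} on the {side} side")
    j = below[0]
    x0, x1 = xs[j - 1], xs[j]
    v0, v1 = vs[j - 1], vs[j]
    return float(x0 + (level - v0) * (x1 - x0) / (v1 - v0))


def penumbra(profile: Profile) -> PenumbraReport:
    """Locate the 20/50/80% crossings of both edges and the 20-80% widths.

    The central-axis value defines the 100% level; the profile is first
    re-centered at the midpoint of its 50% crossings.
    """
    x = profile.positions_mm
    v = profile.values
    cax = profile.value_at(0.0)
    half = 0.5 * cax
    c_l = _crossing_outward(x, v, half, "left")
    c_r = _crossing_outward(x, v, half, "right")
    x = x - 0.5 * (c_l + c_r)
    crossings: dict[str, float] = {}
    for side in ("left", "right"):
        for pct in (20, 50, 80):
            crossings[f"{side}_{pct}"] = _crossing_outward(x, v, pct / 100.0 * cax, side)
    left = abs(crossings["left_20"] - crossings["left_80"])
    right = abs(crossings["right_20"] - crossings["right_80"])
    return PenumbraReport(left, right, crossings)


def pwd(reconstructed: PenumbraReport, reference: PenumbraReport) -> float:
    """Signed penumbra-width difference W_o - W_r (mean of the two edges), mm.

    Positive values mean the reconstructed profile is broader than the
    reference in the high-gradient region.
    """
    return reconstructed.mean_width_mm - reference.mean_width_mm


def pwd_summary(values) -> dict[str, float]:
    """Mean +/- SD of signed PWDs plus the mean and max absolute PWD."""
    v = np.asarray(list(values), dtype=float)
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "mean_abs": float(np.mean(np.abs(v))),
        "max_abs": float(np.max(np.abs(v))),
        "n": int(v.size),
    }


@dataclass(frozen=True)
class GammaReport:
    gamma: np.ndarray
    positions_mm: np.ndarray
    dose_pct: float
    dta_mm: float
    low_dose_threshold_pct: float

    @property
    def pass_rate(self) -> float:
        """Percentage of evaluated reference points with gamma <= 1."""
        return float(100.0 * np.mean(self.gamma <= 1.0 + 1e-12))

    @property
    def max_gamma(self) -> float:
        return float(np.max(self.gamma))


def gamma_1d(
    evaluated: Profile,
    reference: Profile,
    dose_pct: float = 1.0,
    dta_mm: float = 1.0,
    low_dose_threshold_pct: float = 10.0,
    search_step_mm: float = 0.1,
) -> GammaReport:
    """1-D global gamma of ``evaluated`` against ``reference``.

    For each reference point with dose >= threshold% of the reference
    maximum, gamma is the minimum of

        sqrt[ (dD / (dose_pct% of max ref))^2 + (dx / dta)^2 ]

    over the evaluated curve within +/- 3 x dta of the point.  The curve is
    resampled at ``search_step_mm`` and the minimum is taken exactly over
    the resulting polyline (point-to-segment distances in the scaled
    coordinates), so steep gradients do not alias the search.  A point
    passes when gamma <= 1.
    """
    lo = max(evaluated.positions_mm[0], reference.positions_mm[0])
    hi = min(evaluated.positions_mm[-1], reference.positions_mm[-1])
    if hi <= lo:
        raise ValueError("profiles share no common span")
    ref_sel = (reference.positions_mm >= lo) & (reference.positions_mm <= hi)
    ref_x = reference.positions_mm[ref_sel]
    ref_v = reference.values[ref_sel]
    dmax = float(np.max(reference.values))
    keep = ref_v >= low_dose_threshold_pct / 100.0 * dmax
    if not np.any(keep):
        raise ValueError("no reference points above the low-dose threshold")
    ref_x, ref_v = ref_x[keep], ref_v[keep]

    n_fine = int(round((hi - lo) / search_step_mm)) + 1
    ev_x = np.linspace(lo, hi, n_fine)
    ev_v = np.interp(ev_x, evaluated.positions_mm, evaluated.values)

    dose_tol = dose_pct / 100.0 * dmax
    window = 3.0 * dta_mm
    # evaluated polyline in scaled (position/dta, dose/tol) coordinates
    sx = ev_x / dta_mm
    sv = ev_v / dose_tol
    gam = np.empty(ref_x.size)
    for i, (xr, vr) in enumerate(zip(ref_x, ref_v)):
        a = np.searchsorted(ev_x, xr - window, side="left")
        b = np.searchsorted(ev_x, xr + window, side="right")
        px, pv = xr / dta_mm, vr / dose_tol
        ax, av = sx[a : b - 1], sv[a : b - 1]
        bx, bv = sx[a + 1 : b], sv[a + 1 : b]
        ux, uv = bx - ax, bv - av
        t = ((px - ax) * ux + (pv - av) * uv) / (ux * ux + uv * uv)
        t = np.clip(t, 0.0, 1.0)
        dx = ax + t * ux - px
        dv = av + t * uv - pv
        gam[i] = np.sqrt(np.min(dx * dx + dv * dv))
    return GammaReport(gam, ref_x, dose_pct, dta_mm, low_dose_threshold_pct)
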