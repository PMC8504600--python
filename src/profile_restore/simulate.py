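"""Synthetic 6 MV beam-profile generator and ionization-chamber-array forward model.

The measurement device emulated here is a flat ion-chamber array (ICProfiler
class): 65 chambers at 5.0 mm pitch on the Y axis spanning -160..+160 mm, and
63 chambers on the X axis (the +/-5 mm positions are absent).  Each chamber
averages dose over a ~2.9 mm extent along the scan direction, which blurs the
high-gradient penumbra (the volume-averaging effect, VAE).

Ground truth is an analytic flattened-beam model with a dual-source edge:
each field edge is a mixture of a sharp error-function component (the primary
focal source, scale ``sigma``) and a broad one (extra-focal radiation and
phantom scatter, several mm wide), placed at the diverged geometric field
edge.  The envelope is modulated by small flattening-filter "horns" at
shallow depths and a slight "shoulder" rounding at 10 cm, both scaled with
the off-axis distance of the edge (small fields show neither), and sits on
an out-of-field transmission tail that grows with depth as phantom scatter
accumulates.  The per-(plane, depth) core scale ``sigma`` is a shipped
default, fixed once by :func:`calibrate_defaults` so that the array + Makima
baseline reproduces published penumbra-broadening levels for this device
class on an Elekta 6 MV beam (in-plane edges are jaw-defined and sharper
than the MLC-defined cross-plane edges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

__all__ = [
    "BeamGeometry",
    "TruthModelParams",
    "DetectorArraySpec",
    "DiscreteMeasurement",
    "Profile",
    "SimulationConfig",
    "truth_profile",
    "volume_average",
    "sample_array",
    "calibrate_defaults",
    "generate_dataset",
    "default_truth_params",
    "FIELD_SIZES_CM",
    "DEPTHS_CM",
    "PLANES",
    "FINE_GRID_STEP_MM",
    "FINE_GRID_SPAN_MM",
]

FIELD_SIZES_CM = (2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)
DEPTHS_CM = (1.5, 5.0, 10.0)
PLANES = ("in", "cross")

#: fine simulation grid: 0.1 mm over +/-170 mm (well below both the 2.9 mm
#: aperture and the narrowest penumbra widths).
FINE_GRID_STEP_MM = 0.1
FINE_GRID_SPAN_MM = 170.0

_PLANE_ALIASES = {
    "in": "in", "in-plane": "in", "inplane": "in", "y": "in",
    "cross": "cross", "cross-plane": "cross", "crossplane": "cross",
    "cr": "cross", "cr-plane": "cross", "x": "cross",
}


def normalize_plane(plane: str) -> str:
    key = str(plane).strip().lower()
    if key not in _PLANE_ALIASES:
        raise ValueError(f"unknown plane {plane!r}; expected 'in' or 'cross'")
    return _PLANE_ALIASES[key]


@dataclass(frozen=True)
class BeamGeometry:
    """Square-field measurement geometry.

    ``field_size_cm`` is the nominal side at the 100 cm isocenter plane;
    the array surface sits at ``ssd_cm`` = 90 cm and the effective
    measurement depth is ``depth_cm``, so field edges diverge by
    ``(ssd_cm + depth_cm) / 100``.
    """

    field_size_cm: float
    depth_cm: float
    plane: str
    ssd_cm: float = 90.0

    def __post_init__(self):
        object.__setattr__(self, "plane", normalize_plane(self.plane))
        if self.field_size_cm <= 0:
            raise ValueError("field_size_cm must be positive")
        if self.depth_cm <= 0:
            raise ValueError("depth_cm must be positive")
        if self.ssd_cm <= 0:
            raise ValueError("ssd_cm must be positive")

    @property
    def half_width_mm(self) -> float:
        """Geometric field half-width at the measurement plane (mm)."""
        return (self.field_size_cm * 10.0 / 2.0) * (self.ssd_cm + self.depth_cm) / 100.0

    def key(self) -> tuple[str, float]:
        return (self.plane, float(self.depth_cm))


# Edge scales (mm) of the erf penumbra model per (plane, depth_cm).
# Fixed once by the calibrate_defaults search so the volume-averaged,
# 5-mm-sampled, Makima-refit baseline reproduces the published mean
# penumbra-width differences for this array (see scripts/calibrate_defaults.py).
DEFAULT_EDGE_SIGMA_MM: dict[tuple[str, float], float] = {
    ("in", 1.5): 1.1069711374,
    ("in", 5.0): 1.1912387175,
    ("in", 10.0): 1.4129936875,
    ("cross", 1.5): 1.9610452284,
    ("cross", 5.0): 2.0680152209,
    ("cross", 10.0): 1.9891590840,
}

#: Baseline mean penumbra-width differences (mm) the shipped edge scales were
#: calibrated to reproduce: array + Makima fit versus diode-class reference,
#: averaged over the seven field sizes, as reported for this device on an
#: Elekta 6 MV beam.
BASELINE_PWD_TARGETS_MM: dict[tuple[str, float], float] = {
    ("in", 1.5): 1.6,
    ("in", 5.0): 1.8,
    ("in", 10.0): 2.4,
    ("cross", 1.5): 1.2,
    ("cross", 5.0): 1.2,
    ("cross", 10.0): 1.6,
}


def _default_horn_amplitude() -> dict[float, float]:
    # flattening-filter horns at shallow depth; negative value = the slight
    # "shoulder" rounding of the over-flattened beam at 10 cm
    return {1.5: 0.03, 5.0: 0.015, 10.0: -0.02}


def _default_horn_width_frac() -> dict[float, float]:
    return {1.5: 0.15, 5.0: 0.15, 10.0: 0.30}


def _default_tail_level() -> dict[float, float]:
    # out-of-field transmission + phantom scatter, growing with depth
    return {1.5: 0.005, 5.0: 0.012, 10.0: 0.022}


@dataclass(frozen=True)
class TruthModelParams:
    """Parameters of the analytic ground-truth profile family.

    All dose values are relative to the central-axis value 1.0.  The edge is
    a two-component erf mixture: fraction ``1 - scatter_fraction`` with the
    per-(plane, depth) core scale and fraction ``scatter_fraction`` with the
    broad ``scatter_sigma_mm`` (extra-focal/phantom-scatter toe).
    ``horn_width_frac`` expresses the horn Gaussian width per depth as a
    fraction of the field half-width; horn amplitude scales with the square
    of the edge off-axis distance (reference: the 10 x 10 cm^2 edge), so
    small fields are horn-free.  ``tail_level`` maps depth to the
    out-of-field transmission fraction.
    """

    edge_sigma_mm: dict[tuple[str, float], float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_SIGMA_MM)
    )
    scatter_fraction: float = 0.375
    scatter_sigma_mm: float = 7.0
    horn_amplitude: dict[float, float] = field(default_factory=_default_horn_amplitude)
    horn_width_frac: dict[float, float] = field(default_factory=_default_horn_width_frac)
    tail_level: dict[float, float] = field(default_factory=_default_tail_level)

    def __post_init__(self):
        for key, sigma in self.edge_sigma_mm.items():
            if sigma <= 0:
                raise ValueError(f"edge_sigma_mm must be positive, got {sigma} for {key}")
        if not 0.0 <= self.scatter_fraction < 1.0:
            raise ValueError("scatter_fraction must be in [0, 1)")
        if self.scatter_sigma_mm <= 0:
            raise ValueError("scatter_sigma_mm must be positive")
        for depth, amp in self.horn_amplitude.items():
            if not -0.1 <= amp <= 0.1:
                raise ValueError(f"horn amplitude out of [-0.1, 0.1] at depth {depth}: {amp}")
        for depth, tail in self.tail_level.items():
            if not 0.0 <= tail <= 0.05:
                raise ValueError(f"tail_level must be in [0, 0.05], got {tail} at depth {depth}")
        depths = {d for (_, d) in self.edge_sigma_mm}
        for d in depths:
            si = self.edge_sigma_mm.get(("in", d))
            sc = self.edge_sigma_mm.get(("cross", d))
            if si is not None and sc is not None and not si < sc:
                raise ValueError(
                    f"in-plane edge sigma must be smaller than cross-plane at depth {d}"
                )

    def sigma_for(self, geometry: BeamGeometry) -> float:
        key = geometry.key()
        try:
            return self.edge_sigma_mm[key]
        except KeyError:
            raise KeyError(
                f"no edge sigma configured for (plane, depth) = {key}"
            ) from None

    def horn_for(self, geometry: BeamGeometry) -> tuple[float, float, float]:
        """(off-axis-scaled amplitude, width mm, tail level) for a geometry."""
        d = float(geometry.depth_cm)
        try:
            amp = self.horn_amplitude[d]
            frac = self.horn_width_frac[d]
            tail = self.tail_level[d]
        except KeyError:
            raise KeyError(f"no horn/tail parameters configured for depth {d}") from None
        e = geometry.half_width_mm
        e_ref = 50.0 * (geometry.ssd_cm + geometry.depth_cm) / 100.0  # 10x10 edge
        return amp * (e / e_ref) ** 2, frac * e, tail


def default_truth_params() -> TruthModelParams:
    """Shipped simulator defaults (calibrated edge scales, small shallow horns)."""
    return TruthModelParams()


@dataclass(frozen=True)
class DetectorArraySpec:
    """Geometry of one axis of the chamber array."""

    positions_mm: np.ndarray
    pitch_mm: float = 5.0
    aperture_mm: float = 2.9
    axis: str = "Y"

    def __post_init__(self):
        pos = np.asarray(self.positions_mm, dtype=float)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("positions_mm must be a 1-D array with >= 2 entries")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("detector positions must be strictly increasing")
        object.__setattr__(self, "positions_mm", pos)
        if self.aperture_mm < 0:
            raise ValueError("aperture_mm must be non-negative")

    @classmethod
    def y_axis(cls, aperture_mm: float = 2.9) -> "DetectorArraySpec":
        """65 detectors, -160..+160 mm at 5 mm pitch."""
        return cls(np.arange(-160.0, 160.0 + 2.5, 5.0), 5.0, aperture_mm, "Y")

    @classmethod
    def x_axis(cls, aperture_mm: float = 2.9) -> "DetectorArraySpec":
        """63 detectors: the Y set minus the +/-5 mm positions."""
        pos = np.arange(-160.0, 160.0 + 2.5, 5.0)
        pos = pos[np.abs(np.abs(pos) - 5.0) > 1e-9]
        return cls(pos, 5.0, aperture_mm, "X")

    @classmethod
    def for_plane(cls, plane: str, aperture_mm: float = 2.9) -> "DetectorArraySpec":
        """In-plane profiles are read on the Y axis, cross-plane on the X axis."""
        return cls.y_axis(aperture_mm) if normalize_plane(plane) == "in" else cls.x_axis(aperture_mm)


@dataclass(frozen=True)
class DiscreteMeasurement:
    """Array readings at the detector positions for one geometry."""

    geometry: BeamGeometry
    positions_mm: np.ndarray
    readings: np.ndarray
    noise_seed: int | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions_mm, dtype=float)
        vals = np.asarray(self.readings, dtype=float)
        if pos.shape != vals.shape or pos.ndim != 1:
            raise ValueError("positions and readings must be 1-D arrays of equal length")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("detector positions must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("readings must be non-negative")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "readings", vals)


@dataclass(frozen=True)
class Profile:
    """Finely gridded 1-D relative-dose profile on a uniform grid."""

    positions_mm: np.ndarray
    values: np.ndarray
    geometry: BeamGeometry | None = None
    grid_step_mm: float | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions_mm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if pos.shape != vals.shape or pos.ndim != 1 or pos.size < 2:
            raise ValueError("positions and values must be 1-D arrays of equal length >= 2")
        steps = np.diff(pos)
        step = steps[0]
        if not np.all(np.abs(steps - step) < 1e-9):
            raise ValueError("profile grid must be uniform to within 1e-9 mm")
        if not np.all(np.isfinite(vals)):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "grid_step_mm", float(step))

    def value_at(self, x: float) -> float:
        """Linear interpolation at ``x`` (mm); errors outside the grid."""
        pos = self.positions_mm
        if x < pos[0] - 1e-9 or x > pos[-1] + 1e-9:
            raise ValueError(f"position {x} mm outside profile support [{pos[0]}, {pos[-1]}]")
        return float(np.interp(x, pos, self.values))

    def normalized(self) -> "Profile":
        """Rescale so the value at the central axis (x = 0) is 1.0."""
        return replace(self, values=self.values / self.value_at(0.0))

    def plot(self, ax=None, **kwargs):
        """Plot the profile; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.positions_mm, self.values, **kwargs)
        ax.set_xlabel("position (mm)")
        ax.set_ylabel("relative dose")
        return ax


def fine_grid(
    span_mm: float = FINE_GRID_SPAN_MM, step_mm: float = FINE_GRID_STEP_MM
) -> np.ndarray:
    n = int(round(2 * span_mm / step_mm)) + 1
    return np.linspace(-span_mm, span_mm, n)


def _truth_values(x: np.ndarray, geometry: BeamGeometry, params: TruthModelParams) -> np.ndarray:
    e = geometry.half_width_mm

    def edge_pair(sigma: float) -> np.ndarray:
        s = sigma * math.sqrt(2.0)
        return 0.5 * (1.0 + erf((x + e) / s)) - 0.5 * (1.0 + erf((x - e) / s))

    w = params.scatter_fraction
    envelope = (1.0 - w) * edge_pair(params.sigma_for(geometry))
    if w > 0:
        envelope += w * edge_pair(params.scatter_sigma_mm)
    amp, hw, tail = params.horn_for(geometry)
    if amp != 0.0:
        horns = np.exp(-((x - (e - hw)) ** 2) / (2 * hw * hw))
        horns += np.exp(-((x + (e - hw)) ** 2) / (2 * hw * hw))
        envelope = envelope * (1.0 + amp * horns)
    return envelope + tail


def truth_profile(
    geometry: BeamGeometry,
    params: TruthModelParams | None = None,
    grid: np.ndarray | None = None,
) -> Profile:
    """Analytic ground-truth profile on a uniform grid covering +/-170 mm.

    The dose model is a dual-source erf edge pair at the diverged field
    edges (sharp core of scale ``sigma(plane, depth)`` plus a broad
    extra-focal/scatter component), multiplied by symmetric Gaussian
    horn/shoulder terms, plus a depth-dependent transmission tail;
    renormalized to 1.0 on the axis.
    """
    params = params or default_truth_params()
    if grid is None:
        grid = fine_grid()
    grid = np.asarray(grid, dtype=float)
    if grid[0] > -FINE_GRID_SPAN_MM + 1e-9 or grid[-1] < FINE_GRID_SPAN_MM - 1e-9:
        raise ValueError(f"grid must cover at least [-{FINE_GRID_SPAN_MM}, {FINE_GRID_SPAN_MM}] mm")
    values = _truth_values(grid, geometry, params)
    center = _truth_values(np.array([0.0]), geometry, params)[0]
    return Profile(grid, values / center, geometry=geometry)


def volume_average(profile: Profile, aperture_mm: float) -> Profile:
    """Convolve with a unit-area rectangular kernel of width ``aperture_mm``.

    The profile is treated as piecewise linear on its grid and integrated
    exactly over the aperture (trapezoid rule with partial end segments),
    which is what a chamber of that extent reads as it samples the curve.
    Only grid points where the full aperture is supported are returned.
    """
    if aperture_mm < 0:
        raise ValueError("aperture_mm must be non-negative")
    if aperture_mm == 0:
        return profile
    h = profile.grid_step_mm
    if h > aperture_mm / 4 + 1e-12:
        raise ValueError(
            f"grid step {h} mm too coarse for aperture {aperture_mm} mm (need <= aperture/4)"
        )
    half = aperture_mm / 2.0
    m = int(math.floor(half / h + 1e-12))
    s = half - m * h  # partial segment beyond the last full interval
    # piecewise-linear integral as a convolution stencil
    w = np.zeros(2 * (m + 1) + 1)
    c = m + 1
    for j in range(-m, m):  # full intervals [x_j, x_{j+1}]
        w[c + j] += h / 2.0
        w[c + j + 1] += h / 2.0
    if s > 1e-15:
        for sgn in (+1, -1):
            w[c + sgn * m] += s - s * s / (2 * h)
            w[c + sgn * (m + 1)] += s * s / (2 * h)
    else:
        w = w[1:-1]
    if w.size > profile.values.size:
        raise ValueError("aperture wider than profile support")
    averaged = np.convolve(profile.values, w / aperture_mm, mode="valid")
    k = (w.size - 1) // 2
    pos = profile.positions_mm[k : profile.positions_mm.size - k]
    out = Profile(pos, averaged, geometry=profile.geometry)
    return out.normalized()


def sample_array(
    profile: Profile,
    spec: DetectorArraySpec,
    setup_offset_mm: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DiscreteMeasurement:
    """Read the (already volume-averaged) profile at the detector positions.

    Readings are linear interpolations at ``positions + setup_offset``, each
    perturbed by multiplicative Gaussian noise of fractional SD ``noise_sd``,
    then normalized so the reading nearest the central axis is 1.0.
    """
    if abs(setup_offset_mm) > 2.5:
        raise ValueError("setup offset must be within +/-2.5 mm (half detector pitch)")
    sample_at = spec.positions_mm + setup_offset_mm
    lo, hi = profile.positions_mm[0], profile.positions_mm[-1]
    if sample_at[0] < lo - 1e-9 or sample_at[-1] > hi + 1e-9:
        raise ValueError("detector positions fall outside the profile support")
    readings = np.interp(sample_at, profile.positions_mm, profile.values)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        readings = readings * (1.0 + rng.normal(0.0, noise_sd, readings.size))
    center = int(np.argmin(np.abs(spec.positions_mm)))
    readings = readings / readings[center]
    return DiscreteMeasurement(
        geometry=profile.geometry,
        positions_mm=spec.positions_mm.copy(),
        readings=np.clip(readings, 0.0, None),
        noise_seed=seed,
    )


def makima_baseline(
    geometry: BeamGeometry,
    params: TruthModelParams,
    aperture_mm: float = 2.9,
    grid_step_mm: float = 0.5,
    setup_offset_mm: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[Profile, Profile]:
    """Forward chain truth -> aperture -> array -> Makima refit.

    Returns ``(truth, baseline)`` where ``baseline`` is the Makima-resampled
    array measurement on a ``grid_step_mm`` grid.  This is the uncorrected
    profile a user would obtain from the array alone.
    """
    from .interp import makima_resample

    truth = truth_profile(geometry, params)
    blurred = volume_average(truth, aperture_mm)
    spec = DetectorArraySpec.for_plane(geometry.plane, aperture_mm)
    meas = sample_array(blurred, spec, setup_offset_mm, noise_sd, seed)
    return truth, makima_resample(meas, grid_step_mm)


def _chain_mean_pwd(
    plane: str,
    depth_cm: float,
    sigma: float,
    base: TruthModelParams,
    aperture_mm: float = 2.9,
    fields: tuple[float, ...] = FIELD_SIZES_CM,
) -> float:
    from .metrics import penumbra, pwd

    sigmas = dict(base.edge_sigma_mm)
    sigmas[(plane, depth_cm)] = sigma
    # bypass the in<cross ordering check while searching a single key
    params = TruthModelParams.__new__(TruthModelParams)
    object.__setattr__(params, "edge_sigma_mm", sigmas)
    object.__setattr__(params, "scatter_fraction", base.scatter_fraction)
    object.__setattr__(params, "scatter_sigma_mm", base.scatter_sigma_mm)
    object.__setattr__(params, "horn_amplitude", dict(base.horn_amplitude))
    object.__setattr__(params, "horn_width_frac", dict(base.horn_width_frac))
    object.__setattr__(params, "tail_level", dict(base.tail_level))
    vals = []
    for f in fields:
        geo = BeamGeometry(f, depth_cm, plane)
        truth, baseline = makima_baseline(geo, params, aperture_mm)
        vals.append(pwd(penumbra(baseline), penumbra(truth)))
    return float(np.mean(vals))


def calibrate_defaults(
    targets: dict[tuple[str, float], float] | None = None,
    aperture_mm: float = 2.9,
    sigma_bounds: tuple[float, float] = (0.5, 6.0),
    tol_mm: float = 0.05,
    base: TruthModelParams | None = None,
) -> TruthModelParams:
    """Solve for the edge scales that reproduce target baseline mean PWDs.

    For each (plane, depth) a scalar root search over ``sigma`` matches the
    forward-chain mean PWD (over the seven field sizes) to the target within
    ``tol_mm``.  This is the developer-time procedure that fixed
    ``DEFAULT_EDGE_SIGMA_MM``; it is exposed so the defaults can be re-derived.
    """
    targets = dict(targets or BASELINE_PWD_TARGETS_MM)
    base = base or TruthModelParams()
    lo, hi = sigma_bounds
    solved: dict[tuple[str, float], float] = {}
    for (plane, depth), target in targets.items():
        plane = normalize_plane(plane)
        f_lo = _chain_mean_pwd(plane, depth, lo, base, aperture_mm)
        f_hi = _chain_mean_pwd(plane, depth, hi, base, aperture_mm)
        if abs(f_lo - f_hi) < 1e-6:
            raise RuntimeError(
                f"flat calibration objective for {(plane, depth)}: "
                f"PWD({lo})={f_lo:.4g}, PWD({hi})={f_hi:.4g}; "
                "forward chain is insensitive to sigma (degenerate setup)"
            )
        g = lambda s: _chain_mean_pwd(plane, depth, s, base, aperture_mm) - target
        if (f_lo - target) * (f_hi - target) > 0:
            raise RuntimeError(
                f"no sigma in ({lo}, {hi}) mm reaches target {target} mm for "
                f"{(plane, depth)}: PWD spans [{min(f_lo, f_hi):.3f}, {max(f_lo, f_hi):.3f}] mm "
                f"({'decreasing' if f_lo > f_hi else 'increasing'} in sigma)"
            )
        sigma = brentq(g, lo, hi, xtol=1e-4)
        achieved = _chain_mean_pwd(plane, depth, sigma, base, aperture_mm)
        if abs(achieved - target) > tol_mm:
            raise RuntimeError(
                f"calibration for {(plane, depth)} off target: {achieved:.3f} vs {target:.3f} mm"
            )
        solved[(plane, depth)] = float(sigma)
    sigmas = dict(base.edge_sigma_mm)
    sigmas.update(solved)
    return replace(base, edge_sigma_mm=sigmas)


@dataclass(frozen=True)
class SimulationConfig:
    """Dataset-generation settings (defaults are the study conditions)."""

    field_sizes_cm: tuple[float, ...] = FIELD_SIZES_CM
    depths_cm: tuple[float, ...] = DEPTHS_CM
    planes: tuple[str, ...] = PLANES
    aperture_mm: float = 2.9
    grid_step_mm: float = 0.5
    noise_sd: float = 0.0
    setup_offset_mm: float = 0.0
    replicates: int = 1
    seed: int = 0
    params: TruthModelParams = field(default_factory=default_truth_params)


@dataclass(frozen=True)
class DatasetRecord:
    geometry: BeamGeometry
    replicate: int
    seed: int
    measurement: DiscreteMeasurement
    truth: Profile  # fine grid


def generate_dataset(config: SimulationConfig | None = None) -> list[DatasetRecord]:
    """Simulate the full measurement campaign.

    Defaults emit 7 fields x 3 depths x 2 planes = 42 (measurement, truth)
    pairs per replicate; replicates with distinct derived seeds emulate
    repeated measurement sessions.  Deterministic given ``config.seed``.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(config.seed)
    n_geo = len(config.field_sizes_cm) * len(config.depths_cm) * len(config.planes)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_geo * config.replicates)]
    records: list[DatasetRecord] = []
    i = 0
    for rep in range(config.replicates):
        for plane in config.planes:
            spec = DetectorArraySpec.for_plane(plane, config.aperture_mm)
            for depth in config.depths_cm:
                for fs in config.field_sizes_cm:
                    geo = BeamGeometry(fs, depth, plane)
                    truth = truth_profile(geo, config.params)
                    blurred = volume_average(truth, config.aperture_mm)
                    seed = child_seeds[i]
                    i += 1
                    meas = sample_array(
                        blurred, spec, config.setup_offset_mm, config.noise_sd, seed
                    )
                    records.append(DatasetRecord(geo, rep, seed, meas, truth))
    return records
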