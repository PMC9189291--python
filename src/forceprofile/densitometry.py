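"""Gel-lane densitometry: two-Gaussian band fitting and f_FL computation.

Each lane of the assay gel carries at most two species of the same
construct: the arrested chain (A) and the 23-residue-larger full-length
chain (FL).  A lane's intensity cross-section is modelled as a linear
baseline plus two Gaussian bands,

    y(x) = b0 + b1*x + a_FL * exp(-(x-c_FL)^2 / 2s_FL^2)
               + a_A  * exp(-(x-c_A )^2 / 2s_A^2),

fitted by nonlinear least squares.  The migration coordinate increases with
migration distance, so the larger full-length chain sits at the *smaller*
coordinate (c_FL < c_A).  Band intensity is the Gaussian area
a * s * sqrt(2*pi), and the assay statistic is

    f_FL = I_FL / (I_FL + I_A).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_prominences

__all__ = [
    "LaneProfile",
    "BandFit",
    "TwoBandFit",
    "FflMeasurement",
    "FitConfig",
    "AggregateResult",
    "extract_lane_profile",
    "fit_two_bands",
    "compute_ffl",
    "aggregate_replicates",
    "quantify_lanes",
]

MIN_PROFILE_SAMPLES = 16

_SQRT_2PI = math.sqrt(2 * math.pi)


@dataclass(frozen=True)
class LaneProfile:
    """A 1-D intensity cross-section of one gel lane.

    Positions are migration coordinates (monotone increasing, larger =
    migrated further); intensities are arbitrary phosphorimager units.
    """

    positions: np.ndarray
    intensities: np.ndarray
    construct_name: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or inten.ndim != 1 or pos.shape != inten.shape:
            raise ValueError("positions and intensities must be equal-length 1-D arrays")
        if pos.size < MIN_PROFILE_SAMPLES:
            raise ValueError(
                f"profile needs >= {MIN_PROFILE_SAMPLES} samples, got {pos.size}"
            )
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class BandFit:
    """Fitted parameters of a single Gaussian band."""

    center: float
    sigma: float
    amplitude: float

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * _SQRT_2PI


@dataclass(frozen=True)
class TwoBandFit:
    """Joint fit of a lane: full-length band, arrested band, linear baseline."""

    fl_band: BandFit
    a_band: BandFit
    baseline: tuple[float, float]  # (offset, slope)
    residual_rms: float
    converged: bool
    single_band: bool = False  # only one detectable maximum; other band zeroed

    def __post_init__(self) -> None:
        if not self.single_band and self.fl_band.center >= self.a_band.center:
            raise ValueError(
                "full-length band must migrate less (smaller center) than arrested band"
            )


@dataclass(frozen=True)
class FflMeasurement:
    """One lane's fraction full-length."""

    f_fl: float
    construct_name: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_fl <= 1.0:
            raise ValueError(f"f_fl must lie in [0, 1], got {self.f_fl}")


@dataclass(frozen=True)
class FitConfig:
    """Knobs for the two-band fit.

    min_sigma           lower bound on band width, px
    max_sigma_frac      sigma upper bound as a fraction of the profile span
    detect_prominence   peak-detection prominence threshold as a fraction of
                        the profile's intensity range (initialization only)
    expected_centers    optional (fl, a) migration coordinates used to name
                        the surviving band in degenerate single-band lanes;
                        without them a lone band is conservatively called
                        arrested (f_FL = 0)
    """

    min_sigma: float = 1.0
    max_sigma_frac: float = 0.25
    detect_prominence: float = 0.02
    expected_centers: tuple[float, float] | None = None


def extract_lane_profile(
    image: np.ndarray,
    lane_region: tuple[int, int, int, int],
    construct_name: str = "",
    replicate_id: str = "",
) -> LaneProfile:
    """Sum a rectangular lane region across its width into a 1-D profile.

    ``lane_region`` is (row_start, row_stop, col_start, col_stop) with the
    migration axis along rows (row index grows with migration distance).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D intensity grid")
    r0, r1, c0, c1 = lane_region
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise ValueError(f"lane region {lane_region} outside image bounds {image.shape}")
    block = image[r0:r1, c0:c1]
    return LaneProfile(
        positions=np.arange(r0, r1, dtype=float),
        intensities=block.sum(axis=1),
        construct_name=construct_name,
        replicate_id=replicate_id,
    )


def _model(x, b0, b1, c1, s1, a1, c2, s2, a2):
    return (
        b0
        + b1 * x
        + a1 * np.exp(-0.5 * ((x - c1) / s1) ** 2)
        + a2 * np.exp(-0.5 * ((x - c2) / s2) ** 2)
    )


def _model_single(x, b0, b1, c, s, a):
    return b0 + b1 * x + a * np.exp(-0.5 * ((x - c) / s) ** 2)


def _noise_scale(y: np.ndarray) -> float:
    """Robust per-sample noise estimate from first differences (MAD-based).

    Band slopes affect only a minority of samples, so the median of the
    absolute differences tracks the noise floor, not the signal.
    """
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2))


def _initial_peaks(
    y: np.ndarray, min_distance: float, prominence: float, max_distance: float = np.inf
) -> list[int]:
    """Indices of up to two candidate band maxima, ranked by prominence.

    A second maximum is only trusted when its prominence clears several
    times the noise floor; anything weaker is indistinguishable from a
    noise spike, and a real band hiding as a shoulder of the main one is
    recovered better by the seeded refit downstream.
    """
    idx, _ = find_peaks(y, prominence=prominence)
    if idx.size == 0:
        return []
    prom = peak_prominences(y, idx)[0]
    order = np.argsort(prom)[::-1]
    picked = [int(idx[order[0]])]
    second_floor = max(prominence, 6.0 * _noise_scale(y))
    for k in order[1:]:
        if prom[k] < second_floor:
            break
        if min_distance <= abs(int(idx[k]) - picked[0]) <= max_distance:
            picked.append(int(idx[k]))
            break
    return picked


def fit_two_bands(
    profile: LaneProfile,
    expected_separation: float,
    config: FitConfig | None = None,
) -> TwoBandFit:
    """Fit baseline + two Gaussians to a lane profile.

    Initialization uses the two most prominent local maxima at least
    ``expected_separation / 2`` apart; band widths start at
    ``expected_separation / 4``.  If only one maximum is detectable the fit
    degenerates to a single band, the missing band's area is set to zero and
    the result is flagged (``single_band``).  Non-convergence is flagged,
    never silently ignored.
    """
    if expected_separation <= 0:
        raise ValueError("expected_separation must be positive")
    cfg = config or FitConfig()
    x = profile.positions
    y = profile.intensities
    span = x[-1] - x[0]
    yrange = float(y.max() - y.min())
    if yrange <= 0:
        raise ValueError("flat profile: no bands to fit")

    dx = float(np.median(np.diff(x)))
    min_dist_px = expected_separation / 2 / dx
    # the sister band cannot sit much farther than the size difference allows
    max_dist_px = 3.0 * expected_separation / dx
    peaks = _initial_peaks(
        y, min_dist_px, cfg.detect_prominence * yrange, max_dist_px
    )
    b0_init = float(y.min())
    sigma0 = max(expected_separation / 4, cfg.min_sigma)
    sigma_max = max(cfg.max_sigma_frac * span, 2 * cfg.min_sigma)

    if len(peaks) == 0:
        raise ValueError("no detectable band maxima in profile")

    if len(peaks) == 1:
        # A shoulder band closer than expected_separation/2 presents a single
        # maximum; try two-band fits seeded on either side before giving up.
        c = float(x[peaks[0]])
        best: TwoBandFit | None = None
        for second in (c - expected_separation, c + expected_separation):
            if not (x[0] <= second <= x[-1]):
                continue
            amp2 = max(float(np.interp(second, x, y) - b0_init), 1e-9)
            try:
                fit = _fit_shared_sigma(
                    profile,
                    sorted([(c, max(float(y[peaks[0]] - b0_init), 1e-9)), (second, amp2)]),
                    sigma0,
                    sigma_max,
                    cfg,
                    center_window=expected_separation,
                )
            except ValueError:  # coincident centers: unresolved
                continue
            if best is None or fit.residual_rms < best.residual_rms:
                best = fit
        total = best.fl_band.area + best.a_band.area if best is not None else 0.0
        resolved = (
            best is not None
            and best.converged
            and total > 0
            and (best.a_band.center - best.fl_band.center) >= expected_separation / 2
            and min(best.fl_band.area, best.a_band.area) / total >= 5e-3
        )
        if resolved:
            return best
        return _fit_single_band(profile, peaks[0], sigma0, sigma_max, cfg)

    c_init = sorted(float(x[i]) for i in peaks)
    a_init = [max(float(y[i] - b0_init), 1e-9) for i in peaks]
    if x[peaks[0]] > x[peaks[1]]:
        a_init = a_init[::-1]
    seeds = list(zip(c_init, a_init))
    return _fit_from_seeds(profile, seeds, sigma0, sigma_max, cfg)


def _fit_from_seeds(
    profile: LaneProfile,
    seeds: list[tuple[float, float]],
    sigma0: float,
    sigma_max: float,
    cfg: FitConfig,
    center_window: float | None = None,
) -> TwoBandFit:
    """Two-band least squares from (center, amplitude) seeds sorted by center.

    ``center_window`` restricts each center to seed +/- window (used when
    resolving a shoulder band, to keep the optimizer from explaining the
    lane as one broad band plus a far-away noise blip).
    """
    x, y = profile.positions, profile.intensities
    (c1_0, a1_0), (c2_0, a2_0) = seeds
    p0 = [float(y.min()), 0.0, c1_0, sigma0, a1_0, c2_0, sigma0, a2_0]
    if center_window is None:
        c1_lo, c1_hi = x[0], x[-1]
        c2_lo, c2_hi = x[0], x[-1]
    else:
        c1_lo, c1_hi = max(x[0], c1_0 - center_window), min(x[-1], c1_0 + center_window)
        c2_lo, c2_hi = max(x[0], c2_0 - center_window), min(x[-1], c2_0 + center_window)
    lower = [-np.inf, -np.inf, c1_lo, cfg.min_sigma, 0.0, c2_lo, cfg.min_sigma, 0.0]
    upper = [np.inf, np.inf, c1_hi, sigma_max, np.inf, c2_hi, sigma_max, np.inf]

    converged = True
    try:
        popt, _ = curve_fit(_model, x, y, p0=p0, bounds=(lower, upper), maxfev=20000)
    except RuntimeError:
        converged = False
        popt = np.array(p0)
    b0, b1, c1, s1, a1, c2, s2, a2 = (float(v) for v in popt)
    band1 = BandFit(center=c1, sigma=s1, amplitude=a1)
    band2 = BandFit(center=c2, sigma=s2, amplitude=a2)
    # larger chain migrates less: the smaller-coordinate band is full-length
    fl, ab = (band1, band2) if band1.center < band2.center else (band2, band1)
    resid = y - _model(x, *popt)
    return TwoBandFit(
        fl_band=fl,
        a_band=ab,
        baseline=(b0, b1),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=converged,
    )


def _model_shared(x, b0, b1, c1, c2, s, a1, a2):
    return (
        b0
        + b1 * x
        + a1 * np.exp(-0.5 * ((x - c1) / s) ** 2)
        + a2 * np.exp(-0.5 * ((x - c2) / s) ** 2)
    )


def _fit_shared_sigma(
    profile: LaneProfile,
    seeds: list[tuple[float, float]],
    sigma0: float,
    sigma_max: float,
    cfg: FitConfig,
    center_window: float,
) -> TwoBandFit:
    """Two-band fit with a common band width.

    Used when the bands overlap into a single maximum: the two species
    differ by only 23 residues and run with essentially the same width, and
    overlapping data cannot constrain independent widths anyway.
    """
    x, y = profile.positions, profile.intensities
    (c1_0, a1_0), (c2_0, a2_0) = seeds
    p0 = [float(y.min()), 0.0, c1_0, c2_0, sigma0, a1_0, a2_0]
    lower = [
        -np.inf,
        -np.inf,
        max(x[0], c1_0 - center_window),
        max(x[0], c2_0 - center_window),
        cfg.min_sigma,
        0.0,
        0.0,
    ]
    upper = [
        np.inf,
        np.inf,
        min(x[-1], c1_0 + center_window),
        min(x[-1], c2_0 + center_window),
        sigma_max,
        np.inf,
        np.inf,
    ]
    converged = True
    try:
        popt, _ = curve_fit(
            _model_shared, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError:
        converged = False
        popt = np.array(p0)
    b0, b1, c1, c2, s, a1, a2 = (float(v) for v in popt)
    band1 = BandFit(center=c1, sigma=s, amplitude=a1)
    band2 = BandFit(center=c2, sigma=s, amplitude=a2)
    fl, ab = (band1, band2) if band1.center < band2.center else (band2, band1)
    resid = y - _model_shared(x, *popt)
    return TwoBandFit(
        fl_band=fl,
        a_band=ab,
        baseline=(b0, b1),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=converged,
    )


def _fit_single_band(
    profile: LaneProfile,
    peak_idx: int,
    sigma0: float,
    sigma_max: float,
    cfg: FitConfig,
) -> TwoBandFit:
    x, y = profile.positions, profile.intensities
    p0 = [float(y.min()), 0.0, float(x[peak_idx]), sigma0, float(y[peak_idx] - y.min())]
    lower = [-np.inf, -np.inf, x[0], cfg.min_sigma, 0.0]
    upper = [np.inf, np.inf, x[-1], sigma_max, np.inf]
    converged = True
    try:
        popt, _ = curve_fit(_model_single, x, y, p0=p0, bounds=(lower, upper), maxfev=20000)
    except RuntimeError:
        converged = False
        popt = np.array(p0)
    b0, b1, c, s, a = (float(v) for v in popt)
    band = BandFit(center=c, sigma=s, amplitude=a)
    empty = BandFit(center=c, sigma=s, amplitude=0.0)

    as_full_length = False
    if cfg.expected_centers is not None:
        fl_c, a_c = cfg.expected_centers
        as_full_length = abs(c - fl_c) < abs(c - a_c)
    warnings.warn(
        "single detectable band: assigning it to the "
        + ("full-length" if as_full_length else "arrested")
        + " species",
        stacklevel=3,
    )
    resid = y - _model_single(x, *popt)
    fl, ab = (band, empty) if as_full_length else (empty, band)
    return TwoBandFit(
        fl_band=fl,
        a_band=ab,
        baseline=(b0, b1),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=converged,
        single_band=True,
    )


def compute_ffl(
    fit: TwoBandFit, construct_name: str = "", replicate_id: str = ""
) -> FflMeasurement:
    """f_FL = I_FL / (I_FL + I_A) from the fitted band areas."""
    total = fit.fl_band.area + fit.a_band.area
    if total <= 0:
        raise ValueError("both band areas are zero; f_FL undefined")
    return FflMeasurement(
        f_fl=fit.fl_band.area / total,
        construct_name=construct_name,
        replicate_id=replicate_id,
    )


@dataclass(frozen=True)
class AggregateResult:
    """Replicate-aggregated f_FL: mean, standard error of the mean, count."""

    mean: float
    se: float | None
    n: int

    @property
    def se_available(self) -> bool:
        return self.se is not None


def aggregate_replicates(measurements: Sequence[FflMeasurement]) -> AggregateResult:
    """Mean and SE over replicate measurements of one construct.

    SE is the sample standard deviation over sqrt(n); with a single
    measurement the SE is unavailable (None), not zero.
    """
    if not measurements:
        raise ValueError("no measurements to aggregate")
    names = {m.construct_name for m in measurements}
    if len(names) > 1:
        raise ValueError(f"mixed constructs in one aggregate: {sorted(names)}")
    values = np.array([m.f_fl for m in measurements], dtype=float)
    n = values.size
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else None
    return AggregateResult(mean=mean, se=se, n=n)


def quantify_lanes(
    profiles: Iterable[LaneProfile],
    expected_separation: float,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Fit every lane and tabulate per-lane f_FL.

    Returns a DataFrame with columns construct, replicate, f_fl, fl_area,
    a_area, converged, single_band.
    """
    rows = []
    for prof in profiles:
        fit = fit_two_bands(prof, expected_separation, config)
        m = compute_ffl(fit, prof.construct_name, prof.replicate_id)
        rows.append(
            {
                "construct": prof.construct_name,
                "replicate": prof.replicate_id,
                "f_fl": m.f_fl,
                "fl_area": fit.fl_band.area,
                "a_area": fit.a_band.area,
                "converged": fit.converged,
                "single_band": fit.single_band,
            }
        )
    return pd.DataFrame(rows)
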