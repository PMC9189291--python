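"""Relating peak f_FL to equilibrium folding stability.

Ships the published equilibrium folding free energies (kcal/mol, negative =
stable) for the Notch ankyrin constructs, an ordinary least-squares
f_FL-vs-dG fit, a four-parameter logistic alternative, and a nearest-
neighbor decomposition of repeat-protein stability,

    dG(n) = n * dG_intrinsic + (n - 1) * dG_interface,

used to drive the synthetic-data generator.  More negative dG (more stable
domain) corresponds to higher pulling force, hence higher f_FL.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StabilityRecord",
    "LinearFit",
    "SigmoidFit",
    "RepeatModel",
    "builtin_stability_table",
    "fit_linear",
    "fit_sigmoid",
    "calibrate_repeat_model",
    "predict_dG",
]


@dataclass(frozen=True)
class StabilityRecord:
    """Folding free energy of one repeat-array construct."""

    label: str
    n_repeats: int
    dG: float  # kcal/mol

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def builtin_stability_table() -> list[StabilityRecord]:
    """Published equilibrium stabilities of Notch ankyrin repeat arrays.

    Nank1-n contains repeats 1 through n; the single-repeat value is a
    calculated estimate, and M2 is the folding-disrupting A125E/A126F
    double mutant of the full protein (dG ~ 0).
    """
    return [
        StabilityRecord("Nank1-7", 7, -6.65),
        StabilityRecord("Nank1-6", 6, -2.85),
        StabilityRecord("Nank1-5", 5, -2.69),
        StabilityRecord("Nank1-4", 4, +0.37),
        StabilityRecord("single-repeat", 1, +5.5),
        StabilityRecord("M2", 7, 0.0),
    ]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of f_FL against dG."""

    slope: float  # fraction per kcal/mol
    intercept: float
    pearson_r: float
    n: int

    def predict(self, dG: float) -> float:
        return self.intercept + self.slope * dG


def fit_linear(pairs: list[tuple[float, float]]) -> LinearFit:
    """Ordinary least squares of f_FL on dG with Pearson correlation.

    With zero variance in f_FL the correlation is undefined; it is reported
    as 0 with a warning so pipelines stay total.
    """
    if len(pairs) < 2:
        raise ValueError("linear fit needs at least 2 points")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("zero variance in dG: slope undefined")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    syy = float(((y - y.mean()) ** 2).sum())
    slope = sxy / sxx
    intercept = float(y.mean()) - slope * float(x.mean())
    if syy == 0:
        warnings.warn("zero variance in f_FL: Pearson r reported as 0", stacklevel=2)
        r = 0.0
    else:
        r = sxy / math.sqrt(sxx * syy)
    return LinearFit(slope=slope, intercept=intercept, pearson_r=r, n=len(pairs))


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic fit f(dG) = f_min + (f_max - f_min)/(1 + exp(k (dG - dG_mid)))."""

    f_min: float
    f_max: float
    dG_mid: float
    steepness: float
    converged: bool
    underdetermined: bool = False

    def __post_init__(self) -> None:
        if self.f_min > self.f_max:
            raise ValueError("f_min must not exceed f_max")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def predict(self, dG: float | np.ndarray) -> np.ndarray:
        dG = np.asarray(dG, dtype=float)
        return self.f_min + (self.f_max - self.f_min) / (
            1.0 + np.exp(self.steepness * (dG - self.dG_mid))
        )


def _sigmoid(dG, f_min, f_max, dG_mid, k):
    return f_min + (f_max - f_min) / (1.0 + np.exp(k * (dG - dG_mid)))


def fit_sigmoid(
    pairs: list[tuple[float, float]],
    f_min_bound: float = 0.0,
    f_max_bound: float = 1.0,
) -> SigmoidFit:
    """Least-squares logistic fit of f_FL against dG.

    Four free parameters need at least 4 points; with exactly 3 points the
    plateaus are pinned to ``f_min_bound``/``f_max_bound`` and only the
    midpoint and steepness are fitted, and the result is flagged
    underdetermined.
    """
    if len(pairs) < 3:
        raise ValueError("sigmoid fit needs at least 3 points")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)

    underdetermined = len(pairs) == 3
    converged = True
    if underdetermined:
        def pinned(dG, dG_mid, k):
            return _sigmoid(dG, f_min_bound, f_max_bound, dG_mid, k)

        try:
            popt, _ = curve_fit(
                pinned,
                x,
                y,
                p0=[float(np.median(x)), 1.0],
                bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            converged = False
            popt = [float(np.median(x)), 1.0]
        return SigmoidFit(
            f_min=f_min_bound,
            f_max=f_max_bound,
            dG_mid=float(popt[0]),
            steepness=float(popt[1]),
            converged=converged,
            underdetermined=True,
        )

    p0 = [float(y.min()), float(y.max()), float(np.median(x)), 1.0]
    try:
        popt, _ = curve_fit(
            _sigmoid,
            x,
            y,
            p0=p0,
            bounds=([0.0, 0.0, -np.inf, 1e-9], [1.0, 1.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        converged = False
        popt = p0
    f_min, f_max, dG_mid, k = (float(v) for v in popt)
    if f_min > f_max:  # keep the invariant even on a failed fit
        f_min, f_max = f_max, f_min
    return SigmoidFit(
        f_min=f_min,
        f_max=f_max,
        dG_mid=dG_mid,
        steepness=k,
        converged=converged,
    )


@dataclass(frozen=True)
class RepeatModel:
    """Nearest-neighbor stability model dG(n) = n*R + (n-1)*I."""

    dG_intrinsic: float  # R, per repeat
    dG_interface: float  # I, per repeat-repeat interface
    fit_residuals: tuple[float, ...] = ()


def calibrate_repeat_model(
    records: list[StabilityRecord],
    label_pattern: str = r"^Nank",
) -> RepeatModel:
    """Least-squares nearest-neighbor decomposition over the wild-type series.

    Records whose labels do not match ``label_pattern`` (the M2 mutant, the
    extrapolated single-repeat value) are excluded: the model describes the
    additive stability of intact wild-type repeat arrays.
    """
    pat = re.compile(label_pattern)
    used = [r for r in records if pat.search(r.label)]
    if len({r.n_repeats for r in used}) < 2:
        raise ValueError("need >= 2 records with distinct n_repeats after filtering")
    A = np.array([[r.n_repeats, r.n_repeats - 1] for r in used], dtype=float)
    b = np.array([r.dG for r in used], dtype=float)
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("singular design: cannot separate intrinsic and interface terms")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ sol
    return RepeatModel(
        dG_intrinsic=float(sol[0]),
        dG_interface=float(sol[1]),
        fit_residuals=tuple(float(r) for r in resid),
    )


def predict_dG(n_repeats: int, model: RepeatModel) -> float:
    """Predicted folding free energy of an n-repeat array (kcal/mol)."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return n_repeats * model.dG_intrinsic + (n_repeats - 1) * model.dG_interface
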