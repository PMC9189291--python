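"""Force profiles: replicate-aggregated f_FL versus tether length L.

A force profile collects, per construct, the mean fraction full-length
against L (residues from the domain N-terminus to the last AP residue).
Peaks in the profile mark tether lengths at which the domain folds and
pulls on the arrest peptide.  Peak detection works on the irregular L grid
by index-wise neighbor comparison, with topographic prominence and a
residue-based minimum separation as noise filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constructs import ConstructSpec, RepeatSpan, repeats_spanned, DEFAULT_REPEAT_BOUNDARIES

__all__ = [
    "ProfilePoint",
    "ForceProfile",
    "Peak",
    "assemble_profile",
    "detect_peaks",
    "annotate_peaks",
]


@dataclass(frozen=True)
class ProfilePoint:
    """One construct's aggregated measurement on the profile."""

    L: int
    f_fl_mean: float
    se: float | None = None
    n: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_fl_mean <= 1.0:
            raise ValueError(f"f_fl_mean must lie in [0, 1], got {self.f_fl_mean}")
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass(frozen=True)
class ForceProfile:
    """Profile points sorted by increasing L, unique L values."""

    points: tuple[ProfilePoint, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def L(self) -> np.ndarray:
        return np.array([p.L for p in self.points])

    @property
    def f_fl(self) -> np.ndarray:
        return np.array([p.f_fl_mean for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "L": [p.L for p in self.points],
                "f_fl_mean": [p.f_fl_mean for p in self.points],
                "se": [p.se for p in self.points],
                "n": [p.n for p in self.points],
            }
        )


@dataclass(frozen=True)
class Peak:
    """A detected profile maximum."""

    L: int
    f_fl: float
    prominence: float
    repeat_annotation: RepeatSpan | None = None

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise ValueError("peak prominence must be positive")


def assemble_profile(
    points: Sequence[ProfilePoint], metadata: Mapping[str, str] | None = None
) -> ForceProfile:
    """Sort points by L into a ForceProfile; duplicate L values are an error
    (replicates must be aggregated upstream)."""
    if not points:
        raise ValueError("cannot assemble an empty profile")
    Ls = [p.L for p in points]
    if len(set(Ls)) != len(Ls):
        dups = sorted({L for L in Ls if Ls.count(L) > 1})
        raise ValueError(f"duplicate L values in profile: {dups}")
    ordered = tuple(sorted(points, key=lambda p: p.L))
    return ForceProfile(points=ordered, metadata=dict(metadata or {}))


def _prominence(y: np.ndarray, i: int) -> float:
    """Topographic prominence of a local maximum in a discrete series.

    On each side, descend until a value higher than y[i] appears (or the
    series ends), tracking the minimum along the way; the prominence is
    y[i] minus the higher of the two side minima.  For an endpoint the
    missing side is ignored.
    """
    bases = []
    for step, exists in ((-1, i > 0), (1, i < y.size - 1)):
        if not exists:
            continue
        j = i + step
        side_min = y[i]
        while 0 <= j < y.size and y[j] <= y[i]:
            side_min = min(side_min, y[j])
            j += step
        bases.append(side_min)
    return float(y[i] - max(bases))


def detect_peaks(
    profile: ForceProfile,
    min_prominence: float = 0.05,
    min_separation: float = 20.0,
) -> list[Peak]:
    """Local maxima of the profile, filtered by prominence and L separation.

    Interior points are peaks when strictly above both neighbors; an
    endpoint qualifies only when strictly above its single neighbor by at
    least ``min_prominence``.  Candidates below ``min_prominence`` in
    topographic prominence are dropped; of two surviving peaks closer than
    ``min_separation`` residues, the higher one is kept.
    """
    if len(profile) < 3:
        raise ValueError("peak detection needs at least 3 profile points")
    L = profile.L.astype(float)
    y = profile.f_fl
    n = y.size

    candidates: list[int] = []
    if y[0] > y[1] and (y[0] - y[1]) >= min_prominence:
        candidates.append(0)
    for i in range(1, n - 1):
        if y[i] > y[i - 1] and y[i] > y[i + 1]:
            candidates.append(i)
    if y[-1] > y[-2] and (y[-1] - y[-2]) >= min_prominence:
        candidates.append(n - 1)

    peaks = []
    for i in candidates:
        prom = _prominence(y, i)
        if prom >= min_prominence and prom > 0:
            peaks.append((i, prom))

    # enforce separation: keep the higher peak on conflict (ties -> smaller L)
    peaks.sort(key=lambda t: (-y[t[0]], L[t[0]]))
    kept: list[tuple[int, float]] = []
    for i, prom in peaks:
        if all(abs(L[i] - L[j]) >= min_separation for j, _ in kept):
            kept.append((i, prom))

    kept.sort(key=lambda t: -L[t[0]])
    return [
        Peak(L=int(L[i]), f_fl=float(y[i]), prominence=prom) for i, prom in kept
    ]


def annotate_peaks(
    peaks: Sequence[Peak],
    constructs: Sequence[ConstructSpec],
    repeat_boundaries: Sequence[int] = DEFAULT_REPEAT_BOUNDARIES,
) -> list[Peak]:
    """Attach repeat-truncation structure to each peak.

    Each peak's L is looked up in the construct library; the annotation is
    how many complete repeats (plus a partial-repeat tail) the construct's
    domain part spans.
    """
    by_L: dict[int, ConstructSpec] = {}
    for spec in constructs:
        by_L.setdefault(spec.L, spec)
    annotated = []
    for peak in peaks:
        spec = by_L.get(peak.L)
        if spec is None:
            raise KeyError(f"no construct with L = {peak.L} in the library")
        span = repeats_spanned(spec.domain_length, repeat_boundaries)
        annotated.append(
            Peak(L=peak.L, f_fl=peak.f_fl, prominence=peak.prominence, repeat_annotation=span)
        )
    return annotated
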