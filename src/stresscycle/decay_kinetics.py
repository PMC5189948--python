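"""Protein half-life estimation from translation shut-off time courses.

After blocking protein synthesis (chloramphenicol), remaining protein is
followed by immunoblotting and band densitometry.  Each replicate trace is
normalized to its own zero-time intensity, replicates are averaged
pointwise, and a single-exponential decay is fitted by ordinary least
squares on the log scale; the half-life is t1/2 = ln 2 / k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "DecayTimecourse",
    "HalfLifeEstimate",
    "FLOOR_FRACTION",
    "normalize_timecourse",
    "average_replicates",
    "fit_half_life",
    "estimate_half_life",
]

#: Normalized intensities at t > 0 that are <= 0 (saturated background
#: subtraction, lost bands) are floored to this fraction of the t0 signal so
#: the log-linear fit stays defined; the affected points are flagged.
FLOOR_FRACTION = 1e-6

#: A fit is flagged low-confidence when more than this fraction of the
#: points entering it had to be floored.
LOW_CONFIDENCE_FLOOR_FRACTION = 0.30


@dataclass(frozen=True)
class DecayTimecourse:
    """Band-intensity traces over time for one condition.

    ``times`` are minutes since chloramphenicol addition (first point 0,
    strictly increasing); ``intensities`` has one row per replicate on the
    shared time grid, in arbitrary densitometry units.  Any stress
    pre-treatment before the shut-off (e.g. 5 min of ethanol) is metadata
    and does not shift the time origin.
    """

    condition_label: str
    times: np.ndarray
    intensities: np.ndarray
    stress_pre_treatment_min: float = 0.0
    normalized: bool = False
    n_floored: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intens = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)
        if times.ndim != 1 or times.size < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if times[0] != 0:
            raise ValueError("first time point must be 0 (chloramphenicol addition)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if intens.shape[1] != times.size:
            raise ValueError("all replicates must share the time grid")
        if np.any(~np.isfinite(intens)) or np.any(intens < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[0]


@dataclass(frozen=True)
class HalfLifeEstimate:
    """Fitted first-order decay: t1/2 = ln 2 / k, with fit diagnostics.

    ``t_half`` is ``inf`` (and ``"stable"`` appears in ``flags``) when the
    fitted slope is non-negative, i.e. no measurable decay — the behaviour
    seen for stabilized proteins, e.g. under carbon starvation.
    """

    t_half: float
    decay_rate_k: float
    r_squared: float
    n_replicates: int
    normalized_mean: np.ndarray
    normalized_sd: np.ndarray
    times: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.decay_rate_k < 0:
            raise ValueError("decay rate must be non-negative")
        if self.decay_rate_k == 0 and not math.isinf(self.t_half):
            raise ValueError("zero decay rate must report an infinite half-life")


def normalize_timecourse(tc: DecayTimecourse) -> DecayTimecourse:
    """Divide each replicate by its own t0 intensity.

    Requires a strictly positive t0 band in every replicate.  Non-positive
    values at later times are floored to ``FLOOR_FRACTION`` of the t0 signal
    (rather than dropped) and counted in ``n_floored``.
    """
    t0 = tc.intensities[:, 0]
    for r, v in enumerate(t0):
        if v <= 0:
            raise ValueError(f"replicate {r + 1} has non-positive intensity at time 0")
    norm = tc.intensities / t0[:, None]
    floored = norm <= 0
    floored[:, 0] = False
    n_floored = int(np.count_nonzero(floored))
    if n_floored:
        norm = np.where(floored, FLOOR_FRACTION, norm)
        warnings.warn(
            f"{tc.condition_label or 'timecourse'}: floored {n_floored} "
            f"non-positive intensity value(s) to {FLOOR_FRACTION} of t0",
            stacklevel=2,
        )
    return replace(tc, intensities=norm, normalized=True, n_floored=n_floored)


def average_replicates(tc: DecayTimecourse) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample standard deviation across replicates."""
    if tc.n_replicates == 1:
        warnings.warn(
            "single replicate: standard deviations reported as 0", stacklevel=2
        )
        return tc.intensities[0].copy(), np.zeros_like(tc.times)
    mean = tc.intensities.mean(axis=0)
    sd = tc.intensities.std(axis=0, ddof=1)
    return mean, sd


def fit_half_life(
    times: np.ndarray,
    mean_normalized: np.ndarray,
    n_replicates: int = 1,
    normalized_sd: np.ndarray | None = None,
    floored_fraction: float = 0.0,
) -> HalfLifeEstimate:
    """Log-linear OLS fit of a single-exponential decay.

    ln(y) is regressed on t with a free intercept (the intercept absorbs
    loading error at t0); k = -slope.  A non-negative slope is reported as
    k = 0 with an infinite half-life and a ``"stable"`` flag rather than a
    negative rate.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(mean_normalized, dtype=float)
    if t.size < 3:
        raise ValueError("at least 3 time points are required for a fit")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("all normalized values must be finite and > 0 (floor first)")
    fit = stats.linregress(t, np.log(y))
    r_squared = float(fit.rvalue**2)
    flags: list[str] = []
    if floored_fraction > LOW_CONFIDENCE_FLOOR_FRACTION:
        flags.append("low_confidence")
    if fit.slope >= 0:
        k, t_half = 0.0, math.inf
        flags.append("stable")
    else:
        k = float(-fit.slope)
        t_half = math.log(2) / k
    if normalized_sd is None:
        normalized_sd = np.zeros_like(y)
    return HalfLifeEstimate(
        t_half=t_half,
        decay_rate_k=k,
        r_squared=r_squared,
        n_replicates=n_replicates,
        normalized_mean=y,
        normalized_sd=np.asarray(normalized_sd, dtype=float),
        times=t,
        flags=tuple(flags),
    )


def estimate_half_life(
    tc: DecayTimecourse, per_replicate: bool = False
) -> HalfLifeEstimate:
    """Normalize, average and fit a shut-off time course in one call.

    With ``per_replicate=True`` each replicate is fitted separately and the
    reported half-life / rate are the mean across replicates with the spread
    recorded in a ``"t_half_sd=..."`` flag; the default fits the averaged
    curve, which is how multi-replicate shut-off figures are usually drawn.
    """
    norm = tc if tc.normalized else normalize_timecourse(tc)
    mean, sd = average_replicates(norm)
    floored_fraction = norm.n_floored / norm.intensities.size

    if not per_replicate:
        return fit_half_life(
            norm.times, mean,
            n_replicates=norm.n_replicates,
            normalized_sd=sd,
            floored_fraction=floored_fraction,
        )

    fits = [
        fit_half_life(norm.times, row, n_replicates=1,
                      floored_fraction=floored_fraction)
        for row in norm.intensities
    ]
    ks = np.array([f.decay_rate_k for f in fits])
    halves = np.array([f.t_half for f in fits])
    flags = sorted({fl for f in fits for fl in f.flags})
    finite = halves[np.isfinite(halves)]
    if finite.size == len(fits):
        t_half = float(np.mean(halves))
        spread = float(np.std(halves, ddof=1)) if len(fits) > 1 else 0.0
        flags.append(f"t_half_sd={spread:.6g}")
        k = math.log(2) / t_half
    else:
        t_half, k = math.inf, 0.0
        if "stable" not in flags:
            flags.append("stable")
    return HalfLifeEstimate(
        t_half=t_half,
        decay_rate_k=k,
        r_squared=float(np.mean([f.r_squared for f in fits])),
        n_replicates=norm.n_replicates,
        normalized_mean=mean,
        normalized_sd=sd,
        times=norm.times,
        flags=tuple(flags),
    )
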