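"""Nonparametric estimation with left-truncated and right-censored (LTRC) data.

A subject with event time ``X`` enters the study at a random time ``U`` and is
followed until the event or until censoring at ``C``; what is recorded is the
triplet ``(U, Y, Δ)`` with ``Y = min(X, C)`` and ``Δ = I[X ≤ C]``, and only
subjects with ``U ≤ X`` are recorded at all (left truncation).  Under the
standard quasi-independence assumptions, the distribution ``F`` of ``X`` is
estimated by the product-limit (Tsai-Jewell-Wang) estimator, the truncation
distribution ``G`` by inverse-survival weighting of the entry times, and the
residual-censoring distribution ``Q`` (of ``D = C - U``) by a plain
Kaplan-Meier estimator on ``(Y - U, 1 - Δ)``.

The risk set at time ``t`` uses the inclusive convention ``U ≤ t ≤ Y`` on both
sides; records with ``U = Y`` are accepted.  Risk sets of size one ("holes")
zero the survival estimate from that point on; the ``hole_correction`` flag
replaces ``d/r`` by ``d/(r+1)`` so the estimated survival stays positive,
which downstream code (truncation weights, bootstrap resampling) relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np

__all__ = [
    "LTRCError",
    "LengthMismatchError",
    "EntryExceedsTimeError",
    "NoEventsError",
    "NonFiniteError",
    "InvalidStatusError",
    "SurvivalHoleError",
    "LTRCSample",
    "RiskTable",
    "StepCDF",
    "validate_sample",
    "build_risk_table",
    "fit_ltrc_cdf",
    "fit_truncation_cdf",
    "fit_residual_censoring_cdf",
    "estimate_nontruncation",
]

#: numerical tolerance for CDF monotonicity / total-mass assertions
CDF_TOL = 1e-10


class LTRCError(ValueError):
    """Base class for LTRC data and estimation errors."""


class LengthMismatchError(LTRCError):
    """entry/time/status arrays do not have a common length."""


class EntryExceedsTimeError(LTRCError):
    """Some entry time exceeds the observed time (violates U ≤ Y)."""


class NoEventsError(LTRCError):
    """No uncensored record: the event distribution is not estimable."""


class NonFiniteError(LTRCError):
    """A non-finite value appears in entry, time or status."""


class InvalidStatusError(LTRCError):
    """Status codes outside {0, 1}."""


class SurvivalHoleError(LTRCError):
    """Estimated survival is zero at or before an entry time.

    Signals an uncorrected product-limit estimate with a hole (unit risk set)
    at or before some entry time, which makes the inverse-survival weights of
    the truncation-CDF estimator undefined.
    """


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LTRCSample:
    """One group's observed LTRC triplets ``(U_i, Y_i, Δ_i)``.

    Construct through :func:`validate_sample`; the arrays are float64/int8 and
    satisfy ``entry <= time``, ``status ∈ {0,1}`` with at least one event.
    """

    entry: np.ndarray
    time: np.ndarray
    status: np.ndarray
    label: Hashable = "sample"

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())


@dataclass(frozen=True)
class RiskTable:
    """Distinct uncensored event times with event and at-risk counts.

    ``at_risk[i]`` counts records with ``entry ≤ event_times[i] ≤ time``
    (inclusive on both sides).
    """

    event_times: np.ndarray
    deaths: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.deaths > self.at_risk):
            raise LTRCError("deaths exceed the at-risk count")
        if self.event_times.size > 1 and np.any(np.diff(self.event_times) <= 0):
            raise LTRCError("event times are not strictly increasing")


@dataclass(frozen=True)
class StepCDF:
    """Right-continuous step distribution function, possibly defective.

    Stores the atoms (strictly increasing) and the jump sizes.  ``total_mass``
    may be below one: the product-limit estimate is defective when the largest
    observed time is censored or when the hole correction is applied.
    """

    atoms: np.ndarray
    mass: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        atoms = np.atleast_1d(np.asarray(self.atoms, dtype=float))
        mass = np.atleast_1d(np.asarray(self.mass, dtype=float))
        if atoms.shape != mass.shape or atoms.ndim != 1:
            raise LTRCError("atoms and mass must be equal-length 1-d arrays")
        # an empty support (F ≡ 0) arises when a bootstrap resample carries
        # no events; it evaluates to zero everywhere and cannot be sampled
        if atoms.size > 1 and np.any(np.diff(atoms) <= 0):
            raise LTRCError("atoms must be strictly increasing")
        if np.any(mass <= 0):
            raise LTRCError("jump sizes must be positive")
        cum = np.cumsum(mass)
        if atoms.size and cum[-1] > 1.0 + CDF_TOL:
            raise LTRCError(f"total mass {cum[-1]} exceeds 1")
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "mass", mass)
        object.__setattr__(self, "_cum", np.minimum(cum, 1.0))

    @property
    def total_mass(self) -> float:
        return float(self._cum[-1]) if self._cum.size else 0.0

    @property
    def is_proper(self) -> bool:
        return self.total_mass >= 1.0 - CDF_TOL

    def cdf(self, t) -> np.ndarray | float:
        """Right-continuous evaluation F(t) = sum of mass at atoms ≤ t."""
        if self.atoms.size == 0:
            out = np.zeros_like(np.asarray(t, dtype=float))
            return float(out) if np.isscalar(t) else out
        idx = np.searchsorted(self.atoms, t, side="right")
        out = np.where(idx > 0, self._cum[np.maximum(idx - 1, 0)], 0.0)
        return float(out) if np.isscalar(t) else out

    def survival(self, t) -> np.ndarray | float:
        return 1.0 - self.cdf(t)

    def as_proper(self) -> "StepCDF":
        """Assign any mass deficit to the largest atom (Efron's convention).

        Makes a defective estimate usable as a sampling distribution for the
        obvious-bootstrap draw.
        """
        if self.is_proper:
            return self
        if self.atoms.size == 0:
            raise LTRCError("an empty CDF has no atom to carry the deficit")
        deficit = 1.0 - self.total_mass
        mass = self.mass.copy()
        mass[-1] += deficit
        return StepCDF(self.atoms, mass)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Inverse-transform draws on the atoms (requires a proper CDF)."""
        if not self.is_proper:
            raise LTRCError("sampling requires a proper CDF; call as_proper()")
        u = rng.random(n)
        idx = np.minimum(np.searchsorted(self._cum, u, side="left"),
                         self.atoms.size - 1)
        return self.atoms[idx]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_sample(entry, time, status, label: Hashable = "sample") -> LTRCSample:
    """Validate raw arrays into an :class:`LTRCSample`.

    Raises a distinct error for each violated invariant: length mismatch,
    non-finite values, status outside {0,1}, ``entry > time`` (the sampling
    condition ``U ≤ X`` with ``P(U ≤ C) = 1`` forces ``U ≤ Y``), and the
    absence of any uncensored record.
    """
    entry = np.atleast_1d(np.asarray(entry, dtype=float))
    time = np.atleast_1d(np.asarray(time, dtype=float))
    status_arr = np.atleast_1d(np.asarray(status))
    if not (entry.shape == time.shape == status_arr.shape) or entry.ndim != 1:
        raise LengthMismatchError(
            f"entry/time/status lengths differ for group {label!r}: "
            f"{entry.shape}, {time.shape}, {status_arr.shape}"
        )
    if entry.size == 0:
        raise LengthMismatchError(f"empty sample for group {label!r}")
    if not (np.all(np.isfinite(entry)) and np.all(np.isfinite(time))):
        raise NonFiniteError(f"non-finite entry or time in group {label!r}")
    status_f = np.asarray(status_arr, dtype=float)
    if not np.all(np.isfinite(status_f)) or not np.all(np.isin(status_f, (0.0, 1.0))):
        raise InvalidStatusError(f"status must be 0/1 in group {label!r}")
    status_i = status_f.astype(np.int8)
    if np.any(entry > time):
        rows = np.nonzero(entry > time)[0]
        raise EntryExceedsTimeError(
            f"entry exceeds time at index {rows[0]} in group {label!r}"
        )
    if not np.any(status_i == 1):
        raise NoEventsError(f"no uncensored events in group {label!r}")
    return LTRCSample(entry=entry, time=time, status=status_i, label=label)


# ---------------------------------------------------------------------------
# Product-limit estimation
# ---------------------------------------------------------------------------


def _risk_table_arrays(entry: np.ndarray, time: np.ndarray, status: np.ndarray):
    """Distinct event times, tied-event counts and inclusive at-risk counts."""
    event_times, deaths = np.unique(time[status == 1], return_counts=True)
    entry_sorted = np.sort(entry)
    time_sorted = np.sort(time)
    # r(x) = #{U <= x} - #{Y < x}
    at_risk = (
        np.searchsorted(entry_sorted, event_times, side="right")
        - np.searchsorted(time_sorted, event_times, side="left")
    )
    return event_times, deaths, at_risk


def build_risk_table(sample: LTRCSample) -> RiskTable:
    """Risk table with the inclusive convention ``U ≤ x ≤ Y``.

    This deliberately differs from the strict-inequality convention of R's
    ``survfit``; ties of entry times with event times count as at risk, and
    records with ``U = Y`` are accepted.
    """
    t, d, r = _risk_table_arrays(sample.entry, sample.time, sample.status)
    return RiskTable(event_times=t, deaths=d.astype(np.int64),
                     at_risk=r.astype(np.int64))


def _fit_cdf_arrays(entry, time, status, hole_correction: bool):
    """(atoms, mass) of the product-limit CDF from raw arrays (hot path)."""
    event_times, deaths, at_risk = _risk_table_arrays(entry, time, status)
    denom = at_risk + 1 if hole_correction else at_risk
    factors = 1.0 - deaths / denom
    surv = np.cumprod(factors)
    surv_prev = np.concatenate(([1.0], surv[:-1]))
    mass = surv_prev * deaths / denom
    # an uncorrected fit with a hole (r == d) zeroes all later jumps;
    # atoms with no mass are dropped
    keep = mass > 0
    return event_times[keep], mass[keep]


def fit_ltrc_cdf(sample: LTRCSample, hole_correction: bool = True) -> StepCDF:
    """Product-limit estimator of the event-time distribution ``F``.

    ``F(t) = 1 - Π_{x_i ≤ t} (1 - d_i / r_i)`` over the distinct uncensored
    event times, with ``r_i`` replaced by ``r_i + 1`` when ``hole_correction``
    is on (the default used throughout the package).  Reduces to Kaplan-Meier
    without truncation and to the Lynden-Bell estimator without censoring.
    """
    atoms, mass = _fit_cdf_arrays(sample.entry, sample.time, sample.status,
                                  hole_correction)
    return StepCDF(atoms, mass)


def _truncation_weights(sample: LTRCSample, target_cdf: StepCDF) -> np.ndarray:
    surv_at_entry = target_cdf.survival(sample.entry)
    if np.any(surv_at_entry <= 0):
        raise SurvivalHoleError(
            "estimated survival is zero at an entry time; refit the target "
            "CDF with hole_correction=True"
        )
    return 1.0 / surv_at_entry


def fit_truncation_cdf(sample: LTRCSample, target_cdf: StepCDF | None = None) -> StepCDF:
    """Inverse-survival-weighted estimator of the truncation distribution G.

    Each entry time ``U_l`` receives weight proportional to ``1/S(U_l)``
    where ``S`` comes from ``target_cdf`` (fitted with the hole correction
    when not supplied, which guarantees ``S(U_l) > 0``).  ``S`` is evaluated
    right-continuously when an entry time ties an event time.
    """
    if target_cdf is None:
        target_cdf = fit_ltrc_cdf(sample, hole_correction=True)
    w = _truncation_weights(sample, target_cdf)
    atoms, inverse = np.unique(sample.entry, return_inverse=True)
    mass = np.bincount(inverse, weights=w, minlength=atoms.size)
    mass /= mass.sum()
    return StepCDF(atoms, mass)


def estimate_nontruncation(sample: LTRCSample, target_cdf: StepCDF | None = None) -> float:
    """Nontruncation probability γ = P(U ≤ X), harmonic-mean-of-survival form.

    ``γ̂ = n · (Σ_l S(U_l)^{-1})^{-1}`` — the normalising constant of the
    truncation-CDF estimator.
    """
    if target_cdf is None:
        target_cdf = fit_ltrc_cdf(sample, hole_correction=True)
    w = _truncation_weights(sample, target_cdf)
    return float(sample.n / w.sum())


def fit_residual_censoring_cdf(sample: LTRCSample) -> StepCDF:
    """Kaplan-Meier estimator of the residual-censoring distribution Q.

    Works on the residual times ``V_l = Y_l - U_l`` with event indicator
    ``1 - Δ_l`` (censoring of X is the event for D).  At tied residual times,
    D-events precede D-censorings (the standard KM tie rule).  Any remaining
    mass is placed on the largest residual time so the returned CDF is proper
    and directly usable by the bootstrap draw.
    """
    v = sample.time - sample.entry
    d_event = 1 - sample.status  # censoring of X is the event for D
    v_sorted = np.sort(v)
    n = v.size
    if np.any(d_event == 1):
        times, deaths = np.unique(v[d_event == 1], return_counts=True)
        at_risk = n - np.searchsorted(v_sorted, times, side="left")
        factors = 1.0 - deaths / at_risk
        surv = np.cumprod(factors)
        surv_prev = np.concatenate(([1.0], surv[:-1]))
        mass = surv_prev * deaths / at_risk
        atoms = times
    else:
        atoms = np.empty(0)
        mass = np.empty(0)
    deficit = 1.0 - (mass.sum() if mass.size else 0.0)
    if deficit > CDF_TOL:
        vmax = v_sorted[-1]
        if atoms.size and atoms[-1] == vmax:
            mass = mass.copy()
            mass[-1] += deficit
        else:
            atoms = np.concatenate((atoms, [vmax]))
            mass = np.concatenate((mass, [deficit]))
    return StepCDF(atoms, mass)
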