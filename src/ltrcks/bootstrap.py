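"""Obvious-bootstrap approximation of the null distribution.

The asymptotic null laws of the omnibus statistics depend on unknown
population quantities, so p-values are obtained by resampling instead.  The
"obvious bootstrap" redraws the data-generating mechanism from the fitted
pieces: a truncation time ``U`` from ``Ĝ_j``, an event time ``X`` from a
product-limit estimate, and a residual-censoring time ``D`` from ``Q̂_j``
(valid when ``D = C - U`` is independent of ``(U, X)`` on the observable
region); the draw is kept only when the sampling condition ``U ≤ X`` holds,
and the accepted triplet is ``(U, min(X, U + D), I[X ≤ U + D])``.

The null hypothesis enters through the event time: for a record resampled in
group ``j``, the group ``j*`` whose ``F̂`` supplies ``X`` is freshly drawn
with the pooling probabilities ``p_1..p_k``, while ``U`` and ``D`` keep the
group's own truncation and censoring mechanisms.  p-values are the fraction
of replicate statistics at or above the observed one.

Draws are vectorised: each batch draws, in order, the group indices, then
``U``, ``X`` and ``D`` for every pending record from one shared stream, and
rejected records re-enter the next batch; results are reproducible
bit-for-bit for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .estimators import (
    LTRCError,
    LTRCSample,
    StepCDF,
    fit_ltrc_cdf,
    fit_residual_censoring_cdf,
    fit_truncation_cdf,
)
from .statistics import TestConfig, _ks_cvm_from_cdfs

__all__ = [
    "AcceptanceError",
    "TestResult",
    "draw_obvious_triplet",
    "resample_null",
    "bootstrap_pvalues",
]


class AcceptanceError(LTRCError):
    """Rejection sampling failed to accept within the attempt budget.

    Signals (nearly) disjoint supports of the truncation and event-time
    distributions, under which the observable region has vanishing mass.
    """


#: default budget of consecutive rejected draws per record
MAX_ATTEMPTS = 10**6


@dataclass(frozen=True)
class TestResult:
    """Observed statistics, bootstrap replicates and p-values."""

    d_ks: float
    d_cvm: float
    boot_ks: np.ndarray
    boot_cvm: np.ndarray
    p_ks: float
    p_cvm: float
    B: int
    seed: int | None = None


def draw_obvious_triplet(
    G: StepCDF,
    F: StepCDF,
    Q: StepCDF,
    rng: np.random.Generator,
    max_attempts: int = MAX_ATTEMPTS,
) -> tuple[float, float, int]:
    """One accepted LTRC triplet ``(U, Y, Δ)`` from fitted step CDFs.

    Repeats independent draws ``(U, X, D)`` until ``U ≤ X``; the CDFs must be
    proper (apply :meth:`StepCDF.as_proper` to a defective estimate first).
    """
    g, f, q = G.as_proper(), F.as_proper(), Q.as_proper()
    for _ in range(max_attempts):
        u = g.sample(rng, 1)[0]
        x = f.sample(rng, 1)[0]
        d = q.sample(rng, 1)[0]
        if u <= x:
            return float(u), float(min(x, u + d)), int(x <= u + d)
    raise AcceptanceError(
        f"no accepted draw in {max_attempts} attempts; are the supports "
        "of G and F (nearly) disjoint?"
    )


class _NullResampler:
    """Prefitted estimators for repeated H0 resampling of the same samples."""

    def __init__(self, samples: Sequence[LTRCSample], config: TestConfig | None = None):
        config = config or TestConfig()
        self.sizes = np.array([s.n for s in samples], dtype=int)
        self.weights = config.resolve_weights(self.sizes)
        self.labels = [s.label for s in samples]
        self.config = config
        self.f_hats = [
            fit_ltrc_cdf(s, hole_correction=config.hole_correction) for s in samples
        ]
        # sampling distributions: defective mass goes to the largest atom
        self.f_samp = [f.as_proper() for f in self.f_hats]
        self.g_hats = [
            fit_truncation_cdf(s, f) for s, f in zip(samples, self.f_hats)
        ]
        self.q_hats = [fit_residual_censoring_cdf(s) for s in samples]
        self._wcum = np.cumsum(self.weights)

    def _draw_group(
        self, j: int, rng: np.random.Generator, max_attempts: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """n_j accepted records for slot-group j, batched rejection sampling."""
        n = int(self.sizes[j])
        g, q = self.g_hats[j], self.q_hats[j]
        out_u = np.empty(0)
        out_y = np.empty(0)
        out_s = np.empty(0, dtype=np.int8)
        attempts = 0
        while out_u.size < n:
            need = n - out_u.size
            m = max(64, 2 * need)
            attempts += m
            if attempts > max_attempts * n:
                raise AcceptanceError(
                    f"group {self.labels[j]!r}: acceptance budget exhausted"
                )
            # draw order per batch: group index, U, X, D
            jstar = np.searchsorted(self._wcum, rng.random(m), side="left")
            jstar = np.minimum(jstar, len(self.f_samp) - 1)
            u = g.sample(rng, m)
            x = np.empty(m)
            for jj in range(len(self.f_samp)):
                mask = jstar == jj
                if mask.any():
                    x[mask] = self.f_samp[jj].sample(rng, int(mask.sum()))
            d = q.sample(rng, m)
            acc = u <= x
            if acc.any():
                u, x, d = u[acc], x[acc], d[acc]
                out_u = np.concatenate((out_u, u))
                out_y = np.concatenate((out_y, np.minimum(x, u + d)))
                out_s = np.concatenate((out_s, (x <= u + d).astype(np.int8)))
        return out_u[:n], out_y[:n], out_s[:n]

    def resample(
        self, rng: np.random.Generator, max_attempts: int = MAX_ATTEMPTS
    ) -> list[LTRCSample]:
        return [
            LTRCSample(*self._draw_group(j, rng, max_attempts), label=self.labels[j])
            for j in range(len(self.sizes))
        ]

    def statistics(self, resamples: Sequence[LTRCSample]) -> tuple[float, float]:
        cdfs = [
            fit_ltrc_cdf(s, hole_correction=self.config.hole_correction)
            for s in resamples
        ]
        return _ks_cvm_from_cdfs(cdfs, self.sizes.astype(float), self.weights)


def resample_null(
    samples: Sequence[LTRCSample],
    config: TestConfig | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = MAX_ATTEMPTS,
) -> list[LTRCSample]:
    """One H0 resample of the original group sizes.

    Event times come from the ``F̂`` of a freshly drawn group index (pooling
    the groups under H0); truncation and residual-censoring times come from
    the slot group's own ``Ĝ`` and ``Q̂``.  Every resampled record satisfies
    ``U ≤ Y``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    return _NullResampler(samples, config).resample(rng, max_attempts)


def bootstrap_pvalues(
    samples: Sequence[LTRCSample],
    B: int,
    config: TestConfig | None = None,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = MAX_ATTEMPTS,
) -> TestResult:
    """Bootstrap p-values for both omnibus statistics.

    Computes the observed ``D⁰_KS`` and ``D⁰_CvM``, then ``B`` null
    resamples and their statistics; ``p = (1/B) #{b : D^b ≥ D⁰}``.
    Deterministic for a given integer seed or seeded generator.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sampler = _NullResampler(samples, config)
    d_ks, d_cvm = _ks_cvm_from_cdfs(
        sampler.f_hats, sampler.sizes.astype(float), sampler.weights
    )
    boot_ks = np.empty(B)
    boot_cvm = np.empty(B)
    for b in range(B):
        stars = sampler.resample(rng, max_attempts)
        boot_ks[b], boot_cvm[b] = sampler.statistics(stars)
    return TestResult(
        d_ks=d_ks,
        d_cvm=d_cvm,
        boot_ks=boot_ks,
        boot_cvm=boot_cvm,
        p_ks=float(np.mean(boot_ks >= d_ks)),
        p_cvm=float(np.mean(boot_cvm >= d_cvm)),
        B=B,
        seed=seed,
    )
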