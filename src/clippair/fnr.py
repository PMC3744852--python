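"""Closed-form false-negative rate of the paired clipped-read design.

Calling a junction needs at least one usable MS read and one usable SM read
among the n reads that cover it.  A junction-covering read is MS or SM with
probability 1/2 each (its breakpoint offset is uniform along the read), and
its clip is too short to pass the collection threshold with probability

    q1 = (min_clip - 1) / (L/2)            (MS side)
    q2 = (min_clip + dx - 1) / (L/2)       (SM side)

where ``dx`` is the junction homology width: homology is absorbed into the
SM read's matched part, shortening its clip by dx and making the SM side
harder.  The failure probability is obtained by conditioning on the number
``i`` of MS-oriented reads and applying inclusion-exclusion to the events
"no usable MS read" and "no usable SM read":

    FNR = sum_{i=0}^{n} C(n,i) (1/2)^n [ q1^i + q2^(n-i) - q1^i q2^(n-i) ].

A Monte-Carlo verifier simulating reads at the same granularity is provided
as an independent check of the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["FnrParams", "FnrEstimate", "fnr_analytic", "fnr_monte_carlo"]


@dataclass(frozen=True)
class FnrParams:
    """Design parameters of the failure model.

    n         -- junction-covering reads (>= 0); ~ coverage/2 per allele copy.
    read_length -- L, bases; even, so the MS/SM halves are symmetric.
    min_clip  -- collection threshold on the clip length (nS; default policy
                 keeps clips of min_clip and longer).
    dx        -- breakpoint homology width, bases.
    """

    n: int
    read_length: int = 100
    min_clip: int = 11
    dx: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.min_clip < 1:
            raise ValueError("min_clip must be >= 1")
        if self.read_length % 2 or self.read_length < 2 * self.min_clip:
            raise ValueError("read_length must be even and >= 2*min_clip")
        if self.dx < 0:
            raise ValueError("dx must be >= 0")
        if self.min_clip + self.dx - 1 > self.read_length // 2:
            raise ValueError("min_clip + dx - 1 must be <= read_length/2")

    @property
    def q1(self) -> float:
        return (self.min_clip - 1) / (self.read_length / 2)

    @property
    def q2(self) -> float:
        return (self.min_clip + self.dx - 1) / (self.read_length / 2)


@dataclass(frozen=True)
class FnrEstimate:
    estimate: float
    stderr: float
    reps: int

    def agrees_with(self, value: float, n_se: float = 3.0) -> bool:
        return abs(self.estimate - value) <= n_se * self.stderr


def fnr_analytic(p: FnrParams) -> float:
    """Evaluate the closed-form failure probability.

    The binomial sum is accumulated with log-space binomial coefficients so
    large n neither overflows C(n, i) nor loses the tiny tail terms.  The
    bracketed factor 1 - (1 - q1^i)(1 - q2^(n-i)) is non-negative, so the
    sum has no cancellation.  Returns a probability in [0, 1]; n = 0 gives
    exactly 1 (no reads, certain failure).
    """
    n, q1, q2 = p.n, p.q1, p.q2
    if n == 0:
        return 1.0
    log_half = -n * math.log(2.0)
    total = 0.0
    for i in range(n + 1):
        log_comb = (
            math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
        )
        bracket = q1**i + q2 ** (n - i) - q1**i * q2 ** (n - i)
        if bracket > 0.0:
            total += math.exp(log_comb + log_half) * bracket
    return min(max(total, 0.0), 1.0)


def fnr_monte_carlo(
    p: FnrParams, reps: int = 100_000, seed: int = 0, chunk: int = 100_000
) -> FnrEstimate:
    """Estimate the failure probability by read-level simulation.

    Each replicate draws n reads: every read is MS or SM with probability
    1/2, and its clip fails the threshold with probability q1 (MS) or q2
    (SM), matching the uniform-offset geometry of the closed form.  The
    replicate fails when no usable MS read or no usable SM read remains.
    Returns the failure fraction with its binomial standard error.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = p.n
    failures = 0
    if n == 0:
        failures = reps
    else:
        done = 0
        while done < reps:
            m = min(chunk, reps - done)
            is_ms = rng.random((m, n)) < 0.5
            short = rng.random((m, n))
            usable_ms = (is_ms & (short >= p.q1)).any(axis=1)
            usable_sm = (~is_ms & (short >= p.q2)).any(axis=1)
            failures += int((~(usable_ms & usable_sm)).sum())
            done += m
    est = failures / reps
    se = math.sqrt(est * (1.0 - est) / reps)
    return FnrEstimate(estimate=est, stderr=se, reps=reps)
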