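"""Sample size for detecting a correlation, via the Fisher z-transform.

The number of subjects needed to detect a product-moment correlation ``r``
at two-sided level ``alpha`` with the given power is

    C = (1/2) * ln((1 + r) / (1 - r))          (Fisher z of r)
    n = round(((z_{alpha/2} + z_{beta}) / C)^2) + 3

with standard-normal quantiles z.  The squared quotient is rounded to the
nearest integer *before* adding 3 — the convention that reproduces the
published correlation sample-size tables this calculator mirrors (a ceiling
would give one more subject at several entries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs: expected correlation, two-sided alpha, desired power."""

    effect_size_r: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not -1.0 < self.effect_size_r < 1.0:
            raise ValueError(f"effect_size_r must be in (-1, 1), got {self.effect_size_r}")
        if self.effect_size_r == 0.0:
            raise ValueError("effect_size_r must be nonzero (n is infinite at r=0)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must be in (0, 1), got {self.power}")


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform of a correlation: atanh(r)."""
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


def sample_size_correlation(spec: PowerSpec) -> int:
    """Subjects needed to detect the correlation in ``spec``.

    Symmetric in the sign of r; strictly decreasing in |r|, increasing in
    power, increasing as alpha shrinks.
    """
    z_alpha = float(stats.norm.ppf(1.0 - spec.alpha / 2.0))
    z_beta = float(stats.norm.ppf(spec.power))
    c = fisher_z(abs(spec.effect_size_r))
    return int(round(((z_alpha + z_beta) / c) ** 2)) + 3


def sample_size_details(spec: PowerSpec) -> dict:
    """The intermediates a design report prints alongside n."""
    z_alpha = float(stats.norm.ppf(1.0 - spec.alpha / 2.0))
    z_beta = float(stats.norm.ppf(spec.power))
    c = fisher_z(abs(spec.effect_size_r))
    return {
        "n": int(round(((z_alpha + z_beta) / c) ** 2)) + 3,
        "z_alpha": z_alpha,
        "z_beta": z_beta,
        "fisher_c": c,
    }
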