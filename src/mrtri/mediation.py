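"""Mediation and effect-comparison arithmetic on log-scale MR estimates.

The proportion of a total causal effect transmitted through a mediator is
``1 - theta_direct / theta_total``, with the direct effect taken from
multivariable MR (adjusted for the mediator) and the total effect from
univariable MR.  For binary outcomes both effects must be log-odds — the only
scale on which this ratio of odds-ratio logarithms is coherent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MediationResult:
    theta_total: float
    theta_direct: float
    proportion_mediated: float  # as a fraction; .percent for display
    scale: str = "log-odds"
    inconsistent: bool = False  # proportion outside [0, 1], not clipped

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion_mediated


def proportion_mediated(theta_total: float, theta_direct: float,
                        scale: str = "log-odds") -> MediationResult:
    """Proportion mediated = 1 - theta_direct / theta_total.

    Both effects must be on the same (log) scale.  Values outside [0, 1]
    are returned flagged ``inconsistent`` rather than clipped — they arise
    when sampling error or pleiotropy pushes the direct effect past the
    total.
    """
    if theta_total == 0:
        raise ValueError("theta_total must be nonzero")
    prop = 1.0 - theta_direct / theta_total
    return MediationResult(
        theta_total=float(theta_total), theta_direct=float(theta_direct),
        proportion_mediated=float(prop), scale=scale,
        inconsistent=not (0.0 <= prop <= 1.0))


def proportion_mediated_from_or(or_total: float, or_direct: float,
                                ) -> MediationResult:
    """Same, from odds ratios: thetas are their natural logarithms."""
    if or_total <= 0 or or_direct <= 0:
        raise ValueError("odds ratios must be positive")
    return proportion_mediated(np.log(or_total), np.log(or_direct),
                               scale="log-odds")


def effect_ratio(theta_a: float, theta_b: float) -> float:
    """How many times larger effect a is than effect b, on the log scale."""
    if theta_b == 0:
        raise ValueError("theta_b must be nonzero")
    return float(theta_a / theta_b)


def effect_ratio_from_or(or_a: float, or_b: float) -> float:
    """Ratio of log odds ratios: ln(or_a) / ln(or_b)."""
    if or_a <= 0 or or_b <= 0:
        raise ValueError("odds ratios must be positive")
    return effect_ratio(np.log(or_a), np.log(or_b))
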