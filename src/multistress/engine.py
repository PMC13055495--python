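"""Classify 2x2 stressor interactions against the additive null on the link scale.

A fitted factorial model's interaction coefficient measures the departure of
the combined-treatment effect from the "additive" null expectation formed by
summing the two main effects on the model's link scale.  Because additivity
is scale-dependent, classifications are specific to the link: on log and
logit links the back-transformed exp(beta_int) is an interaction ratio
(= 1 under the null), on the identity link beta_int itself is the deviation.

Taxonomy
--------
* synergism    - the combined effect exceeds the additive expectation in the
                 direction the main effects already point;
* antagonism   - the interaction pulls the combined effect back toward (but
                 not past) the null expectation;
* reversal     - the interaction flips the sign of the combined effect
                 relative to the additive expectation;
* none         - the interaction term is not statistically supported;
* indeterminate- the additive or observed combined effect is exactly zero,
                 so no direction can be assigned (only constructed inputs
                 reach this state).

A significant interaction whose confidence interval overlaps a smallest-
effect-size-of-interest (SESOI) band around the null (default +/-5%) keeps
its directional classification but is flagged as a *mild* deviation, in the
spirit of equivalence testing.
"""

from __future__ import annotations

import math
from typing import Optional

from scipy.stats import norm

from multistress.types import (
    InputError,
    ConfigurationError,
    ScaleMismatchError,
    InteractionClass,
    InteractionRatio,
    NullDecomposition,
    SESOIBand,
    StressorCoefficients,
)

__all__ = [
    "decompose_null",
    "interaction_ratio_ci",
    "sesoi_band",
    "classify_interaction",
    "flag_mild",
]


def decompose_null(coef: StressorCoefficients) -> NullDecomposition:
    """Split a fitted model into additive null and observed combined effects.

    Returns the additive expectation ``delta_add = beta_w + beta_p``, the
    observed combined effect ``delta_obs = delta_add + beta_int``, and the
    interaction coefficient itself, all on the model's link scale.
    """
    delta_add = coef.beta_w + coef.beta_p
    return NullDecomposition(
        delta_add=delta_add,
        delta_obs=delta_add + coef.beta_int,
        beta_int=coef.beta_int,
    )


def interaction_ratio_ci(
    coef: StressorCoefficients, level: float = 0.95
) -> InteractionRatio:
    """Back-transformed interaction effect with a Wald confidence interval.

    For log and logit links: ratio = exp(beta_int) with
    CI = exp(beta_int +/- z * se_int), z the standard-normal quantile at
    (1 + level)/2.  For the identity link the coefficient and CI are
    returned untransformed (scale="identity").
    """
    if not (0.0 < level < 1.0):
        raise InputError(f"confidence level must lie in (0, 1), got {level}")
    z = norm.ppf(0.5 * (1.0 + level))
    lo = coef.beta_int - z * coef.se_int
    hi = coef.beta_int + z * coef.se_int
    if coef.link in ("log", "logit"):
        # clamp the link-scale bounds so extreme fits do not overflow exp
        exp_ = lambda v: math.exp(min(max(v, -700.0), 700.0))
        return InteractionRatio(
            ratio=exp_(coef.beta_int),
            ci_low=exp_(lo),
            ci_high=exp_(hi),
            level=level,
            scale="exp",
        )
    return InteractionRatio(
        ratio=coef.beta_int, ci_low=lo, ci_high=hi, level=level, scale="identity"
    )


def sesoi_band(
    link: str,
    percent: float = 5.0,
    reference_quantity: Optional[float] = None,
) -> SESOIBand:
    """Build the smallest-effect-size-of-interest band for a given link.

    Log and logit links use the exp scale: [1 - percent/100, 1 + percent/100]
    (so 5% -> [0.95, 1.05]).  The identity link needs a positive
    ``reference_quantity`` whose +/- percent defines the band around zero;
    typically the magnitude of the additive expectation of the same fit, but
    configurable because the choice of reference is a reporting decision.
    """
    if not percent > 0:
        raise ConfigurationError(f"SESOI percent must be > 0, got {percent}")
    if link in ("log", "logit"):
        if percent >= 100:
            raise ConfigurationError("exp-scale SESOI percent must be < 100")
        half = percent / 100.0
        return SESOIBand(scale="exp", low=1.0 - half, high=1.0 + half)
    if link == "identity":
        if reference_quantity is None or not reference_quantity > 0:
            raise ConfigurationError(
                "identity-link SESOI band needs reference_quantity > 0"
            )
        half = (percent / 100.0) * reference_quantity
        return SESOIBand(
            scale="identity", low=-half, high=half,
            reference_quantity=reference_quantity,
        )
    raise ConfigurationError(f"unknown link {link!r}")


def flag_mild(ratio: InteractionRatio, band: SESOIBand) -> bool:
    """True iff the interaction CI overlaps the SESOI band (closed intervals)."""
    if ratio.scale != band.scale:
        raise ScaleMismatchError(
            f"CI on {ratio.scale!r} scale but band on {band.scale!r} scale"
        )
    return bool(ratio.ci_low <= band.high and band.low <= ratio.ci_high)


def _sign(x: float) -> int:
    # exact-zero sign; fitted estimates are never exactly zero in practice
    return int(x > 0) - int(x < 0)


def classify_interaction(
    coef: StressorCoefficients,
    alpha_sig: float = 0.05,
    band: Optional[SESOIBand] = None,
    level: float = 0.95,
) -> InteractionClass:
    """Classify one fitted 2x2 interaction against the additive null.

    Decision logic, in order:

    1. if ``p_int >= alpha_sig`` the interaction is not statistically
       supported: category "none", code "NA";
    2. decompose into delta_add / delta_obs;
    3. if beta_int, delta_add or delta_obs is exactly zero: "indeterminate"
       (no direction assignable);
    4. sign(delta_obs) != sign(delta_add): reversal, coded R+/- when the
       additive expectation was positive, R-/+ when negative;
    5. main effects of the same sign: synergism when the interaction shares
       that sign (amplification), antagonism otherwise;
    6. opposing (or one-zero) main effects: synergism when the interaction
       reinforces the net additive effect (same sign as delta_add),
       antagonism when it counteracts it.

    The +/- suffix on S/A codes is the sign of delta_obs - the direction of
    the combined treatment relative to the double control.  When ``band``
    is given, any directional classification whose ``level`` Wald CI
    overlaps the band is flagged mild.
    """
    if not (0.0 < alpha_sig < 1.0):
        raise InputError(f"alpha_sig must lie in (0, 1), got {alpha_sig}")
    dec = decompose_null(coef)
    ratio = interaction_ratio_ci(coef, level=level)

    if coef.p_int >= alpha_sig:
        return InteractionClass(
            category="none", code="NA", mild=False, decomposition=dec,
            ratio=ratio, response=coef.response, date_label=coef.date_label,
        )

    s_add = _sign(dec.delta_add)
    s_obs = _sign(dec.delta_obs)
    s_int = _sign(coef.beta_int)
    s_w, s_p = _sign(coef.beta_w), _sign(coef.beta_p)

    if s_int == 0 or s_add == 0 or s_obs == 0:
        category, code = "indeterminate", "NA"
    elif s_obs != s_add:
        category = "reversal"
        code = "R+/-" if s_add > 0 else "R-/+"
    else:
        if s_w == s_p and s_w != 0:
            category = "synergism" if s_int == s_w else "antagonism"
        else:
            category = "synergism" if s_int == s_add else "antagonism"
        code = ("S" if category == "synergism" else "A") + ("+" if s_obs > 0 else "-")

    mild = False
    if band is not None and category in ("synergism", "antagonism", "reversal"):
        mild = flag_mild(ratio, band)

    return InteractionClass(
        category=category, code=code, mild=mild, decomposition=dec,
        ratio=ratio, response=coef.response, date_label=coef.date_label,
    )
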