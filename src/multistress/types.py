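"""Shared domain types and exceptions for the factorial stressor pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

LINKS = ("log", "logit", "identity")
SITES = ("non_polluted", "polluted")
WARMING = ("ambient", "warmed")

#: Interaction-type codes: synergistic / antagonistic positive or negative,
#: and reversals from positive-to-negative / negative-to-positive combined effect.
CODES = ("NA", "S+", "S-", "A+", "A-", "R+/-", "R-/+")
CATEGORIES = ("none", "synergism", "antagonism", "reversal", "indeterminate")


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class InputError(ValueError):
    """Malformed or out-of-contract input data."""


class DegenerateFitError(RuntimeError):
    """A model fit would be degenerate (zero variance, separation, ...)."""


class ScaleMismatchError(ValueError):
    """An interaction CI and a SESOI band live on different scales."""


class PipelineOrderError(RuntimeError):
    """A stage ran before one of its prerequisites (e.g. BH adjustment)."""


@dataclass(frozen=True)
class StressorCoefficients:
    """Link-scale coefficients of one fitted 2x2 factorial model.

    The linear predictor is ``alpha + beta_w*W + beta_p*P + beta_int*W*P``
    with treatment coding: W=1 for warmed (ambient reference), P=1 for the
    polluted site (non-polluted reference).  ``alpha`` may be NaN when a
    coefficient table from an external tool omits the intercept; nothing in
    the interaction classification uses it.
    """

    response: str
    date_label: str
    link: str
    beta_w: float
    beta_p: float
    beta_int: float
    se_w: float
    se_p: float
    se_int: float
    p_w: float
    p_p: float
    p_int: float
    alpha: float = math.nan
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise InputError(f"unknown link {self.link!r}; expected one of {LINKS}")
        for name in ("se_w", "se_p", "se_int"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("p_w", "p_p", "p_int"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise InputError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class GeneFit:
    """Per-gene factorial fit: log2 fold-changes, Wald SEs and p-values.

    ``padj_*`` are Benjamini-Hochberg adjusted values filled in by the
    gene-typing stage; NaN until then.
    """

    gene_id: str
    lfc_w: float
    lfc_p: float
    lfc_int: float
    se_w: float
    se_p: float
    se_int: float
    p_w: float
    p_p: float
    p_int: float
    padj_w: float = math.nan
    padj_p: float = math.nan
    padj_int: float = math.nan


@dataclass(frozen=True)
class NullDecomposition:
    """Additive expectation and observed combined effect on the link scale.

    delta_add = beta_w + beta_p is the null prediction for the combined
    treatment; delta_obs = delta_add + beta_int is the model's actual
    combined-treatment contrast.  delta_obs - delta_add == beta_int exactly.
    """

    delta_add: float
    delta_obs: float
    beta_int: float


@dataclass(frozen=True)
class InteractionRatio:
    """Back-transformed interaction effect with its Wald CI.

    On the ``exp`` scale (log and logit links) the ratio is exp(beta_int):
    the multiplicative deviation of the combined effect from the additive
    expectation (for logit links, a ratio of odds ratios).  On the
    ``identity`` scale the untransformed beta_int and CI are carried.
    """

    ratio: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    scale: str = "exp"

    def __post_init__(self) -> None:
        if self.scale not in ("exp", "identity"):
            raise InputError(f"unknown ratio scale {self.scale!r}")
        if not (self.ci_low <= self.ratio <= self.ci_high):
            raise InputError("CI bounds must bracket the point estimate")


@dataclass(frozen=True)
class SESOIBand:
    """Smallest-effect-size-of-interest equivalence band around the null.

    ``exp`` scale: an interval around 1 (e.g. [0.95, 1.05] for +/-5%).
    ``identity`` scale: +/- percent/100 * reference_quantity around 0.
    """

    scale: str
    low: float
    high: float
    reference_quantity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scale not in ("exp", "identity"):
            raise InputError(f"unknown band scale {self.scale!r}")
        if not self.low < self.high:
            raise InputError("band must have low < high")
        if self.scale == "exp" and not (self.low < 1.0 < self.high):
            raise InputError("exp-scale band must contain 1")
        if self.scale == "identity" and not (self.low < 0.0 < self.high):
            raise InputError("identity-scale band must contain 0")


@dataclass(frozen=True)
class InteractionClass:
    """Outcome of classifying one fitted interaction.

    ``category`` is the taxonomy bucket; ``code`` the six-way directional
    code (NA when the interaction is not statistically supported);
    ``mild`` is True when a SESOI band was supplied and the interaction CI
    overlaps it.
    """

    category: str
    code: str
    mild: bool
    decomposition: NullDecomposition
    ratio: Optional[InteractionRatio] = None
    response: str = ""
    date_label: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InputError(f"unknown category {self.category!r}")
        if self.code not in CODES:
            raise InputError(f"unknown code {self.code!r}")
        if (self.category == "none") != (self.code == "NA") and self.category != "indeterminate":
            raise InputError("category 'none' if and only if code 'NA'")
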