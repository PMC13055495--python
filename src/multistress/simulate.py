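"""Synthetic factorial survey and RNA-seq-like data with known ground truth.

Emulates a fully factorial 2x2 field experiment - two sites (polluted vs.
non-polluted) crossed with two warming treatments (warmed vs. ambient) - with
settlement plates surveyed fortnightly over a season, plus an end-of-season
factorial RNA-seq design.  Generation is statistical, matching the analysis
models' assumptions (no mechanistic population dynamics): each response is
drawn from a GLM-style model whose link-scale linear predictor is

    eta = alpha + beta_w*W + beta_p*P + beta_int*W*P + plate_effect + season(t)

Reproducibility: one root seed spawns independent child streams per plate
(or per gene), so outputs are bit-identical under a fixed seed and invariant
to the order plates/genes are generated in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from multistress.types import ConfigurationError, SITES, WARMING

__all__ = [
    "SimulationConfig",
    "GeneSimConfig",
    "CoefficientGenSpec",
    "simulate_survey",
    "simulate_gene_counts",
    "simulate_coefficients",
]

_FAMILY_LINKS = {
    "count_nb": ("log",),
    "binary": ("logit",),
    "proportion": ("logit",),
    "continuous": ("identity", "log"),
}

#: interval between successive survey dates, in days (fortnightly sampling)
SAMPLING_INTERVAL_DAYS = 14


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic factorial survey response.

    Defaults mirror the emulated field design: 6 plates per treatment cell
    surveyed on 7 fortnightly dates.  ``dispersion`` is the negative-binomial
    dispersion phi (Var = mu + phi*mu^2) for counts, the Gaussian SD for
    continuous responses, and the Beta precision for proportions.
    ``plate_sd`` is the SD of plate-level random intercepts on the link
    scale; ``smooth_amplitude`` scales a shared half-period seasonal
    sinusoid on the link scale.
    """

    n_plates_per_cell: int = 6
    n_dates: int = 7
    response_family: str = "count_nb"
    link: str = "log"
    alpha: float = 2.0
    beta_w: float = 0.0
    beta_p: float = 0.0
    beta_int: float = 0.0
    plate_sd: float = 0.3
    dispersion: float = 0.5
    smooth_amplitude: float = 0.0
    seed: int = 0
    response_name: str = "response"

    def __post_init__(self) -> None:
        if self.n_plates_per_cell < 1:
            raise ConfigurationError("n_plates_per_cell must be >= 1")
        if self.n_dates < 1:
            raise ConfigurationError("n_dates must be >= 1")
        if self.response_family not in _FAMILY_LINKS:
            raise ConfigurationError(
                f"unknown response family {self.response_family!r}"
            )
        if self.link not in _FAMILY_LINKS[self.response_family]:
            raise ConfigurationError(
                f"link {self.link!r} incompatible with family "
                f"{self.response_family!r}; allowed: "
                f"{_FAMILY_LINKS[self.response_family]}"
            )
        if not self.dispersion > 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.plate_sd < 0:
            raise ConfigurationError("plate_sd must be >= 0")


def _draw_response(
    rng: np.random.Generator, eta: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    fam = cfg.response_family
    if fam == "count_nb":
        mu = np.exp(eta)
        # numpy parameterization: n successes, prob p; Var = mu + mu^2/n
        n = 1.0 / cfg.dispersion
        return rng.negative_binomial(n, n / (n + mu)).astype(float)
    if fam == "binary":
        return rng.binomial(1, expit(eta)).astype(float)
    if fam == "proportion":
        m = np.clip(expit(eta), 1e-9, 1.0 - 1e-9)
        nu = cfg.dispersion
        return rng.beta(m * nu, (1.0 - m) * nu)
    # continuous: Gaussian noise around the (possibly back-transformed) mean;
    # clipped at 0 so written tables satisfy the non-negative value schema -
    # defaults keep clipping probability negligible
    mean = eta if cfg.link == "identity" else np.exp(eta)
    return np.maximum(rng.normal(mean, cfg.dispersion), 0.0)


def simulate_survey(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one response across the full plate x date factorial design.

    Returns a long-format table with columns ``plate_id, site, warming, day,
    response, value``: ``n_plates_per_cell * 4`` plates, each observed on
    ``n_dates`` fortnightly days.  Each plate keeps its random intercept
    across dates (repeated measures).  Identical config (seed included)
    reproduces the table bit-for-bit.
    """
    cfg = config
    days = np.arange(cfg.n_dates) * SAMPLING_INTERVAL_DAYS
    day_max = days[-1] if cfg.n_dates > 1 else 1
    season = cfg.smooth_amplitude * np.sin(math.pi * days / day_max)

    root = np.random.SeedSequence(cfg.seed)
    n_plates = 4 * cfg.n_plates_per_cell
    streams = root.spawn(n_plates)

    rows = []
    idx = 0
    for site in SITES:
        for warming in WARMING:
            w = 1.0 if warming == "warmed" else 0.0
            p = 1.0 if site == "polluted" else 0.0
            fixed = cfg.alpha + cfg.beta_w * w + cfg.beta_p * p + cfg.beta_int * w * p
            for k in range(cfg.n_plates_per_cell):
                rng = np.random.Generator(np.random.PCG64(streams[idx]))
                plate_id = f"{'pol' if p else 'non'}_{'wrm' if w else 'amb'}_{k + 1:02d}"
                idx += 1
                plate_eff = rng.normal(0.0, cfg.plate_sd) if cfg.plate_sd > 0 else 0.0
                eta = fixed + plate_eff + season
                values = _draw_response(rng, eta, cfg)
                for d, v in zip(days, values):
                    rows.append((plate_id, site, warming, int(d), cfg.response_name, v))
    return pd.DataFrame(
        rows, columns=["plate_id", "site", "warming", "day", "response", "value"]
    )


# ---------------------------------------------------------------------------
# gene counts

_LN2 = math.log(2.0)

#: log2-coefficient templates (w, p, int) per interaction type, scaled by
#: effect_magnitude; chosen so the implied classification is the labelled
#: type for any independent per-coefficient jitter in [0.7, 1.3]
_TYPE_TEMPLATES: Dict[str, Tuple[float, float, float]] = {
    "null": (0.0, 0.0, 0.0),
    "S+": (1.0, 1.0, 1.0),
    "S-": (-1.0, -1.0, -1.0),
    "A+": (1.0, 1.0, -1.0),
    "A-": (-1.0, -1.0, 1.0),
    "R+/-": (1.0, 1.0, -4.0),
    "R-/+": (-1.0, -1.0, 4.0),
}


def _default_mixture() -> Dict[str, float]:
    # 80% null genes; non-null split mirrors a reversal-dominated community
    # response (~62% reversals, ~29% antagonisms, ~9% synergisms)
    return {
        "null": 0.80,
        "R+/-": 0.062, "R-/+": 0.062,
        "A+": 0.029, "A-": 0.029,
        "S+": 0.009, "S-": 0.009,
    }


@dataclass(frozen=True)
class GeneSimConfig:
    """Parameters of the synthetic factorial RNA-seq-like experiment.

    ``baseline_log_mean`` gives (mean, sd) of per-gene baseline log2
    expression; ``nb_dispersion`` the (asymptotic, scale) parameters of the
    dispersion trend phi(mu) = asymptotic + scale/mu; ``type_mixture`` the
    proportions of interaction types assigned to genes; ``effect_magnitude``
    the log2 fold-change scale of non-null effects.
    """

    n_genes: int = 2000
    n_per_cell: int = 8
    baseline_log_mean: Tuple[float, float] = (6.0, 2.0)
    nb_dispersion: Tuple[float, float] = (0.05, 5.0)
    type_mixture: Dict[str, float] = field(default_factory=_default_mixture)
    effect_magnitude: float = 2.0
    library_size_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_per_cell < 2:
            raise ConfigurationError(
                "n_per_cell must be >= 2 (model unidentifiable otherwise)"
            )
        unknown = set(self.type_mixture) - set(_TYPE_TEMPLATES)
        if unknown:
            raise ConfigurationError(f"unknown interaction types {sorted(unknown)}")
        total = sum(self.type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"type_mixture proportions must sum to 1, got {total}"
            )
        if any(v < 0 for v in self.type_mixture.values()):
            raise ConfigurationError("type_mixture proportions must be >= 0")


def simulate_gene_counts(
    config: GeneSimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples NB count matrix over the 2x2 design.

    Returns ``(counts, samples, truth)``: an integer count matrix indexed by
    gene_id with sample columns, a sample metadata table (sample_id, site,
    warming), and a truth table recording each gene's assigned interaction
    type and true log2 coefficients.  Sample-specific library-size factors
    (log-normal) are included so size-factor normalization is exercised.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_assign, ss_samples, ss_genes = root.spawn(3)

    # samples: 4 cells x n_per_cell
    sample_rows = []
    for site in SITES:
        for warming in WARMING:
            for k in range(cfg.n_per_cell):
                sid = f"{'pol' if site == 'polluted' else 'non'}_" \
                      f"{'wrm' if warming == 'warmed' else 'amb'}_{k + 1}"
                sample_rows.append((sid, site, warming))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "site", "warming"])
    W = (samples["warming"] == "warmed").to_numpy(float)
    P = (samples["site"] == "polluted").to_numpy(float)

    rng_a = np.random.Generator(np.random.PCG64(ss_assign))
    types = list(cfg.type_mixture)
    probs = np.array([cfg.type_mixture[t] for t in types])
    assigned = rng_a.choice(types, size=cfg.n_genes, p=probs / probs.sum())

    rng_s = np.random.Generator(np.random.PCG64(ss_samples))
    size_factors = np.exp(rng_s.normal(0.0, cfg.library_size_sd, len(samples)))

    gene_streams = ss_genes.spawn(cfg.n_genes)
    b_mean, b_sd = cfg.baseline_log_mean
    a0, a1 = cfg.nb_dispersion

    counts = np.empty((cfg.n_genes, len(samples)), dtype=np.int64)
    truth_rows = []
    for i, (gtype, stream) in enumerate(zip(assigned, gene_streams)):
        rng = np.random.Generator(np.random.PCG64(stream))
        baseline = rng.normal(b_mean, b_sd)
        tw, tp, ti = _TYPE_TEMPLATES[gtype]
        jit = rng.uniform(0.7, 1.3, 3)
        lfc_w = tw * cfg.effect_magnitude * jit[0]
        lfc_p = tp * cfg.effect_magnitude * jit[1]
        lfc_int = ti * cfg.effect_magnitude * jit[2]
        log2_mu = baseline + lfc_w * W + lfc_p * P + lfc_int * W * P
        mu = np.exp(_LN2 * log2_mu) * size_factors
        phi = a0 + a1 / max(np.exp(_LN2 * baseline), 1e-8)
        n = 1.0 / phi
        counts[i] = rng.negative_binomial(n, n / (n + mu))
        truth_rows.append((f"gene_{i + 1:05d}", gtype, lfc_w, lfc_p, lfc_int, baseline))

    gene_ids = [r[0] for r in truth_rows]
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples["sample_id"].tolist())
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "type", "lfc_w", "lfc_p", "lfc_int", "baseline_log2"],
    )
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# engine-level coefficient tables

@dataclass(frozen=True)
class CoefficientGenSpec:
    """Distributions for direct engine-level coefficient simulation.

    Each ``beta_*`` is (mean, sd) of a normal draw; each ``se_*`` is
    (mean, sd) of a normal draw resampled until strictly positive.
    """

    beta_w: Tuple[float, float] = (0.0, 1.0)
    beta_p: Tuple[float, float] = (0.0, 1.0)
    beta_int: Tuple[float, float] = (0.0, 1.0)
    se_w: Tuple[float, float] = (0.3, 0.1)
    se_p: Tuple[float, float] = (0.3, 0.1)
    se_int: Tuple[float, float] = (0.3, 0.1)
    link: str = "log"
    #: emulate a true-null interaction: draw beta_int as se_int * N(0, 1),
    #: so its Wald p-value is uniform (the sampling distribution under H0)
    null_sampling_int: bool = False


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise ConfigurationError("SE distribution produces non-positive draws")


def simulate_coefficients(
    n: int, spec: CoefficientGenSpec = CoefficientGenSpec(), seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` self-consistent coefficient records for engine-level tests.

    Wald p-values are computed from the drawn coefficients and SEs as
    ``p = 2 * (1 - Phi(|beta| / se))``, so every record satisfies the Wald
    self-consistency contract by construction.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    cols: Dict[str, np.ndarray] = {}
    for name in ("beta_w", "beta_p", "beta_int"):
        mean, sd = getattr(spec, name)
        cols[name] = rng.normal(mean, sd, n)
    for name in ("se_w", "se_p", "se_int"):
        mean, sd = getattr(spec, name)
        cols[name] = _positive_normal(rng, mean, sd, n)
    if spec.null_sampling_int:
        cols["beta_int"] = cols["se_int"] * rng.standard_normal(n)
    df = pd.DataFrame(cols)
    for b, s, p in (("beta_w", "se_w", "p_w"), ("beta_p", "se_p", "p_p"),
                    ("beta_int", "se_int", "p_int")):
        df[p] = 2.0 * norm.sf(np.abs(df[b]) / df[s])
    df.insert(0, "response", [f"sim_{i + 1:04d}" for i in range(n)])
    df.insert(1, "date_label", "sim")
    df.insert(2, "link", spec.link)
    df["alpha"] = 0.0
    df["n_obs"] = 0
    return df
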