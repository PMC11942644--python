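"""Observer-preference modelling and random-effects pooling.

Readers compare paired images on a five-point ordinal scale (1 = strongly
prefer the conventional image, 3 = no preference, 5 = strongly prefer the
dual-energy image) for a set of anatomic regions.  Per-reader mean scores
are pooled with a DerSimonian–Laird random-effects model, which weights
each reader inversely to their total (within + between) variance; a region
is called significant when the 95% confidence interval of the pooled mean
excludes the neutral score of 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NEUTRAL_SCORE = 3.0
VARIANCE_FLOOR = 1e-6  # constant raters keep a tiny variance instead of being dropped

SOFT_REGIONS = (
    "unobscured lung", "hilum", "minor fissure", "heart border",
    "retrocardiac lung", "subdiaphragmatic lung", "azygoesophageal recess",
    "proximal airway",
)
BONE_REGIONS = (
    "rib", "vertebral body and disc space", "first costochondral joint",
    "clavicle", "scapula",
)
EXTRA_ITEMS = (
    "noise reduction (soft-tissue)", "noise reduction (bone)",
    "overall appearance",
)
SESSION_REGIONS = {
    1: SOFT_REGIONS + BONE_REGIONS + EXTRA_ITEMS,
    2: SOFT_REGIONS + ("overall appearance",),
    3: BONE_REGIONS + ("overall appearance",),
}


@dataclass(frozen=True)
class PreferenceRecord:
    """One reader's score for one participant, region and session."""

    reader_id: str
    participant_id: str
    session: int
    region: str
    score: int

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError("score must be an integer in 1..5")
        if self.session not in SESSION_REGIONS:
            raise ValueError("session must be 1, 2 or 3")
        if self.region not in SESSION_REGIONS[self.session]:
            raise ValueError(
                f"region {self.region!r} is not rated in session {self.session}")


@dataclass(frozen=True)
class ReaderSummary:
    """Per-reader mean score and variance of that mean (s^2 / n)."""

    reader_id: str
    n: int
    y: float
    v: float

    def __post_init__(self) -> None:
        if self.n < 1 or self.v < 0:
            raise ValueError("need n >= 1 and v >= 0")


@dataclass(frozen=True)
class PooledEstimate:
    """DerSimonian–Laird pooled mean with 95% CI and heterogeneity."""

    region: str
    mean: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    k: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("pooled mean must lie inside its CI")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")

    @property
    def significant(self) -> bool:
        return significance_flag(self)[0]


@dataclass(frozen=True)
class ScoreHistogram:
    """Aggregate counts of scores 1..5 across readers and participants."""

    counts: tuple

    def __post_init__(self) -> None:
        if len(self.counts) != 5 or any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError("counts must be five non-negative integers")

    @classmethod
    def from_records(cls, records: Iterable[PreferenceRecord],
                     region: str) -> "ScoreHistogram":
        counts = [0] * 5
        for r in records:
            if r.region == region:
                counts[r.score - 1] += 1
        return cls(tuple(counts))


def summarize_by_reader(records: Iterable[PreferenceRecord],
                        region: str) -> list[ReaderSummary]:
    """Per-reader mean and variance-of-mean for one region.

    The variance of the mean is the sample variance (ddof=1) divided by the
    number of ratings, floored at ``VARIANCE_FLOOR`` so constant raters
    still contribute finite weight.  Order of records is irrelevant.
    """
    scores: dict[str, list[int]] = {}
    for r in records:
        if r.region == region:
            scores.setdefault(r.reader_id, []).append(r.score)
    if not scores:
        raise ValueError(f"no records for region {region!r}")
    out = []
    for reader_id in sorted(scores):
        s = np.asarray(scores[reader_id], float)
        v = float(s.var(ddof=1) / s.size) if s.size > 1 else VARIANCE_FLOOR
        out.append(ReaderSummary(reader_id, s.size, float(s.mean()),
                                 max(v, VARIANCE_FLOOR)))
    return out


def pool_random_effects(summaries: Sequence[ReaderSummary],
                        region: str = "") -> PooledEstimate:
    """DerSimonian–Laird pooling of per-reader summaries.

    Fixed-effect weights w_i = 1/v_i give the heterogeneity statistic
    Q = sum w_i (y_i - y_FE)^2; the between-reader variance is
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(v_i + tau^2) then yield the pooled mean and its normal-
    quantile 95% CI.  A single reader passes through with tau^2 = 0.
    """
    if len(summaries) < 1:
        raise ValueError("need at least one reader summary")
    y = np.array([s.y for s in summaries], float)
    v = np.array([s.v for s in summaries], float)
    if (v < 0).any():
        raise ValueError("variances must be non-negative")
    v = np.maximum(v, VARIANCE_FLOOR)
    k = len(y)
    if k == 1:
        mu, se, tau2, q = y[0], math.sqrt(v[0]), 0.0, 0.0
    else:
        w = 1.0 / v
        y_fe = float(np.sum(w * y) / np.sum(w))
        q = float(np.sum(w * (y - y_fe) ** 2))
        denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (v + tau2)
        mu = float(np.sum(w_star * y) / np.sum(w_star))
        se = float(np.sum(w_star)) ** -0.5
    return PooledEstimate(region, float(mu), float(mu - 1.96 * se),
                          float(mu + 1.96 * se), float(tau2), float(q), k)


def significance_flag(estimate: PooledEstimate,
                      neutral: float = NEUTRAL_SCORE) -> tuple[bool, str | None]:
    """Significance by CI exclusion of the neutral score.

    A CI endpoint exactly at the neutral value counts as not significant
    (closed-interval rule).  The direction states which image type the
    readers preferred.
    """
    if estimate.ci_low > neutral:
        return True, "dual-energy"
    if estimate.ci_high < neutral:
        return True, "conventional"
    return False, None


def count_significant(estimates: Iterable[PooledEstimate],
                      direction: str | None = None) -> int:
    """Number of estimates whose CI excludes neutral, optionally filtered
    by preferred image type ('dual-energy' or 'conventional')."""
    n = 0
    for e in estimates:
        sig, d = significance_flag(e)
        if sig and (direction is None or d == direction):
            n += 1
    return n


# ------------------------------------------------------------- simulation

DEFAULT_THRESHOLDS = (1.5, 2.5, 3.5, 4.5)


@dataclass(frozen=True)
class ReaderSimConfig:
    """Latent-variable score generator for one region.

    Each reader's latent rating is ``3 + delta + b_i + scale * noise``
    (standard normal noise), discretized through strictly increasing
    thresholds into scores 1..5.  ``delta`` is the true region-level
    preference shift; ``reader_biases`` are fixed per-reader calibration
    offsets; ``scale`` is the within-reader noise SD.
    """

    delta: float = 0.5
    reader_biases: tuple = (-0.05, -0.02, 0.02, 0.05)
    scale: float = 0.7
    thresholds: tuple = DEFAULT_THRESHOLDS
    n_participants: int = 52
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.reader_biases) < 1:
            raise ValueError("need at least one reader")
        if self.scale <= 0 or self.n_participants < 1:
            raise ValueError("scale and n_participants must be positive")

    @property
    def k_readers(self) -> int:
        return len(self.reader_biases)


def simulate_reader_scores(config: ReaderSimConfig, region: str = "rib",
                           session: int = 1) -> list[PreferenceRecord]:
    """Draw one replicate of reader scores; reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    records = []
    for i, b in enumerate(config.reader_biases):
        latent = (NEUTRAL_SCORE + config.delta + b
                  + config.scale * rng.standard_normal(config.n_participants))
        score = np.digitize(latent, config.thresholds) + 1
        for p, s in enumerate(score):
            records.append(PreferenceRecord(f"R{i + 1}", f"P{p + 1:03d}",
                                            session, region, int(s)))
    return records


def expected_discretized_mean(config: ReaderSimConfig) -> float:
    """Population mean score under the generator, by Gaussian integration.

    Averages, over the fixed reader biases, the expectation of the
    discretized latent score: E[score] = sum_j j * P(score = j) with
    normal cell probabilities between the thresholds.
    """
    from scipy.stats import norm
    t = np.concatenate([[-np.inf], config.thresholds, [np.inf]])
    total = 0.0
    for b in config.reader_biases:
        mu = NEUTRAL_SCORE + config.delta + b
        p = np.diff(norm.cdf(t, loc=mu, scale=config.scale))
        total += float(np.sum(np.arange(1, 6) * p))
    return total / len(config.reader_biases)


# -------------------------------------------------------------- reporting

def _round_half_away(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * math.copysign(1.0, x)


def table_report(estimates: Sequence[PooledEstimate],
                 histograms: "Sequence[ScoreHistogram] | None" = None) -> str:
    """Tab-separated report rows: region, score counts 1..5, mean to one
    decimal, CI to two decimals, and a star for significant rows.  Rounding
    is half away from zero, matching conventional table formatting."""
    lines = ["region\t1\t2\t3\t4\t5\tmean\t95% CI\tsig"]
    for i, e in enumerate(estimates):
        counts = (histograms[i].counts if histograms is not None
                  else ("", "", "", "", ""))
        mean = f"{_round_half_away(e.mean, 1):.1f}"
        ci = (f"[{_round_half_away(e.ci_low, 2):.2f}; "
              f"{_round_half_away(e.ci_high, 2):.2f}]")
        star = "*" if significance_flag(e)[0] else ""
        lines.append("\t".join([e.region, *map(str, counts), mean, ci, star]))
    return "\n".join(lines)


def forest_plot_data(estimates: Sequence[PooledEstimate]) -> pd.DataFrame:
    """Region, pooled mean and CI bounds as a tidy frame for forest plots."""
    return pd.DataFrame({
        "region": [e.region for e in estimates],
        "mean": [e.mean for e in estimates],
        "ci_low": [e.ci_low for e in estimates],
        "ci_high": [e.ci_high for e in estimates],
        "significant": [significance_flag(e)[0] for e in estimates],
    })


# ----------------------------------------------- published summary tables

TABLE_FILES = {
    "enhanced": "session1_enhanced.tsv",
    "soft": "session2_soft.tsv",
    "bone": "session3_bone.tsv",
}


def load_published_table(session: str) -> pd.DataFrame:
    """Packaged reader-study summary table for one comparison session.

    Columns: region, item kind (anatomic region vs noise/overall item),
    score counts 1..5, pooled mean, CI bounds — as reported in the volunteer
    reader study the pipeline was evaluated with.
    """
    fname = TABLE_FILES[session]
    path = resources.files("dexray").joinpath("data", "reader_tables", fname)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def published_estimates(session: str,
                        anatomic_only: bool = True) -> list[PooledEstimate]:
    """Published pooled means/CIs as PooledEstimate objects.

    Q, tau^2 and k are not derivable from the printed summaries and are
    reported as 0/0/4 placeholders; only mean, CI and significance are
    meaningful here.
    """
    df = load_published_table(session)
    if anatomic_only:
        df = df[df["kind"] == "region"]
    return [PooledEstimate(r.region, r.mean, r.ci_low, r.ci_high, 0.0, 0.0, 4)
            for r in df.itertuples()]
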