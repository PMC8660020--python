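"""Pooled-binary bootstrap inference and multiple-comparison control.

The co-labeling design treats every reporter-positive cell as one Bernoulli
trial: each animal contributes a binary vector (1 = co-labeled), vectors of
animals sharing both factor levels (birthdate x target region, or birthdate
x behavioral condition) are pooled into a group vector, and group pairs are
compared by bootstrap: both vectors are independently resampled with
replacement (10,000 iterations), the difference of the group statistics
(mean, or median for numeric measures) is accumulated, and the pair is
called significant when the percentile confidence interval of that
difference excludes zero (99.9% CI for tracing, 95% elsewhere).  A
two-sided bootstrap p-value (doubled tail proportion, floored at 2/n_iter)
is supplied for Holm-Bonferroni or Šidák family-wise control.

Determinism contract: results are bit-reproducible under a fixed seed, and
invariant to permutation of the entries within each group vector, because
each group's resampling stream is keyed by the group's sorted content.
Swapping the two groups therefore exactly negates the observed difference
and mirrors the confidence interval.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from natalmap.seeding import child_rng

__all__ = [
    "AnimalVector",
    "GroupVector",
    "BootstrapConfig",
    "BootstrapResult",
    "CorrelationResult",
    "build_group_vector",
    "bootstrap_diff_means",
    "count_pairwise_tests",
    "holm_bonferroni",
    "sidak_alpha",
    "bootstrap_correlation",
    "pairwise_bootstrap_suite",
    "animals_to_frame",
    "frame_to_animals",
]


@dataclass(frozen=True)
class AnimalVector:
    """Per-animal co-labeling counts: n_pos co-labeled out of n_total
    reporter-positive cells, with the animal's two design factors."""

    animal_id: str
    birthdate: str
    factor2: str
    n_total: int
    n_pos: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_pos <= self.n_total:
            raise ValueError("need 0 <= n_pos <= n_total")

    @property
    def fraction(self) -> float:
        return self.n_pos / self.n_total

    def binary(self) -> np.ndarray:
        return np.concatenate([np.ones(self.n_pos), np.zeros(self.n_total - self.n_pos)])


@dataclass(frozen=True)
class GroupVector:
    """Pooled values of one design cell plus the contributing animal ids."""

    values: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("empty group vector")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def is_binary(self) -> bool:
        return bool(np.all((self.values == 0) | (self.values == 1)))


@dataclass(frozen=True)
class BootstrapConfig:
    """n_iter resamples; ci_level (0.999 tracing / 0.95 cFos and numeric);
    statistic 'mean' or 'median'; method 'auto' uses the exact binomial
    shortcut for binary-mean bootstraps, 'resample' always draws indices."""

    n_iter: int = 10_000
    ci_level: float = 0.999
    statistic: str = "mean"
    seed: int = 0
    method: str = "auto"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.statistic not in ("mean", "median"):
            raise ValueError("statistic must be 'mean' or 'median'")
        if self.method not in ("auto", "resample"):
            raise ValueError("method must be 'auto' or 'resample'")


@dataclass(frozen=True)
class BootstrapResult:
    observed: float
    ci_lo: float
    ci_hi: float
    significant: bool
    p_boot: float
    n_iter: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_lo: float
    ci_hi: float
    p: float
    slope: float
    slope_ci_lo: float
    slope_ci_hi: float
    n: int


def build_group_vector(
    animals: list[AnimalVector], key: tuple[str, str]
) -> GroupVector:
    """Pool the binary vectors of all animals matching (birthdate, factor2)."""
    birthdate, factor2 = key
    sel = [a for a in animals if a.birthdate == birthdate and a.factor2 == factor2]
    if not sel:
        raise ValueError(f"no animals match key {key}")
    values = np.concatenate([a.binary() for a in sel])
    return GroupVector(values=values, provenance=tuple(a.animal_id for a in sel))


def _as_values(g) -> np.ndarray:
    if isinstance(g, GroupVector):
        return g.values
    v = np.asarray(g, dtype=float)
    if v.size == 0:
        raise ValueError("empty group vector")
    return v


def _content_key(v: np.ndarray) -> str:
    """Stable digest of the sorted content (permutation-invariant)."""
    return hashlib.blake2s(np.sort(v).tobytes()).hexdigest()[:16]


def _resampled_stats(v: np.ndarray, cfg: BootstrapConfig, salt: str) -> np.ndarray:
    """n_iter bootstrap statistics of one group, on its content-keyed stream."""
    rng = child_rng(cfg.seed, "bootstrap", salt, _content_key(v))
    n = v.size
    binary = bool(np.all((v == 0) | (v == 1)))
    if cfg.method == "auto" and cfg.statistic == "mean" and binary:
        # resampled mean of a 0/1 vector is Binomial(n, p_hat)/n exactly
        return rng.binomial(n, v.mean(), size=cfg.n_iter) / n
    v_sorted = np.sort(v)
    stat = np.mean if cfg.statistic == "mean" else np.median
    out = np.empty(cfg.n_iter)
    chunk = max(int(2_000_000 // max(n, 1)), 1)
    for start in range(0, cfg.n_iter, chunk):
        k = min(chunk, cfg.n_iter - start)
        idx = rng.integers(0, n, size=(k, n))
        out[start:start + k] = stat(v_sorted[idx], axis=1)
    return out


def _percentile_ci(draws: np.ndarray, ci_level: float) -> tuple[float, float]:
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _two_sided_p(draws: np.ndarray, n_iter: int) -> float:
    p = 2.0 * min(float(np.mean(draws <= 0)), float(np.mean(draws >= 0)))
    return float(np.clip(p, 2.0 / n_iter, 1.0))


def bootstrap_diff_means(
    a, b, cfg: BootstrapConfig | None = None, salt: str = ""
) -> BootstrapResult:
    """Bootstrap difference of group statistics (A minus B).

    At each iteration both groups are independently resampled with
    replacement at their own sizes and the difference of the configured
    statistic is stored; the percentile interval at ``cfg.ci_level`` gives
    the CI, significance is 0 outside the CI, and ``p_boot`` is the doubled
    smaller tail proportion (floored at 2/n_iter).
    """
    cfg = cfg or BootstrapConfig()
    va, vb = _as_values(a), _as_values(b)
    stat = np.mean if cfg.statistic == "mean" else np.median
    observed = float(stat(va) - stat(vb))
    deltas = _resampled_stats(va, cfg, salt) - _resampled_stats(vb, cfg, salt)
    ci_lo, ci_hi = _percentile_ci(deltas, cfg.ci_level)
    return BootstrapResult(
        observed=observed, ci_lo=ci_lo, ci_hi=ci_hi,
        significant=not (ci_lo <= 0.0 <= ci_hi),
        p_boot=_two_sided_p(deltas, cfg.n_iter), n_iter=cfg.n_iter,
    )


def count_pairwise_tests(levels1: int, levels2: int) -> int:
    """Number of shared-factor pairwise comparisons in a two-factor design.

    Pairs share one factor level and differ in the other:
    levels2 * C(levels1, 2) + levels1 * C(levels2, 2).
    """
    if levels1 < 1 or levels2 < 1:
        raise ValueError("factor levels must be >= 1")
    return levels2 * comb(levels1, 2) + levels1 * comb(levels2, 2)


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Sorted ascending, p_(i) is multiplied by (m - i), running maxima enforce
    monotonicity, values are capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def sidak_alpha(family_alpha: float, m: int) -> float:
    """Šidák per-comparison alpha: 1 - (1 - alpha)^(1/m)."""
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - family_alpha) ** (1.0 / m)


def bootstrap_correlation(x, y, cfg: BootstrapConfig | None = None) -> CorrelationResult:
    """Bootstrap test of the Pearson correlation (paired resampling).

    Reports the observed r with its percentile CI and two-sided bootstrap p,
    plus the least-squares slope and its CI (figure legends report either
    scale).
    """
    cfg = cfg or BootstrapConfig(ci_level=0.95)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal length, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")

    def _r_slope(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xc = xs - xs.mean(axis=-1, keepdims=True)
        yc = ys - ys.mean(axis=-1, keepdims=True)
        cov = (xc * yc).mean(axis=-1)
        vx = (xc ** 2).mean(axis=-1)
        vy = (yc ** 2).mean(axis=-1)
        denom = np.sqrt(vx * vy)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, cov / denom, np.nan), np.where(vx > 0, cov / vx, np.nan)

    r_obs, slope_obs = _r_slope(x, y)
    rng = child_rng(cfg.seed, "correlation")
    n = x.size
    rs = np.empty(cfg.n_iter)
    slopes = np.empty(cfg.n_iter)
    chunk = max(int(2_000_000 // n), 1)
    for start in range(0, cfg.n_iter, chunk):
        k = min(chunk, cfg.n_iter - start)
        idx = rng.integers(0, n, size=(k, n))
        rs[start:start + k], slopes[start:start + k] = _r_slope(x[idx], y[idx])
    ok = np.isfinite(rs)
    rs, slopes = rs[ok], slopes[ok]
    ci_lo, ci_hi = _percentile_ci(rs, cfg.ci_level)
    s_lo, s_hi = _percentile_ci(slopes, cfg.ci_level)
    return CorrelationResult(
        r=float(r_obs), ci_lo=max(ci_lo, -1.0), ci_hi=min(ci_hi, 1.0),
        p=_two_sided_p(rs, cfg.n_iter),
        slope=float(slope_obs), slope_ci_lo=s_lo, slope_ci_hi=s_hi, n=n,
    )


def _admissible_pairs(keys: list) -> list[tuple]:
    """Shared-factor pairs for 2-factor tuple keys; all pairs otherwise."""
    two_factor = all(isinstance(k, tuple) and len(k) == 2 for k in keys)
    pairs = []
    for ka, kb in combinations(keys, 2):
        if two_factor and ka[0] != kb[0] and ka[1] != kb[1]:
            continue
        pairs.append((ka, kb))
    return pairs


def pairwise_bootstrap_suite(
    groups: dict, cfg: BootstrapConfig | None = None, correction: str = "holm",
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """All admissible pairwise bootstrap comparisons with family-wise control.

    ``groups`` maps a key (a (factor1, factor2) tuple for two-factor designs,
    anything hashable otherwise) to a GroupVector or numeric sample.  For
    two-factor designs only pairs sharing a factor level are compared.
    ``correction`` is 'holm' (adjusted p), 'sidak' (per-comparison alpha), or
    'none'.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if correction not in ("holm", "sidak", "none"):
        raise ValueError("correction must be 'holm', 'sidak' or 'none'")
    cfg = cfg or BootstrapConfig()
    keys = list(groups.keys())
    pairs = _admissible_pairs(keys)
    rows = []
    for ka, kb in pairs:
        salt = repr(tuple(sorted((repr(ka), repr(kb)))))
        res = bootstrap_diff_means(groups[ka], groups[kb], cfg, salt=salt)
        rows.append({
            "group_a": ka, "group_b": kb, "observed": res.observed,
            "ci_lo": res.ci_lo, "ci_hi": res.ci_hi,
            "significant": res.significant, "p_boot": res.p_boot,
        })
    table = pd.DataFrame(rows)
    m = len(table)
    if correction == "holm" and m:
        table["p_adj"] = holm_bonferroni(table["p_boot"].to_numpy())
        table["significant_adj"] = table["p_adj"] < family_alpha
    elif correction == "sidak" and m:
        alpha = sidak_alpha(family_alpha, m)
        table["sidak_alpha"] = alpha
        table["significant_adj"] = table["p_boot"] < alpha
    return table


def animals_to_frame(animals: list[AnimalVector]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"animal_id": a.animal_id, "birthdate": a.birthdate, "factor2": a.factor2,
          "n_total": a.n_total, "n_pos": a.n_pos} for a in animals]
    )


def frame_to_animals(df: pd.DataFrame) -> list[AnimalVector]:
    return [AnimalVector(str(r.animal_id), str(r.birthdate), str(r.factor2),
                         int(r.n_total), int(r.n_pos)) for r in df.itertuples()]
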