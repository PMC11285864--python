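"""Migratory-trait derivation and the five-trait statistical battery.

Free-flight pulse experiments compare a sham and a treatment group on five
behavioural traits per bird:

I.   departure probability on the first night after release,
II.  stopover duration (nights until departure),
III. departure timing within the night (fraction of night length elapsed),
IV.  departure direction (degrees clockwise from geographic north),
V.   consistency of the flight direction (signed wrapped difference between
     the bearing at coastline passage and the departure bearing; negative =
     anticlockwise).

Trait I is tested with Pearson's chi-squared with continuity correction,
traits II-III with the Wilcoxon rank-sum test (exact when the sample is
small or tied), and the circular traits IV-V with the Mardia-Watson-Wheeler
uniform-scores test.  Ranks of tied circular data are broken at random;
following the field practice, the tied test is repeated many times and the
median statistic/p-value is reported.  Tests are run for each year x age
subset and for the pooled margins, giving a 5-trait x 9-subset p-value grid;
no multiple-testing correction is applied (raw p-values are reported, and
the grid annotates this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateInputError,
    DegenerateTableError,
    InvalidParameterError,
    SampleSizeError,
    SchemaError,
)

YEARS = (2020, 2021)
AGES = ("juvenile", "adult")
GROUPS = ("sham", "treatment")

TRAIT_NAMES = (
    "departure_probability",
    "stopover_duration",
    "departure_timing",
    "departure_direction",
    "consistency",
)

#: Default number of tie-breaking repetitions for the circular two-sample test.
MWW_DEFAULT_REPS = 10_000

#: Below this total sample size the rank-sum test is always exact.
WILCOXON_EXACT_N = 30

#: Minimum admissible group size for the uniform-scores chi-squared
#: approximation; a warning is emitted below this comfortable size.
MWW_MIN_N = 5
MWW_WARN_N = 10


# ---------------------------------------------------------------------------
# Records and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BirdRecord:
    """One bird's grouping factors and trait observations.

    ``None`` marks a missing observation; ``stopover_nights=None`` with
    ``departed_first_night=False`` represents a bird never seen departing
    (right-censored stopover).
    """

    bird_id: str
    year: int
    age: str
    group: str
    departed_first_night: bool | None = None
    stopover_nights: int | None = None
    night_fraction: float | None = None
    departure_bearing: float | None = None
    coast_bearing: float | None = None
    fuel_load: float | None = None

    def __post_init__(self) -> None:
        if self.year not in YEARS:
            raise SchemaError(f"year must be one of {YEARS}, got {self.year}")
        if self.age not in AGES:
            raise SchemaError(f"age must be one of {AGES}, got {self.age!r}")
        if self.group not in GROUPS:
            raise SchemaError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.stopover_nights is not None and self.stopover_nights < 0:
            raise SchemaError("stopover_nights must be >= 0")
        if self.night_fraction is not None and not 0 <= self.night_fraction <= 1:
            raise SchemaError("night_fraction must be in [0, 1]")
        for name in ("departure_bearing", "coast_bearing"):
            v = getattr(self, name)
            if v is not None and not 0 <= v < 360:
                raise SchemaError(f"{name} must be in [0, 360), got {v}")
        if (self.departed_first_night is not None
                and self.stopover_nights is not None
                and self.departed_first_night != (self.stopover_nights == 0)):
            raise SchemaError(
                "departed_first_night inconsistent with stopover_nights "
                f"for bird {self.bird_id!r}")


@dataclass
class TestResult:
    """Outcome of one two-group trait comparison."""

    method: str
    statistic: float
    p: float
    df: int | None = None
    n: tuple = ()
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Trait derivation
# ---------------------------------------------------------------------------

def wrap_signed_deg(angle: float) -> float:
    """Wrap an angle difference into (-180, 180]; negative = anticlockwise."""
    wrapped = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def derive_traits(records: Iterable[BirdRecord],
                  departure_window_nights: int = 10) -> pd.DataFrame:
    """Build the per-bird trait table from validated records.

    Trait I (first-night departure) uses every bird with known status.
    Traits III-V are restricted to birds that departed within
    ``departure_window_nights`` nights; later departures keep their stopover
    duration (trait II) but are excluded from timing and direction traits.
    Trait V is the signed wrapped difference coast - departure in
    (-180, 180].
    """
    rows = []
    for rec in records:
        if not isinstance(rec, BirdRecord):
            raise SchemaError(f"expected BirdRecord, got {type(rec).__name__}")
        in_window = (rec.stopover_nights is not None
                     and rec.stopover_nights <= departure_window_nights)
        consistency = None
        if (in_window and rec.coast_bearing is not None
                and rec.departure_bearing is not None):
            consistency = wrap_signed_deg(
                rec.coast_bearing - rec.departure_bearing)
        rows.append({
            "bird_id": rec.bird_id,
            "year": rec.year,
            "age": rec.age,
            "group": rec.group,
            "departure_probability": rec.departed_first_night,
            "stopover_duration": rec.stopover_nights,
            "departure_timing": rec.night_fraction if in_window else None,
            "departure_direction": rec.departure_bearing if in_window else None,
            "consistency": consistency,
            "fuel_load": rec.fuel_load,
        })
    df = pd.DataFrame(rows, columns=[
        "bird_id", "year", "age", "group", *TRAIT_NAMES, "fuel_load"])
    return df


# ---------------------------------------------------------------------------
# Trait I: 2x2 chi-squared with continuity correction
# ---------------------------------------------------------------------------

def chi2_yates_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-squared on a 2x2 table with Yates continuity correction.

    The correction is truncated at zero (``max(|O-E| - 0.5, 0)``), so a
    perfectly balanced table yields a statistic of exactly 0 and p = 1.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if np.any(obs < 0):
        raise InvalidParameterError("counts must be >= 0")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateTableError("contingency table has a zero margin")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(np.sum(
        np.maximum(np.abs(obs - expected) - 0.5, 0.0) ** 2 / expected))
    return TestResult(
        method="chi2_yates", statistic=chi2, df=1,
        p=float(sps.chi2.sf(chi2, 1)),
        n=(int(rows[0]), int(rows[1])),
    )


# ---------------------------------------------------------------------------
# Traits II-III: Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _ranksum_null_counts(doubled_scores: np.ndarray, n1: int
                         ) -> tuple[np.ndarray, int]:
    """Permutation distribution of the group-1 doubled-rank sum.

    Dynamic programme over (number of items chosen, shifted score sum);
    ``counts[s]`` is the number of n1-subsets of the pooled sample whose
    doubled midrank sum equals ``s + n1 * min_score``.  Works directly on
    the observed (possibly tied) pooled values, which is what makes the
    exact p-value valid under ties.
    """
    smin = int(doubled_scores.min())
    shifted = doubled_scores - smin
    s_cap = int(np.sort(shifted)[::-1][:n1].sum())
    table = np.zeros((n1 + 1, s_cap + 1))
    table[0, 0] = 1.0
    for s in shifted:
        s = int(s)
        if s == 0:
            for k in range(n1 - 1, -1, -1):
                table[k + 1, :] += table[k, :]
        else:
            for k in range(n1 - 1, -1, -1):
                table[k + 1, s:] += table[k, : s_cap + 1 - s]
    return table[n1], smin


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float],
                     policy: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic is W = (rank sum of x) - n_x(n_x+1)/2, i.e. the
    Mann-Whitney U of the first sample, computed with midranks under ties.

    ``policy`` selects the p-value route:

    - ``exact``: enumerate the permutation distribution of the rank sum on
      the observed pooled values (valid with ties); two-sided p is twice the
      smaller tail, capped at 1.
    - ``normal``: normal approximation with tie-corrected variance and a
      0.5 continuity correction.
    - ``auto``: exact when n_x + n_y <= 30 or ties are present, else normal.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    if policy not in ("auto", "exact", "normal"):
        raise InvalidParameterError(f"unknown policy {policy!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    has_ties = np.unique(pooled).size < pooled.size
    ranksum_x = float(ranks[:n1].sum())
    u_stat = ranksum_x - n1 * (n1 + 1) / 2.0

    use_exact = policy == "exact" or (
        policy == "auto" and (n1 + n2 <= WILCOXON_EXACT_N or has_ties))

    if use_exact:
        doubled = np.rint(2 * ranks).astype(np.int64)
        counts, smin = _ranksum_null_counts(doubled, n1)
        total = counts.sum()
        w_obs = int(np.rint(doubled[:n1].sum())) - smin * n1
        sums = np.arange(counts.size)
        p_lo = counts[sums <= w_obs].sum() / total
        p_hi = counts[sums >= w_obs].sum() / total
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        method = "wilcoxon_exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (u_stat - mu - 0.5 * np.sign(u_stat - mu)) / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
        method = "wilcoxon_normal"

    return TestResult(method=method, statistic=float(u_stat), p=float(p),
                      n=(n1, n2), extras={"ties": bool(has_ties)})


# ---------------------------------------------------------------------------
# Circular tests
# ---------------------------------------------------------------------------

def rayleigh_test(angles_deg: Sequence[float]) -> TestResult:
    """Rayleigh test of circular uniformity.

    r is the mean resultant length; the p-value uses the standard series
    approximation p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with
    R = n r.
    """
    a = np.radians(np.asarray(list(angles_deg), dtype=float))
    n = a.size
    if n < 2:
        raise InvalidParameterError("need at least 2 angles")
    c, s = np.cos(a).sum(), np.sin(a).sum()
    r = float(np.hypot(c, s) / n)
    big_r = n * r
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n * n - big_r * big_r))
                     - (1 + 2 * n)))
    mean_dir = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return TestResult(
        method="rayleigh", statistic=float(n * r * r), p=min(1.0, p),
        n=(n,), extras={"r": r, "mean_direction_deg": mean_dir})


def _mww_w_from_ranks(ranks: np.ndarray, n1: int) -> np.ndarray:
    """Uniform-scores statistic for rank matrices of shape (reps, N)."""
    n = ranks.shape[-1]
    beta = 2.0 * np.pi * ranks / n
    c1 = np.cos(beta[..., :n1]).sum(axis=-1)
    s1 = np.sin(beta[..., :n1]).sum(axis=-1)
    c2 = np.cos(beta[..., n1:]).sum(axis=-1)
    s2 = np.sin(beta[..., n1:]).sum(axis=-1)
    return 2.0 * ((c1**2 + s1**2) / n1 + (c2**2 + s2**2) / (n - n1))


def mww_test(angles1_deg: Sequence[float], angles2_deg: Sequence[float],
             seed: int | None = None, reps: int = MWW_DEFAULT_REPS,
             ) -> TestResult:
    """Mardia-Watson-Wheeler (uniform-scores) two-sample circular test.

    Pooled circular ranks are mapped to uniform scores beta_j = 2 pi j / N;
    the statistic W = 2[(C1^2+S1^2)/n1 + (C2^2+S2^2)/n2] is referred to a
    chi-squared distribution with 2 df.  Tied angles have no unique ranks, so
    ties are broken at random; the test is repeated ``reps`` times with
    independent tie orderings and the median W (and its p) is reported.
    Tie-free data is evaluated once.
    """
    a1 = np.asarray(list(angles1_deg), dtype=float)
    a2 = np.asarray(list(angles2_deg), dtype=float)
    n1, n2 = a1.size, a2.size
    if min(n1, n2) < MWW_MIN_N:
        raise SampleSizeError(
            f"need at least {MWW_MIN_N} angles per group, got {n1}/{n2}")
    if min(n1, n2) < MWW_WARN_N:
        warnings.warn(
            "uniform-scores chi-squared approximation is rough below "
            f"{MWW_WARN_N} per group", stacklevel=2)
    if reps < 1:
        raise InvalidParameterError("reps must be >= 1")

    pooled = np.concatenate([a1, a2]) % 360.0
    n = pooled.size
    uniq = np.unique(pooled)
    has_ties = uniq.size < n

    if not has_ties:
        ranks = sps.rankdata(pooled)[None, :]
        w = float(_mww_w_from_ranks(ranks, n1)[0])
        reps_used = 1
        w_all = np.array([w])
    else:
        rng = np.random.default_rng(seed)
        # jitter below half the smallest gap between distinct values breaks
        # ties uniformly at random without reordering distinct values
        gap = float(np.min(np.diff(uniq))) if uniq.size > 1 else 1.0
        jitter = rng.random((reps, n)) * (0.5 * gap)
        order = np.argsort(pooled[None, :] + jitter, axis=1, kind="stable")
        ranks = np.empty_like(order)
        rows = np.arange(reps)[:, None]
        ranks[rows, order] = np.arange(1, n + 1)[None, :]
        w_all = _mww_w_from_ranks(ranks.astype(float), n1)
        w = float(np.median(w_all))
        reps_used = reps

    p = float(sps.chi2.sf(w, 2))
    return TestResult(
        method="mww_uniform_scores", statistic=w, df=2, p=p, n=(n1, n2),
        extras={"ties": bool(has_ties), "reps": reps_used,
                "median_p": p, "w_iqr": (
                    float(np.percentile(w_all, 25)),
                    float(np.percentile(w_all, 75)))})


def mww_permutation_p(angles1_deg: Sequence[float],
                      angles2_deg: Sequence[float]) -> float:
    """Exhaustive permutation p-value for the uniform-scores statistic.

    Enumerates every assignment of the pooled sample into groups of the
    observed sizes (tie-free data only); feasible for small samples and used
    as an independent reference for the chi-squared approximation.
    """
    from itertools import combinations

    a1 = np.asarray(list(angles1_deg), dtype=float)
    a2 = np.asarray(list(angles2_deg), dtype=float)
    pooled = np.concatenate([a1, a2])
    n, n1 = pooled.size, a1.size
    ranks = sps.rankdata(pooled)
    if np.unique(pooled).size < n:
        raise InvalidParameterError("permutation reference requires tie-free data")
    w_obs = float(_mww_w_from_ranks(ranks[None, :], n1)[0])
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        perm_ranks = np.concatenate([ranks[mask], ranks[~mask]])[None, :]
        if float(_mww_w_from_ranks(perm_ranks, n1)[0]) >= w_obs - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Fuel-load comparison
# ---------------------------------------------------------------------------

def two_sample_t(x: Sequence[float], y: Sequence[float],
                 equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t test (pooled variance by default, Welch
    switchable)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("need at least 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(method="t_test", statistic=0.0, p=1.0,
                              df=x.size + y.size - 2, n=(x.size, y.size))
        raise DegenerateInputError(
            "zero variance in both groups with unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = int(x.size + y.size - 2) if equal_var else int(np.floor(res.df))
    return TestResult(method="t_test" if equal_var else "welch_t",
                      statistic=float(res.statistic), p=float(res.pvalue),
                      df=df, n=(x.size, y.size))


# ---------------------------------------------------------------------------
# The battery
# ---------------------------------------------------------------------------

@dataclass
class BatteryTable:
    """5-trait x 9-subset grid of p-values with backing test results.

    ``pvalues`` has trait rows and (year, age) subset columns; NaN marks a
    cell that was not estimable (empty or too-small group).  ``results``
    maps (trait, subset) to the full :class:`TestResult`.  Raw p-values:
    no multiple-testing correction is applied.
    """

    pvalues: pd.DataFrame
    results: dict
    alpha: float = 0.05

    @property
    def stars(self) -> pd.DataFrame:
        return self.pvalues < self.alpha

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        """Human-readable grid: rounded p-values, ``*`` marking p < alpha."""
        def fmt(p):
            if pd.isna(p):
                return "n.e."
            return f"{p:.{decimals}f}" + ("*" if p < self.alpha else "")
        return self.pvalues.map(fmt)


def _subset_columns():
    for year in (2020, 2021, "pooled"):
        for age in ("juvenile", "adult", "both"):
            yield year, age


def _battery_cell(trait: str, sub: pd.DataFrame, seed: int,
                  reps: int) -> TestResult | None:
    values = {
        g: sub.loc[sub["group"] == g, trait].dropna() for g in GROUPS}
    try:
        if trait == "departure_probability":
            dep = {g: int((values[g] == True).sum()) for g in GROUPS}  # noqa: E712
            stay = {g: int((values[g] == False).sum()) for g in GROUPS}  # noqa: E712
            return chi2_yates_2x2(dep["sham"], stay["sham"],
                                  dep["treatment"], stay["treatment"])
        x = values["sham"].astype(float).to_numpy()
        y = values["treatment"].astype(float).to_numpy()
        if x.size == 0 or y.size == 0:
            return None
        if trait in ("stopover_duration", "departure_timing"):
            return wilcoxon_ranksum(x, y, policy="auto")
        return mww_test(x, y, seed=seed, reps=reps)
    except (DegenerateTableError, SampleSizeError, InvalidParameterError):
        return None


def run_battery(trait_table: pd.DataFrame, seed: int | None = None,
                reps: int = MWW_DEFAULT_REPS, alpha: float = 0.05,
                ) -> BatteryTable:
    """Run the five-trait battery over every year x age subset.

    Subsets are the two years, the two age classes, their four combinations
    and the fully pooled sample (9 columns).  Cells whose subset has an
    empty or too-small group are marked not-estimable (NaN) rather than
    raising.  All randomness (random tie-breaking in the circular tests)
    derives from ``seed`` via a per-cell spawned stream, so a fixed seed
    reproduces the grid exactly.
    """
    ss = np.random.SeedSequence(seed)
    cols = list(_subset_columns())
    child_seeds = ss.generate_state(len(cols) * len(TRAIT_NAMES))
    grid = pd.DataFrame(
        index=list(TRAIT_NAMES),
        columns=pd.MultiIndex.from_tuples(cols, names=["year", "age"]),
        dtype=float)
    results: dict = {}
    k = 0
    for col in cols:
        year, age = col
        sub = trait_table
        if year != "pooled":
            sub = sub[sub["year"] == year]
        if age != "both":
            sub = sub[sub["age"] == age]
        for trait in TRAIT_NAMES:
            res = _battery_cell(trait, sub, int(child_seeds[k]), reps)
            k += 1
            if res is not None:
                grid.loc[trait, col] = res.p
                results[(trait, col)] = res
    return BatteryTable(pvalues=grid, results=results, alpha=alpha)
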