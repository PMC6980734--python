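"""Phenodeviance screening statistics.

A mutant line's phase estimate (activity/food-intake onset or peak, from
the line's mean curve) is compared against the wild-type baseline of the
same centre.  The screen runs in two stages:

* primary: the line's deviation from the wild-type mean is an outlier when
  it falls beyond k = 2 sample standard deviations from the mean of the
  deviation distribution across all lines in the centre (two-sided tails,
  roughly the 5% most extreme lines under a normal null);
* secondary: an outlier is confirmed as a hit when at least 50% of its
  individual mice deviate in the same direction by at least one baseline
  s.d., Cohen's d (pooled s.d.) exceeds 1.2, and the pooled two-sample
  t-test gives p < 0.001.

Bland-Altman limits of agreement quantify whether automated phase calls
can replace a second labelling method (e.g. visual assessment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientLinesError

PARAMETERS = ("onset", "peak")


@dataclass
class GenotypeGroup:
    """Per-line phase estimates for one centre x modality.

    `mouse_onsets`/`mouse_peaks` are the per-animal estimates (typically
    7-8 mice); `mean_onset`/`mean_peak` come from the line's averaged
    curve, which is what the primary screen compares against baseline.
    """

    line_id: str
    centre: str
    modality: str
    mouse_onsets: np.ndarray
    mouse_peaks: np.ndarray
    mean_onset: float
    mean_peak: float
    zygosity: str = ""

    def __post_init__(self):
        self.mouse_onsets = np.asarray(self.mouse_onsets, dtype=float)
        self.mouse_peaks = np.asarray(self.mouse_peaks, dtype=float)
        if self.mouse_onsets.size < 1 or self.mouse_peaks.size < 1:
            raise ValueError("a genotype group needs at least one mouse")

    def mouse_values(self, parameter: str) -> np.ndarray:
        return self.mouse_onsets if parameter == "onset" else self.mouse_peaks

    def mean_value(self, parameter: str) -> float:
        return self.mean_onset if parameter == "onset" else self.mean_peak


@dataclass
class BaselineStats:
    """Wild-type phase distribution of one centre x modality x parameter."""

    centre: str
    modality: str
    parameter: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("baseline needs at least two wild-type mice")
        if self.sd < 0:
            raise ValueError("baseline s.d. cannot be negative")


@dataclass
class ScreenResult:
    """One line x parameter row of the screen report."""

    line_id: str
    centre: str
    modality: str
    parameter: str
    deviation: float       # line mean-curve estimate - wild-type mean, hours
    z: float               # deviation in units of the centre deviation s.d.
    d: float               # Cohen's d (pooled s.d.)
    p: float               # pooled two-sample t-test, two-sided
    concordance: float     # fraction of mice sharing the line's phenotype
    primary_outlier: bool
    secondary_hit: bool = False


@dataclass
class AgreementStats:
    """Bland-Altman agreement between two paired phase-labelling methods."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    coverage: float
    n: int


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled standard deviation with n1 + n2 - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    return float(np.sqrt(s2))


def effect_size_d(group: np.ndarray, baseline: np.ndarray) -> float:
    """Cohen's d: |mean(group) - mean(baseline)| / pooled s.d. (>= 0).

    Zero pooled s.d. with equal means gives d = 0; with unequal means the
    effect is unbounded and the infinite sentinel is returned.
    """
    group = np.asarray(group, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    s = pooled_sd(group, baseline)
    num = abs(float(group.mean() - baseline.mean()))
    if s == 0.0:
        return 0.0 if num == 0.0 else math.inf
    return num / s


def two_tailed_t(group: np.ndarray, baseline: np.ndarray) -> float:
    """Two-sided p of the pooled-variance (Student) two-sample t-test."""
    group = np.asarray(group, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    n1, n2 = group.size, baseline.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    s = pooled_sd(group, baseline)
    num = float(group.mean() - baseline.mean())
    if s == 0.0:
        return 1.0 if num == 0.0 else 0.0
    t = num / (s * math.sqrt(1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    return float(2.0 * stats.t.sf(abs(t), df))


def deviation_outliers(deviations: np.ndarray, k: float = 2.0):
    """Two-sided tail rule of the primary screen.

    A deviation is flagged when it lies more than k sample standard
    deviations from the mean of the deviation distribution.  Returns
    (flags, z-scores); a zero-spread distribution flags nothing.
    """
    dev = np.asarray(deviations, dtype=float)
    if dev.size < 2:
        raise InsufficientLinesError("need at least two lines per centre")
    sd = float(np.std(dev, ddof=1))
    # an (effectively) constant deviation set has no tails
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(dev)))):
        z = np.zeros_like(dev)
    else:
        z = (dev - dev.mean()) / sd
    return np.abs(z) > k, z


def concordance_fraction(
    mouse_values: np.ndarray,
    line_mean: float,
    baseline_mean: float,
    baseline_sd: float,
) -> float:
    """Fraction of mice sharing the line's phenotype direction.

    A mouse counts when its deviation from the baseline mean has the same
    sign as the line's mean-curve deviation and magnitude of at least one
    baseline s.d.  A line sitting exactly on the baseline has no phenotype
    direction and scores 0.
    """
    mouse_values = np.asarray(mouse_values, dtype=float)
    direction = np.sign(line_mean - baseline_mean)
    if direction == 0:
        return 0.0
    margin = (mouse_values - baseline_mean) * direction
    return float(np.mean(margin >= baseline_sd))


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def baseline_from_values(values: np.ndarray, centre: str, modality: str,
                         parameter: str) -> BaselineStats:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("baseline needs at least two wild-type mice")
    return BaselineStats(
        centre=centre, modality=modality, parameter=parameter,
        mean=float(values.mean()),
        sd=float(np.std(values, ddof=1)),
        n=int(values.size),
    )


def primary_screen(
    groups: list[GenotypeGroup],
    wt_values: dict[str, np.ndarray],
    k: float = 2.0,
) -> list[ScreenResult]:
    """Flag outlier lines for each parameter within one centre x modality.

    `wt_values` maps parameter ("onset"/"peak") to the per-mouse wild-type
    estimates of the same centre and modality.  For each parameter the
    line deviations (mean-curve estimate minus wild-type mean) form the
    centre's deviation distribution; lines beyond k sample s.d. from its
    mean are primary outliers.  Effect size, p value and concordance are
    filled in for the secondary stage.
    """
    if len(groups) < 2:
        raise InsufficientLinesError(
            f"{len(groups)} line(s) supplied; need >= 2 for a deviation spread"
        )
    results: list[ScreenResult] = []
    for parameter in PARAMETERS:
        wt = np.asarray(wt_values[parameter], dtype=float)
        base = baseline_from_values(
            wt, groups[0].centre, groups[0].modality, parameter
        )
        deviations = np.array(
            [g.mean_value(parameter) - base.mean for g in groups]
        )
        flags, z = deviation_outliers(deviations, k=k)
        for g, devi, fl, zi in zip(groups, deviations, flags, z):
            mice = g.mouse_values(parameter)
            if mice.size >= 2:
                d = effect_size_d(mice, wt)
                p = two_tailed_t(mice, wt)
            else:
                d, p = 0.0, 1.0
            conc = concordance_fraction(
                mice, g.mean_value(parameter), base.mean, base.sd
            )
            results.append(
                ScreenResult(
                    line_id=g.line_id, centre=g.centre, modality=g.modality,
                    parameter=parameter, deviation=float(devi), z=float(zi),
                    d=d, p=p, concordance=conc, primary_outlier=bool(fl),
                )
            )
    return results


@dataclass(frozen=True)
class SecondaryThresholds:
    d_min: float = 1.2
    p_max: float = 0.001
    concordance_min: float = 0.5


def secondary_screen(
    results: list[ScreenResult],
    thresholds: SecondaryThresholds = SecondaryThresholds(),
) -> list[ScreenResult]:
    """Confirm primary outliers; sets `secondary_hit` in place, returns hits.

    A hit must already be a primary outlier and satisfy all three
    confirmation criteria: concordance >= 50%, d > 1.2 and p < 0.001
    (defaults; configurable via `thresholds`).
    """
    hits = []
    for r in results:
        r.secondary_hit = bool(
            r.primary_outlier
            and r.concordance >= thresholds.concordance_min
            and r.d > thresholds.d_min
            and r.p < thresholds.p_max
        )
        if r.secondary_hit:
            hits.append(r)
    return hits


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementStats:
    """Bland-Altman agreement of two paired measurement methods.

    Differences d_i = a_i - b_i give the bias (mean difference) and the
    95% limits of agreement bias +/- 1.96 s.d.; `coverage` is the fraction
    of differences inside the limits (inclusive).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least three pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    coverage = float(np.mean((d >= lo) & (d <= hi)))
    return AgreementStats(bias=bias, loa_low=lo, loa_high=hi, sd=sd,
                          coverage=coverage, n=int(a.size))


def results_to_frame(results: list[ScreenResult]):
    """Screen results as a tidy DataFrame (one row per line x parameter)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "line_id": r.line_id, "centre": r.centre, "modality": r.modality,
            "parameter": r.parameter, "deviation": r.deviation, "z": r.z,
            "d": r.d, "p": r.p, "concordance": r.concordance,
            "primary_outlier": r.primary_outlier, "secondary_hit": r.secondary_hit,
        }
        for r in results
    ])
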