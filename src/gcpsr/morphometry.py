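"""Basidiospore morphometry: Q values, shape classes, trimmed ranges,
error limits, pairwise significance tests and confidence-ellipse specs.

Conventions follow standard agaric taxonomic practice: the Q value is the
spore length/width ratio; the shape vocabulary maps Q onto named bands
(globose 1.0-1.05, subglobose 1.05-1.15, broadly ellipsoid 1.15-1.3,
ellipsoid 1.3-1.6, elongate 1.6-1.8, cylindrical 2.0-3.0, bacilliform > 3;
the 1.8-2.0 gap of that published scale is surfaced as "unclassified-gap"
rather than silently bridged).  Ranges are written "(min)p10-p90(max)" with
10% of measurements trimmed from each end by the nearest-rank percentile
method.  The error limit EL of a mean is the half-width of its two-sided
95% confidence interval, t(0.975, n-1) * SD / sqrt(n): the radius used for
per-species confidence ellipses in (length, Q) space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MorphometryError

__all__ = [
    "SporeMeasurement",
    "SporeSampleSummary",
    "EllipseSpec",
    "SHAPE_CLASSES",
    "q_value",
    "classify_shape",
    "trimmed_range",
    "render_range",
    "summarize_sample",
    "summary_from_published",
    "error_limit",
    "sd_from_error_limit",
    "welch_test",
    "pairwise_tests",
    "ellipse_spec",
    "spore_notation",
]


@dataclass(frozen=True)
class SporeMeasurement:
    """One spore: length and width in micrometres plus provenance ids."""

    length: float
    width: float
    basidioma_id: str = ""
    specimen_id: str = ""

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise MorphometryError("spore dimensions must be positive")
        if self.length < self.width:
            warnings.warn(
                f"spore length {self.length} < width {self.width}; "
                "measurement axes may be swapped", stacklevel=2)


#: (label, lower, upper) with half-open [lower, upper) intervals.
SHAPE_CLASSES: Tuple[Tuple[str, float, float], ...] = (
    ("globose", 1.0, 1.05),
    ("subglobose", 1.05, 1.15),
    ("broadly ellipsoid", 1.15, 1.3),
    ("ellipsoid", 1.3, 1.6),
    ("elongate", 1.6, 1.8),
    ("unclassified-gap", 1.8, 2.0),
    ("cylindrical", 2.0, 3.0),
    ("bacilliform", 3.0, math.inf),
)


def q_value(length: float, width: float) -> float:
    """Spore length/width ratio."""
    if width <= 0:
        raise MorphometryError("width must be positive")
    return length / width


def classify_shape(q: float) -> str:
    """Name the shape band containing Q (half-open boundaries: a value at a
    boundary belongs to the upper class).  Q < 1 is clamped to globose with
    a warning."""
    if q <= 0:
        raise MorphometryError("Q must be positive")
    if q < 1.0:
        warnings.warn(f"Q = {q} < 1 (width exceeds length); classifying as "
                      "globose", stacklevel=2)
        return "globose"
    for label, lo, hi in SHAPE_CLASSES:
        if lo <= q < hi:
            return label
    return "bacilliform"


def _nearest_rank(sorted_values: Sequence[float], p: float) -> float:
    n = len(sorted_values)
    rank = max(1, math.ceil(p * n))
    return sorted_values[rank - 1]


def trimmed_range(values: Sequence[float], trim: float = 0.10,
                  method: str = "nearest-rank"
                  ) -> Tuple[float, float, float, float]:
    """(abs_min, p_trim, p_{1-trim}, abs_max) for a measurement sample.

    Default nearest-rank percentiles keep the trimmed bounds within observed
    values; ``method="linear"`` interpolates instead.  Requires >= 10 values
    (fewer cannot support a 10% trim; report the raw range instead).
    """
    vals = sorted(float(v) for v in values)
    if len(vals) < 10:
        raise MorphometryError(
            f"need >= 10 values for a trimmed range (got {len(vals)}); "
            "report the raw min-max range instead")
    if method == "nearest-rank":
        lo = _nearest_rank(vals, trim)
        hi = _nearest_rank(vals, 1.0 - trim)
    elif method == "linear":
        lo, hi = np.percentile(vals, [100 * trim, 100 * (1 - trim)])
    else:
        raise MorphometryError(f"unknown percentile method {method!r}")
    return (vals[0], float(lo), float(hi), vals[-1])


def render_range(r: Tuple[float, float, float, float],
                 decimals: int = 1) -> str:
    """Taxonomic range notation "(min)p10-p90(max)" (en dash)."""
    amin, p10, p90, amax = (round(v, decimals) for v in r)
    fmt = f"{{:.{decimals}f}}"
    return (f"({fmt.format(amin)}){fmt.format(p10)}–{fmt.format(p90)}"
            f"({fmt.format(amax)})")


@dataclass(frozen=True)
class SporeSampleSummary:
    """Counts, trimmed ranges, means, SDs and error limits for one sample."""

    species: str
    n_spores: int
    n_basidiomata: int
    n_specimens: int
    length_range: Tuple[float, float, float, float]
    width_range: Tuple[float, float, float, float]
    q_range: Tuple[float, float, float, float]
    l_m: float
    sd_l: float
    el_l: float
    w_m: float
    sd_w: float
    el_w: float
    q_m: float
    sd_q: float
    el_q: float

    def __post_init__(self):
        if not (self.n_spores >= self.n_basidiomata >= self.n_specimens >= 1):
            raise MorphometryError(
                "expected n_spores >= n_basidiomata >= n_specimens >= 1")
        for r in (self.length_range, self.width_range, self.q_range):
            if not (r[0] <= r[1] <= r[2] <= r[3]):
                raise MorphometryError(f"range {r} is not ordered")
        for el in (self.el_l, self.el_w, self.el_q):
            if el < 0:
                raise MorphometryError("error limits must be >= 0")


def summary_from_published(species: str, l_m: float, el_l: float,
                           q_m: float, el_q: float, n: int
                           ) -> SporeSampleSummary:
    """Build a summary from published "mean +/- EL" table values only.

    SDs are stored as NaN and back-derived on demand (e.g. by
    :func:`pairwise_tests`); ranges and width fields are unavailable and
    collapse to the means.
    """
    nan = float("nan")
    return SporeSampleSummary(
        species=species, n_spores=n, n_basidiomata=1, n_specimens=1,
        length_range=(l_m,) * 4, width_range=(l_m / q_m,) * 4,
        q_range=(q_m,) * 4,
        l_m=l_m, sd_l=nan, el_l=el_l,
        w_m=l_m / q_m, sd_w=nan, el_w=0.0,
        q_m=q_m, sd_q=nan, el_q=el_q)


def error_limit(sd: float, n: int, confidence: float = 0.95) -> float:
    """Two-sided confidence half-width of a mean: t(q, n-1) * SD / sqrt(n)."""
    if n < 2:
        raise MorphometryError("need n >= 2 for an error limit")
    q = 1.0 - (1.0 - confidence) / 2.0
    return float(stats.t.ppf(q, n - 1) * sd / math.sqrt(n))


def sd_from_error_limit(el: float, n: int, confidence: float = 0.95) -> float:
    """Back-derive a standard deviation from a printed mean +/- EL and n."""
    if n < 2:
        raise MorphometryError("need n >= 2")
    q = 1.0 - (1.0 - confidence) / 2.0
    return float(el * math.sqrt(n) / stats.t.ppf(q, n - 1))


def summarize_sample(measurements: Sequence[SporeMeasurement],
                     species: str = "",
                     percentile_method: str = "nearest-rank"
                     ) -> SporeSampleSummary:
    """Full summary of one species' spore sample (n >= 10 for the trimmed
    ranges, n >= 2 for the dispersion statistics).

    Q is computed per spore, then summarized like the raw dimensions.  SD
    uses the n-1 denominator; EL is the 95% confidence half-width.
    """
    n = len(measurements)
    if n < 2:
        raise MorphometryError("need at least 2 measurements")
    lengths = np.array([m.length for m in measurements])
    widths = np.array([m.width for m in measurements])
    qs = lengths / widths

    def _stats(x: np.ndarray) -> Tuple[float, float, float]:
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        return mean, sd, error_limit(sd, len(x))

    l_m, sd_l, el_l = _stats(lengths)
    w_m, sd_w, el_w = _stats(widths)
    q_m, sd_q, el_q = _stats(qs)
    ranges = tuple(
        trimmed_range(x, method=percentile_method) if n >= 10
        else (float(x.min()),) * 2 + (float(x.max()),) * 2
        for x in (lengths, widths, qs))
    n_bas = len({m.basidioma_id for m in measurements if m.basidioma_id}) or 1
    n_spec = len({m.specimen_id for m in measurements if m.specimen_id}) or 1
    return SporeSampleSummary(
        species=species, n_spores=n,
        n_basidiomata=n_bas,
        n_specimens=n_spec,
        length_range=ranges[0], width_range=ranges[1], q_range=ranges[2],
        l_m=l_m, sd_l=sd_l, el_l=el_l,
        w_m=w_m, sd_w=sd_w, el_w=el_w,
        q_m=q_m, sd_q=sd_q, el_q=el_q)


def welch_test(mean1: float, sd1: float, n1: int,
               mean2: float, sd2: float, n2: int,
               pooled: bool = False) -> Tuple[float, float, float]:
    """(t, df, p) for a two-sample test from summary statistics.

    Default is Welch's unequal-variance t with Welch-Satterthwaite degrees
    of freedom; ``pooled=True`` gives the classical equal-variance test.
    """
    if min(n1, n2) < 2:
        raise MorphometryError("need n >= 2 in both samples")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if pooled:
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = math.sqrt(v1 + v2)
        df = ((v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
              if v1 + v2 > 0 else float(n1 + n2 - 2))
    if se == 0:
        t = 0.0 if mean1 == mean2 else math.copysign(math.inf, mean1 - mean2)
    else:
        t = (mean1 - mean2) / se
    p = float(2 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return float(t), float(df), p


def pairwise_tests(summaries: Sequence[SporeSampleSummary],
                   alpha: float = 0.01, pooled: bool = False,
                   bonferroni: bool = False) -> pd.DataFrame:
    """Pairwise tests of mean spore length and mean Q between species.

    SDs are taken from the summaries; when a summary stores only error
    limits (sd fields NaN), the SD is back-derived as EL * sqrt(n) / t.
    Returns one row per (pair, variable) with t, df, p and significance at
    ``alpha`` (optionally Bonferroni-adjusted across pairs per variable).
    """
    rows = []
    n_pairs = len(summaries) * (len(summaries) - 1) // 2
    level = alpha / n_pairs if (bonferroni and n_pairs) else alpha
    for i, a in enumerate(summaries):
        for b in summaries[i + 1:]:
            for var, (m1, sd1, el1), (m2, sd2, el2) in (
                    ("length", (a.l_m, a.sd_l, a.el_l),
                     (b.l_m, b.sd_l, b.el_l)),
                    ("q", (a.q_m, a.sd_q, a.el_q),
                     (b.q_m, b.sd_q, b.el_q))):
                s1 = sd1 if not math.isnan(sd1) else sd_from_error_limit(
                    el1, a.n_spores)
                s2 = sd2 if not math.isnan(sd2) else sd_from_error_limit(
                    el2, b.n_spores)
                if math.isnan(s1) or math.isnan(s2):
                    raise MorphometryError(
                        f"{a.species}/{b.species}: neither SD nor EL "
                        f"available for {var}")
                t, df, p = welch_test(m1, s1, a.n_spores, m2, s2, b.n_spores,
                                      pooled=pooled)
                rows.append((a.species, b.species, var, t, df, p, p < level))
    return pd.DataFrame(
        rows, columns=["species_a", "species_b", "variable", "t", "df", "p",
                       "significant"])


@dataclass(frozen=True)
class EllipseSpec:
    """Confidence ellipse in (mean length, mean Q) space.

    Center (l_m, q_m); radii are the error limits of length and Q."""

    species: str
    center: Tuple[float, float]
    radii: Tuple[float, float]

    def __post_init__(self):
        if min(self.radii) < 0:
            raise MorphometryError("ellipse radii must be >= 0")


def ellipse_spec(summary: SporeSampleSummary) -> EllipseSpec:
    return EllipseSpec(species=summary.species,
                       center=(summary.l_m, summary.q_m),
                       radii=(summary.el_l, summary.el_q))


def spore_notation(summary: SporeSampleSummary) -> str:
    """Taxonomic description line for a spore sample.

    "[n/b/s] (min)p10-p90(max) x (min)p10-p90(max) um, [Q = (min)p10-p90
    (max), Qm = x +/- SDy]" with one-decimal micrometre values and
    two-decimal Q values.
    """
    head = (f"[{summary.n_spores}/{summary.n_basidiomata}"
            f"/{summary.n_specimens}]")
    lr = render_range(summary.length_range, 1)
    wr = render_range(summary.width_range, 1)
    qr = render_range(summary.q_range, 2)
    return (f"{head} {lr} × {wr} μm, [Q = {qr}, "
            f"Qm = {summary.q_m:.2f} ± SD{summary.sd_q:.2f}]")
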