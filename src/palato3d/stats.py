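"""Paired nonparametric comparison of ROI measurements.

Wilcoxon signed-rank test (two-sided) with the standard zero-difference
reduction and midranks for ties. The exact null distribution of the positive
rank sum is obtained by dynamic programming over doubled midranks — equivalent
to full enumeration of the 2^n sign assignments — for n <= 25; above that a
tie- and continuity-corrected normal approximation is used. Multiplicity is
handled with the Benjamini–Hochberg step-up adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSampleError, ValidationError

EXACT_LIMIT = 25


@dataclass
class PairedSample:
    """Two measurement vectors aligned by patient id."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == len(self.x) == len(self.y)):
            raise ValidationError("paired sample vectors must have equal length")
        if len(self.x) < 2:
            raise ValidationError("paired sample needs >= 2 patients")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValidationError("paired sample contains missing entries")


@dataclass
class WilcoxonResult:
    statistic: float  # W = smaller signed-rank sum
    pvalue: float
    n_used: int
    n_zero: int
    method: str  # "exact" | "normal"


def _exact_sf_cdf(doubled_ranks: np.ndarray, w2: int):
    """P(W+ <= w) and P(W+ >= w) for the doubled positive rank sum by DP.

    ``doubled_ranks`` are integer 2*midranks; distribution over all 2^n equally
    likely sign vectors.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return cdf, sf


def wilcoxon_signed_rank(x, y=None, mode: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired data (or differences).

    Zero differences are dropped (count reported); |differences| are ranked
    with midranks. ``mode`` is ``exact`` (full-enumeration DP), ``normal``
    (tie/continuity-corrected approximation) or ``auto`` (exact for n <= 25).
    Raises :class:`DegenerateSampleError` when every difference is zero.
    """
    if isinstance(x, PairedSample):
        d = x.x - x.y
    elif y is not None:
        d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    else:
        d = np.asarray(x, dtype=float)
    if mode not in ("exact", "normal", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateSampleError(
            "all paired differences are zero; the signed-rank p-value is undefined"
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_LIMIT)
    if use_exact:
        r2 = np.rint(2 * ranks).astype(np.int64)
        w2 = int(np.rint(2 * w_plus))
        cdf, sf = _exact_sf_cdf(r2, w2)
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # tie correction over groups of tied |differences|
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sigma == 0:
            raise DegenerateSampleError("zero variance (all |differences| tied at one value)")
        z = (w - mu + 0.5) / sigma  # continuity correction toward the mean
        p = min(1.0, 2.0 * sps.norm.cdf(z)) if w <= mu else min(1.0, 2.0 * sps.norm.sf((w - mu - 0.5) / sigma))
        method = "normal"
    return WilcoxonResult(w, float(p), n, n_zero, method)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


@dataclass
class StatsTable:
    """Pairwise test results: one row per ROI pair."""

    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            self.rows, columns=["pair", "statistic", "p_raw", "p_bh", "n", "note"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def pairwise_roi_tests(cohort_values: dict, mode: str = "auto") -> StatsTable:
    """All 10 pairwise ROI comparisons of one metric, BH-adjusted.

    ``cohort_values`` maps ROI name -> per-patient vector (aligned across
    ROIs). Degenerate pairs — zero-variance differences, including the
    all-zero case — are flagged and excluded from the BH family.
    """
    names = list(cohort_values)
    lengths = {len(np.asarray(v)) for v in cohort_values.values()}
    if len(lengths) != 1:
        raise ValidationError("ROI vectors differ in length across the cohort")
    rows = []
    raw = []
    for a, b in combinations(names, 2):
        x = np.asarray(cohort_values[a], dtype=float)
        y = np.asarray(cohort_values[b], dtype=float)
        d = x - y
        if np.ptp(d) == 0 and np.any(d != 0):
            # constant nonzero differences: the signed-rank statistic carries
            # no magnitude information (perfect ties), treat as degenerate
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "statistic": np.nan,
                    "p_raw": np.nan,
                    "p_bh": np.nan,
                    "n": len(x),
                    "note": "degenerate (zero-variance differences)",
                }
            )
            continue
        try:
            res = wilcoxon_signed_rank(x, y, mode=mode)
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "statistic": res.statistic,
                    "p_raw": res.pvalue,
                    "p_bh": np.nan,
                    "n": res.n_used,
                    "note": res.method,
                }
            )
            raw.append(res.pvalue)
        except DegenerateSampleError:
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "statistic": np.nan,
                    "p_raw": np.nan,
                    "p_bh": np.nan,
                    "n": len(x),
                    "note": "degenerate (all differences zero)",
                }
            )
    if raw:
        adj = bh_adjust(raw)
        k = 0
        for row in rows:
            if not np.isnan(row["p_raw"]):
                row["p_bh"] = float(adj[k])
                k += 1
    return StatsTable(rows)
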