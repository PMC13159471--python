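"""Observer-agreement and group-comparison statistics for cap thickness.

Covers the repeated-reading comparison schemes used to validate automated
minimum-cap-thickness measurements against manual expert readings
(Bland–Altman bias and 95% limits of agreement), two-sample
Kolmogorov–Smirnov group comparisons, thin-cap fractions at the usual
vulnerability cut-offs, and summary statistics with the per-case
min/median/max decomposition of triplicate readings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "pair_intra",
    "pair_inter",
    "pair_vs_automated",
    "bland_altman",
    "ks_two_sample",
    "thin_cap_fraction",
    "summarize_distribution",
    "THIN_CAP_THRESHOLDS_UM",
]

logger = logging.getLogger(__name__)

# Conventional thin-cap vulnerability cut-offs, µm.
THIN_CAP_THRESHOLDS_UM = (65.0, 80.0, 95.0, 100.0)


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement summary of paired readings (first − second)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int

    @property
    def loa_range(self) -> float:
        return self.loa_high - self.loa_low


def pair_intra(readings: Mapping[object, Sequence[float]]) -> List[Tuple[float, float]]:
    """Intra-observer pairs: with three readings per case, each reading is
    compared to the other two, giving the three pairs (r1,r2), (r1,r3),
    (r2,r3) per case."""
    pairs: List[Tuple[float, float]] = []
    for case, r in readings.items():
        if len(r) != 3:
            raise ValueError(f"case {case!r}: expected exactly 3 readings, got {len(r)}")
        r1, r2, r3 = r
        pairs.extend([(r1, r2), (r1, r3), (r2, r3)])
    return pairs


def pair_inter(
    obs1: Mapping[object, Sequence[float]],
    obs2: Mapping[object, Sequence[float]],
    scheme: str = "by-repetition",
) -> List[Tuple[float, float]]:
    """Inter-observer pairs between two observers with triplicate readings.

    ``"by-repetition"`` pairs readings of the same repetition index (3 pairs
    per case); ``"all-crossings"`` pairs every reading of observer 1 with
    every reading of observer 2 (9 pairs per case).
    """
    if scheme not in ("by-repetition", "all-crossings"):
        raise ValueError("scheme must be 'by-repetition' or 'all-crossings'")
    pairs: List[Tuple[float, float]] = []
    for case, r1 in obs1.items():
        if case not in obs2:
            logger.warning("case %r missing for second observer; skipped", case)
            continue
        r2 = obs2[case]
        if len(r1) != 3 or len(r2) != 3:
            raise ValueError(f"case {case!r}: both observers need exactly 3 readings")
        if scheme == "by-repetition":
            pairs.extend(zip(r1, r2))
        else:
            pairs.extend((a, b) for a in r1 for b in r2)
    return pairs


def pair_vs_automated(
    manual: Mapping[object, Sequence[float]],
    automated: Mapping[object, Optional[float]],
) -> List[Tuple[float, float]]:
    """Manual-vs-automated pairs: each of the three manual readings of a case
    is compared to the single automated value, giving three pairs per case.
    Cases without an automated value are skipped with a log entry."""
    pairs: List[Tuple[float, float]] = []
    for case, r in manual.items():
        if len(r) != 3:
            raise ValueError(f"case {case!r}: expected exactly 3 manual readings, got {len(r)}")
        auto = automated.get(case)
        if auto is None or not np.isfinite(auto):
            logger.warning("case %r has no automated measurement; skipped", case)
            continue
        pairs.extend((m, float(auto)) for m in r)
    return pairs


def bland_altman(pairs: Iterable[Tuple[float, float]]) -> AgreementResult:
    """Bland–Altman bias and 95% limits of agreement.

    Differences are first − second; the limits are bias ± 1.96 × sample SD
    (n−1 denominator).  No repeated-measures correction is applied.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need at least 2 (first, second) pairs")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_pairs=len(d),
    )


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    Returns ``(D, p)``; the p-value is computed by exact enumeration when the
    smaller sample has at most 10 observations and from the asymptotic
    Kolmogorov distribution otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if min(x.size, y.size) <= 10 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def thin_cap_fraction(
    values: Sequence[float], thresholds: Sequence[float] = THIN_CAP_THRESHOLDS_UM
) -> Dict[float, float]:
    """Percentage of measurements strictly below each thickness cut-off."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    return {float(t): float(100.0 * np.mean(v < t)) for t in thresholds}


def summarize_distribution(
    values: Optional[Sequence[float]] = None,
    triplicates: Optional[Mapping[object, Sequence[float]]] = None,
) -> Dict[str, object]:
    """Overall mean/SD/median/n, optionally with the per-case decomposition of
    triplicate readings into their minimum, median and maximum series."""

    def basic(v: np.ndarray) -> Dict[str, float]:
        return {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "median": float(np.median(v)),
            "n": int(v.size),
        }

    if values is None and triplicates is None:
        raise ValueError("provide values and/or triplicates")
    out: Dict[str, object] = {}
    if values is not None:
        out["overall"] = basic(np.asarray(values, dtype=float))
    if triplicates is not None:
        mins, meds, maxs = [], [], []
        for case, r in triplicates.items():
            if len(r) != 3:
                raise ValueError(f"case {case!r}: expected exactly 3 readings")
            lo, mid, hi = np.sort(np.asarray(r, dtype=float))
            mins.append(lo)
            meds.append(mid)
            maxs.append(hi)
        if values is None:
            pooled = np.concatenate([mins, meds, maxs])
            out["overall"] = basic(pooled)
        out["min_of_repeats"] = basic(np.asarray(mins))
        out["median_of_repeats"] = basic(np.asarray(meds))
        out["max_of_repeats"] = basic(np.asarray(maxs))
    return out
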