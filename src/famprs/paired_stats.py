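"""Within-family paired inference: the Wilcoxon signed-rank machinery.

Conventions match the widely used online signed-rank calculators: exact-zero
differences are dropped before ranking; absolute differences receive
midranks; W is the smaller of the positive/negative rank sums, so its
normal-approximation Z is always <= 0; the alpha-level acceptance region
for W is mean_W +/- z_{1-alpha/2} * sd_W rounded half-away-from-zero to the
nearest integer.  No tie correction is applied to sd_W by default (PRS
differences are continuous, making exact ties measure-zero); a flag turns
it on.

An exact sign-flip enumeration of the W distribution is exposed as a
testing oracle for small n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PairedDifferences:
    """Ordered case-minus-relative differences with tie bookkeeping."""

    values: np.ndarray  # all differences, zeros included
    n_zero: int
    tie_groups: tuple[int, ...]  # sizes (>1) of tied |difference| groups

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "PairedDifferences":
        v = np.asarray(list(values), dtype=float)
        if v.ndim != 1:
            raise ValueError("differences must be one-dimensional")
        if np.isnan(v).any():
            raise ValueError("differences contain NaN")
        nz = v[v != 0]
        _, counts = np.unique(np.abs(nz), return_counts=True)
        ties = tuple(int(c) for c in counts if c > 1)
        return cls(values=v, n_zero=int((v == 0).sum()), tie_groups=ties)

    @classmethod
    def from_pairs(cls, case_scores, relative_scores) -> "PairedDifferences":
        c = np.asarray(case_scores, dtype=float)
        r = np.asarray(relative_scores, dtype=float)
        if c.shape != r.shape:
            raise ValueError("case and relative score vectors differ in length")
        return cls.from_values(c - r)

    @property
    def nonzero(self) -> np.ndarray:
        return self.values[self.values != 0]

    @property
    def n_used(self) -> int:
        return int(self.nonzero.size)


@dataclass
class WilcoxonResult:
    """Signed-rank test summary mirroring a W / critical-values / Z / p report."""

    n_used: int
    w_plus: float | None
    w_minus: float | None
    w: float
    mean_w: float
    sd_w: float
    z: float
    p_two_sided: float
    alpha: float
    critical_low: int
    critical_high: int
    direction: int  # sign of (w_plus - w_minus); 0 when unknown or balanced

    def to_dict(self) -> dict:
        return {
            "n_used": self.n_used,
            "w": self.w,
            "z": self.z,
            "p_two_sided": self.p_two_sided,
            "alpha": self.alpha,
            "critical_low": self.critical_low,
            "critical_high": self.critical_high,
            "direction": self.direction,
        }


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _null_moments(n: int, tie_groups: Iterable[int] = (), tie_correction: bool = False):
    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0
    if tie_correction:
        var_w -= sum(t**3 - t for t in tie_groups) / 48.0
    return mean_w, math.sqrt(var_w)


def critical_interval(n: int, alpha: float) -> tuple[int, int]:
    """Alpha-level acceptance region for W under the null.

    ``mean_W -/+ z_{1-alpha/2} * sd_W`` rounded half-away-from-zero to the
    nearest integer; W outside [low, high] rejects at level alpha.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    mean_w, sd_w = _null_moments(n)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return _round_half_away(mean_w - zcrit * sd_w), _round_half_away(mean_w + zcrit * sd_w)


def wilcoxon_from_summary(n_used: int, w: float, alpha: float = 0.05) -> WilcoxonResult:
    """Recompute Z, p and the critical interval from a reported (N, W) pair.

    Useful for auditing published signed-rank tables where only the smaller
    rank sum and the pair count are printed.
    """
    if n_used < 1:
        raise ValueError("n_used must be >= 1")
    total = n_used * (n_used + 1) / 2.0
    if not 0 <= w <= total:
        raise ValueError(f"W={w} impossible for n={n_used}")
    mean_w, sd_w = _null_moments(n_used)
    z = (w - mean_w) / sd_w
    p = min(1.0, 2 * stats.norm.cdf(z))
    low, high = critical_interval(n_used, alpha)
    return WilcoxonResult(
        n_used=n_used,
        w_plus=None,
        w_minus=None,
        w=w,
        mean_w=mean_w,
        sd_w=sd_w,
        z=z,
        p_two_sided=p,
        alpha=alpha,
        critical_low=low,
        critical_high=high,
        direction=0,
    )


def signed_rank_test(
    diffs: PairedDifferences,
    alpha: float = 0.05,
    tie_correction: bool = False,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test with the smaller-rank-sum W convention.

    Zeros are dropped, |differences| are midranked, ``w = min(W+, W-)``,
    and Z = (w - mean_W)/sd_W is compared to the standard normal; p is the
    two-sided normal tail.  ``tie_correction`` subtracts the usual
    sum(t^3 - t)/48 term from Var(W).
    """
    d = diffs.nonzero
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; signed-rank test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2.0
    w_minus = total - w_plus
    w = min(w_plus, w_minus)
    mean_w, sd_w = _null_moments(n, diffs.tie_groups, tie_correction)
    if sd_w == 0:
        raise ValueError("degenerate null variance (all ranks tied away)")
    z = (w - mean_w) / sd_w
    p = min(1.0, 2 * stats.norm.cdf(z))
    low, high = critical_interval(n, alpha)
    return WilcoxonResult(
        n_used=n,
        w_plus=w_plus,
        w_minus=w_minus,
        w=w,
        mean_w=mean_w,
        sd_w=sd_w,
        z=z,
        p_two_sided=p,
        alpha=alpha,
        critical_low=low,
        critical_high=high,
        direction=int(np.sign(w_plus - w_minus)),
    )


def exact_permutation_p(diffs: PairedDifferences) -> float:
    """Exact two-sided p from the full sign-flip distribution of W.

    Enumerates all 2^n assignments of signs to the midranks (by dynamic
    programming over doubled ranks, so midranks stay integral) and returns
    P(min(W+, W-) <= observed).  Only for n <= 20.
    """
    d = diffs.nonzero
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    ranks2 = np.rint(2 * stats.rankdata(np.abs(d))).astype(int)  # doubled midranks
    w_plus2 = int(ranks2[d > 0].sum())
    total2 = int(ranks2.sum())
    w_obs2 = min(w_plus2, total2 - w_plus2)
    # counts[s] = number of sign vectors with doubled W+ equal to s
    counts = np.zeros(total2 + 1, dtype=np.int64)
    counts[0] = 1
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted if r else counts * 2
    w_min2 = np.minimum(np.arange(total2 + 1), total2 - np.arange(total2 + 1))
    favorable = counts[w_min2 <= w_obs2].sum()
    return float(favorable) / float(2**n)


def run_within_family(
    pairsets: Mapping[str, "PairSet"],
    prs: "PRSTable",
    ped=None,
    alpha: float = 0.05,
    tie_correction: bool = False,
) -> pd.DataFrame:
    """One signed-rank test per case-relative group, plus group descriptives.

    Returns one row per group with columns group, n_pairs, n_used, w,
    critical_low, critical_high, z, p, mean_case_age, mean_relative_age,
    status.  Empty or all-tied groups are reported as skipped, not fatal.
    Case age prefers age-at-onset when the pedigree records one.
    """
    z = prs.z
    rows = []
    for name, ps in pairsets.items():
        pairs = ps.pairs
        base = {
            "group": name,
            "n_pairs": len(pairs),
            "n_used": 0,
            "w": np.nan,
            "critical_low": np.nan,
            "critical_high": np.nan,
            "z": np.nan,
            "p": np.nan,
            "mean_case_age": np.nan,
            "mean_relative_age": np.nan,
            "status": "skipped",
        }
        if len(pairs) == 0:
            logger.warning("group %s: no pairs; skipped", name)
            rows.append(base)
            continue
        missing = [
            i
            for i in pd.concat([pairs["case_id"], pairs["relative_id"]]).unique()
            if i not in z.index or pd.isna(z.loc[i])
        ]
        if missing:
            raise ValueError(f"group {name}: pair members lack z-scores: {missing[:5]}")
        diffs = PairedDifferences.from_pairs(
            z.loc[pairs["case_id"]].to_numpy(), z.loc[pairs["relative_id"]].to_numpy()
        )
        if ped is not None:
            case_ages = [
                ped[i].age_at_onset if ped[i].age_at_onset is not None else ped[i].age
                for i in pairs["case_id"]
            ]
            rel_ages = [ped[i].age for i in pairs["relative_id"]]
            if all(a is not None for a in case_ages):
                base["mean_case_age"] = float(np.mean(case_ages))
            if all(a is not None for a in rel_ages):
                base["mean_relative_age"] = float(np.mean(rel_ages))
        if diffs.n_used == 0:
            logger.warning("group %s: all differences zero; skipped", name)
            rows.append(base)
            continue
        res = signed_rank_test(diffs, alpha=alpha, tie_correction=tie_correction)
        base.update(
            n_used=res.n_used,
            w=res.w,
            critical_low=res.critical_low,
            critical_high=res.critical_high,
            z=res.z,
            p=res.p_two_sided,
            status="tested",
        )
        rows.append(base)
    return pd.DataFrame(rows)
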