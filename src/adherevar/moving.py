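"""Moving-window adherence statistics and rank-based variance standardization.

From month 12 onward, each patient-month gets the mean and the sample
variance of the previous 12 monthly adherence values.  Because a high
moving mean mechanically implies a low moving variance (adherence lives in
[0, 100]), the raw variance carries much of the same information as the
mean.  The standardization implemented here removes that dependence:
patient-months are pooled, sorted by moving mean, cut into consecutive
small-amplitude bins of roughly ``target_class_size`` points, and within
each bin the variances are ranked and mapped through the standard normal
quantile function, ``z = Phi^{-1}(rank / (1 + bin size))``.  The resulting
standardized variance is, by construction, identically distributed in
every bin and hence decorrelated from the moving mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import DataError

__all__ = ["moving_mean_variance", "standardize_variances", "StandardizationMap"]


def moving_mean_variance(
    adherence: pd.DataFrame,
    window: int = 12,
    min_obs: int | None = None,
) -> pd.DataFrame:
    """Per-patient moving mean and sample variance of monthly adherence.

    Parameters
    ----------
    adherence
        Long table with columns ``patient_id``, ``month`` (positive integer,
        months since therapy start) and ``adherence`` (percent, 0-100).
    window
        Width of the trailing window in months (default 12: the statistic at
        month ``t`` summarizes months ``t-11 .. t``).
    min_obs
        Minimum number of observed months required inside the window.  By
        default the full window must be observed (complete-window rule), so
        a patient contributes nothing before their 12th consecutive month.

    Returns
    -------
    DataFrame with columns ``patient_id``, ``month``, ``moving_mean``,
    ``moving_variance`` (sample variance, denominator ``n - 1``), sorted by
    patient then month.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if min_obs is None:
        min_obs = window
    if not 2 <= min_obs <= window:
        raise ValueError(f"min_obs must be in [2, window], got {min_obs}")

    required = {"patient_id", "month", "adherence"}
    missing = required - set(adherence.columns)
    if missing:
        raise DataError(f"adherence table missing columns: {sorted(missing)}")
    months = adherence["month"].to_numpy()
    if not np.issubdtype(np.asarray(months).dtype, np.number) or np.any(months < 1):
        raise DataError("months must be positive integers")
    if np.any(months != np.floor(months)):
        raise DataError("months must be integers")
    dup = adherence.duplicated(subset=["patient_id", "month"])
    if dup.any():
        bad = adherence.loc[dup, ["patient_id", "month"]].iloc[0]
        raise DataError(
            f"duplicate patient-month: patient {bad['patient_id']}, month {bad['month']}"
        )

    out = []
    for pid, grp in adherence.groupby("patient_id", sort=True):
        s = grp.set_index("month")["adherence"].sort_index()
        # reindex onto the full calendar grid so gaps count against min_obs
        full = s.reindex(range(int(s.index.min()), int(s.index.max()) + 1))
        roll = full.rolling(window, min_periods=min_obs)
        mm = roll.mean()
        mv = roll.var(ddof=1)
        keep = mm.notna() & (mm.index >= window)
        if not keep.any():
            continue
        out.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "month": mm.index[keep],
                    "moving_mean": mm[keep].to_numpy(),
                    "moving_variance": mv[keep].to_numpy(),
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["patient_id", "month", "moving_mean", "moving_variance"]
        )
    return pd.concat(out, ignore_index=True)


@dataclass
class StandardizationMap:
    """Fitted mean-bin partition used to standardize moving variances.

    Bins are consecutive in moving-mean order.  ``upper_means[c]`` is the
    largest training mean in bin ``c``; a held-out point is assigned to the
    first bin whose upper mean is >= its moving mean (points beyond the last
    boundary join the last bin).  ``sorted_variances[c]`` holds the bin's
    training variances in increasing order so held-out variances can be
    ranked against them.
    """

    target_class_size: int
    sizes: np.ndarray
    upper_means: np.ndarray
    sorted_variances: list = field(repr=False, default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.sizes)

    def assign_class(self, moving_mean: np.ndarray) -> np.ndarray:
        """Bin index (0-based) for each moving mean, nearest-boundary rule."""
        idx = np.searchsorted(self.upper_means, np.asarray(moving_mean, float))
        return np.clip(idx, 0, self.n_classes - 1)

    def transform(self, moving_mean: np.ndarray, moving_variance: np.ndarray) -> np.ndarray:
        """Standardize held-out (mean, variance) pairs with the fitted map."""
        moving_variance = np.asarray(moving_variance, float)
        cls = self.assign_class(moving_mean)
        z = np.empty(len(cls), dtype=float)
        for c in np.unique(cls):
            sel = cls == c
            n_c = self.sizes[c]
            ranks = np.searchsorted(self.sorted_variances[c], moving_variance[sel], side="right")
            ranks = np.clip(ranks, 1, n_c)
            z[sel] = norm.ppf(ranks / (1.0 + n_c))
        return z

    def to_dict(self) -> dict:
        return {
            "target_class_size": int(self.target_class_size),
            "sizes": [int(s) for s in self.sizes],
            "upper_means": [float(m) for m in self.upper_means],
            "sorted_variances": [[float(v) for v in sv] for sv in self.sorted_variances],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationMap":
        return cls(
            target_class_size=int(d["target_class_size"]),
            sizes=np.asarray(d["sizes"], dtype=int),
            upper_means=np.asarray(d["upper_means"], dtype=float),
            sorted_variances=[np.asarray(sv, dtype=float) for sv in d["sorted_variances"]],
        )


def _class_sizes(n: int, target: int) -> np.ndarray:
    """Near-equal consecutive bin sizes: K = round(N/target), remainder
    spread one-per-bin starting from the first bin."""
    k = max(1, round(n / target))
    base, rem = divmod(n, k)
    sizes = np.full(k, base, dtype=int)
    sizes[:rem] += 1
    return sizes


def standardize_variances(
    points: pd.DataFrame,
    target_class_size: int = 30,
) -> tuple[pd.DataFrame, StandardizationMap]:
    """Rank-based inverse-normal standardization of moving variances.

    The pooled patient-months are stably sorted by ``moving_mean``,
    partitioned into consecutive bins of nearly ``target_class_size``
    points, and within each bin the variance with rank ``k`` (average ranks
    on ties) maps to ``Phi^{-1}(k / (1 + n_c))``.

    Returns the input table with a ``std_variance`` column added (original
    row order preserved) and the fitted :class:`StandardizationMap`.
    """
    n = len(points)
    if n < 2:
        raise DataError(f"need at least 2 pooled points, got {n}")
    means = points["moving_mean"].to_numpy(dtype=float)
    variances = points["moving_variance"].to_numpy(dtype=float)
    if np.isnan(means).any() or np.isnan(variances).any():
        raise DataError("NaN moving mean or variance in pooled points")

    order = np.argsort(means, kind="stable")
    sizes = _class_sizes(n, target_class_size)
    edges = np.concatenate([[0], np.cumsum(sizes)])

    z = np.empty(n, dtype=float)
    upper_means = np.empty(len(sizes), dtype=float)
    sorted_vars: list[np.ndarray] = []
    for c in range(len(sizes)):
        idx = order[edges[c]:edges[c + 1]]
        n_c = sizes[c]
        ranks = rankdata(variances[idx], method="average")
        z[idx] = norm.ppf(ranks / (1.0 + n_c))
        upper_means[c] = means[idx[-1]]
        sorted_vars.append(np.sort(variances[idx]))

    out = points.copy()
    out["std_variance"] = z
    smap = StandardizationMap(
        target_class_size=target_class_size,
        sizes=sizes,
        upper_means=upper_means,
        sorted_variances=sorted_vars,
    )
    return out, smap
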