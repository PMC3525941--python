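"""Measurement layer: sensitivity index d_a, signed r², ROI averages, exact tests.

d_a (Simpson & Fitter) is the mean difference between attended and unattended
feature values divided by the root-mean-square of the two group standard
deviations:

    d_a = (mu_att - mu_unatt) / sqrt((sd_att^2 + sd_unatt^2) / 2)

The signed coefficient of determination (signed r²) is the squared
point-biserial correlation between a feature and the binary class label,
carrying the sign of the group-mean difference.

Exact tests are provided for the small-n designs used here: a Wilcoxon
signed-rank test with the exact sign-flip null (zeros dropped, ties
mid-ranked), Fisher's exact test on 2x2 tables (probability-mass two-sided
rule), and Spearman rank correlation with an exact permutation p for n <= 9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSamples",
    "ROI_WINDOWS",
    "sensitivity_index",
    "signed_r2",
    "grand_average",
    "roi_mean",
    "wilcoxon_signed_rank",
    "fisher_exact",
    "spearman",
    "hit_rate",
]

#: ERP ranges of interest in ms: grand-average components (N1/P2/P3) and
#: attended-minus-unattended difference-wave windows (D1/D2/D3)
ROI_WINDOWS: dict[str, tuple[float, float]] = {
    "N1": (70.0, 125.0),
    "P2": (150.0, 240.0),
    "P3": (250.0, 310.0),
    "D1": (50.0, 90.0),
    "D2": (120.0, 190.0),
    "D3": (200.0, 265.0),
}


@dataclass(frozen=True)
class GroupSamples:
    """Per-trial feature values of the attended and unattended groups."""

    attended: np.ndarray
    unattended: np.ndarray

    def __post_init__(self) -> None:
        for g in (self.attended, self.unattended):
            if np.asarray(g).size < 2:
                raise ValueError("each group needs n >= 2 for dispersion-based indices")


def sensitivity_index(g: GroupSamples) -> float:
    """d_a = mean difference over the RMS of the two sample SDs (ddof=1)."""
    att = np.asarray(g.attended, dtype=float)
    unatt = np.asarray(g.unattended, dtype=float)
    if not (np.all(np.isfinite(att)) and np.all(np.isfinite(unatt))):
        raise ValueError("group samples must be finite")
    num = att.mean() - unatt.mean()
    denom = np.sqrt((att.var(ddof=1) + unatt.var(ddof=1)) / 2.0)
    if denom == 0:
        warnings.warn("zero pooled variance; d_a is infinite", stacklevel=2)
        return float(np.sign(num) * np.inf) if num != 0 else 0.0
    return float(num / denom)


def sensitivity_index_curve(attended: np.ndarray, unattended: np.ndarray) -> np.ndarray:
    """Vectorized d_a per feature column: inputs (n_trials, ...) arrays."""
    att = np.asarray(attended, dtype=float)
    unatt = np.asarray(unattended, dtype=float)
    num = att.mean(axis=0) - unatt.mean(axis=0)
    denom = np.sqrt((att.var(axis=0, ddof=1) + unatt.var(axis=0, ddof=1)) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, num / denom, 0.0)


def signed_r2(values: np.ndarray, labels: np.ndarray) -> float:
    """Signed squared point-biserial correlation of a feature with class labels.

    ``labels`` is binary (bool/0-1, or "left"/"right" with right positive).
    Positive sign means the positive class has the larger mean.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = labels == "right"
    y = labels.astype(float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if np.ptp(values) == 0:
        warnings.warn("constant values; signed r^2 is 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(values, y)[0, 1]
    return float(np.sign(r) * r ** 2)


def signed_r2_curve(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Signed r² per time sample: ``values`` is (n_trials, n_samples)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = labels == "right"
    y = labels.astype(float)
    yc = y - y.mean()
    vc = values - values.mean(axis=0)
    denom = np.sqrt((vc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (vc * yc[:, None]).sum(axis=0) / denom, 0.0)
    return np.sign(r) * r ** 2


def grand_average(epochs: np.ndarray) -> np.ndarray:
    """Mean over epochs of a (n, channels, samples) stack."""
    arr = np.asarray(epochs, dtype=float)
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError("expected a nonempty (n, channels, samples) stack")
    return arr.mean(axis=0)


def roi_mean(avg: np.ndarray, window_ms: tuple[float, float], fs_hz: float) -> np.ndarray:
    """Per-channel mean of a (channels x samples) average within a time window.

    The window is [start_ms, end_ms] relative to epoch start; samples with
    start <= t <= end are averaged.
    """
    start_ms, end_ms = window_ms
    if not start_ms < end_ms:
        raise ValueError("window start must precede end")
    n_samples = avg.shape[-1]
    t_ms = 1000.0 * np.arange(n_samples) / fs_hz
    mask = (t_ms >= start_ms) & (t_ms <= end_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms contains no samples at fs={fs_hz}")
    return np.asarray(avg, dtype=float)[..., mask].mean(axis=-1)


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact null distribution of the positive-rank sum W+ given |d| ranks.

    Ranks are midranks (multiples of 0.5), doubled to integers; returns the
    probability vector over doubled sums 0..2*sum(ranks) and the doubled
    observed-scale factor.  Equivalent to enumerating all 2^n sign
    assignments.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = doubled.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    return dist, float(total)


def wilcoxon_signed_rank(differences: np.ndarray, exact_max_n: int = 25) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties among |d| are mid-ranked.  For up to
    ``exact_max_n`` informative pairs the p value is exact under the
    sign-flip null (all 2^n sign assignments of the observed ranks,
    two-sided by distance of W+ from its null mean); beyond that the normal
    approximation with tie correction is used.

    Returns a dict with ``statistic`` (W+), ``p``, ``n`` (informative pairs),
    and ``method``.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return {"statistic": 0.0, "p": 1.0, "n": 0, "method": "degenerate"}
    ranks = sps.rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        dist, total = _signed_rank_distribution(ranks)
        mean2 = total / 2.0  # null mean of the doubled statistic
        dev = abs(2 * w_plus - mean2)
        sums = np.arange(dist.size)
        p = float(dist[np.abs(sums - mean2) >= dev - 1e-9].sum())
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # variance with midrank tie correction: sum(r_i^2)/4
        var = float((ranks ** 2).sum()) / 4.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal"
    return {"statistic": w_plus, "p": min(1.0, p), "n": int(n), "method": method}


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher's exact test p for a 2x2 count table.

    Two-sidedness by the probability-mass rule: sum of hypergeometric
    probabilities of all tables with the same margins whose probability does
    not exceed the observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or t.sum() == 0:
        raise ValueError("need a 2x2 table of nonnegative counts with positive total")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> dict:
    """Spearman rank correlation with exact permutation p for small n.

    rho is the Pearson correlation of midranks.  For n <= ``exact_max_n``
    the two-sided p is the exact fraction of the n! permutations of y whose
    |rho| is at least the observed |rho|; for larger n the usual t
    approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        from itertools import permutations

        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c ** 2).sum())
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        ry_c = ry - ry.mean()
        ry_norm = np.sqrt((ry_c ** 2).sum())
        for perm in permutations(range(n)):
            r = float(rx_c @ ry_c[list(perm)]) / (denom * ry_norm)
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "asymptotic"
    return {"rho": rho, "p": float(min(1.0, p)), "n": int(n), "method": method}


def hit_rate(hits: int, misses: int) -> float:
    """Hit rate in percent, reported to one decimal place."""
    if hits < 0 or misses < 0:
        raise ValueError("counts must be nonnegative")
    total = hits + misses
    if total == 0:
        raise ValueError("hits + misses must be positive")
    return round(100.0 * hits / total, 1)
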