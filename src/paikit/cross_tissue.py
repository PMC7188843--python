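"""Cross-tissue comparison of PAI effect estimates.

Replication is assessed two ways: by p-value thresholds in the second
tissue (Bonferroni on the number of matched pairs, and nominal 0.05), and
threshold-free via the r_b estimator -- the correlation of *true* effects
between the two tissues, which corrects the naive Pearson correlation of
the estimates for their estimation-error variance.  With independent
cohorts (zero error covariance),

    r_b = cov(b1, b2) / sqrt[(var(b1) - mean(se1^2)) (var(b2) - mean(se2^2))],

with a leave-one-out jackknife over pairs for its standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("paikit")


@dataclass
class RbResult:
    rb: float
    se_rb: float
    n_pairs: int
    clamped: bool = False


def _rb_point(b1, se1, b2, se2) -> float:
    v1 = np.var(b1, ddof=1) - np.mean(se1 ** 2)
    v2 = np.var(b2, ddof=1) - np.mean(se2 ** 2)
    if v1 <= 0 or v2 <= 0:
        return np.nan
    return np.cov(b1, b2, ddof=1)[0, 1] / np.sqrt(v1 * v2)


def rb_estimate(b1, se1, b2, se2, error_corr: float = 0.0) -> RbResult:
    """Error-corrected correlation of effects between two tissues.

    ``error_corr`` is the correlation of estimation errors between the two
    data sets; it is 0 for independent cohorts and subtracts
    ``error_corr * mean(se1 * se2)`` from the covariance otherwise.
    """
    b1, se1 = np.asarray(b1, float), np.asarray(se1, float)
    b2, se2 = np.asarray(b2, float), np.asarray(se2, float)
    n = len(b1)
    if not (len(se1) == len(b2) == len(se2) == n):
        raise ValueError("effect/SE vectors must have equal length")
    if n < 3:
        raise ValueError("need >= 3 pairs for rb")

    def point(idx):
        v1 = np.var(b1[idx], ddof=1) - np.mean(se1[idx] ** 2)
        v2 = np.var(b2[idx], ddof=1) - np.mean(se2[idx] ** 2)
        if v1 <= 0 or v2 <= 0:
            return np.nan
        cov = (np.cov(b1[idx], b2[idx], ddof=1)[0, 1]
               - error_corr * np.mean(se1[idx] * se2[idx]))
        return cov / np.sqrt(v1 * v2)

    full = point(np.arange(n))
    if np.isnan(full):
        logger.info("rb: corrected variance <= 0; estimate undefined")
        return RbResult(np.nan, np.nan, n)

    jack = np.array([point(np.delete(np.arange(n), i)) for i in range(n)])
    jack = jack[~np.isnan(jack)]
    m = len(jack)
    se = float(np.sqrt((m - 1) / m * np.sum((jack - jack.mean()) ** 2))) if m > 1 else np.nan

    clamped = abs(full) > 1
    rb = float(np.clip(full, -1.0, 1.0))
    if clamped:
        logger.info("rb clamped from %.4f to %.1f", full, rb)
    return RbResult(rb=rb, se_rb=se, n_pairs=n, clamped=clamped)


def fisher_r_difference(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p for a difference between two Pearson correlations.

    Fisher z-transformation: z_k = atanh(r_k), var(z_k) = 1/(n_k - 3).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
        if n <= 3:
            raise ValueError("n must be > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(2 * stats.norm.sf(abs(z)))


def replication_summary(records_a: pd.DataFrame, records_b: pd.DataFrame,
                        alpha: float = 0.05, heidi_cut: float = 0.01) -> dict:
    """Replication of tissue-A significant PAIs in tissue B.

    ``records_a`` holds the significant PAIs of the discovery tissue;
    ``records_b`` the full scan of the replication tissue.  Records match on
    (expo_probe, outcome_probe); effect signs are assumed harmonised to a
    common allele coding upstream.  Returns counts/rates at the Bonferroni
    threshold alpha/n_available and at nominal p < 0.05 (both requiring
    p_HEIDI > ``heidi_cut`` in the replication tissue), plus the table of
    sign-discordant Bonferroni-replicated pairs.
    """
    key = ["expo_probe", "outcome_probe"]
    merged = records_a.merge(records_b, on=key, suffixes=("_a", "_b"))
    merged = merged[np.isfinite(merged["p_smr_b"])]
    n_avail = len(merged)
    if n_avail == 0:
        raise ValueError("no matched records between the two tissues")

    thr = alpha / n_avail
    heidi_ok = merged["p_heidi_b"] > heidi_cut
    bonf = (merged["p_smr_b"] < thr) & heidi_ok
    nominal = (merged["p_smr_b"] < 0.05) & heidi_ok
    discordant = merged[bonf & (np.sign(merged["b_xy_a"])
                                != np.sign(merged["b_xy_b"]))]
    return {
        "n_available": n_avail,
        "bonferroni_threshold": thr,
        "n_replicated_bonferroni": int(bonf.sum()),
        "n_replicated_nominal": int(nominal.sum()),
        "rate_bonferroni": float(bonf.mean()),
        "rate_nominal": float(nominal.mean()),
        "n_sign_discordant": int(len(discordant)),
        "sign_discordant": discordant[key + ["b_xy_a", "b_xy_b",
                                             "p_smr_b", "p_heidi_b"]],
    }
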