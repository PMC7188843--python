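"""Resampling- and contingency-based enrichment of predicted PAIs.

Every analysis follows the same recipe: compute an observed overlap (or
mean) statistic on the predicted set, draw ``n_sets`` matched control sets
from the universe of pairs/probes/genes actually tested in the scan, and
report fold enrichment (observed over null mean) with an empirical p-value
(r+1)/(R+1).  Matching is on pair distance (log10 bins), probe DNAm
variance (deciles) or gene-pair distance, mirroring how the controls are
constructed from the tested universe rather than from random genomic
positions.

Randomness: each analysis derives its own sub-seed from the pipeline seed
and the analysis name, so adding analyses never perturbs existing results.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import IntervalSet, PairSet

logger = logging.getLogger("paikit")


def derive_seed(seed: int, name: str) -> int:
    """Stable sub-seed for one named analysis (always < 2^31)."""
    return (int(seed) * 1_000_003 + zlib.crc32(name.encode())) % (2 ** 31)


@dataclass
class EnrichmentResult:
    observed: float
    null_mean: float
    null_sd: float
    n_sets: int
    fold: float
    empirical_p: float
    truncated: bool
    null_values: np.ndarray | None = None

    @property
    def display_p(self) -> str:
        return (f"< {1.0 / self.n_sets:g}" if self.truncated
                else f"{self.empirical_p:.4g}")


def empirical_enrichment(observed: float, null_values,
                         direction: str = "greater",
                         keep_null: bool = True) -> EnrichmentResult:
    """Empirical p and fold from a resampled null distribution.

    p = (#{null >= observed} + 1) / (R + 1) for enrichment ('greater'),
    with >= replaced by <= for depletion ('less').  With R = 1000 and no
    exceedances the p-value is truncated and displayed as "< 0.001".
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 1:
        raise ValueError("need at least one null value")
    R = null_values.size
    if direction == "greater":
        r = int(np.sum(null_values >= observed))
    elif direction == "less":
        r = int(np.sum(null_values <= observed))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    null_mean = float(null_values.mean())
    fold = observed / null_mean if null_mean != 0 else np.nan
    if null_mean == 0:
        logger.info("null mean is 0; fold enrichment undefined")
    return EnrichmentResult(
        observed=float(observed), null_mean=null_mean,
        null_sd=float(null_values.std(ddof=1)) if R > 1 else 0.0,
        n_sets=R, fold=fold, empirical_p=(r + 1) / (R + 1),
        truncated=(r == 0),
        null_values=null_values if keep_null else None)


# ---------------------------------------------------------------------------
# matched control sampling
# ---------------------------------------------------------------------------

def log_distance_bins(values, edges=None, n_bins: int = 20):
    """Bin positive values by log10 into equal-width bins over their range."""
    values = np.asarray(values, dtype=float)
    logs = np.log10(np.clip(values, 1.0, None))
    if edges is None:
        lo, hi = logs.min(), logs.max()
        if hi <= lo:
            hi = lo + 1e-9
        edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.digitize(logs, edges[1:-1]), 0, len(edges) - 2)
    return bins, edges


def decile_bins(values, edges=None):
    """Bin values into deciles of the reference distribution."""
    values = np.asarray(values, dtype=float)
    if edges is None:
        edges = np.quantile(values, np.linspace(0, 1, 11))
    bins = np.clip(np.digitize(values, edges[1:-1]), 0, 9)
    return bins, edges


def sample_matched_controls(target_bins, universe_bins, n_sets: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Sample ``n_sets`` control index sets matched on bin membership.

    Returns an (n_sets, n_targets) array of indices into the universe.  A
    target whose bin is empty in the universe escalates to the nearest
    non-empty adjacent bins (widening by one bin on both sides per step).
    """
    target_bins = np.asarray(target_bins)
    universe_bins = np.asarray(universe_bins)
    members = {b: np.nonzero(universe_bins == b)[0]
               for b in np.unique(universe_bins)}
    n_bins_max = int(max(target_bins.max(initial=0),
                         universe_bins.max(initial=0))) + 1

    pool_for = {}
    for b in np.unique(target_bins):
        pool = members.get(b, np.empty(0, dtype=int))
        width = 0
        while pool.size == 0 and width <= n_bins_max:
            width += 1
            lo, hi = b - width, b + width
            pool = np.nonzero((universe_bins >= lo) & (universe_bins <= hi))[0]
            if pool.size:
                logger.info("empty bin %d widened by %d", b, width)
        if pool.size == 0:
            raise ValueError(f"no universe members near bin {b}")
        pool_for[b] = pool

    out = np.empty((n_sets, len(target_bins)), dtype=int)
    for j, b in enumerate(target_bins):
        pool = pool_for[b]
        out[:, j] = pool[rng.integers(0, pool.size, size=n_sets)]
    return out


# ---------------------------------------------------------------------------
# overlap counters
# ---------------------------------------------------------------------------

def pair_in_same_tad(pairs: pd.DataFrame, tads: IntervalSet,
                     mode: str = "same") -> np.ndarray:
    """Indicator per probe pair: both positions inside one TAD.

    ``mode='same'`` (default) requires a single TAD interval to contain
    both 1-based positions; ``mode='any'`` only requires each position to
    fall in some TAD.
    """
    if mode == "any":
        a = tads.contains_points(pairs["chrom"].astype(str), pairs["bp1"])
        b = tads.contains_points(pairs["chrom"].astype(str), pairs["bp2"])
        return a & b
    if mode != "same":
        raise ValueError(f"unknown TAD mode {mode!r}")
    out = np.zeros(len(pairs), dtype=bool)
    for i, (_, row) in enumerate(pairs.iterrows()):
        out[i] = tads.contains_pair_same_interval(
            str(row["chrom"]), int(row["bp1"]), int(row["bp2"]))
    return out


def pair_overlap_tads(pairs: pd.DataFrame, tads: IntervalSet,
                      mode: str = "same") -> int:
    """Number of probe pairs located within a TAD."""
    return int(pair_in_same_tad(pairs, tads, mode=mode).sum())


def pair_in_loop(pairs: pd.DataFrame, loops: PairSet, pad: int = 0,
                 loop_mask=None) -> np.ndarray:
    """Indicator per probe pair: the two probes sit in the two anchors
    (padded by ``pad`` bp on each side) of one loop, in either orientation."""
    ldf = loops.df if loop_mask is None else loops.df[loop_mask]
    out = np.zeros(len(pairs), dtype=bool)
    if ldf.empty:
        return out
    s1 = ldf["start1"].to_numpy() - pad
    e1 = ldf["end1"].to_numpy() + pad
    s2 = ldf["start2"].to_numpy() - pad
    e2 = ldf["end2"].to_numpy() + pad
    c1 = ldf["chrom1"].to_numpy(dtype=object)
    c2 = ldf["chrom2"].to_numpy(dtype=object)
    for i, (_, row) in enumerate(pairs.iterrows()):
        chrom = str(row["chrom"])
        p, q = int(row["bp1"]) - 1, int(row["bp2"]) - 1
        same = (c1 == chrom) & (c2 == chrom)
        in_a1_p = (s1 <= p) & (p < e1)
        in_a2_q = (s2 <= q) & (q < e2)
        in_a1_q = (s1 <= q) & (q < e1)
        in_a2_p = (s2 <= p) & (p < e2)
        hit = same & ((in_a1_p & in_a2_q) | (in_a1_q & in_a2_p))
        # the two probes must sit in *different* anchors of the loop
        both_same_anchor = same & (((in_a1_p & in_a1_q) & ~(in_a2_p | in_a2_q))
                                   | ((in_a2_p & in_a2_q) & ~(in_a1_p | in_a1_q)))
        out[i] = bool(np.any(hit & ~both_same_anchor)) if np.any(hit) else False
    return out


def pair_overlap_loops(pairs: pd.DataFrame, loops: PairSet, pad: int = 0) -> int:
    return int(pair_in_loop(pairs, loops, pad=pad).sum())


def site_window_overlap(sites: pd.DataFrame, features: IntervalSet,
                        window: int = 10_000) -> int:
    """Sites whose centred window (``window`` bp total) hits >= 1 feature."""
    if window <= 0:
        raise ValueError("window must be positive")
    half = window // 2
    pos0 = sites["bp"].to_numpy(dtype=np.int64) - 1
    hit = features.overlaps_windows(sites["chrom"].astype(str),
                                    pos0 - half, pos0 + half + 1)
    return int(hit.sum())


def site_in_window(sites: pd.DataFrame, features: IntervalSet,
                   window: int = 10_000) -> np.ndarray:
    half = window // 2
    pos0 = sites["bp"].to_numpy(dtype=np.int64) - 1
    return features.overlaps_windows(sites["chrom"].astype(str),
                                     pos0 - half, pos0 + half + 1)


# ---------------------------------------------------------------------------
# enrichment drivers
# ---------------------------------------------------------------------------

def _resampled_counts(indicator: np.ndarray, control_idx: np.ndarray) -> np.ndarray:
    return indicator[control_idx].sum(axis=1)


def pairs_tad_enrichment(pai_pairs: pd.DataFrame, universe_pairs: pd.DataFrame,
                         tads: IntervalSet, n_sets: int = 1000, seed: int = 0,
                         mode: str = "same", n_bins: int = 20) -> EnrichmentResult:
    """Distance-matched resampling enrichment of PAIs within TADs."""
    rng = np.random.default_rng(derive_seed(seed, "tads"))
    indicator = pair_in_same_tad(universe_pairs, tads, mode=mode)
    observed = pair_overlap_tads(pai_pairs, tads, mode=mode)
    ubins, edges = log_distance_bins(universe_pairs["distance"], n_bins=n_bins)
    tbins, _ = log_distance_bins(pai_pairs["distance"], edges=edges)
    idx = sample_matched_controls(tbins, ubins, n_sets, rng)
    return empirical_enrichment(observed, _resampled_counts(indicator, idx))


def pairs_loop_enrichment(pai_pairs: pd.DataFrame, universe_pairs: pd.DataFrame,
                          loops: PairSet, n_sets: int = 1000, seed: int = 0,
                          pad: int = 0, n_bins: int = 20) -> EnrichmentResult:
    rng = np.random.default_rng(derive_seed(seed, "loops"))
    indicator = pair_in_loop(universe_pairs, loops, pad=pad)
    observed = pair_overlap_loops(pai_pairs, loops, pad=pad)
    ubins, edges = log_distance_bins(universe_pairs["distance"], n_bins=n_bins)
    tbins, _ = log_distance_bins(pai_pairs["distance"], edges=edges)
    idx = sample_matched_controls(tbins, ubins, n_sets, rng)
    return empirical_enrichment(observed, _resampled_counts(indicator, idx))


def fisher_loop_enrichment(predicted_pairs: pd.DataFrame,
                           universe_pairs: pd.DataFrame, loops: PairSet,
                           p_thresholds, pad: int = 0) -> pd.DataFrame:
    """Fold enrichment of predicted pairs in significant loops, per loop
    p-value threshold, with Fisher's exact test on the 2x2 table.

    The counting unit is the probe pair (reported explicitly in the
    ``unit`` column).  fold = P(in loop | predicted) / P(in loop | universe);
    its 95% CI uses the normal approximation on the log ratio.
    """
    pred_key = set(zip(predicted_pairs["chrom"].astype(str),
                       predicted_pairs["bp1"], predicted_pairs["bp2"]))
    is_pred = np.array([(c, b1, b2) in pred_key for c, b1, b2 in
                        zip(universe_pairs["chrom"].astype(str),
                            universe_pairs["bp1"], universe_pairs["bp2"])])
    rows = []
    for t in p_thresholds:
        mask = loops.df["p"].to_numpy() < t
        hit = pair_in_loop(universe_pairs, loops, pad=pad, loop_mask=mask)
        a = int((hit & is_pred).sum())
        b = int((~hit & is_pred).sum())
        c = int((hit & ~is_pred).sum())
        d = int((~hit & ~is_pred).sum())
        N = a + b + c + d
        if min(a + b, a + c) == 0 or N == 0:
            rows.append(dict(threshold=t, a=a, b=b, c=c, d=d, fold=np.nan,
                             ci_lo=np.nan, ci_hi=np.nan, p=np.nan, unit="probe_pair"))
            continue
        fold = (a / (a + b)) / ((a + c) / N)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if a > 0:
            se = np.sqrt(1 / a - 1 / (a + b) + 1 / (a + c) - 1 / N)
            ci = (fold * np.exp(-1.96 * se), fold * np.exp(1.96 * se))
        else:
            ci = (np.nan, np.nan)
        rows.append(dict(threshold=t, a=a, b=b, c=c, d=d, fold=fold,
                         ci_lo=ci[0], ci_hi=ci[1], p=p, unit="probe_pair"))
    return pd.DataFrame(rows)


def pids_state_enrichment(pids_probes: pd.DataFrame, states: IntervalSet,
                          universe_probes: pd.DataFrame, n_sets: int = 1000,
                          seed: int = 0) -> dict[str, EnrichmentResult]:
    """Per-chromatin-state enrichment of PIDSs vs variance-matched controls.

    Probes are assigned the state tiling their position ('unannotated' when
    none).  Controls are resampled from the tested universe within deciles
    of DNAm variance.  Proportions across states plus 'unannotated' sum to
    one in every set.
    """
    rng = np.random.default_rng(derive_seed(seed, "states"))
    ulabels = states.labels_at_points(universe_probes["chrom"].astype(str),
                                      universe_probes["bp"])
    tlabels = states.labels_at_points(pids_probes["chrom"].astype(str),
                                      pids_probes["bp"])
    ubins, edges = decile_bins(universe_probes["dnam_variance"])
    tbins, _ = decile_bins(pids_probes["dnam_variance"], edges=edges)
    idx = sample_matched_controls(tbins, ubins, n_sets, rng)

    n_t = len(pids_probes)
    out = {}
    for state in sorted(set(ulabels) | set(tlabels)):
        obs = float(np.mean(tlabels == state))
        null = (ulabels[idx] == state).mean(axis=1)
        out[state] = empirical_enrichment(obs, null)
    return out


def eqtl_pids_enrichment(eqtls: pd.DataFrame, pai_pairs: pd.DataFrame,
                         universe_pairs: pd.DataFrame, n_sets: int = 1000,
                         seed: int = 0, window: int = 10_000,
                         n_bins: int = 20) -> EnrichmentResult:
    """Enrichment of cis-eQTLs in the PIDS windows of their own gene.

    ``pai_pairs``/``universe_pairs`` carry gene_label (the bait promoter's
    gene), chrom, bp2 (the outcome probe / PIDS position) and distance.
    An eQTL counts when it lies within the centred window of a PIDS whose
    bait gene is the eQTL's target gene; distinct eQTLs are counted once.
    The null resamples distance-matched gene-probe pairs from the universe.
    """
    rng = np.random.default_rng(derive_seed(seed, "eqtl"))
    half = window // 2
    by_gene = {g: sub for g, sub in eqtls.groupby("gene_label")}

    def hit_sets(pairs: pd.DataFrame) -> list[np.ndarray]:
        hits = []
        for _, row in pairs.iterrows():
            sub = by_gene.get(row["gene_label"])
            if sub is None:
                hits.append(np.empty(0, dtype=int))
                continue
            m = ((sub["chrom"].astype(str) == str(row["chrom"]))
                 & ((sub["bp"] - int(row["bp2"])).abs() <= half))
            hits.append(sub.index.to_numpy()[m.to_numpy()])
        return hits

    uhits = hit_sets(universe_pairs)
    observed = len(np.unique(np.concatenate(hit_sets(pai_pairs) or
                                            [np.empty(0, dtype=int)])))
    ubins, edges = log_distance_bins(universe_pairs["distance"], n_bins=n_bins)
    tbins, _ = log_distance_bins(pai_pairs["distance"], edges=edges)
    idx = sample_matched_controls(tbins, ubins, n_sets, rng)
    null = np.empty(n_sets)
    for s in range(n_sets):
        sets = [uhits[j] for j in idx[s]]
        null[s] = len(np.unique(np.concatenate(sets))) if sets else 0
    return empirical_enrichment(observed, null)


def expression_group_enrichment(genes_of_interest, tpm: pd.DataFrame,
                                universe_genes, n_sets: int = 1000,
                                seed: int = 0,
                                inactive_tpm: float = 0.1) -> dict[str, EnrichmentResult]:
    """Enrichment of genes across five activity groups.

    Median TPM across samples defines a gene's expression level; genes below
    ``inactive_tpm`` form the inactive group and active genes are split into
    quartiles (Q1..Q4) of their expression.  Controls are plain resamples of
    the universe (gene activity is the quantity under test, so no matching).
    """
    rng = np.random.default_rng(derive_seed(seed, "expression"))
    med = tpm.median(axis=1)
    universe = [g for g in universe_genes if g in med.index]
    interest = [g for g in genes_of_interest if g in med.index]
    n_missing = len(list(genes_of_interest)) - len(interest)
    if n_missing:
        logger.info("expression enrichment: %d genes missing from matrix",
                    n_missing)

    active = med[med >= inactive_tpm]
    qedges = np.quantile(active, [0.25, 0.5, 0.75]) if len(active) else []

    def group_of(g):
        v = med[g]
        if v < inactive_tpm:
            return "inactive"
        return f"Q{int(np.digitize(v, qedges)) + 1}"

    groups = ["inactive", "Q1", "Q2", "Q3", "Q4"]
    ugroups = np.array([group_of(g) for g in universe])
    igroups = np.array([group_of(g) for g in interest])
    idx = rng.integers(0, len(universe), size=(n_sets, len(interest)))
    out = {}
    for grp in groups:
        obs = int(np.sum(igroups == grp))
        null = (ugroups[idx] == grp).sum(axis=1)
        out[grp] = empirical_enrichment(obs, null)
    return out


def coexpression_enrichment(gene_pairs: pd.DataFrame, tpm: pd.DataFrame,
                            universe_pairs: pd.DataFrame, n_sets: int = 1000,
                            seed: int = 0, n_bins: int = 20) -> EnrichmentResult:
    """Mean expression correlation of gene pairs vs distance-matched nulls.

    ``gene_pairs``/``universe_pairs`` carry gene1, gene2 and distance (the
    separation of the two promoter probes).  Pairs with a gene missing from
    the matrix or with zero expression variance are dropped with a log entry.
    """
    rng = np.random.default_rng(derive_seed(seed, "coexpression"))
    X = tpm.to_numpy(dtype=float)
    sd = X.std(axis=1)
    ok_gene = dict(zip(tpm.index, sd > 0))
    gene_row = {g: i for i, g in enumerate(tpm.index)}
    Z = X - X.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = Z / Z.std(axis=1, keepdims=True)

    def pair_r(pairs: pd.DataFrame) -> np.ndarray:
        rs = np.full(len(pairs), np.nan)
        for i, (_, row) in enumerate(pairs.iterrows()):
            g1, g2 = row["gene1"], row["gene2"]
            if not (ok_gene.get(g1) and ok_gene.get(g2)):
                logger.info("co-expression: pair (%s,%s) dropped", g1, g2)
                continue
            rs[i] = np.mean(Z[gene_row[g1]] * Z[gene_row[g2]])
        return rs

    ur = pair_r(universe_pairs)
    tr = pair_r(gene_pairs)
    observed = float(np.nanmean(tr))
    ubins, edges = log_distance_bins(universe_pairs["distance"], n_bins=n_bins)
    tbins, _ = log_distance_bins(gene_pairs["distance"], edges=edges)
    keep = ~np.isnan(ur)
    # restrict the universe to resolvable pairs before resampling
    idx = sample_matched_controls(tbins, ubins[keep], n_sets, rng)
    urk = ur[keep]
    null = urk[idx].mean(axis=1)
    return empirical_enrichment(observed, null)


def sites_feature_enrichment(sites: pd.DataFrame, universe_sites: pd.DataFrame,
                             features: IntervalSet, n_sets: int = 1000,
                             seed: int = 0, window: int = 10_000,
                             name: str = "chip") -> EnrichmentResult:
    """Window-overlap enrichment of PAI DNAm sites in ChIP peaks (or any
    point-feature annotation, e.g. allele-specific-DNAm variants)."""
    rng = np.random.default_rng(derive_seed(seed, name))
    indicator = site_in_window(universe_sites, features, window=window)
    observed = site_window_overlap(sites, features, window=window)
    idx = rng.integers(0, len(universe_sites), size=(n_sets, len(sites)))
    return empirical_enrichment(observed, indicator[idx].sum(axis=1))
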