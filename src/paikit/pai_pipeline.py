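"""Genome-wide promoter-anchored interaction (PAI) scan.

A *bait* is a promoter DNAm probe with at least one genome-wide significant
cis-mQTL instrument.  Each bait is tested as the exposure against every
other probe within the pair window on the same chromosome (excluding probes
inside the bait's own promoter), with the SMR ratio test on the bait's top
instrument followed by the HEIDI heterogeneity test on the LD-pruned
instrument set.  Significance is a Bonferroni bound on the number of pairs
actually tested, and a predicted PAI additionally requires that HEIDI does
not reject homogeneity (p_HEIDI above the cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AssocStat, IntervalSet, MqtlTable, ProbeMeta, SnpMeta
from .smr_heidi import (HeidiResult, SmrResult, align_alleles, heidi_covariance,
                        heidi_select_snps, heidi_test, smr_test, top_instrument,
                        variance_explained)

logger = logging.getLogger("paikit")


@dataclass
class ScanConfig:
    cis_window: int = 2_000_000
    pair_window: int = 2_000_000
    instrument_p: float = 5e-8
    alpha: float = 0.05
    heidi_cutoff: float = 0.01
    heidi_p_include: float = 1.57e-3
    heidi_r2_cap: float = 0.9
    heidi_r2_min: float = 0.05
    heidi_max_snps: int = 20
    heidi_min_snps: int = 3
    heidi_method: str = "satterthwaite"
    heidi_na_passes: bool = False     # NA HEIDI => not a PAI (conservative)
    ambiguous_policy: str = "keep"
    blacklist: IntervalSet | None = None

    def __post_init__(self):
        if self.cis_window <= 0 or self.pair_window <= 0:
            raise ValueError("windows must be positive")
        for t in (self.instrument_p, self.alpha, self.heidi_cutoff):
            if not (0 < t < 1):
                raise ValueError("thresholds must be in (0,1)")

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class PaiRecord:
    exposure: ProbeMeta
    outcome: ProbeMeta
    smr: SmrResult | None
    heidi: HeidiResult | None
    distance: int
    pass_smr: bool = False
    pass_heidi: bool = False
    note: str = ""

    @property
    def p_smr(self) -> float:
        return self.smr.p_smr if self.smr is not None else np.nan

    @property
    def p_heidi(self) -> float:
        return self.heidi.p_heidi if self.heidi is not None else np.nan


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance bound alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# bait definition and pair enumeration
# ---------------------------------------------------------------------------

def _probe_meta_from_row(row) -> ProbeMeta:
    return ProbeMeta(
        probe_id=row["probe_id"], chrom=str(row["chrom"]), bp=int(row["bp"]),
        gene_label=row.get("gene_label"),
        is_promoter=bool(row.get("is_promoter", False)),
        dnam_variance=float(row.get("dnam_variance", 0.0)),
    )


def annotate_probes(probes: pd.DataFrame, mqtl: MqtlTable,
                    promoters: IntervalSet, cfg: ScanConfig) -> pd.DataFrame:
    """Attach promoter membership, top instrument and q2 to the probe table."""
    probes = probes.copy()
    probes["in_promoter"] = promoters.contains_points(
        probes["chrom"].astype(str), probes["bp"])
    if cfg.blacklist is not None:
        probes["blacklisted"] = cfg.blacklist.contains_points(
            probes["chrom"].astype(str), probes["bp"])
    else:
        probes["blacklisted"] = False

    tops, q2s, top_ps = [], [], []
    groups = dict(tuple(mqtl.df.groupby("probe_id", sort=False)))
    for _, row in probes.iterrows():
        sub = groups.get(row["probe_id"])
        top = top_instrument(sub, cfg.instrument_p) if sub is not None else None
        if top is None:
            tops.append(None); q2s.append(np.nan); top_ps.append(np.nan)
            continue
        srow = sub[sub["snp_id"] == top.snp_id].iloc[0]
        stat = AssocStat(float(srow["b"]), float(srow["se"]), float(srow["p"]),
                         None if pd.isna(srow["n"]) else int(srow["n"]))
        try:
            q2 = variance_explained(stat, top)
        except ValueError:
            q2 = np.nan
            logger.info("%s: q^2 undefined (no freq, no n)", row["probe_id"])
        tops.append(top); q2s.append(q2); top_ps.append(stat.p)
    probes["top_snp"] = tops
    probes["top_cis_q2"] = q2s
    probes["top_p"] = top_ps
    return probes


def define_baits(probes: pd.DataFrame, mqtl: MqtlTable,
                 promoters: IntervalSet, cfg: ScanConfig) -> pd.DataFrame:
    """Promoter probes with a significant instrument, outside the blacklist."""
    ann = annotate_probes(probes, mqtl, promoters, cfg)
    baits = ann[ann["in_promoter"] & ~ann["blacklisted"]
                & ann["top_snp"].notna()]
    if baits.empty:
        raise RuntimeError(
            "no baits: no promoter probe has an instrument at "
            f"p < {cfg.instrument_p:g} outside the blacklist")
    return baits.sort_values(["chrom", "bp", "probe_id"],
                             kind="mergesort").reset_index(drop=True)


def enumerate_pairs(bait, probes: pd.DataFrame, promoters: IntervalSet,
                    cfg: ScanConfig) -> pd.DataFrame:
    """Candidate outcome probes for one bait.

    Same chromosome, within the pair window, excluding the bait itself and
    any probe lying in a promoter interval that also contains the bait.
    """
    own = promoters.intervals_at(str(bait["chrom"]), int(bait["bp"]))
    same = probes["chrom"].astype(str) == str(bait["chrom"])
    near = (probes["bp"] - int(bait["bp"])).abs() <= cfg.pair_window
    cand = probes[same & near & (probes["probe_id"] != bait["probe_id"])]
    if len(own):
        pos0 = cand["bp"].to_numpy() - 1
        in_own = np.zeros(len(cand), dtype=bool)
        for _, iv in own.iterrows():
            in_own |= (pos0 >= iv["start"]) & (pos0 < iv["end"])
        cand = cand[~in_own]
    return cand


def orient_promoter_pair(probe_a, probe_b):
    """Choose the exposure for a promoter-promoter pair.

    The probe whose top cis-mQTL explains more DNAm variance is the
    exposure; ties break by smaller top-instrument p, then smaller bp.
    """
    qa = probe_a.get("top_cis_q2", np.nan)
    qb = probe_b.get("top_cis_q2", np.nan)
    if pd.isna(qa) or pd.isna(qb):
        logger.info("q^2 undefined for %s/%s; orienting by instrument p",
                    probe_a["probe_id"], probe_b["probe_id"])
        key_a = (probe_a.get("top_p", np.inf), probe_a["bp"])
        key_b = (probe_b.get("top_p", np.inf), probe_b["bp"])
        return (probe_a, probe_b) if key_a <= key_b else (probe_b, probe_a)
    if qa != qb:
        return (probe_a, probe_b) if qa > qb else (probe_b, probe_a)
    key_a = (probe_a.get("top_p", np.inf), probe_a["bp"])
    key_b = (probe_b.get("top_p", np.inf), probe_b["bp"])
    return (probe_a, probe_b) if key_a <= key_b else (probe_b, probe_a)


# ---------------------------------------------------------------------------
# per-pair test
# ---------------------------------------------------------------------------

def _stats_dicts(df: pd.DataFrame):
    metas, stats_ = {}, {}
    for _, r in df.iterrows():
        if r["b"] == 0 or not (r["se"] > 0):
            continue
        metas[r["snp_id"]] = SnpMeta(
            r["snp_id"], str(r["snp_chr"]), int(r["snp_bp"]), r["a1"], r["a2"],
            None if pd.isna(r.get("freq", np.nan)) else float(r["freq"]))
        stats_[r["snp_id"]] = AssocStat(
            float(r["b"]), float(r["se"]), float(r["p"]),
            None if pd.isna(r["n"]) else int(r["n"]))
    return metas, stats_


def test_pair(expo_stats: pd.DataFrame, outc_stats: pd.DataFrame,
              top: SnpMeta, ld_source, cfg: ScanConfig):
    """SMR + HEIDI for one exposure-outcome probe pair.

    Returns (SmrResult | None, HeidiResult | None, note).
    """
    # only the top instrument and HEIDI candidates are ever used; trimming
    # here keeps per-pair work proportional to the instrument set
    cand_ids = set(expo_stats.loc[expo_stats["p"] < cfg.heidi_p_include,
                                  "snp_id"])
    cand_ids.add(top.snp_id)
    expo_stats = expo_stats[expo_stats["snp_id"].isin(cand_ids)]
    outc_stats = outc_stats[outc_stats["snp_id"].isin(cand_ids)]
    expo_meta, expo_assoc = _stats_dicts(expo_stats)
    outc_meta_raw, outc_assoc_raw = _stats_dicts(outc_stats)

    # harmonise outcome records to the exposure allele coding
    outc_assoc = {}
    for sid, meta in expo_meta.items():
        if sid not in outc_assoc_raw:
            continue
        rec = align_alleles((outc_meta_raw[sid], outc_assoc_raw[sid]),
                            (meta.a1, meta.a2), cfg.ambiguous_policy)
        if rec is not None:
            outc_assoc[sid] = rec[1]

    if top.snp_id not in expo_assoc:
        return None, None, "top instrument lost in validation"
    if top.snp_id not in outc_assoc:
        return None, None, "top instrument absent from outcome stats"

    smr = smr_test(expo_assoc[top.snp_id], outc_assoc[top.snp_id], top_snp=top)

    # HEIDI candidates: exposure SNPs below the inclusion threshold with
    # outcome stats and LD coverage
    cand = expo_stats[(expo_stats["p"] < cfg.heidi_p_include)
                      & expo_stats["snp_id"].isin(outc_assoc)]
    ids = [s for s in cand["snp_id"] if s in expo_assoc]
    ids = ld_source.available(ids) if hasattr(ld_source, "available") else ids
    if top.snp_id not in ids:
        return smr, HeidiResult(1, None, None, np.nan), "no LD for top SNP"
    try:
        ld = ld_source.ld_matrix([expo_meta[s] for s in ids])
    except ValueError as exc:
        return smr, HeidiResult(0, None, None, np.nan), f"LD failure: {exc}"

    snps = heidi_select_snps(
        cand[cand["snp_id"].isin(ids)], ld, top.snp_id,
        p_include=cfg.heidi_p_include, r2_cap=cfg.heidi_r2_cap,
        max_snps=cfg.heidi_max_snps, r2_min=cfg.heidi_r2_min,
        min_snps=cfg.heidi_min_snps)
    if len(snps) < cfg.heidi_min_snps:
        return smr, HeidiResult(len(snps), None, None, np.nan), "too few HEIDI instruments"
    try:
        d, V = heidi_covariance(snps, expo_assoc, outc_assoc, ld)
    except (ZeroDivisionError, ValueError) as exc:
        return smr, HeidiResult(len(snps), None, None, np.nan), f"degenerate V: {exc}"
    p = heidi_test(d, V, method=cfg.heidi_method)
    return smr, HeidiResult(len(snps), d, V, p), ""


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def run_pai_scan(mqtl: MqtlTable, probes: pd.DataFrame, promoters: IntervalSet,
                 ld_source, cfg: ScanConfig | None = None,
                 seed: int = 0) -> list[PaiRecord]:
    """Run the full bait x candidate scan; deterministic given inputs.

    Per-pair failures (missing outcome stats, degenerate covariance) are
    recorded on the record's ``note`` and never abort the scan.
    """
    cfg = cfg or ScanConfig()
    ann = annotate_probes(probes, mqtl, promoters, cfg)
    baits = ann[ann["in_promoter"] & ~ann["blacklisted"] & ann["top_snp"].notna()]
    if baits.empty:
        raise RuntimeError("no baits available for the scan")
    baits = baits.sort_values(["chrom", "bp", "probe_id"], kind="mergesort")
    bait_ids = set(baits["probe_id"])

    groups = dict(tuple(mqtl.df.groupby("probe_id", sort=False)))
    records: list[PaiRecord] = []
    for _, bait in baits.iterrows():
        cands = enumerate_pairs(bait, ann, promoters, cfg)
        for _, cand in cands.iterrows():
            if cand["probe_id"] in bait_ids:
                expo, outc = orient_promoter_pair(bait, cand)
                if expo["probe_id"] != bait["probe_id"]:
                    continue  # tested from the other bait (deduplication)
            else:
                expo, outc = bait, cand
            expo_stats = groups.get(expo["probe_id"])
            outc_stats = groups.get(outc["probe_id"])
            e_meta = _probe_meta_from_row(expo)
            o_meta = _probe_meta_from_row(outc)
            e_meta.top_cis_q2 = expo.get("top_cis_q2")
            dist = abs(int(expo["bp"]) - int(outc["bp"]))
            if outc_stats is None or outc_stats.empty:
                records.append(PaiRecord(e_meta, o_meta, None, None, dist,
                                         note="no outcome summary statistics"))
                continue
            smr, heidi, note = test_pair(expo_stats, outc_stats,
                                         expo["top_snp"], ld_source, cfg)
            records.append(PaiRecord(e_meta, o_meta, smr, heidi, dist, note=note))
    return records


def classify_significant(records: list[PaiRecord],
                         cfg: ScanConfig | None = None) -> list[PaiRecord]:
    """Set pass flags: Bonferroni on the tested-pair count, HEIDI cutoff."""
    cfg = cfg or ScanConfig()
    tested = [r for r in records if r.smr is not None and np.isfinite(r.p_smr)]
    if tested:
        thr = bonferroni_threshold(len(tested), cfg.alpha)
    for r in records:
        if r.smr is None or not np.isfinite(r.p_smr):
            r.pass_smr = False
            r.pass_heidi = False
            continue
        r.pass_smr = r.p_smr < thr
        if r.heidi is None or not np.isfinite(r.p_heidi):
            r.pass_heidi = bool(cfg.heidi_na_passes)
        else:
            r.pass_heidi = r.p_heidi > cfg.heidi_cutoff
    return records


def summarize_pais(records: list[PaiRecord]) -> dict:
    """Counts and distance summaries of the significant PAIs."""
    pais = [r for r in records if r.pass_smr and r.pass_heidi]
    out = {
        "n_tested": sum(1 for r in records
                        if r.smr is not None and np.isfinite(r.p_smr)),
        "n_pai": len(pais),
    }
    if not pais:
        out.update({"n_unique_probes": 0, "n_unique_exposures": 0,
                    "n_genes": 0, "outcomes_per_bait_mean": np.nan,
                    "outcomes_per_bait_median": np.nan,
                    "distance_mean": np.nan, "distance_median": np.nan,
                    "distance_q95": np.nan, "fraction_gt_1mb": np.nan})
        return out
    expo_ids = [r.exposure.probe_id for r in pais]
    probe_ids = expo_ids + [r.outcome.probe_id for r in pais]
    genes = {r.exposure.gene_label for r in pais if r.exposure.gene_label}
    dists = np.array([r.distance for r in pais], dtype=float)
    per_bait = pd.Series(expo_ids).value_counts()
    out.update({
        "n_unique_probes": len(set(probe_ids)),
        "n_unique_exposures": len(set(expo_ids)),
        "n_genes": len(genes),
        "outcomes_per_bait_mean": float(per_bait.mean()),
        "outcomes_per_bait_median": float(per_bait.median()),
        "distance_mean": float(dists.mean()),
        "distance_median": float(np.quantile(dists, 0.5)),
        "distance_q95": float(np.quantile(dists, 0.95)),
        "fraction_gt_1mb": float((dists > 1_000_000).mean()),
    })
    return out
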