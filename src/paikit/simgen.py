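"""Synthetic cohorts, fixtures and calibration experiments.

The generator reproduces the statistical structure the PAI method assumes,
not human genome realism: LD-structured diploid genotypes from paired
first-order Markov haplotypes (closed-form LD decay rho^|i-j|), continuous
standardised methylation phenotypes, and per-SNP OLS summary statistics in
SD units.  Three generative scenarios cover the method's causal diagrams:

pleiotropy    x = beta * g_c + e_x (variance explained q2),
              y = b_xy * x + e_y                  -- one shared causal SNP
linkage       x driven by g_c1, y independently by g_c2,
              corr(g_c1, g_c2) = r_link           -- LD, no shared variant
null_overlap  x as above; y = gamma * e_x + e_y   -- correlated residuals
              with corr(x, y) = r_p and *no* genetic effect on y, the
              worst case for sample overlap between exposure and outcome
              scans drawn from the same cohort.

All phenotypes are standardised to unit variance, matching SD-unit effect
sizes throughout the pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import IntervalSet, MQTL_COLUMNS
from .pai_pipeline import ScanConfig, test_pair
from .smr_heidi import GenotypeLdSource, top_instrument

logger = logging.getLogger("paikit")

STATE_LABELS = ["TssA", "Prom", "Tx", "TxWk", "TxEn", "EnhA", "EnhW",
                "DNase", "ZNF/Rpts", "Het", "PromP", "PromBiv", "ReprPC",
                "Quies"]


@dataclass
class SimScenario:
    """Generative parameters for one exposure/outcome methylation pair."""

    kind: str = "pleiotropy"          # pleiotropy | linkage | null_overlap
    n: int = 2000
    m: int = 100
    ld_decay: float = 0.8
    maf_range: tuple = (0.1, 0.5)
    q2: float = 0.1                   # variance explained on the exposure
    q2_outcome: float | None = None   # linkage only; defaults to q2
    b_xy: float = 0.0                 # pleiotropy only
    r_link: float = 0.0               # linkage only: r between causal SNPs
    r_p: float = 0.0                  # null_overlap only
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.q2 < 1):
            raise ValueError("q2 must be in [0,1)")
        if abs(self.b_xy) > np.sqrt(1.0 / max(self.q2, 1e-12)) and self.kind == "pleiotropy":
            pass  # bound enforced at generation time (outcome variance <= 1)
        if self.kind == "null_overlap" and not (-1 < self.r_p < 1):
            raise ValueError("r_p must be in (-1,1)")


@dataclass
class SimCohort:
    genotypes: np.ndarray             # n x m allele counts
    exposure: np.ndarray
    outcome: np.ndarray
    causal: list                      # causal SNP column indices
    scenario: SimScenario
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(n: int, m: int, ld_decay: float = 0.8,
                       maf_range=(0.1, 0.5), seed=None,
                       rng: np.random.Generator | None = None,
                       return_freqs: bool = False):
    """Diploid allele counts with Markov-chain LD decay.

    2n haplotypes are built site by site: site j copies site j-1 with
    probability rho (= ``ld_decay``) and otherwise draws a fresh allele
    whose frequency is corrected so the marginal stays at the target MAF.
    The resulting haplotype covariance is cov(i,j) = rho^|i-j| f_i (1-f_i)
    for i < j, so the correlation of nearby equal-frequency SNPs is
    rho^|i-j| exactly; diploid counts (sum of two independent haplotypes)
    inherit the same correlation.  Monomorphic columns are redrawn (capped
    retries), breaking LD only for the offending SNP.
    """
    if n < 1 or m < 1:
        raise ValueError("n, m must be >= 1")
    if not (0 <= ld_decay < 1):
        raise ValueError("ld_decay must be in [0,1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    lo, hi = maf_range
    f = rng.uniform(lo, hi, size=m)
    H = np.empty((2 * n, m), dtype=np.int8)
    H[:, 0] = rng.random(2 * n) < f[0]
    marg = np.empty(m)
    marg[0] = f[0]
    for j in range(1, m):
        g = (f[j] - ld_decay * marg[j - 1]) / (1.0 - ld_decay)
        g = min(max(g, 0.0), 1.0)
        marg[j] = ld_decay * marg[j - 1] + (1.0 - ld_decay) * g
        copy = rng.random(2 * n) < ld_decay
        fresh = rng.random(2 * n) < g
        H[:, j] = np.where(copy, H[:, j - 1], fresh)
    G = (H[:n] + H[n:]).astype(np.int8)
    for j in range(m):
        tries = 0
        while G[:, j].min() == G[:, j].max() and tries < 10:
            col = ((rng.random(n) < f[j]).astype(np.int8)
                   + (rng.random(n) < f[j]).astype(np.int8))
            G[:, j] = col
            tries += 1
        if G[:, j].min() == G[:, j].max():
            logger.info("SNP %d still monomorphic after retries", j)
    return (G, marg) if return_freqs else G


# ---------------------------------------------------------------------------
# methylation phenotypes
# ---------------------------------------------------------------------------

def _std(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _pick_linked_snp(G: np.ndarray, c1: int, r_link: float) -> int:
    """Column whose realised correlation with column c1 is nearest r_link."""
    g1 = _std(G[:, c1].astype(float))
    best, best_gap = None, np.inf
    for j in range(G.shape[1]):
        if j == c1 or G[:, j].min() == G[:, j].max():
            continue
        r = float(np.mean(g1 * _std(G[:, j].astype(float))))
        gap = abs(r - r_link)
        if gap < best_gap:
            best, best_gap = j, gap
    return best


def simulate_methylation_pair(G: np.ndarray, scenario: SimScenario,
                              rng: np.random.Generator | None = None) -> SimCohort:
    """Exposure/outcome methylation vectors under the scenario's diagram."""
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    n, m = G.shape
    q2 = scenario.q2
    c1 = m // 2
    g1 = _std(G[:, c1].astype(float))
    e_x = rng.standard_normal(n)
    x = np.sqrt(q2) * g1 + np.sqrt(1.0 - q2) * e_x

    kind = scenario.kind
    if kind == "pleiotropy":
        b = scenario.b_xy
        if b ** 2 > 1.0:
            raise ValueError(f"|b_xy| <= 1 required for unit outcome variance, "
                             f"got {b}")
        y = b * x + np.sqrt(1.0 - b ** 2) * rng.standard_normal(n)
        causal = [c1]
        truth = {"b_xy": b, "q2": q2}
    elif kind == "linkage":
        c2 = _pick_linked_snp(G, c1, scenario.r_link)
        q2y = scenario.q2_outcome if scenario.q2_outcome is not None else q2
        g2 = _std(G[:, c2].astype(float))
        y = np.sqrt(q2y) * g2 + np.sqrt(1.0 - q2y) * rng.standard_normal(n)
        causal = [c1, c2]
        truth = {"q2": q2, "q2_outcome": q2y,
                 "r_link_realised": float(np.mean(g1 * g2))}
    elif kind == "null_overlap":
        r_p = scenario.r_p
        if r_p ** 2 > 1.0 - q2:
            raise ValueError(
                f"target r_p={r_p} unreachable: residual share of x is "
                f"{1 - q2:.3f}, so |r_p| <= {np.sqrt(1 - q2):.3f}")
        gamma = r_p / (1.0 - q2)
        resid = np.sqrt(1.0 - q2) * e_x
        y = gamma * resid + np.sqrt(1.0 - gamma ** 2 * (1.0 - q2)) \
            * rng.standard_normal(n)
        causal = [c1]
        truth = {"r_p": r_p, "q2": q2}
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    return SimCohort(G, x, y, causal, scenario, truth)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def association_scan(G: np.ndarray, phenotype: np.ndarray,
                     snp_ids=None, snp_bp=None, chrom: str = "1",
                     probe_id: str = "probe", probe_bp: int = 1) -> pd.DataFrame:
    """Per-SNP simple linear regression, mQTL-dialect columns.

    Effects are in SD units of the (standardised) phenotype; se is the OLS
    standard error with n-2 residual df and p the two-sided t-test.
    Monomorphic SNPs yield NA rows.
    """
    n, m = G.shape
    y = np.asarray(phenotype, dtype=float)
    y = (y - y.mean()) / y.std()
    Gc = G.astype(float) - G.astype(float).mean(axis=0)
    sxx = (Gc ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (Gc.T @ y) / sxx
        sse = float(y @ y) - b ** 2 * sxx
        s2 = sse / (n - 2)
        se = np.sqrt(s2 / sxx)
        t = b / se
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    mono = sxx == 0
    b[mono] = np.nan
    se[mono] = np.nan
    p[mono] = np.nan
    freq = G.mean(axis=0) / 2.0
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    if snp_bp is None:
        snp_bp = 1000 * (np.arange(m) + 1)
    df = pd.DataFrame({
        "probe_id": probe_id, "probe_chr": chrom, "probe_bp": probe_bp,
        "snp_id": snp_ids, "snp_chr": chrom, "snp_bp": snp_bp,
        "a1": "A", "a2": "G", "freq": freq, "b": b, "se": se, "p": p, "n": n,
    })
    return df[~mono].reset_index(drop=True)


def _smr_heidi_once(cohort: SimCohort, cfg: ScanConfig):
    """Top-instrument SMR + HEIDI on one simulated cohort (both phenotypes
    scanned in the same individuals, i.e. complete sample overlap)."""
    G = cohort.genotypes
    scan_x = association_scan(G, cohort.exposure)
    scan_y = association_scan(G, cohort.outcome)
    top = top_instrument(scan_x, cfg.instrument_p)
    if top is None:
        return None
    ids = list(scan_x["snp_id"])
    ld_source = GenotypeLdSource(
        pd.DataFrame(G.astype(float), columns=[f"snp{j}" for j in range(G.shape[1])])
        [ids])
    smr, heidi, note = test_pair(scan_x, scan_y, top, ld_source, cfg)
    if smr is None:
        return None
    return smr, heidi


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def null_overlap_experiment(n_reps: int = 2000, n: int = 2000, m: int = 100,
                            r_p_dist=(-0.5, 0.5), q2_dist=(0.03, 0.3),
                            ld_decay: float = 0.8, cfg: ScanConfig | None = None,
                            seed: int = 0) -> dict:
    """Calibration of SMR/HEIDI under sample overlap with no shared genetics.

    Each replicate draws r_p ~ U(r_p_dist) and q2 ~ U(q2_dist) (stand-ins
    for the observed cohort distributions), simulates a null_overlap pair in
    one cohort of ``n`` individuals, scans both phenotypes in that same
    cohort and runs SMR + HEIDI whenever an instrument reaches the
    threshold.  Reports the SMR p-value ECDF, KS statistic vs U(0,1) and
    the fraction below 0.05 with a binomial CI.
    """
    cfg = cfg or ScanConfig()
    rng = np.random.default_rng(seed)
    p_smr, p_heidi = [], []
    n_skipped = 0
    for _ in range(n_reps):
        r_p = rng.uniform(*r_p_dist)
        q2 = rng.uniform(*q2_dist)
        sc = SimScenario(kind="null_overlap", n=n, m=m, ld_decay=ld_decay,
                         q2=q2, r_p=r_p)
        G = simulate_genotypes(n, m, ld_decay, sc.maf_range, rng=rng)
        cohort = simulate_methylation_pair(G, sc, rng=rng)
        res = _smr_heidi_once(cohort, cfg)
        if res is None:
            n_skipped += 1
            continue
        smr, heidi = res
        p_smr.append(smr.p_smr)
        if heidi is not None and np.isfinite(heidi.p_heidi):
            p_heidi.append(heidi.p_heidi)
    p_smr = np.array(p_smr)
    p_heidi = np.array(p_heidi)
    ks = stats.kstest(p_smr, "uniform") if p_smr.size else None
    k = int((p_smr < 0.05).sum())
    ci = (stats.binomtest(k, p_smr.size).proportion_ci(0.95)
          if p_smr.size else None)
    return {
        "n_reps": n_reps, "n_used": int(p_smr.size), "n_skipped": n_skipped,
        "p_smr": p_smr, "p_heidi": p_heidi,
        "ks_stat": float(ks.statistic) if ks else np.nan,
        "ks_p": float(ks.pvalue) if ks else np.nan,
        "frac_smr_lt_05": float((p_smr < 0.05).mean()) if p_smr.size else np.nan,
        "frac_ci": (float(ci.low), float(ci.high)) if ci else (np.nan, np.nan),
        "frac_heidi_lt_05": float((p_heidi < 0.05).mean()) if p_heidi.size else np.nan,
    }


def power_experiment(grid: list[dict], n_reps: int = 200, n: int = 2000,
                     m: int = 100, ld_decay: float = 0.8,
                     smr_threshold: float = 1e-4,
                     cfg: ScanConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """SMR power and HEIDI rejection rates over a scenario grid.

    Each grid cell is a dict of SimScenario overrides (kind, b_xy, q2,
    r_link, ...).  The returned table carries per-cell SMR rejection at
    ``smr_threshold``, HEIDI rejection at p < 0.01, and the mean ratio
    estimate b_xy across replicates.
    """
    cfg = cfg or ScanConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for cell in grid:
        p_smr, p_heidi, bxy = [], [], []
        n_skipped = 0
        for _ in range(n_reps):
            sc = SimScenario(n=n, m=m, ld_decay=ld_decay, **cell)
            G = simulate_genotypes(n, m, ld_decay, sc.maf_range, rng=rng)
            cohort = simulate_methylation_pair(G, sc, rng=rng)
            res = _smr_heidi_once(cohort, cfg)
            if res is None:
                n_skipped += 1
                continue
            smr, heidi = res
            p_smr.append(smr.p_smr)
            bxy.append(smr.b_xy)
            if heidi is not None and np.isfinite(heidi.p_heidi):
                p_heidi.append(heidi.p_heidi)
        p_smr, p_heidi = np.array(p_smr), np.array(p_heidi)
        rows.append({**cell,
                     "n_used": p_smr.size, "n_skipped": n_skipped,
                     "smr_power": float((p_smr < smr_threshold).mean())
                     if p_smr.size else np.nan,
                     "heidi_reject": float((p_heidi < cfg.heidi_cutoff).mean())
                     if p_heidi.size else np.nan,
                     "mean_b_xy": float(np.mean(bxy)) if bxy else np.nan,
                     "sd_b_xy": float(np.std(bxy)) if bxy else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def make_fixture_bundle(out_dir, seed: int = 0, n: int = 2000, m: int = 2000,
                        ld_decay: float = 0.9) -> dict:
    """Write a complete, small, self-consistent input set for the CLI.

    One 4 Mb chromosome with ``m`` SNPs every 2 kb and 50 DNAm probes:
    10 promoter probes (genes G1..G10), 6 planted pleiotropic partners
    (b_xy = 0.5, q2 = 0.1), 2 linkage partners (r^2 ~ 0.2), 2 overlap-null
    partners (r_p = 0.3, no genetic effect) and 30 background probes with
    independent genetics.  Interval/expression annotations carry planted
    signal consistent with the pleiotropic pairs.  Returns a dict of file
    paths plus the planted truth (also written to truth.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    q2, b_xy_true, r_p_null = 0.1, 0.5, 0.3

    snp_bp = 1000 + 2000 * np.arange(m)          # 1-based positions
    snp_ids = [f"rs{j + 1}" for j in range(m)]
    G = simulate_genotypes(n, m, ld_decay, (0.1, 0.5), rng=rng)

    # genes and promoter intervals (2 kb around each promoter probe)
    n_genes = 10
    centers = 200_000 + 400_000 * np.arange(n_genes)
    genes = [f"G{k + 1}" for k in range(n_genes)]
    promoters = pd.DataFrame({
        "chrom": chrom, "start": centers - 1000, "end": centers + 1000,
        "label": genes})

    def nearest_snp(bp):
        return int(np.argmin(np.abs(snp_bp - bp)))

    probes, phenos, truth_pairs = [], {}, []
    alt = {"A": "G"}

    def add_probe(pid, bp, gene, is_prom, pheno):
        probes.append(dict(probe_id=pid, chrom=chrom, bp=int(bp),
                           gene_label=gene, is_promoter=is_prom,
                           dnam_variance=float(rng.lognormal(-2.0, 0.5))))
        phenos[pid] = pheno

    # promoter probes: each driven by the SNP nearest its promoter centre
    prom_resid = {}
    for k in range(n_genes):
        c = nearest_snp(centers[k])
        g = _std(G[:, c].astype(float))
        e = rng.standard_normal(n)
        x = np.sqrt(q2) * g + np.sqrt(1 - q2) * e
        prom_resid[k] = e
        add_probe(f"cgP{k + 1}", centers[k], genes[k], True, x)

    # partners 80 kb downstream of each of the first 10 genes
    for k in range(n_genes):
        bp = centers[k] + 80_000
        pid = f"cgD{k + 1}"
        x = phenos[f"cgP{k + 1}"]
        if k < 6:       # pleiotropy: true PAI
            y = b_xy_true * x + np.sqrt(1 - b_xy_true ** 2) * rng.standard_normal(n)
            truth_pairs.append(dict(kind="pleiotropy", expo=f"cgP{k + 1}",
                                    outcome=pid, b_xy=b_xy_true))
        elif k < 8:     # linkage: causal SNP in LD r^2 ~ 0.2 with the bait's
            c1 = nearest_snp(centers[k])
            c2 = _pick_linked_snp(G, c1, np.sqrt(0.2))
            g2 = _std(G[:, c2].astype(float))
            y = np.sqrt(q2) * g2 + np.sqrt(1 - q2) * rng.standard_normal(n)
            truth_pairs.append(dict(kind="linkage", expo=f"cgP{k + 1}",
                                    outcome=pid))
        else:           # overlap null: residual correlation only
            gamma = r_p_null / (1 - q2)
            resid = np.sqrt(1 - q2) * prom_resid[k]
            y = gamma * resid + np.sqrt(1 - gamma ** 2 * (1 - q2)) \
                * rng.standard_normal(n)
            truth_pairs.append(dict(kind="null", expo=f"cgP{k + 1}",
                                    outcome=pid))
        add_probe(pid, bp, None, False, y)

    # background probes with independent genetics
    bg_bp = rng.choice(np.arange(50_000, 3_950_000, 10_000), size=30,
                       replace=False)
    for i, bp in enumerate(sorted(bg_bp)):
        c = nearest_snp(bp)
        g = G[:, c].astype(float)
        if g.std() == 0:
            g = rng.standard_normal(n)
        y = np.sqrt(q2) * _std(g) + np.sqrt(1 - q2) * rng.standard_normal(n)
        add_probe(f"cgB{i + 1}", bp, None, False, y)

    probes_df = pd.DataFrame(probes)

    # cis-mQTL summary statistics for every probe
    frames = []
    for _, pr in probes_df.iterrows():
        cis = np.abs(snp_bp - pr["bp"]) <= 2_000_000
        df = association_scan(G[:, cis], phenos[pr["probe_id"]],
                              snp_ids=[snp_ids[j] for j in np.nonzero(cis)[0]],
                              snp_bp=snp_bp[cis], chrom=chrom,
                              probe_id=pr["probe_id"], probe_bp=int(pr["bp"]))
        frames.append(df)
    mqtl_df = pd.concat(frames, ignore_index=True)[MQTL_COLUMNS]

    # interval annotations with planted signal around the pleiotropic pairs
    tads = pd.DataFrame({
        "chrom": chrom,
        "start": centers - 60_000, "end": centers + 140_000,
        "label": [f"TAD{k + 1}" for k in range(n_genes)]})
    loops = pd.DataFrame({
        "chrom1": chrom, "start1": centers[:6] - 5_000, "end1": centers[:6] + 5_000,
        "chrom2": chrom, "start2": centers[:6] + 75_000, "end2": centers[:6] + 85_000,
        "p": np.round(rng.uniform(1e-6, 1e-3, size=6), 8)})
    bg_loops = pd.DataFrame({
        "chrom1": chrom, "start1": bg_bp[:10] - 5_000, "end1": bg_bp[:10] + 5_000,
        "chrom2": chrom, "start2": bg_bp[:10] + 195_000, "end2": bg_bp[:10] + 205_000,
        "p": np.round(rng.uniform(0.05, 0.5, size=10), 8)})
    loops = pd.concat([loops, bg_loops], ignore_index=True)

    # chromatin states: 2 kb tiles covering the region
    tile = 2000
    starts = np.arange(0, 4_000_000, tile)
    labels = rng.choice(STATE_LABELS, size=len(starts),
                        p=np.full(len(STATE_LABELS), 1 / len(STATE_LABELS)))
    states = pd.DataFrame({"chrom": chrom, "start": starts,
                           "end": starts + tile, "label": labels})

    chip = pd.DataFrame({
        "chrom": chrom,
        "start": np.concatenate([centers + 78_000,
                                 rng.choice(np.arange(0, 3_900_000, 7_000),
                                            size=40, replace=False)]),
        "label": "CTCF"})
    chip["end"] = chip["start"] + 1_500
    chip = chip[["chrom", "start", "end", "label"]].sort_values("start")

    # eQTLs: for the six true PAI genes, one eQTL close to the partner probe
    eqtl = pd.DataFrame({
        "snp_id": [f"eq{k + 1}" for k in range(6)],
        "chrom": chrom,
        "bp": centers[:6] + 80_000 + rng.integers(-3000, 3000, size=6),
        "gene_label": genes[:6],
        "p": np.round(rng.uniform(1e-12, 1e-8, size=6), 16)})
    bg_eqtl = pd.DataFrame({
        "snp_id": [f"eqbg{k + 1}" for k in range(20)],
        "chrom": chrom,
        "bp": rng.choice(np.arange(10_000, 3_990_000, 13_000), size=20,
                         replace=False),
        "gene_label": rng.choice(genes, size=20),
        "p": np.round(rng.uniform(1e-10, 5e-8, size=20), 16)})
    eqtl = pd.concat([eqtl, bg_eqtl], ignore_index=True)

    # expression: genes G1..G10 plus 40 background genes, 100 samples
    n_samp = 100
    expr_genes = genes + [f"BG{k + 1}" for k in range(40)]
    base = rng.lognormal(1.0, 1.0, size=(len(expr_genes), 1))
    noise = rng.standard_normal((len(expr_genes), n_samp))
    tpm = pd.DataFrame(np.abs(base * (1 + 0.5 * noise)), index=expr_genes,
                       columns=[f"s{i + 1}" for i in range(n_samp)])

    paths = {}

    def write(name, fn):
        p = out / name
        fn(p)
        paths[name.split(".")[0]] = str(p)

    write("mqtl.tsv", lambda p: mqtl_df.to_csv(
        p, sep="\t", index=False, na_rep="NA", float_format="%.10g"))
    write("genotypes.tsv", lambda p: pd.DataFrame(
        G, index=[f"ind{i + 1}" for i in range(n)], columns=snp_ids)
        .to_csv(p, sep="\t"))
    write("probes.tsv", lambda p: probes_df.to_csv(
        p, sep="\t", index=False, na_rep="NA", float_format="%.10g"))
    write("promoters.bed", lambda p: promoters.to_csv(
        p, sep="\t", header=False, index=False))
    write("tads.bed", lambda p: tads.to_csv(p, sep="\t", header=False, index=False))
    write("states.bed", lambda p: states.to_csv(p, sep="\t", header=False, index=False))
    write("chip.bed", lambda p: chip.to_csv(p, sep="\t", header=False, index=False))
    write("loops.bedpe", lambda p: loops.to_csv(
        p, sep="\t", header=False, index=False, float_format="%.8g"))
    write("eqtl.tsv", lambda p: eqtl.to_csv(
        p, sep="\t", index=False, float_format="%.16g"))
    write("tpm.tsv", lambda p: tpm.to_csv(p, sep="\t", float_format="%.8g"))
    truth = {"pairs": truth_pairs, "b_xy": b_xy_true, "q2": q2,
             "r_p_null": r_p_null, "seed": seed}
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    paths["truth"] = str(out / "truth.json")
    return paths


# ---------------------------------------------------------------------------
# planted-signal fixtures for the enrichment engine
# ---------------------------------------------------------------------------

def make_state_fixture(seed: int = 0, n_universe: int = 2000,
                       n_pids: int = 300, enha_base: float = 0.1,
                       enha_fold: float = 2.0):
    """Universe probes with a tiled state annotation and a PIDS set whose
    'EnhA' rate is planted at ``enha_fold`` times the universe rate."""
    rng = np.random.default_rng(seed)
    bp = 1000 * np.arange(1, n_universe + 1) + 500
    other = [s for s in STATE_LABELS if s != "EnhA"]
    labels = np.where(rng.random(n_universe) < enha_base, "EnhA",
                      rng.choice(other, size=n_universe))
    universe = pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(n_universe)],
        "chrom": "chr1", "bp": bp,
        "dnam_variance": rng.lognormal(-2.0, 0.5, size=n_universe)})
    states = IntervalSet(pd.DataFrame({
        "chrom": "chr1", "start": bp - 1 - 400, "end": bp - 1 + 400,
        "label": labels}))
    enha_idx = np.nonzero(labels == "EnhA")[0]
    rest_idx = np.nonzero(labels != "EnhA")[0]
    take_enha = rng.random(n_pids) < enha_fold * enha_base
    pids_idx = np.where(take_enha,
                        rng.choice(enha_idx, size=n_pids),
                        rng.choice(rest_idx, size=n_pids))
    return universe, states, universe.iloc[pids_idx].reset_index(drop=True)


def make_eqtl_fixture(seed: int = 0, n_genes: int = 10, probes_per_gene: int = 40,
                      n_pai: int = 100, base_rate: float = 0.2,
                      fold: float = 1.5, window: int = 10_000):
    """Gene-probe pair universe with eQTLs planted in PAI windows at a rate
    chosen so the distance-matched fold enrichment is ``fold``."""
    rng = np.random.default_rng(seed)
    n_u = n_genes * probes_per_gene
    # probes spaced > window apart so windows never overlap
    bp = 20_000 * np.arange(1, n_u + 1)
    genes = np.repeat([f"G{k + 1}" for k in range(n_genes)], probes_per_gene)
    dist = rng.integers(10_000, 500_000, size=n_u)
    universe = pd.DataFrame({"gene_label": genes, "chrom": "chr1",
                             "bp2": bp, "distance": dist})
    pai_idx = rng.choice(n_u, size=n_pai, replace=False)
    is_pai = np.zeros(n_u, dtype=bool)
    is_pai[pai_idx] = True
    # per-pair hit rate: fold * base for PAI pairs solves
    # p1 / ((n_pai p1 + (n_u-n_pai) p0)/n_u) = fold
    p1 = fold * base_rate * (n_u - n_pai) / (n_u - fold * n_pai)
    hit = rng.random(n_u) < np.where(is_pai, p1, base_rate)
    rows = []
    for i in np.nonzero(hit)[0]:
        rows.append(dict(snp_id=f"eq{i}", chrom="chr1",
                         bp=int(bp[i] + rng.integers(-window // 2 + 1,
                                                     window // 2 - 1)),
                         gene_label=genes[i], p=1e-9))
    eqtls = pd.DataFrame(rows, columns=["snp_id", "chrom", "bp",
                                        "gene_label", "p"])
    return universe, universe[is_pai].reset_index(drop=True), eqtls


def make_coexpression_fixture(seed: int = 0, n_planted: int = 40,
                              n_background: int = 160, n_samples: int = 200,
                              r_planted: float = 0.4):
    """Expression matrix with gene pairs co-expressed at ``r_planted`` and
    an independent background universe of pairs."""
    rng = np.random.default_rng(seed)
    rows, pairs, upairs = [], [], []
    gid = 0

    def new_gene(vec):
        nonlocal gid
        gid += 1
        name = f"g{gid}"
        rows.append((name, vec))
        return name

    for i in range(n_planted):
        a = rng.standard_normal(n_samples)
        b = r_planted * a + np.sqrt(1 - r_planted ** 2) \
            * rng.standard_normal(n_samples)
        g1, g2 = new_gene(a), new_gene(b)
        pairs.append(dict(gene1=g1, gene2=g2,
                          distance=int(rng.integers(10_000, 500_000))))
    for i in range(n_background):
        g1 = new_gene(rng.standard_normal(n_samples))
        g2 = new_gene(rng.standard_normal(n_samples))
        upairs.append(dict(gene1=g1, gene2=g2,
                           distance=int(rng.integers(10_000, 500_000))))
    tpm = pd.DataFrame({name: vec for name, vec in rows}).T
    tpm.columns = [f"s{j}" for j in range(n_samples)]
    planted = pd.DataFrame(pairs)
    universe = pd.concat([planted, pd.DataFrame(upairs)], ignore_index=True)
    return planted, universe, tpm
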