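"""SMR ratio test and HEIDI heterogeneity test on mQTL summary statistics.

The exposure is the DNAm level of one CpG probe (x), the outcome the DNAm
level of another (y), and the instrument a cis-SNP (z) strongly associated
with the exposure.  With per-allele effects b_zx and b_zy (SD units), the
ratio estimate of the exposure-on-outcome effect is

    b_xy = b_zy / b_zx,

tested with the two-sided Wald statistic

    T_SMR = z_zx^2 * z_zy^2 / (z_zx^2 + z_zy^2)  ~  chi^2(1)  under H0,

where z = b/se.  T_SMR is bounded by the weaker of the two marginal
chi-squares, so a significant SMR test needs both associations.

HEIDI asks whether the ratio estimate is homogeneous across the other
cis-SNPs in LD with the top instrument: under a single shared causal
variant every instrument estimates the same b_xy, so the differences
d_i = b_xy(i) - b_xy(top) are jointly zero.  Their estimates are
approximately multivariate normal with a covariance driven by LD (r_ij)
and the marginal z-statistics; the test statistic sum_i d_i^2 / V_ii is a
weighted sum of 1-df chi-squares whose weights are the eigenvalues of the
correlation matrix of d.  Small HEIDI p-values indicate linkage (distinct
causal variants) rather than pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .io_formats import AssocStat, SnpMeta

logger = logging.getLogger("paikit")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class InvalidInstrumentError(ValueError):
    """Instrument effect on the exposure is zero (ratio undefined)."""


# ---------------------------------------------------------------------------
# LD matrix
# ---------------------------------------------------------------------------

@dataclass
class LdMatrix:
    """Signed SNP correlation matrix aligned to each SNP's a1 coding."""

    snp_ids: list
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match snp list")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValueError("|r| > 1 in LD matrix")
        w = np.linalg.eigvalsh((self.r + self.r.T) / 2)
        if w.min() < -1e-6:
            raise ValueError(f"LD matrix not PSD (min eigenvalue {w.min():.3g})")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def submatrix(self, snp_ids) -> "LdMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LdMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    @classmethod
    def from_genotypes(cls, counts: np.ndarray | pd.DataFrame,
                       snp_ids=None) -> "LdMatrix":
        """Pearson correlations of centred allele counts (samples x SNPs)."""
        if isinstance(counts, pd.DataFrame):
            snp_ids = list(counts.columns) if snp_ids is None else snp_ids
            counts = counts.to_numpy(dtype=float)
        g = counts - counts.mean(axis=0)
        sd = g.std(axis=0)
        if np.any(sd == 0):
            mono = [snp_ids[i] for i in np.nonzero(sd == 0)[0]]
            raise ValueError(f"monomorphic SNPs in LD reference: {mono[:5]}")
        r = (g / sd).T @ (g / sd) / g.shape[0]
        np.fill_diagonal(r, 1.0)
        r = np.clip((r + r.T) / 2, -1.0, 1.0)
        return cls(list(snp_ids), r)


class GenotypeLdSource:
    """LD from an in-memory allele-count matrix (samples x SNPs).

    ``counted`` optionally maps snp_id -> the allele the counts refer to;
    when provided, correlations are sign-flipped to each query SNP's a1.
    Without it, counts are assumed to already count the a1 allele (the
    plain-matrix dialect carries no allele labels).
    """

    def __init__(self, counts: pd.DataFrame, counted: dict | None = None):
        self.counts = counts
        self.counted = counted or {}

    def available(self, snp_ids):
        return [s for s in snp_ids if s in self.counts.columns]

    def ld_matrix(self, snps: list[SnpMeta]) -> LdMatrix:
        ids = [s.snp_id for s in snps]
        ld = LdMatrix.from_genotypes(self.counts[ids])
        sign = np.ones(len(snps))
        for i, s in enumerate(snps):
            counted = self.counted.get(s.snp_id)
            if counted is not None and counted != s.a1:
                if counted != s.a2:
                    raise ValueError(
                        f"{s.snp_id}: counted allele {counted} not in "
                        f"({s.a1},{s.a2})")
                sign[i] = -1.0
        r = ld.r * np.outer(sign, sign)
        np.fill_diagonal(r, 1.0)
        return LdMatrix(ids, r)


def genotype_ld_from_vcf(path, snp_ids=None) -> GenotypeLdSource:
    """Build an LD source from a VCF; counts refer to the ALT allele."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    cols, counted, ids = [], {}, []
    want = set(snp_ids) if snp_ids is not None else None
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if want is not None and vid not in want:
            continue
        if len(var.ALT) != 1:
            continue
        gts = np.array([g[0] + g[1] for g in var.genotypes], dtype=float)
        cols.append(gts)
        counted[vid] = var.ALT[0]
        ids.append(vid)
    df = pd.DataFrame(np.column_stack(cols) if cols else np.empty((0, 0)),
                      columns=ids)
    return GenotypeLdSource(df, counted)


# ---------------------------------------------------------------------------
# allele harmonisation
# ---------------------------------------------------------------------------

def is_strand_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def align_alleles(target: tuple[SnpMeta, AssocStat],
                  reference_coding: tuple[str, str],
                  ambiguous_policy: str = "keep"):
    """Harmonise a (SnpMeta, AssocStat) record to a reference a1/a2 coding.

    Returns the (possibly flipped) record, or None when the record must be
    dropped (allele-pair mismatch, or A/T / C/G SNP under policy 'drop').
    """
    meta, stat = target
    ref_a1, ref_a2 = (a.upper() for a in reference_coding)
    a1, a2 = meta.a1.upper(), meta.a2.upper()
    if is_strand_ambiguous(a1, a2) and ambiguous_policy == "drop":
        logger.info("%s: strand-ambiguous SNP dropped", meta.snp_id)
        return None
    if (a1, a2) == (ref_a1, ref_a2):
        return meta, stat
    if (a1, a2) == (ref_a2, ref_a1):
        flipped = SnpMeta(meta.snp_id, meta.chrom, meta.bp, ref_a1, ref_a2,
                          None if meta.freq is None else 1.0 - meta.freq)
        return flipped, AssocStat(-stat.b, stat.se, stat.p, stat.n)
    logger.info("%s: allele pair (%s,%s) does not match reference (%s,%s); dropped",
                meta.snp_id, a1, a2, ref_a1, ref_a2)
    return None


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

def top_instrument(cis_stats: pd.DataFrame, p_threshold: float = 5e-8):
    """Most significant cis-SNP below ``p_threshold``, or None.

    Ties on p break by larger |z|, then smaller bp, then lexical snp_id.
    """
    if cis_stats.empty:
        return None
    df = cis_stats[cis_stats["p"] < p_threshold]
    if df.empty:
        return None
    absz = (df["b"] / df["se"]).abs()
    order = pd.DataFrame({"p": df["p"], "negz": -absz,
                          "bp": df["snp_bp"], "snp": df["snp_id"]})
    i = order.sort_values(["p", "negz", "bp", "snp"], kind="mergesort").index[0]
    row = cis_stats.loc[i]
    return SnpMeta(row["snp_id"], str(row["snp_chr"]), int(row["snp_bp"]),
                   row["a1"], row["a2"],
                   None if pd.isna(row.get("freq", np.nan)) else float(row["freq"]))


def variance_explained(top_stat: AssocStat, snp: SnpMeta) -> float:
    """Fraction of DNAm variance explained by the top cis-mQTL.

    q^2 = 2 p (1-p) b^2 for an SD-unit effect b at allele frequency p; when
    the frequency is unavailable the z-based form q^2 = z^2 / (z^2 + n - 2)
    from the same regression is used instead.
    """
    if snp.freq is not None:
        return 2.0 * snp.freq * (1.0 - snp.freq) * top_stat.b ** 2
    if top_stat.n is not None and top_stat.n > 2:
        z2 = top_stat.z ** 2
        return z2 / (z2 + top_stat.n - 2)
    raise ValueError(f"{snp.snp_id}: neither freq nor n available for q^2")


# ---------------------------------------------------------------------------
# SMR ratio test
# ---------------------------------------------------------------------------

@dataclass
class SmrResult:
    top_snp: SnpMeta
    b_xy: float
    se_xy: float
    t_smr: float
    p_smr: float


def smr_test(bzx: AssocStat, bzy: AssocStat, top_snp: SnpMeta | None = None) -> SmrResult:
    """Two-sided Wald test of the ratio estimate b_xy = b_zy / b_zx."""
    if bzx.b == 0:
        raise InvalidInstrumentError("b_zx = 0: ratio estimate undefined")
    z2x, z2y = bzx.z ** 2, bzy.z ** 2
    b_xy = bzy.b / bzx.b
    t = z2x * z2y / (z2x + z2y) if (z2x + z2y) > 0 else 0.0
    p = float(stats.chi2.sf(t, df=1)) if t > 0 else 1.0
    se_xy = abs(b_xy) / np.sqrt(t) if t > 0 else np.inf
    return SmrResult(top_snp=top_snp, b_xy=b_xy, se_xy=se_xy, t_smr=t, p_smr=p)


# ---------------------------------------------------------------------------
# HEIDI
# ---------------------------------------------------------------------------

@dataclass
class HeidiResult:
    nsnp: int
    d: np.ndarray | None
    V: np.ndarray | None
    p_heidi: float  # NaN when not testable


def heidi_select_snps(cis_stats: pd.DataFrame, ld: LdMatrix, top_snp: str,
                      p_include: float = 1.57e-3, r2_cap: float = 0.9,
                      max_snps: int = 20, r2_min: float = 0.05,
                      min_snps: int = 3) -> list[str]:
    """Greedy LD-pruned instrument list for HEIDI, top SNP always first.

    Candidates need exposure p < ``p_include`` and, versus every SNP already
    retained, pairwise r^2 <= ``r2_cap``; SNPs nearly uncorrelated with the
    top instrument (r^2 < ``r2_min``) contribute no heterogeneity information
    and are skipped.  Candidates are ranked by exposure significance and the
    list is truncated at ``max_snps`` (including the top SNP).
    """
    df = cis_stats[cis_stats["snp_id"].isin(ld.snp_ids)]
    absz = (df["b"] / df["se"]).abs()
    order = pd.DataFrame({"p": df["p"], "negz": -absz, "bp": df["snp_bp"],
                          "snp": df["snp_id"]})
    ranked = order.sort_values(["p", "negz", "bp", "snp"], kind="mergesort")
    selected = [top_snp]
    for _, row in ranked.iterrows():
        if len(selected) >= max_snps:
            break
        s = row["snp"]
        if s == top_snp or row["p"] >= p_include:
            continue
        r_top = ld.r_between(s, top_snp)
        if r_top ** 2 > r2_cap or (r2_min > 0 and r_top ** 2 < r2_min):
            continue
        if any(ld.r_between(s, t) ** 2 > r2_cap for t in selected):
            continue
        selected.append(s)
    if len(selected) < min_snps:
        logger.info("HEIDI: only %d instruments retained (< %d)",
                    len(selected), min_snps)
    return selected


def heidi_covariance(snps: list[str], bzx_stats: dict, bzy_stats: dict,
                     ld: LdMatrix):
    """Differences d and their delta-method covariance V.

    ``snps`` lists instrument ids with the top SNP first; ``bzx_stats`` and
    ``bzy_stats`` map snp_id -> AssocStat, all allele-aligned with ``ld``.
    The first-order expansion of b_xy(i) = b_zy(i)/b_zx(i) in the sampling
    errors of both summary statistics gives

        cov(b_xy(i), b_xy(j)) = b_xy(i) b_xy(j) r_ij
                                * [ 1/(z_zx(i) z_zx(j)) + 1/(z_zy(i) z_zy(j)) ]

    (exposure and outcome scans treated as independent), and V follows as
    the covariance of d_i = b_xy(i) - b_xy(top).  V is symmetrised and its
    eigenvalues floored at zero.
    """
    k = len(snps)
    if k < 3:
        raise ValueError("HEIDI needs >= 3 instruments including the top SNP")
    sub = ld.submatrix(snps)
    zx = np.array([bzx_stats[s].z for s in snps])
    zy = np.array([bzy_stats[s].z for s in snps])
    if np.any(zx == 0) or np.any(zy == 0):
        bad = [snps[i] for i in np.nonzero((zx == 0) | (zy == 0))[0]]
        raise ZeroDivisionError(f"zero z-statistic for {bad}")
    bxy = np.array([bzy_stats[s].b / bzx_stats[s].b for s in snps])

    c = (np.outer(bxy, bxy) * sub.r
         * (1.0 / np.outer(zx, zx) + 1.0 / np.outer(zy, zy)))
    # cov(d_i, d_j) with component 0 = top
    V = c[1:, 1:] - c[1:, :1] - c[:1, 1:] + c[0, 0]
    V = (V + V.T) / 2
    w, Q = np.linalg.eigh(V)
    if w.min() < 0:
        V = (Q * np.clip(w, 0.0, None)) @ Q.T
        V = (V + V.T) / 2
    d = bxy[1:] - bxy[0]
    return d, V


def _satterthwaite_p(T: float, lam: np.ndarray) -> float:
    s1, s2 = lam.sum(), (lam ** 2).sum()
    if s1 <= 0 or s2 <= 0:
        return 1.0
    scale = s2 / s1
    df = s1 ** 2 / s2
    return float(stats.chi2.sf(T / scale, df=df))


def _imhof_p(T: float, lam: np.ndarray) -> float:
    """P(sum lam_k chi2_1 > T) by Imhof's exact inversion integral."""
    import math
    import warnings

    lam = [float(x) for x in lam if x > 1e-12]
    half_t = 0.5 * T

    def integrand(u):
        theta = -half_t * u
        log_rho = 0.0
        for x in lam:
            xu = x * u
            theta += 0.5 * math.atan(xu)
            log_rho += 0.25 * math.log1p(xu * xu)
        return math.sin(theta) / (u * math.exp(log_rho))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0, np.inf, limit=2000,
                                epsabs=1e-10, epsrel=1e-8)
    return float(min(max(0.5 + val / np.pi, 1e-300), 1.0))


def heidi_test(d: np.ndarray, V: np.ndarray, method: str = "satterthwaite") -> float:
    """One-sided p-value for heterogeneity of the per-instrument ratios.

    T = sum_i d_i^2 / V_ii is referred to a weighted sum of 1-df chi-squares
    with weights the eigenvalues of the correlation matrix of d.  The
    Satterthwaite two-moment approximation is the fast default; Imhof's
    inversion integral ('imhof') is the numerically exact option.
    """
    d = np.asarray(d, dtype=float)
    V = np.asarray(V, dtype=float)
    keep = np.diag(V) > 1e-12
    if keep.sum() < 2:
        return np.nan
    d, V = d[keep], V[np.ix_(keep, keep)]
    sd = np.sqrt(np.diag(V))
    T = float(np.sum((d / sd) ** 2))
    R = V / np.outer(sd, sd)
    lam = np.clip(np.linalg.eigvalsh((R + R.T) / 2), 0.0, None)
    if method == "satterthwaite":
        return _satterthwaite_p(T, lam)
    if method == "imhof":
        return _imhof_p(T, lam)
    raise ValueError(f"unknown HEIDI method {method!r}")
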