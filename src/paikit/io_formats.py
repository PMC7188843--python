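"""Readers, writers and core record types for the PAI pipeline.

Coordinate conventions
----------------------
Interval annotations (BED/BEDPE) are stored 0-based half-open, exactly as on
disk.  Point features -- DNAm probes and SNPs -- carry 1-based positions, as
in mQTL summary files.  Conversion between the two happens only at query
boundaries: a 1-based point ``bp`` lies inside interval ``[start, end)`` iff
``start <= bp - 1 < end``.

The mQTL summary dialect is a tab-separated table with header columns
``probe_id probe_chr probe_bp snp_id snp_chr snp_bp a1 a2 freq b se p n``
where ``b`` is the additive effect of each ``a1`` allele in SD units of the
DNAm level.  ``freq`` and ``n`` may be relaxed to optional via the dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("paikit")

MQTL_COLUMNS = [
    "probe_id", "probe_chr", "probe_bp", "snp_id", "snp_chr", "snp_bp",
    "a1", "a2", "freq", "b", "se", "p", "n",
]
MQTL_MANDATORY = [c for c in MQTL_COLUMNS if c not in ("freq", "n")]

PAI_COLUMNS = [
    "expo_probe", "expo_chr", "expo_bp", "outcome_probe", "outcome_bp",
    "top_snp", "b_xy", "se_xy", "p_smr", "nsnp_heidi", "p_heidi",
    "distance", "pass_smr", "pass_heidi",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# point-feature metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpMeta:
    """A SNP with its effect-allele coding (a1 = counted/effect allele)."""

    snp_id: str
    chrom: str
    bp: int
    a1: str
    a2: str
    freq: float | None = None

    def __post_init__(self):
        if self.a1 == self.a2:
            raise ValueError(f"{self.snp_id}: a1 == a2 ({self.a1})")
        if self.bp < 1:
            raise ValueError(f"{self.snp_id}: bp must be >= 1")
        if self.freq is not None and not (0.0 < self.freq < 1.0):
            raise ValueError(f"{self.snp_id}: freq {self.freq} outside (0,1)")


@dataclass
class ProbeMeta:
    """A DNAm probe (CpG site) with annotation used by the scan."""

    probe_id: str
    chrom: str
    bp: int
    gene_label: str | None = None
    is_promoter: bool = False
    dnam_variance: float = 0.0
    top_cis_q2: float | None = None

    def __post_init__(self):
        if self.dnam_variance < 0:
            raise ValueError(f"{self.probe_id}: dnam_variance < 0")


@dataclass(frozen=True)
class AssocStat:
    """Per-SNP association statistic in SD units of the phenotype."""

    b: float
    se: float
    p: float
    n: int | None = None

    def __post_init__(self):
        if not (self.se > 0):
            raise ValueError(f"se must be > 0, got {self.se}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0,1], got {self.p}")

    @property
    def z(self) -> float:
        return self.b / self.se


# ---------------------------------------------------------------------------
# mQTL summary table
# ---------------------------------------------------------------------------

@dataclass
class MqtlDialect:
    """Validation knobs for the mQTL summary TSV."""

    require_freq: bool = False
    require_n: bool = False
    cis_window: int = 2_000_000
    chr_style: str | None = None  # None = leave as-is, "chr" / "plain"


def normalize_chrom(name: str, style: str | None) -> str:
    name = str(name)
    if style is None:
        return name
    bare = name[3:] if name.lower().startswith("chr") else name
    return f"chr{bare}" if style == "chr" else bare


@dataclass
class MqtlTable:
    """cis-mQTL summary statistics, one row per (probe, SNP).

    ``df`` holds validated rows; ``n_rejected`` counts rows dropped during
    reading, with reasons in ``rejections``.
    """

    df: pd.DataFrame
    n_rejected: int = 0
    rejections: list = field(default_factory=list)

    @property
    def probe_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["probe_id"]))

    def stats_for(self, probe_id: str) -> pd.DataFrame:
        return self.df[self.df["probe_id"] == probe_id]

    def probe_positions(self) -> pd.DataFrame:
        g = self.df.groupby("probe_id", sort=False).first()
        return g[["probe_chr", "probe_bp"]]


def _validate_mqtl_frame(df: pd.DataFrame, dialect: MqtlDialect):
    rejections = []
    for col in ("probe_bp", "snp_bp"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("freq", "b", "se", "p", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan

    bad = pd.Series(False, index=df.index)

    m = ~(df["se"] > 0)
    rejections += [(i, "se <= 0 or missing") for i in df.index[m & ~bad]]
    bad |= m

    m = ~((df["p"] > 0) & (df["p"] <= 1))
    rejections += [(i, "p outside (0,1]") for i in df.index[m & ~bad]]
    bad |= m

    m = df["a1"].astype(str).str.upper() == df["a2"].astype(str).str.upper()
    rejections += [(i, "a1 == a2") for i in df.index[m & ~bad]]
    bad |= m

    m = (df["freq"] <= 0) | (df["freq"] >= 1)
    m = m.fillna(False)
    rejections += [(i, "freq outside (0,1)") for i in df.index[m & ~bad]]
    bad |= m

    if dialect.require_freq:
        m = df["freq"].isna()
        rejections += [(i, "freq missing") for i in df.index[m & ~bad]]
        bad |= m
    if dialect.require_n:
        m = df["n"].isna()
        rejections += [(i, "n missing") for i in df.index[m & ~bad]]
        bad |= m

    same_chr = df["probe_chr"].astype(str) == df["snp_chr"].astype(str)
    within = (df["snp_bp"] - df["probe_bp"]).abs() <= dialect.cis_window
    m = ~(same_chr & within)
    rejections += [(i, "SNP outside cis window") for i in df.index[m & ~bad]]
    bad |= m

    return df[~bad].copy(), rejections


def read_mqtl_summary(path, dialect: MqtlDialect | None = None) -> MqtlTable:
    """Read and validate a cis-mQTL summary TSV.

    Rows failing validation (se <= 0, p outside (0,1], allele or window
    violations) are dropped and counted; duplicated (probe, SNP) rows keep
    the smaller p.
    """
    dialect = dialect or MqtlDialect()
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "snp_id": str,
                                            "probe_chr": str, "snp_chr": str})
    missing = [c for c in MQTL_MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")

    for col in ("probe_chr", "snp_chr"):
        df[col] = df[col].map(lambda c: normalize_chrom(c, dialect.chr_style))

    df, rejections = _validate_mqtl_frame(df, dialect)
    for i, why in rejections:
        logger.info("mQTL row %s rejected: %s", i, why)

    # duplicate (probe, snp): keep the row with smaller p, deterministically
    df = df.sort_values(["probe_id", "snp_id", "p"], kind="mergesort")
    dup = df.duplicated(["probe_id", "snp_id"], keep="first")
    n_dup = int(dup.sum())
    if n_dup:
        logger.info("mQTL: %d duplicate (probe,snp) rows collapsed", n_dup)
    df = df[~dup]
    df = df.sort_values(["probe_chr", "probe_bp", "probe_id", "snp_bp"],
                        kind="mergesort").reset_index(drop=True)
    df["probe_bp"] = df["probe_bp"].astype(int)
    df["snp_bp"] = df["snp_bp"].astype(int)
    table = MqtlTable(df=df, n_rejected=len(rejections), rejections=rejections)
    table.n_duplicates = n_dup
    return table


def write_mqtl_summary(table: MqtlTable | pd.DataFrame, path) -> None:
    df = table.df if isinstance(table, MqtlTable) else table
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%.10g", columns=MQTL_COLUMNS)


# ---------------------------------------------------------------------------
# interval annotations
# ---------------------------------------------------------------------------

class IntervalSet:
    """Genomic intervals, 0-based half-open, sorted per chromosome.

    Overlap queries use sorted starts with a running maximum of ends, so
    possibly-overlapping inputs are handled without an interval tree.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if (df["start"] >= df["end"]).any():
            raise FormatError("interval with start >= end")
        df["chrom"] = df["chrom"].astype(str)
        self.df = df.sort_values(["chrom", "start", "end"],
                                 kind="mergesort").reset_index(drop=True)
        self._by_chrom = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends,
                                     np.maximum.accumulate(ends),
                                     sub.index.to_numpy())

    def __len__(self):
        return len(self.df)

    # -- point queries (bp is 1-based) ------------------------------------
    def contains_points(self, chroms: Sequence[str], bps: Sequence[int]) -> np.ndarray:
        """Boolean array: does any interval contain each 1-based point?"""
        chroms = np.asarray(chroms, dtype=object)
        pos0 = np.asarray(bps, dtype=np.int64) - 1
        out = np.zeros(len(pos0), dtype=bool)
        for chrom in np.unique(chroms):
            if chrom not in self._by_chrom:
                continue
            starts, ends, cummax, _ = self._by_chrom[chrom]
            sel = chroms == chrom
            hi = np.searchsorted(starts, pos0[sel], side="right")
            ok = hi > 0
            res = np.zeros(int(sel.sum()), dtype=bool)
            res[ok] = cummax[hi[ok] - 1] > pos0[sel][ok]
            out[sel] = res
        return out

    def intervals_at(self, chrom: str, bp: int) -> pd.DataFrame:
        """All intervals containing the 1-based point (linear scan)."""
        if chrom not in self._by_chrom:
            return self.df.iloc[0:0]
        starts, ends, _, idx = self._by_chrom[chrom]
        pos0 = bp - 1
        m = (starts <= pos0) & (pos0 < ends)
        return self.df.loc[idx[m]]

    def labels_at_points(self, chroms, bps, label_col="label",
                         missing="unannotated") -> np.ndarray:
        """First containing interval's label per point (ChromHMM-style tiling)."""
        out = np.full(len(bps), missing, dtype=object)
        for i, (c, b) in enumerate(zip(chroms, bps)):
            hit = self.intervals_at(str(c), int(b))
            if len(hit):
                out[i] = hit.iloc[0][label_col]
        return out

    # -- window queries (0-based half-open windows) -----------------------
    def overlaps_windows(self, chroms, wstarts, wends) -> np.ndarray:
        """Does any interval intersect each window [wstart, wend)?"""
        chroms = np.asarray(chroms, dtype=object)
        a = np.asarray(wstarts, dtype=np.int64)
        b = np.asarray(wends, dtype=np.int64)
        out = np.zeros(len(a), dtype=bool)
        for chrom in np.unique(chroms):
            if chrom not in self._by_chrom:
                continue
            starts, ends, cummax, _ = self._by_chrom[chrom]
            sel = chroms == chrom
            hi = np.searchsorted(starts, b[sel], side="left")
            ok = hi > 0
            res = np.zeros(int(sel.sum()), dtype=bool)
            res[ok] = cummax[hi[ok] - 1] > a[sel][ok]
            out[sel] = res
        return out

    def contains_pair_same_interval(self, chrom, bp1, bp2) -> bool:
        """True if one single interval contains both 1-based points."""
        if chrom not in self._by_chrom:
            return False
        starts, ends, _, _ = self._by_chrom[chrom]
        lo, hi = sorted((bp1 - 1, bp2 - 1))
        return bool(np.any((starts <= lo) & (hi < ends)))


@dataclass
class PairSet:
    """Paired intervals (e.g., Hi-C loops), BEDPE convention, 0-based."""

    df: pd.DataFrame  # chrom1 start1 end1 chrom2 start2 end2 [p]

    def __len__(self):
        return len(self.df)


def read_intervals(path, kind: str = "bed"):
    """Read BED3+ (kind='bed') or BEDPE6+ (kind='bedpe') text.

    BED column 4 (if present) becomes ``label``; BEDPE column 7 (if present)
    is interpreted as a per-loop p-value / score, per the pipeline's dialect.
    Rows with start >= end are rejected with a log entry; unparseable lines
    raise :class:`FormatError` with the line number.
    """
    rows, rejected = [], 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if kind == "bed":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    label = parts[3] if len(parts) > 3 else ""
                    rec = dict(chrom=chrom, start=start, end=end, label=label)
                elif kind == "bedpe":
                    rec = dict(
                        chrom1=parts[0], start1=int(parts[1]), end1=int(parts[2]),
                        chrom2=parts[3], start2=int(parts[4]), end2=int(parts[5]),
                        p=float(parts[6]) if len(parts) > 6 else np.nan,
                    )
                else:
                    raise ValueError(f"unknown kind {kind!r}")
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{ln}: malformed {kind} line ({exc})")
            starts = [rec["start"]] if kind == "bed" else [rec["start1"], rec["start2"]]
            ends = [rec["end"]] if kind == "bed" else [rec["end1"], rec["end2"]]
            if any(s >= e for s, e in zip(starts, ends)):
                logger.info("%s:%d: start >= end, row rejected", path, ln)
                rejected += 1
                continue
            rows.append(rec)
    if kind == "bed":
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
        out = IntervalSet(df)
    else:
        df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                         "chrom2", "start2", "end2", "p"])
        out = PairSet(df)
    out.n_rejected = rejected
    return out


def write_intervals(obj, path) -> None:
    if isinstance(obj, IntervalSet):
        obj.df.to_csv(path, sep="\t", header=False, index=False)
    else:
        obj.df.to_csv(path, sep="\t", header=False, index=False,
                      float_format="%.6g")


# ---------------------------------------------------------------------------
# PAI result table
# ---------------------------------------------------------------------------

def write_pai_table(records: Iterable, path) -> None:
    """Write PAI records as a TSV sorted by (chrom, expo_bp, outcome_bp)."""
    rows = []
    for r in records:
        rows.append({
            "expo_probe": r.exposure.probe_id,
            "expo_chr": r.exposure.chrom,
            "expo_bp": r.exposure.bp,
            "outcome_probe": r.outcome.probe_id,
            "outcome_bp": r.outcome.bp,
            "top_snp": r.smr.top_snp.snp_id if r.smr is not None else "NA",
            "b_xy": r.smr.b_xy if r.smr is not None else np.nan,
            "se_xy": r.smr.se_xy if r.smr is not None else np.nan,
            "p_smr": r.smr.p_smr if r.smr is not None else np.nan,
            "nsnp_heidi": r.heidi.nsnp if r.heidi is not None else 0,
            "p_heidi": r.heidi.p_heidi if r.heidi is not None else np.nan,
            "distance": r.distance,
            "pass_smr": r.pass_smr,
            "pass_heidi": r.pass_heidi,
        })
    df = pd.DataFrame(rows, columns=PAI_COLUMNS)
    if len(df):
        df = df.sort_values(["expo_chr", "expo_bp", "outcome_bp"],
                            kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_pai_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     dtype={"expo_probe": str, "outcome_probe": str,
                            "expo_chr": str, "top_snp": str})
    missing = [c for c in PAI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing PAI columns {missing}")
    return df


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

def read_probe_table(path) -> pd.DataFrame:
    """probe_id, chrom, bp, gene_label, is_promoter, dnam_variance TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    need = ["probe_id", "chrom", "bp"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing probe columns {missing}")
    if "is_promoter" in df.columns:
        df["is_promoter"] = df["is_promoter"].astype(bool)
    if "dnam_variance" in df.columns and (df["dnam_variance"] < 0).any():
        raise FormatError(f"{path}: negative dnam_variance")
    return df


def read_eqtl_table(path) -> pd.DataFrame:
    """snp_id, chrom, bp, gene_label, p TSV of clumped independent cis-eQTLs."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str,
                                            "gene_label": str})
    missing = [c for c in ("snp_id", "chrom", "bp", "gene_label") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing eQTL columns {missing}")
    return df


def read_tpm_matrix(path) -> pd.DataFrame:
    """gene_label x sample TPM matrix (first column = gene_label)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene labels")
    return df.astype(float)


def read_genotype_matrix(path) -> pd.DataFrame:
    """samples x SNPs allele-count matrix ({0,1,2}), SNP ids in the header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals[~np.isnan(vals)], [0, 1, 2]).all():
        raise FormatError(f"{path}: allele counts outside {{0,1,2}}")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
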