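"""Instrument selection, LD clumping, region exclusion, and strength grading.

The selection pipeline mirrors standard two-sample MR practice: keep
genome-wide-significant SNPs (p < 5e-8, strictly), greedily clump within a
10 Mb window at r^2 < 0.001, drop SNPs inside three high-pleiotropy regions
(HLA, ABO, APOE; GRCh37 coordinates already padded to +/-2 Mb), and proxy
missing outcome SNPs at r^2 > 0.6 (strictly).  All inequalities are strict at
their thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GENOME_WIDE_P = 5e-8
LENIENT_P = 5e-6

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive GRCh37 genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.label}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


#: High-pleiotropy regions excluded by default (spans include a 2 Mb pad).
DEFAULT_EXCLUSION_REGIONS = (
    Region("6", 28_909_037, 30_913_661, "HLA"),
    Region("9", 135_130_951, 137_150_617, "ABO"),
    Region("19", 44_409_011, 46_412_650, "APOE"),
)


def load_regions(path: str | Path | None = None) -> tuple[Region, ...]:
    """Read a 4-column TSV (chrom, start, end, label); default = shipped file."""
    if path is None:
        path = _DATA_DIR / "exclusion_regions.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return tuple(Region(str(r.chrom), int(r.start), int(r.end), str(r.label))
                 for r in df.itertuples())


@dataclass
class InstrumentStrength:
    """Instrument count, summed variance explained, and F statistic."""

    n: int
    k: int
    r2_total: float
    f_stat: float
    conditional_f: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.r2_total < 1):
            raise ValueError("r2_total must be in [0, 1)")
        if self.f_stat < 0:
            raise ValueError("f_stat must be >= 0")


class LDLookup:
    """Pairwise r^2 lookup; absent pairs read as 0, self-pairs as 1."""

    def __init__(self, records: pd.DataFrame | None = None):
        self._r2: dict[frozenset, float] = {}
        if records is not None:
            for a, b, r2 in zip(records["snp_a"], records["snp_b"],
                                records["r2"]):
                self._r2[frozenset((a, b))] = float(r2)

    @classmethod
    def from_file(cls, path: str | Path) -> "LDLookup":
        return cls(pd.read_csv(path, sep="\t"))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def partners(self, snp: str) -> dict[str, float]:
        out = {}
        for pair, r2 in self._r2.items():
            if snp in pair:
                others = pair - {snp}
                if others:
                    out[next(iter(others))] = r2
        return out


def select_instruments(table: pd.DataFrame,
                       p_threshold: float = GENOME_WIDE_P) -> list[str]:
    """SNPs with p strictly below threshold, ordered by (chrom, pos)."""
    if table.empty:
        raise ValueError("empty summary-statistics table")
    hits = table[table["P"] < p_threshold]
    hits = hits.sort_values(["CHR", "BP"], key=_chrom_pos_key)
    return hits["SNP"].tolist()


def _chrom_pos_key(s: pd.Series) -> pd.Series:
    if s.name == "CHR":
        def k(c):
            c = str(c)
            return int(c) if c.isdigit() else 100 + ord(c[0])
        return s.map(k)
    return s


def clump(snps: list[str], table: pd.DataFrame, ld: LDLookup,
          r2_max: float = 0.001, window_bp: int = 10_000_000) -> list[str]:
    """Greedy LD clumping: index SNPs ordered by ascending p.

    Repeatedly take the lowest-p unclaimed SNP as an index and claim every
    other unclaimed SNP on the same chromosome within ``window_bp`` of it with
    r^2 >= ``r2_max``.  Ties on p break by (chrom, pos).  Output order follows
    (chrom, pos).  SNPs unknown to the LD lookup are treated as r^2 = 0.
    """
    sub = table.set_index("SNP").loc[snps]
    order = sorted(
        snps,
        key=lambda s: (sub.at[s, "P"], _chrom_sort(sub.at[s, "CHR"]),
                       sub.at[s, "BP"]),
    )
    claimed: set[str] = set()
    index_snps: list[str] = []
    for idx in order:
        if idx in claimed:
            continue
        index_snps.append(idx)
        claimed.add(idx)
        c, p = str(sub.at[idx, "CHR"]), int(sub.at[idx, "BP"])
        for other in snps:
            if other in claimed:
                continue
            if str(sub.at[other, "CHR"]) != c:
                continue
            if abs(int(sub.at[other, "BP"]) - p) > window_bp:
                continue
            if ld.r2(idx, other) >= r2_max:
                claimed.add(other)
    index_snps.sort(key=lambda s: (_chrom_sort(sub.at[s, "CHR"]),
                                   sub.at[s, "BP"]))
    return index_snps


def _chrom_sort(c) -> int:
    c = str(c)
    return int(c) if c.isdigit() else 100 + ord(c[0])


def exclude_regions(snps: list[str], table: pd.DataFrame,
                    regions: tuple[Region, ...] = DEFAULT_EXCLUSION_REGIONS,
                    ) -> list[str]:
    """Drop SNPs falling inside any exclusion region (inclusive bounds)."""
    sub = table.set_index("SNP").loc[snps]
    keep = []
    for s in snps:
        chrom, pos = str(sub.at[s, "CHR"]), int(sub.at[s, "BP"])
        if not any(r.contains(chrom, pos) for r in regions):
            keep.append(s)
    return keep


def find_proxy(snp: str, target_table: pd.DataFrame, ld: LDLookup,
               r2_min: float = 0.6) -> str | None:
    """Best proxy present in the target table with r^2 strictly above r2_min.

    Ties on r^2 break by nearest position (when the target table carries BP),
    then lexicographic id.  Returns None when no candidate qualifies.
    """
    present = set(target_table["SNP"])
    if snp in present:
        raise ValueError(f"{snp} already present in target table")
    cands = [(other, r2) for other, r2 in ld.partners(snp).items()
             if other in present and r2 > r2_min]
    if not cands:
        return None
    pos = target_table.set_index("SNP")["BP"] if "BP" in target_table else None
    snp_pos = pos.get(snp, np.nan) if pos is not None else np.nan

    def key(item):
        other, r2 = item
        dist = abs(pos[other] - snp_pos) if pos is not None and not np.isnan(
            snp_pos) and other in pos.index else np.inf
        return (-r2, dist, other)

    return min(cands, key=key)[0]


def pool_mvmr_instruments(per_exposure_tables: list[pd.DataFrame],
                          ld: LDLookup,
                          p_threshold: float = GENOME_WIDE_P,
                          priority: str = "min-p-across",
                          r2_max: float = 0.001,
                          window_bp: int = 10_000_000,
                          regions: tuple[Region, ...] =
                          DEFAULT_EXCLUSION_REGIONS) -> list[str]:
    """Pool per-exposure instrument lists for multivariable MR.

    The union of each exposure's univariable-significant SNPs is scored by the
    lowest p across exposures (or by a single named exposure's p when
    ``priority`` is a trait name), then clumped and region-filtered with the
    univariable parameters.  Scoring precedes pruning, so an LD clump is
    represented by the SNP that is most significant for *any* exposure.
    """
    if len(per_exposure_tables) < 2:
        raise ValueError("MVMR pooling requires >= 2 exposures")
    names = [t["TRAIT"].iloc[0] for t in per_exposure_tables]
    if priority not in ("min-p-across", *names):
        raise ValueError(f"priority {priority!r} not an exposure: {names}")

    union: set[str] = set()
    for t in per_exposure_tables:
        union.update(select_instruments(t, p_threshold))
    if not union:
        return []

    indexed = [t.set_index("SNP") for t in per_exposure_tables]
    rows = []
    for snp in union:
        ps, chrom, bp = [], None, None
        for name, t in zip(names, indexed):
            if snp in t.index:
                ps.append((t.at[snp, "P"], name))
                chrom, bp = t.at[snp, "CHR"], t.at[snp, "BP"]
        if priority == "min-p-across":
            score = min(p for p, _ in ps)
        else:
            match = [p for p, name in ps if name == priority]
            score = match[0] if match else 1.0
        rows.append({"SNP": snp, "CHR": chrom, "BP": bp, "P": score})
    pooled = pd.DataFrame(rows)
    out = clump(pooled["SNP"].tolist(), pooled, ld, r2_max, window_bp)
    return exclude_regions(out, pooled, regions)


def classify_bmi_whr_groups(snps: list[str], bmi_table: pd.DataFrame,
                            whr_table: pd.DataFrame, alpha: float = 0.05,
                            ) -> dict[str, list[str]]:
    """Partition SNPs by joint association pattern with BMI and WHR.

    Each SNP is oriented so its BMI effect is positive; the WHR effect then
    classifies it: ``bmi+whr+`` (WHR p < alpha, positive), ``bmi+whr-``
    (WHR p < alpha, negative), or ``bmi_only`` (WHR p >= alpha).  The three
    groups are disjoint and exhaustive.
    """
    bmi = bmi_table.set_index("SNP")
    whr = whr_table.set_index("SNP")
    groups: dict[str, list[str]] = {"bmi+whr+": [], "bmi+whr-": [],
                                    "bmi_only": []}
    for s in snps:
        if s not in bmi.index or s not in whr.index:
            raise ValueError(f"SNP {s} missing from BMI or WHR table")
        sign = 1.0 if bmi.at[s, "BETA"] >= 0 else -1.0
        whr_beta = sign * whr.at[s, "BETA"]
        if whr.at[s, "P"] < alpha:
            groups["bmi+whr+" if whr_beta > 0 else "bmi+whr-"].append(s)
        else:
            groups["bmi_only"].append(s)
    return groups


def variance_explained(beta: float, eaf: float,
                       trait_type: str = "continuous",
                       prevalence: float | None = None) -> float:
    """Per-SNP variance explained (r^2).

    Continuous traits on the SD scale: ``r^2 = 2 * eaf * (1-eaf) * beta^2``.
    Binary traits: the log-odds effect is mapped to the liability scale with
    the threshold-model conversion ``r = beta * sqrt(2*eaf*(1-eaf)) *
    K*(1-K) / z``, where K is the population prevalence and z the standard
    normal density at the liability threshold, and r^2 = r**2.
    """
    if eaf is None or np.isnan(eaf):
        raise ValueError("variance_explained requires EAF")
    if not (0 < eaf < 1):
        raise ValueError("EAF must be in (0, 1)")
    if trait_type == "continuous":
        return float(2 * eaf * (1 - eaf) * beta ** 2)
    if trait_type == "binary":
        if prevalence is None or not (0 < prevalence < 1):
            raise ValueError("binary trait requires prevalence in (0, 1)")
        k = prevalence
        z = stats.norm.pdf(stats.norm.ppf(1 - k))
        r = beta * np.sqrt(2 * eaf * (1 - eaf)) * k * (1 - k) / z
        return float(r ** 2)
    raise ValueError(f"unknown trait_type {trait_type!r}")


def f_statistic(n: int, k: int, r2_total: float) -> float:
    """Instrument-strength F = ((n - k - 1) / k) * (R2 / (1 - R2))."""
    if n <= k + 1:
        raise ValueError("requires n > k + 1")
    if not (0 <= r2_total < 1):
        raise ValueError("r2_total must be in [0, 1)")
    return ((n - k - 1) / k) * (r2_total / (1 - r2_total))


def instrument_strength(table: pd.DataFrame, snps: list[str],
                        prevalence: float | None = None) -> InstrumentStrength:
    """Summed per-SNP r^2 and the F statistic for a selected instrument set."""
    sub = table.set_index("SNP").loc[snps]
    trait_type = str(sub["TRAIT_TYPE"].iloc[0])
    r2 = sum(variance_explained(b, f, trait_type, prevalence)
             for b, f in zip(sub["BETA"], sub["EAF"]))
    n = int(sub["N"].max())
    k = len(snps)
    return InstrumentStrength(n=n, k=k, r2_total=float(r2),
                              f_stat=f_statistic(n, k, r2))
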