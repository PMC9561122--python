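"""GWAS summary-statistics data model, file I/O, and allele harmonization.

Tables of per-SNP associations are held as :class:`pandas.DataFrame` objects in
the native column dialect (``SNP, CHR, BP, EA, OA, EAF, BETA, SE, P, N`` plus
``TRAIT`` and ``TRAIT_TYPE``).  :func:`harmonize` aligns one or more exposure
tables and an outcome table onto a common effect allele per SNP, producing a
:class:`HarmonizedSet` — the single input type consumed by every MR estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Native TSV column order.
NATIVE_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N",
                  "TRAIT", "TRAIT_TYPE"]

#: Column-name maps for common public dialects -> native names.
DIALECTS: dict[str, dict[str, str]] = {
    "native": {c: c for c in NATIVE_COLUMNS},
    # GWAS-catalog-flavoured headers
    "gwas_catalog": {
        "variant_id": "SNP", "chromosome": "CHR", "base_pair_location": "BP",
        "effect_allele": "EA", "other_allele": "OA",
        "effect_allele_frequency": "EAF", "beta": "BETA",
        "standard_error": "SE", "p_value": "P", "n": "N",
    },
}

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record for one trait.

    ``beta`` is per effect-allele copy: SD units for continuous traits,
    log-odds for binary traits.  Positions are 1-based GRCh37.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int
    trait_id: str
    trait_type: Literal["continuous", "binary"] = "continuous"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")


@dataclass
class HarmonizedSet:
    """k SNPs x (m exposures + 1 outcome), all oriented to one effect allele.

    ``exposure_beta``/``exposure_se`` are (k, m); ``outcome_beta``/``outcome_se``
    are (k,).  ``flags`` records per-SNP provenance (allele flipped per trait,
    palindromic, proxy substituted).
    """

    snp_ids: list[str]
    exposure_names: list[str]
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_name: str
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    outcome_type: Literal["continuous", "binary"] = "continuous"
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.exposure_beta = np.atleast_2d(np.asarray(self.exposure_beta, float))
        self.exposure_se = np.atleast_2d(np.asarray(self.exposure_se, float))
        if self.exposure_beta.shape[0] != len(self.snp_ids):
            # accept (m, k) input from 1-D promotion
            self.exposure_beta = self.exposure_beta.T
            self.exposure_se = self.exposure_se.T
        self.outcome_beta = np.asarray(self.outcome_beta, float)
        self.outcome_se = np.asarray(self.outcome_se, float)
        k = len(self.snp_ids)
        if k < 1:
            raise ValueError("HarmonizedSet requires k >= 1 SNPs")
        if self.exposure_beta.shape != (k, len(self.exposure_names)):
            raise ValueError("exposure matrix shape mismatch")
        if np.isnan(self.exposure_beta).any() or np.isnan(self.outcome_beta).any():
            raise ValueError("HarmonizedSet must have no missing cells")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    @property
    def scale(self) -> str:
        return "log-odds" if self.outcome_type == "binary" else "beta-SD"

    def subset(self, idx: Sequence[int]) -> "HarmonizedSet":
        idx = list(idx)
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            exposure_names=self.exposure_names,
            exposure_beta=self.exposure_beta[idx],
            exposure_se=self.exposure_se[idx],
            outcome_name=self.outcome_name,
            outcome_beta=self.outcome_beta[idx],
            outcome_se=self.outcome_se[idx],
            outcome_type=self.outcome_type,
            flags=self.flags.iloc[idx].reset_index(drop=True)
            if self.flags is not None else None,
        )

    def single_exposure(self, name: str | None = None) -> "HarmonizedSet":
        """Project onto one exposure (default: the first)."""
        j = 0 if name is None else self.exposure_names.index(name)
        return HarmonizedSet(
            snp_ids=list(self.snp_ids),
            exposure_names=[self.exposure_names[j]],
            exposure_beta=self.exposure_beta[:, [j]],
            exposure_se=self.exposure_se[:, [j]],
            outcome_name=self.outcome_name,
            outcome_beta=self.outcome_beta,
            outcome_se=self.outcome_se,
            outcome_type=self.outcome_type,
            flags=self.flags,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide export, one row per SNP."""
        d: dict[str, object] = {"SNP": self.snp_ids}
        for j, name in enumerate(self.exposure_names):
            d[f"beta_{name}"] = self.exposure_beta[:, j]
            d[f"se_{name}"] = self.exposure_se[:, j]
        d[f"beta_{self.outcome_name}"] = self.outcome_beta
        d[f"se_{self.outcome_name}"] = self.outcome_se
        return pd.DataFrame(d)


@dataclass
class MREstimate:
    """One estimator's causal-effect output."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    scale: str = "beta-SD"
    exposure: str = ""
    outcome: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
                raise ValueError("estimate outside its own CI")

    @property
    def odds_ratio(self) -> float | None:
        """exp(estimate), reported only on the log-odds scale."""
        return float(np.exp(self.estimate)) if self.scale == "log-odds" else None

    def to_row(self) -> dict:
        row = {
            "method": self.method, "exposure": self.exposure,
            "outcome": self.outcome, "scale": self.scale,
            "estimate": self.estimate, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pval, "n_snps": self.n_snps,
            "or": self.odds_ratio,
        }
        for key in ("cochran_q", "egger_intercept", "egger_intercept_p"):
            if key in self.diagnostics:
                row[key] = self.diagnostics[key]
        return row


def _normal_ci(estimate: float, se: float) -> tuple[float, float, float]:
    z = estimate / se if se > 0 else np.inf * np.sign(estimate)
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    half = stats.norm.ppf(0.975) * se
    return estimate - half, estimate + half, float(p)


def make_estimate(method: str, estimate: float, se: float, n_snps: int,
                  scale: str = "beta-SD", exposure: str = "", outcome: str = "",
                  diagnostics: dict | None = None) -> MREstimate:
    lo, hi, p = _normal_ci(estimate, se)
    return MREstimate(method=method, estimate=float(estimate), se=float(se),
                      ci_low=lo, ci_high=hi, pval=p, n_snps=n_snps, scale=scale,
                      exposure=exposure, outcome=outcome,
                      diagnostics=diagnostics or {})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sumstats(path: str | Path, dialect: str = "native",
                  trait_id: str | None = None,
                  trait_type: str | None = None) -> pd.DataFrame:
    """Read a summary-statistics TSV into the native dialect.

    Rows with missing BETA or SE, or non-positive SE, are dropped with a
    logged count.  P-values grossly inconsistent with beta/se trigger a
    warning, never a failure.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "chromosome": str})
    df = df.rename(columns=DIALECTS[dialect])
    required = {"SNP", "CHR", "BP", "EA", "OA", "BETA", "SE", "P", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "EAF" not in df.columns:
        df["EAF"] = np.nan
    if trait_id is not None:
        df["TRAIT"] = trait_id
    elif "TRAIT" not in df.columns:
        df["TRAIT"] = Path(path).stem
    if trait_type is not None:
        df["TRAIT_TYPE"] = trait_type
    elif "TRAIT_TYPE" not in df.columns:
        df["TRAIT_TYPE"] = "continuous"

    bad = df["BETA"].isna() | df["SE"].isna() | (df["SE"] <= 0)
    if bad.any():
        logger.warning("%s: dropped %d rows with missing beta/se or se<=0",
                       path, int(bad.sum()))
        df = df[~bad]
    dup = df.duplicated(subset=["TRAIT", "SNP"])
    if dup.any():
        raise ValueError(f"{path}: duplicated (trait, snp_id) pairs: "
                         f"{df.loc[dup, 'SNP'].tolist()[:5]}")
    with np.errstate(divide="ignore"):
        implied = 2 * stats.norm.sf(np.abs(df["BETA"] / df["SE"]))
    off = np.abs(np.log10(np.maximum(implied, 1e-300))
                 - np.log10(np.maximum(df["P"], 1e-300))) > 1.0
    if off.any():
        logger.warning("%s: %d p-values inconsistent with beta/se (kept)",
                       path, int(off.sum()))
    df = df[NATIVE_COLUMNS].reset_index(drop=True)
    df["CHR"] = df["CHR"].astype(str)
    return df


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a native-dialect table; lossless inverse of :func:`read_sumstats`."""
    cols = [c for c in NATIVE_COLUMNS if c in table.columns]
    table.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="NA",
                              float_format="%.10g")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((ea, oa)) in PALINDROMIC_PAIRS


def _complement(a: str) -> str:
    return a.translate(_COMPLEMENT)


def _orient_row(ref_ea: str, ref_oa: str, ea: str, oa: str):
    """Return (sign, flipped, ok) mapping a trait's alleles onto the reference.

    Tries direct match, swap, strand complement, and complement+swap, in that
    order.  ``sign`` multiplies beta; ``flipped`` marks an allele swap.
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return 1.0, False, True
    if (ea, oa) == (ref_oa, ref_ea):
        return -1.0, True, True
    cea, coa = _complement(ea), _complement(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return 1.0, False, True
    if (cea, coa) == (ref_oa, ref_ea):
        return -1.0, True, True
    return 0.0, False, False


def harmonize(exposure_tables: Sequence[pd.DataFrame],
              outcome_table: pd.DataFrame,
              palindrome_policy: str = "eaf",
              eaf_ambiguous: tuple[float, float] = (0.42, 0.58),
              proxy_map: dict[str, str] | None = None) -> HarmonizedSet:
    """Align exposure and outcome effects onto a common effect allele per SNP.

    The first exposure's reported alleles define the reference orientation.
    For every other trait, a swapped allele pair negates beta and replaces EAF
    by 1-EAF; pairs incompatible even after strand complement are removed with
    a log message.  Palindromic (A/T, C/G) SNPs are handled per policy:

    - ``"eaf"`` (default): dropped when the reference EAF falls in
      ``eaf_ambiguous``, otherwise oriented by comparing minor-allele side;
      palindromes with missing EAF are dropped.
    - ``"strict"``: all palindromic SNPs dropped.
    - ``"keep"``: treated like any other SNP (forward-strand inputs only).

    ``proxy_map`` maps an exposure SNP id to the outcome-table SNP id standing
    in for it (see ``instruments.find_proxy``); the proxy row's own alleles
    are harmonized, and the SNP is flagged ``proxy``.
    """
    if palindrome_policy not in ("eaf", "strict", "keep"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    proxy_map = proxy_map or {}

    tables = list(exposure_tables) + [outcome_table]
    indexed = [t.set_index("SNP", drop=False) for t in tables]
    out_idx = indexed[-1]
    exposure_names = [t["TRAIT"].iloc[0] for t in exposure_tables]
    outcome_name = outcome_table["TRAIT"].iloc[0]
    outcome_type = str(outcome_table["TRAIT_TYPE"].iloc[0])

    # intersection across all traits, with proxy substitution on the outcome
    common: list[str] = []
    for snp in indexed[0].index:
        if all(snp in t.index for t in indexed[1:-1]):
            if snp in out_idx.index or snp in proxy_map:
                common.append(snp)
    if not common:
        raise ValueError("empty SNP intersection across traits")

    rows = []
    for snp in common:
        ref = indexed[0].loc[snp]
        ref_ea, ref_oa, ref_eaf = ref["EA"], ref["OA"], ref["EAF"]
        palin = is_palindromic(ref_ea, ref_oa)
        if palin and palindrome_policy == "strict":
            logger.info("dropping palindromic SNP %s (strict policy)", snp)
            continue
        if palin and palindrome_policy == "eaf":
            if pd.isna(ref_eaf):
                logger.info("dropping palindromic SNP %s (no EAF)", snp)
                continue
            lo, hi = eaf_ambiguous
            if lo <= ref_eaf <= hi:
                logger.info("dropping palindromic SNP %s (EAF %.3f ambiguous)",
                            snp, ref_eaf)
                continue

        betas, ses, flips = [], [], []
        ok = True
        for t_i, tab in enumerate(indexed):
            lookup = snp
            used_proxy = False
            if t_i == len(indexed) - 1 and snp not in out_idx.index:
                lookup = proxy_map[snp]
                used_proxy = True
            rec = tab.loc[lookup]
            if t_i == len(indexed) - 1 and used_proxy:
                # proxy carries its own alleles; orientation only by EAF side
                sign = 1.0
                if not pd.isna(rec["EAF"]) and not pd.isna(ref_eaf):
                    if (rec["EAF"] - 0.5) * (ref_eaf - 0.5) < 0:
                        sign = -1.0
                betas.append(sign * rec["BETA"])
                ses.append(rec["SE"])
                flips.append(sign < 0)
                continue
            sign, flipped, match = _orient_row(ref_ea, ref_oa, rec["EA"], rec["OA"])
            if not match:
                logger.warning("SNP %s: alleles %s/%s incompatible with %s/%s "
                               "in trait %d; removed", snp, rec["EA"], rec["OA"],
                               ref_ea, ref_oa, t_i)
                ok = False
                break
            if palin and palindrome_policy == "eaf" and not pd.isna(rec["EAF"]):
                # alleles cannot resolve strand for palindromes; use allele
                # frequency side instead
                eaf_here = rec["EAF"] if sign > 0 else 1 - rec["EAF"]
                if (eaf_here - 0.5) * (ref_eaf - 0.5) < 0:
                    sign, flipped = -sign, not flipped
            betas.append(sign * rec["BETA"])
            ses.append(rec["SE"])
            flips.append(flipped)
        if not ok:
            continue
        rows.append((snp, betas, ses, flips, palin,
                     snp not in out_idx.index))

    if not rows:
        raise ValueError("no SNPs survived harmonization")

    m = len(exposure_names)
    snp_ids = [r[0] for r in rows]
    beta_mat = np.array([r[1] for r in rows], float)
    se_mat = np.array([r[2] for r in rows], float)
    flags = pd.DataFrame({
        "SNP": snp_ids,
        "palindromic": [r[4] for r in rows],
        "proxy": [r[5] for r in rows],
        "any_allele_flip": [any(r[3]) for r in rows],
    })
    return HarmonizedSet(
        snp_ids=snp_ids,
        exposure_names=exposure_names,
        exposure_beta=beta_mat[:, :m],
        exposure_se=se_mat[:, :m],
        outcome_name=outcome_name,
        outcome_beta=beta_mat[:, m],
        outcome_se=se_mat[:, m],
        outcome_type="binary" if outcome_type == "binary" else "continuous",
        flags=flags,
    )
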