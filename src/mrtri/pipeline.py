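"""End-to-end orchestration: selection -> clumping -> harmonization -> MR.

:func:`run_pipeline` reproduces the full triangulation workflow over a set of
in-memory summary-statistics tables: univariable estimator suite per
exposure/outcome pair (optionally bidirectional), the multivariable suite
with pooled instruments and conditional F statistics, and mediation
arithmetic comparing univariable total with multivariable direct effects.
Every threshold used is captured in the run log, and a fixed seed makes the
whole report deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import instruments as ins
from . import multivariable as mv
from . import univariable as uv
from .mediation import proportion_mediated
from .sumstats import HarmonizedSet, harmonize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    exposures: list[str] = dc_field(default_factory=list)
    outcome: str = "outcome"
    p_threshold: float = ins.GENOME_WIDE_P
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    proxy_r2: float = 0.6
    exclude_regions: bool = True
    methods: tuple[str, ...] = tuple(uv.UNIVARIABLE_METHODS)
    mvmr_methods: tuple[str, ...] = tuple(mv.MVMR_METHODS)
    pooling: str = "min-p-across"
    bidirectional: bool = False
    run_mvmr: bool = True
    n_boot: int = 200
    presso_n_sim: int = 500
    prevalence: float | None = None
    seed: int = 0


@dataclass
class PipelineReport:
    estimates: pd.DataFrame
    strength: pd.DataFrame
    mediation: pd.DataFrame
    log: dict

    def write(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(d / "mr_estimates.tsv", sep="\t", index=False,
                              float_format="%.10g")
        self.strength.to_csv(d / "instrument_strength.tsv", sep="\t",
                             index=False, float_format="%.10g")
        self.mediation.to_csv(d / "mediation.tsv", sep="\t", index=False,
                              float_format="%.10g")
        with open(d / "run_log.txt", "w") as fh:
            for key, val in sorted(self.log.items()):
                fh.write(f"{key}\t{val}\n")


def _instrument_set(table: pd.DataFrame, ld: ins.LDLookup,
                    cfg: PipelineConfig) -> list[str]:
    snps = ins.select_instruments(table, cfg.p_threshold)
    if not snps:
        return []
    snps = ins.clump(snps, table, ld, cfg.clump_r2, cfg.clump_window_bp)
    if cfg.exclude_regions:
        snps = ins.exclude_regions(snps, table)
    return snps


def _with_proxies(snps: list[str], outcome_table: pd.DataFrame,
                  ld: ins.LDLookup, cfg: PipelineConfig
                  ) -> tuple[list[str], dict[str, str]]:
    present = set(outcome_table["SNP"])
    kept, proxy_map = [], {}
    for s in snps:
        if s in present:
            kept.append(s)
            continue
        proxy = ins.find_proxy(s, outcome_table, ld, cfg.proxy_r2)
        if proxy is None:
            logger.info("SNP %s absent from outcome and no proxy; dropped", s)
            continue
        kept.append(s)
        proxy_map[s] = proxy
    return kept, proxy_map


def _run_univariable(h: HarmonizedSet, cfg: PipelineConfig) -> list:
    out = []
    for name in cfg.methods:
        fn = uv.UNIVARIABLE_METHODS[name]
        try:
            if name in ("weighted_median", "weighted_mode"):
                est = fn(h, n_boot=cfg.n_boot, seed=cfg.seed)
            elif name == "mr_presso":
                est = fn(h, n_sim=cfg.presso_n_sim, seed=cfg.seed)
            else:
                est = fn(h)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"stage univariable:{name} "
                               f"({h.exposure_names[0]} -> {h.outcome_name})"
                               f" failed: {exc}") from exc
        out.append(est)
    return out


def run_pipeline(tables: dict[str, pd.DataFrame], ld: ins.LDLookup,
                 cfg: PipelineConfig) -> PipelineReport:
    """Run the full workflow and return deterministic tabular reports.

    ``tables`` maps trait id -> native-dialect summary statistics; the
    exposures and outcome named in ``cfg`` must be present.  Any stage error
    propagates with its stage name attached.
    """
    for t in (*cfg.exposures, cfg.outcome):
        if t not in tables:
            raise KeyError(f"trait {t!r} not among supplied tables")
    estimates, strength_rows, mediation_rows = [], [], []
    log = {
        "p_threshold": cfg.p_threshold, "clump_r2": cfg.clump_r2,
        "clump_window_bp": cfg.clump_window_bp, "proxy_r2": cfg.proxy_r2,
        "exclude_regions": cfg.exclude_regions, "pooling": cfg.pooling,
        "seed": cfg.seed, "n_boot": cfg.n_boot,
        "presso_n_sim": cfg.presso_n_sim,
    }

    pairs = [(e, cfg.outcome) for e in cfg.exposures]
    if cfg.bidirectional:
        pairs += [(cfg.outcome, e) for e in cfg.exposures]

    total_effects: dict[tuple[str, str], float] = {}
    for exp_name, out_name in pairs:
        exp_t, out_t = tables[exp_name], tables[out_name]
        try:
            snps = _instrument_set(exp_t, ld, cfg)
        except ValueError as exc:
            raise RuntimeError(f"stage select ({exp_name}): {exc}") from exc
        if not snps:
            logger.warning("no instruments for %s at p<%g; pair skipped",
                           exp_name, cfg.p_threshold)
            log[f"k_{exp_name}->{out_name}"] = 0
            continue
        snps, proxy_map = _with_proxies(snps, out_t, ld, cfg)
        if not snps:
            log[f"k_{exp_name}->{out_name}"] = 0
            continue
        sub = exp_t[exp_t["SNP"].isin(snps)]
        h = harmonize([sub], out_t, proxy_map=proxy_map)
        log[f"k_{exp_name}->{out_name}"] = h.n_snps
        prev = cfg.prevalence if str(
            exp_t["TRAIT_TYPE"].iloc[0]) == "binary" else None
        st = ins.instrument_strength(exp_t, [s for s in snps
                                             if s in set(h.snp_ids)], prev)
        strength_rows.append({"exposure": exp_name, "outcome": out_name,
                              "analysis": "univariable", "n": st.n,
                              "k": st.k, "r2_total": st.r2_total,
                              "f_stat": st.f_stat, "conditional_f": np.nan})
        for est in _run_univariable(h, cfg):
            estimates.append(est.to_row())
            if est.method in ("ivw", "wald_ratio"):
                total_effects[(exp_name, out_name)] = est.estimate

    direct_effects: dict[str, float] = {}
    if cfg.run_mvmr and len(cfg.exposures) >= 2:
        exp_tables = [tables[e] for e in cfg.exposures]
        try:
            pooled = ins.pool_mvmr_instruments(
                exp_tables, ld, cfg.p_threshold, cfg.pooling,
                cfg.clump_r2, cfg.clump_window_bp,
                ins.DEFAULT_EXCLUSION_REGIONS if cfg.exclude_regions else ())
        except ValueError as exc:
            raise RuntimeError(f"stage mvmr-pool: {exc}") from exc
        out_t = tables[cfg.outcome]
        pooled, proxy_map = _with_proxies(pooled, out_t, ld, cfg)
        subs = []
        for t in exp_tables:
            # MVMR requires every pooled SNP in every exposure table
            subs.append(t[t["SNP"].isin(pooled)])
        common = set.intersection(*(set(s["SNP"]) for s in subs))
        subs = [s[s["SNP"].isin(common)] for s in subs]
        h = harmonize(subs, out_t, proxy_map=proxy_map)
        log["k_mvmr"] = h.n_snps
        cond = mv.conditional_f(h)
        for name, cf in cond.items():
            if cf < 10:
                logger.warning("conditional F for %s is %.2f (< 10): "
                               "weak-instrument bias possible", name, cf)
            strength_rows.append({"exposure": name, "outcome": cfg.outcome,
                                  "analysis": "mvmr", "n": np.nan,
                                  "k": h.n_snps, "r2_total": np.nan,
                                  "f_stat": np.nan, "conditional_f": cf})
        for mname in cfg.mvmr_methods:
            fn = mv.MVMR_METHODS[mname]
            try:
                if mname == "mvmr_median":
                    ests = fn(h, n_boot=cfg.n_boot, seed=cfg.seed)
                else:
                    ests = fn(h)
            except ValueError as exc:
                raise RuntimeError(f"stage {mname}: {exc}") from exc
            for est in ests:
                estimates.append(est.to_row())
                if mname == "mvmr_ivw":
                    direct_effects[est.exposure] = est.estimate

        for exp_name in cfg.exposures:
            key = (exp_name, cfg.outcome)
            if key in total_effects and exp_name in direct_effects:
                med = proportion_mediated(total_effects[key],
                                          direct_effects[exp_name],
                                          scale=h.scale)
                others = [e for e in cfg.exposures if e != exp_name]
                mediation_rows.append({
                    "exposure": exp_name, "outcome": cfg.outcome,
                    "mediators": ",".join(others),
                    "theta_total": med.theta_total,
                    "theta_direct": med.theta_direct,
                    "proportion_mediated_pct": med.percent,
                    "inconsistent": med.inconsistent,
                })

    est_df = pd.DataFrame(estimates)
    return PipelineReport(
        estimates=est_df,
        strength=pd.DataFrame(strength_rows),
        mediation=pd.DataFrame(mediation_rows),
        log=log,
    )
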