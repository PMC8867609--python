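"""End-to-end orchestration: simulate -> qc -> region stats -> screen -> associate.

One YAML configuration drives the whole run; every stage writes its
outputs under the run directory and the manifest (JSON) records the
config hash, seed and per-stage bookkeeping (input = retained + removed).
Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import association, qc, regionstats, screening
from .errors import MethaploError, ValidationError
from .io_formats import (
    RegionPanel,
    read_beta_matrix,
    read_read_patterns,
    read_region_panel,
    read_sample_meta,
    write_beta_matrix,
    write_read_patterns,
    write_region_panel,
    write_sample_meta,
)
from .simulate import EffectSpec, SimConfig, simulate_beta_cohorts, simulate_read_cohort

logger = logging.getLogger(__name__)

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "n_cases": 60,
        "n_controls": 60,
        "depth_mean": 150.0,
        "rho": 0.4,
        "baseline_pi": 0.5,
        "subject_sd": 0.4,
        "conversion_rate": 0.99,
        "miss_rate": 0.01,
        "n_regions": 2,
        "cpgs_per_region": 4,
        "effects": {},
        "beta": {
            "n_probes": 300,
            "n_spiked": 5,
            "delta_beta": 0.05,
            "noise_sd": 0.05,
            "n1_case": 60,
            "n1_ctrl": 60,
            "n2_case": 50,
            "n2_ctrl": 50,
            "blacklist_frac": 0.05,
            "miss_frac": 0.02,
        },
    },
    "qc": {
        "min_conversion": 0.95,
        "min_depth": 100,
        "max_site_missing": 0.30,
    },
    "screen": {
        "p_thresh": 0.05,
        "delta_thresh": 0.015,
        "max_probe_missing": 0.10,
        "knn_k": 10,
        "welch": False,
    },
    "associate": {
        "covariates": ["age", "family_history_bc", "family_history_other"],
        "bonferroni_m": 1,
    },
}


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-backed, defaults applied)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = _merge(_DEFAULTS, self.raw or {})
        q = self.raw["qc"]
        if not (0.0 <= q["min_conversion"] <= 1.0):
            raise ValidationError("qc.min_conversion outside [0, 1]")
        if q["min_depth"] < 0:
            raise ValidationError("qc.min_depth must be >= 0")
        if not (0.0 <= q["max_site_missing"] <= 1.0):
            raise ValidationError("qc.max_site_missing outside [0, 1]")
        s = self.raw["screen"]
        if not (0.0 < s["p_thresh"] <= 1.0):
            raise ValidationError("screen.p_thresh outside (0, 1]")
        if s["delta_thresh"] < 0:
            raise ValidationError("screen.delta_thresh must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(raw=data)

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def default_panel(n_regions: int, cpgs_per_region: int) -> dict[str, RegionPanel]:
    """Synthetic amplicon panel: evenly spaced CpGs on chr1."""
    panels = {}
    for r in range(n_regions):
        rid = f"R{r + 1}"
        start = 1_000_000 * (r + 1)
        panels[rid] = RegionPanel(
            region_id=rid,
            chrom="chr1",
            cpg_positions=tuple(start + 10 * i for i in range(cpgs_per_region)),
        )
    return panels


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute every stage, write outputs under *out_dir*, return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    def _fail(stage: str, msg: str):
        manifest["stages"][stage] = {"status": "failed", "error": msg}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise MethaploError(f"stage {stage!r}: {msg}")

    # -- stage: simulate ---------------------------------------------------
    sim = cfg["simulate"]
    if "inputs" in cfg.raw:
        paths = cfg.raw["inputs"]
        panels = read_region_panel(paths["regions"])
        rps = read_read_patterns(paths["reads"])
        meta = read_sample_meta(paths["meta"])
        bm1 = read_beta_matrix(paths["beta1"])
        bm2 = read_beta_matrix(paths["beta2"])
        manifest["stages"]["simulate"] = {"status": "skipped (external inputs)"}
    else:
        panels = default_panel(int(sim["n_regions"]), int(sim["cpgs_per_region"]))
        sim_cfg = SimConfig(
            n_cases=int(sim["n_cases"]),
            n_controls=int(sim["n_controls"]),
            depth_mean=float(sim["depth_mean"]),
            rho=float(sim["rho"]),
            baseline_pi=sim["baseline_pi"],
            subject_sd=float(sim["subject_sd"]),
            conversion_rate=float(sim["conversion_rate"]),
            miss_rate=float(sim["miss_rate"]),
            seed=cfg.seed,
        )
        effects = [
            EffectSpec(target=rid, delta_logit=float(d))
            for rid, d in sim["effects"].items()
        ]
        rps, meta = simulate_read_cohort(panels, sim_cfg, effects)
        bcfg = sim["beta"]
        bm1, bm2 = simulate_beta_cohorts(
            n_probes=int(bcfg["n_probes"]),
            n_spiked=int(bcfg["n_spiked"]),
            delta_beta=float(bcfg["delta_beta"]),
            noise_sd=float(bcfg["noise_sd"]),
            n1_case=int(bcfg["n1_case"]),
            n1_ctrl=int(bcfg["n1_ctrl"]),
            n2_case=int(bcfg["n2_case"]),
            n2_ctrl=int(bcfg["n2_ctrl"]),
            seed=cfg.seed + 1,
            blacklist_frac=float(bcfg["blacklist_frac"]),
            miss_frac=float(bcfg["miss_frac"]),
        )
        write_region_panel(panels, out / "regions.bed")
        write_read_patterns(rps, out / "reads.tsv")
        write_sample_meta(meta, out / "meta.tsv")
        write_beta_matrix(bm1, out / "beta_cohort1.tsv")
        write_beta_matrix(bm2, out / "beta_cohort2.tsv")
        manifest["stages"]["simulate"] = {
            "status": "ok",
            "n_samples": len(meta),
            "n_regions": len(panels),
            "n_read_entries": len(rps),
            "n_probes": int(len(bm1.probe_ids)),
        }

    rps.validate_against_panel(panels)

    # -- stage: qc ---------------------------------------------------------
    qcfg = cfg["qc"]
    n_pairs_in = len(rps.depth_table())
    filtered, report = qc.apply_qc(
        rps, panels, meta,
        min_conversion=float(qcfg["min_conversion"]),
        min_depth=int(qcfg["min_depth"]),
        max_site_missing=float(qcfg["max_site_missing"]),
    )
    report.sample_records.to_csv(out / "qc_samples.tsv", sep="\t", index=False)
    report.site_records.to_csv(out / "qc_sites.tsv", sep="\t", index=False)
    n_pairs_kept = len(filtered.depth_table())
    sites_removed = int((~report.site_records["kept"]).sum())
    manifest["stages"]["qc"] = {
        "status": "ok",
        "sample_regions_in": n_pairs_in,
        "sample_regions_kept": n_pairs_kept,
        "sample_regions_removed": n_pairs_in - n_pairs_kept,
        "sites_in": len(report.site_records),
        "sites_kept": len(report.site_records) - sites_removed,
        "sites_removed": sites_removed,
    }
    if n_pairs_kept == 0:
        _fail("qc", "no samples remain after QC")

    # -- stage: region stats ----------------------------------------------
    measures = {}
    for rid, panel in panels.items():
        if rid not in filtered.region_ids:
            continue
        mask = report.site_mask(panel)
        if not mask.any():
            logger.warning("region %s: all sites failed QC; skipping", rid)
            continue
        wml_s = regionstats.wml_by_sample(filtered, panel, site_kept=mask)
        mhb_s = regionstats.mhb_by_sample(filtered, panel)
        measures[f"{rid}_WML"] = wml_s
        measures[f"{rid}_MHB"] = mhb_s
        ht = regionstats.haplotype_table(filtered, panel)
        ht.table.to_csv(out / f"haplotypes_{rid}.tsv", sep="\t", index=False)
        betas = regionstats.sample_beta_frame(filtered, panel)
        com = regionstats.comethylation(betas, region_id=rid)
        com.rho.to_csv(out / f"comethylation_{rid}.tsv", sep="\t")
    if not measures:
        _fail("region_stats", "no region survived QC")
    measures_df = pd.DataFrame(measures)
    measures_df.index.name = "sample_id"
    measures_df.to_csv(out / "measures.tsv", sep="\t", na_rep="NA")
    manifest["stages"]["region_stats"] = {
        "status": "ok",
        "n_measures": len(measures),
        "n_samples": int(len(measures_df)),
    }

    # -- stage: screen -----------------------------------------------------
    scfg = cfg["screen"]
    dmc_a, dmc_b, inter = screening.screen_cohorts(
        bm1, bm2,
        p_thresh=float(scfg["p_thresh"]),
        delta_thresh=float(scfg["delta_thresh"]),
        max_probe_missing=float(scfg["max_probe_missing"]),
        k=int(scfg["knn_k"]),
        welch=bool(scfg["welch"]),
    )
    dmc_a.to_csv(out / "dmc_cohort1.tsv", sep="\t", index_label="probe_id")
    dmc_b.to_csv(out / "dmc_cohort2.tsv", sep="\t", index_label="probe_id")
    inter.to_csv(out / "dmc_intersection.tsv", sep="\t", index_label="probe_id")
    manifest["stages"]["screen"] = {
        "status": "ok",
        "probes_in": int(len(bm1.probe_ids)),
        "probes_tested_cohort1": int(len(dmc_a)),
        "selected_cohort1": int(dmc_a["selected"].sum()),
        "selected_cohort2": int(dmc_b["selected"].sum()),
        "intersection": int(len(inter)),
    }

    # -- stage: associate --------------------------------------------------
    acfg = cfg["associate"]
    status = pd.Series({sid: m.status for sid, m in meta.items()})
    cov_cols = list(acfg["covariates"])
    cov_df = pd.DataFrame(
        {
            sid: {
                "age": meta[sid].age,
                "family_history_bc": meta[sid].family_history_bc,
                "family_history_other": meta[sid].family_history_other,
            }
            for sid in meta
        }
    ).T
    rows = []
    for name, series in measures_df.items():
        vals = series.dropna()
        st = status.loc[vals.index]
        try:
            cut = association.youden_cutoff(vals.to_numpy(), st.to_numpy())
        except ValidationError as exc:
            logger.warning("measure %s: %s", name, exc)
            continue
        labels, _ = association.dichotomize(vals, cut.cutoff)
        table = association.crosstab(labels, st)
        res = association.odds_ratio_2x2(table)
        row = {
            "measure": name,
            "cutoff": cut.cutoff,
            "youden_j": cut.j,
            "a_case_hypo": table.a,
            "b_case_hyper": table.b,
            "c_control_hypo": table.c,
            "d_control_hyper": table.d,
            "or_univariate": round(res.or_point, 3),
            "ci_low": round(res.ci_low, 3),
            "ci_high": round(res.ci_high, 3),
            "chi2": round(res.chi2, 3) if res.chi2 is not None else np.nan,
            "p_value": res.p_value,
        }
        cov_sub = cov_df.loc[vals.index, cov_cols].astype(float)
        if cov_cols and res.converged and not cov_sub.isna().any().any():
            try:
                fit = association.logistic_fit(
                    st.to_numpy(), labels.loc[vals.index].to_numpy(),
                    covariates=cov_sub, exposure_name=name,
                )
                adj = fit[name]
                row["or_adjusted"] = round(adj.or_point, 3)
                row["ci_low_adj"] = round(adj.ci_low, 3)
                row["ci_high_adj"] = round(adj.ci_high, 3)
                row["p_adjusted_model"] = adj.p_value
            except ValidationError as exc:
                logger.warning("adjusted model for %s failed: %s", name, exc)
        rows.append(row)
    if not rows:
        _fail("associate", "no measure could be dichotomized")
    assoc_df = pd.DataFrame(rows)
    m = int(acfg["bonferroni_m"])
    if m > 1 and len(assoc_df) <= m:
        assoc_df["p_bonferroni"] = association.bonferroni(
            assoc_df["p_value"].to_numpy(), m
        )
    assoc_df.to_csv(out / "association.tsv", sep="\t", index=False, na_rep="NA")
    manifest["stages"]["associate"] = {
        "status": "ok",
        "n_measures": int(len(assoc_df)),
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
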