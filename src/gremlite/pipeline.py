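"""Config-driven end-to-end analysis runner.

A single YAML (or dict) config describes the cohort (simulated or a
PLINK prefix), the QC regime, the liability parameters, which partition
schemes to run, and the permutation budgets.  ``run_pipeline`` executes
the stages in dependency order — QC, PCA, GRM, REML with liability
transform, partitioned heritability, GWAS with and without the
skin-color covariate, eQTL enrichment — and writes one consolidated JSON
report carrying every stage's numbers plus full provenance (seeds,
thresholds, package version).  Every random draw descends from the
single root seed via named substreams, so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import gremlite
from gremlite import qc as qc_mod
from gremlite.architecture import (
    chromosome_lengths,
    h2_length_regression,
    maf_bin_h2,
    per_chromosome_h2,
)
from gremlite.assoc import gwas_logistic
from gremlite.enrichment import eqtl_enrichment
from gremlite.grm import compute_grm, pca
from gremlite.io import read_plink
from gremlite.reml import LiabilityParams, fit_reml
from gremlite.sim import SimConfig, assign_annotations, simulate_case_control_cohort, simulate_skin_color

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "ConfigError"]

_VALID_SCHEMES = ("chromosome", "maf_bin")
_VALID_REGIMES = ("standard", "stringent", "none")


class ConfigError(ValueError):
    """One or more configuration problems, all collected."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline config:\n  - " + "\n  - ".join(errors))


@dataclass
class PipelineConfig:
    """Normalized pipeline parameters (defaults materialized)."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    input_prefix: str | None = None  # PLINK prefix; None -> simulate
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    qc_regime: str = "stringent"
    prevalence_K: float = 0.02
    n_pcs_heritability: int = 20
    n_pcs_association: int = 2
    partition_schemes: list[str] = field(default_factory=lambda: ["chromosome", "maf_bin"])
    gwas_skin_color: bool = True
    enrichment: dict = field(
        default_factory=lambda: {"run": True, "top_k": 100, "B": 50, "threshold": 0.01}
    )
    overwrite: bool = False


def validate_config(source) -> PipelineConfig:
    """Load and validate a config path / dict, collecting every error.

    Raises :class:`ConfigError` listing all problems at once rather than
    stopping at the first.
    """
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text())
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise ConfigError([f"YAML parse error{line}: {exc}"]) from exc
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    errors: list[str] = []
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown option {key!r}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})

    if not 0 < cfg.prevalence_K < 1:
        errors.append(f"prevalence_K must be in (0,1), got {cfg.prevalence_K}")
    if cfg.qc_regime not in _VALID_REGIMES:
        errors.append(f"unknown qc_regime {cfg.qc_regime!r}; valid: {_VALID_REGIMES}")
    for scheme in cfg.partition_schemes:
        if scheme not in _VALID_SCHEMES:
            errors.append(f"unknown partition scheme {scheme!r}; valid: {_VALID_SCHEMES}")
    if cfg.input_prefix is not None and not Path(f"{cfg.input_prefix}.bed").exists():
        errors.append(f"input prefix {cfg.input_prefix!r}: no .bed file found")
    if cfg.n_pcs_heritability < 0 or cfg.n_pcs_association < 0:
        errors.append("PC counts must be >= 0")
    if cfg.enrichment.get("run") and cfg.enrichment.get("B", 0) < 1:
        errors.append("enrichment.B must be >= 1")
    if cfg.input_prefix is None:
        try:
            SimConfig(**{**cfg.simulate, "seed": cfg.seed})
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate block: {exc}")
    if errors:
        raise ConfigError(errors)
    return cfg


def _substream(root_seed: int, name: str) -> int:
    """Stable per-stage seed below 2^31 derived from the root seed."""
    h = np.random.SeedSequence([root_seed, zlib.crc32(name.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute all configured stages; returns (and writes) the report.

    Refuses to overwrite a previous run's report unless
    ``overwrite: true`` is set.  Any stage failure raises with the stage
    name in the message.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    out = Path(cfg.out_dir)
    report_path = out / "report.json"
    if report_path.exists() and not cfg.overwrite:
        raise FileExistsError(
            f"{report_path} exists from a previous run; set overwrite: true to replace it"
        )
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "provenance": {
            "package_version": gremlite.__version__,
            "seed": cfg.seed,
            "config": {k: v for k, v in cfg.__dict__.items()},
        },
        "stages": {},
        "timings_s": {},
    }

    @contextmanager
    def stage(name: str):
        t0 = time.perf_counter()
        try:
            yield
        except ConfigError:
            raise
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["timings_s"][name] = round(time.perf_counter() - t0, 3)

    # ------------------------------------------------------------ input
    with stage("input"):
        if cfg.input_prefix is not None:
            geno = read_plink(cfg.input_prefix)
            truth = None
        else:
            sim_cfg = SimConfig(**{**cfg.simulate, "seed": _substream(cfg.seed, "simulate")})
            geno, labels, truth = simulate_case_control_cohort(sim_cfg)
            if cfg.gwas_skin_color:
                geno.samples["skin_color"] = simulate_skin_color(
                    geno, sim_cfg.skin_color_loci, sim_cfg.skin_color_noise_sd,
                    _substream(cfg.seed, "skin_color"),
                )
        if cfg.gwas_skin_color and "skin_color" not in geno.samples:
            raise ConfigError(["skin-color GWAS requested but the data carries no skin color"])
        status = geno.samples["status"].to_numpy()
        if pd.isna(status).any():
            raise ValueError("missing case/control status")
    report["stages"]["input"] = {
        "n_samples": geno.n,
        "n_snps": geno.m,
        "case_fraction": float(np.mean(status)),
        "simulated": cfg.input_prefix is None,
    }
    if truth is not None:
        report["stages"]["input"]["true_h2"] = truth.target_h2

    # --------------------------------------------------------------- qc
    with stage('qc'):
        if cfg.qc_regime != "none":
            regime = qc_mod.STANDARD_QC if cfg.qc_regime == "standard" else qc_mod.STRINGENT_QC
            regime = qc_mod.QCConfig(**{**regime.__dict__, "relatedness_max": None})
            geno, snp_report = qc_mod.filter_snps(geno, regime, status=status)
            geno, sample_report = qc_mod.filter_samples(geno, regime)
            status = geno.samples["status"].to_numpy()
            report["stages"]["qc"] = {
                "regime": cfg.qc_regime,
                "snps": snp_report.as_dict(),
                "samples": sample_report.as_dict(),
            }

    # -------------------------------------------------------- grm + pca
    with stage('grm_pca'):
        grm = compute_grm(geno)
        k_max = max(cfg.n_pcs_heritability, cfg.n_pcs_association)
        k_max = min(k_max, geno.n - 1)
        pcs = pca(grm, k_max) if k_max > 0 else None
        report["stages"]["pca"] = {
            "k": k_max,
            "n_outliers": int(pcs.outlier.sum()) if pcs else 0,
            "degenerate": bool(pcs.degenerate) if pcs else None,
        }

    # ------------------------------------------------------------- reml
    with stage('reml'):
        liability = LiabilityParams(K=cfg.prevalence_K, P=float(np.mean(status)))
        cov_h2 = pcs.components[:, : min(cfg.n_pcs_heritability, k_max)] if pcs else None
        fit = fit_reml(status, cov_h2, [grm], component_names=["genome"], liability=liability)
        report["stages"]["reml"] = {
            "h2_obs": float(fit.h2_obs[0]),
            "h2_obs_se": float(fit.h2_obs_se[0]),
            "h2_liability": float(fit.h2_liab[0]),
            "h2_liability_se": float(fit.h2_liab_se[0]),
            "liability_factor": liability.factor,
            "logL": fit.logL,
            "converged": fit.converged,
            "K": cfg.prevalence_K,
            "P": float(np.mean(status)),
        }

    # ------------------------------------------------------- partitions
    with stage('partitions'):
        partitions = {}
        for scheme in cfg.partition_schemes:
            if scheme == "chromosome":
                part = per_chromosome_h2(geno, status, cov_h2, liability_params=liability)
                entry = {
                    "table": part.table.to_dict(orient="records"),
                    "joint": part.joint,
                    "h2_obs_sum": float(part.table["h2_obs"].sum()),
                }
                if len(part.table) >= 3:
                    reg = h2_length_regression(part.table, chromosome_lengths(geno))
                    entry["length_regression"] = {
                        "r": reg.r,
                        "p": reg.p_value,
                        "slope": reg.slope,
                        "outliers": reg.outliers,
                    }
                partitions["chromosome"] = entry
            elif scheme == "maf_bin":
                part = maf_bin_h2(geno, status, cov_h2, liability_params=liability)
                partitions["maf_bin"] = {
                    "table": part.table.to_dict(orient="records"),
                    "joint": part.joint,
                    "h2_obs_sum": float(part.table["h2_obs"].sum()),
                }
        if partitions:
            report["stages"]["partitions"] = partitions

    # ------------------------------------------------------------- gwas
    with stage('gwas'):
        cov_assoc_arr = pcs.components[:, : min(cfg.n_pcs_association, k_max)] if pcs else None
        cov_assoc = None
        cols = {}
        for col in ("age", "sex"):
            if col in geno.samples:
                cols[col] = geno.samples[col].astype(float)
        if cov_assoc_arr is not None:
            for j in range(cov_assoc_arr.shape[1]):
                cols[f"pc{j + 1}"] = cov_assoc_arr[:, j]
        if cols:
            cov_assoc = pd.DataFrame(cols)
        scan = gwas_logistic(geno, status=status, covariates=cov_assoc)
        scan.table.to_csv(out / "gwas.tsv", sep="\t", index=False)
        report["stages"]["gwas"] = {
            "lambda_gc": scan.lambda_gc,
            "covariates": scan.covariate_names,
            "min_p": float(np.nanmin(scan.table["p"])),
            "n_genome_wide": int((scan.table["p"] < 5e-8).sum()),
            "n_suggestive": int((scan.table["p"] < 1e-5).sum()),
        }
        if cfg.gwas_skin_color:
            scan_sc = gwas_logistic(
                geno, status=status, covariates=cov_assoc, include_skin_color=True
            )
            report["stages"]["gwas_skin_color"] = {
                "lambda_gc": scan_sc.lambda_gc,
                "n_dropped_missing_skin": scan_sc.n_dropped,
                "min_p": float(np.nanmin(scan_sc.table["p"])),
            }

    # ------------------------------------------------------- enrichment
    with stage('enrichment'):
        if cfg.enrichment.get("run", False):
            thr = cfg.enrichment.get("threshold", 0.01)
            ann = assign_annotations(
                geno.snps["snp"],
                genic_fraction=0.49,
                eqtl_fraction_by_threshold={thr: cfg.enrichment.get("eqtl_fraction", 0.23)},
                seed=_substream(cfg.seed, "annotations"),
            )
            enr = eqtl_enrichment(
                geno,
                status,
                cov_assoc,
                ann[f"eqtl_{thr:g}"].to_numpy(),
                top_k=min(cfg.enrichment.get("top_k", 100), geno.m),
                B=cfg.enrichment.get("B", 50),
                seed=_substream(cfg.seed, "enrichment"),
            )
            report["stages"]["enrichment"] = {
                "observed_count": enr.observed_count,
                "empirical_p": enr.p_value,
                "top_k": enr.top_k,
                "B": enr.effective_B,
                "threshold": thr,
            }

    report_path.write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
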