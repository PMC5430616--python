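"""Configuration-driven orchestration of the full scan pipeline.

Stage order: qc -> prune -> pca -> proxies -> admix -> freqs -> scan ->
report.  Every stage writes its artifact into the output directory and the
final manifest records parameters, seeds, per-stage counts and sha256
checksums of the written files, which is sufficient to replay the run.
Identical config and inputs reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .admixture import component_freqs_given_Q, fit_supervised, fit_unsupervised
from .fst import fst_bootstrap_ci, fst_sample
from .genotypes import GenotypeMatrix, QcThresholds, allele_freq, filter_snps, intersect_snps, ld_prune
from .pca import pca_fit, pca_project
from .proxies import proxy_size_curve, rank_by_pc, select_proxies
from .scan import regions_to_bed, scan_lsbl, scan_pairwise, top_regions
from .simulate import CohortSpec, make_study

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["qc", "prune", "pca", "proxies", "admix", "freqs", "scan", "report"]

#: Allowed config keys; nested dicts validate recursively, None allows any value.
_SCHEMA: dict[str, Any] = {
    "seed": None,
    "out_dir": None,
    "input": {
        "mode": None,
        "cohort_spec": None,  # CohortSpec fields, validated by the dataclass
        "cohort": None,
        "cohort_format": None,
        "reference": None,
        "reference_format": None,
    },
    "qc": {"call_rate_min": None, "maf_min": None},
    "prune": {"r2_max": None, "window_snps": None, "step_snps": None},
    "pca": {"n_components": None},
    "proxies": {
        "poles": None,
        "n_proxy": None,
        "auto_n_candidates": None,
        "auto_B": None,
    },
    "admixture": {"K": None, "mode": None, "tol": None, "max_iter": None, "n_restarts": None},
    "scan": {"mode": None, "focal": None, "comparison": None, "top_k": None, "merge_bp": None},
    "bootstrap": {"B": None, "alpha": None},
}

_DEFAULTS: dict[str, Any] = {
    "qc": {"call_rate_min": 0.99, "maf_min": 0.05},
    "prune": {"r2_max": 0.3, "window_snps": 50, "step_snps": 5},
    "pca": {"n_components": 4},
    "proxies": {"n_proxy": 30, "auto_n_candidates": [10, 20, 30, 40], "auto_B": 60},
    "admixture": {"K": 3, "mode": "supervised", "tol": 1e-7, "max_iter": 2000, "n_restarts": 3},
    "scan": {"mode": "lsbl", "focal": "amr", "comparison": None, "top_k": 10, "merge_bp": 1_000_000},
    "bootstrap": {"B": 1000, "alpha": 0.05},
}


class ConfigError(ValueError):
    pass


def _validate_keys(data: dict, schema: dict, path: str = "") -> None:
    for key, value in data.items():
        if key not in schema:
            raise ConfigError(f"unknown config key {path + key!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {path + key!r} must be a mapping")
            _validate_keys(value, sub, path + key + ".")


@dataclass
class PipelineConfig:
    raw: dict = field(repr=False)
    seed: int = 0
    out_dir: Path = Path("admixscan_run")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        _validate_keys(data, _SCHEMA)
        if "seed" not in data:
            raise ConfigError("config must set an explicit 'seed'")
        if "input" not in data:
            raise ConfigError("config must declare an 'input' section")
        merged = copy.deepcopy(_DEFAULTS)
        for section, defaults in _DEFAULTS.items():
            merged[section].update(data.get(section, {}))
        merged["input"] = data["input"]
        mode = merged["input"].get("mode")
        if mode not in {"simulate", "files"}:
            raise ConfigError("input.mode must be 'simulate' or 'files'")
        if mode == "files":
            for key in ("cohort", "reference"):
                path = merged["input"].get(key)
                if path is None or not Path(path).exists():
                    raise ConfigError(f"input.{key} file not found: {path}")
        if merged["admixture"]["mode"] == "supervised" and "poles" not in merged["proxies"]:
            raise ConfigError("proxies.poles required for a supervised run")
        return cls(
            raw=merged,
            seed=int(data["seed"]),
            out_dir=Path(data.get("out_dir", "admixscan_run")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, until: str = "report") -> dict:
    """Execute the stages in order up to ``until``; returns the run manifest."""
    if until not in STAGES:
        raise ConfigError(f"unknown stage {until!r}; stages are {STAGES}")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config": config.raw,
        "stages": [],
        "outputs": {},
    }
    state: dict[str, Any] = {}
    seeds = np.random.SeedSequence(config.seed).generate_state(len(STAGES) + 1)

    _load_inputs(config, state, out, manifest)
    for stage_idx, stage in enumerate(STAGES):
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, state, out, manifest, int(seeds[stage_idx]))
        except Exception:
            logger.error("stage %s failed; partial outputs preserved in %s", stage, out)
            _write_manifest(manifest, out)
            raise
        manifest["stages"].append(
            {"name": stage, "seconds": round(time.perf_counter() - t0, 3)}
        )
        logger.info("stage %s done in %.2fs", stage, manifest["stages"][-1]["seconds"])
        if stage == until:
            break
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _load_inputs(config: PipelineConfig, state: dict, out: Path, manifest: dict) -> None:
    inp = config["input"]
    if inp["mode"] == "simulate":
        spec_kwargs = dict(inp.get("cohort_spec") or {})
        spec_kwargs.setdefault("seed", config.seed)
        for key in ("drift", "dirichlet_alpha", "labels", "ancestral_freq_range"):
            if key in spec_kwargs and isinstance(spec_kwargs[key], list):
                spec_kwargs[key] = tuple(spec_kwargs[key])
        if "outliers" in spec_kwargs:
            spec_kwargs["outliers"] = tuple(tuple(o) for o in spec_kwargs["outliers"])
        spec = CohortSpec(**spec_kwargs)
        study = make_study(spec)
        state["cohort"] = study.cohort
        state["reference"] = study.combined().subset_samples(
            [s for pool in study.proxy_pools.values() for s in pool.samples]
        )
        state["truth"] = study.truth
        manifest["input"] = {"mode": "simulate", "cohort_spec": spec_kwargs}
    else:
        state["cohort"] = gio.read_genotypes(inp["cohort"], inp.get("cohort_format"))
        state["reference"] = gio.read_genotypes(inp["reference"], inp.get("reference_format"))
        manifest["input"] = {
            "mode": "files",
            "cohort": str(inp["cohort"]),
            "cohort_sha256": _sha256(Path(inp["cohort"])),
            "reference": str(inp["reference"]),
            "reference_sha256": _sha256(Path(inp["reference"])),
        }


def _stage_qc(config, state, out, manifest, seed) -> None:
    thr = QcThresholds(**config["qc"])
    cohort, report = filter_snps(state["cohort"], thr)
    cohort, reference = intersect_snps(cohort, state["reference"])
    state["cohort_qc"] = cohort
    state["reference_qc"] = reference
    gio.write_genotypes(cohort, out / "cohort_qc.tsv")
    manifest["qc"] = {
        "snps_in": state["cohort"].n_snps,
        "snps_after_filters": report.n_retained,
        "snps_after_intersection": cohort.n_snps,
        "samples": cohort.n_samples,
    }


def _stage_prune(config, state, out, manifest, seed) -> None:
    kept = ld_prune(state["cohort_qc"], **config["prune"])
    state["pruned_ids"] = kept
    (out / "pruned_snps.txt").write_text("\n".join(kept) + "\n")
    manifest["prune"] = {"snps_in": state["cohort_qc"].n_snps, "snps_retained": len(kept)}


def _stage_pca(config, state, out, manifest, seed) -> None:
    cohort = state["cohort_qc"].subset_snps(state["pruned_ids"])
    reference = state["reference_qc"].subset_snps(state["pruned_ids"])
    model, scores = pca_fit(cohort, cohort.samples, config["pca"]["n_components"])
    ref_scores = pca_project(model, reference)
    state["pca_model"] = model
    state["cohort_scores"] = scores
    state["reference_scores"] = ref_scores
    scores.to_csv(out / "cohort_scores.tsv", sep="\t")
    ref_scores.to_csv(out / "reference_scores.tsv", sep="\t")
    manifest["pca"] = {
        "n_components": model.n_components,
        "eigenvalues": model.eigenvalues.tolist(),
    }


def _stage_proxies(config, state, out, manifest, seed) -> None:
    cfg = config["proxies"]
    poles = cfg.get("poles")
    if config["admixture"]["mode"] != "supervised":
        state["panels"] = []
        manifest["proxies"] = {"skipped": "unsupervised run"}
        return
    rankings = {
        pole["ancestry"]: rank_by_pc(
            state["reference_scores"], pole["pc_index"], pole["direction"]
        )
        for pole in poles
    }
    n_proxy = cfg["n_proxy"]
    if n_proxy == "auto":
        combined = _combined_matrix(state, pruned=True)
        curve = proxy_size_curve(
            combined, rankings, cfg["auto_n_candidates"], B=cfg["auto_B"], seed=seed
        )
        n_proxy = curve.argmin_n
        pd.DataFrame(
            {"n": curve.n_values, "se_mean": curve.se_mean}
        ).to_csv(out / "proxy_size_curve.tsv", sep="\t", index=False)
    pc_info = {p["ancestry"]: (p["pc_index"], p["direction"]) for p in poles}
    panels = select_proxies(rankings, int(n_proxy), pc_info)
    state["panels"] = panels
    rows = [
        {"sample_id": sid, "ancestry": p.ancestry, "rank": r + 1}
        for p in panels
        for r, sid in enumerate(p.sample_ids)
    ]
    pd.DataFrame(rows).to_csv(out / "proxy_panels.tsv", sep="\t", index=False)
    manifest["proxies"] = {"n_proxy": int(n_proxy), "ancestries": [p.ancestry for p in panels]}


def _combined_matrix(state, pruned: bool) -> GenotypeMatrix:
    cohort = state["cohort_qc"]
    reference = state["reference_qc"]
    if pruned:
        cohort = cohort.subset_snps(state["pruned_ids"])
        reference = reference.subset_snps(state["pruned_ids"])
    return GenotypeMatrix(
        list(cohort.samples) + list(reference.samples),
        list(cohort.snps),
        np.vstack([cohort.dosage, reference.dosage]),
    )


def _stage_admix(config, state, out, manifest, seed) -> None:
    cfg = config["admixture"]
    if cfg["mode"] == "supervised":
        proxy_ids = [s for p in state["panels"] for s in p.sample_ids]
        assignment = {s: p.ancestry for p in state["panels"] for s in p.sample_ids}
        combined = _combined_matrix(state, pruned=True)
        cohort_ids = state["cohort_qc"].samples
        used = combined.subset_samples(list(cohort_ids) + proxy_ids)
        fit = fit_supervised(
            used, assignment, K=cfg["K"], seed=seed, tol=cfg["tol"],
            max_iter=cfg["max_iter"], n_restarts=cfg["n_restarts"],
        )
    else:
        fit = fit_unsupervised(
            state["cohort_qc"].subset_snps(state["pruned_ids"]), cfg["K"], seed=seed,
            tol=cfg["tol"], max_iter=cfg["max_iter"], n_restarts=cfg["n_restarts"],
        )
    state["fit"] = fit
    q = fit.q_frame()
    q.index.name = "sample_id"
    q.to_csv(out / "ancestry_Q.tsv", sep="\t")
    np.savetxt(out / "admixture.Q", fit.Q, fmt="%.6f")
    np.savetxt(out / "admixture.P", fit.P.T, fmt="%.6f")
    manifest["admix"] = {
        "mode": fit.mode, "K": fit.K, "loglik": fit.loglik,
        "n_iter": fit.n_iter, "converged": fit.converged,
        "mean_ancestry": {
            c: float(m) for c, m in zip(
                fit.components, fit.Q[: state["cohort_qc"].n_samples].mean(axis=0)
            )
        },
    }


def _stage_freqs(config, state, out, manifest, seed) -> None:
    fit = state["fit"]
    if fit.mode == "supervised":
        full = _combined_matrix(state, pruned=False)
        full = full.subset_samples(fit.samples)
    else:
        full = state["cohort_qc"]
    P_full = component_freqs_given_Q(full, fit.Q)
    state["P_full"] = P_full
    state["freq_snps"] = full.snps
    df = pd.DataFrame(P_full.T, columns=[f"f_{c}" for c in fit.components])
    df.insert(0, "id", [s.id for s in full.snps])
    df.to_csv(out / "component_freqs.tsv", sep="\t", index=False)
    manifest["freqs"] = {"snps": int(P_full.shape[1])}


def _stage_scan(config, state, out, manifest, seed) -> None:
    cfg = config["scan"]
    fit = state["fit"]
    P_full = state["P_full"]
    snps = state["freq_snps"]
    if cfg["mode"] == "lsbl":
        focal = fit.components.index(cfg["focal"])
        table = scan_lsbl(P_full, snps, focal=focal, component_names=fit.components)
    elif cfg["mode"] == "pairwise":
        comparison = cfg.get("comparison")
        if comparison is None:
            raise ConfigError("scan.comparison panel required in pairwise mode")
        focal = fit.components.index(cfg["focal"])
        comp_samples = [
            s for s in state["reference_qc"].samples if s.startswith(comparison)
        ]
        full_ref = state["reference_qc"]
        freq, n = allele_freq(full_ref, comp_samples)
        table = scan_pairwise(
            P_full[focal], freq, snps, mode="param",
            focal_name=cfg["focal"], comp_name=comparison,
        )
        q_bar = float(fit.Q[: state["cohort_qc"].n_samples, focal].mean())
        n_focal = np.full(len(snps), max(2, round(2 * state["cohort_qc"].n_samples * q_bar)))
        pairs = fst_sample(P_full[focal], n_focal, freq, np.maximum(n, 2))
        bcfg = config["bootstrap"]
        ci = fst_bootstrap_ci(pairs, B=bcfg["B"], alpha=bcfg["alpha"], seed=seed)
        manifest["scan_fst_ci"] = {
            "point": ci.point, "lower": ci.lower, "upper": ci.upper, "B": ci.B,
        }
    else:
        raise ConfigError("scan.mode must be 'lsbl' or 'pairwise'")
    state["scan_table"] = table
    table.to_tsv(out / "scan.tsv")
    manifest["scan"] = {"mode": cfg["mode"], "summary": table.summary}


def _stage_report(config, state, out, manifest, seed) -> None:
    cfg = config["scan"]
    regions = top_regions(state["scan_table"], k=cfg["top_k"], merge_bp=cfg["merge_bp"])
    rows = [
        {
            "region": r.region_id, "chrom": r.chromosome, "start": r.start_bp,
            "end": r.end_bp, "n_snps": len(r.snp_ids),
            "snps": ",".join(r.snp_ids), "max_stat": r.max_stat,
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(out / "regions.tsv", sep="\t", index=False)
    regions_to_bed(regions).to_csv(out / "regions.bed", sep="\t", index=False, header=False)
    manifest["report"] = {"top_k": cfg["top_k"], "n_regions": len(regions)}


_STAGE_FUNCS = {
    "qc": _stage_qc,
    "prune": _stage_prune,
    "pca": _stage_pca,
    "proxies": _stage_proxies,
    "admix": _stage_admix,
    "freqs": _stage_freqs,
    "scan": _stage_scan,
    "report": _stage_report,
}
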