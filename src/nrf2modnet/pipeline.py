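"""End-to-end pipeline orchestration with a manifest for reproducibility.

Stage order: simulate (optional) -> fold-change -> modules -> scores ->
screen + enrichment (optional, needs knockdown inputs) -> classify ->
evaluate.  Every run writes its stage outputs plus ``manifest.json``
recording the configuration hash, seed and a checksum per output file, so a
rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enrichment_mod
from . import io as io_mod
from . import network as network_mod
from . import performance as perf_mod
from . import scoring as scoring_mod
from . import screen as screen_mod
from . import synthetic as synthetic_mod

log = logging.getLogger("nrf2modnet")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {"enabled": True, "design": {}, "sirna": {"enabled": True}},
    "network": {
        "candidate_powers": [4, 6, 8, 10],
        "min_module_size": 5,
        "merge_eigengene_correlation": 0.8,
        "cut_height": 0.99,
    },
    "thresholds": {"perturbation": 2.0, "adjusted_p": 0.05},
    "enrichment": {"universe": "matrix"},
    "evaluate": {"features": ["reactivity", "bioactivation", "dili_concern"]},
    "inputs": {},
}


def merge_config(user: dict | None) -> dict:
    def deep(a, b):
        out = dict(a)
        for k, v in (b or {}).items():
            out[k] = deep(a[k], v) if isinstance(v, dict) and isinstance(a.get(k), dict) else v
        return out

    return deep(DEFAULT_CONFIG, user or {})


def load_config(path) -> dict:
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Execute all stages; returns the machine-readable run summary."""
    config = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    summary: dict = {"seed": seed, "stages": {}}
    stage = "init"
    try:
        # --- inputs -------------------------------------------------------
        stage = "simulate"
        if config["synthetic"]["enabled"]:
            design = synthetic_mod.SyntheticDesign(seed=seed, **config["synthetic"]["design"])
            intensities, sheet, truth = synthetic_mod.generate_perturbation_dataset(design)
            io_mod.write_expression_matrix(intensities, outdir / "intensities.tsv")
            sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
            truth.gene_module_assignment.rename("module_id").to_csv(
                outdir / "truth_modules.tsv", sep="\t"
            )
            truth.compound_labels.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
            annotations = truth.compound_labels
            log.info("simulate: %d genes, %d samples", *intensities.shape)
        else:
            truth = None
            intensities = io_mod.read_expression_matrix(config["inputs"]["intensities"])
            sheet = io_mod.read_sample_sheet(config["inputs"]["sample_sheet"])
            annotations = io_mod.read_compound_annotations(config["inputs"]["annotations"])

        # --- fold changes -------------------------------------------------
        stage = "fold-change"
        fcm = io_mod.compute_fold_changes(intensities, sheet)
        fcm.write_tsv(outdir / "fold_changes.tsv")
        vehicle_cols = sheet.loc[sheet["is_vehicle"].astype(int) == 1, "sample_id"]
        vehicle_intensity = intensities[vehicle_cols].mean(axis=1)

        # --- module detection --------------------------------------------
        stage = "modules"
        net_cfg = network_mod.NetworkConfig(
            candidate_powers=tuple(config["network"]["candidate_powers"]),
            min_module_size=int(config["network"]["min_module_size"]),
            merge_eigengene_correlation=float(config["network"]["merge_eigengene_correlation"]),
            cut_height=float(config["network"]["cut_height"]),
        )
        mset = network_mod.detect_modules(fcm, net_cfg, vehicle_intensity)
        assignment = mset.assignment()
        summary["stages"]["modules"] = {
            "soft_power_used": mset.soft_power_used,
            "power_selection_tstats": {
                str(k): (None if not np.isfinite(v) else float(v))
                for k, v in mset.power_selection_tstats.items()
            },
            "n_modules": len(mset.modules),
            "n_assigned": int((assignment != "").sum()),
        }
        log.info("modules: %d modules at power %s", len(mset.modules), mset.soft_power_used)

        # --- scores -------------------------------------------------------
        stage = "score"
        scores = scoring_mod.compute_module_scores(fcm, mset)
        corrs = scoring_mod.eigengene_gene_correlation(fcm, mset, scores)
        scores.z_scores.reset_index().to_csv(outdir / "module_scores.tsv", sep="\t", index=False)
        membership = pd.DataFrame(
            [
                (m.module_id, g, corrs[m.module_id][g], m.hub_gene == g)
                for m in mset.modules
                for g in m.genes
            ],
            columns=["module_id", "gene", "eigengene_correlation", "is_hub"],
        )
        membership.to_csv(outdir / "module_membership.tsv", sep="\t", index=False)

        if truth is not None:
            from sklearn.metrics import adjusted_rand_score

            truth_labels = truth.gene_module_assignment
            pred = assignment.loc[truth_labels.index]
            summary["stages"]["modules"]["recovery_ari"] = float(
                adjusted_rand_score(truth_labels.to_numpy(), pred.to_numpy())
            )

        # --- siRNA screen + enrichment -----------------------------------
        stage = "screen"
        sirna_cfg = config["synthetic"].get("sirna", {})
        screen_genes: set[str] | None = None
        alpha = float(config["thresholds"]["adjusted_p"])
        if config["synthetic"]["enabled"] and sirna_cfg.get("enabled", True):
            params = {k: v for k, v in sirna_cfg.items() if k != "enabled"}
            params.setdefault("gene_universe", list(fcm.genes))
            if truth is not None and truth.nrf2_dependent_genes is not None:
                params.setdefault("target_genes", list(truth.nrf2_dependent_genes.index))
                # NRF2-repressed genes live outside the planted modules, as
                # most screen genes did not meet co-expression criteria
                unassigned = truth.gene_module_assignment
                pool = list(unassigned.index[unassigned == ""])
                params.setdefault("repressed_genes", pool[-15:])
            params.setdefault("seed", seed + 1)
            s_int, s_sheet, s_truth = synthetic_mod.generate_sirna_dataset(**params)
            nrf2_res, keap1_res, hits = screen_mod.run_screen(s_int, s_sheet, alpha=alpha)
            screen_mod.hits_to_frame(hits).to_csv(outdir / "screen_hits.tsv", sep="\t", index=False)
            screen_genes = {h.gene for h in hits}
            summary["stages"]["screen"] = {"n_hits": len(hits)}
        elif "sirna_intensities" in config["inputs"]:
            s_int = io_mod.read_expression_matrix(config["inputs"]["sirna_intensities"])
            s_sheet = pd.read_csv(config["inputs"]["sirna_sheet"], sep="\t")
            nrf2_res, keap1_res, hits = screen_mod.run_screen(s_int, s_sheet, alpha=alpha)
            screen_mod.hits_to_frame(hits).to_csv(outdir / "screen_hits.tsv", sep="\t", index=False)
            screen_genes = {h.gene for h in hits}
            summary["stages"]["screen"] = {"n_hits": len(hits)}
        else:
            log.info("screen: no siRNA inputs configured; stage skipped")

        stage = "enrich"
        enriched_modules: list[str] = []
        if screen_genes:
            universe = set(fcm.genes)
            if config["enrichment"]["universe"] == "assigned":
                universe = {g for m in mset.modules for g in m.genes}
            tested = screen_genes & universe
            if tested:
                enr = enrichment_mod.hypergeometric_enrichment(mset, tested, universe, alpha=alpha)
                enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                enriched_modules = list(enr.loc[enr["enriched"], "module_id"])
                summary["stages"]["enrich"] = {"n_tested": len(enr), "n_enriched": len(enriched_modules)}
            else:
                log.info("enrich: no screen hits inside the universe; stage skipped")
        else:
            log.info("enrich: no screen hits available; stage skipped")

        # --- classification and evaluation -------------------------------
        stage = "classify"
        threshold = float(config["thresholds"]["perturbation"])
        # the pathway-associated metric uses the screen-enriched modules when
        # the screen ran; otherwise every module contributes
        eval_modules = enriched_modules or list(scores.z_scores.columns)
        calls = perf_mod.call_perturbations(scores.z_scores, eval_modules, threshold=threshold)
        calls.to_csv(outdir / "perturbation_calls.tsv", sep="\t")
        summary["stages"]["classify"] = {
            "modules_used": eval_modules,
            "n_positive_combined": int(calls["positive_combined"].sum()),
            "threshold": threshold,
        }

        stage = "evaluate"
        reports = []
        max_combined = scores.z_scores[eval_modules].groupby(level="compound").max().max(axis=1)
        for feature in config["evaluate"]["features"]:
            try:
                rep = perf_mod.performance_indicators(calls, annotations, feature)
            except ValueError as exc:
                log.info("evaluate: feature %s skipped (%s)", feature, exc)
                continue
            pos_labels, neg_labels = perf_mod.FEATURE_CLASSES[feature]
            col = perf_mod.FEATURE_COLUMN[feature]
            ann = annotations.set_index("compound")[col]
            in_contrast = ann[ann.isin(pos_labels + neg_labels)]
            labels = in_contrast.isin(pos_labels)
            auc, _ = perf_mod.roc_auc(max_combined.loc[in_contrast.index], labels)
            rep["auc"] = auc
            reports.append(rep)
        report_df = pd.DataFrame(reports)
        report_df.to_csv(outdir / "performance.tsv", sep="\t", index=False)
        summary["stages"]["evaluate"] = {
            r["feature"]: {k: r[k] for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "auc")}
            for r in reports
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    # --- manifest --------------------------------------------------------
    cfg_text = json.dumps(config, sort_keys=True, default=str)
    summary["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {
        "config_sha256": summary["config_sha256"],
        "seed": seed,
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
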