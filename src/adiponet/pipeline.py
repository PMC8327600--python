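"""Configuration-driven orchestration of the synthetic end-to-end analysis.

``run_pipeline`` executes the stages in dependency order (simulate ->
network discovery -> preservation -> enrichment bookkeeping -> partitioned
heritability -> PRS -> TWAS -> fine-mapping -> eQTL/DE), writes each stage's
outputs under the configured directory, and records a JSON manifest of
output files, SHA-256 checksums and the seeds used.  Stages absent from the
config are skipped and noted in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as anio
from .simdata import (SimConfig, simulate_genotypes, simulate_expression,
                      simulate_traits, simulate_sumstats, network_cis_window)
from .network import ModuleDetector, module_trait_association
from .preservation import preservation_zsummary
from .ldsc import LdscRegression, gene_set_annotation
from .prs import LdpredInf, quantile_odds_ratios, score_individuals
from .twas import (cis_window_variants, CisExpressionModel, twas_association,
                   bonferroni_gate)
from .focus import FocusFineMapper, predicted_expression_corr
from .eqtl_de import cis_eqtl_scan, trans_eqtl_eigengene, de_moderated

logger = logging.getLogger(__name__)

STAGE_ORDER = ["synthdata", "netdiscover", "netpreserve", "ldscreg", "prs",
               "twas", "focus", "eqtl_de"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages on synthetic data; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": {}, "skipped": []}
    state: dict = {}

    def record(stage: str, files: dict[str, Path], extra: dict | None = None):
        entry = {"outputs": {k: str(v) for k, v in files.items()},
                 "sha256": {k: _sha256(Path(v)) for k, v in files.items()}}
        if extra:
            entry["info"] = extra
        manifest["stages"][stage] = entry

    for stage in STAGE_ORDER:
        if stage not in config:
            manifest["skipped"].append(stage)
            continue
        params = config[stage] or {}
        logger.info("stage %s", stage)
        if stage == "synthdata":
            fields = {f.name for f in dataclasses.fields(SimConfig)}
            cfg = SimConfig(**{k: v for k, v in params.items()
                               if k in fields}, seed=seed)
            panel = simulate_genotypes(cfg)
            expr, truth = simulate_expression(panel, cfg)
            quant, binary, sex, ttruth = simulate_traits(panel, truth, cfg)
            ss = simulate_sumstats(panel, quant)
            state.update(cfg=cfg, panel=panel, expr=expr, truth=truth,
                         quant=quant, binary=binary, sex=sex,
                         trait_truth=ttruth, sumstats=ss)
            files = {}
            files["dosages"] = outdir / "dosages.tsv"
            anio.write_dosage_tsv(panel, files["dosages"])
            files["expression"] = outdir / "expression.tsv"
            anio.write_expression_tsv(expr, files["expression"])
            files["annotation_bed"] = outdir / "genes.bed"
            files["tss"] = outdir / "tss.tsv"
            anio.write_annotation(truth.gene_annot, files["annotation_bed"],
                                  files["tss"])
            files["sumstats"] = outdir / "sumstats.tsv"
            anio.write_sumstats(ss, files["sumstats"])
            files["truth"] = outdir / "truth.json"
            anio.write_truth(truth, files["truth"])
            record(stage, files)
        elif stage == "netdiscover":
            det = ModuleDetector(power=params.get("power", 6),
                                 cut_height=params.get("cut_height", 0.99),
                                 min_module_size=params.get(
                                     "min_module_size", 20))
            det.fit(state["expr"])
            traits = pd.DataFrame({"quant": state["quant"]},
                                  index=state["expr"].index)
            assoc = module_trait_association(det.eigengenes_, traits)
            state["detector"] = det
            files = {"labels": outdir / "labels.tsv",
                     "eigengenes": outdir / "eigengenes.tsv",
                     "kme": outdir / "kme.tsv",
                     "module_trait": outdir / "module_trait.tsv"}
            det.labels_.rename("module").to_csv(files["labels"], sep="\t",
                                                index_label="gene")
            det.eigengenes_.to_csv(files["eigengenes"], sep="\t")
            det.kme_.to_csv(files["kme"], sep="\t")
            assoc.to_csv(files["module_trait"], sep="\t", index=False)
            record(stage, files,
                   {"n_modules": int((det.labels_ != "unassigned").any() and
                                     det.eigengenes_.shape[1])})
        elif stage == "netpreserve":
            rng = np.random.default_rng(seed + 10)
            expr = state["expr"]
            half = rng.permutation(len(expr))
            test = expr.iloc[half[: len(expr) // 2]]
            pres = preservation_zsummary(expr, test,
                                         state["detector"].labels_,
                                         n_perm=params.get("n_perm", 100),
                                         seed=seed + 11)
            files = {"preservation": outdir / "preservation.tsv"}
            pres.to_csv(files["preservation"], sep="\t", index=False)
            record(stage, files)
        elif stage == "ldscreg":
            truth = state["truth"]
            ann = gene_set_annotation(state["panel"].variants,
                                      truth.gene_annot,
                                      gene_set=truth.module_genes,
                                      flank=params.get("flank", 500_000))
            reg = LdscRegression(n_blocks=params.get("n_blocks", 20))
            reg.fit(state["sumstats"], state["panel"], ann)
            files = {"partitioned_h2": outdir / "partitioned_h2.tsv"}
            reg.result_.table.to_csv(files["partitioned_h2"], sep="\t",
                                     index=False)
            record(stage, files, {"h2_total": reg.h2_total_,
                                  "intercept": reg.intercept_})
        elif stage == "prs":
            model = LdpredInf(h2=params.get("h2", state["cfg"].h2_trait))
            model.fit(state["sumstats"], state["panel"])
            scores = model.predict(state["panel"])
            tables = quantile_odds_ratios(scores, state["quant"],
                                          strata=state["sex"])
            files = {"weights": outdir / "prs_weights.tsv"}
            model.weights_.weights.to_csv(files["weights"], sep="\t",
                                          index=False)
            for s, t in tables.items():
                f = outdir / f"prs_quantile_or_sex{s}.tsv"
                t.to_csv(f, sep="\t", index=False)
                files[f"quantile_or_sex{s}"] = f
            record(stage, files,
                   {"prs_trait_r": float(np.corrcoef(
                       scores, state["quant"])[0, 1])})
        elif stage == "twas":
            truth = state["truth"]
            panel = state["panel"]
            flank = params.get("flank", 500_000)
            rows, gene_models = [], {}
            genes = params.get("genes") or [truth.hub_gene]
            for gene in genes:
                g = truth.gene_annot.loc[gene]
                cis = cis_window_variants(g, panel.variants, flank=flank)
                idx = cis.index.to_numpy()
                cem = CisExpressionModel(seed=seed)
                cem.fit(panel.dosages[:, idx],
                        state["expr"][gene].to_numpy())
                if not cem.passed_:
                    continue
                z = panel.standardized()[:, idx]
                V = z.T @ z / panel.n_individuals
                zg = state["sumstats"]["Z"].to_numpy()[idx]
                zt, p = twas_association(cem.coef_, zg, V)
                gene_models[gene] = (cem, idx, V)
                rows.append((gene, cem.model_, cem.cv_r2_, cem.cv_p_,
                             cem.hsq_, cem.hsq_p_, zt, p))
            tab = pd.DataFrame(rows, columns=["gene", "model", "cv_r2",
                                              "cv_p", "hsq", "hsq_p",
                                              "z_twas", "p"])
            if len(tab):
                tab["significant"] = bonferroni_gate(tab["p"].to_numpy(),
                                                     len(tab))
            state["twas_table"] = tab
            state["gene_models"] = gene_models
            files = {"twas": outdir / "twas.tsv"}
            tab.to_csv(files["twas"], sep="\t", index=False)
            record(stage, files)
        elif stage == "focus":
            tab = state.get("twas_table")
            gm = state.get("gene_models", {})
            if tab is None or len(tab) < 1:
                manifest["skipped"].append(stage)
                continue
            genes = list(tab["gene"])
            all_idx = sorted(set(np.concatenate(
                [gm[g][1] for g in genes])))
            pos = {j: i for i, j in enumerate(all_idx)}
            W = np.zeros((len(genes), len(all_idx)))
            for gi, g in enumerate(genes):
                cem, idx, _ = gm[g]
                for w, j in zip(cem.coef_, idx):
                    W[gi, pos[j]] = w
            zstd = state["panel"].standardized()[:, all_idx]
            V = zstd.T @ zstd / state["panel"].n_individuals
            fm = FocusFineMapper()
            fm.fit(tab["z_twas"].to_numpy(), genes=genes, W=W, V=V)
            out = pd.DataFrame({
                "gene": genes, "z_twas": tab["z_twas"],
                "pip": fm.pip_.to_numpy(),
                "in_credible_set": [g in fm.credible_set_ for g in genes]})
            files = {"finemap": outdir / "finemap.tsv",
                     "config_posterior": outdir / "config_posterior.tsv"}
            out.to_csv(files["finemap"], sep="\t", index=False)
            fm.result_.config_table.to_csv(files["config_posterior"],
                                           sep="\t", index=False)
            record(stage, files)
        elif stage == "eqtl_de":
            truth = state["truth"]
            scan = cis_eqtl_scan(state["expr"][[truth.hub_gene]],
                                 state["panel"], truth.gene_annot,
                                 window=params.get("window", 1e6))
            hub_idx = int(np.flatnonzero(
                state["panel"].variants["snp"] == truth.hub_variant)[0])
            eg = state["detector"].eigengenes_.iloc[:, 0].to_numpy()
            beta, se, p = trans_eqtl_eigengene(
                eg, state["panel"].dosages[:, hub_idx])
            files = {"cis_eqtl": outdir / "cis_eqtl.tsv",
                     "trans_eqtl": outdir / "trans_eqtl.tsv"}
            scan.to_csv(files["cis_eqtl"], sep="\t", index=False)
            pd.DataFrame([{"variant": truth.hub_variant, "beta": beta,
                           "se": se, "p": p}]).to_csv(
                files["trans_eqtl"], sep="\t", index=False)
            record(stage, files)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
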