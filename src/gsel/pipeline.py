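"""End-to-end orchestration: simulate -> QC -> structure -> GWAS ->
prediction -> CV grid, with per-stage seeds, output hashing and a JSON
provenance manifest. Reruns with an identical config reproduce identical
output hashes."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluate, gwas, io, qc, simdata, structure
from .config import PipelineConfig
from .predict import bayesb_gibbs, gblup_reml
from .types import GenotypeMatrix, PhenotypeTable, batch_design

log = logging.getLogger("gsel.pipeline")

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause!r}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.data = {"config": config.model_dump(), "stages": {}}

    def record(self, stage: str, files: list[Path], seed: Optional[int], elapsed: float):
        self.data["stages"][stage] = {
            "seed": seed,
            "elapsed_s": round(elapsed, 3),
            "outputs": {str(f.relative_to(self.out_dir)): _sha256(f) for f in files},
        }

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        payload = dict(self.data)
        # elapsed timers vary run to run; hashes must not
        payload["stages"] = {
            k: {kk: vv for kk, vv in v.items() if kk != "elapsed_s"}
            for k, v in self.data["stages"].items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; returns a report dict with stage outputs
    and the manifest path. A stage failure aborts with the stage name while
    earlier outputs stay on disk."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir, config)
    report: dict = {"out_dir": str(out_dir)}

    def run_stage(name, fn):
        t0 = time.monotonic()
        seed = config.stage_seed(name)
        log.info("stage=%s seed=%d start", name, seed)
        try:
            files = fn(seed)
        except Exception as exc:
            manifest.write()
            raise PipelineError(name, exc) from exc
        elapsed = time.monotonic() - t0
        manifest.record(name, files, seed, elapsed)
        log.info("stage=%s seed=%d elapsed=%.2fs done", name, seed, elapsed)

    state: dict = {}

    def stage_data(seed):
        files = []
        if config.simulate is not None:
            s = config.simulate
            pop = simdata.simulate_dataset(
                n_founders=s.n_founders,
                n_offspring=s.n_offspring,
                m=s.m,
                n_chrom=s.n_chrom,
                chrom_length=s.chrom_length,
                maf_range=(s.maf_min, s.maf_max),
                ld_rho=s.ld_rho,
                n_qtl=s.n_qtl,
                h2_target=s.h2_target,
                n_batches=s.n_batches,
                missing_rate=s.missing_rate,
                seed=seed,
            )
            state["genotypes"] = pop.genotypes
            state["phenotypes"] = pop.phenotypes
            files.append(io.write_phenotypes(pop.phenotypes, out_dir / "phenotypes.csv"))
            ped_path = out_dir / "pedigree.csv"
            pop.pedigree.to_csv(ped_path, index=False)
            files.append(ped_path)
        else:
            f = config.files
            if f.genotypes_vcf:
                state["genotypes"] = io.read_vcf(f.genotypes_vcf)
            else:
                state["genotypes"] = io.read_plink(f.genotypes_plink)
            state["phenotypes"] = io.read_phenotypes(f.phenotypes_csv)
        return files

    def stage_qc(seed):
        thr = qc.QCThresholds(
            maf_min=config.qc.maf_min,
            snp_call_min=config.qc.snp_call_min,
            ind_call_min=config.qc.ind_call_min,
        )
        filtered, rep = qc.apply_qc(state["genotypes"], thr)
        for line in rep.log_lines():
            log.info("qc: %s", line)
        complete = qc.impute_naive(filtered, mode=config.qc.impute_mode, seed=seed)
        state["genotypes_qc"] = complete
        # align phenotypes to surviving individuals
        ph: PhenotypeTable = state["phenotypes"]
        keep = pd.Index(ph.ids).get_indexer(complete.ids)
        if (keep < 0).any():
            raise ValueError("QC kept individuals absent from the phenotype table")
        state["phenotypes"] = PhenotypeTable(
            ids=ph.ids[keep],
            value=ph.value[keep],
            batch=ph.batch[keep],
            true_bv=None if ph.true_bv is None else ph.true_bv[keep],
        )
        path = out_dir / "qc_report.json"
        path.write_text(rep.to_json(indent=2))
        report["qc"] = rep
        return [path]

    def stage_structure(seed):
        grm = structure.grm_vanraden(state["genotypes_qc"]).with_ridge(
            config.predict.ridge
        )
        k = max(config.gwas.n_pcs, 1)
        pcs = structure.pca_structure(grm, k=max(k, 10))
        state["grm"] = grm
        state["pca"] = pcs
        report["n_significant_pcs"] = pcs.n_significant
        f1 = io.write_grm_csv(grm, out_dir / "grm.csv")
        f2 = out_dir / "pcs.csv"
        pcs.scores_frame(ids=state["genotypes_qc"].ids).to_csv(f2, index=False)
        return [f1, f2]

    def stage_gwas(seed):
        ph = state["phenotypes"]
        X = batch_design(ph.batch)
        if config.gwas.n_pcs > 0:
            X = np.column_stack([X, state["pca"].scores[:, : config.gwas.n_pcs]])
        null = gwas.fit_null_mlm(ph.value, X, state["grm"])
        res = gwas.scan_association(state["genotypes_qc"], ph.value, X, null)
        thr = gwas.compute_thresholds(
            m_tests=len(res), alpha=config.gwas.alpha, suggestive=config.gwas.suggestive
        )
        log.info(
            "gwas thresholds: genome-wide p<=%.3g (-log10=%.2f), suggestive p<=%.3g",
            thr.genome_wide_p,
            thr.genome_wide_neglog10,
            thr.suggestive_p,
        )
        res = gwas.classify_snps(res, thr)
        state["gwas"] = res
        report["gwas_counts"] = gwas.count_classes(res)
        files = []
        f1 = out_dir / "gwas_results.tsv"
        res.to_csv(f1, sep="\t", index=False)
        files.append(f1)
        f1j = out_dir / "gwas_results.json"
        res.to_json(f1j, orient="records", indent=2)
        files.append(f1j)
        man, qq = gwas.export_manhattan_qq(res)
        f2, f3 = out_dir / "manhattan.csv", out_dir / "qq.csv"
        man.to_csv(f2, index=False)
        qq.to_csv(f3, index=False)
        files += [f2, f3]
        if config.gwas.annotation_gff3:
            ann = gwas.annotate_candidates(
                res, config.gwas.annotation_gff3, window_bp=config.gwas.annotation_window_bp
            )
            f4 = out_dir / "candidate_genes.csv"
            ann.to_csv(f4, index=False)
            files.append(f4)
        return files

    def stage_predict(seed):
        ph = state["phenotypes"]
        X = batch_design(ph.batch)
        rows = []
        gebvs = {}
        if "GBLUP" in config.predict.models:
            vc, model = gblup_reml(ph.value, X, state["grm"])
            rows.append(
                {
                    "method": "GBLUP",
                    "sigma_g2": vc.sigma_g2,
                    "sigma_e2": vc.sigma_e2,
                    "sigma_p2": vc.sigma_p2,
                    "h2": vc.h2,
                    "se_sigma_g2": vc.se_sigma_g2,
                    "se_sigma_e2": vc.se_sigma_e2,
                }
            )
            gebvs["GBLUP"] = model.gebv
        if "BayesB" in config.predict.models:
            from .predict import CHAIN_PROFILES

            chain = CHAIN_PROFILES[config.predict.chain_profile]
            res = bayesb_gibbs(
                ph.value,
                X,
                state["genotypes_qc"].dosages,
                pi=config.predict.pi,
                seed=seed,
                **chain,
            )
            rows.append(
                {
                    "method": "BayesB",
                    "sigma_g2": res.vc.sigma_g2,
                    "sigma_e2": res.vc.sigma_e2,
                    "sigma_p2": res.vc.sigma_p2,
                    "h2": res.vc.h2,
                    "se_sigma_g2": None,
                    "se_sigma_e2": None,
                }
            )
            gebvs["BayesB"] = res.gebv
        vc_df = pd.DataFrame(rows)
        report["variance_components"] = vc_df
        f1 = out_dir / "variance_components.csv"
        vc_df.to_csv(f1, index=False)
        gebv_df = pd.DataFrame({"id": ph.ids, **gebvs})
        f2 = out_dir / "gebv.csv"
        gebv_df.to_csv(f2, index=False)
        return [f1, f2]

    def stage_cv(seed):
        ph = state["phenotypes"]
        m = state["genotypes_qc"].n_snps
        panels = []
        for p in config.cv.panels:
            if p.mode == "all" or (p.size is not None and p.size <= m):
                panels.append(
                    evaluate.PanelSpec(mode=p.mode, size=p.size, seed=seed)
                )
        folds = evaluate.make_folds(
            ph.n, k=config.cv.k, repeats=config.cv.repeats, seed=seed
        )
        cells, agg = evaluate.run_cv_experiment(
            state["genotypes_qc"],
            ph.value,
            ph.batch,
            models=tuple(config.predict.models),
            panels=panels,
            folds=folds,
            leakage_mode=config.cv.leakage_mode,
            gwas_results=state.get("gwas"),
            chain_profile=config.predict.chain_profile,
            seed=seed,
        )
        report["cv_aggregate"] = agg
        f1, f2 = out_dir / "cv_cells.csv", out_dir / "cv_aggregate.csv"
        cells.to_csv(f1, index=False)
        agg.to_csv(f2, index=False)
        return [f1, f2]

    run_stage("data", stage_data)
    run_stage("qc", stage_qc)
    run_stage("structure", stage_structure)
    run_stage("gwas", stage_gwas)
    run_stage("predict", stage_predict)
    run_stage("cv", stage_cv)

    report["manifest"] = str(manifest.write())
    return report
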