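"""Validated pipeline configuration (pydantic schema).

Every random operation derives its seed from the global seed hashed with
the stage name, so adding a stage never perturbs the randomness of earlier
stages.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["PipelineConfig", "derive_seed", "load_config"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage-local seed: SHA-256 of ``"<seed>:<stage>"`` folded to 32 bits."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


class SimulateSpec(BaseModel):
    n_founders: int = Field(400, ge=2)
    n_offspring: int = Field(1120, ge=1)
    m: int = Field(2000, ge=1)
    n_chrom: int = Field(18, ge=1)
    chrom_length: int = Field(50_000_000, ge=1)
    maf_min: float = Field(0.05, gt=0, le=0.5)
    maf_max: float = Field(0.5, gt=0, le=0.5)
    ld_rho: float = Field(0.5, ge=0, lt=1)
    n_qtl: int = Field(200, ge=0)
    h2_target: float = Field(0.40, ge=0, le=1)
    n_batches: int = Field(4, ge=1)
    missing_rate: float = Field(0.008, ge=0, lt=1)


class FileSpec(BaseModel):
    genotypes_vcf: Optional[str] = None
    genotypes_plink: Optional[str] = None
    phenotypes_csv: str

    @model_validator(mode="after")
    def _one_genotype_source(self):
        if (self.genotypes_vcf is None) == (self.genotypes_plink is None):
            raise ValueError("provide exactly one of genotypes_vcf / genotypes_plink")
        return self


class QCSpec(BaseModel):
    maf_min: float = Field(0.05, ge=0, le=1)
    snp_call_min: float = Field(0.95, ge=0, le=1)
    ind_call_min: float = Field(0.80, ge=0, le=1)
    impute_mode: Literal["mean", "sample"] = "mean"


class GwasSpec(BaseModel):
    n_pcs: int = Field(3, ge=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    suggestive: float = Field(1e-5, gt=0, lt=1)
    annotation_gff3: Optional[str] = None
    annotation_window_bp: int = Field(50_000, ge=0)


class PredictSpec(BaseModel):
    models: List[Literal["GBLUP", "BayesB"]] = ["GBLUP", "BayesB"]
    chain_profile: Literal["fast", "paper"] = "fast"
    pi: float = Field(0.95, ge=0, le=1)
    ridge: float = Field(1e-6, ge=0)


class PanelSpecConfig(BaseModel):
    mode: Literal["top_gwas", "random", "all"] = "all"
    size: Optional[int] = Field(None, ge=1)

    @model_validator(mode="after")
    def _size_when_needed(self):
        if self.mode != "all" and self.size is None:
            raise ValueError("size required unless mode='all'")
        return self


class CVSpec(BaseModel):
    k: int = Field(5, ge=2)
    repeats: int = Field(10, ge=1)
    panels: List[PanelSpecConfig] = [PanelSpecConfig(mode="all")]
    leakage_mode: Literal["fold_safe", "whole_data"] = "fold_safe"


class PipelineConfig(BaseModel):
    simulate: Optional[SimulateSpec] = None
    files: Optional[FileSpec] = None
    qc: QCSpec = QCSpec()
    gwas: GwasSpec = GwasSpec()
    predict: PredictSpec = PredictSpec()
    cv: CVSpec = CVSpec()
    seed: int = 0
    out_dir: str = "gsel_out"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.simulate is None) == (self.files is None):
            raise ValueError("provide exactly one of 'simulate' or 'files'")
        return self

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)
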