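"""One-command end-to-end pipeline: module -> co-eQTLs -> PCI -> phenotypes.

Stages run strictly in order (prep, network, seed module, enrichment,
co-eQTL scan, selection, PCI fit and cross-validation, optional frozen-
weights replication, phenotype associations); every stage's outputs are
written before the next begins and a manifest records configuration hash,
per-file checksums and warnings. All randomness derives from the single
configured seed through a documented splitting scheme (SHA-256 of
``"{seed}:{stage}"`` reduced mod 2^31).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .assoc import hypergeom_enrichment, roc_auc, spearman_assoc
from .containers import ValidationError
from .network import (
    NetworkConfig,
    adjacency,
    detect_modules,
    intramodular_connectivity,
    module_eigengene,
    seed_module,
    select_soft_power,
    topological_overlap,
)
from .pci import (
    SelectionConfig,
    coeqtl_scan,
    crossvalidate_pci,
    fit_pci,
    replicate_pci,
    score_pci,
    snps_in_gene_windows,
)
from .prep import filter_by_quality, residualize

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed", "load_config"]

log = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    expression: str
    genotypes: str
    covariates: str
    snp_meta: str
    gene_coords: str
    seed_gene: str
    out_dir: str
    seed: int
    risk_genes: str | None = None
    phenotypes: str | None = None
    replication_expression: str | None = None
    replication_genotypes: str | None = None
    replication_covariates: str | None = None
    min_quality: float | None = None
    window_bp: int = 100_000
    network: NetworkConfig = field(default_factory=NetworkConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    k_folds: int = 5
    bed_coords: bool = False

    def validate_paths(self) -> None:
        for name in (
            "expression",
            "genotypes",
            "covariates",
            "snp_meta",
            "gene_coords",
            "risk_genes",
            "phenotypes",
            "replication_expression",
            "replication_genotypes",
            "replication_covariates",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"configured path for {name!r} does not exist: {p}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    net = NetworkConfig(**raw.pop("network", {}))
    sel = SelectionConfig(**raw.pop("selection", {}))
    return PipelineConfig(network=net, selection=sel, **raw)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, str], info: dict | None = None) -> None:
        checks = {k: _sha256(v) for k, v in outputs.items()}
        self.stages.append(
            {
                "stage": stage,
                "outputs": outputs,
                "checksums": checks,
                "info": info or {},
                "time": time.time(),
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _prep(expr, covars, min_quality):
    if min_quality is not None:
        expr = filter_by_quality(expr, min_quality)
    covars_aligned = covars.aligned_to(expr.sample_ids)
    return residualize(expr, covars_aligned)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full chain; halts on stage failure with stage name and cause."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = RunManifest(config_hash=_config_hash(config), version=__version__)

    stage = "prep"
    try:
        cov_raw = pd.read_csv(config.covariates, sep="\t", index_col=0, na_values=["NA"])
        quality = cov_raw.pop("quality") if "quality" in cov_raw.columns else None
        expr = cio.read_expression(config.expression, quality)
        from .containers import CovariateTable

        covars = CovariateTable(cov_raw)
        resid = _prep(expr, covars, config.min_quality)
        cio.write_expression(resid, out / "expression_resid.tsv")
        manifest.record(stage, {"expression_resid": str(out / "expression_resid.tsv")},
                        {"n_samples": resid.n_samples, "n_genes": resid.n_genes})

        stage = "network"
        power = select_soft_power(resid, config.network)
        adj = adjacency(resid, power, config.network.signed)
        tom = topological_overlap(adj)
        partition = detect_modules(tom, config.network)

        stage = "seed_module"
        label, members = seed_module(partition, config.seed_gene)
        eig = module_eigengene(resid, members, config.seed_gene)
        kin = intramodular_connectivity(adj, members)
        kme = {
            g: float(np.corrcoef(resid.values.loc[g], eig.scores)[0, 1]) for g in members
        }
        modules = pd.DataFrame(
            {"gene": partition.labels.index, "module": partition.labels.to_numpy()}
        ).set_index("gene")
        modules["kIN"] = kin.set_index("gene")["kIN"]
        modules["kME"] = pd.Series(kme)
        modules.to_csv(out / "modules.tsv", sep="\t", na_rep="NA")
        eig.scores.rename("ME").to_csv(out / "eigengene.tsv", sep="\t")
        report = {
            "power": power,
            "signed": config.network.signed,
            "module_sizes": {int(k): int(v) for k, v in partition.module_sizes.items()},
            "seed_module_label": label,
            "seed_module_size": len(members),
            "explained_variance_fraction": eig.explained_variance_fraction,
        }
        with open(out / "network_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        manifest.record(
            "network",
            {
                "modules": str(out / "modules.tsv"),
                "eigengene": str(out / "eigengene.tsv"),
                "network_report": str(out / "network_report.json"),
            },
            report,
        )

        if config.risk_genes is not None:
            stage = "enrichment"
            risk = {
                line.strip()
                for line in Path(config.risk_genes).read_text().splitlines()
                if line.strip()
            }
            background = set(resid.gene_ids)
            hits_bg = len(risk & background)
            hits_mod = len(risk & set(members))
            p_enrich = hypergeom_enrichment(len(members), hits_mod, len(background), hits_bg)
            enr = {
                "module_size": len(members),
                "module_hits": hits_mod,
                "background_size": len(background),
                "background_hits": hits_bg,
                "p": p_enrich,
            }
            with open(out / "enrichment.json", "w") as fh:
                json.dump(enr, fh, indent=2)
            manifest.record(stage, {"enrichment": str(out / "enrichment.json")}, enr)

        stage = "coeqtl_scan"
        snp_meta = cio.read_snp_meta(config.snp_meta)
        geno = cio.read_genotypes(config.genotypes, snp_meta)
        coords = cio.read_gene_coords(config.gene_coords, bed=config.bed_coords)
        member_coords = coords.loc[coords.index.intersection(members)]
        candidates, mapping = snps_in_gene_windows(snp_meta, member_coords, config.window_bp)
        geno_cand = geno.subset_snps(candidates).subset_samples(eig.scores.index)
        scan = coeqtl_scan(eig, geno_cand)
        scan.to_csv(out / "coeqtl.tsv", sep="\t", na_rep="NA")
        mapping.to_csv(out / "snp_gene_map.tsv", sep="\t", index=False)
        manifest.record(
            stage,
            {"coeqtl": str(out / "coeqtl.tsv"), "snp_gene_map": str(out / "snp_gene_map.tsv")},
            {"n_candidates": len(candidates)},
        )

        stage = "pci_fit"
        from .pci import select_snps

        selected, trace = select_snps(scan, geno_cand, config.selection, me=eig)
        model = fit_pci(eig, geno_cand, selected, min_group=config.selection.min_group)
        model.selection = {
            "method": config.selection.method,
            "alpha": config.selection.alpha,
            "r2_max": config.selection.r2_max,
        }
        model.to_json(out / "model.json")
        scores = score_pci(model, geno.subset_samples(eig.scores.index))
        scores.rename("PCI").to_csv(out / "scores.tsv", sep="\t")
        if trace is not None:
            trace.to_csv(out / "selection_trace.tsv", sep="\t", index=False)
        manifest.record(
            stage,
            {"model": str(out / "model.json"), "scores": str(out / "scores.tsv")},
            {"n_selected": len(model.snp_ids), "training_r2": model.training_r2},
        )

        stage = "pci_cv"
        cv = crossvalidate_pci(
            eig,
            geno_cand,
            config.selection,
            k_folds=config.k_folds,
            seed=stage_seed(config.seed, "cv"),
        )
        cv_out = {
            "pooled_r": cv.pooled_r,
            "pooled_p_one_tailed": cv.pooled_p_one_tailed,
            "fold_r": cv.fold_r,
            "n_failed_folds": cv.n_failed_folds,
        }
        with open(out / "cv.json", "w") as fh:
            json.dump(cv_out, fh, indent=2)
        manifest.record(stage, {"cv": str(out / "cv.json")}, cv_out)

        if config.replication_expression is not None:
            stage = "replication"
            rep_cov_raw = pd.read_csv(
                config.replication_covariates, sep="\t", index_col=0, na_values=["NA"]
            )
            rep_quality = (
                rep_cov_raw.pop("quality") if "quality" in rep_cov_raw.columns else None
            )
            rep_expr = cio.read_expression(config.replication_expression, rep_quality)
            from .containers import CovariateTable as CT

            rep_resid = _prep(rep_expr, CT(rep_cov_raw), None)
            rep_geno = cio.read_genotypes(config.replication_genotypes)
            rep = replicate_pci(model, rep_resid, members, config.seed_gene, rep_geno)
            rep_out = {
                "r": rep.r,
                "p_one_tailed": rep.p_one_tailed,
                "n": rep.n,
                "n_module_genes_used": rep.n_module_genes_used,
                "strata": rep.strata,
            }
            with open(out / "replication.json", "w") as fh:
                json.dump(rep_out, fh, indent=2)
            manifest.record(stage, {"replication": str(out / "replication.json")}, rep_out)

        if config.phenotypes is not None:
            stage = "associations"
            phen = cio.read_phenotypes(config.phenotypes)
            common = phen.index.intersection(scores.index)
            rows = []
            if "improvement" in phen.columns:
                res = spearman_assoc(
                    phen.loc[common, "improvement"], scores.loc[common], sidedness="two"
                )
                rows.append(("spearman_improvement", res.estimate, res.statistic, res.p,
                             res.sidedness, res.n))
            if "responder" in phen.columns and phen.loc[common, "responder"].nunique() == 2:
                res = roc_auc(scores.loc[common], phen.loc[common, "responder"])
                rows.append(("roc_responder", res.estimate, res.statistic, res.p,
                             res.sidedness, res.n))
            assoc = pd.DataFrame(
                rows, columns=["test", "estimate", "stat", "p", "sidedness", "n"]
            )
            assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
            manifest.record(stage, {"associations": str(out / "associations.tsv")})
    except Exception as exc:
        manifest.warnings.append(f"stage {stage!r} failed: {exc}")
        manifest.write(out / "manifest.json")
        raise ValidationError(f"pipeline halted at stage {stage!r}: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest
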