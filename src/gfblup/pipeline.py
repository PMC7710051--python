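"""End-to-end pipeline: mine -> partition -> QC -> GRM -> REML -> CV (-> GWAS).

Configuration is a YAML file; every run directory receives the resolved
config, a log with the seed, and all intermediate artifacts, each report
stamped with the config hash that produced it.  A ``simulate`` block in the
config generates the input files first (genotypes, phenotypes, annotation,
lexicon, corpus), so the bundled toy config runs fully offline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io, simulate as sim, textmine, grm as grm_mod, gwas as gwas_mod
from .cv import compare_models
from .exceptions import ParameterError, ValidationError
from .model import GenomicMixedModel
from .reml import heritability

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 1,
    "paths": {
        "genotypes": "inputs/geno",       # PLINK prefix
        "phenotypes": "inputs/pheno.csv",
        "annotation": "inputs/genes.tsv",
        "lexicon": "inputs/lexicon.tsv",
        "corpus": "inputs/corpus.jsonl",
    },
    "trait": "y",
    "id_col": "id",
    "fixed": {"categorical": [], "numeric": []},
    "qc": {"maf_min": 0.01, "max_missing": 0.1},
    "textmine": {"include_intergenic": True, "count": "occurrences"},
    "varcomp": {"tol": 1.0e-8, "max_iter": 200},
    "cv": {"k": 10, "varcomp_policy": "per_fold"},
    "gwas": {"enabled": False},
    "simulate": None,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see :data:`DEFAULT_CONFIG`)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cfg = {**DEFAULT_CONFIG, **self.raw}
        for key in ("paths", "fixed", "qc", "textmine", "varcomp", "cv", "gwas"):
            cfg[key] = {**DEFAULT_CONFIG[key], **(self.raw.get(key) or {})}
        qc = cfg["qc"]
        if not 0 <= qc["maf_min"] < 0.5:
            raise ParameterError("qc.maf_min out of range")
        if not 0 <= qc["max_missing"] <= 1:
            raise ParameterError("qc.max_missing out of range")
        if cfg["cv"]["k"] < 2:
            raise ParameterError("cv.k must be >= 2")
        self.cfg = cfg
        blob = json.dumps(cfg, sort_keys=True, default=str).encode()
        self._hash = hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def validate_paths(self, base: Path) -> None:
        if self.cfg.get("simulate"):
            return  # inputs are generated
        p = self.cfg["paths"]
        missing = []
        for key, rel in p.items():
            path = base / rel
            if key == "genotypes":
                if not path.with_suffix(".bed").exists():
                    missing.append(str(path) + ".bed")
            elif not path.exists():
                missing.append(str(path))
        if missing:
            raise ValidationError(f"missing input files: {missing}")

    @property
    def hash(self) -> str:
        return self._hash


def _simulate_inputs(cfg: dict, base: Path) -> None:
    """Write synthetic inputs per the config's ``simulate`` block."""
    s = cfg["simulate"]
    seed = int(cfg["seed"])
    (base / "inputs").mkdir(parents=True, exist_ok=True)
    panel, ann = sim.simulate_genotypes(
        n=s.get("n", 300), m=s.get("m", 2000), n_chrom=s.get("n_chrom", 5),
        maf_range=tuple(s.get("maf_range", (0.05, 0.5))), seed=seed)
    io.write_plink(panel, base / cfg["paths"]["genotypes"])
    io.write_annotation(ann, base / cfg["paths"]["annotation"])

    # Plant a handful of gene symbols; the planted genes drive the QTL set.
    symbols = list(ann.table["symbol"].iloc[:: max(1, len(ann.table) // 12)][:10])
    lex = io.GeneLexicon(set(symbols))
    io.write_lexicon(lex, base / cfg["paths"]["lexicon"])
    planted = {s_: 3 + i for i, s_ in enumerate(symbols)}
    corpus, _ = sim.simulate_corpus(lex, planted, ["impact", "pigs"],
                                    n_docs=s.get("n_docs", 30), seed=seed)
    io.write_corpus(corpus, base / cfg["paths"]["corpus"])

    mined = textmine.mine_genes(corpus, lex)
    part = textmine.select_snps(mined, ann, panel,
                                cfg["textmine"]["include_intergenic"])
    spec = sim.ArchitectureSpec(
        h2=s.get("h2", 0.4), n_qtl=s.get("n_qtl", 100),
        f_tm=s.get("f_tm", 0.5),
        fixed_effects=s.get("fixed_effects", {"site": {"A": 0.0, "B": 0.5}}))
    pheno, _ = sim.simulate_phenotype(panel, part, spec, seed=seed)
    pheno.data.drop(columns=["y_missing", "covariate_missing"]).to_csv(
        base / cfg["paths"]["phenotypes"], index=False)
    cfg["fixed"]["categorical"] = list(spec.fixed_effects)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full flow; returns the run directory.

    Any stage failure aborts with the stage name; intermediates written by
    completed stages persist in the run directory.
    """
    base = Path(outdir)
    base.mkdir(parents=True, exist_ok=True)
    cfg = config.cfg
    tag = config.hash
    log = logging.FileHandler(base / f"run_{tag}.log")
    log.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("gfblup")
    root.addHandler(log)
    root.setLevel(logging.INFO)
    stage = "validate"
    try:
        config.validate_paths(base)
        if cfg.get("simulate"):
            stage = "simulate"
            _simulate_inputs(cfg, base)
        (base / f"config_{tag}.yaml").write_text(yaml.safe_dump(cfg))
        logger.info("run %s seed=%s", tag, cfg["seed"])

        stage = "read"
        panel = io.read_plink(base / cfg["paths"]["genotypes"])
        pheno = io.read_phenotypes(base / cfg["paths"]["phenotypes"],
                                   trait=cfg["trait"], id_col=cfg["id_col"],
                                   categorical=cfg["fixed"]["categorical"],
                                   numeric=cfg["fixed"]["numeric"])
        ann = io.read_annotation(base / cfg["paths"]["annotation"])
        lex = io.read_lexicon(base / cfg["paths"]["lexicon"])
        corpus = io.read_corpus(base / cfg["paths"]["corpus"])

        stage = "mine"
        mined = textmine.mine_genes(corpus, lex, count=cfg["textmine"]["count"])
        mined.to_frame().to_csv(base / f"mined_genes_{tag}.tsv", sep="\t",
                                index=False)

        stage = "qc"
        panel, report = grm_mod.apply_snp_qc(panel, cfg["qc"]["maf_min"],
                                             cfg["qc"]["max_missing"])
        (base / f"qc_report_{tag}.json").write_text(json.dumps(vars(report)))

        stage = "partition"
        part = textmine.select_snps(mined, ann, panel,
                                    cfg["textmine"]["include_intergenic"])
        io.write_snp_extract(panel, part, "tm", base / f"tm_snps_{tag}.txt")

        stage = "reml"
        fixed = cfg["fixed"]
        rows = []
        for model_no, sets in ((1, ["all"]), (2, ["exp"]), (3, ["exp", "tm"])):
            grms = [grm_mod.build_grm(panel, part.indices(s), set_name=s)
                    for s in sets]
            mdl = GenomicMixedModel.from_dataframe(pheno, grms)
            res = mdl.fit(tol=cfg["varcomp"]["tol"],
                          max_iter=cfg["varcomp"]["max_iter"])
            for name, v in res.varcomp.components.items():
                rows.append((model_no, name, v, res.varcomp.se.get(name)))
            rows.append((model_no, "e", res.varcomp.sigma2_e,
                         res.varcomp.se.get("e")))
            rows.append((model_no, "h2", heritability(res.varcomp, model_no),
                         None))
        import pandas as pd
        pd.DataFrame(rows, columns=["model", "component", "estimate", "se"]) \
            .to_csv(base / f"varcomp_{tag}.tsv", sep="\t", index=False)

        stage = "cv"
        table = compare_models(panel, pheno, part, k=cfg["cv"]["k"],
                               seed=int(cfg["seed"]),
                               varcomp_policy=cfg["cv"]["varcomp_policy"])
        table.to_csv(base / f"cv_report_{tag}.tsv", sep="\t", index=False)

        if cfg["gwas"]["enabled"]:
            stage = "gwas"
            adj = gwas_mod.adjust_phenotype(pheno)
            order = {s: i for i, s in enumerate(adj.data[cfg["id_col"]])}
            y_c = adj.data["y_c"].to_numpy()[[order[s] for s in panel.samples]]
            loco = gwas_mod.loco_grm_set(panel)
            vc = gwas_mod.estimate_loco_varcomp(y_c, loco)
            scan = gwas_mod.assoc_scan(y_c, panel, part.indices("tm"), loco, vc)
            scan.to_csv(base / f"gwas_{tag}.tsv", sep="\t", index=False)
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        root.removeHandler(log)
        log.close()
    return base
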