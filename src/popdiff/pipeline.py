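"""Reproducible orchestration of the catalog → selection → differentiation →
risk stages, driven by a YAML configuration.

The pipeline executes requested stages in dependency order, captures every
warning, seeds every stochastic stage from a single top-level seed, and
writes a :class:`RunManifest` (config snapshot, input digests, seeds,
warnings, output paths) next to the stage outputs so that identical
configuration and inputs reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings as _warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import (
    ld_prune,
    load_ld_records,
    parse_catalog,
    rank_evidence,
    select_cross_ethnic,
    select_replicated,
)
from .differentiation import ensemble_test, fst_enrichment, snp_directional_p
from .errors import DataError, SchemaError
from .frequencies import FrequencyTable, RegionMap, load_frequencies
from .risk import (
    GenotypeMatrix,
    build_locus_models,
    permutation_contrast_test,
    prune_models,
    score_matrix,
)
from .synthetic_data import SimulationConfig, simulate_corpus, write_corpus

KNOWN_STAGES = (
    "simulate",
    "select",
    "snp-test",
    "ensemble-test",
    "fst",
    "pgr",
    "grs",
    "permute",
)


@dataclasses.dataclass
class RunManifest:
    command: str
    config: dict
    input_digests: dict[str, str]
    seeds: dict[str, int]
    versions: dict[str, str]
    warnings: dict[str, list[str]]
    outputs: dict[str, str]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(cfg: dict, field: str, stage: str):
    if field not in cfg:
        raise SchemaError(f"config: missing field {stage}.{field}")
    return cfg[field]


class _Context:
    """Loaded inputs and intermediate products shared across stages."""

    def __init__(self, config: dict, out_dir: Path):
        self.config = config
        self.out = out_dir
        self.table: FrequencyTable | None = None
        self.records = None
        self.ld = None
        self.genotypes: GenotypeMatrix | None = None
        self.selected: list[tuple[str, str]] = []  # (rsid, risk_allele)
        self.region_map = RegionMap.default(config.get("scheme", "hapmap"))
        self.seed = int(config.get("seed", 0))
        self.input_paths: dict[str, str] = {}

    def load_inputs(self) -> None:
        inputs = self.config.get("inputs", {})
        for key, loader in (
            ("frequencies", lambda p: load_frequencies(p)),
            ("catalog", lambda p: parse_catalog(p)),
            ("ld", lambda p: load_ld_records(p)),
        ):
            path = inputs.get(key)
            if path is None:
                continue
            if not Path(path).exists():
                raise SchemaError(f"config: inputs.{key} file not found: {path}")
            self.input_paths[key] = str(path)
            obj = loader(path)
            if key == "frequencies":
                self.table = obj
            elif key == "catalog":
                self.records = obj.records
            else:
                self.ld = obj
        gpath, spath = inputs.get("genotypes"), inputs.get("samples")
        if gpath and spath:
            for p in (gpath, spath):
                if not Path(p).exists():
                    raise SchemaError(f"config: input file not found: {p}")
            self.input_paths["genotypes"] = str(gpath)
            self.input_paths["samples"] = str(spath)
            if str(gpath).endswith(".vcf"):
                self.genotypes = GenotypeMatrix.from_vcf(gpath, spath)
            else:
                self.genotypes = GenotypeMatrix.from_tsv(gpath, spath)


def run_pipeline(config_path) -> RunManifest:
    """Run the stages requested in a YAML config; returns the manifest.

    On any stage failure the partially written outputs of that stage are
    removed and the error is re-raised annotated with the stage name.
    """
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise SchemaError("config: top level must be a mapping")
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise SchemaError(f"config: unknown stage(s) {unknown}; known: {list(KNOWN_STAGES)}")
    out_dir = Path(_require(config, "out_dir", "<top>"))
    out_dir.mkdir(parents=True, exist_ok=True)

    ctx = _Context(config, out_dir)
    ctx.load_inputs()

    manifest = RunManifest(
        command=f"run {config_path}",
        config=config,
        input_digests={k: _sha256(v) for k, v in ctx.input_paths.items()},
        seeds={"pipeline": ctx.seed},
        versions={"popdiff": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        warnings={},
        outputs={},
    )

    for stage in stages:
        func = _STAGES[stage]
        written: list[Path] = []
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            try:
                outputs = func(ctx, config.get(stage.replace("-", "_"), {}) or {}, manifest)
                written = [Path(p) for p in outputs.values()]
            except Exception as exc:
                for p in written:
                    p.unlink(missing_ok=True)
                raise type(exc)(f"[stage {stage}] {exc}") from exc
        manifest.warnings[stage] = [str(w.message) for w in caught]
        manifest.outputs.update({f"{stage}:{k}": str(v) for k, v in outputs.items()})

    manifest.write(out_dir / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stages


def _stage_simulate(ctx: _Context, cfg: dict, manifest: RunManifest) -> dict:
    cfg = dict(cfg)
    cfg.setdefault("seed", ctx.seed)
    sim = SimulationConfig(**cfg)
    corpus = simulate_corpus(sim)
    paths = write_corpus(corpus, ctx.out / "corpus")
    ctx.table = corpus.frequencies
    ctx.records = parse_catalog(paths["catalog"]).records
    ctx.ld = load_ld_records(paths["ld"])
    ctx.genotypes = corpus.genotypes
    manifest.seeds["simulate"] = sim.seed
    return paths


def _stage_select(ctx: _Context, cfg: dict, manifest: RunManifest) -> dict:
    if ctx.records is None:
        raise DataError("no catalog loaded (run simulate or provide inputs.catalog)")
    mode = cfg.get("mode", "cross-ethnic")
    if mode == "cross-ethnic":
        summaries = select_cross_ethnic(
            ctx.records,
            min_populations=int(cfg.get("min_populations", 5)),
            p_discovery=float(cfg.get("p_discovery", 1e-6)),
            p_gwas=float(cfg.get("p_gwas", 1e-6)),
            p_candidate=float(cfg.get("p_candidate", 0.01)),
        )
    elif mode == "replicated":
        summaries = select_replicated(
            ctx.records,
            p_threshold=float(cfg.get("p_threshold", 5e-8)),
            min_papers=int(cfg.get("min_papers", 2)),
        )
    else:
        raise SchemaError(f"config: select.mode must be cross-ethnic|replicated, got {mode!r}")
    ranked = rank_evidence(summaries)
    kept = ranked
    if ctx.ld is not None:
        kept_ids = set(
            ld_prune(
                [s.rsid for s in ranked],
                ctx.ld,
                float(cfg.get("ld_r2", 0.7)),
                cfg.get("panel", "CEU"),
                strict=bool(cfg.get("ld_strict", True)),
            )
        )
        kept = [s for s in ranked if s.rsid in kept_ids]
    ctx.selected = [(s.rsid, s.risk_allele) for s in kept]
    path = ctx.out / "selected.tsv"
    pd.DataFrame([dataclasses.asdict(s) for s in ranked]).assign(
        kept=[s.rsid in {r for r, _ in ctx.selected} for s in ranked]
    ).to_csv(path, sep="\t", index=False)
    return {"selected": path}


def _need_selection(ctx: _Context, cfg: dict) -> list[tuple[str, str]]:
    if cfg.get("snps"):
        return [tuple(x) for x in cfg["snps"]]
    if not ctx.selected:
        raise DataError("no selected SNPs (run select first or provide snps)")
    return ctx.selected


def _stage_snp_test(ctx: _Context, cfg: dict, manifest: RunManifest) -> dict:
    snps = _need_selection(ctx, cfg)
    rows = []
    for rsid, risk in snps:
        res = snp_directional_p(
            ctx.table,
            rsid,
            risk,
            ctx.region_map,
            cfg.get("region_high", "African"),
            cfg.get("region_low", "Asian"),
            cfg.get("region_ref", "European"),
            tolerance=float(cfg.get("tolerance", 0.01)),
            min_pool=int(cfg.get("min_pool", 50)),
            exclusions=[r for r, _ in snps if r != rsid],
        )
        rows.append(dataclasses.asdict(res))
    path = ctx.out / "snp_tests.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return {"snp_tests": path}


def _stage_ensemble(ctx: _Context, cfg: dict, manifest: RunManifest) -> dict:
    snps = _need_selection(ctx, cfg)
    contrasts = cfg.get(
        "contrasts", [["African", "European"], ["Asian", "European"]]
    )
    seed = int(cfg.get("seed", ctx.seed))
    manifest.seeds["ensemble-test"] = seed
    results = {}
    for region, ref in contrasts:
        res = ensemble_test(
            ctx.table,
            snps,
            ctx.region_map,
            (region, ref),
            null_source=cfg.get("null", "genome"),
            n_resamples=int(cfg.get("n_resamples", 10_000)),
            tolerance=float(cfg.get("tolerance", 0.05)),
            seed=seed,
            min_pool=int(cfg.get("min_pool", 1)),
        )
        results[f"{region}-{ref}"] = res.to_provenance()
    path = ctx.out / "ensemble.json"
    Path(path).write_text(json.dumps(results, indent=2) + "\n")
    return {"ensemble": path}


def _stage_fst(ctx: _Context, cfg: dict, manifest: RunManifest) -> dict:
    snps = _need_selection(ctx, cfg)
    regions = cfg.get("regions", ["African", "European", "Asian"])
    res = fst_enrichment(
        [r for r, _ in snps],
        ctx.table,
        ctx.region_map,
        regions,
        maf_region=cfg.get("maf_region", "European"),
        estimator=cfg.get("estimator", "nei"),
    )
    tsv = ctx.out / "fst.tsv"
    res.per_snp.to_csv(tsv, sep="\t")
    pjson = ctx.out / "fst_pvalues.json"
    Path(pjson).write_text(json.dumps(res.p_values, indent=2) + "\n")
    return {"fst": tsv, "fst_pvalues": pjson}


def _models(ctx: _Context, cfg: dict):
    if ctx.records is None or ctx.genotypes is None:
        raise DataError("pgr/grs/permute require a catalog and genotypes")
    models = build_locus_models(ctx.records)
    wanted = {r for r, _ in ctx.selected} if ctx.selected else None
    if wanted:
        models = [m for m in models if m.rsid in wanted]
    models = [m for m in models if m.rsid in ctx.genotypes.dosages.columns]
    if ctx.ld is not None:
        models = prune_models(
            models,
            ctx.ld,
            cfg.get("panel", "CEU"),
            r2_threshold=float(cfg.get("ld_r2", 0.3)),
            strict=False,
        )
    if not models:
        raise DataError("no usable locus model")
    return models


def _stage_pgr(ctx: _Context, cfg: dict, manifest: RunManifest) -> dict:
    models = _models(ctx, cfg)
    scores = score_matrix(ctx.genotypes, models, with_grs=False)
    path = ctx.out / "pgr.tsv"
    pd.DataFrame([dataclasses.asdict(s) for s in scores]).to_csv(path, sep="\t", index=False)
    return {"pgr": path}


def _stage_grs(ctx: _Context, cfg: dict, manifest: RunManifest) -> dict:
    models = _models(ctx, cfg)
    scores = score_matrix(ctx.genotypes, models, with_grs=True)
    path = ctx.out / "grs.tsv"
    pd.DataFrame([dataclasses.asdict(s) for s in scores]).to_csv(path, sep="\t", index=False)
    return {"grs": path}


def _stage_permute(ctx: _Context, cfg: dict, manifest: RunManifest) -> dict:
    models = _models(ctx, cfg)
    seed = int(cfg.get("seed", ctx.seed))
    manifest.seeds["permute"] = seed
    res = permutation_contrast_test(
        ctx.genotypes,
        models,
        ctx.region_map,
        ctx.table,
        groups=tuple(cfg.get("groups", ["African", "Asian", "European"])),
        n_perm=int(cfg.get("n_perm", 100_000)),
        tolerance=float(cfg.get("tolerance", 0.05)),
        seed=seed,
    )
    path = ctx.out / "permute.json"
    Path(path).write_text(
        json.dumps(
            {
                "observed": res.observed,
                "p_values": res.p_values,
                "group_means": res.group_means,
                "n_perm": res.n_perm,
                "seed": res.seed,
                "pool_sizes": res.pool_sizes,
            },
            indent=2,
        )
        + "\n"
    )
    return {"permute": path}


_STAGES = {
    "simulate": _stage_simulate,
    "select": _stage_select,
    "snp-test": _stage_snp_test,
    "ensemble-test": _stage_ensemble,
    "fst": _stage_fst,
    "pgr": _stage_pgr,
    "grs": _stage_grs,
    "permute": _stage_permute,
}
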