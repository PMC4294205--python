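"""Stage orchestration: validated config, atomic outputs, run manifests.

Each stage is a pure function of (inputs, config, seed): outputs are
written to a temporary file and renamed into place, and a per-stage JSON
manifest records the config hash, input checksums, output checksums and row
counts, so two runs with identical inputs and seed produce byte-identical
outputs and manifests (up to the timestamp field).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import pandas as pd
import yaml

from . import __version__
from .context import context_distribution
from .coexpression import ExpressionMatrix, coexpression_screen, results_to_frame
from .genome import filter_lncrnas, read_bed, read_gtf, write_gtf
from .gwas import (
    dedup_snps,
    expand_ld,
    GenotypePanel,
    map_snps_to_features,
    read_history,
    read_merge_table,
    read_snp_catalog,
    resolve_rsid,
    write_snp_catalog,
)
from .interactions import call_interactions, rbp_count_per_lncrna, shared_sites
from .synthetic import ScenarioConfig, generate_scenario, write_scenario

logger = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "context", "interactions", "cobind",
          "coexpress", "gwas", "all")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "out"
    seed: int = 0
    annotation: Optional[str] = None
    bed_dir: Optional[str] = None
    expression: dict[str, str] = field(default_factory=dict)  # cohort -> tsv
    genotypes: dict[str, str] = field(default_factory=dict)  # population -> tsv
    catalogs: dict[str, str] = field(default_factory=dict)  # source -> tsv
    merge_table: Optional[str] = None
    history: Optional[str] = None
    strand_policy: str = "same_strand"
    lncrna_filter_policy: str = "same_strand"
    min_overlap: int = 1
    min_rbps: int = 2
    alpha: float = 0.05
    criterion: str = "p"
    log_transform: bool = True
    r2_threshold: float = 0.5
    ld_window: int = 250_000

    def validate(self) -> None:
        problems = []
        if not (0.0 < self.alpha < 1.0):
            problems.append(f"alpha: must be in (0,1), got {self.alpha}")
        if self.criterion not in ("p", "q"):
            problems.append(f"criterion: must be 'p' or 'q', got {self.criterion!r}")
        if self.lncrna_filter_policy not in ("same_strand", "any_strand"):
            problems.append(
                f"lncrna_filter_policy: unknown value {self.lncrna_filter_policy!r}"
            )
        if self.strand_policy not in ("same_strand", "any_strand"):
            problems.append(f"strand_policy: unknown value {self.strand_policy!r}")
        if self.min_overlap < 1:
            problems.append(f"min_overlap: must be >= 1, got {self.min_overlap}")
        if self.min_rbps < 2:
            problems.append(f"min_rbps: must be >= 2, got {self.min_rbps}")
        if not (0.0 < self.r2_threshold <= 1.0):
            problems.append(f"r2_threshold: must be in (0,1], got {self.r2_threshold}")
        if self.ld_window <= 0:
            problems.append(f"ld_window: must be positive, got {self.ld_window}")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = raw.pop("params", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = [k for k in list(raw) + list(params) if k not in known]
        if unknown:
            raise ConfigError(f"unknown config fields: {unknown}")
        cfg = cls(**{**raw, **params})
        cfg.validate()
        return cfg

    def autodiscover_inputs(self) -> None:
        """Fill unset input paths from a previous simulate run's out_dir/inputs."""
        inputs = Path(self.out_dir) / "inputs"
        if not inputs.is_dir():
            return
        if self.annotation is None and (inputs / "annotation.gtf").exists():
            self.annotation = str(inputs / "annotation.gtf")
        if self.bed_dir is None and (inputs / "sites").is_dir():
            self.bed_dir = str(inputs / "sites")
        if not self.expression:
            self.expression = {
                p.stem.removeprefix("expression_"): str(p)
                for p in sorted(inputs.glob("expression_*.tsv"))
            }
        if not self.genotypes:
            self.genotypes = {
                p.stem.removeprefix("genotypes_"): str(p)
                for p in sorted(inputs.glob("genotypes_*.tsv"))
            }
        if not self.catalogs:
            self.catalogs = {
                p.stem.removeprefix("snps_"): str(p)
                for p in sorted(inputs.glob("snps_*.tsv"))
            }
        if self.merge_table is None and (inputs / "rs_merge.tsv").exists():
            self.merge_table = str(inputs / "rs_merge.tsv")
        if self.history is None and (inputs / "rs_history.tsv").exists():
            self.history = str(inputs / "rs_history.tsv")

    # input paths are content-addressed separately in the manifest, so the
    # config hash covers only the analysis parameters and seed
    _PATH_FIELDS = ("out_dir", "annotation", "bed_dir", "expression",
                    "genotypes", "catalogs", "merge_table", "history")

    def config_hash(self) -> str:
        params = {k: v for k, v in dataclasses.asdict(self).items()
                  if k not in self._PATH_FIELDS}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, sep="\t", index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _require(cfg: PipelineConfig, **paths) -> None:
    missing = [f"{name}: {p}" for name, p in paths.items()
               if p is None or not Path(p).exists()]
    if missing:
        raise ConfigError("missing stage dependencies: " + "; ".join(missing))


def _load_annotation(cfg: PipelineConfig):
    _require(cfg, annotation=cfg.annotation)
    ann = read_gtf(cfg.annotation)
    return filter_lncrnas(ann, cfg.lncrna_filter_policy)


def _load_sites(cfg: PipelineConfig) -> dict[str, list]:
    _require(cfg, bed_dir=cfg.bed_dir)
    sites = {}
    for bed in sorted(Path(cfg.bed_dir).glob("*.bed")):
        rbp = bed.stem
        sites[rbp] = read_bed(bed, rbp=rbp, experiment_id=rbp)
    if not sites:
        raise ConfigError(f"no BED files found in {cfg.bed_dir}")
    return sites


def _manifest(stage: str, cfg: PipelineConfig, inputs: dict[str, str],
              outputs: dict[str, Path], counts: dict[str, int]) -> dict:
    man = {
        "stage": stage,
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {k: _sha256(v) for k, v in inputs.items() if v and Path(v).exists()},
        "outputs": {k: _sha256(v) for k, v in outputs.items()},
        "row_counts": counts,
    }
    out = Path(cfg.out_dir) / f"manifest_{stage}.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        json.dump(man, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return man


def stage_simulate(cfg: PipelineConfig) -> dict:
    scen = generate_scenario(ScenarioConfig(seed=cfg.seed))
    inputs_dir = Path(cfg.out_dir) / "inputs"
    paths = write_scenario(scen, inputs_dir)
    # point the config at the generated inputs so later stages find them
    cfg.annotation = str(inputs_dir / "annotation.gtf")
    cfg.bed_dir = str(inputs_dir / "sites")
    cfg.expression = {m.cohort: str(inputs_dir / f"expression_{m.cohort}.tsv")
                      for m in scen.matrices}
    cfg.genotypes = {p.population: str(inputs_dir / f"genotypes_{p.population}.tsv")
                     for p in scen.panels}
    cfg.catalogs = {s: str(inputs_dir / f"snps_{s}.tsv") for s in scen.catalogs}
    cfg.merge_table = str(inputs_dir / "rs_merge.tsv")
    cfg.history = str(inputs_dir / "rs_history.tsv")
    outputs = {k: Path(v) for k, v in paths.items() if Path(v).is_file()}
    return _manifest("simulate", cfg, {}, outputs,
                     {"genes": len(scen.annotation),
                      "rbps": len(scen.sites_by_rbp)})


def stage_annotate(cfg: PipelineConfig) -> dict:
    _require(cfg, annotation=cfg.annotation)
    ann = read_gtf(cfg.annotation)
    n_before = sum(1 for _ in ann.transcripts())
    filtered = filter_lncrnas(ann, cfg.lncrna_filter_policy)
    n_after = sum(1 for _ in filtered.transcripts())
    logger.info("annotate: transcripts in=%d out=%d", n_before, n_after)
    out = Path(cfg.out_dir) / "annotation.filtered.gtf"
    out.parent.mkdir(parents=True, exist_ok=True)
    tmp = out.with_suffix(".gtf.tmp")
    write_gtf(filtered, tmp)
    os.replace(tmp, out)
    return _manifest("annotate", cfg, {"annotation": cfg.annotation},
                     {"filtered_gtf": out},
                     {"transcripts_in": n_before, "transcripts_out": n_after})


def stage_context(cfg: PipelineConfig) -> dict:
    ann = _load_annotation(cfg)
    sites = _load_sites(cfg)
    same_strand = cfg.strand_policy == "same_strand"
    rows = []
    for rbp, ss in sites.items():
        dist = context_distribution(ss, ann, rbp=rbp, same_strand=same_strand)
        for cat, n in dist.counts.items():
            rows.append({"rbp": rbp, "category": cat, "count": n,
                         "fraction": dist.fractions[cat]})
    df = pd.DataFrame(rows)
    out = Path(cfg.out_dir) / "context_distribution.tsv"
    _atomic_write_df(df, out)
    return _manifest("context", cfg, {"annotation": cfg.annotation},
                     {"context_distribution": out}, {"rows": len(df)})


def stage_interactions(cfg: PipelineConfig) -> dict:
    ann = _load_annotation(cfg)
    sites = _load_sites(cfg)
    inter = call_interactions(sites, ann,
                              same_strand=cfg.strand_policy == "same_strand")
    rows = [
        {"rbp": it.rbp, "gene_id": it.gene_id, "gene_symbol": it.gene_symbol,
         "n_sites": it.n_sites, "n_experiments": it.n_experiments,
         "sites": ",".join(str(s.interval) for s in it.sites)}
        for it in inter
    ]
    df = pd.DataFrame(rows, columns=["rbp", "gene_id", "gene_symbol",
                                     "n_sites", "n_experiments", "sites"])
    out = Path(cfg.out_dir) / "interactions.tsv"
    _atomic_write_df(df, out)
    counts, hist = rbp_count_per_lncrna(inter, ann)
    hist_df = pd.DataFrame(sorted(hist.items()), columns=["n_rbps", "n_lncrnas"])
    hist_out = Path(cfg.out_dir) / "rbp_count_histogram.tsv"
    _atomic_write_df(hist_df, hist_out)
    return _manifest("interactions", cfg, {"annotation": cfg.annotation},
                     {"interactions": out, "rbp_count_histogram": hist_out},
                     {"interactions": len(df)})


def stage_cobind(cfg: PipelineConfig) -> dict:
    sites = _load_sites(cfg)
    shared = shared_sites(sites, min_overlap=cfg.min_overlap, min_rbps=cfg.min_rbps)
    rows = [
        {"chrom": s.region.chrom, "start": s.region.start, "end": s.region.end,
         "strand": s.region.strand, "rbps": ",".join(sorted(s.rbps)),
         "n_rbps": len(s.rbps), "jaccard": round(s.jaccard, 6)}
        for s in shared
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "rbps", "n_rbps", "jaccard"])
    out = Path(cfg.out_dir) / "shared_sites.tsv"
    _atomic_write_df(df, out)
    return _manifest("cobind", cfg, {}, {"shared_sites": out},
                     {"shared_sites": len(df)})


def stage_coexpress(cfg: PipelineConfig) -> dict:
    inter_path = Path(cfg.out_dir) / "interactions.tsv"
    if not inter_path.exists():
        raise ConfigError(f"missing stage dependency: interactions table {inter_path}")
    inter = pd.read_csv(inter_path, sep="\t")
    pairs = list(dict.fromkeys(zip(inter["rbp"], inter["gene_id"])))
    matrices = [ExpressionMatrix.from_tsv(p, cohort)
                for cohort, p in sorted(cfg.expression.items())]
    if not matrices:
        raise ConfigError("missing stage dependency: no expression matrices configured")
    results, summary = coexpression_screen(
        pairs, matrices, alpha=cfg.alpha, criterion=cfg.criterion,
        log_transform=cfg.log_transform,
    )
    df = results_to_frame(results)
    out = Path(cfg.out_dir) / "coexpression.tsv"
    _atomic_write_df(df, out)
    sum_out = Path(cfg.out_dir) / "coexpression_summary.tsv"
    _atomic_write_df(summary, sum_out)
    return _manifest("coexpress", cfg, dict(cfg.expression),
                     {"coexpression": out, "summary": sum_out},
                     {"tests": len(df),
                      "significant_pairs": int(summary["significant"].sum())})


def stage_gwas(cfg: PipelineConfig) -> dict:
    _require(cfg, merge_table=cfg.merge_table, history=cfg.history)
    if not cfg.catalogs:
        raise ConfigError("missing stage dependency: no SNP catalogs configured")
    merge = read_merge_table(cfg.merge_table)
    history = read_history(cfg.history)
    catalogs = []
    n_collected = 0
    for source, path in sorted(cfg.catalogs.items()):
        recs = read_snp_catalog(path, source=source)
        n_collected += len(recs)
        resolved = []
        for rec in recs:
            rsid = resolve_rsid(rec.rsid, merge, history)
            if rsid is None:
                continue
            resolved.append(dataclasses.replace(rec, rsid=rsid))
        catalogs.append(resolved)
    unique = dedup_snps(catalogs)
    panels = [GenotypePanel.from_tsv(p, pop)
              for pop, p in sorted(cfg.genotypes.items())]
    expanded = expand_ld(unique, panels, r2_threshold=cfg.r2_threshold,
                         window=cfg.ld_window)
    ann = _load_annotation(cfg)
    sites = _load_sites(cfg)
    table, summary = map_snps_to_features(expanded, ann, sites)
    out = Path(cfg.out_dir) / "snp_annotation.tsv"
    _atomic_write_df(table, out)
    funnel = {
        "collected": n_collected,
        "unique": len(unique),
        "ld_expanded": len(expanded),
        "exonic": summary["n_exonic"],
        "splice_site": summary["n_splice_site"],
        "in_binding_site": summary["n_in_binding_site"],
        "exonic_and_binding": summary["n_exonic_and_binding"],
    }
    logger.info("gwas funnel: %s", funnel)
    sum_df = pd.DataFrame([{**funnel, **{k: v for k, v in summary.items()
                                         if k.startswith("n_distinct")}}])
    sum_out = Path(cfg.out_dir) / "snp_summary.tsv"
    _atomic_write_df(sum_df, sum_out)
    exp_out = Path(cfg.out_dir) / "snps_expanded.tsv"
    tmp = exp_out.with_suffix(".tsv.tmp")
    exp_out.parent.mkdir(parents=True, exist_ok=True)
    write_snp_catalog(expanded, tmp)
    os.replace(tmp, exp_out)
    return _manifest("gwas", cfg, dict(cfg.catalogs),
                     {"snp_annotation": out, "snp_summary": sum_out,
                      "snps_expanded": exp_out},
                     funnel)


_STAGE_FUNCS: dict[str, Callable[[PipelineConfig], dict]] = {
    "simulate": stage_simulate,
    "annotate": stage_annotate,
    "context": stage_context,
    "interactions": stage_interactions,
    "cobind": stage_cobind,
    "coexpress": stage_coexpress,
    "gwas": stage_gwas,
}

_ALL_ORDER = ("annotate", "context", "interactions", "cobind", "coexpress", "gwas")


def run_stage(stage: str, cfg: PipelineConfig) -> list[dict]:
    """Run one stage (or 'all' in dependency order); returns manifests."""
    cfg.validate()
    if stage != "simulate":
        cfg.autodiscover_inputs()
    if stage == "all":
        return [_STAGE_FUNCS[s](cfg) for s in _ALL_ORDER]
    if stage not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return [_STAGE_FUNCS[stage](cfg)]
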