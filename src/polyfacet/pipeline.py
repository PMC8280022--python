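"""End-to-end orchestration: simulate -> qc -> score -> evaluate.

A RunConfig (YAML-style key-value file or dict) drives all stages from
one master seed; every output file carries the config hash so a results
tree is self-describing, and the RunManifest records per-stage seeds,
checksums and wall-clock.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plinkio
from .config import ConfigError, FailureSpec, QCThresholds, SimulationConfig
from .datatypes import GenotypeDataset, SummaryStatistics
from .evalstats import (
    run_battery,
    sex_stratified_battery,
)
from .genoqc import run_qc
from .scoring import build_scores
from .simdata import DEFAULT_DISCOVERY_NS, simulate_study

log = logging.getLogger("polyfacet")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed below 2^31 from the master
    seed and the stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either a ``simulation`` block (SimulationConfig fields) or explicit
    input paths (``genotypes`` PLINK prefix, ``sumstats`` mapping of
    label -> path, ``phenotypes`` path) must be present.
    """

    seed: int = 0
    out_dir: str = "polyfacet_run"
    simulation: dict | None = None
    genotypes: str | None = None
    sumstats: dict[str, str] | None = None
    phenotypes: str | None = None
    qc: dict = dc_field(default_factory=dict)
    clump: bool = True
    clump_r2: float = 0.1
    clump_kb: float = 250.0
    fixed_pt: float = 0.05
    fdr_q: float = 0.05
    n_covariate_pcs: int = 4
    sex_stratified: bool = True
    write_plink: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        errors = [f"unknown config key: {k}" for k in raw if k not in known]
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if cfg.simulation is None and cfg.genotypes is None:
            errors.append("config needs either a 'simulation' block or a 'genotypes' path")
        if cfg.genotypes is not None and cfg.simulation is None:
            if cfg.sumstats is None:
                errors.append("file-based runs need a 'sumstats' label->path mapping")
            if cfg.phenotypes is None:
                errors.append("file-based runs need a 'phenotypes' path")
        if cfg.simulation is not None:
            sim_kw = {k: v for k, v in cfg.simulation.items() if not k.startswith("inject_")}
            if "maf_range" in sim_kw:
                sim_kw["maf_range"] = tuple(sim_kw["maf_range"])
            try:
                SimulationConfig(**{**sim_kw, "seed": 0})
            except (ConfigError, TypeError) as exc:
                errors.append(f"simulation block: {exc}")
        if errors:
            raise ConfigError("; ".join(errors))
        return cfg

    def content_hash(self) -> str:
        # the output location is not part of the scientific content
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        failures = {
            k[len("inject_"):]: v
            for k, v in config.simulation.items()
            if k.startswith("inject_")
        }
        sim_kw = {k: v for k, v in config.simulation.items() if not k.startswith("inject_")}
        if "maf_range" in sim_kw:
            sim_kw["maf_range"] = tuple(sim_kw["maf_range"])
        study = simulate_study(
            SimulationConfig(**{**sim_kw, "seed": stage_seed(config.seed, "simulate")})
        )
        dataset, sumstats, phenotypes = study.dataset, study.sumstats, study.phenotypes
        if failures:
            from .simdata import inject_qc_failures
            spec = FailureSpec(seed=stage_seed(config.seed, "inject"), **failures)
            dataset, _ = inject_qc_failures(dataset, spec)
        return dataset, sumstats, phenotypes, study.truth
    dataset = plinkio.read_plink(config.genotypes)
    sumstats = {
        label: plinkio.read_sumstats(path) for label, path in config.sumstats.items()
    }
    phenotypes = plinkio.read_phenotypes(config.phenotypes)
    return dataset, sumstats, phenotypes, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write the results tree.

    Returns the RunManifest as a dict (also written as manifest.json).
    Any stage failure aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    header = [f"config_hash={chash}", f"seed={config.seed}"]
    manifest: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "seed": stage_seed(config.seed, name),
            }
            log.info("stage %s: done (%.2fs)", name, manifest["stages"][name]["seconds"])
            return result
        return wrap

    dataset, sumstats, phenotypes, truth = stage("simulate")(lambda: _load_inputs(config))

    if config.write_plink and config.simulation is not None:
        plinkio.write_plink(dataset, out / "cohort")
        for label, ss in sumstats.items():
            plinkio.write_sumstats(ss, out / f"sumstats_{label}.tsv")
        plinkio.write_phenotypes(phenotypes, out / "phenotypes.tsv")
        if truth is not None:
            truth.true_betas.rename_axis("id").reset_index().to_csv(
                out / "ground_truth_betas.tsv", sep="\t", index=False
            )

    thresholds = QCThresholds(**config.qc)
    clean, pcs, report = stage("qc")(
        lambda: run_qc(dataset, thresholds, seed=stage_seed(config.seed, "qc"))
    )
    report.to_tsv(out / "qc_report.tsv")
    _write_table(pcs, out / "pcs.tsv", header + ["per-sample stratification PCs"])

    def _score():
        result = {}
        for label, ss in sumstats.items():
            result[label], rep = build_scores(
                clean, ss, label=label,
                clump_variants=config.clump, clump_r2=config.clump_r2,
                clump_kb=config.clump_kb, fixed_pt=config.fixed_pt,
            )
            log.info("label %s harmonization: %s", label, rep)
        return result

    scores = stage("score")(_score)

    pc_cols = [f"PC{i + 1}" for i in range(config.n_covariate_pcs)]
    covariates = pcs[["iid"] + pc_cols].merge(
        phenotypes[["iid", "sex", "age"]], on="iid"
    )[["iid", "sex", "age"] + pc_cols]

    def _evaluate():
        table, best_pts = run_battery(
            scores, phenotypes, covariates, q=config.fdr_q,
            covariate_names=["sex", "age"] + pc_cols,
        )
        strat = None
        if config.sex_stratified:
            strat = sex_stratified_battery(
                scores, phenotypes, covariates, best_pts, q=config.fdr_q,
                covariate_names=["sex", "age"] + pc_cols,
            )
        return table, best_pts, strat

    table, best_pts, strat = stage("evaluate")(_evaluate)
    _write_table(table, out / "associations.tsv", header + [
        "one row per score label x phenotype x threshold scheme",
        "incremental_r2 = R2(full) - R2(base); p_adjusted = Benjamini-Hochberg",
    ])
    if strat is not None:
        _write_table(strat, out / "associations_by_sex.tsv", header + [
            "sex-stratified battery; best-fit PT fixed at the full-sample choice",
        ])
    for label, scoreset in scores.items():
        df = pd.DataFrame(
            {
                "fid": clean.samples["fid"].to_numpy(),
                "iid": clean.samples["iid"].to_numpy(),
                "score_fixed": scoreset.fixed.scores_at(scoreset.fixed.pts[0]),
                "score_all": scoreset.all.scores_at(scoreset.all.pts[0]),
            }
        )
        _write_table(df, out / f"scores_{label}.tsv", header + [
            f"n_snps fixed={int(scoreset.fixed.counts[0])} all={int(scoreset.all.counts[0])}",
        ])

    (out / "summary.txt").write_text(render_report(table) + "\n")
    for f in sorted(out.glob("*.tsv")):
        manifest["stages"].setdefault("outputs", {})[f.name] = _sha256(f)
    manifest["stages"]["outputs"]["summary.txt"] = _sha256(out / "summary.txt")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _stars(p_adj: float) -> str:
    if p_adj <= 0.001:
        return "***"
    if p_adj <= 0.01:
        return "**"
    if p_adj <= 0.05:
        return "*"
    return ""


def render_report(table: pd.DataFrame) -> str:
    """Human-readable per-scheme summary of incremental R2 in percent
    with significance stars at adjusted p <= 0.05 / 0.01 / 0.001."""
    if table is None or len(table) == 0:
        return "no association results to report"
    lines = []
    for scheme in ("fixed", "best", "all"):
        sub = table[table["scheme"] == scheme]
        if len(sub) == 0:
            continue
        lines.append(f"scheme: {scheme}")
        for label in sub["score_label"].unique():
            part = sub[sub["score_label"] == label]
            lines.append(f"  {label}-PGS")
            for row in part.itertuples(index=False):
                lines.append(
                    f"    {row.phenotype:<24} incremental R2 = "
                    f"{100.0 * row.incremental_r2:5.2f}%"
                    f"  (PT={row.pt:g}, n_snps={row.n_snps}) {_stars(row.p_adjusted)}"
                )
        lines.append("")
    return "\n".join(lines).rstrip()


def plot_battery(table: pd.DataFrame, path: str | Path) -> None:
    """Optional grouped bar chart of incremental R2 (percent) per scheme,
    one panel per threshold scheme, stars at the adjusted-p levels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    schemes = [s for s in ("fixed", "best", "all") if (table["scheme"] == s).any()]
    fig, axes = plt.subplots(len(schemes), 1, figsize=(10, 3.2 * len(schemes)), squeeze=False)
    for ax, scheme in zip(axes[:, 0], schemes):
        sub = table[table["scheme"] == scheme]
        labels = list(sub["score_label"].unique())
        phenos = list(sub["phenotype"].unique())
        width = 0.8 / max(len(labels), 1)
        for i, label in enumerate(labels):
            part = sub[sub["score_label"] == label].set_index("phenotype").loc[phenos]
            xs = np.arange(len(phenos)) + i * width
            bars = ax.bar(xs, 100.0 * part["incremental_r2"], width=width, label=label)
            for rect, (_, row) in zip(bars, part.iterrows()):
                star = _stars(row["p_adjusted"])
                if star:
                    ax.text(rect.get_x() + rect.get_width() / 2, rect.get_height(),
                            star, ha="center", va="bottom", fontsize=8)
        ax.set_xticks(np.arange(len(phenos)) + 0.4 - width / 2)
        ax.set_xticklabels(phenos, rotation=30, ha="right", fontsize=8)
        ax.set_ylabel("incremental R2 (%)")
        ax.set_title(f"scheme: {scheme}")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
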