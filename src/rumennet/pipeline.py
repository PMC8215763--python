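"""End-to-end orchestration: simulate -> preprocess -> network -> keystone ->
temporal DE -> enzyme profiles, with a config file and a summary report."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io_tables, keystone, network, preprocess, synthetic_data, temporal_de
from . import enzyme_profiles
from .io_tables import ExpressionTable, SampleDesign
from .synthetic_data import GeneratorConfig


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters; defaults mirror the reference analysis
    (min_genes 10, IQR quantile 0.25, |rho| > 0.7, BH alpha 0.1, DE alpha 0.1,
    top fractions 0.9 / 0.95, top-2 keystones per cluster)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    min_genes: int = 10
    iqr_quantile: float = 0.25
    iqr_mode: str = "iqr"
    pseudocount: float = 1.0
    exclude_baseline: bool = True
    rho_min: float = 0.7
    alpha: float = 0.1
    threshold_on: str = "abs"
    cluster_edges: str = "positive"
    top_k: int = 2
    keystone_scope: str = "full"
    de_alpha: float = 0.1
    de_top_fraction: float = 0.9
    enzyme_top_fraction: float = 0.95
    enzyme_alpha: float = 0.1
    tukey_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        gen = data.pop("generator", {})
        if isinstance(gen, dict):
            gen_known = {f.name for f in dataclasses.fields(GeneratorConfig)}
            gen_unknown = set(gen) - gen_known
            if gen_unknown:
                raise ValueError(f"unknown generator key(s): {sorted(gen_unknown)}")
            for tup_key in ("genes_per_family_range", "gene_length_range", "timepoints_h"):
                if tup_key in gen and isinstance(gen[tup_key], list):
                    gen[tup_key] = tuple(gen[tup_key])
            gen = GeneratorConfig(**gen)
        cfg = cls(generator=gen, **data)
        if "seed" in data and "generator" not in data:
            cfg = dataclasses.replace(cfg, generator=cfg.generator.with_seed(cfg.seed))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["enzyme_tag_fractions"] = dict(d["generator"]["enzyme_tag_fractions"])
        return d


def run_all(
    config: PipelineConfig,
    outdir: str | Path,
    table: ExpressionTable | None = None,
    design: SampleDesign | None = None,
    skip_enzymes: bool = False,
) -> dict:
    """Run every stage, write result tables and ``summary.json``.

    Without an input bundle the synthetic generator supplies one (and the
    generated bundle is written out alongside the results).  Returns the
    summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    if table is None or design is None:
        bundle = synthetic_data.simulate(config.generator)
        table, design = bundle.table, bundle.design
        io_tables.write_bundle(table, design, outdir / "bundle")

    stages = preprocess.preprocess_counts(
        table, design,
        min_genes=config.min_genes,
        iqr_quantile=config.iqr_quantile,
        iqr_mode=config.iqr_mode,
        pseudocount=config.pseudocount,
        exclude_baseline=config.exclude_baseline,
    )
    rlog = stages["rlog"]
    io_tables.write_table(rlog.values.rename_axis("family"),
                          outdir / "family_matrix.tsv", index=True)

    cm = network.spearman_correlations(rlog)
    net = network.build_network(cm, stages["filtered"],
                                rho_min=config.rho_min, alpha=config.alpha,
                                threshold_on=config.threshold_on)
    net = network.detect_clusters(net, seed=config.seed, edges=config.cluster_edges)
    io_tables.write_network(net, outdir)

    report = keystone.keystone_report(net, top_k=config.top_k, scope=config.keystone_scope)
    io_tables.write_table(report.reset_index(), outdir / "keystones.tsv")
    keystones = keystone.top_keystones(report)

    de = temporal_de.run_de(table, design, alpha=config.de_alpha,
                            top_fraction=config.de_top_fraction)
    io_tables.write_table(de.letters.reset_index(), outdir / "de_patterns.tsv")
    io_tables.write_table(de.patterns["summary"], outdir / "pattern_summary.tsv")

    summary = {
        "n_samples": len(design.sample_ids),
        "n_genes": len(table.counts),
        "n_families_input": int(table.gene_meta["family"].nunique()),
        "n_families_network": len(rlog.families),
        "n_edges": net.number_of_edges(),
        "n_clusters": int(net.graph["n_clusters"]),
        "modularity": float(net.graph["modularity"]),
        "keystones": keystones,
        "n_features": len(de.feature_table),
        "n_de_features": int(de.screen["significant_time"].sum()),
        "n_pairwise_comparisons": (
            int(de.pairwise.groupby("feature").size().iloc[0]) if len(de.pairwise) else 0
        ),
        "n_de_patterns": (
            int(de.patterns["summary"]["pattern_key"].nunique())
            if len(de.patterns["summary"]) else 0
        ),
    }

    if not skip_enzymes:
        enz = enzyme_profiles.run_enzymes(
            table, design,
            top_fraction=config.enzyme_top_fraction,
            alpha=config.enzyme_alpha,
            tukey_alpha=config.tukey_alpha,
        )
        io_tables.write_table(enz.retained.reset_index(), outdir / "enzyme_profiles.tsv")
        io_tables.write_table(enz.letters, outdir / "enzyme_letters.tsv")
        io_tables.write_table(enz.contributions, outdir / "enzyme_contributions.tsv")
        summary["n_enzyme_families_tested"] = len(enz.anova)
        summary["n_enzyme_families_significant"] = (
            int(enz.anova["significant"].sum()) if len(enz.anova) else 0
        )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
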