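"""Readers and writers for the annotated count-table bundle and result tables.

This module is the single authority for column naming and identifier
conventions.  The input bundle is three tab-separated files:

``counts.tsv``
    ``gene_id`` plus one integer column per sample.
``gene_meta.tsv``
    ``gene_id, family, genus, functional_cluster, enzyme_tag, length_bp``.
    ``enzyme_tag`` is empty for untagged genes (e.g. ``GH5``, ``M24``,
    ``LuxS`` otherwise).
``design.tsv``
    ``sample_id, animal_id, timepoint_h``.  Timepoint 0 is reserved for the
    pre-incubation baseline sample.

Timepoints are stored as hours (numeric) and labelled ``T{h}`` in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

GENE_META_COLUMNS = ["family", "genus", "functional_cluster", "enzyme_tag", "length_bp"]
DESIGN_COLUMNS = ["animal_id", "timepoint_h"]

#: ORF floor: predicted coding sequences of at least 100 amino acids.
MIN_ORF_BP = 100 * 3


class BundleError(ValueError):
    """A validation problem in the count-table bundle, naming the offender."""


def timepoint_label(hours: float) -> str:
    """Report label for a timepoint, e.g. ``T1`` for the 1 h sample."""
    return f"T{hours:g}"


@dataclass(frozen=True)
class SampleDesign:
    """Mapping of sample id to (animal id, incubation timepoint in hours)."""

    table: pd.DataFrame  # indexed by sample_id; columns animal_id, timepoint_h

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise BundleError(f"design table missing column(s): {missing}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise BundleError(f"duplicate sample id in design: {dup!r}")
        pairs = self.table[["animal_id", "timepoint_h"]]
        if pairs.duplicated().any():
            a, t = pairs[pairs.duplicated()].iloc[0]
            raise BundleError(f"duplicate (animal, timepoint) pair: ({a!r}, {t!r})")
        if (self.table["timepoint_h"] < 0).any():
            raise BundleError("negative timepoint in design")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def is_baseline(self) -> pd.Series:
        """Boolean per sample; timepoint 0 is the pre-incubation baseline."""
        return self.table["timepoint_h"] == 0

    @property
    def timepoints(self) -> list[float]:
        """Sorted non-baseline timepoints (hours)."""
        t = sorted(set(self.table.loc[~self.is_baseline, "timepoint_h"]))
        return [float(x) for x in t]

    def non_baseline_samples(self) -> list[str]:
        return list(self.table.index[~self.is_baseline])

    def animals(self, include_baseline: bool = False) -> list[str]:
        tab = self.table if include_baseline else self.table[~self.is_baseline]
        return sorted(set(tab["animal_id"]))


@dataclass(frozen=True)
class ExpressionTable:
    """Gene x sample count matrix with per-gene annotation.

    ``counts`` is indexed by gene id with one integer column per sample;
    ``gene_meta`` is indexed by gene id with columns
    ``family, genus, functional_cluster, enzyme_tag, length_bp``.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise BundleError(f"duplicate gene id: {dup!r}")
        missing = [c for c in GENE_META_COLUMNS if c not in self.gene_meta.columns]
        if missing:
            raise BundleError(f"gene_meta missing column(s): {missing}")
        if not self.counts.index.equals(self.gene_meta.index):
            extra = self.counts.index.difference(self.gene_meta.index)
            if len(extra):
                raise BundleError(f"gene missing from gene_meta: {extra[0]!r}")
            raise BundleError("gene_meta/counts gene id mismatch")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            g = self.counts.index[np.where(vals < 0)[0][0]]
            raise BundleError(f"negative count for gene {g!r}")
        if (self.gene_meta["length_bp"] <= 0).any():
            g = self.gene_meta.index[self.gene_meta["length_bp"] <= 0][0]
            raise BundleError(f"non-positive gene length for {g!r}")
        short = self.gene_meta["length_bp"] < MIN_ORF_BP
        if short.any():
            warnings.warn(
                f"{int(short.sum())} gene(s) shorter than the {MIN_ORF_BP} bp ORF "
                "floor (first: "
                f"{self.gene_meta.index[short][0]!r})",
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def validate_against(self, design: SampleDesign) -> None:
        """Check that count columns and design samples agree exactly."""
        missing = [s for s in self.sample_ids if s not in design.table.index]
        if missing:
            raise BundleError(f"sample {missing[0]!r} in counts but not in design")
        missing = [s for s in design.table.index if s not in self.counts.columns]
        if missing:
            raise BundleError(f"sample {missing[0]!r} in design but not in counts")


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(table: ExpressionTable, design: SampleDesign, outdir: str | Path) -> dict[str, Path]:
    """Write the three-file TSV bundle; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "gene_meta": outdir / "gene_meta.tsv",
        "design": outdir / "design.tsv",
    }
    table.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    table.gene_meta.rename_axis("gene_id").to_csv(paths["gene_meta"], sep="\t")
    design.table.rename_axis("sample_id").to_csv(paths["design"], sep="\t")
    return paths


def read_bundle(
    counts_path: str | Path,
    gene_meta_path: str | Path,
    design_path: str | Path,
) -> tuple[ExpressionTable, SampleDesign]:
    """Read and validate the three-file bundle.

    Raises :class:`BundleError` naming the offending identifier on a missing
    column, duplicate gene id, negative count or counts/design sample
    mismatch.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(gene_meta_path, sep="\t", index_col="gene_id")
    dsn = pd.read_csv(design_path, sep="\t", index_col="sample_id")
    dsn["animal_id"] = dsn["animal_id"].astype(str)
    if "enzyme_tag" in meta.columns:
        meta["enzyme_tag"] = meta["enzyme_tag"].astype("string")
    if not counts.dtypes.map(lambda d: np.issubdtype(d, np.number)).all():
        bad = counts.dtypes[~counts.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        raise BundleError(f"non-numeric count column: {bad.index[0]!r}")
    table = ExpressionTable(counts=counts, gene_meta=meta.loc[counts.index])
    design = SampleDesign(table=dsn)
    table.validate_against(design)
    return table, design


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, outdir: str | Path, stem: str = "network") -> dict[str, Path]:
    """Write a family network as GraphML plus a flat edge list.

    Edge records carry Spearman rho, BH-adjusted p and sign; node records
    carry total expression and cluster label.  GraphML preserves typed
    attributes so a round trip reproduces the graph exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = graph.copy()
    for _, data in g.nodes(data=True):
        if data.get("cluster") is None:
            data["cluster"] = ""
    graphml = outdir / f"{stem}.graphml"
    nx.write_graphml(g, graphml)
    rows = [
        {
            "source": u,
            "target": v,
            "rho": d.get("rho", np.nan),
            "p_adj": d.get("p_adj", np.nan),
            "sign": d.get("sign", ""),
        }
        for u, v, d in g.edges(data=True)
    ]
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p_adj", "sign"])
    edges_path = outdir / "edges.tsv"
    edges.to_csv(edges_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        [
            {
                "family": n,
                "total_expression": d.get("total_expression", np.nan),
                "cluster": d.get("cluster", ""),
            }
            for n, d in g.nodes(data=True)
        ]
    )
    nodes_path = outdir / "nodes.tsv"
    nodes.to_csv(nodes_path, sep="\t", index=False)
    return {"graphml": graphml, "edges": edges_path, "nodes": nodes_path}


def read_network(graphml_path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    g = nx.read_graphml(graphml_path)
    for _, data in g.nodes(data=True):
        if data.get("cluster") == "":
            data["cluster"] = None
    return g


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a result table as TSV (tab, UTF-8, header row)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
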