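"""Readers and writers for the pipeline's TSV table schemas.

All tables are UTF-8, tab-delimited, ``.`` decimal, empty field =
missing (never 0). Writers and readers round-trip losslessly; pandas
does the actual parsing.

Schemas
-------
expression
    rows = genes, first column ``gene_id``, then one column per
    technical replicate named ``<sample_id>:<rep#>``.
group map
    ``sample_id, group`` (optional ``year, nest``).
spectral counts (long form)
    ``hit_id, protein_group, is_decoy, sample_id, band, count``.
spike-in
    ``sample_id, band, spikein_count``.
genotypes
    ``specimen_id, year, rearing, locus1..locusK`` with ``/``-separated
    allele labels, empty = failed amplification.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExpressionStudy, GenotypeTable, SpectralCountTable

__all__ = [
    "write_expression_study",
    "read_expression_study",
    "write_group_map",
    "read_group_map",
    "write_spectral_table",
    "read_spectral_table",
    "write_genotype_table",
    "read_genotype_table",
    "write_matrix",
    "read_matrix",
]

_SEP = "\t"


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "feature_id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep=_SEP, na_rep="")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP, index_col=0)


def write_group_map(groups: pd.Series, path: str | Path) -> None:
    frame = pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()})
    frame.to_csv(path, sep=_SEP, index=False)


def read_group_map(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep=_SEP)
    s = pd.Series(frame["group"].to_numpy(), index=frame["sample_id"], name="group")
    s.index.name = None
    return s


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

def write_expression_study(study: ExpressionStudy, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.expression.tsv``, ``<prefix>.groups.tsv`` and,
    when truth labels exist, ``<prefix>.truth.tsv``; returns the paths."""
    prefix = Path(prefix)
    flat = study.quantities.copy()
    flat.columns = [f"{s}:{r}" for s, r in study.quantities.columns]
    flat.index.name = "gene_id"
    expr_path = prefix.with_suffix(".expression.tsv")
    flat.to_csv(expr_path, sep=_SEP, na_rep="")
    groups_path = prefix.with_suffix(".groups.tsv")
    write_group_map(study.groups, groups_path)
    paths = {"expression": expr_path, "groups": groups_path}
    if study.truth:
        truth_path = prefix.with_suffix(".truth.tsv")
        rows = [
            {"gene_id": g, "log2_effect": e}
            for g, e in study.truth.get("log2_effect", {}).items()
        ]
        pd.DataFrame(rows).to_csv(truth_path, sep=_SEP, index=False)
        paths["truth"] = truth_path
    return paths


def read_expression_study(
    expression_path: str | Path,
    groups_path: str | Path,
    control_gene_id: str,
    replicate_runs: dict | None = None,
    contig_pairs: list | None = None,
) -> ExpressionStudy:
    flat = pd.read_csv(expression_path, sep=_SEP, index_col="gene_id")
    flat.index.name = None
    cols = [c.rsplit(":", 1) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(
        [(s, int(r)) for s, r in cols], names=["sample", "rep"]
    )
    groups = read_group_map(groups_path)
    return ExpressionStudy(
        quantities=flat,
        groups=groups,
        control_gene_id=control_gene_id,
        replicate_runs=replicate_runs or {},
        contig_pairs=contig_pairs or [],
    )


# ---------------------------------------------------------------------------
# spectral-count tables
# ---------------------------------------------------------------------------

def write_spectral_table(table: SpectralCountTable, prefix: str | Path) -> dict[str, Path]:
    prefix = Path(prefix)
    long = (
        table.counts.stack(["sample", "band"], future_stack=True)
        .rename("count")
        .reset_index()
        .rename(columns={"level_0": "hit_id"})
    )
    long.columns = ["hit_id", "sample_id", "band", "count"]
    pg = table.protein_group if table.protein_group is not None else pd.Series(
        table.counts.index, index=table.counts.index
    )
    long.insert(1, "protein_group", long["hit_id"].map(pg).to_numpy())
    long.insert(2, "is_decoy", long["hit_id"].map(table.decoy).astype(int).to_numpy())
    counts_path = prefix.with_suffix(".spectral.tsv")
    long.to_csv(counts_path, sep=_SEP, index=False)
    groups_path = prefix.with_suffix(".groups.tsv")
    write_group_map(table.groups, groups_path)
    paths = {"spectral": counts_path, "groups": groups_path, "mode": table.mode}
    if table.spike_in is not None:
        spike = table.spike_in.rename("spikein_count").reset_index()
        spike.columns = ["sample_id", "band", "spikein_count"]
        spike_path = prefix.with_suffix(".spikein.tsv")
        spike.to_csv(spike_path, sep=_SEP, index=False)
        paths["spikein"] = spike_path
    return paths


def read_spectral_table(
    counts_path: str | Path,
    groups_path: str | Path,
    mode: str,
    spikein_path: str | Path | None = None,
) -> SpectralCountTable:
    long = pd.read_csv(counts_path, sep=_SEP)
    groups = read_group_map(groups_path)
    counts = long.pivot_table(
        index="hit_id", columns=["sample_id", "band"], values="count", aggfunc="first"
    ).fillna(0)
    counts = counts.astype(np.int64)
    counts.columns.names = ["sample", "band"]
    # preserve first-appearance hit order
    order = long["hit_id"].drop_duplicates().to_list()
    counts = counts.loc[order]
    counts.index.name = None
    meta = long.drop_duplicates("hit_id").set_index("hit_id")
    decoy = meta["is_decoy"].astype(bool).rename("is_decoy")
    protein_group = meta["protein_group"].rename("protein_group")
    spike = None
    if spikein_path is not None:
        sp = pd.read_csv(spikein_path, sep=_SEP)
        spike = pd.Series(
            sp["spikein_count"].to_numpy(),
            index=pd.MultiIndex.from_frame(
                sp[["sample_id", "band"]].rename(
                    columns={"sample_id": "sample"}
                )
            ),
            name="spikein_count",
        ).reindex(counts.columns)
    return SpectralCountTable(
        counts=counts,
        spike_in=spike,
        groups=groups,
        decoy=decoy,
        mode=mode,  # type: ignore[arg-type]
        protein_group=protein_group,
    )


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def write_genotype_table(table: GenotypeTable, prefix: str | Path) -> dict[str, Path]:
    prefix = Path(prefix)
    rows = []
    for sp in table.specimens:
        row = {"specimen_id": sp, "year": "", "rearing": ""}
        for locus in table.loci:
            alleles = table.genotypes.loc[sp, locus]
            row[locus] = "/".join(str(a) for a in alleles)
        rows.append(row)
    geno_path = prefix.with_suffix(".genotypes.tsv")
    pd.DataFrame(rows).to_csv(geno_path, sep=_SEP, index=False)
    paths = {"genotypes": geno_path}
    if table.truth is not None:
        truth_path = prefix.with_suffix(".truth.tsv")
        table.truth.rename_axis("specimen_id").reset_index().to_csv(
            truth_path, sep=_SEP, index=False
        )
        paths["truth"] = truth_path
    return paths


def read_genotype_table(path: str | Path) -> GenotypeTable:
    frame = pd.read_csv(path, sep=_SEP, dtype=str).fillna("")
    loci = [c for c in frame.columns if c not in ("specimen_id", "year", "rearing")]

    def parse(cell: str) -> tuple:
        if cell == "":
            return ()
        parts = cell.split("/")
        out = []
        for p in parts:
            try:
                out.append(int(p))
            except ValueError:
                out.append(p)
        return tuple(out)

    geno = pd.DataFrame(
        [[parse(frame.loc[i, locus]) for locus in loci] for i in frame.index],
        index=frame["specimen_id"].to_list(),
        columns=loci,
    )
    return GenotypeTable(genotypes=geno, truth=None)
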