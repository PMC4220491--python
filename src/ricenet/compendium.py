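"""Expression compendium container and preprocessing.

A compendium is a genes x samples matrix of already-normalized expression
values pooled from several microarray datasets ("stages"), each sample
carrying a dataset label and the whole compendium a condition label
(control or stress).  Preprocessing mirrors the standard upstream of
coexpression analysis: replicate averaging, per-stage scaling of the pooled
value distribution to mean 0 / s.d. 1, and aggregation of several datasets
on their common gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

CONDITIONS = ("control", "stress")


@dataclass
class ExpressionCompendium:
    """Genes x samples expression matrix with sample metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Real-valued matrix, index = gene ids, columns = sample ids.
    dataset_of_sample : pandas.Series
        Maps each sample id to its dataset/stage id.
    condition : str
        Either ``"control"`` or ``"stress"``.
    """

    data: pd.DataFrame
    dataset_of_sample: pd.Series
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DataError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.data.index.has_duplicates:
            raise DataError("duplicate gene ids in compendium")
        if self.data.columns.has_duplicates:
            raise DataError("duplicate sample ids in compendium")
        self.dataset_of_sample = pd.Series(self.dataset_of_sample)
        missing = [s for s in self.data.columns if s not in self.dataset_of_sample.index]
        if missing:
            raise DataError(f"samples without dataset assignment: {missing[:5]}")
        self.dataset_of_sample = self.dataset_of_sample.loc[self.data.columns]
        if not np.isfinite(self.data.to_numpy()).all():
            raise DataError("non-finite expression values in compendium")

    # -- convenience ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def datasets(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.dataset_of_sample:
            seen.setdefault(d)
        return list(seen)


def average_replicates(
    compendium: ExpressionCompendium, replicate_groups: Mapping[str, str]
) -> ExpressionCompendium:
    """Average technical/biological replicate columns into one column per group.

    ``replicate_groups`` maps sample id -> group id; an empty mapping is the
    identity.  Groups must not span datasets (the averaged column inherits the
    dataset label of its members).
    """
    if not replicate_groups:
        return ExpressionCompendium(
            compendium.data.copy(), compendium.dataset_of_sample.copy(), compendium.condition
        )
    missing = [s for s in compendium.sample_ids if s not in replicate_groups]
    if missing:
        raise DataError(f"samples not assigned to a replicate group: {missing[:5]}")

    groups: dict[str, list[str]] = {}
    for sample in compendium.sample_ids:  # preserve column order of first appearance
        groups.setdefault(replicate_groups[sample], []).append(sample)

    cols = {}
    ds = {}
    for group, members in groups.items():
        member_ds = {compendium.dataset_of_sample[m] for m in members}
        if len(member_ds) > 1:
            raise DataError(f"replicate group {group!r} spans datasets {sorted(member_ds)}")
        cols[group] = compendium.data[members].mean(axis=1)
        ds[group] = next(iter(member_ds))
    out = pd.DataFrame(cols, index=compendium.data.index)
    return ExpressionCompendium(out, pd.Series(ds), compendium.condition)


def scale_within_stage(
    compendium: ExpressionCompendium, per_gene: bool = False
) -> ExpressionCompendium:
    """Scale each dataset/stage block to pooled mean 0 and s.d. 1.

    By default the *pooled* distribution of all values in a stage block (all
    genes, all samples of that stage) is centred and scaled with the
    population s.d. (divisor n), so the post-condition holds exactly.  With
    ``per_gene=True`` each gene row is scaled separately within the stage.
    """
    out = compendium.data.copy().astype(float)
    for dataset in compendium.datasets():
        samples = [s for s in compendium.sample_ids if compendium.dataset_of_sample[s] == dataset]
        if len(samples) < 2:
            raise DataError(f"single-sample stage {dataset!r} cannot be scaled")
        block = out[samples].to_numpy()
        if per_gene:
            mu = block.mean(axis=1, keepdims=True)
            sd = block.std(axis=1, ddof=0, keepdims=True)
            if np.any(sd == 0):
                raise DataError(f"degenerate stage {dataset!r}: constant gene row")
        else:
            mu = block.mean()
            sd = block.std(ddof=0)
            if sd == 0:
                raise DataError(f"degenerate stage {dataset!r}: constant block")
        out[samples] = (block - mu) / sd
    return ExpressionCompendium(out, compendium.dataset_of_sample.copy(), compendium.condition)


def assemble_compendium(matrices: Sequence[ExpressionCompendium]) -> ExpressionCompendium:
    """Concatenate datasets column-wise on the intersection of their genes.

    Genes are restricted to the intersection across all inputs, in sorted id
    order; columns are concatenated in input order.  All inputs must share the
    condition label.
    """
    if not matrices:
        raise DataError("assemble_compendium requires at least one matrix")
    conditions = {m.condition for m in matrices}
    if len(conditions) > 1:
        raise DataError(f"mixed condition labels {sorted(conditions)}")
    common: set[str] = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise DataError("empty gene intersection across datasets")
    genes = sorted(common)
    data = pd.concat([m.data.loc[genes] for m in matrices], axis=1)
    ds = pd.concat([m.dataset_of_sample for m in matrices])
    return ExpressionCompendium(data, ds, matrices[0].condition)


# ----------------------------------------------------------------------
# TSV dialects: expression matrix (first column gene_id) and sample map
# (sample_id, dataset_id, condition).
# ----------------------------------------------------------------------

def write_expression_tsv(data: pd.DataFrame, path: str | Path) -> None:
    data.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.index.name = None  # faithful round trip with in-memory matrices
    return df


def write_sample_map_tsv(
    dataset_of_sample: pd.Series, condition: str, path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "sample_id": dataset_of_sample.index,
            "dataset_id": dataset_of_sample.to_numpy(),
            "condition": condition,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_map_tsv(path: str | Path) -> tuple[pd.Series, str]:
    df = pd.read_csv(path, sep="\t")
    conditions = df["condition"].unique()
    if len(conditions) != 1:
        raise DataError(f"sample map mixes conditions {sorted(conditions)}")
    return pd.Series(df["dataset_id"].to_numpy(), index=df["sample_id"]), conditions[0]


def read_compendium(matrix_path: str | Path, sample_map_path: str | Path) -> ExpressionCompendium:
    data = read_expression_tsv(matrix_path)
    ds, condition = read_sample_map_tsv(sample_map_path)
    return ExpressionCompendium(data, ds, condition)
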