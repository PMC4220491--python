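"""TF x process association networks, condition contrast and TF screening.

Gene-level specific scores S_ij are summarized per functional gene set
(GO-style biological process) by a Stouffer combination over member genes:

    A(j, k) = sum_{i in G_k, i != gene(j)} S_ij / sqrt(|G_k n genes(S) \\ {j}|)

Running the full composition (scaling, correlation, Fisher-Z,
standardization, CLR/Stouffer, summarization) independently on a control
and a stress compendium yields two conditional networks whose contrast
classifies each (TF, process) association as maintained, attenuated to
zero, flipped in sign, gained under stress, or other.  Candidate
regulators of a set of query processes are screened as the TFs positively
associated with *all* of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compendium import ExpressionCompendium, scale_within_stage
from .exceptions import DataError
from .ontology import GeneSetCollection
from .scoring import SpecificScoreMatrix, specific_scores_from_compendium

CATEGORIES = ("maintained", "attenuated_to_none", "flipped", "gained", "other")


@dataclass
class TFProcessNetwork:
    """TF x process association-score matrix for one condition."""

    association: pd.DataFrame  # TFs x processes
    condition: str
    member_counts: pd.Series  # process -> number of scored member genes

    def __post_init__(self) -> None:
        if not np.isfinite(self.association.to_numpy()).all():
            raise DataError("non-finite association scores")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.association.index)

    @property
    def process_ids(self) -> list[str]:
        return list(self.association.columns)


def process_association_scores(
    scores: SpecificScoreMatrix,
    sets: GeneSetCollection,
    condition: str = "control",
    min_size: int = 5,
) -> TFProcessNetwork:
    """Summarize gene-level S into TF x process association scores.

    Stouffer combination over the member genes of each process present in
    the score matrix, excluding each TF's own gene from its sets.  Processes
    with fewer than ``min_size`` scorable members are dropped with a warning.
    """
    gene_index = scores.values.index
    gene_set = set(gene_index)
    s = scores.values.to_numpy(dtype=float)
    tf_ids = scores.tf_ids

    cols: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    dropped = []
    for term, members in sets.sets.items():
        present = sorted(members & gene_set)
        if len(present) < min_size:
            dropped.append(term)
            continue
        rows = gene_index.get_indexer(present)
        block = s[rows]  # members x TFs
        total = block.sum(axis=0)
        # each TF's own gene contributes S=0 (self-pair) to the sum, but must
        # not inflate the denominator
        n_members = np.full(len(tf_ids), len(present), dtype=float)
        for j, tf in enumerate(tf_ids):
            if tf in members:
                n_members[j] -= 1
        if np.any(n_members <= 0):
            dropped.append(term)
            continue
        cols[term] = total / np.sqrt(n_members)
        counts[term] = len(present)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} process(es) with <{min_size} scorable members",
            stacklevel=2,
        )
    if not cols:
        raise DataError("no process with enough scorable members")
    assoc = pd.DataFrame(cols, index=tf_ids)
    return TFProcessNetwork(assoc, condition, pd.Series(counts))


def build_conditional_networks(
    control: ExpressionCompendium,
    stress: ExpressionCompendium,
    tf_ids: Sequence[str],
    sets: GeneSetCollection,
    min_size: int = 5,
    scale: bool = True,
    analytic_standardization: bool = False,
) -> tuple[TFProcessNetwork, TFProcessNetwork]:
    """Run the full composition per condition and return the two networks."""
    if set(control.gene_ids) != set(stress.gene_ids):
        raise DataError("control and stress compendia must share the gene universe")
    nets = []
    for comp in (control, stress):
        prepped = scale_within_stage(comp) if scale else comp
        s = specific_scores_from_compendium(
            prepped, tf_ids, analytic_standardization=analytic_standardization
        )
        nets.append(
            process_association_scores(s, sets, condition=comp.condition, min_size=min_size)
        )
    return nets[0], nets[1]


def contrast_associations(
    net_control: TFProcessNetwork,
    net_stress: TFProcessNetwork,
    tau_pos: float = 2.0,
    tau_zero: float = 1.0,
) -> pd.DataFrame:
    """Classify every (TF, process) pair by its control vs stress association.

    Categories (z-scale thresholds tau_pos > tau_zero > 0):

    - ``maintained``:          a_c > tau_pos and a_s > tau_pos
    - ``attenuated_to_none``:  a_c > tau_pos and |a_s| <= tau_zero
    - ``flipped``:             a_c > tau_pos and a_s < -tau_zero
    - ``gained``:              a_s > tau_pos and a_c <= tau_zero (symmetric rule)
    - ``other``:               anything else
    """
    if list(net_control.association.index) != list(net_stress.association.index) or list(
        net_control.association.columns
    ) != list(net_stress.association.columns):
        raise DataError("networks must share TF and process axes")
    a_c = net_control.association.to_numpy(dtype=float)
    a_s = net_stress.association.to_numpy(dtype=float)

    cat = np.full(a_c.shape, "other", dtype=object)
    cat[(a_c > tau_pos) & (a_s > tau_pos)] = "maintained"
    cat[(a_c > tau_pos) & (np.abs(a_s) <= tau_zero)] = "attenuated_to_none"
    cat[(a_c > tau_pos) & (a_s < -tau_zero)] = "flipped"
    cat[(a_s > tau_pos) & (a_c <= tau_zero)] = "gained"

    tf_idx, proc_idx = np.meshgrid(
        np.arange(a_c.shape[0]), np.arange(a_c.shape[1]), indexing="ij"
    )
    return pd.DataFrame(
        {
            "tf_id": np.asarray(net_control.association.index)[tf_idx.ravel()],
            "process_id": np.asarray(net_control.association.columns)[proc_idx.ravel()],
            "a_control": a_c.ravel(),
            "a_stress": a_s.ravel(),
            "category": cat.ravel(),
        }
    )


def screen_candidate_tfs(
    net_control: TFProcessNetwork,
    tf_subset: Iterable[str],
    query_process_ids: Sequence[str],
    de_regulated_tfs: Iterable[str] | None = None,
    tau_pos: float = 2.0,
) -> pd.DataFrame:
    """Screen for TFs positively associated with *all* query processes.

    Candidates are ``tf_subset`` intersected with ``de_regulated_tfs`` (when
    given).  A TF passes iff its association exceeds ``tau_pos`` on every
    query process.  The returned table lists every candidate with its
    per-query profile, minimum association over the queries, and pass flag,
    sorted passers-first by minimum association descending.
    """
    missing = [p for p in query_process_ids if p not in net_control.association.columns]
    if missing:
        raise DataError(f"query processes absent from network: {missing}")
    candidates = [t for t in net_control.tf_ids if t in set(tf_subset)]
    if de_regulated_tfs is not None:
        de_set = set(de_regulated_tfs)
        candidates = [t for t in candidates if t in de_set]
    if not candidates:
        raise DataError("empty candidate TF set after intersection")
    block = net_control.association.loc[candidates, list(query_process_ids)]
    min_assoc = block.min(axis=1)
    passes = (block > tau_pos).all(axis=1)
    out = block.copy()
    out["min_association"] = min_assoc
    out["passes"] = passes
    out = out.sort_values(
        by=["passes", "min_association"], ascending=[False, False], kind="mergesort"
    )
    out.index.name = "tf_id"
    return out.reset_index()


# ----------------------------------------------------------------------
# Model / Results interface
# ----------------------------------------------------------------------

class ConditionalNetworkModel:
    """Conditional TF-process association network model.

    Built from a control and a stress expression compendium, the TF list and
    a (pruned) gene-set collection; :meth:`fit` runs the whole inference
    composition per condition and returns a
    :class:`ConditionalNetworkResults`.
    """

    def __init__(
        self,
        control: ExpressionCompendium,
        stress: ExpressionCompendium,
        tf_ids: Sequence[str],
        gene_sets: GeneSetCollection,
        min_size: int = 5,
        scale: bool = True,
        analytic_standardization: bool = False,
    ) -> None:
        self.control = control
        self.stress = stress
        self.tf_ids = list(tf_ids)
        self.gene_sets = gene_sets
        self.min_size = min_size
        self.scale = scale
        self.analytic_standardization = analytic_standardization

    def fit(self, tau_pos: float = 2.0, tau_zero: float = 1.0) -> "ConditionalNetworkResults":
        net_c, net_s = build_conditional_networks(
            self.control,
            self.stress,
            self.tf_ids,
            self.gene_sets,
            min_size=self.min_size,
            scale=self.scale,
            analytic_standardization=self.analytic_standardization,
        )
        contrast = contrast_associations(net_c, net_s, tau_pos=tau_pos, tau_zero=tau_zero)
        return ConditionalNetworkResults(self, net_c, net_s, contrast, tau_pos, tau_zero)


@dataclass
class ConditionalNetworkResults:
    """Fitted conditional networks, their contrast and screening helpers."""

    model: ConditionalNetworkModel
    network_control: TFProcessNetwork
    network_stress: TFProcessNetwork
    contrast: pd.DataFrame
    tau_pos: float
    tau_zero: float

    def screen(
        self,
        tf_subset: Iterable[str] | None = None,
        query_process_ids: Sequence[str] | None = None,
        de_regulated_tfs: Iterable[str] | None = None,
    ) -> pd.DataFrame:
        if tf_subset is None:
            tf_subset = self.network_control.tf_ids
        if query_process_ids is None:
            query_process_ids = self.network_control.process_ids
        return screen_candidate_tfs(
            self.network_control,
            tf_subset,
            query_process_ids,
            de_regulated_tfs,
            tau_pos=self.tau_pos,
        )

    def summary(self) -> str:
        counts = self.contrast["category"].value_counts()
        lines = [
            "Conditional TF-process association network",
            "==========================================",
            f"TFs: {len(self.network_control.tf_ids)}"
            f"   processes: {len(self.network_control.process_ids)}",
            f"thresholds: tau_pos={self.tau_pos:g}, tau_zero={self.tau_zero:g}",
            "contrast categories:",
        ]
        for cat in CATEGORIES:
            lines.append(f"  {cat:<20s} {int(counts.get(cat, 0)):6d}")
        return "\n".join(lines)

    # -- exports -------------------------------------------------------
    def to_edge_list(self) -> pd.DataFrame:
        """Long-format (tf, process, a_control, a_stress, category) table."""
        return self.contrast.copy()

    def plot_contrast(self, tf_id: str, ax=None):
        """Scatter of a TF's process associations, control (x) vs stress (y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        sub = self.contrast[self.contrast["tf_id"] == tf_id]
        ax.scatter(sub["a_control"], sub["a_stress"], s=12)
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel("association score (control)")
        ax.set_ylabel("association score (stress)")
        ax.set_title(f"{tf_id}: process associations")
        return ax

    def plot_heatmap(self, condition: str = "control", ax=None):
        """Heatmap of the association matrix, TFs ordered by hierarchical
        clustering of their association rows (display only)."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import pdist

        net = self.network_control if condition == "control" else self.network_stress
        a = net.association.to_numpy()
        order = (
            leaves_list(average(pdist(a, metric="euclidean"))) if a.shape[0] > 2 else range(a.shape[0])
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(a[list(order)], aspect="auto", cmap="coolwarm")
        ax.set_yticks(range(len(net.tf_ids)))
        ax.set_yticklabels([net.tf_ids[i] for i in order], fontsize=5)
        ax.set_xticks(range(len(net.process_ids)))
        ax.set_xticklabels(net.process_ids, rotation=90, fontsize=5)
        plt.colorbar(im, ax=ax, label="association score")
        return ax
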