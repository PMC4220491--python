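"""Two-group differential expression and gene-set enrichment.

The microarray DE stage: a nonspecific interquartile-range filter (genes
whose IQR falls strictly below the median IQR are dropped), an
empirical-Bayes moderated t-test with variance shrinkage toward a prior
fitted by moment matching on the scaled-F distribution of the per-gene
sample variances, Benjamini-Hochberg q-values, and a strict q < 0.01 call.
Differentially expressed genes are then tested per gene set with the
upper-tail hypergeometric test, BH-adjusted, and the significant sets are
connected into an overlap graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .compendium import ExpressionCompendium
from .exceptions import DataError
from .ontology import GeneSetCollection, jaccard


def iqr_filter(data: pd.DataFrame) -> list[str]:
    """Nonspecific variation filter.

    Computes each gene's interquartile range across samples (quartiles by
    linear interpolation) and removes genes whose IQR is strictly below the
    median IQR of all genes.  Returns the retained gene ids in input order.
    """
    if data.shape[1] < 4:
        raise DataError("IQR filter needs >= 4 samples")
    q1, q3 = np.percentile(data.to_numpy(dtype=float), [25, 75], axis=1)
    iqr = q3 - q1
    med = np.median(iqr)
    keep = iqr >= med
    return [g for g, k in zip(data.index, keep) if k]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching fit of the prior (d0, s0^2) for variance shrinkage.

    Under the hierarchical model the sample variances follow a scaled F
    distribution; matching the mean and variance of log(s^2) (via digamma /
    trigamma moments of log chi-square variables) yields the prior degrees
    of freedom d0 (possibly infinite) and prior variance s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise DataError("too few positive sample variances to fit a prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # no excess dispersion beyond chi-square sampling noise: infinite
        # prior df, and the pooled mean variance is the MLE of the scale
        d0 = np.inf
        s0_sq = s2[ok].mean()
    return d0, float(s0_sq)


def moderated_t_test(
    data: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    reference: str | None = None,
    moderated: bool = True,
) -> pd.DataFrame:
    """Per-gene two-group (moderated) t-test.

    The contrast is group2 - group1 where group1 is ``reference`` (default:
    the lexicographically first label).  With ``moderated=True`` residual
    variances are shrunk toward the fitted prior:

        s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

    and the t-statistic is referred to a t distribution on d0 + d degrees of
    freedom (capped at the total residual df across genes).  With
    ``moderated=False`` this is the ordinary pooled equal-variance t-test.

    Returns a DataFrame indexed by gene with columns ``log_ratio``, ``t``,
    ``p``, ``s2``, ``s2_post`` and ``df_total``.
    """
    groups = pd.Series(groups)
    groups = groups.loc[data.columns]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise DataError(f"need exactly two groups, got {labels}")
    if reference is None:
        reference = labels[0]
    other = [l for l in labels if l != reference][0]
    g1 = data.loc[:, groups == reference].to_numpy(dtype=float)
    g2 = data.loc[:, groups == other].to_numpy(dtype=float)
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError("each group needs >= 2 samples (variance undefined)")
    df_resid = n1 + n2 - 2
    delta = g2.mean(axis=1) - g1.mean(axis=1)
    ss = ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (g2 - g2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    if moderated:
        d0, s0_sq = fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        # total df capped at the pooled residual df across genes
        df_total = min(d0 + df_resid, df_resid * len(s2))
    else:
        s2_post = s2
        df_total = df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / (np.sqrt(s2_post) * se_factor)
    # zero pooled variance with zero difference: no evidence, p = 1
    degenerate = (s2_post == 0) & (delta == 0)
    t = np.where(degenerate, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "log_ratio": delta,
            "t": t,
            "p": p,
            "s2": s2,
            "s2_post": s2_post,
            "df_total": df_total,
        },
        index=data.index,
    )


def p_to_q(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (pi0 = 1), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    table: pd.DataFrame, q_threshold: float = 0.01, q_column: str = "q"
) -> list[str]:
    """Genes with q strictly below the threshold, sorted by (q, gene id)."""
    sig = table[table[q_column] < q_threshold]
    return sorted(sig.index, key=lambda g: (sig.loc[g, q_column], g))


def hypergeometric_enrichment(
    de_genes: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene set in the DE list.

    For a universe of N genes, a set of K, a DE list of n and overlap k, the
    p-value is P(X >= k) for X ~ Hypergeometric(N, K, n); q-values are BH
    across the tested sets, significance is q < ``q_threshold`` (strict).
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty gene universe")
    de = set(de_genes)
    if not de <= uni:
        raise DataError("DE genes must be a subset of the universe")
    rows = []
    for term, members in sets.sets.items():
        in_uni = members & uni
        k = len(in_uni & de)
        rows.append((term, k, len(in_uni), len(de), len(uni)))
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N"])
    df["p"] = stats.hypergeom.sf(df["k"] - 1, df["N"], df["K"], df["n"])
    df["p"] = df["p"].clip(upper=1.0, lower=np.nextafter(0, 1))
    df["q"] = p_to_q(df["p"].to_numpy())
    df["significant"] = df["q"] < q_threshold
    return df.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)


def gene_set_overlap_graph(
    enrichment: pd.DataFrame,
    de_genes: Iterable[str],
    sets: GeneSetCollection,
    overlap_jaccard: float = 0.25,
) -> nx.Graph:
    """Graph of significant sets, edges joining significantly overlapping ones.

    Nodes are the significant sets (attributes: set size K, overlap k, q);
    an undirected edge joins two sets whose *DE-overlap* gene sets have a
    Jaccard coefficient >= ``overlap_jaccard``.
    """
    de = set(de_genes)
    sig = enrichment[enrichment["significant"]]
    graph = nx.Graph()
    overlaps: dict[str, frozenset[str]] = {}
    for row in sig.itertuples(index=False):
        overlaps[row.term_id] = frozenset(sets[row.term_id] & de)
        graph.add_node(row.term_id, size=int(row.K), k=int(row.k), q=float(row.q))
    terms = list(overlaps)
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            if not (overlaps[a] | overlaps[b]):
                continue
            if jaccard(overlaps[a], overlaps[b]) >= overlap_jaccard:
                graph.add_edge(a, b)
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


# ----------------------------------------------------------------------
# Model / Results interface
# ----------------------------------------------------------------------

class TwoGroupDEModel:
    """Two-group differential-expression model for an expression experiment.

    Parameters
    ----------
    compendium : ExpressionCompendium or pandas.DataFrame
        Genes x samples expression values.
    groups : mapping or Series
        Sample id -> group label (exactly two labels).
    """

    def __init__(
        self,
        compendium: ExpressionCompendium | pd.DataFrame,
        groups: Mapping[str, str] | pd.Series,
        reference: str | None = None,
    ) -> None:
        self.data = compendium.data if isinstance(compendium, ExpressionCompendium) else compendium
        self.groups = pd.Series(groups)
        self.reference = reference

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, groups: Mapping[str, str] | pd.Series, **kwargs
    ) -> "TwoGroupDEModel":
        return cls(data, groups, **kwargs)

    def fit(
        self,
        nonspecific_filter: bool = True,
        moderated: bool = True,
        q_threshold: float = 0.01,
    ) -> "DEResults":
        retained = iqr_filter(self.data) if nonspecific_filter else list(self.data.index)
        table = moderated_t_test(
            self.data.loc[retained], self.groups, reference=self.reference, moderated=moderated
        )
        table["q"] = p_to_q(table["p"].to_numpy())
        full = table.reindex(self.data.index)
        full["filtered"] = ~full.index.isin(retained)
        return DEResults(self, full, retained, q_threshold)


@dataclass
class DEResults:
    """Fitted DE table with q-values, call list and enrichment helper."""

    model: TwoGroupDEModel
    table: pd.DataFrame
    retained: list[str]
    q_threshold: float

    @property
    def de_genes(self) -> list[str]:
        tested = self.table.loc[self.retained]
        return call_de(tested, q_threshold=self.q_threshold)

    def enrich(
        self,
        sets: GeneSetCollection,
        universe: Iterable[str] | None = None,
        q_threshold: float = 0.01,
    ) -> pd.DataFrame:
        if universe is None:
            universe = list(self.model.data.index)
        return hypergeometric_enrichment(self.de_genes, universe, sets, q_threshold=q_threshold)

    def summary(self) -> str:
        n_genes = self.table.shape[0]
        n_tested = len(self.retained)
        de = self.de_genes
        lines = [
            "Two-group differential expression (moderated t)",
            "===============================================",
            f"genes: {n_genes}   retained by IQR filter: {n_tested}",
            f"q threshold: {self.q_threshold:g}   DE genes: {len(de)}",
        ]
        if de:
            head = self.table.loc[de[:10], ["log_ratio", "t", "p", "q"]]
            lines.append(head.to_string(float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")
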