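"""ceRNA pair inference and mixed-network assembly.

A lncRNA and a transcription factor (TF) compete for the same microRNAs when
their miRNA target sets overlap more than chance allows.  Each lncRNA-TF pair
is scored with the hypergeometric upper tail of its shared-miRNA count against
the miRNA universe, then filtered on expression correlation: pairs with
``p < 0.05`` and Pearson correlation ``> 0.6`` (both strict) are called
significant and combined with TF-TF protein-protein interaction (PPI) edges
into a single undirected typed network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .io import ExpressionMatrix, InteractionTable

logger = logging.getLogger(__name__)


@dataclass
class CeRNATestResult:
    """Shared-miRNA test for one lncRNA-TF pair.

    ``m_l`` / ``m_t`` are the pair members' miRNA target-set sizes, ``k`` the
    shared count, ``N`` the miRNA universe size, ``p`` the hypergeometric
    upper tail P(X >= k), and ``pcc`` the expression Pearson correlation
    (None until computed).
    """

    lncrna_id: str
    tf_id: str
    m_l: int
    m_t: int
    k: int
    N: int
    p: float
    pcc: float | None = None


def hypergeom_upper_tail(k: int, m_l: int, m_t: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m_l, m_t).

    Models the shared-miRNA count of a pair whose members target ``m_l`` and
    ``m_t`` miRNAs out of a universe of ``N``.  Delegates to scipy's
    log-space survival function for numerical stability.
    """
    if N < 0 or m_l < 0 or m_t < 0 or k < 0:
        raise ValueError("all arguments must be non-negative")
    if m_l > N or m_t > N:
        raise ValueError(f"target-set sizes ({m_l}, {m_t}) cannot exceed the universe N={N}")
    if k > min(m_l, m_t):
        raise ValueError(f"shared count k={k} cannot exceed min(m_l, m_t)={min(m_l, m_t)}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m_l, m_t))


def score_all_pairs(
    mirna_lncrna: InteractionTable,
    mirna_tf: InteractionTable,
    universe: int | set[str] | None = None,
    include_empty: bool = False,
) -> list[CeRNATestResult]:
    """Hypergeometric shared-miRNA test for every (lncRNA, TF) pair.

    ``universe`` defaults to the union of source miRNAs across both tables;
    an explicit size or miRNA id set overrides it.  Pairs sharing no miRNA
    are omitted unless ``include_empty`` (then recorded with p = 1).
    """
    if len(mirna_lncrna) == 0 or len(mirna_tf) == 0:
        raise ValueError("both interaction tables must be non-empty")
    lnc_sets = mirna_lncrna.sources_by_target()
    tf_sets = mirna_tf.sources_by_target()
    if universe is None:
        N = len(mirna_lncrna.sources | mirna_tf.sources)
    elif isinstance(universe, int):
        N = universe
    else:
        N = len(set(universe))
    if N <= 0:
        raise ValueError("miRNA universe is empty")
    results: list[CeRNATestResult] = []
    for lnc in sorted(lnc_sets):
        s_l = lnc_sets[lnc]
        for tf in sorted(tf_sets):
            s_t = tf_sets[tf]
            k = len(s_l & s_t)
            if k == 0 and not include_empty:
                continue
            results.append(
                CeRNATestResult(
                    lncrna_id=lnc,
                    tf_id=tf,
                    m_l=len(s_l),
                    m_t=len(s_t),
                    k=k,
                    N=N,
                    p=hypergeom_upper_tail(k, len(s_l), len(s_t), N),
                )
            )
    return results


def pearson_correlation(x, y) -> float:
    """Product-moment correlation on pairwise-complete observations.

    Samples missing in either vector are excluded; fewer than 3 complete
    pairs or a zero-variance vector is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need >=3 paired non-missing observations")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation undefined for zero-variance vector")
    return float(np.corrcoef(xs, ys)[0, 1])


def filter_significant_pairs(
    results: list[CeRNATestResult],
    expr: ExpressionMatrix,
    p_threshold: float = 0.05,
    pcc_threshold: float = 0.6,
) -> list[CeRNATestResult]:
    """Retain pairs with p < p_threshold AND expression PCC > pcc_threshold.

    Both inequalities are strict.  Correlation is computed only for pairs
    already passing the hypergeometric threshold; pairs missing expression
    for either member are dropped and counted in the log.
    """
    retained: list[CeRNATestResult] = []
    n_missing = 0
    gene_index = set(expr.values.index)
    for res in results:
        if not (res.p < p_threshold):
            continue
        if res.lncrna_id not in gene_index or res.tf_id not in gene_index:
            n_missing += 1
            continue
        pcc = pearson_correlation(
            expr.values.loc[res.lncrna_id].to_numpy(),
            expr.values.loc[res.tf_id].to_numpy(),
        )
        res.pcc = pcc
        if pcc > pcc_threshold:
            retained.append(res)
    if n_missing:
        logger.info("filter_significant_pairs: dropped %d pairs lacking expression", n_missing)
    return retained


def assemble_network(
    significant_pairs: list[CeRNATestResult],
    ppi: InteractionTable | None = None,
    include_all_ppi: bool = False,
) -> nx.Graph:
    """Union of significant ceRNA pairs and TF-TF PPI edges.

    Nodes carry ``kind`` ('lncRNA'/'TF'); edges carry ``etype`` ('ceRNA' with
    test evidence, or 'PPI').  By default PPI edges are added only between
    TFs already present in a significant ceRNA pair; ``include_all_ppi``
    admits every PPI TF.  An id appearing as both lncRNA and TF is an error.
    """
    net = nx.Graph()
    lnc_ids = {r.lncrna_id for r in significant_pairs}
    tf_ids = {r.tf_id for r in significant_pairs}
    clash = lnc_ids & tf_ids
    if clash:
        raise ValueError(f"ids appear as both lncRNA and TF: {sorted(clash)[:5]}")
    for r in significant_pairs:
        if r.lncrna_id == r.tf_id:
            continue
        net.add_node(r.lncrna_id, kind="lncRNA")
        net.add_node(r.tf_id, kind="TF")
        if not net.has_edge(r.lncrna_id, r.tf_id):
            net.add_edge(
                r.lncrna_id, r.tf_id,
                etype="ceRNA", m_l=r.m_l, m_t=r.m_t, k=r.k, N=r.N, p=r.p,
                **({"pcc": r.pcc} if r.pcc is not None else {}),
            )
    if ppi is not None:
        for _, row in ppi.df.iterrows():
            a, b = row["source_id"], row["target_id"]
            if a == b:
                continue
            if a in lnc_ids or b in lnc_ids:
                raise ValueError(f"PPI member {a if a in lnc_ids else b!r} is a lncRNA id")
            if not include_all_ppi and (a not in tf_ids or b not in tf_ids):
                continue
            net.add_node(a, kind="TF")
            net.add_node(b, kind="TF")
            if not net.has_edge(a, b):
                net.add_edge(a, b, etype="PPI")
    return net
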