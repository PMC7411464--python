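"""FIMO-style PWM scanning with exact p-values, promoter derivation, and the
lncRNA-TF crosstalk network.

A window of sequence is scored by the log2 odds of the position weight
matrix (PWM) against a 0-order background.  Per-position scores are
discretised to integers (granularity 1/1000 of a log2 unit) so the exact
null score distribution under the background model can be computed by
dynamic programming — a column-by-column convolution of the discretised
score distributions — and each observed score mapped to
P(background window scores >= observed).  Hits on the minus strand are
scored against the reverse-complemented matrix at the same forward-strand
offset convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cerna import hypergeom_upper_tail
from .io import PWM

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GRANULARITY = 1000
PSEUDOCOUNT = 1e-3


@dataclass
class MotifHit:
    """A PWM occurrence: offset is the 0-based start of the matched window on
    the forward strand of the region."""

    motif_id: str
    region_id: str
    offset: int
    strand: str
    score: float
    p: float


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _int_score_matrix(pwm: PWM, background: np.ndarray) -> np.ndarray:
    """(width, 4) integer-discretised log2-odds scores; zero probabilities
    get a pseudocount so no score is -inf."""
    mat = pwm.matrix.copy()
    mat[mat == 0] = PSEUDOCOUNT
    logodds = np.log2(mat / background)
    return np.rint(logodds * GRANULARITY).astype(np.int64)


class ScoreNull:
    """Exact null distribution of the integer window score under the
    background model, built by per-column convolution."""

    def __init__(self, int_scores: np.ndarray, background: np.ndarray):
        mins = int_scores.min(axis=1)
        maxs = int_scores.max(axis=1)
        dist = np.array([1.0])
        lo = 0
        for j in range(int_scores.shape[0]):
            new = np.zeros(len(dist) + int(maxs[j] - mins[j]))
            for b in range(4):
                s = int(int_scores[j, b] - mins[j])
                new[s : s + len(dist)] += background[b] * dist
            dist = new
            lo += int(mins[j])
        self.lo = lo
        self.hi = lo + len(dist) - 1
        # suffix[i] = P(score >= lo + i)
        self.suffix = np.cumsum(dist[::-1])[::-1]

    def pvalue(self, int_score: int) -> float:
        """P(background window score >= int_score); monotone non-increasing."""
        if int_score <= self.lo:
            return 1.0
        if int_score > self.hi:
            return 0.0
        return float(self.suffix[int_score - self.lo])

    def pvalues(self, int_scores: np.ndarray) -> np.ndarray:
        idx = np.clip(int_scores - self.lo, 0, len(self.suffix) - 1)
        out = self.suffix[idx]
        out = np.where(int_scores <= self.lo, 1.0, out)
        out = np.where(int_scores > self.hi, 0.0, out)
        return out


def _window_int_scores(seq_idx: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores for every window plus a validity mask (no N inside)."""
    w = int_scores.shape[0]
    n_win = len(seq_idx) - w + 1
    if n_win <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(seq_idx > 3, 0, seq_idx)
    for j in range(w):
        col = safe[j : j + n_win]
        scores += int_scores[j, col]
        valid &= seq_idx[j : j + n_win] <= 3
    return scores, valid


def pwm_scan(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    region_id: str = "seq",
) -> list[MotifHit]:
    """Scan both strands of a sequence, returning hits with p < p_threshold.

    Windows containing N are skipped; a motif wider than the sequence yields
    an empty result.  Hits are sorted by offset, then strand.
    """
    seq = sequence.upper()
    bg = np.asarray(background, float) if background is not None else np.asarray(pwm.background)
    w = pwm.width
    if w > len(seq):
        return []
    seq_idx = np.array([_BASE_INDEX.get(c, 4) for c in seq], dtype=np.int64)
    hits: list[MotifHit] = []
    for strand in "+-":
        if strand == "+":
            ints = _int_score_matrix(pwm, bg)
        else:
            # reverse-complement the matrix: reverse columns, swap A<->T, C<->G
            rc = pwm.matrix[::-1, ::-1]
            ints = _int_score_matrix(PWM(pwm.motif_id, rc, bg), bg)
        null = ScoreNull(ints, bg)
        scores, valid = _window_int_scores(seq_idx, ints)
        pvals = null.pvalues(scores)
        for off in np.nonzero(valid & (pvals < p_threshold))[0]:
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    region_id=region_id,
                    offset=int(off),
                    strand=strand,
                    score=float(scores[off]) / GRANULARITY,
                    p=float(pvals[off]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_regions(
    sequences: dict[str, str],
    motifs: list[PWM],
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
) -> list[MotifHit]:
    """Scan every motif against every named region sequence."""
    hits: list[MotifHit] = []
    for pwm in motifs:
        for region_id in sorted(sequences):
            hits.extend(
                pwm_scan(sequences[region_id], pwm, p_threshold=p_threshold,
                         background=background, region_id=region_id)
            )
    return hits


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.motif_id, h.region_id, h.offset, h.strand, h.score, h.p) for h in hits],
        columns=["motif_id", "region_id", "start", "strand", "score", "p"],
    )


# ---------------------------------------------------------------------------
# promoter regions
# ---------------------------------------------------------------------------


def promoter_regions(
    annotation: pd.DataFrame, flank: int = 2000, contig_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """+/-flank windows around the strand-aware TSS, 0-based half-open.

    TSS = ``start`` for + strand genes, ``end - 1`` for - strand genes; the
    promoter is [TSS - flank, TSS + flank) clipped to the contig.
    """
    rows = []
    for _, rec in annotation.iterrows():
        strand = rec["strand"]
        if strand not in ("+", "-"):
            raise ValueError(f"gene {rec['gene_id']}: unknown strand {strand!r}")
        tss = int(rec["start"]) if strand == "+" else int(rec["end"]) - 1
        start = max(0, tss - flank)
        end = tss + flank
        if contig_lengths and rec["chrom"] in contig_lengths:
            end = min(end, contig_lengths[rec["chrom"]])
        rows.append(
            (f"promoter:{rec['gene_id']}", rec["chrom"], start, end, strand,
             "promoter", rec["gene_id"])
        )
    return pd.DataFrame(
        rows,
        columns=["region_id", "chrom", "start", "end", "strand", "kind", "linked_gene_id"],
    )


# ---------------------------------------------------------------------------
# crosstalk network
# ---------------------------------------------------------------------------


def build_crosstalk_network(
    net: nx.Graph,
    hits: list[MotifHit],
    regions: pd.DataFrame,
    motif_to_tf: dict[str, str],
    hub_fraction: float = 0.20,
) -> nx.Graph:
    """ceRNA edges whose TF has a motif hit in the lncRNA's linked regions,
    restricted to the top ``hub_fraction`` of lncRNAs by network degree.

    Edges of the result are always a subset of the input's ceRNA edges.
    Motifs with no TF mapping are skipped with a warning in the log.
    """
    kinds = nx.get_node_attributes(net, "kind")
    lncs = [n for n in net.nodes if kinds.get(n) == "lncRNA"]
    n_top = math.floor(hub_fraction * len(lncs))
    btw = nx.betweenness_centrality(net, normalized=True)
    top_lncs = set(
        sorted(lncs, key=lambda v: (-net.degree[v], -btw[v], str(v)))[:n_top]
    )
    region_gene = dict(zip(regions["region_id"], regions["linked_gene_id"]))
    # gene -> set of TFs with >=1 hit in a region linked to that gene
    bound: dict[str, set[str]] = {}
    for h in hits:
        tf = motif_to_tf.get(h.motif_id)
        if tf is None:
            logger.warning("motif %s has no TF mapping; hit skipped", h.motif_id)
            continue
        gene = region_gene.get(h.region_id)
        if gene is None:
            continue
        bound.setdefault(gene, set()).add(tf)
    out = nx.Graph()
    for u, v, d in net.edges(data=True):
        if d.get("etype") != "ceRNA":
            continue
        lnc, tf = (u, v) if kinds.get(u) == "lncRNA" else (v, u)
        if lnc in top_lncs and tf in bound.get(lnc, ()):
            out.add_node(lnc, kind="lncRNA")
            out.add_node(tf, kind="TF")
            out.add_edge(lnc, tf, **d)
    return out


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------


def gene_set_overrepresentation(
    query_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query in named gene sets.

    Per set: k = |query & set|, K = |set|, n = |query|, N = |universe|,
    p = P(overlap >= k).  ``adjust`` adds Benjamini-Hochberg values.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    rows = []
    for name in sorted(gene_sets):
        gset = set(gene_sets[name]) & universe
        k = len(query & gset)
        p = hypergeom_upper_tail(k, len(gset), len(query), len(universe))
        rows.append((name, k, len(gset), len(query), len(universe), p))
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if adjust and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
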