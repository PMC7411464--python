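"""Seeded synthetic-data generators with known ground truth.

Every generator is fully deterministic given its seed and plants exactly the
statistical structure the downstream analyses assume:

* miRNA-target tables where designated lncRNA-TF pairs share a guaranteed
  excess of miRNAs over an independent Bernoulli baseline;
* log-scale expression in which the members of each planted pair are
  correlated through a shared latent factor (x = sqrt(rho) z_pair +
  sqrt(1-rho) z_own gives Pearson correlation exactly rho in expectation),
  with optional tumor-vs-normal mean shifts on designated genes;
* exponential survival times under proportional hazards
  (hazard = baseline * exp(sum_g coef_g * expr_g)) with independent
  exponential censoring;
* DNA regions of i.i.d. background composition carrying motif consensus
  sequences planted at known positions and strands.

Non-planted pairs satisfy the null of both ceRNA tests by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PWM, ExpressionMatrix, InteractionTable, SUBTYPES, STAGES
from .motifs import reverse_complement


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic dataset."""

    true_cerna_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_correlation: float | None = None
    planted_overlap_boost: int | None = None
    risk_genes: dict[str, float] = field(default_factory=dict)
    planted_motif_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    group_shift: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_cerna_pairs": sorted(list(p) for p in self.true_cerna_pairs),
            "planted_correlation": self.planted_correlation,
            "planted_overlap_boost": self.planted_overlap_boost,
            "risk_genes": self.risk_genes,
            "planted_motif_sites": [list(s) for s in self.planted_motif_sites],
            "group_shift": self.group_shift,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def generate_interactions(
    n_mirna: int,
    n_lncrna: int,
    n_tf: int,
    baseline_rate: float,
    true_pairs: list[tuple[int, int]] | int,
    shared_boost: int,
    seed: int,
) -> tuple[InteractionTable, InteractionTable, PlantedTruth]:
    """Bipartite miRNA-target tables with planted shared-miRNA excess.

    Each miRNA targets each lncRNA/TF independently with ``baseline_rate``;
    for every true pair a further ``shared_boost`` miRNAs are wired to BOTH
    members, guaranteeing overlap excess.  ``true_pairs`` is either a list of
    (lncRNA index, TF index) tuples or a count drawn as disjoint pairs.
    """
    if not 0 <= baseline_rate < 1:
        raise ValueError("baseline_rate must be in [0, 1)")
    if shared_boost > n_mirna:
        raise ValueError(f"shared_boost={shared_boost} exceeds n_mirna={n_mirna}")
    rng = np.random.default_rng(seed)
    mirnas = _ids("miR-", n_mirna)
    lncs = _ids("LNC", n_lncrna)
    tfs = _ids("TF", n_tf)
    if isinstance(true_pairs, int):
        if true_pairs > min(n_lncrna, n_tf):
            raise ValueError("more true pairs requested than disjoint pairs available")
        pair_idx = [(i, i) for i in range(true_pairs)]
    else:
        pair_idx = list(true_pairs)
    lnc_mat = rng.random((n_mirna, n_lncrna)) < baseline_rate
    tf_mat = rng.random((n_mirna, n_tf)) < baseline_rate
    if shared_boost * len(pair_idx) > n_mirna:
        raise ValueError(
            "cannot plant disjoint boost sets: shared_boost * n_pairs exceeds n_mirna"
        )
    # disjoint boost sets so non-planted pairs stay at the baseline null
    perm = rng.permutation(n_mirna)
    truth_pairs: set[tuple[str, str]] = set()
    for idx, (li, ti) in enumerate(pair_idx):
        boost = perm[idx * shared_boost : (idx + 1) * shared_boost]
        lnc_mat[boost, li] = True
        tf_mat[boost, ti] = True
        truth_pairs.add((lncs[li], tfs[ti]))

    def to_table(mat: np.ndarray, targets: list[str], kind: str) -> InteractionTable:
        rows = [
            (mirnas[i], targets[j], kind)
            for i, j in zip(*np.nonzero(mat))
        ]
        if not rows:
            rows = []
        df = pd.DataFrame(rows, columns=["source_id", "target_id", "target_kind"])
        return InteractionTable(df=df, target_kind=kind)

    truth = PlantedTruth(true_cerna_pairs=truth_pairs, planted_overlap_boost=shared_boost)
    return to_table(lnc_mat, lncs, "lncRNA"), to_table(tf_mat, tfs, "TF"), truth


def generate_expression(
    genes: list[str],
    n_tumor: int,
    n_normal: int,
    true_pairs: set[tuple[str, str]],
    rho: float,
    group_shift: float,
    noise_sd: float = 1.0,
    seed: int = 0,
    shift_genes: list[str] | None = None,
    baseline: float = 8.0,
) -> ExpressionMatrix:
    """Log-scale expression with planted pair correlation and group shifts.

    Members of each true pair share a latent standard-normal factor so their
    Pearson correlation is ``rho``; ``shift_genes`` (default: the true-pair
    members) get ``group_shift`` added in tumor samples.  Values are centred
    at ``baseline`` with marginal SD ``noise_sd``.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    n = n_tumor + n_normal
    if n < 3:
        raise ValueError("need >=3 samples (correlation undefined below that)")
    rng = np.random.default_rng(seed)
    samples = [f"TUMOR-{i + 1:04d}" for i in range(n_tumor)] + [
        f"NORMAL-{i + 1:04d}" for i in range(n_normal)
    ]
    values = pd.DataFrame(
        rng.standard_normal((len(genes), n)), index=list(genes), columns=samples
    )
    sign = np.sign(rho) if rho else 1.0
    for lnc, tf in sorted(true_pairs):
        z = rng.standard_normal(n)
        a = abs(rho)
        for g, s in ((lnc, 1.0), (tf, sign)):
            if g in values.index:
                own = rng.standard_normal(n)
                values.loc[g] = s * np.sqrt(a) * z + np.sqrt(1 - a) * own
    values = baseline + noise_sd * values
    shift_targets = shift_genes if shift_genes is not None else sorted(
        {g for pair in true_pairs for g in pair}
    )
    if group_shift:
        tumor_cols = samples[:n_tumor]
        for g in shift_targets:
            if g in values.index:
                values.loc[g, tumor_cols] += group_shift
    meta = pd.DataFrame(
        {"tissue": ["tumor"] * n_tumor + ["normal"] * n_normal}, index=samples
    )
    return ExpressionMatrix(values=values, sample_meta=meta)


def generate_survival(
    samples: list[str],
    risk_genes: dict[str, float],
    expr: ExpressionMatrix,
    baseline_hazard: float = 1e-3,
    censor_rate: float = 5e-4,
    seed: int = 0,
    center: bool = True,
) -> pd.DataFrame:
    """Exponential survival under proportional hazards with planted effects.

    hazard_i = baseline_hazard * exp(sum_g coef_g * expr_g,i); censoring is
    independent exponential at ``censor_rate`` (0 = none).  Expression is
    mean-centred per gene before entering the hazard by default, which fixes
    the marginal event-time scale without changing the hazard ratios.
    Subtype and stage labels are assigned at random for downstream subset
    analyses and carry no planted signal.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    missing = [g for g in risk_genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"risk genes absent from expression: {missing[:5]}")
    rng = np.random.default_rng(seed)
    lp = np.zeros(len(samples))
    for g, coef in sorted(risk_genes.items()):
        x = expr.values.loc[g, samples].to_numpy(dtype=float)
        if center:
            x = x - x.mean()
        lp += coef * x
    hazards = baseline_hazard * np.exp(lp)
    event_times = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        censor_times = rng.exponential(1.0 / censor_rate, size=len(samples))
    else:
        censor_times = np.full(len(samples), np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    subtype = rng.choice(SUBTYPES, size=len(samples))
    stage = rng.choice(STAGES, size=len(samples), p=[0.3, 0.35, 0.25, 0.1])
    tissue = ["tumor"] * len(samples)
    if expr.sample_meta is not None:
        tissue = [expr.sample_meta.loc[s, "tissue"] if s in expr.sample_meta.index else "tumor"
                  for s in samples]
    df = pd.DataFrame(
        {
            "sample_id": samples,
            "time": time,
            "event": event,
            "subtype": subtype,
            "stage": stage,
            "tissue": tissue,
        }
    )
    return df.set_index("sample_id", drop=False)


def generate_network(
    n_lncrna: int = 200,
    n_tf: int = 100,
    n_cerna_edges: int = 500,
    n_ppi_edges: int = 150,
    skew: float = 1.2,
    seed: int = 0,
):
    """Typed mixed network with a right-skewed degree distribution.

    ceRNA edges are sampled between lncRNAs and TFs with endpoint
    probabilities proportional to rank^-skew, producing hub-dominated,
    roughly power-law degrees; PPI edges are sampled among TFs the same way.
    Simple graph (no duplicates/self-loops), deterministic per seed.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    lncs = _ids("LNC", n_lncrna)
    tfs = _ids("TF", n_tf)

    def rank_probs(n: int) -> np.ndarray:
        w = (np.arange(1, n + 1)) ** (-skew)
        return w / w.sum()

    net = nx.Graph()
    net.add_nodes_from(lncs, kind="lncRNA")
    net.add_nodes_from(tfs, kind="TF")
    p_l, p_t = rank_probs(n_lncrna), rank_probs(n_tf)
    guard = 0
    n_cerna = 0
    while n_cerna < n_cerna_edges:
        u = lncs[rng.choice(n_lncrna, p=p_l)]
        v = tfs[rng.choice(n_tf, p=p_t)]
        if not net.has_edge(u, v):
            net.add_edge(u, v, etype="ceRNA")
            n_cerna += 1
        guard += 1
        if guard > 100 * n_cerna_edges:
            raise RuntimeError("could not place requested ceRNA edges")
    guard = 0
    n_ppi = 0
    while n_ppi < n_ppi_edges:
        a, b = (tfs[i] for i in rng.choice(n_tf, size=2, p=p_t))
        if a != b and not net.has_edge(a, b):
            net.add_edge(a, b, etype="PPI")
            n_ppi += 1
        guard += 1
        if guard > 100 * n_ppi_edges:
            raise RuntimeError("could not place requested PPI edges")
    return net


def generate_regions_with_motifs(
    n_regions: int,
    region_len: int,
    motifs: list[PWM],
    planted_sites: list[tuple[int, str, int, str]],
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame, PlantedTruth]:
    """i.i.d.-background DNA regions carrying planted motif consensus sites.

    ``planted_sites`` rows are (region index, motif_id, position, strand);
    the motif's per-column argmax consensus is written at the position
    (reverse-complemented for '-').  Overlapping planted sites within a
    region are an error, as is a site extending past the region end.
    Background base probabilities: G = C = gc/2, A = T = (1-gc)/2.
    """
    rng = np.random.default_rng(seed)
    by_id = {m.motif_id: m for m in motifs}
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: dict[str, list[str]] = {}
    region_ids = [f"region{i + 1:03d}" for i in range(n_regions)]
    for rid in region_ids:
        seqs[rid] = list("".join(rng.choice(list("ACGT"), size=region_len, p=probs)))
    occupied: dict[int, list[tuple[int, int]]] = {}
    truth_sites: list[tuple[str, str, int, str]] = []
    for ridx, motif_id, pos, strand in planted_sites:
        pwm = by_id[motif_id]
        if pos + pwm.width > region_len:
            raise ValueError(
                f"site at {pos} of motif {motif_id} (w={pwm.width}) exceeds region_len={region_len}"
            )
        for s, e in occupied.get(ridx, []):
            if pos < e and s < pos + pwm.width:
                raise ValueError(f"overlapping planted sites in region index {ridx}")
        occupied.setdefault(ridx, []).append((pos, pos + pwm.width))
        site = pwm.consensus()
        if strand == "-":
            site = reverse_complement(site)
        rid = region_ids[ridx]
        seqs[rid][pos : pos + pwm.width] = list(site)
        truth_sites.append((rid, motif_id, pos, strand))
    sequences = {rid: "".join(chars) for rid, chars in seqs.items()}
    regions = pd.DataFrame(
        {
            "region_id": region_ids,
            "chrom": region_ids,
            "start": 0,
            "end": region_len,
            "strand": "+",
            "kind": "promoter",
            "linked_gene_id": region_ids,
        }
    )
    truth = PlantedTruth(planted_motif_sites=truth_sites)
    return sequences, regions, truth
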