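"""Readers and writers for every external representation the pipeline touches.

Tabular files are tab-separated with optional ``#``-prefixed comment lines.
Genomic intervals are 0-based half-open internally and in BED output; 1-based
inputs must be converted at the boundary by the caller.  Readers reject
malformed input with an error naming the offending line or cell rather than
coercing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TARGET_KINDS = ("lncRNA", "TF", "mRNA")
EDGE_TYPES = ("ceRNA", "PPI")
MISSING_TOKENS = {"", "NA", "NaN", "nan", "null", "NULL"}


class FormatError(ValueError):
    """Malformed input file; message carries the line or cell location."""


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------


@dataclass
class InteractionTable:
    """Bipartite miRNA -> target edge list with a single target kind.

    ``df`` has columns ``source_id``, ``target_id``, ``target_kind`` and holds
    no duplicate (source, target) rows; ``n_duplicates_dropped`` reports how
    many were removed at load time.
    """

    df: pd.DataFrame
    target_kind: str
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        if self.target_kind not in TARGET_KINDS:
            raise ValueError(f"unknown target kind {self.target_kind!r}")

    @property
    def sources(self) -> set[str]:
        return set(self.df["source_id"])

    @property
    def targets(self) -> set[str]:
        return set(self.df["target_id"])

    def sources_by_target(self) -> dict[str, frozenset[str]]:
        """Map each target id to the frozenset of miRNAs hitting it."""
        out: dict[str, frozenset[str]] = {}
        for tgt, grp in self.df.groupby("target_id", sort=True):
            out[str(tgt)] = frozenset(grp["source_id"])
        return out

    def __len__(self) -> int:
        return len(self.df)


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_interaction_table(path, target_kind: str, header: bool = False) -> InteractionTable:
    """Load a two-column (source_id, target_id) TSV edge list.

    Duplicate rows are dropped (first kept) and counted; empty ids are an
    error naming the line.
    """
    rows: list[tuple[str, str]] = []
    first = True
    for lineno, line in _data_lines(path):
        if first and header:
            first = False
            continue
        first = False
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected >=2 tab-separated fields")
        src, tgt = fields[0].strip(), fields[1].strip()
        if not src or not tgt:
            raise FormatError(f"{path}: line {lineno}: empty source or target id")
        rows.append((src, tgt))
    if not rows:
        raise FormatError(f"{path}: no interaction rows found")
    df = pd.DataFrame(rows, columns=["source_id", "target_id"])
    n_before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    df["target_kind"] = target_kind
    return InteractionTable(df=df, target_kind=target_kind, n_duplicates_dropped=n_before - len(df))


def write_interaction_table(table: InteractionTable, path) -> None:
    table.df[["source_id", "target_id"]].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with optional sample annotations.

    Missing values are NaN and stay missing: downstream correlations use
    pairwise-complete observations, never zero-filled ones.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def vector(self, gene: str) -> pd.Series:
        return self.values.loc[gene]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column, one column per sample.

    Duplicate gene ids are rejected; a non-numeric, non-missing cell raises
    with its (gene, sample) coordinates.  Missing tokens (empty, NA, NaN,
    null) are stored as NaN.
    """
    lines = list(_data_lines(path))
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    header = lines[0][1].split("\t")
    samples = [s.strip() for s in header[1:]]
    if not samples:
        raise FormatError(f"{path}: header has no sample columns")
    genes: list[str] = []
    data: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise FormatError(
                f"{path}: line {lineno}: expected {len(samples) + 1} fields, got {len(fields)}"
            )
        gene = fields[0].strip()
        if gene in genes:
            raise FormatError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
        row: list[float] = []
        for sample, cell in zip(samples, fields[1:]):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                row.append(math.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric value {cell!r} "
                    f"at gene {gene!r}, sample {sample!r}"
                ) from None
        genes.append(gene)
        data.append(row)
    if not genes:
        raise FormatError(f"{path}: no gene rows found")
    values = pd.DataFrame(data, index=genes, columns=samples, dtype=float)
    return ExpressionMatrix(values=values)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

SUBTYPES = ("LumA", "LumB", "Her2", "Basal", "Normal-like")
STAGES = ("I", "II", "III", "IV")

CLINICAL_COLUMNS = ["sample_id", "time", "event", "subtype", "stage", "tissue"]


def read_clinical_table(path) -> pd.DataFrame:
    """Read per-sample survival/annotation TSV into a validated DataFrame.

    Required columns: sample_id, time (days, >= 0), event (0/1).  Optional:
    subtype, stage, tissue; unknown values there must be 'NA'.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    if (df["time"] < 0).any():
        raise FormatError(f"{path}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"{path}: event must be 0 or 1")
    for col, allowed in (("subtype", SUBTYPES), ("stage", STAGES), ("tissue", ("tumor", "normal"))):
        if col in df.columns:
            bad = ~(df[col].isin(allowed) | df[col].isin(["NA"]) | df[col].isna())
            if bad.any():
                raise FormatError(f"{path}: invalid {col} value {df.loc[bad, col].iloc[0]!r}")
    return df.set_index("sample_id", drop=False)


def write_clinical_table(clinical: pd.DataFrame, path) -> None:
    cols = [c for c in CLINICAL_COLUMNS if c in clinical.columns]
    clinical[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# gene annotation (BED-like)
# ---------------------------------------------------------------------------


def read_gene_annotation(path) -> pd.DataFrame:
    """Read BED6 (chrom, start, end, gene_id, score, strand), 0-based half-open."""
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}: line {lineno}: BED6 needs 6 fields")
        chrom, start, end, gene_id, _score, strand = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
        if start_i >= end_i:
            raise FormatError(f"{path}: line {lineno}: start must be < end")
        if strand not in ("+", "-"):
            raise FormatError(f"{path}: line {lineno}: strand must be + or -")
        rows.append((gene_id, chrom, start_i, end_i, strand))
    if not rows:
        raise FormatError(f"{path}: empty annotation")
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write a RegionSet-style frame as BED6 (name = region_id)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            name = r.get("region_id", r.get("gene_id", "."))
            strand = r.get("strand", "+")
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------


@dataclass
class PWM:
    """Position probability matrix over (A, C, G, T) with a background model."""

    motif_id: str
    matrix: np.ndarray  # (width, 4) row-stochastic
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if (self.matrix < 0).any():
            raise ValueError("PWM entries must be non-negative")
        if np.abs(self.matrix.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("PWM rows must sum to 1 within 1e-6")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


def read_motifs_meme(path) -> list[PWM]:
    """Parse MEME minimal format into PWMs.

    Rows off by < 1e-3 from summing to 1 are renormalised silently; larger
    deviations are an error.  Only the ACGT alphabet is accepted.
    """
    background = np.full(4, 0.25)
    motifs: list[PWM] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip() if "=" in line else line.split()[-1]
            if alpha.upper() != "ACGT":
                raise FormatError(f"{path}: alphabet {alpha!r} is not ACGT")
        elif line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {motif_id} has no probability matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {motif_id} has no probability matrix")
            header = lines[i]
            width = None
            tokens = header.replace("=", " = ").split()
            for j, tok in enumerate(tokens):
                if tok == "w" and j + 2 < len(tokens):
                    width = int(tokens[j + 2])
            if width is None:
                raise FormatError(f"{path}: motif {motif_id}: missing 'w=' in matrix header")
            rows = []
            for k in range(width):
                i += 1
                vals = [float(v) for v in lines[i].split()]
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}: motif {motif_id}: row {k + 1} has {len(vals)} columns, expected 4"
                    )
                total = sum(vals)
                if abs(total - 1.0) >= 1e-3:
                    raise FormatError(
                        f"{path}: motif {motif_id}: row {k + 1} sums to {total:.4f}, "
                        "outside the 1e-3 tolerance"
                    )
                rows.append([v / total for v in vals])
            motifs.append(PWM(motif_id=motif_id, matrix=np.array(rows), background=background))
        i += 1
    if not motifs:
        raise FormatError(f"{path}: no MOTIF blocks found")
    return motifs


def write_motifs_meme(motifs: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# network round-trip (node table + edge table TSVs)
# ---------------------------------------------------------------------------

_EDGE_ATTRS = ("m_l", "m_t", "k", "N", "p", "pcc")


def write_network(net: nx.Graph, base_path) -> None:
    """Write ``<base>.nodes.tsv`` and ``<base>.edges.tsv``.

    Node kinds, edge types and numeric ceRNA evidence round-trip exactly
    (floats are written with 17 significant digits).
    """
    base = str(base_path)
    with open(base + ".nodes.tsv", "w") as fh:
        fh.write("node_id\tkind\n")
        for node in sorted(net.nodes):
            fh.write(f"{node}\t{net.nodes[node].get('kind', 'NA')}\n")
    with open(base + ".edges.tsv", "w") as fh:
        fh.write("u\tv\tetype\t" + "\t".join(_EDGE_ATTRS) + "\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            d = net.edges[u, v]
            vals = []
            for a in _EDGE_ATTRS:
                x = d.get(a)
                if x is None:
                    vals.append("")
                elif isinstance(x, (int, np.integer)):
                    vals.append(str(int(x)))
                else:
                    vals.append(f"{float(x):.17g}")
            fh.write(f"{u}\t{v}\t{d.get('etype', 'NA')}\t" + "\t".join(vals) + "\n")


def read_network(base_path) -> nx.Graph:
    base = str(base_path)
    net = nx.Graph()
    with open(base + ".nodes.tsv") as fh:
        header = fh.readline()
        if not header.startswith("node_id"):
            raise FormatError(f"{base}.nodes.tsv: missing node_id header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            node, kind = line.split("\t")
            net.add_node(node, kind=kind)
    with open(base + ".edges.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            u, v, etype = fields[0], fields[1], fields[2]
            if etype not in EDGE_TYPES:
                raise FormatError(f"{base}.edges.tsv: line {lineno}: unknown edge type {etype!r}")
            attrs: dict[str, float | int] = {"etype": etype}
            for name, raw in zip(_EDGE_ATTRS, fields[3:]):
                if raw == "":
                    continue
                attrs[name] = int(raw) if name in ("m_l", "m_t", "k", "N") else float(raw)
            net.add_edge(u, v, **attrs)
    return net


def networks_equal(a: nx.Graph, b: nx.Graph) -> bool:
    """Node-for-node, edge-for-edge equality including attributes."""
    if set(a.nodes) != set(b.nodes) or set(map(frozenset, a.edges)) != set(map(frozenset, b.edges)):
        return False
    for n in a.nodes:
        if a.nodes[n] != b.nodes[n]:
            return False
    for u, v in a.edges:
        da, db = dict(a.edges[u, v]), dict(b.edges[u, v])
        if set(da) != set(db):
            return False
        for key in da:
            xa, xb = da[key], db[key]
            if isinstance(xa, float) or isinstance(xb, float):
                if not (np.isnan(xa) and np.isnan(xb)) and xa != xb:
                    return False
            elif xa != xb:
                return False
    return True
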