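import networkx as nx
import numpy as np
import pytest

from cernaforge.io import PWM


@pytest.fixture
def toy_network() -> nx.Graph:
    """Small mixed ceRNA/PPI network with typed nodes."""
    g = nx.Graph()
    for lnc in ("L1", "L2", "L3"):
        g.add_node(lnc, kind="lncRNA")
    for tf in ("T1", "T2", "T3"):
        g.add_node(tf, kind="TF")
    g.add_edge("L1", "T1", etype="ceRNA", m_l=5, m_t=4, k=3, N=10, p=0.01, pcc=0.7)
    g.add_edge("L2", "T1", etype="ceRNA", m_l=6, m_t=4, k=2, N=10, p=0.04, pcc=0.65)
    g.add_edge("L3", "T2", etype="ceRNA", m_l=3, m_t=5, k=2, N=10, p=0.03, pcc=0.8)
    g.add_edge("T1", "T2", etype="PPI")
    g.add_edge("T2", "T3", etype="PPI")
    return g


@pytest.fixture
def sharp_pwm() -> PWM:
    """Width-8 motif with 0.97 consensus probability per column."""
    row = [0.01, 0.01, 0.01, 0.97]
    mat = np.array([np.roll(row, i % 4) for i in range(8)], dtype=float)
    return PWM(motif_id="SHARP", matrix=mat)


def peel_core_number(adj: dict) -> dict:
    """Independent k-core oracle: iterative minimum-degree peeling.

    core(v) = the largest removal-time degree seen up to v's removal.
    """
    adj = {v: set(ns) for v, ns in adj.items()}
    core = {}
    kmax = 0
    while adj:
        v = min(adj, key=lambda u: (len(adj[u]), str(u)))
        kmax = max(kmax, len(adj[v]))
        core[v] = kmax
        for u in adj[v]:
            adj[u].discard(v)
        del adj[v]
    return core
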