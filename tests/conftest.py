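import networkx as nx
import numpy as np
import pandas as pd
import pytest


@pytest.fixture(scope="session")
def small_bundle():
    """One coherent small synthetic dataset shared across read-only tests."""
    from dmegnet import make_expression, make_methylation, make_survival

    beta, ann, meth_truth = make_methylation(
        n_genes=400, probes_per_gene_region=3, n_per_group=30, delta=0.4, seed=11
    )
    expr, expr_truth = make_expression(n_genes=400, n_per_group=30, lfc=1.5, seed=12)
    surv, surv_truth = make_survival(
        expr, {"G00000": 1.0, "G00001": -0.8}, baseline_rate=0.1, censor_rate=0.03, seed=13
    )
    return {
        "beta": beta,
        "annotation": ann,
        "meth_truth": meth_truth,
        "expr": expr,
        "expr_truth": expr_truth,
        "surv": surv,
        "surv_truth": surv_truth,
        "group_a": [c for c in beta.columns if c.startswith("A")],
        "group_b": [c for c in beta.columns if c.startswith("B")],
    }


@pytest.fixture(scope="session")
def toy_graph():
    """Small deterministic graph for hand-checkable distance computations."""
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("b", "f"), ("f", "g"), ("a", "h")]
    )
    return g


def brute_force_bh(pvals):
    """Independent step-up oracle: adj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pairwise_auc(scores, positive_mask):
    """Exhaustive pair-counting AUC with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    pos = s[np.asarray(positive_mask, dtype=bool)]
    neg = s[~np.asarray(positive_mask, dtype=bool)]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))
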