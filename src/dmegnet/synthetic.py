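"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be generated here: probe-level
methylation beta matrices with group-wise shifts planted in specific gene
regions, log2 expression matrices with planted fold-changes, a scale-free
protein-interaction network with drugs whose targets cluster near a disease
gene set, and survival times whose log-hazard is a known linear combination
of gene expression. A single integer seed fully determines every output, so
downstream calls are reproducible and testable without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as _io

__all__ = [
    "REGIONS",
    "SyntheticTruth",
    "make_methylation",
    "make_expression",
    "make_network_and_drugs",
    "make_survival",
    "write_bundle",
]

#: Gene regions the methylation generator plants signal in (the three the
#: downstream integration uses).
REGIONS: tuple[str, ...] = ("Body", "TSS200", "TSS1500")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generator call.

    Planted sets are disjoint from the background by construction and every
    planted gene exists in the emitted matrices.
    """

    seed: int
    planted_dmg: set[tuple[str, str, str]] = field(default_factory=set)  # (gene, region, hyper|hypo)
    planted_deg: set[tuple[str, str]] = field(default_factory=set)  # (gene, up|down)
    planted_dmeg_groups: dict[str, str] = field(default_factory=dict)
    proximal_drugs: set[str] = field(default_factory=set)
    disease_genes: set[str] = field(default_factory=set)
    prognostic_coefficients: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_dmg": sorted(self.planted_dmg),
            "planted_deg": sorted(self.planted_deg),
            "planted_dmeg_groups": self.planted_dmeg_groups,
            "proximal_drugs": sorted(self.proximal_drugs),
            "disease_genes": sorted(self.disease_genes),
            "prognostic_coefficients": self.prognostic_coefficients,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _sample_names(n_per_group: int) -> list[str]:
    return [f"A{i:03d}" for i in range(n_per_group)] + [f"B{i:03d}" for i in range(n_per_group)]


def make_methylation(
    n_genes: int = 2000,
    probes_per_gene_region: int = 3,
    n_per_group: int = 30,
    delta: float = 0.4,
    frac_hyper: float = 0.0125,
    frac_hypo: float = 0.0125,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a probe-level beta matrix with planted group-B shifts.

    Background probes draw iid Beta(2, 2) values (bounded, unimodal,
    mid-range). A fraction of genes is planted as hypermethylated
    (+``delta`` in group B) or hypomethylated (−``delta``) within one
    designated region only; their baseline is skewed low (Beta(2, 6)) before
    a hyper shift and high (Beta(6, 2)) before a hypo shift so the shift is
    not truncated by the [0, 1] clip. Samples A* form group A, B* group B.

    Returns (beta matrix [probe x sample], probe annotation, truth).
    """
    if not 0 < delta < 1:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    if frac_hyper + frac_hypo > 1:
        raise ValueError("frac_hyper + frac_hypo must be <= 1")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    samples = _sample_names(n_per_group)
    group_b = np.arange(n_per_group, 2 * n_per_group)

    n_hyper = round(frac_hyper * n_genes)
    n_hypo = round(frac_hypo * n_genes)
    planted_idx = rng.choice(n_genes, size=n_hyper + n_hypo, replace=False)
    hyper_idx = set(planted_idx[:n_hyper].tolist())
    hypo_idx = set(planted_idx[n_hyper:].tolist())
    # planted region cycles deterministically through the vocabulary
    region_of = {g: REGIONS[k % len(REGIONS)] for k, g in enumerate(sorted(hyper_idx | hypo_idx))}

    rows = []
    probe_ids: list[str] = []
    ann_rows: list[tuple[str, str, str]] = []
    truth = SyntheticTruth(seed=seed)
    probe_no = 0
    for gi, gene in enumerate(genes):
        for region in REGIONS:
            planted_dir = None
            if gi in hyper_idx and region_of[gi] == region:
                planted_dir = "hyper"
            elif gi in hypo_idx and region_of[gi] == region:
                planted_dir = "hypo"
            for _ in range(probes_per_gene_region):
                if planted_dir == "hyper":
                    base = rng.beta(2, 6, size=2 * n_per_group)
                    base[group_b] += delta
                elif planted_dir == "hypo":
                    base = rng.beta(6, 2, size=2 * n_per_group)
                    base[group_b] -= delta
                else:
                    base = rng.beta(2, 2, size=2 * n_per_group)
                rows.append(np.clip(base, 0.0, 1.0))
                probe_ids.append(f"cg{probe_no:07d}")
                ann_rows.append((probe_ids[-1], gene, region))
                probe_no += 1
            if planted_dir is not None:
                truth.planted_dmg.add((gene, region, planted_dir))

    beta = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=samples)
    ann = pd.DataFrame(ann_rows, columns=["probe", "gene", "region"])
    return beta, ann, truth


def make_expression(
    n_genes: int = 2000,
    n_per_group: int = 30,
    lfc: float = 1.5,
    planted: dict[str, str] | None = None,
    n_up: int = 12,
    n_down: int = 13,
    sd: float = 1.0,
    seed: int = 0,
    marker_gene: str = "PD1",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a log2 expression matrix with planted fold-changes.

    Background genes share a group-independent mean (drawn once per gene
    from N(6, 1.5)); planted genes are shifted by +/-``lfc`` in group B.
    ``planted`` maps gene name -> "up"/"down"; when None, ``n_up``/``n_down``
    genes are chosen at random. A designated marker gene (default "PD1") is
    appended whose group-B values straddle the group-A mean, so
    reference-mean stratification splits group B roughly in half.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    samples = _sample_names(n_per_group)
    gene_pos = {g: i for i, g in enumerate(genes)}

    if planted is None:
        if n_up + n_down > n_genes:
            raise ValueError("n_up + n_down exceeds n_genes")
        idx = rng.choice(n_genes, size=n_up + n_down, replace=False)
        planted = {genes[i]: "up" for i in idx[:n_up]}
        planted.update({genes[i]: "down" for i in idx[n_up:]})
    else:
        missing = [g for g in planted if g not in gene_pos]
        if missing:
            raise ValueError(f"planted genes not in matrix: {missing}")

    base_mean = rng.normal(6.0, 1.5, size=n_genes)
    values = base_mean[:, None] + rng.normal(0.0, sd, size=(n_genes, 2 * n_per_group))
    for gene, direction in planted.items():
        shift = lfc if direction == "up" else -lfc
        values[gene_pos[gene], n_per_group:] += shift

    # marker gene: group-A values tight around 5, group-B values straddling
    # the group-A mean so both marker classes are populated
    marker = np.concatenate(
        [rng.normal(5.0, 0.3, size=n_per_group), 5.0 + rng.normal(0.0, 1.5, size=n_per_group)]
    )
    expr = pd.DataFrame(
        np.vstack([values, marker]), index=genes + [marker_gene], columns=samples
    )
    truth = SyntheticTruth(seed=seed, planted_deg={(g, d) for g, d in planted.items()})
    return expr, truth


def make_network_and_drugs(
    n_nodes: int = 500,
    mean_degree: float = 6.0,
    n_disease: int = 25,
    n_proximal_drugs: int = 1,
    n_decoy_drugs: int = 50,
    targets_per_drug: int = 8,
    seed: int = 0,
) -> tuple[nx.Graph, set[str], dict[str, set[str]], SyntheticTruth]:
    """Generate a scale-free interaction network, a disease set, and drugs.

    The graph grows by preferential attachment (degree heterogeneity matters
    for the degree-based target weight) and is reduced to its giant
    component. Proximal drugs draw their targets from the disease set and
    its direct neighbours; decoy drugs draw targets uniformly from all
    nodes, so a proximity screen should separate the two.
    """
    if n_nodes < 50:
        raise ValueError("need at least 50 nodes")
    if targets_per_drug > n_nodes:
        raise ValueError("targets_per_drug exceeds node count")
    rng = np.random.default_rng(seed)
    m = max(1, round(mean_degree / 2))
    graph = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    giant = max(nx.connected_components(graph), key=len)
    graph = graph.subgraph(giant).copy()
    mapping = {old: f"G{old:05d}" for old in graph.nodes}
    graph = nx.relabel_nodes(graph, mapping)
    nodes = sorted(graph.nodes)

    disease = set(rng.choice(nodes, size=n_disease, replace=False).tolist())
    disease_sorted = sorted(disease)
    neighbours = sorted({v for s in disease for v in graph.neighbors(s)} - disease)

    drugs: dict[str, set[str]] = {}
    truth = SyntheticTruth(seed=seed, disease_genes=set(disease))
    for i in range(n_proximal_drugs):
        name = f"drug_prox{i:03d}"
        # three quarters of the targets hit disease genes directly, the rest
        # their direct neighbours: the target set sits tightly on the module
        n_core = min(-(-3 * targets_per_drug // 4), len(disease_sorted))
        n_ring = min(targets_per_drug - n_core, len(neighbours))
        targets = set(rng.choice(disease_sorted, size=n_core, replace=False).tolist())
        targets |= set(rng.choice(neighbours, size=n_ring, replace=False).tolist())
        drugs[name] = targets
        truth.proximal_drugs.add(name)
    for i in range(n_decoy_drugs):
        name = f"drug_decoy{i:03d}"
        drugs[name] = set(rng.choice(nodes, size=targets_per_drug, replace=False).tolist())
    return graph, disease, drugs, truth


def make_survival(
    expr: pd.DataFrame,
    coefficients: dict[str, float],
    baseline_rate: float = 0.1,
    censor_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate exponential survival times from a linear log-hazard.

    Per-sample hazard is ``baseline_rate * exp(lp)`` where lp is the
    per-gene-centred linear predictor sum(coef_g * (x_g - mean_g)); centring
    keeps the hazard scale set by ``baseline_rate``. Censoring times are
    independent Exponential(``censor_rate``); ``censor_rate=0`` disables
    censoring. Returns a (sample, time, event) table.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    missing = [g for g in coefficients if g not in expr.index]
    if missing:
        raise ValueError(f"model genes absent from expression matrix: {missing}")
    rng = np.random.default_rng(seed)
    n = expr.shape[1]
    lp = np.zeros(n)
    for gene, coef in coefficients.items():
        x = expr.loc[gene].to_numpy(dtype=float)
        lp += coef * (x - x.mean())
    hazard = baseline_rate * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    surv = pd.DataFrame({"time": observed, "event": event}, index=expr.columns)
    surv.index.name = "sample"
    truth = SyntheticTruth(seed=seed, prognostic_coefficients=dict(coefficients))
    return surv, truth


def write_bundle(outdir: str | Path, seed: int = 0, **kwargs) -> None:
    """Generate one coherent input bundle and write every artifact as TSV/JSON.

    Emits: beta.tsv, probe_annotation.tsv, expression.tsv, edges.tsv,
    drug_targets.tsv, disease_genes.txt, survival.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    beta, ann, t_meth = make_methylation(seed=seed, **kwargs.get("methylation", {}))
    expr, t_expr = make_expression(seed=seed + 1, **kwargs.get("expression", {}))
    graph, disease, drugs, t_net = make_network_and_drugs(seed=seed + 2, **kwargs.get("network", {}))
    coefs = kwargs.get("coefficients", {"G00000": 1.0, "G00001": -0.7})
    surv, t_surv = make_survival(expr, coefs, seed=seed + 3, **kwargs.get("survival", {}))

    _io.write_matrix(beta, outdir / "beta.tsv", index_label="probe")
    _io.write_probe_annotation(ann, outdir / "probe_annotation.tsv")
    _io.write_matrix(expr, outdir / "expression.tsv", index_label="gene")
    _io.write_edge_list(graph, outdir / "edges.tsv")
    _io.write_drug_targets(drugs, outdir / "drug_targets.tsv")
    (outdir / "disease_genes.txt").write_text("\n".join(sorted(disease)) + "\n")
    _io.write_survival(surv, outdir / "survival.tsv")
    truth = SyntheticTruth(
        seed=seed,
        planted_dmg=t_meth.planted_dmg,
        planted_deg=t_expr.planted_deg,
        proximal_drugs=t_net.proximal_drugs,
        disease_genes=t_net.disease_genes,
        prognostic_coefficients=t_surv.prognostic_coefficients,
    )
    truth.to_json(outdir / "truth.json")
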