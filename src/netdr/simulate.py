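"""Synthetic FIN, disease cohort and drug library with a planted signal.

The generator emulates the statistical shape of the method's real inputs:
a sparse weighted interaction network with a heavily right-skewed weight
histogram (Beta-distributed weights, most mass near the 0.1 pruning floor),
a network-localized disease module whose genes pass the FDR/fold-change DEG
filter, and a drug library in which one "reversal" drug anti-correlates
with the disease z-scores on the module genes while the remaining decoys
place equally sized DEG sets uniformly at random.

The reversal drug perturbs a large fraction (not all) of the module genes
plus a few off-module genes: a drug whose DEG set coincided exactly with
the disease seeds would make DAPN and DGN identical, the AUC reference set
would cover the whole ranked list, and the similarity statistic would be
undefined.  Partial overlap keeps the planted signal strong while the
statistic stays well-posed.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from netdr.network import WeightedNetwork, GeneModule, prune_network, build_module
from netdr.signatures import (
    DrugSignature,
    DiseaseSignature,
    DiseaseRecord,
    write_drug_signature,
    write_disease_table,
)
from netdr.network import write_network


class SimulationError(RuntimeError):
    pass


@dataclass
class SimSpec:
    """Generator settings; defaults are the study conditions of the
    planted-signal benchmark."""

    n_genes: int = 500
    edge_model: str = "erdos_renyi"  # or "barabasi_albert"
    mean_degree: float = 10.0
    weight_beta: tuple[float, float] = (0.7, 5.0)
    weight_floor: float = 0.1
    n_disease_seeds: int = 40
    n_drugs: int = 25
    reversal_strength: float = 0.9
    deg_z_scale: float = 1.5
    disease_z_floor: float = 3.0  # minimum |z| of a disease DEG (DE z-statistic scale)
    module_extra_degree: float = 4.0  # added intra-module degree (functional-module density)
    module_coverage: float = 0.8  # fraction of module genes the reversal drug perturbs
    drug_deg_factor: float = 1.5  # drug DEG-set size as a multiple of the disease module size
    rng_seed: int = 0

    def __post_init__(self):
        if not self.n_disease_seeds < self.n_genes:
            raise ValueError("n_disease_seeds must be < n_genes")
        if self.mean_degree < 2:
            raise ValueError("mean_degree must be >= 2")
        if not 0.0 <= self.reversal_strength <= 1.0:
            raise ValueError("reversal_strength must be in [0, 1]")
        if self.edge_model not in ("erdos_renyi", "barabasi_albert"):
            raise ValueError(f"unknown edge_model {self.edge_model!r}")


@dataclass
class SimStudy:
    """One simulated study: inputs plus the planted ground truth."""

    network: WeightedNetwork
    disease: DiseaseSignature
    drugs: list[DrugSignature]
    reversal_drug_id: str
    module_genes: frozenset[str]
    spec: SimSpec


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_network(spec: SimSpec, rng: np.random.Generator | None = None) -> WeightedNetwork:
    """Random weighted network, pruned at the standard 0.1 weight floor.

    Edges come from an Erdős–Rényi or Barabási–Albert model at the requested
    mean degree; weights are Beta(a, b) draws.  Resamples (up to 100 times)
    until the largest connected component holds ≥ 90% of the surviving
    nodes, so the disease module can be planted in one component.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    names = _gene_names(spec.n_genes)
    a, b = spec.weight_beta
    for _ in range(100):
        seed = int(rng.integers(0, 2**31 - 1))
        if spec.edge_model == "erdos_renyi":
            g = nx.gnp_random_graph(spec.n_genes, spec.mean_degree / (spec.n_genes - 1), seed=seed)
        else:
            g = nx.barabasi_albert_graph(spec.n_genes, max(1, round(spec.mean_degree / 2)), seed=seed)
        weights = rng.beta(a, b, size=g.number_of_edges())
        weights = np.clip(weights, 1e-9, 1.0)
        wg = nx.Graph()
        for (u, v), w in zip(g.edges(), weights):
            wg.add_edge(names[u], names[v], weight=float(w))
        try:
            net = prune_network(WeightedNetwork(wg), spec.weight_floor)
        except Exception:
            continue  # all weights below the floor; resample
        components = list(nx.connected_components(net.graph))
        largest = max(components, key=len)
        if len(largest) >= 0.9 * net.n_nodes and len(largest) > spec.n_disease_seeds:
            return net
    raise SimulationError(
        "could not generate a network whose largest component covers 90% of nodes "
        "in 100 attempts; increase mean_degree or adjust the weight distribution"
    )


def _bfs_module(net: WeightedNetwork, start: str, size: int, rng: np.random.Generator) -> list[str]:
    """Connected gene set grown by BFS from ``start``; neighbor order is
    shuffled so different seeds give different modules."""
    seen = {start}
    order = [start]
    queue = deque([start])
    while queue and len(order) < size:
        node = queue.popleft()
        neigh = sorted(net.neighbors(node))
        rng.shuffle(neigh)
        for nb in neigh:
            if nb not in seen:
                seen.add(nb)
                order.append(nb)
                queue.append(nb)
                if len(order) >= size:
                    break
    return order[:size]


def _densify_module(
    net: WeightedNetwork, module: list[str], spec: SimSpec, rng: np.random.Generator
) -> None:
    """Add random intra-module edges (in place) until the module's internal
    degree rises by ``module_extra_degree`` on average.

    A disease module is a functional unit, so its genes interact more
    densely than the network background; the extra edges carry weights
    drawn from the same Beta distribution, resampled to survive the
    pruning floor.
    """
    n_extra = round(spec.module_extra_degree * len(module) / 2)
    g = net.graph
    a, b = spec.weight_beta
    candidates = [
        (u, v)
        for i, u in enumerate(module)
        for v in module[i + 1:]
        if not g.has_edge(u, v)
    ]
    if not candidates or n_extra == 0:
        return
    chosen = rng.choice(len(candidates), size=min(n_extra, len(candidates)), replace=False)
    for ci in chosen:
        u, v = candidates[ci]
        w = 0.0
        while w < spec.weight_floor:
            w = float(rng.beta(a, b))
        g.add_edge(u, v, weight=w)


def simulate_disease(
    spec: SimSpec,
    net: WeightedNetwork,
    rng: np.random.Generator | None = None,
) -> DiseaseSignature:
    """Plant a connected, densified disease module and dress it with DEG
    statistics.

    The module is grown by BFS inside the largest component and receives
    extra intra-module edges (added to ``net`` in place) so it is denser
    than the network background, as functional disease modules are.  Module
    genes emulate a coherently up-regulated disease program: z is a
    positive DE z-statistic (``disease_z_floor`` + scaled half-normal),
    FDR ~ U(0, 0.009) and log2FC ≥ 1, so the standard FDR < 0.01 / |FC| ≥ 2
    filter recovers exactly the planted set; all other network genes get
    sub-threshold background values.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    components = sorted(nx.connected_components(net.graph), key=len, reverse=True)
    giant = sorted(components[0])
    if len(giant) < spec.n_disease_seeds:
        raise SimulationError("largest component smaller than the requested disease module")
    start = giant[int(rng.integers(0, len(giant)))]
    module_order = _bfs_module(net, start, spec.n_disease_seeds, rng)
    _densify_module(net, module_order, spec, rng)
    module = set(module_order)
    records: dict[str, DiseaseRecord] = {}
    for gene in sorted(net.nodes):
        if gene in module:
            z = float(spec.disease_z_floor + spec.deg_z_scale * abs(rng.normal()))
            log2fc = 1.0 + abs(rng.normal(0.0, 0.5))
            fdr = float(rng.uniform(0.0, 0.009))
        else:
            z = float(np.clip(rng.normal(0.0, 0.4), -0.99, 0.99))
            log2fc = float(rng.uniform(-0.9, 0.9))
            fdr = float(rng.uniform(0.02, 1.0))
        records[gene] = DiseaseRecord(log2fc=log2fc, fdr=fdr, z=z)
    return DiseaseSignature(cohort_id=f"sim-cohort-{spec.rng_seed}", records=records)


def _supra_threshold(magnitude: float, margin: float = 0.05) -> float:
    """Push |z| above the DEG threshold of 1 while preserving sign."""
    return magnitude if abs(magnitude) > 1.0 + margin else math.copysign(1.0 + margin, magnitude)


def simulate_drugs(
    spec: SimSpec,
    net: WeightedNetwork,
    disease: DiseaseSignature,
    rng: np.random.Generator | None = None,
) -> tuple[list[DrugSignature], str]:
    """Drug library: one reversal drug plus size-matched random decoys.

    The reversal drug's z on its perturbed module genes is
    ``−(r·z_dis + sqrt(1−r²)·σ·η)`` with η standard normal and σ the spread
    of the disease z on the module, giving correlation ≈ r with the negated
    disease signature (exactly −z_dis at r = 1).  Its DEG set is
    ``module_coverage`` of the module genes plus random off-module filler;
    every drug's DEG set has ``drug_deg_factor × |module|`` genes, since
    perturbation signatures affect more genes than a disease DEG list.
    With r = 0 the library is all decoys.  Returns the signatures and the
    reversal drug's id.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    genes = sorted(net.nodes)
    module = sorted(g for g, rec in disease.records.items()
                    if rec.fdr < 0.01 and 2.0 ** abs(rec.log2fc) >= 2.0)
    deg_size = round(spec.drug_deg_factor * len(module))
    module_set = set(module)
    off_module = [g for g in genes if g not in module_set]
    r = spec.reversal_strength
    reversal_index = int(rng.integers(0, spec.n_drugs)) if r > 0 else -1
    sigma = float(np.std([disease.records[g].z for g in module])) or 1.0

    drugs: list[DrugSignature] = []
    reversal_id = ""
    for i in range(spec.n_drugs):
        drug_id = f"drug_{i:03d}"
        zs = {g: float(np.clip(rng.normal(0.0, 0.3), -0.99, 0.99)) for g in genes}
        if i == reversal_index:
            n_mod = max(1, round(spec.module_coverage * len(module)))
            perturbed = list(rng.choice(module, size=n_mod, replace=False))
            filler = list(rng.choice(off_module, size=deg_size - n_mod, replace=False))
            for g in perturbed:
                raw = -(r * disease.records[g].z
                        + math.sqrt(max(0.0, 1.0 - r * r)) * sigma * rng.normal())
                if raw == 0.0:
                    raw = -disease.records[g].z
                zs[g] = _supra_threshold(raw)
            for g in filler:
                zs[g] = _supra_threshold(
                    math.copysign(1.0 + spec.deg_z_scale * abs(rng.normal()),
                                  rng.normal())
                )
            reversal_id = drug_id
        else:
            deg_genes = rng.choice(genes, size=deg_size, replace=False)
            for g in deg_genes:
                zs[g] = _supra_threshold(
                    math.copysign(1.0 + spec.deg_z_scale * abs(rng.normal()),
                                  rng.normal())
                )
        drugs.append(DrugSignature(drug_id=drug_id, zscores=zs, cell_line="sim", dose="sim"))
    return drugs, reversal_id


def simulate_study(spec: SimSpec) -> SimStudy:
    """Full study from one seed: network, disease cohort, drug library.

    A single RNG seeded from ``spec.rng_seed`` drives the three stages in a
    fixed order (network, disease, drugs), so every run is replayable."""
    rng = np.random.default_rng(spec.rng_seed)
    net = simulate_network(spec, rng)
    disease = simulate_disease(spec, net, rng)
    drugs, reversal_id = simulate_drugs(spec, net, disease, rng)
    module = frozenset(
        g for g, rec in disease.records.items()
        if rec.fdr < 0.01 and 2.0 ** abs(rec.log2fc) >= 2.0
    )
    return SimStudy(
        network=net,
        disease=disease,
        drugs=drugs,
        reversal_drug_id=reversal_id,
        module_genes=module,
        spec=spec,
    )


def write_study(study: SimStudy, out_dir: str | Path) -> None:
    """Write fin.tsv, disease.tsv, drugs/*.tsv, manifest.tsv and truth.json."""
    out = Path(out_dir)
    (out / "drugs").mkdir(parents=True, exist_ok=True)
    write_network(study.network, out / "fin.tsv")
    write_disease_table(study.disease, out / "disease.tsv")
    with (out / "manifest.tsv").open("w") as fh:
        fh.write("drug_id\tcell_line\tdose\tpath\n")
        for drug in study.drugs:
            rel = f"drugs/{drug.drug_id}.tsv"
            write_drug_signature(drug, out / rel)
            fh.write(f"{drug.drug_id}\t{drug.cell_line}\t{drug.dose}\t{rel}\n")
    truth = {
        "reversal_drug_id": study.reversal_drug_id,
        "module_genes": sorted(study.module_genes),
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in study.spec.__dict__.items()
        },
    }
    with (out / "truth.json").open("w") as fh:
        json.dump(truth, fh, indent=2)
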