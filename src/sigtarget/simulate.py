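"""Synthetic L1000-like benchmark compendia with planted drug-target
structure.

Knockdown signatures carry a strong negative Z at the knocked-down
gene's own landmark slot and attenuated effects on its network
neighbours.  Direct-mode drugs mimic their planted target's knockdown
consensus; indirect-mode drugs mimic the mean of the target's
neighbours' knockdowns instead (zero direct term), recreating the
dissociation between direct and partner-level correlation the features
are designed to detect.  All randomness flows from one seed through
named substreams.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import io as stio
from .types import PPINetwork, SampleMeta, SignatureMatrix

log = logging.getLogger(__name__)

_SUBSTREAMS = {"network": 1, "kd": 2, "drugs": 3, "baseline": 4, "truth": 5,
               "annotation": 6, "ctl_noise": 7}

LOC_LABELS = ["intracellular", "transmembrane", "extracellular", "unknown"]
LOC_PROBS = [0.5, 0.25, 0.15, 0.1]


@dataclass
class SimulationConfig:
    n_genes: int = 978
    n_kd_genes: int = 100
    n_cells: int = 4
    n_drugs: int = 20
    n_controls_per_cell: int = 5
    direct_strength: float = 0.8  # alpha
    indirect_strength: float = 0.7  # beta, neighbour attenuation
    noise_sd: float = 1.0
    activity_prob: float = 0.8
    mode_mix: float = 0.65  # fraction of direct-mode drugs
    attachment_degree: int = 2
    replicates: int = 2
    kd_effect: float = 8.0
    baseline_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("direct_strength", "indirect_strength", "activity_prob",
                     "mode_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_kd_genes", "n_cells", "n_controls_per_cell",
                     "replicates", "attachment_degree"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_drugs < 0:
            raise ValueError("n_drugs must be >= 0")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_kd_genes > self.n_genes:
            raise ValueError("n_kd_genes cannot exceed n_genes")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _SUBSTREAMS[stream]])


@dataclass
class DrugTruth:
    drug: str
    target: str
    mode: str  # direct | indirect
    active_cells: list[str]


@dataclass
class BenchmarkBundle:
    """Everything the pipeline consumes, in memory."""

    config: SimulationConfig
    signatures: SignatureMatrix
    meta: list[SampleMeta]
    network: PPINetwork
    truth: dict[str, DrugTruth]
    targets: dict[str, set[str]]
    locmap: dict[str, str]


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """(kd gene names, full landmark gene list).  The first n_kd_genes
    landmark slots are the KD genes' own transcripts."""
    kd = [f"G{i:04d}" for i in range(1, config.n_kd_genes + 1)]
    extra = [f"L{i:04d}" for i in range(config.n_kd_genes + 1, config.n_genes + 1)]
    return kd, kd + extra


def _cell_names(config: SimulationConfig) -> list[str]:
    return [f"CELL{chr(ord('A') + i)}" for i in range(config.n_cells)]


def generate_network(config: SimulationConfig) -> PPINetwork:
    """Scale-free-like graph over the KD genes via preferential
    attachment: a complete seed graph on m+1 nodes, then each new node
    attaches to m distinct degree-weighted existing nodes.  Edge count
    is C(m+1, 2) + m * (n - m - 1)."""
    m = config.attachment_degree
    if config.n_kd_genes < m + 1:
        raise ValueError("need at least attachment_degree + 1 KD genes")
    rng = config.rng("network")
    kd_genes, _ = _gene_names(config)
    net = PPINetwork()
    seed_nodes = kd_genes[: m + 1]
    for i, a in enumerate(seed_nodes):
        for b in seed_nodes[i + 1:]:
            net.add_edge(a, b)
    # repeated-node list realizes degree-proportional sampling
    attachment_pool: list[str] = []
    for a in seed_nodes:
        attachment_pool += [a] * m
    for new in kd_genes[m + 1:]:
        chosen: set[str] = set()
        while len(chosen) < m:
            chosen.add(attachment_pool[rng.integers(len(attachment_pool))])
        for t in sorted(chosen):  # sorted: independent of hash seed
            net.add_edge(new, t)
            attachment_pool.append(t)
        attachment_pool += [new] * m
    return net


def _effect_matrix(
    config: SimulationConfig, network: PPINetwork
) -> tuple[np.ndarray, dict[str, int]]:
    """Column g = deterministic knockdown effect of gene g over all
    landmark slots: -kd_effect at its own slot, -kd_effect * beta at
    neighbours' slots."""
    kd_genes, all_genes = _gene_names(config)
    idx = {g: i for i, g in enumerate(all_genes)}
    eff = np.zeros((config.n_genes, config.n_kd_genes))
    for j, g in enumerate(kd_genes):
        eff[idx[g], j] = -config.kd_effect
        for nb in network.partners(g):
            eff[idx[nb], j] = -config.kd_effect * config.indirect_strength
    return eff, idx


def _cell_baselines(config: SimulationConfig) -> dict[str, np.ndarray]:
    rng = config.rng("baseline")
    return {
        c: rng.normal(0.0, config.baseline_sd, size=config.n_genes)
        for c in _cell_names(config)
    }


def generate_kd_signatures(
    network: PPINetwork, config: SimulationConfig
) -> tuple[SignatureMatrix, list[SampleMeta]]:
    """Replicated knockdown signatures for every (KD gene, cell)."""
    kd_genes, all_genes = _gene_names(config)
    cells = _cell_names(config)
    eff, _ = _effect_matrix(config, network)
    baselines = _cell_baselines(config)
    rng = config.rng("kd")
    cols, ids, meta = [], [], []
    for cell in cells:
        b = baselines[cell]
        for g_idx, gene in enumerate(kd_genes):
            for rep in range(config.replicates):
                z = (
                    eff[:, g_idx]
                    + b
                    + rng.normal(0.0, config.noise_sd, size=config.n_genes)
                )
                sid = f"kd:{gene}:{cell}:r{rep + 1}"
                cols.append(z)
                ids.append(sid)
                meta.append(
                    SampleMeta(
                        sample_id=sid,
                        perturbagen_id=f"sh{gene}",
                        pert_type="kd",
                        cell_line=cell,
                        kd_gene=gene,
                    )
                )
    matrix = SignatureMatrix(
        gene_ids=all_genes, sample_ids=ids, z=np.column_stack(cols)
    )
    return matrix, meta


def _plant_truth(
    config: SimulationConfig, network: PPINetwork
) -> dict[str, DrugTruth]:
    rng = config.rng("truth")
    kd_genes, _ = _gene_names(config)
    cells = _cell_names(config)
    truth: dict[str, DrugTruth] = {}
    # indirect-mode targets need at least one network neighbour
    connected = [g for g in kd_genes if network.degree(g) > 0]
    for i in range(config.n_drugs):
        drug = f"DRUG{i + 1:04d}"
        direct = rng.random() < config.mode_mix
        pool = kd_genes if direct else connected
        target = pool[rng.integers(len(pool))]
        active = [c for c in cells if rng.random() < config.activity_prob]
        if not active:
            active = [cells[rng.integers(len(cells))]]
        truth[drug] = DrugTruth(
            drug=drug,
            target=target,
            mode="direct" if direct else "indirect",
            active_cells=active,
        )
    return truth


def generate_drug_signatures(
    kd_matrix: SignatureMatrix,
    kd_meta: list[SampleMeta],
    truth: dict[str, DrugTruth],
    network: PPINetwork,
    config: SimulationConfig,
) -> tuple[SignatureMatrix, list[SampleMeta]]:
    """Drug-treatment and control signatures given planted truth.

    Active cell, direct mode: alpha * target-KD consensus + noise.
    Active cell, indirect mode: beta * mean of the target's neighbours'
    KD consensuses + noise (no direct term).  Inactive cells and
    controls are baseline + noise.
    """
    kd_genes, all_genes = _gene_names(config)
    gene_idx = {g: i for i, g in enumerate(all_genes)}
    cells = _cell_names(config)
    baselines = _cell_baselines(config)
    # consensus per (gene, cell) from the generated replicates
    cons: dict[tuple[str, str], np.ndarray] = {}
    by_key: dict[tuple[str, str], list[str]] = {}
    for m in kd_meta:
        by_key.setdefault((m.kd_gene, m.cell_line), []).append(m.sample_id)
    for key, samples in by_key.items():
        cons[key] = kd_matrix.columns(samples).mean(axis=1)

    rng = config.rng("drugs")
    cols, ids, meta = [], [], []
    for drug in sorted(truth):
        t = truth[drug]
        if t.target not in set(kd_genes):
            raise ValueError(f"truth for {drug} references unknown gene {t.target!r}")
        for cell in cells:
            noise = rng.normal(0.0, config.noise_sd, size=config.n_genes)
            if cell in t.active_cells:
                if t.mode == "direct":
                    z = config.direct_strength * cons[(t.target, cell)] + noise
                else:
                    neighbours = sorted(network.partners(t.target))
                    stack = np.stack([cons[(nb, cell)] for nb in neighbours])
                    z = config.indirect_strength * stack.mean(axis=0) + noise
                    # the drug perturbs the target's function, not its
                    # transcript: drop the coherent self-slot effect so
                    # only partner-level correlation remains
                    z[gene_idx[t.target]] = noise[gene_idx[t.target]]
            else:
                z = baselines[cell] + noise
            sid = f"drug:{drug}:{cell}"
            cols.append(z)
            ids.append(sid)
            meta.append(
                SampleMeta(
                    sample_id=sid,
                    perturbagen_id=drug,
                    pert_type="drug",
                    cell_line=cell,
                )
            )
    ctl_rng = config.rng("ctl_noise")
    for cell in cells:
        for i in range(config.n_controls_per_cell):
            z = baselines[cell] + ctl_rng.normal(
                0.0, config.noise_sd, size=config.n_genes
            )
            sid = f"ctl:{cell}:{i + 1}"
            cols.append(z)
            ids.append(sid)
            meta.append(
                SampleMeta(
                    sample_id=sid,
                    perturbagen_id="DMSO",
                    pert_type="control",
                    cell_line=cell,
                )
            )
    matrix = SignatureMatrix(
        gene_ids=all_genes, sample_ids=ids, z=np.column_stack(cols)
    )
    return matrix, meta


def _annotations(
    config: SimulationConfig,
) -> dict[str, str]:
    rng = config.rng("annotation")
    kd_genes, _ = _gene_names(config)
    labels = rng.choice(LOC_LABELS, size=len(kd_genes), p=LOC_PROBS)
    return dict(zip(kd_genes, labels))


def generate_benchmark(
    config: SimulationConfig, out_dir: str | os.PathLike | None = None
) -> BenchmarkBundle:
    """Full benchmark bundle; optionally written to disk in the formats
    the pipeline consumes (GCT 1.2 + TSVs, truth in a separate file)."""
    if config.n_drugs == 0:
        log.warning("generating a benchmark with zero drugs")
    network = generate_network(config)
    kd_matrix, kd_meta = generate_kd_signatures(network, config)
    truth = _plant_truth(config, network)
    drug_matrix, drug_meta = generate_drug_signatures(
        kd_matrix, kd_meta, truth, network, config
    )
    merged = SignatureMatrix(
        gene_ids=kd_matrix.gene_ids,
        sample_ids=kd_matrix.sample_ids + drug_matrix.sample_ids,
        z=np.hstack([kd_matrix.z, drug_matrix.z]),
    )
    meta = kd_meta + drug_meta
    targets = {d: {t.target} for d, t in truth.items()}
    locmap = _annotations(config)
    bundle = BenchmarkBundle(
        config=config,
        signatures=merged,
        meta=meta,
        network=network,
        truth=truth,
        targets=targets,
        locmap=locmap,
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        stio.write_gct(merged, os.path.join(out_dir, "signatures.gct"))
        stio.write_sample_meta(meta, os.path.join(out_dir, "sample_meta.tsv"))
        stio.write_ppi(network, os.path.join(out_dir, "ppi.tsv"))
        stio.write_drug_targets(targets, os.path.join(out_dir, "drug_targets.tsv"))
        stio.write_localization(locmap, os.path.join(out_dir, "localization.tsv"))
        truth_rows = [
            (t.drug, t.target, t.mode, ",".join(t.active_cells))
            for t in truth.values()
        ]
        pd.DataFrame(
            truth_rows, columns=["drug", "target", "mode", "active_cells"]
        ).to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
        pd.Series(asdict(config)).to_json(
            os.path.join(out_dir, "config.json"), indent=2
        )
    return bundle
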