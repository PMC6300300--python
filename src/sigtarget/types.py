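"""Core domain types: signature matrices, sample metadata, interaction
networks, candidate spaces, and the small annotation tables.

A :class:`SignatureMatrix` is a genes x samples matrix of differential
expression Z-scores.  :class:`SampleMeta` records what perturbation each
column corresponds to (drug treatment, gene knockdown, or control) and in
which cell line it was measured.  :class:`Compendium` bundles the two and
caches the consensus (replicate-averaged) signatures that every feature
is computed from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DuplicateIdError,
    MetadataError,
    MissingControlError,
    MissingDataError,
    UnknownDrugError,
)

PERT_TYPES = ("drug", "kd", "control")


@dataclass
class SignatureMatrix:
    """Genes x samples matrix of differential-expression Z-scores.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers (landmark genes), unique, in matrix order.
    sample_ids : list of str
        Column identifiers, unique, in matrix order.
    z : ndarray of shape (n_genes, n_samples)
        Finite Z-score values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("z must be a 2-D array")
        if len(self.gene_ids) != self.z.shape[0]:
            raise ValueError(
                f"gene count {len(self.gene_ids)} != row count {self.z.shape[0]}"
            )
        if len(self.sample_ids) != self.z.shape[1]:
            raise ValueError(
                f"sample count {len(self.sample_ids)} != column count {self.z.shape[1]}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DuplicateIdError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.z)):
            bad = np.argwhere(~np.isfinite(self.z))[0]
            raise ValueError(f"non-finite value at row {bad[0]}, column {bad[1]}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return self.z.shape[0]

    @property
    def n_samples(self) -> int:
        return self.z.shape[1]

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def column(self, sample_id: str) -> np.ndarray:
        try:
            return self.z[:, self._sample_index[sample_id]]
        except KeyError:
            raise MissingDataError(f"sample {sample_id!r} not in matrix") from None

    def columns(self, sample_ids: list[str]) -> np.ndarray:
        idx = [self._sample_index[s] for s in sample_ids]
        return self.z[:, idx]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one signature column."""

    sample_id: str
    perturbagen_id: str
    pert_type: str
    cell_line: str
    kd_gene: str = ""

    def __post_init__(self) -> None:
        if self.pert_type not in PERT_TYPES:
            raise MetadataError(
                f"sample {self.sample_id!r}: unknown pert_type {self.pert_type!r} "
                f"(expected one of {PERT_TYPES})"
            )
        if self.pert_type == "kd" and not self.kd_gene:
            raise MetadataError(
                f"sample {self.sample_id!r}: kd row requires a kd_gene"
            )
        if self.pert_type != "kd" and self.kd_gene:
            raise MetadataError(
                f"sample {self.sample_id!r}: kd_gene set on a {self.pert_type} row"
            )


class PPINetwork:
    """Undirected gene-gene interaction graph.

    Stored as an adjacency map of sets; symmetric by construction, no
    self-loops.
    """

    def __init__(self, edges: list[tuple[str, str]] | None = None):
        self._adj: dict[str, set[str]] = {}
        for a, b in edges or []:
            self.add_edge(a, b)

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            return
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(p) for p in self._adj.values()) // 2

    def partners(self, gene: str) -> set[str]:
        return self._adj.get(gene, set())

    def degree(self, gene: str) -> int:
        return len(self._adj.get(gene, ()))

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for a in sorted(self._adj):
            for b in sorted(self._adj[a]):
                if a < b:
                    out.append((a, b))
        return out


@dataclass
class CandidateSpace:
    """For a drug: the cell lines it was profiled in and the candidate
    target genes with knockdown signatures in every one of those cells."""

    drug: str
    cells: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.cells:
            raise MissingDataError(f"drug {self.drug!r}: empty cell set")
        if not self.genes:
            raise MissingDataError(f"drug {self.drug!r}: empty candidate gene set")
        self.cells = sorted(self.cells)
        self.genes = sorted(self.genes)


# Simple alias types for the annotation tables.
DrugTargetMap = dict  # drug -> set of gene symbols
LocalizationMap = dict  # gene -> one of {intracellular, transmembrane, extracellular, unknown}
DockingScoreTable = dict  # (drug, gene) -> float; absence of key = no structure


def consensus_signature(replicates: np.ndarray) -> np.ndarray:
    """Element-wise mean over replicate columns.

    ``replicates`` is (n_genes, n_replicates); a single replicate is
    returned unchanged.  Zero replicates is an error.
    """
    replicates = np.asarray(replicates, dtype=float)
    if replicates.ndim == 1:
        return replicates
    if replicates.shape[1] == 0:
        raise MissingDataError("consensus of zero replicates")
    return replicates.mean(axis=1)


class Compendium:
    """Signature matrix + metadata with cached consensus signatures.

    Consensus drug signatures are keyed by (drug, cell), knockdown
    consensuses by (gene, cell); replicates are averaged (see
    :func:`consensus_signature`).
    """

    def __init__(self, signatures: SignatureMatrix, meta: list[SampleMeta]):
        self.signatures = signatures
        self.meta = list(meta)
        known = set(signatures.sample_ids)
        for m in self.meta:
            if m.sample_id not in known:
                raise MetadataError(
                    f"metadata sample {m.sample_id!r} not a matrix column"
                )
        self._drug_samples: dict[tuple[str, str], list[str]] = {}
        self._kd_samples: dict[tuple[str, str], list[str]] = {}
        self._control_samples: dict[str, list[str]] = {}
        for m in self.meta:
            if m.pert_type == "drug":
                self._drug_samples.setdefault(
                    (m.perturbagen_id, m.cell_line), []
                ).append(m.sample_id)
            elif m.pert_type == "kd":
                self._kd_samples.setdefault(
                    (m.kd_gene, m.cell_line), []
                ).append(m.sample_id)
            else:
                self._control_samples.setdefault(m.cell_line, []).append(m.sample_id)
        self._consensus_cache: dict[tuple[str, str, str], np.ndarray] = {}
        self._kd_matrix_cache: dict[tuple[str, tuple[str, ...]], np.ndarray] = {}

    # -- lookups ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return self.signatures.gene_ids

    def drugs(self) -> list[str]:
        return sorted({d for d, _ in self._drug_samples})

    def cells(self) -> list[str]:
        return sorted({m.cell_line for m in self.meta})

    def drug_cells(self, drug: str) -> list[str]:
        cells = sorted({c for d, c in self._drug_samples if d == drug})
        if not cells:
            raise UnknownDrugError(f"drug {drug!r} has no treatment samples")
        return cells

    def kd_genes(self, cell: str) -> set[str]:
        return {g for g, c in self._kd_samples if c == cell}

    def has_kd(self, gene: str, cell: str) -> bool:
        return (gene, cell) in self._kd_samples

    def control_sample_ids(self, cell: str) -> list[str]:
        try:
            return self._control_samples[cell]
        except KeyError:
            raise MissingControlError(f"no control samples in cell {cell!r}") from None

    # -- consensus signatures -------------------------------------------
    def _consensus(self, kind: str, key: str, cell: str) -> np.ndarray:
        cache_key = (kind, key, cell)
        hit = self._consensus_cache.get(cache_key)
        if hit is not None:
            return hit
        table = self._drug_samples if kind == "drug" else self._kd_samples
        try:
            samples = table[(key, cell)]
        except KeyError:
            raise MissingDataError(
                f"no {kind} samples for {key!r} in cell {cell!r}"
            ) from None
        sig = consensus_signature(self.signatures.columns(samples))
        self._consensus_cache[cache_key] = sig
        return sig

    def drug_signature(self, drug: str, cell: str) -> np.ndarray:
        return self._consensus("drug", drug, cell)

    def kd_signature(self, gene: str, cell: str) -> np.ndarray:
        return self._consensus("kd", gene, cell)

    def kd_matrix(self, genes: list[str], cell: str) -> np.ndarray:
        """Stack of KD consensus signatures, shape (len(genes), n_genes)."""
        key = (cell, tuple(genes))
        hit = self._kd_matrix_cache.get(key)
        if hit is None:
            hit = np.stack([self.kd_signature(g, cell) for g in genes])
            self._kd_matrix_cache[key] = hit
        return hit

    def control_matrix(self, cell: str) -> np.ndarray:
        return self.signatures.columns(self.control_sample_ids(cell))


def build_candidate_space(comp: Compendium, drug: str) -> CandidateSpace:
    """Candidate space for a drug under the intersection policy.

    Cells are those where the drug was profiled and at least one KD
    exists; candidate genes are those with a KD consensus signature in
    every such cell.
    """
    cells = [c for c in comp.drug_cells(drug) if comp.kd_genes(c)]
    if not cells:
        raise MissingDataError(f"drug {drug!r}: no profiled cell has knockdowns")
    genes: set[str] | None = None
    for c in cells:
        kd = comp.kd_genes(c)
        genes = kd if genes is None else genes & kd
    if not genes:
        raise MissingDataError(f"drug {drug!r}: no gene has KDs in all cells")
    return CandidateSpace(drug=drug, cells=cells, genes=sorted(genes))
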