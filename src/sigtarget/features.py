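"""Per-(drug, candidate gene, cell) feature computation.

Six features per row:

- ``f_cor``     signed Pearson correlation between the drug consensus
                signature and the candidate's knockdown consensus.
- ``f_PC``      degree-corrected enrichment of the candidate's interaction
                partners among the knockdowns most correlated with the drug
                (fold form: observed fraction / expected fraction).
- ``f_CS``      mean correlation of the drug signature with the cell's
                control samples; low values flag an "active" cell.
- ``f_DE_mean`` mean |Z| of the candidate's partners in the drug signature.
- ``f_DE_max``  max |Z| of the candidate's partners in the drug signature.
- ``f_loc``     cellular localization encoding (+1 intracellular,
                -1 transmembrane/extracellular, 0 unknown).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ZeroVarianceError
from .types import CandidateSpace, Compendium, PPINetwork

log = logging.getLogger(__name__)

#: default size of the top-correlated-KD list used by the partner
#: enrichment feature (50 and 200 behave similarly).
DEFAULT_TOP_X = 100

FEATURE_COLUMNS = ["f_cor", "f_PC", "f_CS", "f_DE_mean", "f_DE_max", "f_loc"]

LOC_ENCODING = {
    "intracellular": 1,
    "transmembrane": -1,
    "extracellular": -1,
    "unknown": 0,
}


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("correlation undefined for zero-variance input")
    r = float((xc * yc).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))


def _pearson_rows(matrix: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each matrix row against v (vectorized)."""
    mc = matrix - matrix.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    sm = np.sqrt((mc * mc).sum(axis=1))
    sv = np.sqrt((vc * vc).sum())
    if sv == 0.0 or np.any(sm == 0.0):
        raise ZeroVarianceError("correlation undefined for zero-variance input")
    return np.clip(mc @ vc / (sm * sv), -1.0, 1.0)


def direct_correlation(drug: str, gene: str, cell: str, comp: Compendium) -> float:
    """Signed correlation between drug and knockdown consensus signatures."""
    return pearson(comp.drug_signature(drug, cell), comp.kd_signature(gene, cell))


def top_correlated_kds(
    drug: str,
    cell: str,
    comp: Compendium,
    candidates: list[str],
    x: int = DEFAULT_TOP_X,
) -> list[str]:
    """The min(x, N) candidate genes whose KD consensus correlates best
    (signed, descending) with the drug signature; ties break
    lexicographically by gene id."""
    if x <= 0:
        raise ValueError(f"x must be positive, got {x}")
    genes = sorted(candidates)
    r = _pearson_rows(comp.kd_matrix(genes, cell), comp.drug_signature(drug, cell))
    order = np.lexsort((genes, -r))  # descending r, then gene id
    return [genes[i] for i in order[: min(x, len(genes))]]


def indirect_correlation(
    gene: str,
    network: PPINetwork,
    top_list: list[str],
    candidates: list[str],
    x: int = DEFAULT_TOP_X,
) -> float:
    """Degree-corrected partner enrichment.

    With ``k`` = partners of the gene inside the top list and ``deg`` =
    partners inside the candidate frame, returns ``(k/deg) / (x_eff/N)``
    where ``x_eff = min(x, N)``; genes with no in-frame partners (or
    absent from the network) score 0.
    """
    n = len(candidates)
    if n <= 0:
        raise ValueError("empty candidate frame")
    if gene not in network:
        log.debug("gene %s not in interaction network; f_PC = 0", gene)
        return 0.0
    partners = network.partners(gene)
    deg = len(partners.intersection(candidates))
    if deg == 0:
        return 0.0
    k = len(partners.intersection(top_list))
    expected = min(x, n) / n
    return (k / deg) / expected


def cell_selection(drug: str, cell: str, comp: Compendium) -> float:
    """Mean correlation of the drug signature with each control sample."""
    v = comp.drug_signature(drug, cell)
    controls = comp.control_matrix(cell)
    return float(np.mean(_pearson_rows(controls.T, v)))


def partner_expression_features(
    gene: str, drug_signature: np.ndarray, network: PPINetwork, gene_index: dict
) -> tuple[float, float]:
    """(mean |Z|, max |Z|) of the gene's partners in the drug signature,
    over partners that are measured genes; (0, 0) if there are none."""
    idx = sorted(gene_index[p] for p in network.partners(gene) if p in gene_index)
    if not idx:
        return 0.0, 0.0
    vals = np.abs(np.asarray(drug_signature)[idx])
    return float(vals.mean()), float(vals.max())


def localization_feature(gene: str, locmap: dict[str, str]) -> int:
    return LOC_ENCODING.get(locmap.get(gene, "unknown"), 0)


def assemble_feature_table(
    space: CandidateSpace,
    comp: Compendium,
    network: PPINetwork,
    locmap: dict[str, str] | None = None,
    x: int = DEFAULT_TOP_X,
) -> pd.DataFrame:
    """Complete |genes| x |cells| feature block for one drug.

    Returns a DataFrame with columns drug, gene, cell and the six
    features, ordered by (gene, cell).
    """
    locmap = locmap or {}
    drug = space.drug
    genes = space.genes  # sorted by CandidateSpace
    gene_index = {g: i for i, g in enumerate(comp.gene_ids)}
    # partner landmark indices are cell-independent; sorted so float
    # reductions are bit-reproducible across interpreter hash seeds
    partner_idx = {
        g: np.array(
            sorted(gene_index[p] for p in network.partners(g) if p in gene_index),
            dtype=int,
        )
        for g in genes
    }
    f_loc = np.array([localization_feature(g, locmap) for g in genes], dtype=float)
    deg_in_frame = np.array(
        [len(network.partners(g).intersection(genes)) for g in genes], dtype=float
    )
    n = len(genes)
    x_eff = min(x, n)

    blocks = []
    for cell in space.cells:
        v = comp.drug_signature(drug, cell)
        kd = comp.kd_matrix(genes, cell)
        f_cor = _pearson_rows(kd, v)
        order = np.lexsort((genes, -f_cor))
        top = {genes[i] for i in order[:x_eff]}
        k_top = np.array(
            [len(network.partners(g).intersection(top)) for g in genes], dtype=float
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            f_pc = np.where(
                deg_in_frame > 0, (k_top / deg_in_frame) / (x_eff / n), 0.0
            )
        f_cs = cell_selection(drug, cell, comp)
        abs_v = np.abs(v)
        de_mean = np.zeros(n)
        de_max = np.zeros(n)
        for i, g in enumerate(genes):
            idx = partner_idx[g]
            if idx.size:
                vals = abs_v[idx]
                de_mean[i] = vals.mean()
                de_max[i] = vals.max()
        blocks.append(
            pd.DataFrame(
                {
                    "drug": drug,
                    "gene": genes,
                    "cell": cell,
                    "f_cor": f_cor,
                    "f_PC": f_pc,
                    "f_CS": f_cs,
                    "f_DE_mean": de_mean,
                    "f_DE_max": de_max,
                    "f_loc": f_loc,
                }
            )
        )
    table = pd.concat(blocks, ignore_index=True)
    table = table.sort_values(["gene", "cell"], kind="mergesort").reset_index(drop=True)
    return table


def assemble_all_features(
    comp: Compendium,
    network: PPINetwork,
    locmap: dict[str, str] | None = None,
    drugs: list[str] | None = None,
    x: int = DEFAULT_TOP_X,
) -> pd.DataFrame:
    """Feature tables for every drug (or a subset), concatenated."""
    from .types import build_candidate_space

    tables = []
    for d in sorted(drugs if drugs is not None else comp.drugs()):
        space = build_candidate_space(comp, d)
        tables.append(assemble_feature_table(space, comp, network, locmap, x))
    return pd.concat(tables, ignore_index=True)
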