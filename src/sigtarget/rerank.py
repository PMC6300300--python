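"""Re-ranking of the genomic top-K by externally supplied docking scores.

No docking engine is invoked here: scores arrive as a (drug, gene) ->
score table (lower = better), produced by any external run or by the
mock provider below.  Candidates without a score ("structureless") are
appended after the scored ones in their genomic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ranking import RankedTargets

log = logging.getLogger(__name__)

DEFAULT_TOP_K = 100


@dataclass
class RerankResult:
    """Ordered re-ranked candidates for one drug."""

    drug: str
    genes: list[str]  # final order, rank 1 first
    genomic_ranks: list[int]
    scores: list[float | None]  # None = no structure

    @property
    def final_ranks(self) -> list[int]:
        return list(range(1, len(self.genes) + 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": self.drug,
                "gene": self.genes,
                "genomic_rank": self.genomic_ranks,
                "docking_score": [np.nan if s is None else s for s in self.scores],
                "final_rank": self.final_ranks,
            }
        )

    def rank_of(self, gene: str) -> int | None:
        try:
            return self.genes.index(gene) + 1
        except ValueError:
            return None


def rerank_top_k(
    ranked: RankedTargets,
    scores: dict[tuple[str, str], float],
    k: int = DEFAULT_TOP_K,
) -> RerankResult:
    """Reorder the genomic top-K: scored candidates ascending by score
    (stable), unscored candidates appended in genomic order."""
    top = ranked.genes[: min(k, len(ranked.genes))]
    entries = [(g, i + 1, scores.get((ranked.drug, g))) for i, g in enumerate(top)]
    scored = [e for e in entries if e[2] is not None]
    unscored = [e for e in entries if e[2] is None]
    scored.sort(key=lambda e: e[2])  # Python sort is stable: ties keep genomic order
    final = scored + unscored
    return RerankResult(
        drug=ranked.drug,
        genes=[e[0] for e in final],
        genomic_ranks=[e[1] for e in final],
        scores=[e[2] for e in final],
    )


def cutoff_filter(result: RerankResult, quantile: float = 0.5) -> set[str]:
    """Hit set: scored candidates strictly better (lower) than the given
    quantile of the drug's own score distribution."""
    vals = np.array([s for s in result.scores if s is not None], dtype=float)
    if vals.size == 0:
        log.warning("drug %s: no scored candidates; empty hit set", result.drug)
        return set()
    cut = float(np.quantile(vals, quantile))
    return {
        g
        for g, s in zip(result.genes, result.scores)
        if s is not None and s < cut
    }


def mock_score_provider(
    truth: dict[str, str],
    candidates: dict[str, list[str]],
    margin: float = 3.0,
    noise_sd: float = 1.0,
    structureless_fraction: float = 0.3,
    target_structure_prob: float = 1.0,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Synthetic docking-score table standing in for a real docking run.

    Planted targets (``truth``: drug -> target gene) draw scores centred
    ``margin * noise_sd`` below (better than) decoys.  A seeded fraction
    of decoys is structureless (absent from the table); planted targets
    lack a structure with probability ``1 - target_structure_prob``.
    """
    rng = np.random.default_rng(seed)
    table: dict[tuple[str, str], float] = {}
    for drug in sorted(candidates):
        target = truth.get(drug)
        for gene in candidates[drug]:
            if gene == target:
                if rng.random() >= target_structure_prob:
                    continue
                loc = -margin * noise_sd
            else:
                if rng.random() < structureless_fraction:
                    continue
                loc = 0.0
            table[(drug, gene)] = float(rng.normal(loc, noise_sd))
    return table
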