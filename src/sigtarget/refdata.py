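"""Bundled reference tables from a published drug-target benchmark.

Two small TSVs ship with the package:

* ``benchmark29_rankings.tsv`` — per-drug best-known-target rankings of
  29 FDA-approved drugs profiled in 7 cell lines (candidate pool of
  2634 KD genes), under each single-feature ranker and the combined
  models (random / dir / ind / cs / max_de / mean_de / lr / rf).
* ``benchmark152_groups.tsv`` — top-100/top-50 drug counts for the two
  random-forest architectures on 152 drugs, grouped by the number of
  cell lines each drug was profiled in.

These are evaluation inputs (the rankings themselves), not expected
outputs; the evaluation module recomputes all summary statistics from
them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: candidate pool size underlying the 29-drug benchmark rankings
BENCHMARK29_POOL = 2634

RANKING_COLUMNS = ["random", "dir", "ind", "cs", "max_de", "mean_de", "lr", "rf"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("sigtarget.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_benchmark29() -> pd.DataFrame:
    """29-drug benchmark rankings, one row per drug.

    ``targets`` is a comma-separated list of known target genes; the
    ranking columns hold the rank of the best-ranked known target under
    each method.
    """
    df = _load("benchmark29_rankings.tsv")
    df["n_targets"] = df["targets"].str.split(",").map(len)
    return df


def load_benchmark152_groups() -> pd.DataFrame:
    """Per-cell-count group counts for the 152-drug benchmark."""
    return _load("benchmark152_groups.tsv")
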