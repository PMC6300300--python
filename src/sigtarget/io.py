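"""Readers and writers for the on-disk formats.

Signature matrices travel as tab-separated GCT 1.2 (``#1.2`` header,
NAME/Description columns).  Everything else — sample metadata, edge
lists, drug-target annotations, localization labels, docking scores —
is plain TSV.
"""

from __future__ import annotations

import logging
import os

import pandas as pd

from .errors import (
    DimensionError,
    DuplicateIdError,
    EmptyNetworkError,
    MetadataError,
    ParseError,
)
from .types import PPINetwork, SampleMeta, SignatureMatrix

log = logging.getLogger(__name__)

META_COLUMNS = ["sample_id", "perturbagen_id", "pert_type", "cell_line", "kd_gene"]


def read_gct(path: str | os.PathLike) -> SignatureMatrix:
    """Parse a GCT 1.2 file into a :class:`SignatureMatrix`."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise ParseError(f"{path}: line 1: expected '#1.2' header, got {version!r}")
        dims = fh.readline().strip().split("\t")
        if len(dims) < 2:
            raise ParseError(f"{path}: line 2: expected '<rows>\\t<cols>'")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError:
            raise ParseError(f"{path}: line 2: non-integer dimensions {dims!r}") from None
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0].upper() != "NAME":
            raise ParseError(f"{path}: line 3: expected NAME/Description header")
        sample_ids = header[2:]
        if len(sample_ids) != n_cols:
            raise DimensionError(
                f"{path}: header declares {n_cols} samples, found {len(sample_ids)}"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise DuplicateIdError(f"{path}: duplicate sample identifiers")
        gene_ids: list[str] = []
        values: list[list[float]] = []
        for lineno, line in enumerate(fh, start=4):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_cols + 2:
                raise DimensionError(
                    f"{path}: line {lineno}: expected {n_cols + 2} fields, "
                    f"got {len(parts)}"
                )
            gene_ids.append(parts[0])
            row = []
            for j, cell in enumerate(parts[2:]):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}, column {j + 3}: "
                        f"non-numeric value {cell!r}"
                    ) from None
            values.append(row)
    if len(gene_ids) != n_rows:
        raise DimensionError(
            f"{path}: header declares {n_rows} rows, found {len(gene_ids)}"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise DuplicateIdError(f"{path}: duplicate gene identifiers")
    return SignatureMatrix(gene_ids=gene_ids, sample_ids=sample_ids, z=values)


def write_gct(matrix: SignatureMatrix, path: str | os.PathLike) -> None:
    """Write a :class:`SignatureMatrix` as GCT 1.2."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, gene in enumerate(matrix.gene_ids):
            row = "\t".join(repr(float(v)) for v in matrix.z[i])
            fh.write(f"{gene}\t{gene}\t{row}\n")


def read_sample_meta(path: str | os.PathLike) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing metadata columns {missing}")
    records = [
        SampleMeta(
            sample_id=r.sample_id,
            perturbagen_id=r.perturbagen_id,
            pert_type=r.pert_type,
            cell_line=r.cell_line,
            kd_gene=r.kd_gene,
        )
        for r in df.itertuples(index=False)
    ]
    ids = [m.sample_id for m in records]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError(f"{path}: duplicate sample_id in metadata")
    return records


def write_sample_meta(meta: list[SampleMeta], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            (m.sample_id, m.perturbagen_id, m.pert_type, m.cell_line, m.kd_gene)
            for m in meta
        ],
        columns=META_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_ppi(path: str | os.PathLike, *, allow_empty: bool = False) -> PPINetwork:
    """Read a two-column edge list; extra columns are ignored.

    Symmetric duplicates and self-loops are dropped.
    """
    net = PPINetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns")
            net.add_edge(parts[0], parts[1])
    if net.n_edges == 0:
        if allow_empty:
            log.warning("%s: empty interaction network", path)
        else:
            raise EmptyNetworkError(f"{path}: no edges parsed")
    return net


def write_ppi(net: PPINetwork, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in net.edges():
            fh.write(f"{a}\t{b}\n")


def read_drug_targets(path: str | os.PathLike) -> dict[str, set[str]]:
    """TSV with columns drug, target; one row per (drug, target) pair."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    targets: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        targets.setdefault(r.drug, set()).add(r.target)
    return targets


def write_drug_targets(targets: dict[str, set[str]], path: str | os.PathLike) -> None:
    rows = [(d, g) for d in sorted(targets) for g in sorted(targets[d])]
    pd.DataFrame(rows, columns=["drug", "target"]).to_csv(path, sep="\t", index=False)


def read_localization(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["gene"], df["localization"]))


def write_localization(locmap: dict[str, str], path: str | os.PathLike) -> None:
    rows = sorted(locmap.items())
    pd.DataFrame(rows, columns=["gene", "localization"]).to_csv(
        path, sep="\t", index=False
    )


def read_docking_scores(path: str | os.PathLike) -> dict[tuple[str, str], float]:
    """TSV with columns drug, gene, score.  A missing (drug, gene) pair
    means no structure was available; it is never encoded as zero."""
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "gene": str, "score": float})
    table = {(r.drug, r.gene): float(r.score) for r in df.itertuples(index=False)}
    for key, score in table.items():
        if not pd.notna(score) or score in (float("inf"), float("-inf")):
            raise ParseError(f"{path}: non-finite docking score for {key}")
    return table


def write_docking_scores(
    table: dict[tuple[str, str], float], path: str | os.PathLike
) -> None:
    rows = [(d, g, s) for (d, g), s in sorted(table.items())]
    pd.DataFrame(rows, columns=["drug", "gene", "score"]).to_csv(
        path, sep="\t", index=False
    )
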