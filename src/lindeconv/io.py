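"""Tabular I/O: TSV readers/writers for the package's data objects.

All matrices are dense TSV with header rows of cell or fraction names
(problem sizes of ~1,500 cells make sparse formats unnecessary); sort
matrices carry their per-fraction reporter/polarity metadata in a YAML
sidecar next to the TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .lineage import LineageTree, SymmetryMap
from .sort_model import Fraction, FractionMeasurements, SortMatrix

__all__ = [
    "write_lineage", "write_symmetry",
    "write_expression", "read_expression",
    "write_sort_matrix", "read_sort_matrix",
    "write_measurements", "read_measurements",
]


def write_lineage(tree: LineageTree, path: str | Path) -> None:
    tree.to_frame().to_csv(path, sep="\t", index=False)


def write_symmetry(sym: SymmetryMap, path: str | Path) -> None:
    pd.DataFrame(list(sym.pairs), columns=["left_root", "right_root"]) \
        .to_csv(path, sep="\t", index=False)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     truth_path: str | Path | None = None) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")
    if truth_path is not None and expr.truth is not None:
        expr.truth_frame().to_csv(truth_path, sep="\t", index_label="gene")


def read_expression(path: str | Path,
                    truth_path: str | Path | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0).to_numpy(dtype=bool)
    return ExpressionMatrix(df.to_numpy(), list(df.index.astype(str)),
                            list(df.columns), truth=truth)


def _sidecar(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".yaml")


def write_sort_matrix(sort: SortMatrix, path: str | Path) -> None:
    sort.to_frame().to_csv(path, sep="\t", index_label="fraction")
    meta = [{"reporter": f.reporter, "polarity": f.polarity} for f in sort.fractions]
    _sidecar(path).write_text(yaml.safe_dump({"fractions": meta}, sort_keys=False))


def read_sort_matrix(path: str | Path) -> SortMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = _sidecar(path)
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())["fractions"]
        fractions = [Fraction(m["reporter"], m["polarity"]) for m in meta]
    else:  # infer polarity from row labels
        fractions = []
        for label in df.index.astype(str):
            if label == "all":
                fractions.append(Fraction("all", "all"))
            elif label.endswith("-"):
                fractions.append(Fraction(label[:-1], "negative"))
            else:
                fractions.append(Fraction(label.rstrip("+"), "positive"))
    return SortMatrix(df.to_numpy(), fractions, list(df.columns))


def write_measurements(meas: FractionMeasurements, path: str | Path) -> None:
    meas.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_measurements(path: str | Path) -> FractionMeasurements:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FractionMeasurements(df.to_numpy(), list(df.index.astype(str)),
                                list(df.columns))
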