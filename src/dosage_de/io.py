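"""Plain-text serialization: count TSV/MTX, metadata, spike tables, results.

Counts travel as a gene x library TSV whose first column is ``gene_id``
and whose header names the libraries, or as a MatrixMarket ``.mtx`` file
with ``.rows`` / ``.cols`` sidecar index files.  Library metadata, spike
references, ground truth and all result tables are TSV; run manifests are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .de_testing import ComparisonResult
from .errors import ValidationError
from .synthetic_data import CountMatrix, ExperimentDesign, SpikeInReference


def write_design_tsv(design: ExperimentDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> ExperimentDesign:
    return ExperimentDesign.from_frame(pd.read_csv(path, sep="\t"))


def write_spike_reference_tsv(spikes: SpikeInReference, path: str | Path) -> None:
    spikes.species.to_csv(path, sep="\t", index=False)


def read_spike_reference_tsv(path: str | Path) -> SpikeInReference:
    return SpikeInReference(species=pd.read_csv(path, sep="\t"))


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_counts_mtx(matrix: CountMatrix, path: str | Path) -> None:
    """MatrixMarket integer matrix plus .rows/.cols sidecar id lists."""
    path = Path(path)
    sparse = scipy.sparse.csr_matrix(matrix.counts.to_numpy())
    scipy.io.mmwrite(str(path), sparse, field="integer")
    Path(str(path) + ".rows").write_text("\n".join(matrix.gene_ids) + "\n")
    Path(str(path) + ".cols").write_text("\n".join(matrix.library_ids) + "\n")


def _check_cell_values(df: pd.DataFrame) -> None:
    vals = df.to_numpy()
    bad = ~np.isfinite(vals) | (vals < 0) | (vals != np.round(vals))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"invalid count {vals[i, j]!r} at gene {df.index[i]!r}, "
            f"library {df.columns[j]!r}"
        )


def read_counts(
    path: str | Path,
    design: ExperimentDesign,
    spike_ids: set[str] | frozenset[str] = frozenset(),
) -> CountMatrix:
    """Read a counts TSV or MTX file and reconcile it against the design.

    Rows whose id appears in ``spike_ids`` are flagged as spike species.
    Raises :class:`ValidationError` naming the offending cell for negative
    or non-integer entries, and a reconciliation error naming missing or
    extra libraries.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(str(path))
        genes = Path(str(path) + ".rows").read_text().split()
        libs = Path(str(path) + ".cols").read_text().split()
        df = pd.DataFrame(
            np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat),
            index=pd.Index(genes, name="gene_id"),
            columns=libs,
        )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"malformed numeric cell in {path}: {exc}") from exc
    _check_cell_values(df)
    design_ids = design.library_ids
    missing = [l for l in design_ids if l not in df.columns]
    extra = [l for l in df.columns if l not in design_ids]
    if missing or extra:
        raise ValidationError(
            f"metadata/matrix library mismatch: missing {missing}, extra {extra}"
        )
    df = df[design_ids].astype(np.int64)
    is_spike = pd.Series(df.index.isin(spike_ids), index=df.index)
    return CountMatrix(counts=df, is_spike=is_spike, design=design)


def write_comparison_tsv(result: ComparisonResult, path: str | Path) -> None:
    out = result.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_comparison_tsv(
    path: str | Path, comparison_id: str, alpha: float = 0.05
) -> ComparisonResult:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ComparisonResult(
        comparison_id=comparison_id,
        table=table,
        n_tested=len(table),
        alpha=alpha,
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
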