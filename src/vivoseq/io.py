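"""Reading and writing of the pipeline's on-disk formats.

Traces travel as long-format CSV (cell_id, time_s, f_cell, f_background)
with the stimulus protocol as a JSON sidecar; expression matrices as TSV
(genes x cells) or Matrix Market triplets with genes.tsv
(id, length_bp, biotype) and cells.tsv (id, cdna_pg_ul, mito_fraction,
n_genes_detected, label) sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .calcium import FluorescenceTrace, StimulusProtocol
from .qc import CellQCRecord, ExpressionMatrix, QCReport


# -- calcium traces ---------------------------------------------------------

def write_traces_csv(path, traces: list[FluorescenceTrace]) -> None:
    frames = []
    for tr in traces:
        t = np.arange(tr.f_cell.size) / tr.frame_rate_hz
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "time_s": t,
                    "f_cell": tr.f_cell,
                    "f_background": tr.f_background,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path, frame_rate_hz: float = 30.0) -> list[FluorescenceTrace]:
    frame = pd.read_csv(path)
    required = {"cell_id", "time_s", "f_cell", "f_background"}
    if not required.issubset(frame.columns):
        raise ValueError(f"traces CSV must have columns {sorted(required)}")
    traces = []
    for cell_id, grp in frame.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            FluorescenceTrace(
                cell_id=str(cell_id),
                f_cell=grp["f_cell"].to_numpy(),
                f_background=grp["f_background"].to_numpy(),
                frame_rate_hz=frame_rate_hz,
            )
        )
    return traces


def write_protocol_json(path, protocol: StimulusProtocol) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "onsets_s": list(protocol.onsets_s),
                "stim_duration_s": protocol.stim_duration_s,
                "isi_s": protocol.isi_s,
                "frame_rate_hz": protocol.frame_rate_hz,
                "pre_baseline_window_s": list(protocol.pre_baseline_window_s),
            },
            indent=1,
        )
    )


def read_protocol_json(path) -> StimulusProtocol:
    d = json.loads(Path(path).read_text())
    return StimulusProtocol(
        onsets_s=tuple(d["onsets_s"]),
        stim_duration_s=d["stim_duration_s"],
        isi_s=d["isi_s"],
        frame_rate_hz=d["frame_rate_hz"],
        pre_baseline_window_s=tuple(d.get("pre_baseline_window_s", (2.0, 4.0))),
    )


# -- expression matrices ----------------------------------------------------

def write_expression_tsv(prefix, matrix: ExpressionMatrix,
                         records: list[CellQCRecord] | None = None) -> None:
    """Write <prefix>_matrix.tsv, <prefix>_genes.tsv and optional <prefix>_cells.tsv."""
    prefix = Path(prefix)
    matrix.values.to_csv(f"{prefix}_matrix.tsv", sep="\t", index_label="gene")
    matrix.gene_meta.to_csv(f"{prefix}_genes.tsv", sep="\t", index_label="gene")
    if records is not None:
        write_cells_tsv(f"{prefix}_cells.tsv", records)


def read_expression_tsv(prefix, value_kind: str = "counts") -> ExpressionMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(f"{prefix}_matrix.tsv", sep="\t", index_col="gene")
    gene_meta = pd.read_csv(f"{prefix}_genes.tsv", sep="\t", index_col="gene")
    return ExpressionMatrix(values, gene_meta, value_kind=value_kind)


def write_expression_mtx(prefix, matrix: ExpressionMatrix) -> None:
    """Matrix Market triplet plus gene/cell id sidecars."""
    prefix = Path(prefix)
    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(matrix.values.to_numpy()))
    matrix.gene_meta.to_csv(f"{prefix}_genes.tsv", sep="\t", index_label="gene")
    pd.Series(matrix.cell_ids, name="cell").to_csv(
        f"{prefix}_barcodes.tsv", sep="\t", index=False
    )


def read_expression_mtx(prefix, value_kind: str = "counts") -> ExpressionMatrix:
    prefix = Path(prefix)
    mat = spio.mmread(f"{prefix}.mtx").toarray()
    gene_meta = pd.read_csv(f"{prefix}_genes.tsv", sep="\t", index_col="gene")
    cells = pd.read_csv(f"{prefix}_barcodes.tsv", sep="\t")["cell"]
    values = pd.DataFrame(mat, index=gene_meta.index, columns=list(cells))
    return ExpressionMatrix(values, gene_meta, value_kind=value_kind)


def write_cells_tsv(path, records: list[CellQCRecord]) -> None:
    pd.DataFrame(
        {
            "cell": [r.cell_id for r in records],
            "cdna_pg_ul": [r.cdna_pg_ul for r in records],
            "mito_fraction": [r.mito_fraction for r in records],
            "n_genes_detected": [r.n_genes_detected for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_cells_tsv(path) -> list[CellQCRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [
        CellQCRecord(
            cell_id=str(row["cell"]),
            cdna_pg_ul=float(row["cdna_pg_ul"]),
            mito_fraction=float(row["mito_fraction"]),
            n_genes_detected=int(row["n_genes_detected"]),
            label=str(row.get("label", "unknown")),
        )
        for _, row in frame.iterrows()
    ]


def write_qc_report_json(path, report: QCReport) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "summary": report.summary(),
                "removed": report.removed,
                "kept_cells": report.kept_cells,
                "stage_order": list(report.stage_order),
            },
            indent=1,
        )
    )
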