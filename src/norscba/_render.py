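"""Small table renderers (CSV and markdown) for grids and DataFrames."""

from __future__ import annotations

import csv
from decimal import Decimal

import pandas as pd

from .uncertainty import SensitivityGrid

__all__ = ["grid_to_frame", "grid_to_csv", "grid_to_markdown", "frame_to_markdown"]


def _fmt(cell) -> str:
    if isinstance(cell, tuple):  # (net benefit, ratio) pairs of the two-way grid
        return f"{cell[0]} ({cell[1]})"
    return str(cell)


def grid_to_frame(grid: SensitivityGrid) -> pd.DataFrame:
    frame = pd.DataFrame(
        [[_fmt(c) for c in row] for row in grid.cells],
        index=[str(r) for r in grid.row_axis],
        columns=[str(c) for c in grid.col_axis],
    )
    frame.index.name = grid.row_label
    frame.columns.name = grid.col_label
    return frame


def grid_to_csv(grid: SensitivityGrid, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([grid.row_label] + [str(c) for c in grid.col_axis])
        for r, row in zip(grid.row_axis, grid.cells):
            writer.writerow([str(r)] + [_fmt(c) for c in row])


def frame_to_markdown(frame: pd.DataFrame) -> str:
    table = frame.reset_index()
    headers = [str(c) for c in table.columns]
    body = [[str(v) for v in row] for row in table.itertuples(index=False)]
    widths = [max(len(h), *(len(r[i]) for r in body)) if body else len(h)
              for i, h in enumerate(headers)]
    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    rule = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    return "\n".join([line(headers), rule, *(line(r) for r in body)])


def grid_to_markdown(grid: SensitivityGrid) -> str:
    return frame_to_markdown(grid_to_frame(grid))
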