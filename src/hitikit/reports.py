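"""Report assembly helpers shared by the CLI and analysis drivers."""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import pandas as pd


def percent_reduction(before: float, after: float) -> float:
    """Percent reduction from an initial to a final percentage/value,
    e.g. transduced-cell persistence between two timepoints."""
    if before <= 0:
        raise ValueError("initial value must be positive")
    return 100.0 * (before - after) / before


def rows_to_tsv(rows: Iterable[Mapping], path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")
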