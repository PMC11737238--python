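"""Class- and individual-balanced training data via select-then-bootstrap.

Random forests handle class imbalance poorly, and telemetry datasets are
doubly imbalanced: phases differ in length and individuals differ in fix
counts.  The scheme here equalizes both at once: for every
(individual, phase) cell, draw ``n_select`` steps without replacement, then
draw ``n_select`` steps with replacement from that subset ``n_boot`` times,
yielding exactly ``n_select * n_boot`` rows per cell (1,200 with the
defaults of 10 and 120).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResampleConfig:
    n_select: int = 10
    n_boot: int = 120
    seed: int = 0
    shortfall_policy: str = "error"    # "error" | "top_up"
    two_stage: bool = True

    def __post_init__(self) -> None:
        if self.n_select < 1 or self.n_boot < 1:
            raise ValueError("n_select and n_boot must be >= 1")
        if self.shortfall_policy not in ("error", "top_up"):
            raise ValueError(f"unknown shortfall_policy {self.shortfall_policy!r}")


def resample(rows: pd.DataFrame, cfg: ResampleConfig) -> pd.DataFrame:
    """Balanced bootstrap of the feature table.

    Cells are the (individual_id, phase) groups, processed in sorted order so
    a seed fully determines the output.  With ``two_stage`` (default), each
    cell first contributes ``n_select`` distinct rows, then ``n_boot``
    bootstrap replicates of size ``n_select`` are drawn from that subset;
    the one-stage alternative draws ``n_select * n_boot`` rows with
    replacement from the whole cell.  The ``source_row`` column records the
    index of the originating input row; resampling never fabricates values.

    Raises
    ------
    ValueError
        If a cell holds fewer than ``n_select`` rows and
        ``shortfall_policy="error"`` (the message names the cell).
    """
    rng = np.random.default_rng(cfg.seed)
    target = cfg.n_select * cfg.n_boot
    pieces = []
    for (ind, phase), g in rows.groupby(["individual_id", "phase"], sort=True):
        if len(g) < cfg.n_select:
            if cfg.shortfall_policy == "error":
                raise ValueError(
                    f"cell (individual={ind!r}, phase={phase!r}) has only "
                    f"{len(g)} rows, need >= {cfg.n_select}"
                )
            log.warning(
                "cell (%s, %s): %d < %d rows; topping up with replacement",
                ind, phase, len(g), cfg.n_select,
            )
            selected = rng.choice(g.index.to_numpy(), cfg.n_select, replace=True)
        else:
            selected = rng.choice(g.index.to_numpy(), cfg.n_select, replace=False)
        if cfg.two_stage:
            drawn = rng.choice(selected, size=target, replace=True)
        else:
            drawn = rng.choice(g.index.to_numpy(), size=target, replace=True)
        piece = rows.loc[drawn].copy()
        piece["source_row"] = drawn
        pieces.append(piece)
    if not pieces:
        raise ValueError("no (individual, phase) cells in input")
    return pd.concat(pieces, ignore_index=True)
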