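"""Glioblastoma cellular-state classification (AC/MES/NPC/OPC).

Each cell receives four meta-module scores (astrocyte-like AC, mesenchymal
MES, neural-progenitor NPC, oligodendrocyte-progenitor OPC; the combined
MES score uses the 100-gene union of the MES1 and MES2 sub-modules).  The
scores are projected onto a two-axis "butterfly" plot whose quadrants give
the state: AC-like (x<0, y<0), MES-like (x>0, y<0), NPC-like (x>0, y>0),
OPC-like (x<0, y>0).

Three projection modes are shipped:

* ``corrected`` (default) — y separates the OPC/NPC hemifield from AC/MES
  by D = max(OPC, NPC) - max(AC, MES), with the within-hemifield contrast
  on x; log2(|.|+1) compresses the axes.  This mode realizes the stated
  quadrant semantics for dominant cells.
* ``as_written`` — a published branch/formula pairing kept verbatim for
  audit; it can take log2 of non-positive arguments (flagged as undefined
  cells) and leaves dominant NPC or AC cells on a quadrant boundary.
* ``argmax`` — state is simply the largest of the four scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import anndata as ad
import numpy as np
import pandas as pd

from . import scoring
from .genesets import GeneSetCollection

__all__ = ["meta_module_scores", "project_2d", "composition", "StateAssignment"]

STATES = ("AC-like", "MES-like", "NPC-like", "OPC-like")
STATE_SETS = ("AC", "MES", "MES1", "MES2", "NPC", "OPC")
MODES = ("corrected", "as_written", "argmax")


def meta_module_scores(
    adata: ad.AnnData,
    gene_sets: GeneSetCollection,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell AC/MES/MES1/MES2/NPC/OPC module scores.

    The combined MES score is computed from the ``MES`` set (the 100-gene
    MES1+MES2 union) when present, else from the concatenated sub-lists.
    """
    missing = [s for s in ("AC", "MES1", "MES2", "NPC", "OPC") if s not in gene_sets]
    if missing:
        raise KeyError(f"missing state gene sets: {missing}")
    out = {}
    for i, name in enumerate(STATE_SETS):
        if name == "MES" and "MES" not in gene_sets:
            genes: Iterable[str] = list(gene_sets["MES1"]) + list(gene_sets["MES2"])
        else:
            genes = gene_sets[name]
        # distinct control draws per set, all reproducible from the seed
        out[name] = scoring.module_score(
            adata, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + i
        )
    return pd.DataFrame(out, index=adata.obs_names)


@dataclass
class StateAssignment:
    """Result of the two-axis projection: per-cell x, y, state and flags."""

    table: pd.DataFrame  # columns: x, y, state, undefined, boundary
    mode: str

    @property
    def classified(self) -> pd.DataFrame:
        return self.table[~self.table["undefined"]]

    def counts(self) -> dict[str, int]:
        return {
            "classified": int((~self.table["undefined"]).sum()),
            "undefined": int(self.table["undefined"].sum()),
            "boundary": int(self.table["boundary"].sum()),
            "total": len(self.table),
        }


def _signed_log2(d: np.ndarray) -> np.ndarray:
    return np.sign(d) * np.log2(np.abs(d) + 1.0)


def _quadrant_state(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    state = np.full(len(x), "", dtype=object)
    state[(x < 0) & (y < 0)] = "AC-like"
    state[(x > 0) & (y < 0)] = "MES-like"
    state[(x > 0) & (y > 0)] = "NPC-like"
    state[(x < 0) & (y > 0)] = "OPC-like"
    return state


def project_2d(scores: pd.DataFrame, mode: str = "corrected") -> StateAssignment:
    """Project four state scores to (x, y) and assign the quadrant state.

    ``scores`` must carry columns AC, MES, NPC, OPC.  Cells landing exactly
    on an axis (x = 0 or y = 0) are assigned by the argmax fallback and
    flagged ``boundary``; in ``as_written`` mode cells whose branch formula
    would take log2 of a non-positive argument are flagged ``undefined``
    and excluded from composition summaries.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    for col in ("AC", "MES", "NPC", "OPC"):
        if col not in scores:
            raise KeyError(f"scores missing column {col!r}")
    acs = scores["AC"].to_numpy(float)
    mes = scores["MES"].to_numpy(float)
    npc = scores["NPC"].to_numpy(float)
    opc = scores["OPC"].to_numpy(float)
    n = len(scores)
    undefined = np.zeros(n, dtype=bool)
    boundary = np.zeros(n, dtype=bool)
    argmax_state = np.array(STATES)[
        np.argmax(np.column_stack([acs, mes, npc, opc]), axis=1)
    ]

    if mode == "argmax":
        x = np.zeros(n)
        y = np.zeros(n)
        state = argmax_state.astype(object)
    elif mode == "corrected":
        d = np.maximum(opc, npc) - np.maximum(acs, mes)
        y = _signed_log2(d)
        x = np.where(d > 0, _signed_log2(npc - opc), _signed_log2(mes - acs))
        state = _quadrant_state(x, y)
    else:  # as_written
        d1 = np.maximum(opc, npc) - np.maximum(acs, mes)
        y_arg = np.where(d1 > 0, (opc - npc) + 1.0, (acs - mes) + 1.0)
        undefined |= y_arg <= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.where(d1 > 0, np.log2(np.maximum(y_arg, 1e-300)),
                         -np.log2(np.maximum(y_arg, 1e-300)))
        d2 = np.maximum(acs, opc) - np.maximum(mes, npc)
        x_arg = np.where(d2 < 0, (acs - opc) + 1.0, (mes - npc) + 1.0)
        undefined |= x_arg <= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(d2 < 0, -np.log2(np.maximum(x_arg, 1e-300)),
                         np.log2(np.maximum(x_arg, 1e-300)))
        x = np.where(undefined, np.nan, x)
        y = np.where(undefined, np.nan, y)
        state = _quadrant_state(np.nan_to_num(x), np.nan_to_num(y))

    if mode != "argmax":
        on_axis = ~undefined & ((x == 0) | (y == 0))
        boundary = on_axis
        if mode == "corrected":
            # exact ties resolved by the dominant score, counted separately
            state = np.where(on_axis, argmax_state, state)
        # as_written keeps boundary cells unassigned: the verbatim rule
        # leaves them outside every quadrant, which is the documented
        # inconsistency of that formulation
    state = np.where(undefined, "", state)

    table = pd.DataFrame(
        {"x": x, "y": y, "state": state, "undefined": undefined, "boundary": boundary},
        index=scores.index,
    )
    return StateAssignment(table=table, mode=mode)


def composition(sa: StateAssignment, meta: pd.DataFrame) -> pd.DataFrame:
    """Per line x condition state proportions over classified cells.

    ``meta`` is indexed like the assignment table with ``line`` and
    ``condition`` columns.  Proportions sum to 1 within each group; empty
    groups are an error.
    """
    tab = sa.table.join(meta[["line", "condition"]])
    tab = tab[(~tab["undefined"]) & (tab["state"] != "")]
    rows = []
    for (line, cond), grp in tab.groupby(["line", "condition"], observed=True):
        if len(grp) == 0:
            raise ValueError(f"empty group {line}/{cond}")
        row = {"line": line, "condition": cond, "n_cells": len(grp)}
        for s in STATES:
            row[s] = float((grp["state"] == s).mean())
        rows.append(row)
    if not rows:
        raise ValueError("no classified cells")
    return pd.DataFrame(rows)
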