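"""Dual-screen substrate nomination from bait-vs-control intensity tables.

Per screen: log2-transform present intensities, average replicates on the
log2 scale, and compute delta = log2(bait) - log2(control), imputing a
missing control at a floor (half the screen's minimum present intensity by
default) so that detected-in-bait / absent-in-control proteins are kept as
maximal evidence.  The cross-validation filter retains proteins identified
in the bait sample of both screens with delta strictly above
log2(threshold_fold) in both.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .synthetic_data import IntensityTable

DEFAULT_FLOOR_FACTOR = 0.5
DEFAULT_THRESHOLD_FOLD = 2.0


def screen_enrichment(
    table: IntensityTable,
    floor_factor: float = DEFAULT_FLOOR_FACTOR,
    require_control_identified: bool = False,
) -> pd.DataFrame:
    """Per-protein bait-over-control log2 enrichment for one screen.

    Returns a frame indexed by protein_id with columns
    ``identified_in_bait``, ``identified_in_control``, ``log2_bait``,
    ``delta``, ``control_imputed``.  ``delta`` is NaN for proteins not
    identified in the bait sample (no enrichment is defined for them); with
    ``require_control_identified`` proteins missing from the control sample
    are likewise excluded instead of floor-imputed.
    """
    bait_cols = table.samples("bait")
    control_cols = table.samples("control")
    if not bait_cols:
        raise ValueError(f"screen {table.screen_id!r} declares no bait sample")
    log2i = np.log2(table.intensities)
    log2_bait = log2i[bait_cols].mean(axis=1, skipna=False)
    log2_ctrl = log2i[control_cols].mean(axis=1, skipna=False)

    in_bait = log2_bait.notna()
    in_ctrl = log2_ctrl.notna()

    floor = np.log2(float(np.nanmin(table.intensities.to_numpy())) * floor_factor)
    imputed = in_bait & ~in_ctrl
    delta = log2_bait - log2_ctrl.where(in_ctrl, floor)
    delta[~in_bait] = np.nan
    if require_control_identified:
        delta[~in_ctrl] = np.nan

    return pd.DataFrame(
        {
            "identified_in_bait": in_bait,
            "identified_in_control": in_ctrl,
            "log2_bait": log2_bait,
            "delta": delta,
            "control_imputed": imputed,
        }
    )


def cross_validate(
    first: pd.DataFrame,
    second: pd.DataFrame,
    threshold_fold: float = DEFAULT_THRESHOLD_FOLD,
    bait_id: str | None = None,
    screen_names: Tuple[str, str] = ("flag", "bioid"),
) -> pd.DataFrame:
    """Join two screen enrichments and apply the dual two-fold filter.

    A protein passes iff it was identified in the bait sample of BOTH
    screens and its delta strictly exceeds log2(threshold_fold) in both.
    The result is sorted by min(delta_first, delta_second) descending; the
    bait protein is flagged (``is_bait``) and never counted as a candidate.
    """
    if threshold_fold <= 0:
        raise ValueError("threshold_fold must be > 0")
    shared = first.index.union(second.index)
    if first.index.intersection(second.index).empty:
        raise ValueError("screens share no protein identifiers")
    a, b = screen_names
    out = pd.DataFrame(index=shared)
    out.index.name = "protein_id"
    for name, enr in ((a, first), (b, second)):
        out[f"delta_{name}"] = enr["delta"].reindex(shared)
        out[f"identified_{name}"] = (
            enr["identified_in_bait"].reindex(shared).fillna(False).astype(bool)
        )
    cut = np.log2(threshold_fold)
    passes = (
        out[f"identified_{a}"]
        & out[f"identified_{b}"]
        & (out[f"delta_{a}"] > cut)
        & (out[f"delta_{b}"] > cut)
    )
    out["is_bait"] = out.index == bait_id if bait_id is not None else False
    out["passes"] = passes & ~out["is_bait"]
    out["min_delta"] = out[[f"delta_{a}", f"delta_{b}"]].min(axis=1)
    return out.sort_values("min_delta", ascending=False, kind="mergesort")


def scatter_export(
    enrichment: pd.DataFrame,
    xval: pd.DataFrame,
    path,
    threshold_fold: float = DEFAULT_THRESHOLD_FOLD,
    plot_path=None,
) -> pd.DataFrame:
    """Export the per-screen scatter (x = log2 bait intensity, y = delta)
    with cross-validation flags; optionally render the figure with the
    two-fold cutoff line."""
    cut = float(np.log2(threshold_fold))
    table = enrichment.loc[
        enrichment["identified_in_bait"], ["log2_bait", "delta"]
    ].copy()
    table["passes"] = xval["passes"].reindex(table.index).fillna(False).astype(bool)
    table["is_bait"] = xval["is_bait"].reindex(table.index).fillna(False).astype(bool)
    table["threshold_log2"] = cut
    table.index.name = "protein_id"
    table.to_csv(path, sep="\t")

    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(table["log2_bait"], table["delta"], s=10, c="grey", label="identified")
        sel = table["passes"]
        ax.scatter(
            table.loc[sel, "log2_bait"], table.loc[sel, "delta"],
            s=14, c="tab:green", label="cross-validated",
        )
        bait = table["is_bait"]
        if bait.any():
            ax.scatter(
                table.loc[bait, "log2_bait"], table.loc[bait, "delta"],
                s=20, c="tab:red", label="bait",
            )
        ax.axhline(cut, color="red", linestyle=":", label=f"{threshold_fold:g}-fold")
        ax.set_xlabel("log2 bait intensity")
        ax.set_ylabel("log2 bait / control")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return table


# ---------------------------------------------------------------------------
# TSV I/O: long-format intensities + sample sheet
# ---------------------------------------------------------------------------

def write_intensity_tsv(table: IntensityTable, intensity_path, sample_sheet_path) -> None:
    long = (
        table.intensities.reset_index()
        .melt(id_vars="protein_id", var_name="sample_id", value_name="intensity")
    )
    long.to_csv(intensity_path, sep="\t", index=False)
    sheet = pd.DataFrame(
        {
            "sample_id": list(table.sample_roles),
            "screen_id": table.screen_id,
            "role": [table.sample_roles[s] for s in table.sample_roles],
        }
    )
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_intensity_tsv(intensity_path, sample_sheet_path) -> IntensityTable:
    long = pd.read_csv(intensity_path, sep="\t")
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    screen_ids = sheet["screen_id"].unique()
    if len(screen_ids) != 1:
        raise ValueError(f"sample sheet must declare exactly one screen_id, got {list(screen_ids)}")
    wide = long.pivot(index="protein_id", columns="sample_id", values="intensity")
    wide = wide.reindex(long["protein_id"].drop_duplicates())
    wide = wide[list(sheet["sample_id"])]
    wide.columns.name = None
    roles = dict(zip(sheet["sample_id"], sheet["role"]))
    return IntensityTable(str(screen_ids[0]), wide, roles)
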