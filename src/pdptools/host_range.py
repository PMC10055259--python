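"""Liquid-culture host-range scoring from 96-well growth curves.

A fixed phage dose is added to exponential-phase cultures of each candidate
host and optical density (OD660) is followed in a plate reader.  The liquid
assay score (LAS) of a phage-host pair is the mean area under the infected
growth curve expressed as a percentage of the mean area under the host's
phage-free control curve on the same plate: 100 means no inhibition, values
near 0 mean complete growth suppression.  Scores are assembled into a
phage x host matrix whose rows and columns can be ordered by supplied
phylogenies (Newick).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellRole",
    "WellCondition",
    "PlateLayout",
    "GrowthCurveSet",
    "HostRangeMatrix",
    "auc_trapezoid",
    "liquid_assay_score",
    "score_matrix",
    "leaf_order",
    "order_matrix_by_trees",
    "read_growth_curves",
    "write_growth_curves",
    "read_layout",
    "write_layout",
]


class WellRole(str, enum.Enum):
    INFECTED = "infected"
    PHAGE_FREE_CONTROL = "phage_free_control"
    CELL_FREE_BLANK = "cell_free_blank"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class WellCondition:
    """What one well contains: host strain, phage (or None), replicate, role."""

    host: str | None
    phage: str | None
    replicate: int
    role: WellRole


@dataclass
class PlateLayout:
    """Mapping from well id (e.g. ``A1``) to its condition.

    Invariant: every host appearing in an infected well also has at least
    one phage-free control well.
    """

    wells: dict[str, WellCondition]

    def __post_init__(self) -> None:
        if len(self.wells) > 96:
            raise ValueError("a plate holds at most 96 wells")
        missing = self.hosts_missing_controls()
        if missing:
            raise ValueError(
                f"hosts with infected wells but no phage-free control: {sorted(missing)}"
            )

    def hosts_missing_controls(self) -> set[str]:
        infected_hosts = {
            c.host for c in self.wells.values() if c.role == WellRole.INFECTED and c.host
        }
        control_hosts = {
            c.host
            for c in self.wells.values()
            if c.role == WellRole.PHAGE_FREE_CONTROL and c.host
        }
        return infected_hosts - control_hosts

    def wells_for(self, role: WellRole, host: str | None = None, phage: str | None = None
                  ) -> list[str]:
        out = []
        for well, c in self.wells.items():
            if c.role != role:
                continue
            if host is not None and c.host != host:
                continue
            if phage is not None and c.phage != phage:
                continue
            out.append(well)
        return out


def make_standard_layout(
    hosts: Sequence[str], phages: Sequence[str], replicates: int = 3, n_blanks: int = 3
) -> PlateLayout:
    """Build a layout in the standard design: per host, a phage-free control
    and each phage condition in triplicate, plus shared cell-free blanks."""
    wells: dict[str, WellCondition] = {}
    rows = "ABCDEFGH"

    def well_id(i: int) -> str:
        return f"{rows[i // 12]}{i % 12 + 1}"

    i = 0
    for host in hosts:
        for rep in range(1, replicates + 1):
            wells[well_id(i)] = WellCondition(host, None, rep, WellRole.PHAGE_FREE_CONTROL)
            i += 1
        for phage in phages:
            for rep in range(1, replicates + 1):
                wells[well_id(i)] = WellCondition(host, phage, rep, WellRole.INFECTED)
                i += 1
    for rep in range(1, n_blanks + 1):
        wells[well_id(i)] = WellCondition(None, None, rep, WellRole.CELL_FREE_BLANK)
        i += 1
    if i > 96:
        raise ValueError(f"layout needs {i} wells; a plate holds 96")
    return PlateLayout(wells=wells)


@dataclass
class GrowthCurveSet:
    """OD time-series for every well of one plate, on a shared time grid.

    ``od`` is a frame indexed by time in minutes with one column per well.
    """

    timepoints: np.ndarray
    od: pd.DataFrame
    layout: PlateLayout

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if len(self.od) != len(self.timepoints):
            raise ValueError("OD table and time grid differ in length")
        if not np.all(np.isfinite(self.od.to_numpy(dtype=float))):
            raise ValueError("OD readings contain non-finite values")
        unknown = set(self.od.columns) - set(self.layout.wells)
        if unknown:
            raise ValueError(f"wells absent from layout: {sorted(unknown)}")


@dataclass
class HostRangeMatrix:
    """Phage x host liquid-assay-score grid (percent); NaN marks pairs with
    no data (masked, distinct from a true score of 0)."""

    scores: pd.DataFrame  # index = phages, columns = hosts
    unplaced_rows: list[str] = field(default_factory=list)
    unplaced_cols: list[str] = field(default_factory=list)

    @property
    def phages(self) -> list[str]:
        return list(self.scores.index)

    @property
    def hosts(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# AUC and the score
# ---------------------------------------------------------------------------

def auc_trapezoid(
    times_min: np.ndarray,
    readings: np.ndarray,
    blank: float | np.ndarray = 0.0,
) -> float:
    """Blank-subtracted trapezoidal area under a growth curve, in OD*hours.

    The blank (a constant or a per-timepoint curve on the same grid) is
    subtracted pointwise and negative values are floored at zero before
    integration over the full time window.
    """
    times = np.asarray(times_min, dtype=float)
    y = np.asarray(readings, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two timepoints")
    if y.shape != times.shape:
        raise ValueError("readings and time grid differ in shape")
    blank_arr = np.asarray(blank, dtype=float)
    if blank_arr.ndim > 0 and blank_arr.shape != times.shape:
        raise ValueError("blank curve is not on the same time grid")
    corrected = np.maximum(y - blank_arr, 0.0)
    return float(np.trapezoid(corrected, times / 60.0))


def liquid_assay_score(
    infected_aucs: Iterable[float], control_aucs: Iterable[float]
) -> float:
    """LAS = 100 * mean(infected AUCs) / mean(phage-free control AUCs).

    Values above 100 (noise, or growth enhancement) are reported as-is.
    """
    infected = np.asarray(list(infected_aucs), dtype=float)
    control = np.asarray(list(control_aucs), dtype=float)
    if infected.size == 0 or control.size == 0:
        raise ValueError("need at least one AUC in each group")
    control_mean = control.mean()
    if control_mean <= 0:
        raise ValueError("phage-free control mean AUC must be positive")
    return float(100.0 * infected.mean() / control_mean)


def score_matrix(curves: GrowthCurveSet) -> HostRangeMatrix:
    """Compute one LAS per (phage, host) pair present in the layout.

    The per-timepoint mean of the plate's cell-free blanks is subtracted
    from every curve before integration (zero if the plate has no blanks);
    each host's score uses that host's own phage-free controls.  Pairs with
    no infected wells are left masked (NaN).
    """
    layout = curves.layout
    times = curves.timepoints

    blank_wells = layout.wells_for(WellRole.CELL_FREE_BLANK)
    if blank_wells:
        blank_curve = curves.od[blank_wells].to_numpy(dtype=float).mean(axis=1)
    else:
        blank_curve = np.zeros_like(times)

    def well_auc(well: str) -> float:
        return auc_trapezoid(times, curves.od[well].to_numpy(dtype=float), blank_curve)

    hosts: list[str] = []
    phages: list[str] = []
    for c in layout.wells.values():
        if c.role == WellRole.INFECTED:
            if c.host not in hosts:
                hosts.append(c.host)
            if c.phage not in phages:
                phages.append(c.phage)

    control_aucs: dict[str, list[float]] = {}
    for host in hosts:
        wells = [w for w in layout.wells_for(WellRole.PHAGE_FREE_CONTROL, host=host)
                 if w in curves.od.columns]
        if not wells:
            bad = layout.wells_for(WellRole.INFECTED, host=host)
            raise ValueError(
                f"host {host!r} (infected wells {bad}) has no measured phage-free control"
            )
        control_aucs[host] = [well_auc(w) for w in wells]

    grid = pd.DataFrame(np.nan, index=phages, columns=hosts, dtype=float)
    for phage in phages:
        for host in hosts:
            wells = [w for w in layout.wells_for(WellRole.INFECTED, host=host, phage=phage)
                     if w in curves.od.columns]
            if not wells:
                continue
            infected = [well_auc(w) for w in wells]
            grid.loc[phage, host] = liquid_assay_score(infected, control_aucs[host])
    return HostRangeMatrix(scores=grid)


# ---------------------------------------------------------------------------
# tree-based ordering
# ---------------------------------------------------------------------------

def leaf_order(newick: str) -> list[str]:
    """Leaf labels of a Newick tree in depth-first left-to-right order, as
    written in the string."""
    import dendropy

    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"could not parse Newick tree: {exc}") from exc
    labels = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if not label:
            raise ValueError("tree contains a leaf with an empty label")
        labels.append(label)
    if len(set(labels)) != len(labels):
        raise ValueError("tree contains duplicate leaf labels")
    return labels


def order_matrix_by_trees(
    matrix: HostRangeMatrix,
    phage_tree: str | None = None,
    host_tree: str | None = None,
) -> HostRangeMatrix:
    """Reorder rows/columns to follow the leaf order of the supplied trees.

    Values are only permuted, never changed.  Labels present in the matrix
    but absent from a tree are appended after the tree-ordered labels in
    their original order and reported in ``unplaced_rows``/``unplaced_cols``.
    Tree leaves without a matrix row/column are ignored.
    """

    def resolve(labels: list[str], newick: str | None) -> tuple[list[str], list[str]]:
        if newick is None:
            return labels, []
        order = leaf_order(newick)
        placed = [x for x in order if x in labels]
        unplaced = [x for x in labels if x not in set(order)]
        return placed + unplaced, unplaced

    row_order, unplaced_rows = resolve(matrix.phages, phage_tree)
    col_order, unplaced_cols = resolve(matrix.hosts, host_tree)
    return HostRangeMatrix(
        scores=matrix.scores.loc[row_order, col_order],
        unplaced_rows=unplaced_rows,
        unplaced_cols=unplaced_cols,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_growth_curves(curves: GrowthCurveSet, path: str | Path) -> None:
    """Write curves as long-format CSV (well, minute, od)."""
    long = (
        curves.od.assign(minute=curves.timepoints)
        .melt(id_vars="minute", var_name="well", value_name="od")
        [["well", "minute", "od"]]
    )
    long.to_csv(path, index=False)


def read_growth_curves(path: str | Path, layout: PlateLayout) -> GrowthCurveSet:
    """Read long-format (well, minute, od) CSV back into a GrowthCurveSet."""
    long = pd.read_csv(path)
    wide = long.pivot(index="minute", columns="well", values="od").sort_index()
    return GrowthCurveSet(
        timepoints=wide.index.to_numpy(dtype=float),
        od=wide.reset_index(drop=True),
        layout=layout,
    )


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    rows = [
        {
            "well": well,
            "host": c.host or "",
            "phage": c.phage or "",
            "replicate": c.replicate,
            "role": c.role.value,
        }
        for well, c in layout.wells.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_layout(path: str | Path) -> PlateLayout:
    frame = pd.read_csv(path, dtype={"well": str, "host": str, "phage": str})
    wells = {}
    for _, row in frame.iterrows():
        host = row["host"] if isinstance(row["host"], str) and row["host"] else None
        phage = row["phage"] if isinstance(row["phage"], str) and row["phage"] else None
        wells[row["well"]] = WellCondition(
            host=host, phage=phage, replicate=int(row["replicate"]),
            role=WellRole(row["role"]),
        )
    return PlateLayout(wells=wells)


def write_matrix(matrix: HostRangeMatrix, out_dir: str | Path) -> None:
    """Write the score matrix CSV (empty cell = masked) and an ordered-label
    sidecar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix.scores.to_csv(out_dir / "las_matrix.csv")
    sidecar = {
        "phage_order": matrix.phages,
        "host_order": matrix.hosts,
        "unplaced_phages": matrix.unplaced_rows,
        "unplaced_hosts": matrix.unplaced_cols,
    }
    (out_dir / "las_order.json").write_text(json.dumps(sidecar, indent=2))
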