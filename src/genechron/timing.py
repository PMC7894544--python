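"""Temporal aggregation of reconciliation output.

Reconciliation places each event in a feasible time interval (a slice of the
chronogram crossed with a species branch); the reported event date is the
interval midpoint.  This module turns per-gene event lists into the headline
summaries of such an analysis:

* gene-birth interval tables — the birth of a gene family is bracketed by
  the chronogram nodes above and below its host branch, reported with their
  95% credible intervals, the midpoint date, and the geologic era containing
  the midpoint;
* era assignment against a configurable geologic-era table (defaults follow
  the international chronostratigraphic chart);
* event-density tables binning event midpoints through time, overall and for
  horizontal transfers alone, with genes ordered by their earliest event.

Reported dates are rounded half-even to two decimals.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .reconcile import ReconciliationResult
from .trees import DatedTree

__all__ = [
    "Era",
    "EraTable",
    "DEFAULT_ERAS",
    "event_midpoint",
    "assign_era",
    "birth_interval_table",
    "compile_birth_intervals",
    "event_density",
    "plot_event_density",
]


@dataclasses.dataclass(frozen=True)
class Era:
    name: str
    older: float     # Mya, inclusive
    younger: float   # Mya, exclusive


@dataclasses.dataclass
class EraTable:
    """Ordered geologic eras; each era covers the half-open interval
    (younger, older], so a boundary age belongs to the older era."""

    eras: list[Era]

    def __post_init__(self) -> None:
        for a, b in zip(self.eras, self.eras[1:]):
            if abs(a.younger - b.older) > 1e-9:
                raise ValueError(
                    f"eras must be contiguous: {a.name} ends at {a.younger}, "
                    f"{b.name} starts at {b.older}"
                )
            if a.older <= a.younger:
                raise ValueError(f"era {a.name} has nonpositive span")

    @property
    def older_bound(self) -> float:
        return self.eras[0].older

    @property
    def younger_bound(self) -> float:
        return self.eras[-1].younger

    @classmethod
    def from_mapping(cls, rows: Iterable[tuple[str, float, float]]) -> "EraTable":
        return cls([Era(n, o, y) for n, o, y in rows])


DEFAULT_ERAS = EraTable.from_mapping([
    ("Eoarchean", 4000.0, 3600.0),
    ("Paleoarchean", 3600.0, 3200.0),
    ("Mesoarchean", 3200.0, 2800.0),
    ("Neoarchean", 2800.0, 2500.0),
    ("Paleoproterozoic", 2500.0, 1600.0),
    ("Mesoproterozoic", 1600.0, 1000.0),
    ("Neoproterozoic", 1000.0, 541.0),
    ("Phanerozoic", 541.0, 0.0),
])


def _round2(x: float) -> float:
    """Round half-even to two decimals (the convention of the output tables)."""
    return float(round(float(x), 2))


def event_midpoint(older: float, younger: float) -> float:
    """Midpoint of a feasible interval: the reported date of an event that
    could have occurred anywhere between ``older`` and ``younger`` Mya."""
    if younger < 0:
        raise ValueError("ages must be nonnegative")
    if older < younger:
        raise ValueError(f"interval must run older -> younger (got {older} < {younger})")
    return (older + younger) / 2.0


def assign_era(age: float, eras: EraTable = DEFAULT_ERAS) -> str:
    """Name of the era containing ``age``.

    Adjacent eras share exactly one boundary age, assigned to the *older*
    era: an era spanning older..younger Mya holds ages in [younger, older),
    and the oldest era also holds its own older bound.
    """
    if not (eras.younger_bound <= age <= eras.older_bound):
        raise ValueError(
            f"age {age} outside the era table range "
            f"[{eras.younger_bound}, {eras.older_bound}]"
        )
    if age == eras.older_bound:
        return eras.eras[0].name
    for era in eras.eras:
        if era.younger <= age < era.older:
            return era.name
    return eras.eras[-1].name  # unreachable given the range check


BIRTH_COLUMNS = ["gene", "upper", "upper_lo95", "upper_hi95",
                 "lower", "lower_lo95", "lower_hi95", "midpoint", "era"]


def compile_birth_intervals(rows: pd.DataFrame,
                            eras: EraTable = DEFAULT_ERAS) -> pd.DataFrame:
    """Finish a birth-interval table from bounding node dates.

    ``rows`` needs columns ``gene``, ``upper``, ``lower`` (older and younger
    bounding node dates, Mya) and may carry the four credible-interval
    columns.  Adds the midpoint and era, rounds to two decimals, and sorts by
    midpoint descending (oldest birth first).
    """
    out = rows.copy()
    for col in ("upper_lo95", "upper_hi95", "lower_lo95", "lower_hi95"):
        if col not in out.columns:
            out[col] = np.nan
    mids = [event_midpoint(u, l) for u, l in zip(out["upper"], out["lower"])]
    out["midpoint"] = mids
    out["era"] = [assign_era(m, eras) for m in out["midpoint"]]
    for col in ("upper", "upper_lo95", "upper_hi95", "lower", "lower_lo95",
                "lower_hi95", "midpoint"):
        out[col] = out[col].map(lambda v: _round2(v) if pd.notna(v) else v)
    out = out.sort_values("midpoint", ascending=False, kind="mergesort")
    return out[BIRTH_COLUMNS].reset_index(drop=True)


def birth_interval_table(results: Mapping[str, ReconciliationResult],
                         chronogram: DatedTree,
                         node_table: Optional[pd.DataFrame] = None,
                         eras: EraTable = DEFAULT_ERAS,
                         warn=print) -> pd.DataFrame:
    """Birth-interval table for each gene's BIRTH event.

    The birth is bracketed by the node above its host branch (upper, the
    earliest possible timing) and the node below (lower, the latest).
    Credible intervals come from ``node_table`` (index: node id; columns
    ``mean_age``, ``lo95``, ``hi95``) when given; otherwise the chronogram's
    point ages are used with degenerate intervals.  Genes without a BIRTH
    event are skipped with a warning.
    """

    def node_row(node_id: str) -> tuple[float, float, float]:
        if node_table is not None and node_id in node_table.index:
            r = node_table.loc[node_id]
            return float(r["mean_age"]), float(r["lo95"]), float(r["hi95"])
        age = chronogram.node_by_id(node_id).age
        return float(age), float(age), float(age)

    rows = []
    for gene, res in results.items():
        births = [e for e in res.events if e.event_class == "BIRTH"]
        if not births:
            warn(f"gene {gene}: no BIRTH event; row omitted")
            continue
        birth = births[0]
        if birth.branch == "root":
            root = chronogram.root
            upper = node_row(root.id)
            older_child = max(root.children, key=lambda c: c.age)
            lower = node_row(older_child.id)
        else:
            child = chronogram.node_by_id(birth.branch)
            upper = node_row(child.parent.id)
            lower = node_row(child.id)
        rows.append({
            "gene": gene,
            "upper": upper[0], "upper_lo95": upper[1], "upper_hi95": upper[2],
            "lower": lower[0], "lower_lo95": lower[1], "lower_hi95": lower[2],
        })
    frame = pd.DataFrame(rows, columns=["gene", "upper", "upper_lo95", "upper_hi95",
                                        "lower", "lower_lo95", "lower_hi95"])
    if frame.empty:
        return pd.DataFrame(columns=BIRTH_COLUMNS)
    return compile_birth_intervals(frame, eras)


def event_density(events: pd.DataFrame, bin_width: float = 100.0,
                  classes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Bin event midpoints per gene, overall and for HGT alone.

    ``events`` needs columns ``gene``, ``event_class``, ``midpoint_Mya``.
    Returns one row per (gene, class group, bin) with the event count and the
    within-group proportion, plus ``order_key`` — the gene's earliest (oldest)
    event midpoint, the ordering used when stacking per-gene panels.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if events.empty:
        return pd.DataFrame(columns=["gene", "group", "bin_older", "bin_younger",
                                     "count", "proportion", "order_key"])
    if classes is not None:
        events = events[events["event_class"].isin(classes)]
    top = float(events["midpoint_Mya"].max())
    n_bins = max(1, int(np.ceil(top / bin_width)))
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    rows = []
    for gene, sub in events.groupby("gene", sort=True):
        order_key = float(sub["midpoint_Mya"].max())
        for group, mask in (("all", np.ones(len(sub), dtype=bool)),
                            ("HGT", (sub["event_class"] == "HGT").to_numpy())):
            mids = sub["midpoint_Mya"].to_numpy()[mask]
            counts, _ = np.histogram(mids, bins=edges)
            total = counts.sum()
            for b in range(n_bins):
                rows.append({
                    "gene": gene, "group": group,
                    "bin_older": edges[b + 1], "bin_younger": edges[b],
                    "count": int(counts[b]),
                    "proportion": counts[b] / total if total else 0.0,
                    "order_key": order_key,
                })
    return pd.DataFrame(rows)


def plot_event_density(density: pd.DataFrame, path) -> None:
    """Histogram + kernel-density overlay per gene (all events vs HGT only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = (density[["gene", "order_key"]].drop_duplicates()
             .sort_values("order_key", ascending=False)["gene"].tolist())
    if not genes:
        return
    from scipy import stats as _stats

    fig, axes = plt.subplots(len(genes), 1, figsize=(7, 2.2 * len(genes)),
                             squeeze=False, sharex=True)
    for ax, gene in zip(axes[:, 0], genes):
        sub = density[density["gene"] == gene]
        for group, color in (("all", "tab:blue"), ("HGT", "tab:green")):
            g = sub[sub["group"] == group].sort_values("bin_younger")
            ax.bar(g["bin_younger"], g["proportion"],
                   width=(g["bin_older"] - g["bin_younger"]).to_numpy(),
                   align="edge", alpha=0.45, color=color, label=group)
            # Gaussian kernel-density overlay (rule-of-thumb bandwidth),
            # reconstructed from bin midpoints weighted by counts
            mids = (0.5 * (g["bin_older"] + g["bin_younger"])).to_numpy()
            counts = g["count"].to_numpy(dtype=float)
            if counts.sum() >= 2 and (counts > 0).sum() >= 2:
                sample = np.repeat(mids, counts.astype(int))
                if np.ptp(sample) > 0:
                    kde = _stats.gaussian_kde(sample)
                    width = float((g["bin_older"] - g["bin_younger"]).iloc[0])
                    xs = np.linspace(g["bin_younger"].min(),
                                     g["bin_older"].max(), 200)
                    ax.plot(xs, kde(xs) * width, color=color, lw=1.2)
        ax.set_ylabel(gene, rotation=0, ha="right")
        ax.legend(loc="upper right", fontsize=7)
    axes[-1, 0].set_xlabel("age (Mya)")
    axes[-1, 0].invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
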