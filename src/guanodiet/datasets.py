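"""Diet-matrix treatments built from a filtered MOTU table.

Four treatments of the same underlying detections:

* ``occurrence`` — binary presence/absence, the substrate for the others
* ``wpoo`` — each detection weighted by the inverse of its sample's prey
  richness; global item weights are the average of these over samples
* ``rra`` — relative read abundance, counts normalized per sample
* ``family`` — items collapsed to family (order-level fallback units)
* ``norare`` — items detected in exactly one sample removed

plus the community-vs-small sampling-regime comparison and a taxonomy
composition summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .niche import breadth_comparison
from .read_pipeline import MotuTable, TaxonRecord

__all__ = [
    "DietMatrix",
    "to_occurrence",
    "wpoo_weights",
    "rra_weights",
    "drop_rare_items",
    "collapse_to_family",
    "regime_comparison",
    "composition_summary",
]

TREATMENTS = ("occurrence", "wpoo", "rra", "family_wpoo", "norare_wpoo")


@dataclass
class DietMatrix:
    """Per-sample prey weights under one treatment.

    ``data`` is samples x items. For normalized treatments every sample
    with at least one detected item is a probability vector; occurrence
    entries are 0/1. ``empty_samples`` logs samples with no items left.
    """

    data: pd.DataFrame
    treatment: str
    empty_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("diet weights must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    def richness(self) -> pd.Series:
        """Number of detected items per sample."""
        return (self.data > 0).sum(axis=1)


def _counts_frame(table) -> pd.DataFrame:
    if isinstance(table, MotuTable):
        return table.counts
    return table


def to_occurrence(table) -> DietMatrix:
    """Binarize read counts: weight 1 iff count > 0."""
    counts = _counts_frame(table)
    occ = (counts > 0).astype(int)
    empty = list(occ.index[occ.sum(axis=1) == 0])
    return DietMatrix(data=occ, treatment="occurrence", empty_samples=empty)


def wpoo_weights(occ: DietMatrix) -> tuple[DietMatrix, pd.Series]:
    """Inverse-richness weighted occurrences, plus the global item summary.

    Sample ``k`` with ``n_k`` detected items gives each of them weight
    ``1/n_k``; the global weighted percentage of occurrence of item ``i``
    is the mean of those weights over the samples with at least one item
    (empty samples are excluded from the average and logged).
    """
    if occ.treatment != "occurrence":
        raise ValueError("wpoo_weights expects an occurrence matrix")
    mat = occ.data.to_numpy(dtype=float)
    n_k = mat.sum(axis=1)
    weights = np.zeros_like(mat)
    nonempty = n_k > 0
    weights[nonempty] = mat[nonempty] / n_k[nonempty, None]
    dm = DietMatrix(
        data=pd.DataFrame(weights, index=occ.data.index, columns=occ.data.columns),
        treatment="wpoo",
        empty_samples=list(occ.data.index[~nonempty]),
    )
    n_used = int(nonempty.sum())
    if n_used == 0:
        raise ValueError("no sample with detected items")
    global_wpoo = pd.Series(
        weights[nonempty].sum(axis=0) / n_used, index=occ.data.columns, name="wpoo"
    )
    return dm, global_wpoo


def rra_weights(table) -> DietMatrix:
    """Relative read abundance: counts normalized within each sample."""
    counts = _counts_frame(table).astype(float)
    totals = counts.sum(axis=1)
    empty = list(counts.index[totals == 0])
    safe = totals.replace(0, np.nan)
    data = counts.div(safe, axis=0).fillna(0.0)
    return DietMatrix(data=data, treatment="rra", empty_samples=empty)


def drop_rare_items(occ: DietMatrix) -> tuple[DietMatrix, list[str]]:
    """Remove items detected in exactly one sample (dataset singletons).

    Samples left with no items are retained and flagged, never dropped.
    """
    if occ.treatment != "occurrence":
        raise ValueError("drop_rare_items expects an occurrence matrix")
    detections = (occ.data > 0).sum(axis=0)
    removed = list(detections.index[detections == 1])
    kept = occ.data.drop(columns=removed)
    empty = list(kept.index[kept.sum(axis=1) == 0])
    return DietMatrix(data=kept, treatment="occurrence", empty_samples=empty), removed


def _family_unit(rec: TaxonRecord) -> str:
    if rec.family:
        return rec.family
    if rec.order:
        return f"order:{rec.order}:unresolved"
    raise ValueError(f"item {rec.motu_id} has neither family nor order")


def collapse_to_family(table, taxonomy: dict[str, TaxonRecord]):
    """Aggregate items by family; order-only items form per-order units.

    Accepts a ``MotuTable`` / counts frame (counts are summed) or an
    occurrence ``DietMatrix`` (occurrences are OR-ed). Returns the same
    kind of object it was given.
    """
    is_occ = isinstance(table, DietMatrix)
    frame = table.data if is_occ else _counts_frame(table)
    missing = [c for c in frame.columns if c not in taxonomy]
    if missing:
        raise KeyError(f"taxonomy missing for items: {missing[:5]}")
    units = {col: _family_unit(taxonomy[col]) for col in frame.columns}
    grouped = frame.T.groupby(frame.columns.map(units)).sum().T
    if is_occ:
        grouped = (grouped > 0).astype(int)
        return DietMatrix(
            data=grouped, treatment="occurrence", empty_samples=list(table.empty_samples)
        )
    return grouped


def regime_comparison(occ_by_regime: dict[str, DietMatrix], alpha: float = 0.05) -> dict:
    """Compare sampling regimes (e.g. community vs small replicates).

    For each regime: per-sample richness mean/sd and total (union)
    richness; across regimes: the number of shared items and, when both
    regimes have >= 3 samples, the breadth-comparison cascade applied to
    the richness distributions.
    """
    if len(occ_by_regime) < 2:
        raise ValueError("need at least two regimes")
    per_regime = {}
    item_sets = {}
    for regime, occ in occ_by_regime.items():
        rich = occ.richness()
        detected = occ.data.columns[(occ.data > 0).any(axis=0)]
        item_sets[regime] = set(detected)
        per_regime[regime] = {
            "n_samples": int(len(occ.data)),
            "mean_richness": float(rich.mean()),
            "sd_richness": float(rich.std(ddof=1)) if len(rich) > 1 else float("nan"),
            "total_richness": int(len(detected)),
        }
    names = list(occ_by_regime)
    shared = set.intersection(*item_sets.values())
    union = set.union(*item_sets.values())
    out = {
        "regimes": per_regime,
        "shared_items": len(shared),
        "union_items": len(union),
    }
    if len(names) == 2:
        a = occ_by_regime[names[0]].richness().to_numpy()
        b = occ_by_regime[names[1]].richness().to_numpy()
        # Shapiro is undefined on constant groups; skip the cascade there
        if a.size >= 3 and b.size >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
            res = breadth_comparison(a, b, alpha=alpha)
            out["richness_test"] = {
                "t_variant": res.t_variant,
                "t_p": res.t_p,
                "variance_test": res.variance_test,
                "variance_p": res.variance_p,
            }
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def composition_summary(taxonomy) -> dict:
    """Taxonomic composition of a retained prey list.

    Reports per-class counts and integer-rounded percentages of all
    items, per-order counts and percentages within class Insecta, the
    number of distinct non-empty families and orders, and how many items
    lack a species-level assignment.
    """
    records = list(taxonomy.values()) if isinstance(taxonomy, dict) else list(taxonomy)
    n = len(records)
    if n == 0:
        raise ValueError("empty taxonomy")
    classes = pd.Series([r.class_ for r in records])
    class_counts = classes.value_counts().to_dict()
    class_pct = {c: _round_half_up(100.0 * k / n) for c, k in class_counts.items()}
    insects = [r for r in records if r.class_ == "Insecta"]
    order_counts = pd.Series([r.order for r in insects]).value_counts().to_dict() if insects else {}
    order_pct = {
        o: _round_half_up(100.0 * k / len(insects)) for o, k in order_counts.items()
    }
    unresolved = [r for r in records if not r.species]
    return {
        "n_items": n,
        "class_counts": class_counts,
        "class_pct": class_pct,
        "n_insects": len(insects),
        "insect_order_counts": order_counts,
        "insect_order_pct": order_pct,
        "n_families": len({r.family for r in records if r.family}),
        "n_orders": len({r.order for r in records if r.order}),
        "n_unresolved_species": len(unresolved),
        "pct_unresolved_species": _round_half_up(100.0 * len(unresolved) / n),
    }
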