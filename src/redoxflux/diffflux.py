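"""Differential-flux statistics between two sampled conditions.

For each reaction shared by a reference and an alternative sample set,
the comparison reports the Kolmogorov-Smirnov statistic between the two
flux distributions and the log2 fold change of the sample medians, with
fixed descriptive significance cutoffs (KS >= 0.2 and |log2FC| >= 0.5).
No p-values are computed: the cutoffs are a descriptive screen, not a
hypothesis test, so no multiple-testing correction applies.

Fold changes use absolute medians (|median| + eps) so direction
reversals never produce undefined logarithms; a reversal is reported in
the separate ``sign_flip`` field.  Reactions quiescent in both
conditions (both |medians| < eps) are excluded from significance calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import MetabolicModel, ModelError
from .sampling import FluxSampleSet

__all__ = ["DiffRecord", "PathwayDelta", "ks_statistic", "log2_fold_change",
           "differential_flux_table", "aggregate_by_pathway",
           "KS_CUTOFF", "LOG2FC_CUTOFF"]

KS_CUTOFF = 0.2
LOG2FC_CUTOFF = 0.5
DEFAULT_EPSILON = 1e-6  # mmol gDW^-1 h^-1


@dataclass
class DiffRecord:
    reaction_id: str
    median_ref: float
    median_alt: float
    log2fc: float
    ks: float
    significant: bool
    sign_flip: bool = False
    quiescent: bool = False


@dataclass
class PathwayDelta:
    subsystem: str
    total_flux_change: float  # sum over significant reactions of (median_alt - median_ref)
    n_significant: int


def ks_statistic(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov statistic: the supremum over all
    points of the absolute ECDF difference.  Symmetric in its arguments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ModelError("KS statistic requires nonempty samples")
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, grid, side="right") / xs.size
    cdf_y = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def log2_fold_change(median_ref: float, median_alt: float,
                     epsilon: float = DEFAULT_EPSILON) -> float:
    """log2((|median_alt| + eps) / (|median_ref| + eps)); eps regularizes
    zero medians (both zero -> 0)."""
    if not (math.isfinite(median_ref) and math.isfinite(median_alt)):
        raise ModelError("medians must be finite")
    return math.log2((abs(median_alt) + epsilon) / (abs(median_ref) + epsilon))


def differential_flux_table(
    ref: FluxSampleSet,
    alt: FluxSampleSet,
    epsilon: float = DEFAULT_EPSILON,
    ks_cutoff: float = KS_CUTOFF,
    lfc_cutoff: float = LOG2FC_CUTOFF,
) -> list[DiffRecord]:
    """One :class:`DiffRecord` per reaction shared by both sample sets.

    A reaction is significant when KS >= ``ks_cutoff`` and |log2FC| >=
    ``lfc_cutoff`` and it is not quiescent in both conditions.  When the
    reaction sets differ, the intersection is used with a warning.
    """
    shared = [rid for rid in ref.reaction_ids if rid in set(alt.reaction_ids)]
    if not shared:
        raise ModelError("sample sets share no reactions")
    if len(shared) != len(ref.reaction_ids) or len(shared) != len(alt.reaction_ids):
        warnings.warn("sample sets have different reactions; using the intersection",
                      stacklevel=2)
    records = []
    for rid in shared:
        xr = ref.column(rid)
        xa = alt.column(rid)
        med_r = float(np.median(xr))
        med_a = float(np.median(xa))
        lfc = log2_fold_change(med_r, med_a, epsilon)
        ks = ks_statistic(xr, xa)
        quiescent = abs(med_r) < epsilon and abs(med_a) < epsilon
        significant = (not quiescent) and ks >= ks_cutoff and abs(lfc) >= lfc_cutoff
        records.append(DiffRecord(
            reaction_id=rid, median_ref=med_r, median_alt=med_a,
            log2fc=lfc, ks=ks, significant=significant,
            sign_flip=(med_r * med_a < 0 and not quiescent), quiescent=quiescent,
        ))
    return records


def aggregate_by_pathway(records: list[DiffRecord], model: MetabolicModel) -> list[PathwayDelta]:
    """Total flux change of significant reactions grouped by subsystem,
    sorted by |total change| descending; empty subsystems are labelled
    "unassigned"."""
    totals: dict[str, list[float]] = {}
    for rec in records:
        if not rec.significant:
            continue
        subsystem = "unassigned"
        if model.has_reaction(rec.reaction_id):
            subsystem = model.reaction(rec.reaction_id).subsystem or "unassigned"
        totals.setdefault(subsystem, []).append(rec.median_alt - rec.median_ref)
    deltas = [PathwayDelta(name, float(sum(vals)), len(vals)) for name, vals in totals.items()]
    deltas.sort(key=lambda d: abs(d.total_flux_change), reverse=True)
    return deltas
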