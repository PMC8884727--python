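"""Lineage-bias classification of clones and derived summaries.

A clone's bias class is the set of lineages receiving strictly more than a
threshold fraction (default 10%) of its normalized output, rendered in the
canonical lineage order M, B, E: a clone with >10% of its output in M and
E but not B is "ME"-biased, one above threshold everywhere is the balanced
"MBE", and one above threshold in a single lineage is restricted ("M",
"B", "E").  Auxiliary compartments (dendritic cells, megakaryocyte
progenitors) do not enter the core classification; clones detected only
there get an "<aux>-only" label.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL_ORDER = ("M", "B", "E")
UNCLASSIFIED = "unclassified"


def clone_proportions(row: pd.Series, lineages: Sequence[str] | None = None) -> pd.Series:
    """Per-clone output proportions over the chosen lineages.

    Raises on an all-zero row; callers exclude such clones.
    """
    if lineages is not None:
        row = row[list(lineages)]
    total = float(row.sum())
    if total <= 0:
        raise ValueError("clone has zero output over the chosen lineages")
    return row.astype(float) / total


def classify_clone(
    proportions: Mapping[str, float],
    threshold: float = 0.10,
    order: Sequence[str] = CANONICAL_ORDER,
) -> str:
    """Bias label from output proportions: lineages strictly above threshold.

    Exactly the threshold counts as "under".  An empty member set (possible
    for threshold >= 1/3) yields "unclassified".
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    members = [lin for lin in order if float(proportions[lin]) > threshold]
    return "".join(members) if members else UNCLASSIFIED


def classify_matrix(
    matrix: pd.DataFrame,
    threshold: float = 0.10,
    lineages: Sequence[str] = CANONICAL_ORDER,
) -> pd.Series:
    """Classify every clone of a barcode-by-lineage matrix.

    Clones with zero output over ``lineages`` are excluded from the result.
    """
    labels = {}
    sub = matrix[list(lineages)]
    for bc, row in sub.iterrows():
        if row.sum() <= 0:
            continue
        labels[bc] = classify_clone(clone_proportions(row), threshold, order=lineages)
    return pd.Series(labels, dtype=object, name="clone_class")


def classify_with_auxiliary(
    matrix: pd.DataFrame,
    aux: str,
    threshold: float = 0.10,
    lineages: Sequence[str] = CANONICAL_ORDER,
) -> pd.Series:
    """Classification extended with an "<aux>-only" category.

    Clones with any M/B/E output are classified on M/B/E proportions only
    (the auxiliary compartment never enters the core label); clones with
    zero M/B/E output but positive output in the auxiliary compartment are
    labeled e.g. "DC-only".  Clones zero everywhere are excluded.
    """
    if aux not in matrix.columns:
        raise ValueError(f"auxiliary column {aux!r} absent from matrix")
    labels = {}
    core = matrix[list(lineages)]
    for bc in matrix.index:
        core_sum = float(core.loc[bc].sum())
        if core_sum > 0:
            labels[bc] = classify_clone(clone_proportions(core.loc[bc]), threshold, order=lineages)
        elif float(matrix.loc[bc, aux]) > 0:
            labels[bc] = f"{aux}-only"
    return pd.Series(labels, dtype=object, name="clone_class")


def class_frequencies(classification: pd.Series) -> pd.Series:
    """Percent of classified clones per bias class (sums to 100)."""
    if len(classification) == 0:
        raise ValueError("no classified clones")
    return classification.value_counts(normalize=True) * 100.0


def class_contributions(
    matrix: pd.DataFrame,
    classification: pd.Series,
    lineages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Class-by-lineage percentage contributions.

    A class's contribution to a lineage is the summed normalized output of
    that class's clones in the lineage divided by the lineage total, x100.
    Lineages with zero total are reported as NaN.  Only classified clones
    contribute.
    """
    cols = list(lineages) if lineages is not None else list(matrix.columns)
    sub = matrix.loc[classification.index, cols]
    totals = sub.sum(axis=0)
    by_class = sub.groupby(classification).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = by_class.divide(totals, axis=1) * 100.0
    contrib[by_class.columns[totals <= 0]] = np.nan
    return contrib


#: equilateral-triangle vertices used for ternary plots, unit side
_TRIANGLE = {
    0: np.array([0.0, 0.0]),
    1: np.array([1.0, 0.0]),
    2: np.array([0.5, np.sqrt(3.0) / 2.0]),
}


def ternary_coordinates(
    proportions: Mapping[str, float],
    vertex_order: Sequence[str] = CANONICAL_ORDER,
    size: float | None = None,
) -> tuple[float, float, float | None]:
    """Barycentric map of 3-lineage proportions onto an equilateral triangle.

    The three lineages in ``vertex_order`` sit at the triangle's corners
    (bottom-left, bottom-right, apex).  ``size`` is carried through
    unchanged for plotting (the clone's summed pre-normalization output).
    """
    p = np.array([float(proportions[lin]) for lin in vertex_order])
    if len(p) != 3 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("need nonnegative 3-lineage proportions summing to 1")
    xy = sum(p[i] * _TRIANGLE[i] for i in range(3))
    return float(xy[0]), float(xy[1]), size


def ternary_table(
    matrix: pd.DataFrame,
    lineages: Sequence[str] = CANONICAL_ORDER,
) -> pd.DataFrame:
    """Ternary coordinates + sizes for every clone with output in ``lineages``."""
    rows = []
    sub = matrix[list(lineages)]
    for bc, row in sub.iterrows():
        s = float(row.sum())
        if s <= 0:
            continue
        x, y, _ = ternary_coordinates(clone_proportions(row), vertex_order=lineages)
        rows.append({"barcode": bc, "x": x, "y": y, "size": s})
    return pd.DataFrame(rows).set_index("barcode") if rows else pd.DataFrame(
        columns=["x", "y", "size"]
    )


def compartment_overlap(
    matrix: pd.DataFrame,
    hspc_column: str = "HSPC",
    lineages: Sequence[str] = CANONICAL_ORDER,
) -> dict:
    """Overlap between mature-lineage clones and the progenitor compartment.

    Presence means strictly positive post-QC abundance.  Returns per-clone
    presence flags, the percentage of each mature lineage's barcodes also
    detected in the progenitor compartment (and the reverse), the split of
    each mature lineage's output between progenitor-present and -absent
    clones, and the count of clones detected only in the progenitor
    compartment (reported separately, not folded into lineage totals).
    """
    if hspc_column not in matrix.columns:
        raise ValueError(f"no {hspc_column!r} column in matrix")
    present = matrix[hspc_column] > 0
    mature = matrix[list(lineages)]

    pct_lineage_in_hspc = {}
    for lin in lineages:
        det = mature[lin] > 0
        n = int(det.sum())
        pct_lineage_in_hspc[lin] = 100.0 * float((det & present).sum()) / n if n else np.nan

    hspc_clones = present
    n_hspc = int(hspc_clones.sum())
    in_mature = (mature > 0).any(axis=1)
    pct_hspc_in_mature = (
        100.0 * float((hspc_clones & in_mature).sum()) / n_hspc if n_hspc else np.nan
    )

    split = {}
    for lin in lineages:
        total = float(mature[lin].sum())
        if total <= 0:
            split[lin] = {"present": np.nan, "absent": np.nan}
            continue
        from_present = float(mature.loc[present, lin].sum())
        split[lin] = {
            "present": 100.0 * from_present / total,
            "absent": 100.0 * (total - from_present) / total,
        }

    hspc_only = int((present & ~in_mature).sum())
    return {
        "presence": present,
        "pct_lineage_barcodes_in_hspc": pct_lineage_in_hspc,
        "pct_hspc_barcodes_in_mature": pct_hspc_in_mature,
        "contribution_split": split,
        "n_hspc_only": hspc_only,
    }
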