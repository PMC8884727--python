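"""QC cascade turning raw barcode count tables into per-mouse clone matrices.

The cascade, applied in this fixed order:

1. drop samples with fewer than ``min_reads`` total reads;
2. normalize every retained sample to ``norm_total`` reads (fractional
   values kept, no rounding);
3. merge technical replicates: reject the sample if the Pearson
   correlation between the two replicates (over the union of barcodes
   detected in either) is below ``r_min``; otherwise zero barcodes seen in
   only one replicate and take the entrywise mean;
4. drop merged samples with fewer than ``min_barcodes`` nonzero barcodes;
5. cross-run sharing correction: for mice of one transduction batch
   sequenced on different runs, if barcode sharing across runs exceeds
   sharing within runs, zero low-abundance entries of the cross-run-shared
   barcodes (threshold chosen from a small quantile grid) until it does
   not;
6. assemble one barcode-by-lineage matrix per mouse, excluding mice for
   which any lineage sample failed QC.

Zeroing steps never renormalize, so clone-matrix column sums are at most
``norm_total``.  Every removal is logged in the cascade report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from clonotrace.barcode_extract import CountTable


@dataclass(frozen=True)
class FilterParams:
    min_reads: int = 5000
    norm_total: int = 100_000
    r_min: float = 0.9
    min_barcodes: int = 10
    sharing_correction: bool = True
    quartile_grid: tuple[float, ...] = (0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= 1:
            raise ValueError("r_min must be in (0, 1]")
        if min(self.min_reads, self.min_barcodes, self.norm_total) <= 0:
            raise ValueError("min_reads, min_barcodes and norm_total must be positive")
        if any(not 0 < q < 1 for q in self.quartile_grid):
            raise ValueError("quartile_grid entries must be in (0, 1)")


@dataclass
class CloneMatrix:
    """Per-mouse barcode-by-lineage matrix of normalized abundances."""

    mouse: str
    abundance: pd.DataFrame  # barcodes x lineages, reads per norm_total
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")

    def write(self, path: str | Path) -> None:
        self.abundance.rename_axis("barcode").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path, mouse: str = "") -> "CloneMatrix":
        return cls(mouse=mouse, abundance=pd.read_csv(path, sep="\t", index_col=0))


def filter_min_reads(table: CountTable, params: FilterParams = FilterParams()) -> CountTable:
    """Drop samples whose total read count is below ``min_reads``."""
    sums = table.counts.sum(axis=0)
    keep = sums[sums >= params.min_reads].index
    dropped = [s for s in table.counts.columns if s not in set(keep)]
    out = CountTable(
        counts=table.counts[list(keep)],
        samples=table.samples.loc[table.samples.index.intersection(keep, sort=False)],
        rejected=dict(table.rejected),
    )
    out.samples = table.samples.loc[[s for s in table.samples.index if s in set(keep)]]
    out.dropped_min_reads = dropped  # type: ignore[attr-defined]
    return out


def normalize_total(sample_counts: pd.Series, params: FilterParams = FilterParams()) -> pd.Series:
    """Scale a sample's counts so they sum exactly to ``norm_total``."""
    total = float(sample_counts.sum())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero sample")
    return sample_counts.astype(float) * (params.norm_total / total)


def replicate_consensus(
    rep_a: pd.Series,
    rep_b: pd.Series,
    params: FilterParams = FilterParams(),
) -> tuple[pd.Series | None, dict]:
    """Merge two normalized technical replicates or reject the sample.

    The Pearson correlation is computed on normalized values over the
    union of barcodes detected in either replicate.  Returns (merged,
    info); merged is None when the sample is rejected (r below ``r_min``
    or degenerate zero-variance replicate), and info records r and the
    barcodes zeroed for being detected in only one replicate.
    """
    if not rep_a.index.equals(rep_b.index):
        union = rep_a.index.union(rep_b.index)
        rep_a = rep_a.reindex(union, fill_value=0.0)
        rep_b = rep_b.reindex(union, fill_value=0.0)
    detected = (rep_a > 0) | (rep_b > 0)
    a = rep_a[detected].to_numpy(dtype=float)
    b = rep_b[detected].to_numpy(dtype=float)
    info: dict = {"n_union": int(detected.sum())}
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        info.update(r=np.nan, status="rejected_degenerate")
        return None, info
    r = float(np.corrcoef(a, b)[0, 1])
    info["r"] = r
    if r < params.r_min:
        info["status"] = "rejected_low_r"
        return None, info
    singleton = ((rep_a > 0) ^ (rep_b > 0))
    merged = (rep_a + rep_b) / 2.0
    merged[singleton] = 0.0
    info["status"] = "merged"
    info["n_singleton_zeroed"] = int(singleton.sum())
    return merged, info


def filter_min_barcodes(merged: pd.Series, params: FilterParams = FilterParams()) -> bool:
    """True iff the merged sample has at least ``min_barcodes`` nonzero barcodes."""
    return int((merged > 0).sum()) >= params.min_barcodes


def _presence_sets(samples: Mapping[tuple[str, str], pd.Series]) -> dict[str, set[str]]:
    """Barcode presence set per mouse (nonzero in any of its samples)."""
    sets: dict[str, set[str]] = {}
    for (mouse, _lin), vec in samples.items():
        sets.setdefault(mouse, set()).update(vec.index[vec > 0])
    return sets


def _pair_sharing(b1: set[str], b2: set[str]) -> float:
    """Percent barcodes shared between two mice (mean of both directions)."""
    if not b1 or not b2:
        return 0.0
    inter = len(b1 & b2)
    return 100.0 * 0.5 * (inter / len(b1) + inter / len(b2))


def _sharing_stats(
    presence: Mapping[str, set[str]], run_of: Mapping[str, str]
) -> tuple[float | None, float | None]:
    """(within-run, cross-run) mean pairwise sharing over one batch's mice."""
    within, cross = [], []
    for m1, m2 in combinations(sorted(presence), 2):
        s = _pair_sharing(presence[m1], presence[m2])
        (within if run_of[m1] == run_of[m2] else cross).append(s)
    w = float(np.mean(within)) if within else None
    c = float(np.mean(cross)) if cross else None
    return w, c


def equalize_run_sharing(
    samples: dict[tuple[str, str], pd.Series],
    meta: pd.DataFrame,
    params: FilterParams = FilterParams(),
) -> tuple[dict[tuple[str, str], pd.Series], dict]:
    """Equalize cross-run barcode sharing to within-run sharing per batch.

    ``samples`` maps (mouse, lineage) to merged normalized vectors; ``meta``
    gives each mouse's sequencing run and transduction batch (columns
    "mouse", "run", "batch"; one row per mouse or per sample).  For every
    batch whose mice span several runs, if the mean pairwise percentage of
    barcodes shared between mice sequenced on different runs exceeds the
    within-run mean, entries of those cross-run-shared barcodes that fall
    below an abundance threshold are zeroed; the threshold is the smallest
    quantile on ``quartile_grid`` (taken over all nonzero abundances of the
    batch's samples) that brings cross-run sharing down to within-run
    sharing.  A batch with no within-run pair is held to a baseline of
    zero sharing.  Returns adjusted samples and a per-batch report.
    """
    for col in ("mouse", "run", "batch"):
        if col not in meta.columns:
            raise ValueError(f"run/batch metadata missing column {col!r}")
    mouse_meta = meta.drop_duplicates("mouse").set_index("mouse")
    run_of = mouse_meta["run"].astype(str).to_dict()
    batch_of = mouse_meta["batch"].astype(str).to_dict()

    out = {k: v.copy() for k, v in samples.items()}
    report: dict = {"batches": {}}
    mice_present = sorted({m for (m, _l) in samples})
    for m in mice_present:
        if m not in run_of:
            raise ValueError(f"mouse {m!r} absent from run/batch metadata")

    by_batch: dict[str, list[str]] = {}
    for m in mice_present:
        by_batch.setdefault(batch_of[m], []).append(m)

    for batch, mice in by_batch.items():
        runs = {run_of[m] for m in mice}
        entry: dict = {"mice": mice, "runs": sorted(runs)}
        if len(mice) < 2 or len(runs) < 2:
            entry["status"] = "no_op"
            report["batches"][batch] = entry
            continue
        batch_keys = [k for k in out if k[0] in set(mice)]
        presence = _presence_sets({k: out[k] for k in batch_keys})
        within, cross = _sharing_stats(presence, run_of)
        w0 = 0.0 if within is None else within
        entry["within_before"] = w0
        entry["cross_before"] = cross
        if cross is None or cross <= w0:
            entry["status"] = "no_op"
            report["batches"][batch] = entry
            continue

        shared: set[str] = set()
        for m1, m2 in combinations(sorted(presence), 2):
            if run_of[m1] != run_of[m2]:
                shared |= presence[m1] & presence[m2]
        pooled = np.concatenate(
            [out[k][out[k] > 0].to_numpy(dtype=float) for k in batch_keys]
        )
        applied = None
        for q in sorted(params.quartile_grid):
            thr = float(np.quantile(pooled, q))
            trial = {}
            for k in batch_keys:
                v = out[k].copy()
                mask = v.index.isin(shared) & (v < thr) & (v > 0)
                v[mask] = 0.0
                trial[k] = v
            p2 = _presence_sets(trial)
            w2, c2 = _sharing_stats(p2, run_of)
            w2 = 0.0 if w2 is None else w2
            if c2 is None or c2 <= w2:
                applied = (q, thr, trial, w2, c2)
                break
        if applied is None:
            # largest grid quantile as a best effort, logged
            q = max(params.quartile_grid)
            thr = float(np.quantile(pooled, q))
            trial = {}
            for k in batch_keys:
                v = out[k].copy()
                mask = v.index.isin(shared) & (v < thr) & (v > 0)
                v[mask] = 0.0
                trial[k] = v
            p2 = _presence_sets(trial)
            w2, c2 = _sharing_stats(p2, run_of)
            applied = (q, thr, trial, 0.0 if w2 is None else w2, c2)
            entry["warning"] = "no grid quantile equalized sharing; largest applied"
        q, thr, trial, w2, c2 = applied
        n_zeroed = sum(
            int(((out[k] > 0) & (trial[k] == 0)).sum()) for k in batch_keys
        )
        zeroed_barcodes = sorted(
            set().union(
                *[set(out[k].index[(out[k] > 0) & (trial[k] == 0)]) for k in batch_keys]
            )
        )
        for k in batch_keys:
            out[k] = trial[k]
        entry.update(
            status="corrected",
            quantile=q,
            threshold=thr,
            within_after=w2,
            cross_after=c2,
            n_entries_zeroed=n_zeroed,
            zeroed_barcodes=zeroed_barcodes,
        )
        report["batches"][batch] = entry
    return out, report


def build_clone_matrix(
    mouse: str,
    lineage_vectors: Mapping[str, pd.Series],
    log: list[str] | None = None,
) -> CloneMatrix:
    """Assemble a mouse's lineage vectors into a barcode-by-lineage matrix.

    Barcodes zero across all lineages are dropped.  Raises if no lineage
    vector is supplied (the mouse is then excluded upstream).
    """
    if not lineage_vectors:
        raise ValueError(f"no surviving samples for mouse {mouse!r}")
    df = pd.DataFrame(lineage_vectors).fillna(0.0)
    df = df.loc[df.sum(axis=1) > 0]
    return CloneMatrix(mouse=mouse, abundance=df, log=list(log or []))


def run_cascade(
    table: CountTable,
    params: FilterParams = FilterParams(),
) -> tuple[dict[str, CloneMatrix], dict]:
    """Apply the full QC cascade and return per-mouse clone matrices + report.

    A mouse is excluded if any lineage sample present in the input sample
    sheet fails a QC step, mirroring the exclusion of animals with failing
    subset samples.
    """
    report: dict = {"params": params.__dict__ | {"quartile_grid": list(params.quartile_grid)}}

    # 1. minimum read depth
    t1 = filter_min_reads(table, params)
    report["min_reads_dropped"] = getattr(t1, "dropped_min_reads", [])

    # 2. normalization
    normalized: dict[str, pd.Series] = {
        s: normalize_total(t1.counts[s], params) for s in t1.counts.columns
    }

    # 3. replicate consensus per (mouse, lineage)
    meta = table.samples
    pairs: dict[tuple[str, str], dict[str, str]] = {}
    for sid, row in meta.iterrows():
        pairs.setdefault((str(row["mouse"]), str(row["lineage"])), {})[str(row["replicate"])] = str(sid)
    merged: dict[tuple[str, str], pd.Series] = {}
    rep_report: dict[str, dict] = {}
    for key, reps in sorted(pairs.items()):
        name = f"{key[0]}/{key[1]}"
        have = [r for r in ("A", "B") if reps.get(r) in normalized]
        if len(have) < 2:
            rep_report[name] = {"status": "rejected_missing_replicate", "present": have}
            continue
        m, info = replicate_consensus(normalized[reps["A"]], normalized[reps["B"]], params)
        rep_report[name] = info
        if m is not None:
            merged[key] = m
    report["replicates"] = rep_report

    # 4. minimum barcode count
    min_bc_dropped = []
    for key in list(merged):
        if not filter_min_barcodes(merged[key], params):
            min_bc_dropped.append(f"{key[0]}/{key[1]}")
            del merged[key]
    report["min_barcodes_dropped"] = min_bc_dropped

    # 5. cross-run sharing correction
    if params.sharing_correction and merged:
        mouse_meta = meta.reset_index()[["mouse", "run", "batch"]]
        merged, sharing_report = equalize_run_sharing(merged, mouse_meta, params)
        report["sharing"] = sharing_report
    else:
        report["sharing"] = {"batches": {}}

    # 6. per-mouse assembly with whole-mouse exclusion
    # lineage order preserved from the sample sheet
    expected: dict[str, list[str]] = {}
    for _sid, row in meta.iterrows():
        lins = expected.setdefault(str(row["mouse"]), [])
        if str(row["lineage"]) not in lins:
            lins.append(str(row["lineage"]))
    matrices: dict[str, CloneMatrix] = {}
    excluded = []
    for mouse, lineages in sorted(expected.items()):
        surviving = {lin: merged[(mouse, lin)] for lin in lineages if (mouse, lin) in merged}
        if len(surviving) != len(lineages):
            missing = sorted(set(lineages) - set(surviving))
            excluded.append({"mouse": mouse, "failed_lineages": missing})
            continue
        log = [f"lineages: {list(lineages)}"]
        matrices[mouse] = build_clone_matrix(mouse, surviving, log=log)
    report["excluded_mice"] = excluded
    return matrices, report
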