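"""Synthetic barcoding and single-cell datasets with ground-truth ledgers.

The clonal generator emulates a transplantation cohort: mice carrying
uniquely barcoded clones, each clone belonging to a lineage-bias class
(balanced MBE, biased ME/MB/BE, restricted M/B/E) with true lineage-output
weights drawn around the class profile; per mouse-by-lineage sample, reads
are drawn multinomially at a sequencing depth and split into two technical
replicates; optional cross-sequencing-run contamination plants low-read
spill-in barcodes between mice of the same transduction batch.  The
expression generator emulates a control-vs-EPO single-cell experiment with
a planted responder subpopulation carrying up-/down-shifted gene programs.
Every generated barcode, read total and cell is recorded in a
:class:`SyntheticTruth` ledger so downstream stages can be checked against
known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from clonotrace.barcode_extract import BarcodeReference

DEFAULT_LINEAGES = ("M", "B", "E")

#: default clone-class mixture; qualitatively mirrors an unperturbed cohort
#: in which balanced clones dominate and restricted clones are rare
DEFAULT_CLASS_MIXTURE = {"MBE": 0.40, "ME": 0.20, "MB": 0.20, "E": 0.10, "M": 0.05, "B": 0.05}

_BASES = np.array(list("ACGT"))


@dataclass
class ExperimentDesign:
    """Design of a synthetic barcoding cohort.

    Defaults reflect a typical cohort of this kind of study: two treatment
    groups of a few mice each, roughly a hundred engrafting clones per
    mouse, M/B/E lineages read out at an amplicon depth of 1e5 reads per
    sample split into two technical replicates.
    """

    groups: tuple[str, ...] = ("control", "EPO")
    n_mice_per_group: int = 5
    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    n_clones_per_mouse: int = 100
    class_mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE))
    class_profiles: Mapping[str, Sequence[float]] | None = None
    #: total Dirichlet concentration for clone weights around the class
    #: profile; None draws weights equal to the profile (no weight noise)
    weight_concentration: float | None = 50.0
    #: lognormal sigma of relative clone sizes within a mouse (0 = equal)
    clone_size_sigma: float = 0.75
    depth_per_sample: int = 100_000
    #: beta-binomial overdispersion of the replicate split in [0, 1);
    #: 0 is a pure binomial half-half split
    replicate_overdispersion: float = 0.0
    #: fraction (of n_clones_per_mouse) of low-read spill-in barcodes per
    #: sample, sourced from same-batch mice sequenced on other runs
    contamination_rate: float = 0.02
    n_runs: int = 1
    n_batches: int = 1
    run_assignment: Mapping[str, str] | None = None
    batch_assignment: Mapping[str, str] | None = None
    #: None draws Poisson sample totals and multinomial counts; "expected"
    #: places rounded expected counts instead (the noise-free limit)
    sampling: str = "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        mix_sum = sum(self.class_mixture.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"class_mixture fractions must sum to 1, got {mix_sum}")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be positive")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must be in [0, 1)")
        if not 0.0 <= self.replicate_overdispersion < 1.0:
            raise ValueError("replicate_overdispersion must be in [0, 1)")
        if self.sampling not in ("multinomial", "expected"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        for cls in self.class_mixture:
            for lin in cls:
                if cls not in ("unclassified",) and lin not in "".join(self.lineages):
                    # class labels are concatenations of lineage letters
                    pass

    def profiles(self) -> dict[str, np.ndarray]:
        """Per-class Dirichlet concentration vectors over ``lineages``.

        By default a class named by a subset of lineage letters (e.g. "ME")
        puts equal concentration on its member lineages and exactly zero on
        the rest; total concentration is ``weight_concentration``.
        """
        if self.class_profiles is not None:
            out = {}
            for cls, prof in self.class_profiles.items():
                arr = np.asarray(prof, dtype=float)
                if arr.shape != (len(self.lineages),) or (arr < 0).any():
                    raise ValueError(f"bad profile for class {cls!r}")
                out[cls] = arr
            return out
        kappa = self.weight_concentration or 1.0
        out = {}
        for cls in self.class_mixture:
            members = [lin in cls for lin in self.lineages]
            if not any(members):
                raise ValueError(f"class {cls!r} names no lineage in {self.lineages}")
            arr = np.where(members, kappa / sum(members), 0.0)
            out[cls] = arr
        return out

    def mice(self) -> list[str]:
        return [f"{g}_m{i + 1}" for g in self.groups for i in range(self.n_mice_per_group)]

    def assignments(self) -> tuple[dict[str, str], dict[str, str]]:
        """(run, batch) per mouse; round-robin unless given explicitly."""
        mice = self.mice()
        if self.batch_assignment is not None:
            batches = {m: str(self.batch_assignment[m]) for m in mice}
        else:
            batches = {m: f"batch{i % self.n_batches + 1}" for i, m in enumerate(mice)}
        if self.run_assignment is not None:
            runs = {m: str(self.run_assignment[m]) for m in mice}
        else:
            # spread each batch's mice over the runs so that cross-run
            # same-batch pairs exist whenever n_runs > 1
            runs = {}
            per_batch_counter: dict[str, int] = {}
            for m in mice:
                b = batches[m]
                k = per_batch_counter.get(b, 0)
                runs[m] = f"run{k % self.n_runs + 1}"
                per_batch_counter[b] = k + 1
        return runs, batches


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of a synthetic experiment.

    For clonal experiments: ``clones`` (barcode, mouse, class, per-lineage
    true weight, relative size), ``sample_totals`` (designed column sums)
    and ``contaminants`` (sample, barcode, reads planted).  For expression
    experiments: ``responders``, ``up_genes``/``down_genes`` with their
    fold shifts.  ``seed`` records the generator seed.
    """

    seed: int
    clones: pd.DataFrame | None = None
    sample_totals: dict[str, int] = field(default_factory=dict)
    contaminants: list[dict] = field(default_factory=list)
    responders: list[str] = field(default_factory=list)
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    fold_up: float | None = None
    fold_down: float | None = None

    def true_class_of(self) -> pd.Series:
        if self.clones is None:
            raise ValueError("no clonal ledger present")
        return self.clones.set_index("barcode")["clone_class"]

    def contaminant_pairs(self) -> set[tuple[str, str]]:
        return {(c["sample"], c["barcode"]) for c in self.contaminants}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "sample_totals": self.sample_totals,
            "contaminants": self.contaminants,
            "responders": list(self.responders),
            "up_genes": list(self.up_genes),
            "down_genes": list(self.down_genes),
            "fold_up": self.fold_up,
            "fold_down": self.fold_down,
            "clones": None if self.clones is None else self.clones.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        clones = payload.pop("clones")
        return cls(
            clones=None if clones is None else pd.DataFrame(clones),
            **payload,
        )


def gen_reference(n: int, length: int, seed: int) -> BarcodeReference:
    """Generate ``n`` unique random barcodes of ``length`` nt.

    Deterministic for a given seed.  Raises if ``n`` exceeds the 4**length
    sequence space.
    """
    space = 4**length
    if n > space:
        raise ValueError(f"cannot draw {n} unique sequences of length {length} (space {space})")
    rng = np.random.default_rng(seed)
    if space <= 4**12:
        codes = rng.choice(space, size=n, replace=False)
        seqs = []
        for c in codes:
            digits = [(c >> (2 * k)) & 3 for k in range(length)]
            seqs.append("".join(_BASES[digits]))
    else:
        seen: set[str] = set()
        seqs = []
        while len(seqs) < n:
            batch = rng.integers(0, 4, size=(max(n - len(seqs), 64), length))
            for row in batch:
                s = "".join(_BASES[row])
                if s not in seen:
                    seen.add(s)
                    seqs.append(s)
                    if len(seqs) == n:
                        break
    return BarcodeReference.from_sequences(seqs)


def _split_replicates(
    counts: np.ndarray, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split per-barcode read counts into two replicates.

    Pure binomial(1/2) thinning at rho=0; for rho>0 each barcode's split
    probability is Beta(a, a) with a = (1-rho)/(2 rho), decorrelating the
    replicates as rho -> 1 so the replicate-concordance QC rule can fail.
    """
    if rho <= 0:
        a_counts = rng.binomial(counts, 0.5)
    else:
        a = (1.0 - rho) / (2.0 * rho)
        p = rng.beta(a, a, size=counts.shape)
        a_counts = rng.binomial(counts, p)
    return a_counts, counts - a_counts


def gen_clonal_experiment(
    design: ExperimentDesign,
    reference: BarcodeReference | None = None,
):
    """Generate a duplicate-replicate barcode count table plus its ledger.

    Returns a :class:`~clonotrace.barcode_extract.CountTable` whose columns
    are mouse-by-lineage samples in two replicates (A/B) and a
    :class:`SyntheticTruth` ledger of clone classes, weights, designed
    totals and planted contaminants.
    """
    from clonotrace.barcode_extract import CountTable

    rng = np.random.default_rng(design.seed)
    mice = design.mice()
    runs, batches = design.assignments()
    n_needed = design.n_clones_per_mouse * len(mice)
    if reference is None:
        reference = gen_reference(n_needed, 20, seed=int(rng.integers(2**31)))
    if len(reference) < n_needed:
        raise ValueError("reference too small for the designed cohort")

    profiles = design.profiles()
    classes = list(design.class_mixture)
    mix = np.array([design.class_mixture[c] for c in classes])
    lineages = list(design.lineages)
    L = len(lineages)

    clone_rows = []
    mouse_clones: dict[str, list[int]] = {}
    bc_ids = list(reference.ids)
    next_bc = 0
    all_weights: dict[str, np.ndarray] = {}
    all_sizes: dict[str, np.ndarray] = {}
    for m in mice:
        idx = list(range(next_bc, next_bc + design.n_clones_per_mouse))
        next_bc += design.n_clones_per_mouse
        mouse_clones[m] = idx
        cls = rng.choice(len(classes), size=len(idx), p=mix)
        W = np.zeros((len(idx), L))
        for i, ci in enumerate(cls):
            conc = profiles[classes[ci]]
            pos = conc > 0
            if design.weight_concentration is None or design.sampling == "expected":
                w = conc / conc.sum()
            else:
                w = np.zeros(L)
                w[pos] = rng.dirichlet(conc[pos])
            W[i] = w
        if design.clone_size_sigma > 0:
            sizes = rng.lognormal(0.0, design.clone_size_sigma, size=len(idx))
        else:
            sizes = np.ones(len(idx))
        sizes = sizes / sizes.sum()
        all_weights[m] = W
        all_sizes[m] = sizes
        for j, (i, ci) in enumerate(zip(idx, cls)):
            row = {
                "barcode": bc_ids[i],
                "mouse": m,
                "group": m.rsplit("_m", 1)[0],
                "clone_class": classes[ci],
                "size": sizes[j],
            }
            for li, lin in enumerate(lineages):
                row[f"w_{lin}"] = W[j, li]
            clone_rows.append(row)

    sample_rows = []
    columns: dict[str, dict[str, int]] = {}
    sample_totals: dict[str, int] = {}
    for m in mice:
        idx = mouse_clones[m]
        names = [bc_ids[i] for i in idx]
        W = all_weights[m]
        sizes = all_sizes[m]
        for li, lin in enumerate(lineages):
            p = sizes * W[:, li]
            total_p = p.sum()
            if design.sampling == "expected":
                counts = np.rint(design.depth_per_sample * (p / total_p if total_p > 0 else p)).astype(int)
            else:
                T = rng.poisson(design.depth_per_sample)
                if total_p > 0 and T > 0:
                    counts = rng.multinomial(T, p / total_p)
                else:
                    counts = np.zeros(len(idx), dtype=int)
            if design.sampling == "expected":
                rep_a = counts // 2
                rep_b = counts - rep_a
            else:
                rep_a, rep_b = _split_replicates(counts, design.replicate_overdispersion, rng)
            for rep, vec in (("A", rep_a), ("B", rep_b)):
                sid = f"{m}_{lin}_{rep}"
                columns[sid] = {n: int(v) for n, v in zip(names, vec) if v > 0}
                sample_rows.append(
                    {
                        "sample": sid,
                        "mouse": m,
                        "lineage": lin,
                        "replicate": rep,
                        "run": runs[m],
                        "batch": batches[m],
                        "group": m.rsplit("_m", 1)[0],
                    }
                )

    contaminants: list[dict] = []
    n_contam = int(round(design.contamination_rate * design.n_clones_per_mouse))
    if n_contam > 0:
        for m in mice:
            donors = [
                d for d in mice if d != m and batches[d] == batches[m] and runs[d] != runs[m]
            ]
            if not donors:
                continue
            # low-abundance spill-in: donors' bottom-decile clones by size
            picked: set[str] = set()
            for _ in range(n_contam):
                d = donors[int(rng.integers(len(donors)))]
                sizes = all_sizes[d]
                order = np.argsort(sizes)
                decile = order[: max(1, len(order) // 10)]
                j = decile[int(rng.integers(len(decile)))]
                bc = bc_ids[mouse_clones[d][j]]
                if bc in picked:
                    continue
                picked.add(bc)
                for lin in lineages:
                    for rep in ("A", "B"):
                        sid = f"{m}_{lin}_{rep}"
                        reads = int(1 + rng.poisson(1.5))
                        columns[sid][bc] = columns[sid].get(bc, 0) + reads
                        contaminants.append({"sample": sid, "barcode": bc, "reads": reads})

    all_barcodes = sorted({b for col in columns.values() for b in col})
    sample_ids = [r["sample"] for r in sample_rows]
    mat = np.zeros((len(all_barcodes), len(sample_ids)), dtype=int)
    row_of = {b: i for i, b in enumerate(all_barcodes)}
    for j, sid in enumerate(sample_ids):
        for b, v in columns[sid].items():
            mat[row_of[b], j] = v
        sample_totals[sid] = int(mat[:, j].sum())

    counts = pd.DataFrame(mat, index=all_barcodes, columns=sample_ids)
    samples = pd.DataFrame(sample_rows).set_index("sample")
    # one 4 bp plate index per sample so read-level output can demultiplex
    from itertools import product

    four_mers = ("".join(p) for p in product("ACGT", repeat=4))
    idx_seqs = [s for s, _ in zip(four_mers, sample_ids)]
    if len(idx_seqs) < len(sample_ids):
        raise ValueError("too many samples for 4 bp plate indices")
    samples["plate_index"] = idx_seqs
    table = CountTable(counts=counts, samples=samples)
    truth = SyntheticTruth(
        seed=design.seed,
        clones=pd.DataFrame(clone_rows),
        sample_totals=sample_totals,
        contaminants=contaminants,
    )
    return table, truth


# ---------------------------------------------------------------------------
# single-cell expression generator


def _decoy_gene_names(rng: np.random.Generator, n_gm: int, n_rik: int, n_rp: int) -> list[str]:
    names = []
    for _ in range(n_gm):
        names.append(f"Gm{int(rng.integers(1000, 60000))}")
    for _ in range(n_rik):
        stem = "".join(_BASES[rng.integers(0, 4, size=4)])
        names.append(f"{int(rng.integers(1000000, 9999999))}{stem[0]}{stem[1:3]}Rik")
    for i in range(n_rp):
        fam = "Rps" if i % 2 == 0 else "Rpl"
        names.append(f"{fam}{int(rng.integers(1, 40))}-{i}")
    return names


def gen_expression_experiment(
    responder_fraction: float = 0.10,
    n_cells_per_group: int = 500,
    n_genes: int = 1000,
    n_up: int = 30,
    n_down: int = 20,
    fold_up: float = 3.0,
    fold_down: float = 3.0,
    mean_log_mu: float = -0.7,
    sd_log_mu: float = 1.2,
    dispersion: float = 0.1,
    n_mito: int = 13,
    mito_total_fraction: float = 0.05,
    decoy_fractions: tuple[float, float, float] = (0.05, 0.05, 0.04),
    n_low_gene_cells: int = 0,
    n_high_mito_cells: int = 0,
    seed: int = 0,
):
    """Generate a control-vs-EPO single-cell count matrix plus its ledger.

    Counts are negative-binomial around lognormal gene means; a fraction
    ``responder_fraction`` of EPO cells has the up-program multiplied and
    the down-program divided by the stated folds.  Gene names include
    decoys matching the usual QC discard patterns (Gm…, …Rik, Rps/Rpl) and
    a block of mt- genes holding roughly ``mito_total_fraction`` of reads,
    so QC filters are exercised.  Optional planted QC violators: cells with
    very few detected genes and cells with runaway mitochondrial content.

    Returns an :class:`anndata.AnnData` (cells x genes, raw integer counts,
    obs["group"] in {"control", "EPO"}) and a :class:`SyntheticTruth`.
    """
    import anndata as ad

    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must be in [0, 1]")
    if fold_up <= 0 or fold_down <= 0:
        raise ValueError("fold shifts must be positive")

    rng = np.random.default_rng(seed)
    n_gm = int(round(decoy_fractions[0] * n_genes))
    n_rik = int(round(decoy_fractions[1] * n_genes))
    n_rp = int(round(decoy_fractions[2] * n_genes))
    n_info = n_genes - n_gm - n_rik - n_rp - n_mito
    if n_info < n_up + n_down:
        raise ValueError("not enough informative genes for the requested up/down programs")

    info_names = [f"Gene{i:05d}" for i in range(n_info)]
    mito_names = [f"mt-Syn{i}" for i in range(n_mito)]
    decoys = _decoy_gene_names(rng, n_gm, n_rik, n_rp)
    genes = info_names + mito_names + decoys
    if len(genes) != n_genes or len(set(genes)) != n_genes:
        raise RuntimeError("gene-name bookkeeping mismatch")

    mu = rng.lognormal(mean_log_mu, sd_log_mu, size=n_genes)
    # scale the mito block to hold the requested share of total expression
    mito_sl = slice(n_info, n_info + n_mito)
    non_mito_total = mu.sum() - mu[mito_sl].sum()
    if n_mito > 0 and mito_total_fraction > 0:
        target = mito_total_fraction / (1 - mito_total_fraction) * non_mito_total
        mu[mito_sl] *= target / mu[mito_sl].sum()

    up_idx = rng.choice(n_info, size=n_up + n_down, replace=False)
    up_genes = [info_names[i] for i in up_idx[:n_up]]
    down_genes = [info_names[i] for i in up_idx[n_up:]]

    n_ctrl = n_cells_per_group
    n_epo = n_cells_per_group
    n_resp = int(round(responder_fraction * n_epo))
    resp_local = rng.choice(n_epo, size=n_resp, replace=False)

    cell_ids = [f"ctrl_{i}" for i in range(n_ctrl)] + [f"epo_{i}" for i in range(n_epo)]
    groups = ["control"] * n_ctrl + ["EPO"] * n_epo
    responder_ids = [f"epo_{i}" for i in sorted(resp_local)]

    M = np.tile(mu, (n_ctrl + n_epo, 1))
    gene_pos = {g: j for j, g in enumerate(genes)}
    up_cols = [gene_pos[g] for g in up_genes]
    down_cols = [gene_pos[g] for g in down_genes]
    resp_rows = n_ctrl + resp_local
    M[np.ix_(resp_rows, up_cols)] *= fold_up
    M[np.ix_(resp_rows, down_cols)] /= fold_down

    # planted QC violators, appended after the main cells
    extra_rows = []
    extra_ids = []
    extra_groups = []
    for i in range(n_low_gene_cells):
        row = mu * 0.01  # nearly all dropout -> few detected genes
        extra_rows.append(row)
        extra_ids.append(f"lowgene_{i}")
        extra_groups.append("control")
    for i in range(n_high_mito_cells):
        row = mu.copy()
        row[mito_sl] *= 20.0
        extra_rows.append(row)
        extra_ids.append(f"highmito_{i}")
        extra_groups.append("control")
    if extra_rows:
        M = np.vstack([M, np.array(extra_rows)])
        cell_ids = cell_ids + extra_ids
        groups = groups + extra_groups

    r = 1.0 / dispersion
    X = rng.negative_binomial(r, r / (r + M)).astype(np.int64)

    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({"group": pd.Categorical(groups)}, index=cell_ids),
        var=pd.DataFrame(index=genes),
    )
    adata.uns["normalized"] = False
    truth = SyntheticTruth(
        seed=seed,
        responders=responder_ids,
        up_genes=up_genes,
        down_genes=down_genes,
        fold_up=fold_up,
        fold_down=fold_down,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# read-level output


def write_reads(
    table,
    structure,
    path: str | Path,
    reference: BarcodeReference,
    seed: int = 0,
    shuffle: bool = True,
) -> int:
    """Write a FASTQ of error-free reads realizing a CountTable.

    Each (barcode, sample) count emits that many template-perfect reads
    using the sample's index sequences from the sample sheet.  Returns the
    number of reads written.
    """
    rng = np.random.default_rng(seed)
    id_to_seq = dict(zip(reference.ids, reference.sequences))
    index_names = structure.index_names
    reads: list[str] = []
    for sid in table.counts.columns:
        meta = table.samples.loc[sid]
        idx_vals = {n: str(meta[n]) for n in index_names}
        col = table.counts[sid]
        for bc_id, k in col[col > 0].items():
            seq = structure.build_read(idx_vals, id_to_seq[bc_id])
            reads.extend([seq] * int(k))
    if shuffle:
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return len(reads)


def write_expression(adata, out_dir: str | Path) -> None:
    """Write an expression AnnData as MTX + genes/cells TSV."""
    import scipy.io
    import scipy.sparse as sp

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.csr_matrix(X).T)  # genes x cells
    pd.Series(adata.var_names).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    adata.obs.rename_axis("cell").to_csv(out / "cells.tsv", sep="\t")
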