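"""Exact-match extraction of barcode counts from amplicon reads.

A sequencing read from a barcoding library is a concatenation of index
segments (plate/sample indices used for demultiplexing), constant segments
(primer-derived common sequence) and exactly one barcode segment.  A read
is counted iff every constant segment matches perfectly, its index
combination maps to a known sample, and its barcode is present in the
reference list of library barcodes; everything else is tallied with a
rejection reason.  No mismatches are tolerated anywhere.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

_NUCLEOTIDES = frozenset("ACGT")

#: sample-sheet columns required by the QC cascade downstream
SAMPLE_SHEET_COLUMNS = ("sample", "mouse", "lineage", "replicate", "run", "batch", "group")

REJECT_TRUNCATED = "truncated"
REJECT_CONSTANT_MISMATCH = "constant_mismatch"
REJECT_UNKNOWN_INDEX = "unknown_index"
REJECT_UNKNOWN_BARCODE = "non_reference_barcode"


@dataclass(frozen=True)
class BarcodeReference:
    """Reference list of library barcodes (unique, uniform-length, ACGT)."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("reference sequences must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("reference sequences must have uniform length")
        for s in self.sequences:
            if not _NUCLEOTIDES.issuperset(s):
                raise ValueError(f"non-ACGT character in reference sequence {s!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def seq_to_id(self) -> dict[str, str]:
        return dict(zip(self.sequences, self.ids))

    @classmethod
    def from_sequences(cls, sequences: Sequence[str], prefix: str = "BC") -> "BarcodeReference":
        ids = tuple(f"{prefix}{i:06d}" for i in range(len(sequences)))
        return cls(ids=ids, sequences=tuple(sequences))

    @classmethod
    def read(cls, path: str | Path) -> "BarcodeReference":
        """Read a reference list from FASTA or one-sequence-per-line text."""
        path = Path(path)
        text = path.read_text()
        if text.lstrip().startswith(">"):
            from Bio import SeqIO

            ids, seqs = [], []
            for rec in SeqIO.parse(str(path), "fasta"):
                ids.append(rec.id)
                seqs.append(str(rec.seq).upper())
            return cls(ids=tuple(ids), sequences=tuple(seqs))
        seqs = [ln.strip().upper() for ln in text.splitlines() if ln.strip()]
        return cls.from_sequences(seqs)

    def write(self, path: str | Path, fmt: str = "fasta") -> None:
        path = Path(path)
        if fmt == "fasta":
            with open(path, "w") as fh:
                for bid, seq in zip(self.ids, self.sequences):
                    fh.write(f">{bid}\n{seq}\n")
        elif fmt == "text":
            path.write_text("\n".join(self.sequences) + "\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


@dataclass(frozen=True)
class Segment:
    """One segment of the read template.

    kind is "index" (variable, demultiplexes; ``name`` must match a
    sample-sheet column holding the expected sequence per sample),
    "constant" (must equal ``expected`` exactly) or "barcode" (looked up
    in the reference).
    """

    kind: str
    length: int
    expected: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("index", "constant", "barcode"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "constant":
            if self.expected is None or len(self.expected) != self.length:
                raise ValueError("constant segment needs an expected sequence of its length")
        if self.kind == "index" and self.name is None:
            raise ValueError("index segment needs a name matching a sample-sheet column")


@dataclass(frozen=True)
class ReadStructure:
    """Ordered template of segments with exactly one barcode segment."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        n_bc = sum(1 for s in self.segments if s.kind == "barcode")
        if n_bc != 1:
            raise ValueError(f"read structure needs exactly one barcode segment, got {n_bc}")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def index_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments if s.kind == "index")

    def build_read(self, index_values: Mapping[str, str], barcode: str) -> str:
        """Assemble the read a perfectly sequenced molecule would produce."""
        parts = []
        for seg in self.segments:
            if seg.kind == "constant":
                parts.append(seg.expected)
            elif seg.kind == "index":
                val = index_values[seg.name]
                if len(val) != seg.length:
                    raise ValueError(f"index {seg.name!r} value {val!r} has wrong length")
                parts.append(val)
            else:
                if len(barcode) != seg.length:
                    raise ValueError("barcode has wrong length for structure")
                parts.append(barcode)
        return "".join(parts)


def default_read_structure(barcode_length: int = 20) -> ReadStructure:
    # 4 bp plate index, then the common sequence the nested PCR leaves
    # upstream of the barcode insert, then the barcode itself.
    return ReadStructure(
        segments=(
            Segment(kind="index", length=4, name="plate_index"),
            Segment(kind="constant", length=19, expected="CTAGAACACTCGAGATCAG"),
            Segment(kind="barcode", length=barcode_length),
        )
    )


@dataclass
class CountTable:
    """Barcode-by-sample count matrix with per-sample metadata.

    ``counts`` rows are barcode ids (subset of the reference), columns are
    sample ids; ``samples`` is the sample sheet indexed by sample id.
    ``rejected`` tallies reads that failed template parsing.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    rejected: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")

    @property
    def n_assigned(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_rejected(self) -> int:
        return int(sum(self.rejected.values()))

    def write(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.rename_axis("barcode").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def read(cls, counts_path: str | Path, samples_path: str | Path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0).rename_axis(None)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
        return cls(counts=counts, samples=samples)


def validate_sample_sheet(samples: pd.DataFrame, index_names: Sequence[str] = ()) -> None:
    """Check required columns, unique (mouse, lineage, replicate) and unique index combos."""
    required = [c for c in SAMPLE_SHEET_COLUMNS if c != "sample"]
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    trip = samples[["mouse", "lineage", "replicate"]]
    if trip.duplicated().any():
        dup = trip[trip.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (mouse, lineage, replicate) in sample sheet: {dup}")
    if index_names:
        missing_idx = [c for c in index_names if c not in samples.columns]
        if missing_idx:
            raise ValueError(f"sample sheet missing index columns: {missing_idx}")
        combos = samples[list(index_names)]
        if combos.duplicated().any():
            dup = combos[combos.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate index combination in sample sheet: {dup}")


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzip-aware)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    from Bio import SeqIO

    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def extract_counts(
    reads: Iterable[str] | str | Path,
    structure: ReadStructure,
    reference: BarcodeReference,
    sample_sheet: pd.DataFrame,
) -> CountTable:
    """Demultiplex reads into a barcode-by-sample count table.

    Each read either increments exactly one (barcode, sample) cell or is
    rejected with a reason (truncated / constant mismatch / unknown index
    combination / barcode absent from the reference).  Assigned plus
    rejected reads always equal input reads, and the result is invariant
    to read order.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)

    index_names = structure.index_names
    validate_sample_sheet(sample_sheet, index_names=index_names)

    combo_to_sample: dict[tuple[str, ...], str] = {}
    for sid, row in sample_sheet.iterrows():
        combo_to_sample[tuple(str(row[n]).upper() for n in index_names)] = str(sid)

    seq_to_id = reference.seq_to_id()
    sample_ids = [str(s) for s in sample_sheet.index]
    col_of = {s: j for j, s in enumerate(sample_ids)}

    # (barcode id, sample) -> count, densified at the end
    cells: dict[tuple[str, str], int] = {}
    rejected = {
        REJECT_TRUNCATED: 0,
        REJECT_CONSTANT_MISMATCH: 0,
        REJECT_UNKNOWN_INDEX: 0,
        REJECT_UNKNOWN_BARCODE: 0,
    }

    segs = structure.segments
    total_len = structure.total_length
    for read in reads:
        read = read.upper()
        if len(read) < total_len:
            rejected[REJECT_TRUNCATED] += 1
            continue
        pos = 0
        idx_vals: list[str] = []
        barcode_seq = ""
        ok = True
        for seg in segs:
            piece = read[pos : pos + seg.length]
            pos += seg.length
            if seg.kind == "constant":
                if piece != seg.expected:
                    rejected[REJECT_CONSTANT_MISMATCH] += 1
                    ok = False
                    break
            elif seg.kind == "index":
                idx_vals.append(piece)
            else:
                barcode_seq = piece
        if not ok:
            continue
        sample = combo_to_sample.get(tuple(idx_vals))
        if sample is None:
            rejected[REJECT_UNKNOWN_INDEX] += 1
            continue
        bc_id = seq_to_id.get(barcode_seq)
        if bc_id is None:
            rejected[REJECT_UNKNOWN_BARCODE] += 1
            continue
        cells[(bc_id, sample)] = cells.get((bc_id, sample), 0) + 1

    barcodes = sorted({b for b, _ in cells})
    counts = pd.DataFrame(0, index=barcodes, columns=sample_ids, dtype=int)
    arr = counts.to_numpy()
    row_of = {b: i for i, b in enumerate(barcodes)}
    for (b, s), k in cells.items():
        arr[row_of[b], col_of[s]] = k
    counts = pd.DataFrame(arr, index=barcodes, columns=sample_ids)
    return CountTable(counts=counts, samples=sample_sheet.copy(), rejected=rejected)
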