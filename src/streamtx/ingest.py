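"""Discovery and parsing of newly arrived FASTQ batches.

Emulates watching a sequencer's output directory: each scan returns batch
files not seen before, in filename order (the simulator zero-pads minute
stamps, so lexicographic order is temporal order).  A file is eligible as
soon as it exists under its final name; the simulator renames atomically, so
no size-stability polling is needed.
"""

from __future__ import annotations

import gzip
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from streamtx.errors import ConfigurationError, FastqParseError

MANIFEST_COLUMNS = ("barcode", "sample_id", "condition")


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities) or not self.sequence:
            raise FastqParseError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)} (or empty)")


@dataclass
class StreamState:
    """Registry of consumed batch files; never forgets, never decreases."""

    seen_files: set[Path] = field(default_factory=set)
    reads_consumed: dict[str, int] = field(default_factory=dict)
    last_scan_time: float = 0.0

    def note_reads(self, sample_id: str, n: int) -> None:
        self.reads_consumed[sample_id] = self.reads_consumed.get(sample_id, 0) + n


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ConfigurationError(
            f"manifest {path} lacks columns: {sorted(missing)}")
    if manifest["barcode"].duplicated().any():
        raise ConfigurationError("duplicate barcodes in manifest")
    return manifest


def discover_new_batches(run_dir: str | Path,
                         manifest: pd.DataFrame,
                         state: StreamState) -> list[tuple[str, Path]]:
    """Return unseen ``(sample_id, path)`` batch files, ordered by filename.

    Barcode directories absent from the manifest are skipped with a warning
    (unclassified or foreign barcodes).  ``state.seen_files`` is updated, so
    a second call without new arrivals returns an empty list.
    """
    run_dir = Path(run_dir)
    pass_dir = run_dir / "fastq_pass"
    if not pass_dir.is_dir():
        raise ConfigurationError(f"{run_dir} has no fastq_pass/ directory")
    barcode_to_sample = dict(zip(manifest["barcode"], manifest["sample_id"]))
    fresh: list[tuple[str, Path]] = []
    for bc_dir in sorted(pass_dir.iterdir()):
        if not bc_dir.is_dir():
            continue
        sample = barcode_to_sample.get(bc_dir.name)
        if sample is None:
            warnings.warn(f"barcode directory {bc_dir.name} not in manifest; "
                          "skipped", stacklevel=2)
            continue
        for path in bc_dir.iterdir():
            if path.suffix in (".fastq", ".fq") or path.name.endswith(
                    (".fastq.gz", ".fq.gz")):
                if path not in state.seen_files:
                    fresh.append((sample, path))
    fresh.sort(key=lambda item: (item[1].name, item[0]))
    state.seen_files.update(p for _, p in fresh)
    state.last_scan_time = time.time()
    return fresh


def read_fastq(path: str | Path, sample_id: str = "") -> list[ReadRecord]:
    """Parse one FASTQ batch (gzip accepted by extension).

    Read IDs are taken up to the first whitespace.  Truncated or inconsistent
    records raise :class:`FastqParseError` naming the record offset.
    """
    path = Path(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    records: list[ReadRecord] = []
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ at record {len(records) + 1}: "
                    f"{exc}") from exc
            rid = title.split()[0] if title.split() else title
            try:
                records.append(ReadRecord(rid, seq, qual, sample_id))
            except FastqParseError as exc:
                raise FastqParseError(
                    f"{path}: record {len(records) + 1}: {exc}") from exc
    return records
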