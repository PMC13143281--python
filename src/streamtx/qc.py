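"""Per-iteration quality control for a streaming sequencing run.

Four layers, each cheap enough to recompute after every batch:

* read-length summaries (streaming histogram; mean exact, median and N50
  from 100 nt bins),
* genes detected (>0 assigned reads) per sample and per condition — the
  gene-detection saturation curve,
* gene-composition change between consecutive iterations (which genes are
  newly detected),
* plateau detection on the saturation curve: once no new genes appear for a
  window of iterations, additional sequencing is unlikely to widen the
  detected transcriptome and the run can be stopped,
* wall-clock stage timings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from streamtx.errors import MonotonicityError

BIN_WIDTH = 100  # nt; bins centered on multiples of the width


@dataclass
class LengthSummary:
    """Streaming read-length statistics per sample.

    Lengths are binned to the nearest multiple of ``BIN_WIDTH``; median and
    N50 are reported as bin representatives (exact for lengths on the grid),
    while the mean uses exact running totals.
    """

    n: dict[str, int] = field(default_factory=dict)
    total_length: dict[str, int] = field(default_factory=dict)
    hist: dict[str, np.ndarray] = field(default_factory=dict)

    def update(self, sample_id: str, lengths: Sequence[int]) -> "LengthSummary":
        lengths = np.asarray(lengths, dtype=np.int64)
        if lengths.size == 0:
            return self
        bins = np.rint(lengths / BIN_WIDTH).astype(np.int64)
        h = self.hist.get(sample_id, np.zeros(0, dtype=np.int64))
        need = int(bins.max()) + 1
        if len(h) < need:
            h = np.concatenate([h, np.zeros(need - len(h), dtype=np.int64)])
        np.add.at(h, bins, 1)
        self.hist[sample_id] = h
        self.n[sample_id] = self.n.get(sample_id, 0) + len(lengths)
        self.total_length[sample_id] = (self.total_length.get(sample_id, 0)
                                        + int(lengths.sum()))
        return self

    def _stats_from_hist(self, h: np.ndarray) -> tuple[float, float]:
        """(median, N50) as bin representatives."""
        n = h.sum()
        if n == 0:
            return float("nan"), float("nan")
        mids = np.arange(len(h)) * BIN_WIDTH
        cum = np.cumsum(h)
        median = mids[int(np.searchsorted(cum, (n + 1) / 2))]
        bases = h * mids
        # N50: smallest length L such that reads of length >= L hold half
        # the bases (computed from the largest bin downwards)
        rev_cum = np.cumsum(bases[::-1])[::-1]
        half = bases.sum() / 2
        idx = np.nonzero(rev_cum >= half)[0]
        n50 = mids[idx[-1]] if len(idx) else mids[-1]
        return float(median), float(n50)

    def summary(self, condition_of: Mapping[str, str] | None = None
                ) -> pd.DataFrame:
        """Per-sample rows, plus per-condition (and combined) pooled rows."""
        rows = []

        def row(label: str, kind: str, samples: list[str]) -> None:
            n = sum(self.n.get(s, 0) for s in samples)
            tot = sum(self.total_length.get(s, 0) for s in samples)
            hs = [self.hist[s] for s in samples if s in self.hist]
            if hs:
                size = max(len(h) for h in hs)
                pooled = np.zeros(size, dtype=np.int64)
                for h in hs:
                    pooled[: len(h)] += h
            else:
                pooled = np.zeros(0, dtype=np.int64)
            median, n50 = self._stats_from_hist(pooled)
            rows.append({"label": label, "kind": kind, "n": n,
                         "mean": tot / n if n else float("nan"),
                         "median": median, "n50": n50})

        for s in sorted(self.n):
            row(s, "sample", [s])
        if condition_of is not None:
            conds: dict[str, list[str]] = {}
            for s in self.n:
                conds.setdefault(condition_of[s], []).append(s)
            for c in sorted(conds):
                row(c, "condition", conds[c])
            row("combined", "combined", list(self.n))
        return pd.DataFrame(rows)

    def histogram_frame(self) -> pd.DataFrame:
        rows = []
        for s, h in sorted(self.hist.items()):
            for b in np.nonzero(h)[0]:
                rows.append({"sample_id": s, "length_bin": int(b) * BIN_WIDTH,
                             "count": int(h[b])})
        return pd.DataFrame(rows, columns=["sample_id", "length_bin", "count"])


def genes_detected(gene_counts: pd.DataFrame,
                   condition_of: Mapping[str, str]
                   ) -> tuple[dict[str, int], dict[str, int]]:
    """Genes with >0 assigned reads, per sample and per condition (pooled)."""
    per_sample = {s: int((gene_counts[s] > 0).sum())
                  for s in gene_counts.columns}
    per_condition: dict[str, int] = {}
    conds: dict[str, list[str]] = {}
    for s in gene_counts.columns:
        conds.setdefault(condition_of[s], []).append(s)
    for c, samples in conds.items():
        per_condition[c] = int((gene_counts[samples].sum(axis=1) > 0).sum())
    return per_sample, per_condition


def detected_sets(gene_counts: pd.DataFrame,
                  condition_of: Mapping[str, str]) -> dict[str, set[str]]:
    """Per-condition sets of genes with pooled count > 0."""
    out: dict[str, set[str]] = {}
    conds: dict[str, list[str]] = {}
    for s in gene_counts.columns:
        conds.setdefault(condition_of[s], []).append(s)
    for c, samples in conds.items():
        mask = gene_counts[samples].sum(axis=1) > 0
        out[c] = set(gene_counts.index[mask])
    return out


@dataclass
class CompositionDelta:
    iteration: int
    new_genes: dict[str, set[str]]

    @property
    def n_new(self) -> dict[str, int]:
        return {c: len(g) for c, g in self.new_genes.items()}


def composition_delta(prev_detected: Mapping[str, set[str]],
                      gene_counts: pd.DataFrame,
                      condition_of: Mapping[str, str],
                      iteration: int = 0) -> CompositionDelta:
    """Genes detected now but not in any earlier iteration, per condition."""
    current = detected_sets(gene_counts, condition_of)
    new_genes: dict[str, set[str]] = {}
    for c, cur in current.items():
        prev = set(prev_detected.get(c, set()))
        if not prev <= cur:
            raise MonotonicityError(
                f"condition {c}: previously detected genes vanished "
                f"({sorted(prev - cur)[:5]} ...)")
        new_genes[c] = cur - prev
    return CompositionDelta(iteration, new_genes)


@dataclass
class SaturationCurve:
    """Genes-detected trajectory across iterations (monotone)."""

    iterations: list[int] = field(default_factory=list)
    per_sample: list[dict[str, int]] = field(default_factory=list)
    per_condition: list[dict[str, int]] = field(default_factory=list)

    def append(self, iteration: int, sample_counts: dict[str, int],
               condition_counts: dict[str, int]) -> None:
        if self.per_condition:
            for c, v in condition_counts.items():
                if v < self.per_condition[-1].get(c, 0):
                    raise MonotonicityError(
                        f"genes detected for {c} decreased to {v}")
        self.iterations.append(iteration)
        self.per_sample.append(dict(sample_counts))
        self.per_condition.append(dict(condition_counts))

    def condition_series(self, condition: str) -> list[int]:
        return [row.get(condition, 0) for row in self.per_condition]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it, ps, pc in zip(self.iterations, self.per_sample,
                              self.per_condition):
            for s, v in ps.items():
                rows.append({"iteration": it, "label": s, "kind": "sample",
                             "genes_detected": v})
            for c, v in pc.items():
                rows.append({"iteration": it, "label": c, "kind": "condition",
                             "genes_detected": v})
        return pd.DataFrame(
            rows, columns=["iteration", "label", "kind", "genes_detected"])


def detect_plateau(values: Sequence[int], window: int = 3,
                   epsilon: int = 0) -> tuple[bool, int | None]:
    """First iteration (1-based) after which the last ``window`` consecutive
    gains in genes detected are all <= ``epsilon``.

    Returns ``(False, None)`` when fewer than ``window + 1`` iterations are
    available or no such window exists.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = list(values)
    if len(values) < window + 1:
        return False, None
    deltas = [b - a for a, b in zip(values, values[1:])]
    for end in range(window - 1, len(deltas)):
        if all(d <= epsilon for d in deltas[end - window + 1: end + 1]):
            return True, end + 2  # deltas[i] ends at iteration i+2 (1-based)
    return False, None


class TimingLog:
    """Append-only TSV log of per-iteration stage wall times."""

    COLUMNS = ("iteration", "stage", "seconds")

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.rows: list[tuple[int, str, float]] = []
        if self.path is not None and not self.path.exists():
            self.path.write_text("\t".join(self.COLUMNS) + "\n")

    def record(self, iteration: int, stage: str, seconds: float) -> None:
        if seconds < 0:
            raise ValueError("stage timing cannot be negative")
        self.rows.append((iteration, stage, seconds))
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(f"{iteration}\t{stage}\t{seconds:.6f}\n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)
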