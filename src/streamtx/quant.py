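"""Minimizer-sketch read-to-transcript assignment and monotone counting.

Long reads are matched to transcripts by shared canonical minimizers: the
smallest canonical k-mer (minimum of a k-mer and its reverse complement) in
each window of w consecutive k-mers.  A read is ASSIGNED to the transcript
sharing the most distinct minimizers when that count clears ``min_hits`` and
beats the runner-up by ``margin``; ties or thin margins are AMBIGUOUS and
excluded from downstream testing (conservative unique-assignment policy, no
fractional multi-mapping).  Canonical minimizers make assignment strand
agnostic.

Counting is transcript-first: a transcript hit increments its gene, so gene
counts are always the column sums of their isoforms' counts.  All counters
are monotone non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from streamtx.errors import ConfigurationError

if TYPE_CHECKING:  # pragma: no cover
    from streamtx.ingest import ReadRecord
    from streamtx.simulate import Reference

ASSIGNED = "ASSIGNED"
AMBIGUOUS = "AMBIGUOUS"
UNASSIGNED = "UNASSIGNED"

_CODE_LUT = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[_b + 32] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit integer code of every k-mer (forward strand)."""
    n = len(codes) - k + 1
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)[:n]
    return windows @ powers


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-independent) code of each k-mer of ``seq``."""
    codes = _encode(seq)
    fwd = _kmer_codes(codes, k)
    rc = _kmer_codes(3 - codes[::-1], k)[::-1]
    return np.minimum(fwd, rc)


def minimizers(seq: str, k: int, w: int,
               with_positions: bool = False):
    """Minimizers of ``seq``: per window of ``w`` k-mers, the smallest
    canonical k-mer code.  Consecutive windows sharing one occurrence yield
    it once.  Returns unique codes, or (codes, positions) pairs."""
    if len(seq) < k + w - 1:
        w = max(1, len(seq) - k + 1)
    if len(seq) < k:
        empty = np.empty(0, dtype=np.int64)
        return (empty, empty) if with_positions else empty
    canon = canonical_kmers(seq, k)
    win = np.lib.stride_tricks.sliding_window_view(canon, w)
    pos = win.argmin(axis=1) + np.arange(win.shape[0])
    vals = canon[pos]
    # dedupe identical (value, position) occurrences across windows
    key = (vals << 32) | pos
    uniq = np.unique(key)
    if with_positions:
        return uniq >> 32, (uniq & 0xFFFFFFFF).astype(np.int64)
    return np.unique(uniq >> 32)


@dataclass
class MinimizerIndex:
    """Sorted-array postings of minimizer -> transcripts (and positions)."""

    k: int
    w: int
    transcript_ids: list[str]
    keys: np.ndarray          # sorted unique minimizer codes
    offsets: np.ndarray       # CSR offsets into tx/pos, len(keys)+1
    tx: np.ndarray            # transcript row index per posting
    pos: np.ndarray           # k-mer position per posting
    ukeys: np.ndarray         # sorted unique minimizer codes (distinct tx)
    uoffsets: np.ndarray
    utx: np.ndarray           # distinct transcripts per minimizer

    def postings(self, minimizer: int) -> list[tuple[str, int]]:
        i = int(np.searchsorted(self.keys, minimizer))
        if i >= len(self.keys) or self.keys[i] != minimizer:
            return []
        sl = slice(self.offsets[i], self.offsets[i + 1])
        return [(self.transcript_ids[t], int(p))
                for t, p in zip(self.tx[sl], self.pos[sl])]


def build_index(reference: "Reference", k: int = 15, w: int = 10) -> MinimizerIndex:
    """Index every transcript's minimizers.  ``k`` must be odd so a k-mer
    never equals its own reverse complement."""
    if k % 2 == 0:
        raise ConfigurationError("k must be odd")
    shortest = min(t.length for t in reference.transcripts.values())
    if k > shortest:
        raise ConfigurationError(
            f"k={k} exceeds shortest transcript length {shortest}")
    t_ids = list(reference.transcript_ids)
    all_keys, all_tx, all_pos = [], [], []
    for ti, tid in enumerate(t_ids):
        vals, pos = minimizers(reference.transcripts[tid].sequence, k, w,
                               with_positions=True)
        all_keys.append(vals)
        all_pos.append(pos)
        all_tx.append(np.full(len(vals), ti, dtype=np.int64))
    keys = np.concatenate(all_keys)
    tx = np.concatenate(all_tx)
    pos = np.concatenate(all_pos)
    order = np.lexsort((pos, tx, keys))
    keys, tx, pos = keys[order], tx[order], pos[order]
    ukeys_full, counts = np.unique(keys, return_counts=True)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    # distinct-transcript postings for hit counting
    pair = (keys << 20) | tx  # transcript index < 2^20
    upair = np.unique(pair)
    ukeys_d = upair >> 20
    utx = (upair & ((1 << 20) - 1)).astype(np.int64)
    ukeys, ucounts = np.unique(ukeys_d, return_counts=True)
    uoffsets = np.concatenate(([0], np.cumsum(ucounts)))
    return MinimizerIndex(k, w, t_ids, ukeys_full, offsets, tx, pos,
                          ukeys, uoffsets, utx)


@dataclass
class Assignment:
    read_id: str
    status: str
    transcript_id: str | None
    hit_count: int

    def __post_init__(self) -> None:
        if (self.transcript_id is not None) != (self.status == ASSIGNED):
            raise ValueError("transcript_id set iff status is ASSIGNED")


def _expand_csr(starts: np.ndarray, lens: np.ndarray) -> np.ndarray:
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    rep = np.repeat(starts - np.concatenate(([0], np.cumsum(lens)[:-1])), lens)
    return rep + np.arange(total)


def assign_read(sequence: str, index: MinimizerIndex,
                min_hits: int = 5, margin: int = 2,
                read_id: str = "") -> Assignment:
    """Best-hit transcript assignment by distinct shared minimizers.

    ASSIGNED to the top transcript iff its hit count reaches ``min_hits``
    and beats the second best by at least ``margin``; AMBIGUOUS when the
    top count suffices but the margin does not (including exact ties);
    otherwise UNASSIGNED.
    """
    if len(sequence) < index.k:
        return Assignment(read_id, UNASSIGNED, None, 0)
    mins = minimizers(sequence, index.k, index.w)
    valid = np.searchsorted(index.ukeys, mins)
    inb = valid < len(index.ukeys)
    valid = valid[inb]
    valid = valid[index.ukeys[valid] == mins[inb]]
    if len(valid) == 0:
        return Assignment(read_id, UNASSIGNED, None, 0)
    starts = index.uoffsets[valid]
    lens = index.uoffsets[valid + 1] - starts
    cand = index.utx[_expand_csr(starts, lens)]
    hits = np.bincount(cand, minlength=len(index.transcript_ids))
    best_i = int(hits.argmax())
    best = int(hits[best_i])
    hits[best_i] = 0
    second = int(hits.max()) if len(hits) > 1 else 0
    if best < min_hits:
        return Assignment(read_id, UNASSIGNED, None, best)
    if best - second < margin:
        return Assignment(read_id, AMBIGUOUS, None, best)
    return Assignment(read_id, ASSIGNED, index.transcript_ids[best_i], best)


def assign_reads(records: Iterable["ReadRecord"], index: MinimizerIndex,
                 min_hits: int = 5, margin: int = 2) -> list[Assignment]:
    return [assign_read(r.sequence, index, min_hits, margin, r.read_id)
            for r in records]


class CountState:
    """Monotone transcript x sample and gene x sample count matrices.

    Per sample the conservation identity
    ``sum(transcript_counts) + ambiguous + unassigned == total`` holds after
    every update, and gene counts equal the sum of their transcripts'.
    """

    def __init__(self, reference: "Reference", samples: Sequence[str]):
        self.reference = reference
        self.samples = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ConfigurationError("duplicate sample ids")
        self._col = {s: j for j, s in enumerate(self.samples)}
        n_t, n_g, n_s = (len(reference.transcript_ids),
                         len(reference.gene_ids), len(self.samples))
        self._t = np.zeros((n_t, n_s), dtype=np.int64)
        self._g = np.zeros((n_g, n_s), dtype=np.int64)
        self._gene_row = np.array(
            [reference.gene_index[reference.gene_of[t]]
             for t in reference.transcript_ids])
        self.ambiguous = dict.fromkeys(self.samples, 0)
        self.unassigned = dict.fromkeys(self.samples, 0)
        self.total = dict.fromkeys(self.samples, 0)

    def update_counts(self, assignments: Sequence[Assignment],
                      sample_id: str) -> "CountState":
        if sample_id not in self._col:
            raise KeyError(f"unknown sample {sample_id!r}")
        j = self._col[sample_id]
        tx_rows = []
        for a in assignments:
            if a.status == ASSIGNED:
                try:
                    tx_rows.append(
                        self.reference.transcript_index[a.transcript_id])
                except KeyError:
                    raise KeyError(
                        f"assignment to unknown transcript {a.transcript_id!r}"
                    ) from None
            elif a.status == AMBIGUOUS:
                self.ambiguous[sample_id] += 1
            else:
                self.unassigned[sample_id] += 1
        if tx_rows:
            inc = np.bincount(np.asarray(tx_rows), minlength=self._t.shape[0])
            self._t[:, j] += inc
            gi = np.zeros(self._g.shape[0], dtype=np.int64)
            np.add.at(gi, self._gene_row, inc)
            self._g[:, j] += gi
        self.total[sample_id] += len(assignments)
        return self

    # -- views --------------------------------------------------------------

    @property
    def transcript_counts(self) -> pd.DataFrame:
        return pd.DataFrame(self._t.copy(),
                            index=self.reference.transcript_ids,
                            columns=self.samples)

    @property
    def gene_counts(self) -> pd.DataFrame:
        return pd.DataFrame(self._g.copy(), index=self.reference.gene_ids,
                            columns=self.samples)

    def assigned_total(self, sample_id: str) -> int:
        return int(self._t[:, self._col[sample_id]].sum())

    def check_conservation(self) -> None:
        for s in self.samples:
            lhs = self.assigned_total(s) + self.ambiguous[s] + self.unassigned[s]
            if lhs != self.total[s]:
                raise AssertionError(
                    f"conservation violated for {s}: {lhs} != {self.total[s]}")
            j = self._col[s]
            gsum = np.zeros(self._g.shape[0], dtype=np.int64)
            np.add.at(gsum, self._gene_row, self._t[:, j])
            if not np.array_equal(gsum, self._g[:, j]):
                raise AssertionError(f"gene/transcript count mismatch for {s}")


def brute_force_assign(sequence: str, reference: "Reference") -> list[str]:
    """Oracle: transcripts containing the read (or its reverse complement)
    as an exact substring.  Independent of the minimizer machinery."""
    from streamtx.simulate import reverse_complement

    rc = reverse_complement(sequence)
    return [tid for tid, t in reference.transcripts.items()
            if sequence in t.sequence or rc in t.sequence]
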