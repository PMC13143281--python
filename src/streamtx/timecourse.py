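"""Scheduled snapshots and cross-snapshot persistence of DE calls.

A snapshot freezes the accumulated counts at a scheduled time (minutes
post-sequencing-initiation), runs the full QC + DE (genes and transcripts)
+ DTU battery on the frozen matrices, and writes the per-snapshot tables.
Across snapshots, DEG membership is summarized as Venn region counts (one
region per non-empty subset signature of the snapshot set) and a persistent
set: genes significant at every snapshot with a consistent direction.  Both
the sign-consistent and the direction-agnostic intersections are reported,
since a Venn diagram alone ignores direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from streamtx import de as de_mod
from streamtx import dtu as dtu_mod
from streamtx.quant import CountState


@dataclass
class Snapshot:
    """Frozen analysis state at one scheduled time."""

    time_minutes: int
    gene_counts: pd.DataFrame
    transcript_counts: pd.DataFrame
    size_factors: pd.Series | None
    de_genes: pd.DataFrame | None
    de_transcripts: pd.DataFrame | None
    dtu: pd.DataFrame | None
    qc: dict = field(default_factory=dict)

    @property
    def de_available(self) -> bool:
        return self.de_genes is not None


def _de_feasible(counts: pd.DataFrame, groups: Mapping[str, str],
                 contrast: tuple[str, str]) -> bool:
    g = de_mod._groups_to_series(groups, counts.columns)
    for cond in contrast:
        cols = [s for s in counts.columns if g[s] == cond]
        nonzero = sum(counts[s].sum() > 0 for s in cols)
        if nonzero < 2:
            return False
    return bool((counts.to_numpy() > 0).all(axis=1).any())


def take_snapshot(state: CountState,
                  time_minutes: int,
                  groups: Mapping[str, str] | pd.Series,
                  contrast: tuple[str, str],
                  outdir: str | Path | None = None,
                  padj_threshold: float = 0.05,
                  min_total_count: int = 10,
                  dtu_min_gene_count: int = 10) -> Snapshot:
    """Freeze ``state`` and run the analysis battery on it.

    When either condition lacks two samples with nonzero libraries (or no
    feature is positive everywhere, so size factors are undefined) the
    snapshot is still written, with DE/DTU marked unavailable.
    """
    state.check_conservation()
    gene_counts = state.gene_counts
    tx_counts = state.transcript_counts
    sf = de_tab = dte_tab = dtu_tab = None
    if _de_feasible(gene_counts, groups, contrast):
        sf = de_mod.size_factors(gene_counts)
        norm = de_mod.normalize(gene_counts, sf)
        disp = de_mod.estimate_dispersions(norm, groups)
        de_tab = de_mod.wald_test(gene_counts, sf, disp, groups, contrast,
                                  min_total_count=min_total_count)
        tx_sf = sf  # library-level factors shared across feature levels
        tx_disp = de_mod.estimate_dispersions(
            de_mod.normalize(tx_counts, tx_sf), groups)
        dte_tab = de_mod.wald_test(tx_counts, tx_sf, tx_disp, groups,
                                   contrast, min_total_count=min_total_count)
        dtu_tab = dtu_mod.dtu_test(tx_counts, state.reference.tx2gene,
                                   groups, contrast,
                                   min_gene_count=dtu_min_gene_count)
    snap = Snapshot(time_minutes, gene_counts, tx_counts, sf,
                    de_tab, dte_tab, dtu_tab)
    if outdir is not None:
        write_snapshot(snap, outdir, groups)
    return snap


def write_snapshot(snap: Snapshot, outdir: str | Path,
                   groups: Mapping[str, str] | pd.Series) -> Path:
    t = snap.time_minutes
    outdir = Path(outdir) / f"snapshot_{t:04d}"
    outdir.mkdir(parents=True, exist_ok=True)
    snap.gene_counts.to_csv(outdir / f"gene_counts_{t}.tsv", sep="\t")
    snap.transcript_counts.to_csv(outdir / f"transcript_counts_{t}.tsv",
                                  sep="\t")
    if not snap.de_available:
        (outdir / "de_unavailable.txt").write_text(
            "differential expression unavailable: insufficient replicates "
            "with nonzero libraries or size factors undefined\n")
        return outdir
    snap.size_factors.to_csv(outdir / f"size_factors_{t}.tsv", sep="\t")
    snap.de_genes.to_csv(outdir / f"de_genes_{t}.tsv", sep="\t")
    snap.de_transcripts.to_csv(outdir / f"de_transcripts_{t}.tsv", sep="\t")
    snap.dtu.to_csv(outdir / f"dtu_{t}.tsv", sep="\t")
    trans = de_mod.transform_log(snap.gene_counts, snap.size_factors)
    try:
        pca_res = de_mod.pca(trans)
        coords = pca_res.coordinates.copy()
        coords.loc["explained_variance_fraction"] = np.concatenate(
            [pca_res.explained_variance_fraction,
             np.zeros(coords.shape[1]
                      - len(pca_res.explained_variance_fraction))])
        coords.to_csv(outdir / f"pca_{t}.tsv", sep="\t")
    except ValueError:
        pass
    de_mod.sample_distances(trans).to_csv(outdir / f"distances_{t}.tsv",
                                          sep="\t")
    return outdir


# ---------------------------------------------------------------------------
# Cross-snapshot persistence


@dataclass
class PersistenceReport:
    """DEG membership across snapshots and its Venn decomposition.

    ``membership`` holds +1/-1/0 (up / down / not significant) per gene and
    snapshot; ``venn_regions`` maps a boolean signature over snapshots to
    the number of union genes with exactly that membership pattern, so the
    region counts partition the union of DEG sets.
    """

    snapshot_times: list[int]
    membership: pd.DataFrame
    venn_regions: dict[tuple[bool, ...], int]
    persistent_set: set[str]
    persistent_set_any_sign: set[str]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        venn = pd.DataFrame(
            [{"signature": "".join("1" if b else "0" for b in sig),
              "count": n} for sig, n in sorted(self.venn_regions.items())])
        return self.membership, venn


def deg_overlap(snapshots: Sequence[Snapshot],
                padj_threshold: float = 0.05,
                lfc_threshold: float = 0.0) -> PersistenceReport:
    """Cross-reference DEG sets across snapshots.

    Significance is padj < threshold (plus an optional |log2FC| cutoff,
    off by default).  Returns Venn region counts over all non-empty
    signatures and both the sign-consistent and direction-agnostic
    persistent intersections.
    """
    with_de = [s for s in snapshots if s.de_available]
    if len(with_de) < 1:
        raise ValueError("no snapshot carries a DE table")
    times = [s.time_minutes for s in with_de]
    genes = sorted(set().union(*[set(s.de_genes.index) for s in with_de]))
    member = pd.DataFrame(0, index=genes,
                          columns=[f"t{t}" for t in times], dtype=int)
    for s in with_de:
        tab = s.de_genes
        sig = (tab["padj"] < padj_threshold) & \
              (tab["log2FC"].abs() >= lfc_threshold)
        sig = sig.fillna(False)
        member.loc[tab.index[sig], f"t{s.time_minutes}"] = \
            np.sign(tab.loc[sig, "log2FC"]).astype(int)

    in_set = member != 0
    union_mask = in_set.any(axis=1)
    venn: dict[tuple[bool, ...], int] = {}
    patterns = in_set[union_mask]
    if len(patterns):
        grouped = patterns.groupby(list(patterns.columns)).size()
        for sig_key, count in grouped.items():
            key = sig_key if isinstance(sig_key, tuple) else (sig_key,)
            venn[tuple(bool(b) for b in key)] = int(count)
    for sig in product([False, True], repeat=len(times)):
        if any(sig):
            venn.setdefault(sig, 0)

    everywhere = in_set.all(axis=1)
    consistent = everywhere & member.apply(
        lambda row: len(set(row[row != 0])) == 1, axis=1)
    return PersistenceReport(
        times, member,
        venn,
        set(member.index[consistent]),
        set(member.index[everywhere]),
    )
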