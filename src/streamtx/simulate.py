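"""Synthetic nanopore-style transcriptome runs with ground truth.

This module builds a synthetic reference transcriptome (FASTA + GTF + BED +
gene/transcript map), derives condition-specific expression profiles
(fold changes, knockouts, overexpression/rescue, strain-specific marker
genes such as antibiotic-resistance cassettes, rRNA-class depletion or
enrichment factors, heat-shock-style induction, isoform-usage switches),
samples 3'-anchored error-prone long reads, and writes a timed run directory
that emulates a sequencer's ``fastq_pass/<barcode>/`` output, together with
a truth ledger recording every read's transcript of origin and each gene's
true differential-expression label.

Two counts-level generators (:func:`simulate_count_matrix`,
:func:`simulate_nb_counts`) draw count matrices directly from the same
expression profiles — equivalent in distribution to error-free unique
assignment of the simulated reads — for scenarios whose sequencing depth
would make read-level emission pointless for the statistical question.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from streamtx.errors import ConfigurationError

GENE_CLASSES = ("mRNA", "rRNA", "mito_rRNA", "marker")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G (ASCII)
_RC_TABLE = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_class: str
    transcript_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ConfigurationError(
                f"unknown gene_class {self.gene_class!r} for {self.gene_id}"
            )
        if not self.transcript_ids:
            raise ConfigurationError(f"gene {self.gene_id} has no transcripts")


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ScenarioConfig:
    """Two-condition experimental design for the synthetic run.

    The second entry of ``conditions`` is the perturbed strain or treatment:
    fold changes, knockouts, overexpression and induction all describe that
    condition relative to the first.  ``marker_map`` lists foreign genes
    (KanR/HygR/AmpR-like cassettes) carried — and hence expressible — only by
    the listed condition; every marker gene is nevertheless present in the
    annotation for all samples, which is what makes foreign-transcript
    detection meaningful.
    """

    n_genes: int = 2000
    isoforms_per_gene: int | Sequence[float] = 1
    conditions: tuple[str, str] = ("control", "treated")
    fold_change_set: dict[str, float] = field(default_factory=dict)
    knockout_set: set[str] = field(default_factory=set)
    overexpression_set: dict[str, float] = field(default_factory=dict)
    marker_map: dict[str, set[str]] = field(default_factory=dict)
    class_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    induced_set: dict[str, float] = field(default_factory=dict)
    isoform_switch_set: set[str] = field(default_factory=set)
    switch_major_fraction: float = 0.8
    abundance_boost: dict[str, float] = field(default_factory=dict)
    replicates_per_condition: int = 3
    rrna_genes: int = 0
    mito_rrna_genes: int = 0
    rrna_abundance_boost: float = 50.0
    marker_abundance_boost: float = 3.0
    abundance_log_sigma: float = 1.0
    replicate_log_sigma: float = 0.2
    length_log_median: float = 1500.0
    length_log_sigma: float = 0.35
    min_transcript_length: int = 200
    isoform_shared_prefix_frac: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        if self.replicates_per_condition < 2:
            raise ConfigurationError("replicates_per_condition must be >= 2")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ConfigurationError("exactly two distinct conditions required")
        for g, f in {**self.fold_change_set, **self.overexpression_set,
                     **self.induced_set}.items():
            if f <= 0:
                raise ConfigurationError(f"fold change for {g} must be > 0")
        if self.knockout_set & set(self.overexpression_set):
            raise ConfigurationError(
                "a gene cannot be both knocked out and overexpressed "
                "within one condition"
            )
        if self.rrna_genes + self.mito_rrna_genes > self.n_genes:
            raise ConfigurationError("rRNA-class genes exceed n_genes")
        for cond in self.marker_map:
            if cond not in self.conditions:
                raise ConfigurationError(f"marker condition {cond!r} unknown")


@dataclass
class ExpressionProfile:
    """Per-condition gene abundance simplex plus per-gene isoform usage."""

    condition: str
    abundance: dict[str, float]
    isoform_usage: dict[str, np.ndarray]

    def validate(self, atol: float = 1e-9) -> None:
        total = sum(self.abundance.values())
        if abs(total - 1.0) > atol:
            raise ConfigurationError(f"abundance sums to {total}, not 1")
        for g, u in self.isoform_usage.items():
            if abs(float(u.sum()) - 1.0) > atol:
                raise ConfigurationError(f"isoform usage of {g} not a simplex")


@dataclass
class RunSchedule:
    """Timing of batch arrival and of analysis snapshots, in minutes PSI.

    ``reads_per_batch_per_sample`` is either a constant or one value per
    batch, allowing throughput decay (or growth) over the run.
    """

    total_minutes: int = 1440
    batch_interval_minutes: int = 30
    reads_per_batch_per_sample: int | Sequence[int] = 1000
    snapshot_minutes: tuple[int, ...] = (60, 120, 300, 600, 1440)

    def __post_init__(self) -> None:
        snaps = tuple(self.snapshot_minutes)
        if list(snaps) != sorted(set(snaps)):
            raise ConfigurationError("snapshot_minutes must be strictly increasing")
        if snaps and (snaps[0] < 0 or snaps[-1] > self.total_minutes):
            raise ConfigurationError("snapshot_minutes outside [0, total_minutes]")
        self.snapshot_minutes = snaps

    @property
    def batch_minutes(self) -> list[int]:
        step = self.batch_interval_minutes
        return list(range(step, self.total_minutes + 1, step))

    def reads_for_batch(self, batch_index: int) -> int:
        r = self.reads_per_batch_per_sample
        if isinstance(r, (int, np.integer)):
            return int(r)
        return int(r[batch_index])


@dataclass
class TruthLedger:
    """Ground truth of a simulated run.

    ``read_origin`` maps read_id -> transcript_id, ``de_labels`` maps
    gene_id -> up/down/null for the perturbed-vs-reference contrast, and
    ``sample_profiles`` holds each replicate's realized gene abundances
    (condition profile perturbed by replicate-level lognormal noise).
    """

    read_origin: dict[str, str] = field(default_factory=dict)
    read_batch: dict[str, str] = field(default_factory=dict)
    de_labels: dict[str, str] = field(default_factory=dict)
    sample_profiles: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": list(self.read_origin),
                "transcript_id": list(self.read_origin.values()),
                "batch": [self.read_batch[r] for r in self.read_origin],
            }
        )


class Reference:
    """A synthetic transcriptome: gene models plus transcript sequences."""

    def __init__(self, genes: Sequence[GeneModel],
                 transcripts: Mapping[str, TranscriptModel]):
        self.genes = list(genes)
        self.transcripts = dict(transcripts)
        gene_ids = [g.gene_id for g in self.genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise ConfigurationError("duplicate gene IDs in reference")
        if len(self.transcripts) != sum(len(g.transcript_ids) for g in self.genes):
            raise ConfigurationError("duplicate transcript IDs in reference")
        self.gene_ids = gene_ids
        self.transcript_ids = [t for g in self.genes for t in g.transcript_ids]
        self.gene_of = {t.transcript_id: t.gene_id
                        for t in self.transcripts.values()}
        self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self.transcript_index = {t: i for i, t in enumerate(self.transcript_ids)}
        self._by_gene = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_gene[gene_id]

    @property
    def tx2gene(self) -> pd.Series:
        return pd.Series({t: self.gene_of[t] for t in self.transcript_ids},
                         name="gene_id")

    # -- serialization ------------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA / GTF (1-based closed) / BED (0-based half-open) / map.

        Genes are laid end to end on a single synthetic contig with 1 kb
        spacers; each transcript is a single exon spanning its own length at
        the gene start, which is all downstream consumers need.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "transcripts.fasta",
            "gtf": outdir / "annotation.gtf",
            "bed": outdir / "genes.bed",
            "map": outdir / "tx2gene.tsv",
        }
        with open(paths["fasta"], "w") as fa:
            for tid in self.transcript_ids:
                seq = self.transcripts[tid].sequence
                fa.write(f">{tid} gene={self.gene_of[tid]}\n")
                for i in range(0, len(seq), 80):
                    fa.write(seq[i:i + 80] + "\n")
        contig = "chrSim"
        with open(paths["gtf"], "w") as gtf, open(paths["bed"], "w") as bed:
            start0 = 0  # 0-based gene start on the synthetic contig
            for gene in self.genes:
                span = max(self.transcripts[t].length
                           for t in gene.transcript_ids)
                attrs = (f'gene_id "{gene.gene_id}"; '
                         f'gene_biotype "{gene.gene_class}";')
                gtf.write("\t".join([
                    contig, "streamtx", "gene", str(start0 + 1),
                    str(start0 + span), ".", "+", ".", attrs]) + "\n")
                for tid in gene.transcript_ids:
                    tlen = self.transcripts[tid].length
                    tattrs = attrs + f' transcript_id "{tid}";'
                    for feat in ("transcript", "exon"):
                        gtf.write("\t".join([
                            contig, "streamtx", feat, str(start0 + 1),
                            str(start0 + tlen), ".", "+", ".", tattrs]) + "\n")
                bed.write("\t".join([
                    contig, str(start0), str(start0 + span),
                    gene.gene_id, "0", "+"]) + "\n")
                start0 += span + 1000
        with open(paths["map"], "w") as m:
            m.write("transcript_id\tgene_id\tgene_class\n")
            for tid in self.transcript_ids:
                gid = self.gene_of[tid]
                m.write(f"{tid}\t{gid}\t{self.gene(gid).gene_class}\n")
        return paths

    @classmethod
    def load(cls, refdir: str | Path) -> "Reference":
        """Load a reference previously written by :meth:`write`."""
        from Bio import SeqIO

        refdir = Path(refdir)
        mapping = pd.read_csv(refdir / "tx2gene.tsv", sep="\t")
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(refdir / "transcripts.fasta"), "fasta")}
        genes: dict[str, list[str]] = {}
        classes: dict[str, str] = {}
        for row in mapping.itertuples(index=False):
            genes.setdefault(row.gene_id, []).append(row.transcript_id)
            classes[row.gene_id] = row.gene_class
        gene_models = [GeneModel(g, classes[g], tuple(ts))
                       for g, ts in genes.items()]
        transcripts = {
            tid: TranscriptModel(tid, row_gene, seqs[tid])
            for row_gene, tids in genes.items() for tid in tids
        }
        return cls(gene_models, transcripts)


# ---------------------------------------------------------------------------
# Reference construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _draw_isoform_count(cfg: ScenarioConfig, rng: np.random.Generator) -> int:
    spec = cfg.isoforms_per_gene
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    probs = np.asarray(spec, dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(np.arange(1, len(probs) + 1), p=probs))


def build_reference(config: ScenarioConfig,
                    seed: int | None = None,
                    outdir: str | Path | None = None) -> Reference:
    """Generate the synthetic transcriptome described by ``config``.

    Marker genes named in ``marker_map`` are appended beyond ``n_genes`` with
    class ``marker`` so the annotation carries them for every sample.
    Isoforms of one gene share a 5' prefix and carry isoform-specific 3'
    tails, mimicking alternative last exons; since reads are 3'-anchored this
    keeps isoforms distinguishable while still exercising shared sequence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes: list[GeneModel] = []
    transcripts: dict[str, TranscriptModel] = {}
    width = max(4, len(str(config.n_genes)))

    classes = (["rRNA"] * config.rrna_genes
               + ["mito_rRNA"] * config.mito_rrna_genes)
    classes += ["mRNA"] * (config.n_genes - len(classes))

    def add_gene(gene_id: str, gene_class: str, n_iso: int) -> None:
        lengths = np.exp(rng.normal(np.log(config.length_log_median),
                                    config.length_log_sigma, size=n_iso))
        lengths = np.maximum(lengths.astype(int), config.min_transcript_length)
        backbone = _random_seq(rng, int(lengths.max()))
        tids = []
        for j, ln in enumerate(lengths):
            prefix_len = int(config.isoform_shared_prefix_frac * ln)
            seq = backbone[:prefix_len] + _random_seq(rng, int(ln) - prefix_len)
            tid = f"{gene_id}.t{j + 1}"
            if tid in transcripts:
                raise ConfigurationError(f"duplicate transcript id {tid}")
            transcripts[tid] = TranscriptModel(tid, gene_id, seq)
            tids.append(tid)
        genes.append(GeneModel(gene_id, gene_class, tuple(tids)))

    for i, gene_class in enumerate(classes):
        add_gene(f"G{i + 1:0{width}d}", gene_class,
                 _draw_isoform_count(config, rng))
    marker_ids = sorted({g for gs in config.marker_map.values() for g in gs})
    for mid in marker_ids:
        if any(g.gene_id == mid for g in genes):
            raise ConfigurationError(f"duplicate gene id {mid}")
        add_gene(mid, "marker", 1)

    ref = Reference(genes, transcripts)
    if outdir is not None:
        ref.write(outdir)
    return ref


# ---------------------------------------------------------------------------
# Expression profiles


def make_expression_profiles(reference: Reference,
                             scenario: ScenarioConfig) -> dict[str, ExpressionProfile]:
    """Build the per-condition abundance simplexes and isoform usages.

    Base abundances are lognormal across genes (rRNA-class genes boosted so
    they dominate total RNA as in real libraries); condition-specific edits
    (fold changes, knockouts, overexpression, induction, per-class factors,
    marker carriage) are applied multiplicatively before renormalization, so
    a configured fold change f satisfies
    ``abundance_B(g)/abundance_A(g) = f`` pre-normalization.
    """
    scenario.validate()
    known = set(reference.gene_ids)
    for gid in (set(scenario.fold_change_set) | scenario.knockout_set
                | set(scenario.overexpression_set) | set(scenario.induced_set)
                | scenario.isoform_switch_set | set(scenario.abundance_boost)
                | {g for gs in scenario.marker_map.values() for g in gs}):
        if gid not in known:
            raise ConfigurationError(f"configured gene {gid!r} not in reference")

    rng = np.random.default_rng([scenario.seed, 0xE])
    base = np.exp(rng.normal(0.0, scenario.abundance_log_sigma,
                             size=len(reference.gene_ids)))
    for i, g in enumerate(reference.genes):
        if g.gene_class in ("rRNA", "mito_rRNA"):
            base[i] *= scenario.rrna_abundance_boost
        elif g.gene_class == "marker":
            base[i] = np.median(base) * scenario.marker_abundance_boost
    median_base = float(np.median(base))
    for gid, factor in scenario.abundance_boost.items():
        # pin targeted genes (e.g. knockouts of well-expressed genes) to a
        # chosen multiple of the median expression level
        base[reference.gene_index[gid]] = median_base * factor

    usage_a: dict[str, np.ndarray] = {}
    usage_b: dict[str, np.ndarray] = {}
    for g in reference.genes:
        n_iso = len(g.transcript_ids)
        u = (np.ones(1) if n_iso == 1
             else rng.dirichlet(np.full(n_iso, 2.0)))
        u = u / u.sum()
        if g.gene_id in scenario.isoform_switch_set and n_iso >= 2:
            # defined usage switch: the major isoform carries
            # switch_major_fraction in the reference condition, the rest is
            # spread evenly; the perturbed condition reverses the simplex
            major = scenario.switch_major_fraction
            u = np.full(n_iso, (1.0 - major) / (n_iso - 1))
            u[0] = major
        usage_a[g.gene_id] = u
        usage_b[g.gene_id] = (u[::-1].copy()
                              if g.gene_id in scenario.isoform_switch_set else u)

    cond_a, cond_b = scenario.conditions
    profiles: dict[str, ExpressionProfile] = {}
    for cond, usage in ((cond_a, usage_a), (cond_b, usage_b)):
        w = base.copy()
        carried = {g for c, gs in scenario.marker_map.items()
                   if c == cond for g in gs}
        for i, g in enumerate(reference.genes):
            gid = g.gene_id
            if g.gene_class == "marker" and gid not in carried:
                w[i] = 0.0
            if cond == cond_b:
                if gid in scenario.knockout_set:
                    w[i] = 0.0
                if gid in scenario.fold_change_set:
                    w[i] *= scenario.fold_change_set[gid]
                if gid in scenario.overexpression_set:
                    w[i] *= scenario.overexpression_set[gid]
                if gid in scenario.induced_set:
                    w[i] *= scenario.induced_set[gid]
            factor = scenario.class_factors.get((cond, g.gene_class))
            if factor is not None:
                w[i] *= factor
        total = w.sum()
        if total <= 0:
            raise ConfigurationError(f"all-zero expression profile for {cond}")
        abundance = {g: float(x / total)
                     for g, x in zip(reference.gene_ids, w)}
        profiles[cond] = ExpressionProfile(cond, abundance, usage)
        profiles[cond].validate()
    return profiles


def true_de_labels(scenario: ScenarioConfig) -> dict[str, str]:
    """Expected DE direction (perturbed vs reference) per configured gene."""
    labels: dict[str, str] = {}
    for g, f in scenario.fold_change_set.items():
        labels[g] = "up" if f > 1 else ("down" if f < 1 else "null")
    for g, f in scenario.overexpression_set.items():
        labels[g] = "up" if f > 1 else "down"
    for g, f in scenario.induced_set.items():
        labels[g] = "up" if f > 1 else "down"
    for g in scenario.knockout_set:
        labels[g] = "down"
    cond_a, cond_b = scenario.conditions
    for g in scenario.marker_map.get(cond_b, set()):
        labels[g] = "up"
    for g in scenario.marker_map.get(cond_a, set()):
        labels[g] = "down"
    return labels


# ---------------------------------------------------------------------------
# Read sampling


@dataclass
class LengthModel:
    """Truncated lognormal read lengths, clipped to [min_length, transcript]."""

    median: float = 1000.0
    sigma_log: float = 0.6
    min_length: int = 100

    def draw(self, rng: np.random.Generator, transcript_length: int) -> int:
        ln = np.exp(rng.normal(np.log(self.median), self.sigma_log)) \
            if self.sigma_log > 0 else self.median
        return int(np.clip(int(ln), min(self.min_length, transcript_length),
                           transcript_length))


@dataclass
class ErrorModel:
    substitution: float = 0.02
    insertion: float = 0.01
    deletion: float = 0.01


_QUAL_CHAR = "?"  # constant Q30 placeholder


def _apply_errors(seq: str, em: ErrorModel, rng: np.random.Generator) -> str:
    if em.substitution == em.insertion == em.deletion == 0:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = np.searchsorted(_BASES, codes)  # ACGT -> 0..3 (bases are sorted)
    u = rng.random(len(idx))
    sub = u < em.substitution
    if sub.any():
        idx = idx.copy()
        idx[sub] = (idx[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    keep = rng.random(len(idx)) >= em.deletion
    ins = rng.random(len(idx)) < em.insertion
    # layout: each template position contributes its kept base, then any
    # inserted base immediately after it
    slots = keep.astype(np.int64) + ins.astype(np.int64)
    starts = np.concatenate(([0], np.cumsum(slots)[:-1]))
    out = np.empty(int(slots.sum()), dtype=np.uint8)
    out[starts[keep]] = _BASES[idx[keep]]
    if ins.any():
        out[starts[ins] + keep[ins]] = _BASES[
            rng.integers(0, 4, size=int(ins.sum()))]
    return out.tobytes().decode("ascii")


def sample_read(transcript: TranscriptModel,
                length_model: LengthModel,
                error_model: ErrorModel,
                rng: np.random.Generator) -> tuple[str, str]:
    """Draw one 3'-anchored read from ``transcript``.

    Returns ``(sequence, qualities)``.  The fragment covers the transcript's
    3' end (emulating oligo(dT)-primed double-stranded cDNA), is reported on
    either strand with probability 1/2, and then passes through the
    substitution/insertion/deletion channel.
    """
    ln = length_model.draw(rng, transcript.length)
    frag = transcript.sequence[transcript.length - ln:]
    if rng.random() < 0.5:
        frag = reverse_complement(frag)
    frag = _apply_errors(frag, error_model, rng)
    return frag, _QUAL_CHAR * len(frag)


# ---------------------------------------------------------------------------
# Manifests and per-sample profiles


def make_manifest(scenario: ScenarioConfig) -> pd.DataFrame:
    """Barcode -> sample -> condition table for the scenario's design."""
    rows = []
    bc = 1
    for cond in scenario.conditions:
        for rep in range(1, scenario.replicates_per_condition + 1):
            rows.append({"barcode": f"barcode{bc:02d}",
                         "sample_id": f"{cond}_{rep}", "condition": cond})
            bc += 1
    return pd.DataFrame(rows)


def _replicate_profiles(reference: Reference,
                        profiles: Mapping[str, ExpressionProfile],
                        manifest: pd.DataFrame,
                        sigma: float,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-sample transcript-level sampling weights.

    Each replicate perturbs its condition's gene abundances by i.i.d.
    lognormal noise (biological variability), renormalizes, then spreads
    gene mass over isoforms by the condition's usage simplex.
    """
    t_index = reference.transcript_index
    out: dict[str, np.ndarray] = {}
    for row in manifest.itertuples(index=False):
        prof = profiles[row.condition]
        gene_w = np.array([prof.abundance[g] for g in reference.gene_ids])
        if sigma > 0:
            gene_w = gene_w * np.exp(rng.normal(0.0, sigma, size=len(gene_w)))
        gene_w = gene_w / gene_w.sum()
        tw = np.zeros(len(t_index))
        for gi, g in enumerate(reference.genes):
            usage = prof.isoform_usage[g.gene_id]
            for u, tid in zip(usage, g.transcript_ids):
                tw[t_index[tid]] = gene_w[gi] * u
        out[row.sample_id] = tw
    return out


# ---------------------------------------------------------------------------
# Run-directory simulation


def simulate_run(reference: Reference,
                 profiles: Mapping[str, ExpressionProfile],
                 schedule: RunSchedule,
                 manifest: pd.DataFrame,
                 seed: int,
                 outdir: str | Path,
                 scenario: ScenarioConfig | None = None,
                 length_model: LengthModel | None = None,
                 error_model: ErrorModel | None = None,
                 replicate_log_sigma: float | None = None,
                 overwrite: bool = False) -> TruthLedger:
    """Write a timed ``fastq_pass/<barcode>/batch_<t>_<i>.fastq`` run directory.

    Per batch and sample, read counts per transcript are multinomial draws
    from the sample's replicate profile.  Batch files are written to a
    temporary name and renamed into place, so a watcher never sees a partial
    file.  Returns the truth ledger (also written as TSV alongside the run).
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise ConfigurationError(
            f"run directory {outdir} exists and is not empty "
            "(pass overwrite=True to replace)")
    for cond in manifest["condition"].unique():
        if cond not in profiles:
            raise ConfigurationError(f"no expression profile for {cond!r}")
    length_model = length_model or LengthModel()
    error_model = error_model or ErrorModel()
    if replicate_log_sigma is None:
        replicate_log_sigma = (scenario.replicate_log_sigma
                               if scenario is not None else 0.2)

    rng = np.random.default_rng([seed, 0x5EED])
    sample_weights = _replicate_profiles(reference, profiles, manifest,
                                         replicate_log_sigma, rng)
    ledger = TruthLedger()
    if scenario is not None:
        ledger.de_labels = true_de_labels(scenario)
    gene_names = reference.gene_ids
    for sid, tw in sample_weights.items():
        gene_w = np.zeros(len(gene_names))
        for tid, w in zip(reference.transcript_ids, tw):
            gene_w[reference.gene_index[reference.gene_of[tid]]] += w
        ledger.sample_profiles[sid] = dict(zip(gene_names, gene_w))

    t_ids = reference.transcript_ids
    for row in manifest.itertuples(index=False):
        (outdir / "fastq_pass" / row.barcode).mkdir(parents=True, exist_ok=True)

    for bi, minute in enumerate(schedule.batch_minutes):
        n_reads = schedule.reads_for_batch(bi)
        for row in manifest.itertuples(index=False):
            bc_dir = outdir / "fastq_pass" / row.barcode
            fname = f"batch_{minute:04d}_{bi:03d}.fastq"
            counts = (rng.multinomial(n_reads, sample_weights[row.sample_id])
                      if n_reads > 0 else np.zeros(len(t_ids), dtype=int))
            fd, tmp = tempfile.mkstemp(dir=bc_dir, suffix=".tmp")
            serial = 0
            with os.fdopen(fd, "w") as fh:
                for ti in np.nonzero(counts)[0]:
                    tr = reference.transcripts[t_ids[ti]]
                    for _ in range(int(counts[ti])):
                        rid = f"{row.sample_id}_{minute:04d}_{serial:06d}"
                        serial += 1
                        seq, qual = sample_read(tr, length_model,
                                                error_model, rng)
                        fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
                        ledger.read_origin[rid] = tr.transcript_id
                        ledger.read_batch[rid] = fname
            os.replace(tmp, bc_dir / fname)

    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    ledger.to_frame().to_csv(outdir / "truth_ledger.tsv", sep="\t", index=False)
    if ledger.de_labels:
        pd.DataFrame({"gene_id": list(ledger.de_labels),
                      "label": list(ledger.de_labels.values())}
                     ).to_csv(outdir / "truth_de_labels.tsv",
                              sep="\t", index=False)
    return ledger


# ---------------------------------------------------------------------------
# Counts-level generators (deep scenarios)


def simulate_count_matrix(reference: Reference,
                          profiles: Mapping[str, ExpressionProfile],
                          manifest: pd.DataFrame,
                          depth: int,
                          seed: int,
                          replicate_log_sigma: float = 0.2,
                          snapshot_depths: Sequence[int] | None = None,
                          ) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """Multinomial transcript/gene count matrices at one or more depths.

    ``snapshot_depths`` (cumulative, non-decreasing; defaults to ``[depth]``)
    yields one pair of cumulative matrices per snapshot, with increments drawn
    independently per interval — exactly what streaming accumulation of an
    error-free run produces.  Returns ``(transcript_frames, gene_frames)``.
    """
    depths = list(snapshot_depths) if snapshot_depths is not None else [depth]
    if any(b < a for a, b in zip(depths, depths[1:])):
        raise ConfigurationError("snapshot depths must be non-decreasing")
    rng = np.random.default_rng([seed, 0xC0])
    weights = _replicate_profiles(reference, profiles, manifest,
                                  replicate_log_sigma, rng)
    samples = list(manifest["sample_id"])
    t_mat = np.zeros((len(reference.transcript_ids), len(samples)), dtype=np.int64)
    gene_rows = np.array([reference.gene_index[reference.gene_of[t]]
                          for t in reference.transcript_ids])
    t_frames, g_frames = [], []
    prev = 0
    for d in depths:
        inc = d - prev
        prev = d
        for j, sid in enumerate(samples):
            if inc > 0:
                t_mat[:, j] += rng.multinomial(inc, weights[sid])
        g_mat = np.zeros((len(reference.gene_ids), len(samples)), dtype=np.int64)
        np.add.at(g_mat, gene_rows, t_mat)
        t_frames.append(pd.DataFrame(t_mat.copy(),
                                     index=reference.transcript_ids,
                                     columns=samples))
        g_frames.append(pd.DataFrame(g_mat, index=reference.gene_ids,
                                     columns=samples))
    return t_frames, g_frames


def simulate_nb_counts(n_genes: int,
                       n_per_group: int,
                       mu: float | np.ndarray,
                       alpha: float,
                       log2fc: float | np.ndarray = 0.0,
                       seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Gamma-Poisson (negative binomial) count matrix for two groups.

    Variance is mu + alpha*mu^2; ``log2fc`` shifts group B means.  Returns
    (counts genes x samples, condition labels per sample).
    """
    rng = np.random.default_rng([seed, 0xB])
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_genes,))
    lfc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_genes,))
    cols, names, conds = [], [], []
    for grp, m in (("A", mu), ("B", mu * 2.0 ** lfc)):
        for r in range(n_per_group):
            lam = (rng.gamma(1.0 / alpha, m * alpha) if alpha > 0 else m)
            cols.append(rng.poisson(lam))
            names.append(f"{grp}_{r + 1}")
            conds.append(grp)
    counts = pd.DataFrame(np.column_stack(cols),
                          index=[f"G{i + 1:05d}" for i in range(n_genes)],
                          columns=names)
    return counts, pd.Series(conds, index=names, name="condition")
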