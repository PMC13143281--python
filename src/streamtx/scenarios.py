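"""Standard study scenarios for validating the pipeline by simulation.

Each function builds one of the package's canonical seeded experiments —
the conditions under which the method's operating characteristics
(assignment accuracy, type-I error, power, persistence, marker detection,
saturation, usage-switch detection) are measured.  The scenarios are
deliberately fixed: they define what "the standard power scenario" etc.
mean everywhere in the package, tests and reproduction script alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from streamtx import de as de_mod
from streamtx import dtu as dtu_mod
from streamtx import simulate as sim

CONTRAST = ("control", "treated")


def run_de(gene_counts: pd.DataFrame, groups: pd.Series,
           contrast=CONTRAST, min_total_count: int = 10) -> pd.DataFrame:
    """The full snapshot-level DE battery on one count matrix."""
    sf = de_mod.size_factors(gene_counts)
    disp = de_mod.estimate_dispersions(de_mod.normalize(gene_counts, sf),
                                       groups)
    return de_mod.wald_test(gene_counts, sf, disp, groups, contrast,
                            min_total_count=min_total_count)


@dataclass
class Scenario:
    config: sim.ScenarioConfig
    reference: sim.Reference
    profiles: dict[str, sim.ExpressionProfile]
    manifest: pd.DataFrame

    @property
    def groups(self) -> pd.Series:
        return pd.Series(dict(zip(self.manifest["sample_id"],
                                  self.manifest["condition"])))


def _build(config: sim.ScenarioConfig) -> Scenario:
    ref = sim.build_reference(config)
    return Scenario(config, ref, sim.make_expression_profiles(ref, config),
                    sim.make_manifest(config))


def assigner_scenario(seed: int = 1) -> Scenario:
    """500 single-isoform genes for read-assignment accuracy checks."""
    return _build(sim.ScenarioConfig(n_genes=500, isoforms_per_gene=1,
                                     seed=seed))


def power_scenario(seed: int = 7) -> Scenario:
    """2,000 genes, 100 of them shifted 4x up in the treated condition."""
    fc_genes = [f"G{i + 1:04d}" for i in range(100)]
    return _build(sim.ScenarioConfig(
        n_genes=2000, seed=seed,
        fold_change_set={g: 4.0 for g in fc_genes}))


POWER_TRUE_GENES = tuple(f"G{i + 1:04d}" for i in range(100))
POWER_DEPTH = 200_000
# cumulative depths at the five snapshots: geometric doubling to full depth
STREAMING_DEPTHS = (12_500, 25_000, 50_000, 100_000, 200_000)


def knockout_marker_scenario(seed: int = 3) -> Scenario:
    """Engineered-strain analog: one knockout, one strain-specific marker.

    The knockout targets a well-expressed gene (pinned near 3x the median
    level), as real deletion strains do; the resistance-cassette-like
    marker is annotated for both conditions but expressed only in the
    engineered one.
    """
    return _build(sim.ScenarioConfig(
        n_genes=300, seed=seed, knockout_set={"G0010"},
        marker_map={"treated": {"KanR"}},
        abundance_boost={"G0010": 3.0}))


def saturation_scenario(seed: int = 9) -> Scenario:
    """200 genes with mild abundance spread, for saturation/plateau runs."""
    return _build(sim.ScenarioConfig(n_genes=200, seed=seed,
                                     abundance_log_sigma=0.5))


def dtu_null_scenario(seed: int = 6) -> Scenario:
    """500 two-isoform genes with identical usage in both conditions."""
    return _build(sim.ScenarioConfig(
        n_genes=500, seed=seed, isoforms_per_gene=[0.0, 1.0],
        replicates_per_condition=5))


def dtu_switch_scenario(seed: int = 4) -> Scenario:
    """A 0.8<->0.2 usage switch on one well-expressed two-isoform gene.

    Roughly a tenth of genes carry two isoforms; the switch gene is pinned
    near twice the median expression so its per-sample total sits around
    200 at the scenario depth of 100k reads per sample.
    """
    return _build(sim.ScenarioConfig(
        n_genes=500, seed=seed, isoforms_per_gene=[0.9, 0.1],
        isoform_switch_set={"G0001"}, abundance_boost={"G0001": 2.0},
        replicates_per_condition=5))


DTU_DEPTH = 100_000
DTU_SWITCH_GENE = "G0001"


def saturation_curve(scn: Scenario, reads_per_iteration: int,
                     n_iterations: int, seed: int) -> list[int]:
    """Genes-detected trajectory for one sample accumulating reads."""
    rng = np.random.default_rng([seed, 0x5A])
    weights = np.array([scn.profiles["control"].abundance[g]
                        for g in scn.reference.gene_ids])
    counts = np.zeros(len(weights), dtype=np.int64)
    curve = []
    for _ in range(n_iterations):
        counts += rng.multinomial(reads_per_iteration, weights)
        curve.append(int((counts > 0).sum()))
    return curve
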