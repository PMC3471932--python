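"""End-to-end orchestration of the three screen stages.

* ``control_qc`` -- a 48/48 FCCP-vs-DMSO control plate: well statistics,
  per-parameter control variability, and the KS-based Z'.
* ``primary`` -- single high dose (100 uM) in both media, 7 parameters x 2
  conditions = 14-component vectors, 20%-change activity calls, inactives
  designated group IV, Euclidean distances for review.
* ``secondary`` -- 10-point dose series in both media for the selected
  compounds, SCRIT assembly per biological replicate, replicate-consistency
  filtering (> 0.2 pairwise Pearson distance removes the compound),
  Pearson-distance clustering, MDS, and group I-V assignment.

Stages are pure functions of their inputs; every bundle embeds a hash of the
run configuration, and per-well/per-compound exclusions are logged as
structured records rather than silently dropped.  When no measured feature
tables are supplied, plates are simulated from the phenotype models, so the
whole pipeline runs without instrument data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify, scrit, synthetic_data, well_stats
from .errors import ConfigurationError
from .plate_core import (
    CONDITIONS,
    DoseSeries,
    build_control_plate,
    build_dose_response_plate,
    build_primary_screen_plate,
)

__all__ = [
    "RunConfig",
    "run_control_qc",
    "run_primary_screen",
    "run_secondary_screen",
    "simulate_secondary_wellstats",
]

#: Parameters of the full single-dose fingerprint (7 params x 2 conditions = 14).
PRIMARY_PARAMETERS = (
    "tmrm_peripheral_integral",
    "tmrm_max_pixel",
    "hoechst_mean",
    "hoechst_integral",
    "nuclear_area",
    "nuclear_circularity",
    scrit.VIABILITY,
)

#: Default secondary-screen parameters (3 x 10 x 2 = 60-component vectors).
SECONDARY_PARAMETERS = (
    "tmrm_peripheral_integral",
    "hoechst_mean",
    scrit.VIABILITY,
)


@dataclass
class RunConfig:
    """Serializable run settings; the hash of this object stamps every output."""

    stage: str = "secondary"
    seed: int = 0
    compounds: dict = field(default_factory=dict)  # name -> archetype
    parameters: tuple = SECONDARY_PARAMETERS
    conditions: tuple = CONDITIONS
    dose_top: float = 100.0
    dose_ratio: float = 3.0
    dose_points: int = 10
    n_replicates: int = 2
    n_cells_per_well: int = 500
    activity_cutoff: float = 0.2
    replicate_threshold: float = 0.2
    gate: float | None = None  # None -> histogram-valley detection w/ default fallback
    linkage: str = "average"
    n_clusters: int = 5
    interference: tuple = ()  # compounds excluded from automated analysis

    def __post_init__(self) -> None:
        if self.stage not in ("control_qc", "primary", "secondary"):
            raise ConfigurationError(f"unknown stage {self.stage!r}")
        if self.activity_cutoff <= 0 or self.replicate_threshold <= 0:
            raise ConfigurationError("thresholds must be positive")
        self.parameters = tuple(self.parameters)
        self.conditions = tuple(self.conditions)
        self.interference = tuple(self.interference)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def dose_series(self) -> DoseSeries:
        return DoseSeries(self.dose_top, self.dose_ratio, self.dose_points)

    def sim_config(self) -> synthetic_data.SimulationConfig:
        return synthetic_data.SimulationConfig(
            n_cells_per_well=self.n_cells_per_well, seed=self.seed
        )

    def models(self) -> dict[str, synthetic_data.PhenotypeModel]:
        if not self.compounds:
            return synthetic_data.benchmark_models()
        return {
            name: synthetic_data.make_phenotype_model(arch)
            for name, arch in self.compounds.items()
        }


def _ks_parameters(parameters: Sequence[str]) -> list[str]:
    return [p for p in parameters if p != scrit.VIABILITY]


def run_control_qc(config: RunConfig, features=None, layout=None) -> dict:
    """Control-plate QC: 48/48 layout, well statistics, Z', per-parameter spread.

    The reported Z' is a robustness/reproducibility readout of the assay
    window, not a pass/fail screen criterion; QC fails only when it cannot
    be computed (missing or degenerate controls).
    """
    if layout is None:
        layout = build_control_plate(6, plate_id=f"control_s{config.seed}")
    if features is None:
        features = synthetic_data.simulate_plate(layout, {}, config.sim_config())
    report = well_stats.plate_qc(features, layout, parameters=_ks_parameters(config.parameters) or None, gate=config.gate)
    report["config_hash"] = config.hash()
    report["qc_pass"] = report.get("z_prime") is not None
    return report


def run_primary_screen(config: RunConfig, wellstats: pd.DataFrame | None = None) -> dict:
    """Single-dose pre-screen: 14-component vectors and activity calls.

    Duplicate plates per condition are averaged into one fingerprint per
    compound; a compound is active on a >= 20% change in any component, and
    inactive compounds are designated group IV.  Compounds flagged for
    marker interference are excluded from the automated calls but listed.
    """
    models = config.models()
    log: list[dict] = []
    if wellstats is None:
        frames = []
        names = list(models)
        for cond in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                layout = build_primary_screen_plate(
                    names,
                    dose=config.dose_top,
                    condition=cond,
                    plate_id=f"primary_{cond}_r{rep}",
                )
                feats = synthetic_data.simulate_plate(layout, models, config.sim_config())
                stats = well_stats.compute_well_statistics(
                    feats,
                    layout,
                    parameters=_ks_parameters(PRIMARY_PARAMETERS),
                    gate=config.gate,
                )
                stats["plate_id"] = layout.plate_id
                stats["replicate"] = "pooled"  # duplicate plates average together
                frames.append(stats)
        wellstats = pd.concat(frames, ignore_index=True)
    missing_conditions = set(config.conditions) - set(wellstats["condition"])
    if missing_conditions:
        raise ConfigurationError(
            f"primary screen lacks condition(s): {sorted(missing_conditions)}"
        )

    control_viab = wellstats.loc[
        (wellstats["role"] == "negative_control") & ~wellstats["excluded"].astype(bool),
        "viability_rescaled",
    ].mean()
    result = scrit.build_scrit(
        wellstats, parameters=PRIMARY_PARAMETERS, conditions=config.conditions
    )
    for rec in result.excluded:
        log.append({"event": "vector_excluded", **rec})

    calls = []
    vectors = []
    for v in result.vectors:
        if v.compound in config.interference:
            log.append(
                {
                    "event": "interference_excluded",
                    "compound": v.compound,
                    "reason": "marker interference flag",
                }
            )
            continue
        call = scrit.primary_screen_select(
            v,
            cutoff=config.activity_cutoff,
            control_viability_rescaled=float(control_viab),
        )
        calls.append(call)
        vectors.append(v)

    table = pd.DataFrame(
        [
            {
                "compound": c.compound,
                "active": c.active,
                "group": c.group or "",
                "triggers": ";".join(c.triggers),
            }
            for c in calls
        ]
    )
    bundle: dict = {
        "config_hash": config.hash(),
        "calls": table,
        "vectors": vectors,
        "log": log,
        "control_viability_rescaled": float(control_viab),
    }
    if len(vectors) >= 2:
        bundle["distances"] = classify.distance_matrix(vectors, metric="euclidean")
    return bundle


def simulate_secondary_wellstats(
    models: Mapping[str, synthetic_data.PhenotypeModel],
    config: RunConfig,
    compounds_per_plate: int = 4,
) -> pd.DataFrame:
    """Simulate the full secondary screen and return its well statistics.

    Compounds are packed four per 96-well plate (two replicate dose rows
    each, averaged within-plate); each biological replicate is a separate
    plate run per condition, with its own in-plate controls and pooled
    negative-control normalisation.
    """
    names = list(models)
    series = config.dose_series()
    chunks = [
        names[i : i + compounds_per_plate]
        for i in range(0, len(names), compounds_per_plate)
    ]
    frames = []
    for rep in range(1, config.n_replicates + 1):
        for cond in config.conditions:
            for pi, chunk in enumerate(chunks):
                layout = build_dose_response_plate(
                    chunk,
                    series,
                    condition=cond,
                    plate_id=f"secondary_r{rep}_{cond}_p{pi}",
                )
                feats = synthetic_data.simulate_plate(layout, models, config.sim_config())
                stats = well_stats.compute_well_statistics(
                    feats,
                    layout,
                    parameters=_ks_parameters(config.parameters),
                    gate=config.gate,
                )
                stats["plate_id"] = layout.plate_id
                stats["replicate"] = str(rep)
                frames.append(stats)
    return pd.concat(frames, ignore_index=True)


def run_secondary_screen(
    config: RunConfig,
    wellstats: pd.DataFrame | None = None,
    references: Mapping[str, scrit.SCRITVector] | None = None,
) -> dict:
    """Dose-response screen: SCRIT vectors -> filtering -> clustering -> groups.

    Returns a bundle with the vectors, replicate-consistency reports,
    Pearson distance matrix, dendrogram (linkage + Newick), 2-D/3-D MDS
    coordinates, per-item and per-compound group labels, and a structured
    log of every exclusion.  Deterministic for a fixed config.
    """
    models = config.models()
    log: list[dict] = []
    if wellstats is None:
        wellstats = simulate_secondary_wellstats(models, config)

    result = scrit.build_scrit(
        wellstats, parameters=config.parameters, conditions=config.conditions
    )
    for rec in result.excluded:
        log.append({"event": "vector_excluded", **rec})

    by_compound: dict[str, list[scrit.SCRITVector]] = {}
    for v in result.vectors:
        if v.compound in config.interference:
            log.append(
                {
                    "event": "interference_excluded",
                    "compound": v.compound,
                    "reason": "marker interference flag",
                }
            )
            continue
        by_compound.setdefault(v.compound, []).append(v)

    kept: list[scrit.SCRITVector] = []
    consistency = {}
    for compound, vecs in sorted(by_compound.items()):
        ok, report = scrit.replicate_consistency(
            vecs, threshold=config.replicate_threshold
        )
        consistency[compound] = report
        if report.flagged:
            log.append(
                {
                    "event": "replicate_outlier",
                    "compound": compound,
                    "max_pairwise_distance": report.max_distance,
                }
            )
        kept.extend(ok)

    if len(kept) < 2:
        raise ConfigurationError("fewer than two vectors survive replicate filtering")

    D = classify.distance_matrix(kept, metric="pearson")
    cluster = classify.hierarchical_cluster(
        D, linkage=config.linkage, n_clusters=config.n_clusters
    )
    if references is None:
        doses = sorted({d for _, _, d in kept[0].index})
        references = synthetic_data.archetype_references(
            parameters=list(config.parameters),
            doses=doses,
            conditions=config.conditions,
        )
    labels = classify.assign_groups(cluster, kept, references)

    compound_groups: dict[str, str] = {}
    for compound, vecs in sorted(by_compound.items()):
        member_labels = [labels[v.item_id] for v in vecs if v.item_id in labels]
        if member_labels:
            values, counts = np.unique(member_labels, return_counts=True)
            compound_groups[compound] = str(values[np.argmax(counts)])

    return {
        "config_hash": config.hash(),
        "wellstats": wellstats,
        "vectors": kept,
        "consistency": consistency,
        "distances": D,
        "cluster": cluster,
        "newick": classify.dendrogram_newick(cluster),
        "mds_2d": classify.mds_embed(D, dims=2),
        "mds_3d": classify.mds_embed(D, dims=3),
        "item_groups": labels,
        "compound_groups": compound_groups,
        "log": log,
    }


def write_secondary_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write the secondary-screen bundle as plain-text artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["wellstats"].to_csv(out / "wellstats.tsv", sep="\t", index=False)
    scrit.write_scrit_table(bundle["vectors"], out / "scrit.tsv")
    bundle["distances"].to_frame().to_csv(out / "distances.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(bundle["newick"] + "\n")
    bundle["mds_2d"].to_csv(out / "mds_2d.tsv", sep="\t")
    bundle["mds_3d"].to_csv(out / "mds_3d.tsv", sep="\t")
    pd.Series(bundle["item_groups"], name="group").rename_axis("item").to_csv(
        out / "labels.tsv", sep="\t"
    )
    with open(out / "log.jsonl", "w") as fh:
        for rec in bundle["log"]:
            fh.write(json.dumps({"config_hash": bundle["config_hash"], **rec}) + "\n")
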