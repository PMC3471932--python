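"""SCRIT vectors: multifactorial compound-response fingerprints.

A Specialized-Cell-Response-to-Induced-Toxicity (SCRIT) vector concatenates,
for one compound replicate, the normalised per-well statistics over

    parameters x conditions x doses

in a fixed order: parameter-major, glucose medium (``glu_plus``) before
galactose medium (``glu_minus``), doses ascending.  KS-based parameters
enter as the signed KS distance against the in-plate untreated control
(already in [-1, 1]); viability enters as the rescaled live fraction
(2 f - 1).  The classic shapes are 2 x 10 x 2 = 40 components (TMRM
peripheral integral + viability over a 10-point dose series in both media),
3 x 10 x 2 = 60 (adding the Hoechst mean), and the single-dose primary
screen's 7 x 1 x 2 = 14.

Replicate wells at the same dose within one plate run are averaged into one
well statistic before assembly; separate plate runs (biological replicates)
yield separate vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError
from .plate_core import CONDITIONS

__all__ = [
    "VIABILITY",
    "SCRITVector",
    "BuildResult",
    "ActivityCall",
    "ConsistencyReport",
    "component_index",
    "build_scrit",
    "primary_screen_select",
    "replicate_consistency",
    "truncate_scrit",
    "write_scrit_table",
    "read_scrit_table",
]

#: Pseudo-parameter name selecting the rescaled viability instead of a KS column.
VIABILITY = "viability"


def component_index(
    parameters: Sequence[str],
    conditions: Sequence[str],
    doses: Sequence[float],
) -> tuple[tuple[str, str, float], ...]:
    """Canonical component ordering: parameter-major, then condition, then dose ascending."""
    if not parameters or not conditions or not doses:
        raise ContractError("parameters, conditions and doses must be non-empty")
    doses_sorted = sorted(doses)
    return tuple(
        (p, c, d) for p in parameters for c in conditions for d in doses_sorted
    )


@dataclass(frozen=True)
class SCRITVector:
    """Ordered, normalised response fingerprint of one compound replicate."""

    compound: str
    replicate: str
    values: np.ndarray
    index: tuple[tuple[str, str, float], ...]  # (parameter, condition, dose)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) != len(self.index):
            raise ContractError("SCRIT values and component index disagree in length")
        if len(set(self.index)) != len(self.index):
            raise ContractError("SCRIT component index contains duplicates")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def item_id(self) -> str:
        return f"{self.compound}/{self.replicate}"

    def labels(self) -> list[str]:
        return [f"{p}|{c}|{d:g}" for p, c, d in self.index]

    def parameters(self) -> list[str]:
        seen: list[str] = []
        for p, _, _ in self.index:
            if p not in seen:
                seen.append(p)
        return seen

    def truncate(
        self,
        conditions: Sequence[str] | None = None,
        parameters: Sequence[str] | None = None,
        doses: Sequence[float] | None = None,
    ) -> "SCRITVector":
        return truncate_scrit(self, conditions=conditions, parameters=parameters, doses=doses)


class BuildResult(NamedTuple):
    vectors: list[SCRITVector]
    excluded: list[dict]  # one record per (compound, replicate) left out, with reason


def build_scrit(
    wellstats: pd.DataFrame,
    parameters: Sequence[str],
    conditions: Sequence[str] = CONDITIONS,
    doses: Sequence[float] | None = None,
    dose_decimals: int = 6,
) -> BuildResult:
    """Assemble SCRIT vectors from a well-statistics table.

    *wellstats* is the output of :func:`scritscreen.well_stats.compute_well_statistics`
    for one or more plates, optionally carrying a ``replicate`` column naming
    the biological replicate each row belongs to (absent -> single replicate
    ``"1"``).  Only non-excluded ``test`` wells contribute; wells sharing a
    (compound, replicate, condition, dose) cell are averaged.  A vector with
    any missing cell is flagged incomplete and excluded with its reason
    recorded; row order never matters.
    """
    stats = wellstats.copy()
    if "replicate" not in stats.columns:
        stats["replicate"] = "1"
    stats = stats[(stats["role"] == "test") & (~stats["excluded"].astype(bool))]
    if doses is None:
        doses = sorted(set(np.round(stats["dose"].astype(float), dose_decimals)))
    index = component_index(list(parameters), list(conditions), list(doses))

    def col_for(param: str) -> str:
        return "viability_rescaled" if param == VIABILITY else f"ks_{param}"

    for p in parameters:
        if col_for(p) not in wellstats.columns:
            raise ContractError(f"well statistics lack a column for parameter {p!r}")

    stats["_dose_key"] = np.round(stats["dose"].astype(float), dose_decimals)
    grouped = stats.groupby(["compound", "replicate", "condition", "_dose_key"])
    means = {p: grouped[col_for(p)].mean() for p in parameters}

    vectors: list[SCRITVector] = []
    excluded: list[dict] = []
    pairs = sorted(set(zip(stats["compound"], stats["replicate"].astype(str))))
    for compound, rep in pairs:
        values = np.empty(len(index))
        missing: list[str] = []
        for i, (p, c, d) in enumerate(index):
            key = (compound, rep, c, round(float(d), dose_decimals))
            if key in means[p].index:
                values[i] = means[p].loc[key]
            else:
                values[i] = np.nan
                missing.append(f"{p}|{c}|{d:g}")
        if missing or np.isnan(values).any():
            excluded.append(
                {
                    "compound": compound,
                    "replicate": rep,
                    "reason": f"incomplete vector; missing components: {missing[:5]}"
                    + ("..." if len(missing) > 5 else ""),
                }
            )
            continue
        vectors.append(
            SCRITVector(compound=compound, replicate=rep, values=values, index=index)
        )
    return BuildResult(vectors=vectors, excluded=excluded)


@dataclass(frozen=True)
class ActivityCall:
    """Primary-screen verdict for one compound vector."""

    compound: str
    active: bool
    triggers: tuple[str, ...]
    group: str | None  # "IV" for inactives, None otherwise


def primary_screen_select(
    vector: SCRITVector,
    cutoff: float = 0.2,
    control_viability_rescaled: float = 1.0,
) -> ActivityCall:
    """Activity call from a single-dose multi-parameter vector.

    A compound is *active* when any KS component changes by at least
    *cutoff* in magnitude, or when the live fraction moves by at least
    *cutoff* (i.e. 20 percentage points, = 2 x cutoff on the rescaled
    [-1, 1] viability scale) from the in-plate negative-control viability.
    Inactive compounds are designated group IV.
    """
    n_doses = len({d for _, _, d in vector.index})
    if n_doses != 1:
        raise ContractError(
            f"primary screen expects a single-dose vector, got {n_doses} doses"
        )
    triggers = []
    for (p, c, d), v in zip(vector.index, vector.values):
        if p == VIABILITY:
            if abs(v - control_viability_rescaled) >= 2 * cutoff:
                triggers.append(f"{p}|{c}|{d:g}")
        elif abs(v) >= cutoff:
            triggers.append(f"{p}|{c}|{d:g}")
    active = bool(triggers)
    return ActivityCall(
        compound=vector.compound,
        active=active,
        triggers=tuple(triggers),
        group=None if active else "IV",
    )


@dataclass(frozen=True)
class ConsistencyReport:
    compound: str
    n_replicates: int
    max_distance: float
    distances: tuple[tuple[str, str, float], ...]
    flagged: bool


def replicate_consistency(
    vectors: Sequence[SCRITVector],
    threshold: float = 0.2,
    metric: str = "pearson",
) -> tuple[list[SCRITVector], ConsistencyReport]:
    """Flag compounds whose replicates disagree.

    Computes all pairwise distances among one compound's replicate vectors;
    if any pair exceeds *threshold* the whole compound is flagged as an
    outlier and removed (returned kept-list empty), matching the treatment
    of irreproducible compounds in the screen.  A single replicate passes
    with a warning.
    """
    from .classify import pearson_distance  # local import to avoid cycle

    if not vectors:
        raise ContractError("no replicate vectors supplied")
    compound = vectors[0].compound
    if any(v.compound != compound for v in vectors):
        raise ContractError("replicate_consistency expects vectors of one compound")
    if len(vectors) == 1:
        warnings.warn(
            f"compound {compound}: single replicate, consistency not assessable",
            stacklevel=2,
        )
        report = ConsistencyReport(compound, 1, 0.0, (), False)
        return list(vectors), report

    dists = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            if metric == "pearson":
                d = pearson_distance(vectors[i].values, vectors[j].values)
            elif metric == "euclidean":
                d = float(np.linalg.norm(vectors[i].values - vectors[j].values))
            else:
                raise DomainError(f"unknown metric {metric!r}")
            dists.append((vectors[i].replicate, vectors[j].replicate, float(d)))
    max_d = max(d for _, _, d in dists)
    flagged = max_d > threshold
    report = ConsistencyReport(
        compound=compound,
        n_replicates=len(vectors),
        max_distance=max_d,
        distances=tuple(dists),
        flagged=flagged,
    )
    return ([] if flagged else list(vectors)), report


def truncate_scrit(
    vector: SCRITVector,
    conditions: Sequence[str] | None = None,
    parameters: Sequence[str] | None = None,
    doses: Sequence[float] | None = None,
) -> SCRITVector:
    """Restrict a vector to a subset of conditions / parameters / doses.

    Component ordering is preserved; truncations compose (two successive
    truncations equal the combined one).  An empty selection is a contract
    error.
    """
    keep = np.ones(len(vector), dtype=bool)
    for i, (p, c, d) in enumerate(vector.index):
        if conditions is not None and c not in conditions:
            keep[i] = False
        if parameters is not None and p not in parameters:
            keep[i] = False
        if doses is not None and not any(np.isclose(d, x) for x in doses):
            keep[i] = False
    if not keep.any():
        raise ContractError("truncation selects no components")
    new_index = tuple(t for t, k in zip(vector.index, keep) if k)
    return replace(vector, values=vector.values[keep], index=new_index)


# ---------------------------------------------------------------------------
# Serialisation: TSV (one row per vector) + the component index as labels
# ---------------------------------------------------------------------------


def write_scrit_table(vectors: Sequence[SCRITVector], path: str | Path) -> None:
    if not vectors:
        raise ContractError("nothing to write")
    labels = vectors[0].labels()
    for v in vectors:
        if v.labels() != labels:
            raise ContractError("vectors have differing component indices")
    frame = pd.DataFrame(
        [[v.compound, v.replicate, *v.values] for v in vectors],
        columns=["compound", "replicate", *labels],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_scrit_table(path: str | Path) -> list[SCRITVector]:
    frame = pd.read_csv(path, sep="\t")
    label_cols = [c for c in frame.columns if c not in ("compound", "replicate")]
    index = []
    for lab in label_cols:
        p, c, d = lab.rsplit("|", 2)
        index.append((p, c, float(d)))
    index = tuple(index)
    return [
        SCRITVector(
            compound=str(r["compound"]),
            replicate=str(r["replicate"]),
            values=r[label_cols].to_numpy(dtype=float),
            index=index,
        )
        for _, r in frame.iterrows()
    ]
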