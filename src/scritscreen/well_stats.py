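"""Per-well statistics: signed KS distances, TO-PRO-3 gating, viability, and Z'.

Every treated well is compared with the pooled distribution of all
negative-control cells on the same plate.  For the intensity and morphology
parameters the comparison is a *signed* two-sample Kolmogorov-Smirnov
distance: the value of F_ref - F_sample at the point where |F_ref - F_sample|
is maximal, so a shift of the sample toward higher intensities gives a
positive value (the sample CDF lies below the reference) and a loss of signal
gives a negative value.  TO-PRO-3 is bimodal (live/dead), so it is summarised
instead as the fraction of cells below an intensity gate (live cells), then
rescaled to [-1, +1] to share the KS range.

Plate quality is summarised with the standard screening-window statistic

    Z' = 1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n|

computed on the per-well |KS| of the TMRM peripheral integral for positive
(FCCP) and negative (DMSO) control wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import ContractError, DomainError, QCError
from .plate_core import FEATURE_COLUMNS, CellFeatureTable, PlateLayout

__all__ = [
    "DEFAULT_TOPRO_GATE",
    "MIN_CELLS_PER_WELL",
    "EmpiricalDistribution",
    "GateResult",
    "ZPrimeResult",
    "signed_ks",
    "pooled_control",
    "choose_topro_gate",
    "viability_fraction",
    "rescale_viability",
    "zprime",
    "zprime_ks",
    "compute_well_statistics",
    "plate_qc",
]

#: Fallback TO-PRO-3 intensity gate, 10**3.25 a.u.
DEFAULT_TOPRO_GATE = 10.0**3.25

#: Wells with fewer cells than this are excluded from downstream statistics.
MIN_CELLS_PER_WELL = 50


@dataclass(frozen=True)
class EmpiricalDistribution:
    """Sorted sample with a right-continuous empirical CDF F(x) = #{v <= x}/n."""

    values: np.ndarray

    @classmethod
    def from_values(cls, values) -> "EmpiricalDistribution":
        arr = np.sort(np.asarray(values, dtype=float))
        if arr.size == 0:
            raise DomainError("empirical distribution needs at least one value")
        return cls(arr)

    @property
    def n(self) -> int:
        return self.values.size

    def cdf(self, x) -> np.ndarray:
        return np.searchsorted(self.values, x, side="right") / self.n


def signed_ks(
    sample: EmpiricalDistribution | Sequence[float],
    reference: EmpiricalDistribution | Sequence[float],
) -> float:
    """Signed two-sample KS distance, exact over all CDF breakpoints.

    Returns F_ref(x*) - F_sample(x*) where x* maximises |F_ref - F_sample|
    over the pooled support; ties in |.| resolve to the smallest x.  Positive
    values mean the sample is shifted toward higher values than the reference
    (e.g. the nicardipine-like TMRM increase); negative values mean a loss of
    signal (e.g. FCCP-induced TMRM collapse).
    """
    if not isinstance(sample, EmpiricalDistribution):
        sample = EmpiricalDistribution.from_values(sample)
    if not isinstance(reference, EmpiricalDistribution):
        reference = EmpiricalDistribution.from_values(reference)
    support = np.unique(np.concatenate([sample.values, reference.values]))
    diff = reference.cdf(support) - sample.cdf(support)
    i = int(np.argmax(np.abs(diff)))  # first occurrence = smallest x
    return float(diff[i])


def pooled_control(
    features: CellFeatureTable,
    layout: PlateLayout,
    parameter: str,
) -> EmpiricalDistribution:
    """Pool all negative-control cells on the plate for one parameter."""
    if parameter not in FEATURE_COLUMNS:
        raise ContractError(f"unknown feature parameter {parameter!r}")
    neg_wells = {w.well for w in layout.wells_with_role("negative_control")}
    if not neg_wells:
        raise QCError(f"plate {layout.plate_id}: no negative-control wells")
    mask = features.frame["well"].isin(neg_wells)
    values = features.frame.loc[mask, parameter].to_numpy(dtype=float)
    if values.size == 0:
        raise QCError(f"plate {layout.plate_id}: negative-control wells contain no cells")
    return EmpiricalDistribution.from_values(values)


@dataclass(frozen=True)
class GateResult:
    """TO-PRO-3 gate value plus how it was obtained ('valley' or 'default')."""

    gate: float
    method: str


def choose_topro_gate(
    topro_values,
    default: float = DEFAULT_TOPRO_GATE,
    bin_width: float = 0.05,
    smooth_bins: float = 2.0,
    min_mode_separation: float = 0.5,
) -> GateResult:
    """Locate the live/dead valley of the log10 TO-PRO-3 intensity histogram.

    The histogram (bin width 0.05 in log10 units) is smoothed with a Gaussian
    kernel and scanned for its two most prominent modes; the gate is placed at
    the density minimum between them.  When no bimodality is detected (modes
    absent or closer than *min_mode_separation* decades) the empirical
    default gate of 10**3.25 a.u. is returned instead.
    """
    values = np.asarray(topro_values, dtype=float)
    values = values[values > 0]
    if values.size < 100:
        return GateResult(default, "default")
    logv = np.log10(values)
    lo = np.floor(logv.min() / bin_width) * bin_width
    hi = np.ceil(logv.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges.size < 8:
        return GateResult(default, "default")
    hist, _ = np.histogram(logv, bins=edges)
    density = gaussian_filter1d(hist.astype(float), smooth_bins)
    peaks, props = find_peaks(density, prominence=0.10 * density.max())
    if peaks.size < 2:
        return GateResult(default, "default")
    # two most prominent modes, in position order
    order = np.argsort(props["prominences"])[::-1][:2]
    p1, p2 = sorted(peaks[order])
    centers = (edges[:-1] + edges[1:]) / 2
    if centers[p2] - centers[p1] < min_mode_separation:
        return GateResult(default, "default")
    # centre of the between-mode density minimum (the minimum is a wide
    # plateau of near-zero bins when the modes are far apart)
    between = density[p1 : p2 + 1]
    low = np.flatnonzero(between <= between.min() + 1e-6 * density.max())
    valley = p1 + int(low[(len(low) - 1) // 2])
    return GateResult(float(10 ** centers[valley]), "valley")


def viability_fraction(topro_values, gate: float) -> float:
    """Fraction of live (TO-PRO-3-negative, intensity <= gate) cells."""
    values = np.asarray(topro_values, dtype=float)
    if values.size == 0:
        raise DomainError("viability of an empty well is undefined")
    return float(np.mean(values <= gate))


def rescale_viability(fraction: float) -> float:
    """Map a live fraction in [0, 1] onto [-1, +1] to share the KS range.

    0 (all dead) -> -1; 1 (all live) -> +1.
    """
    if not 0.0 <= fraction <= 1.0:
        raise DomainError(f"viability fraction outside [0, 1]: {fraction}")
    return 2.0 * fraction - 1.0


@dataclass(frozen=True)
class ZPrimeResult:
    mu_p: float
    mu_n: float
    sigma_p: float
    sigma_n: float
    z_prime: float


def zprime(mu_p: float, mu_n: float, sigma_p: float, sigma_n: float) -> ZPrimeResult:
    """Screening-window statistic 1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n|."""
    if mu_p == mu_n:
        raise QCError("Z' undefined: control means coincide")
    z = 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)
    return ZPrimeResult(mu_p, mu_n, sigma_p, sigma_n, z)


def zprime_ks(
    features: CellFeatureTable,
    layout: PlateLayout,
    parameter: str = "tmrm_peripheral_integral",
) -> ZPrimeResult:
    """Plate Z' on per-well |KS| of *parameter* against the pooled negative control.

    Each control well (positive and negative alike) contributes the absolute
    signed-KS distance of its own cells versus the plate-pooled negative
    control; Z' is then the standard formula on those two samples of KS
    values.  Sample standard deviations (ddof=1) are used.
    """
    pos = [w.well for w in layout.wells_with_role("positive_control")]
    neg = [w.well for w in layout.wells_with_role("negative_control")]
    if len(pos) < 2 or len(neg) < 2:
        raise QCError("Z' needs at least two control wells of each kind")
    ref = pooled_control(features, layout, parameter)
    grouped = features.frame.groupby("well")[parameter]

    def well_ks(wells: list[str]) -> np.ndarray:
        out = []
        for w in wells:
            if w not in grouped.groups:
                continue
            vals = grouped.get_group(w).to_numpy(dtype=float)
            if vals.size == 0:
                continue
            out.append(abs(signed_ks(vals, ref)))
        return np.asarray(out)

    ks_p, ks_n = well_ks(pos), well_ks(neg)
    if ks_p.size < 2 or ks_n.size < 2:
        raise QCError("Z' needs at least two populated control wells of each kind")
    return zprime(
        float(ks_p.mean()),
        float(ks_n.mean()),
        float(ks_p.std(ddof=1)),
        float(ks_n.std(ddof=1)),
    )


def compute_well_statistics(
    features: CellFeatureTable,
    layout: PlateLayout,
    parameters: Sequence[str] | None = None,
    gate: float | None = None,
    min_cells: int = MIN_CELLS_PER_WELL,
) -> pd.DataFrame:
    """Per-well signed KS (per parameter) and gated viability for a plate.

    Returns one row per well present in *features*, with columns: the well
    annotation from the layout, ``n_cells``, ``gate``, ``viability``,
    ``viability_rescaled``, one ``ks_<parameter>`` column per requested KS
    parameter, and ``excluded`` / ``exclusion_reason``.  Wells with fewer
    than *min_cells* cells are flagged and excluded rather than dropped.
    """
    if parameters is None:
        parameters = list(FEATURE_COLUMNS)
    unknown = [p for p in parameters if p not in FEATURE_COLUMNS]
    if unknown:
        raise ContractError(f"unknown KS parameter(s): {unknown}")
    assignments = layout.by_well()
    frame = features.frame
    stray = [w for w in pd.unique(frame["well"]) if w not in assignments]
    if stray:
        raise ContractError(f"feature table contains wells absent from layout: {stray}")

    refs = {p: pooled_control(features, layout, p) for p in parameters}
    if gate is None:
        gate_result = choose_topro_gate(frame["topro_mean"].to_numpy(dtype=float))
    else:
        gate_result = GateResult(float(gate), "fixed")

    rows = []
    for wid, group in frame.groupby("well", sort=True):
        a = assignments[wid]
        n = len(group)
        row: dict = {
            "well": wid,
            "compound": a.compound,
            "dose": a.dose,
            "condition": a.condition,
            "role": a.role,
            "n_cells": n,
            "gate": gate_result.gate,
            "gate_method": gate_result.method,
            "excluded": False,
            "exclusion_reason": "",
        }
        if n < min_cells:
            row["excluded"] = True
            row["exclusion_reason"] = f"only {n} cells (< {min_cells})"
            row["viability"] = np.nan
            row["viability_rescaled"] = np.nan
            for p in parameters:
                row[f"ks_{p}"] = np.nan
        else:
            frac = viability_fraction(group["topro_mean"], gate_result.gate)
            row["viability"] = frac
            row["viability_rescaled"] = rescale_viability(frac)
            for p in parameters:
                row[f"ks_{p}"] = signed_ks(group[p].to_numpy(dtype=float), refs[p])
        rows.append(row)
    return pd.DataFrame(rows)


def plate_qc(
    features: CellFeatureTable,
    layout: PlateLayout,
    parameters: Sequence[str] | None = None,
    gate: float | None = None,
) -> dict:
    """Machine-readable plate QC report.

    Contains control-well counts, the TO-PRO-3 gate, per-parameter KS means /
    SDs / CVs over positive-control wells, Z' when computable, and the list
    of excluded wells with reasons.
    """
    stats = compute_well_statistics(features, layout, parameters=parameters, gate=gate)
    parameters = parameters or list(FEATURE_COLUMNS)
    ok = stats[~stats["excluded"]]
    report: dict = {
        "plate_id": layout.plate_id,
        "n_wells": int(len(stats)),
        "n_positive_controls": int((stats["role"] == "positive_control").sum()),
        "n_negative_controls": int((stats["role"] == "negative_control").sum()),
        "gate": float(stats["gate"].iloc[0]) if len(stats) else None,
        "gate_method": stats["gate_method"].iloc[0] if len(stats) else None,
        "excluded_wells": [
            {"well": r["well"], "reason": r["exclusion_reason"]}
            for _, r in stats[stats["excluded"]].iterrows()
        ],
        "warnings": [],
        "parameters": {},
    }
    for role in ("positive_control", "negative_control"):
        sub = ok[ok["role"] == role]
        report[f"{role}_viability_mean"] = (
            float(sub["viability"].mean()) if len(sub) else None
        )
    for p in parameters:
        col = f"ks_{p}"
        entry: dict = {}
        for role, tag in (("positive_control", "pos"), ("negative_control", "neg")):
            vals = ok.loc[ok["role"] == role, col].abs()
            if len(vals) >= 2:
                mean, sd = float(vals.mean()), float(vals.std(ddof=1))
                entry[f"{tag}_ks_mean"] = mean
                entry[f"{tag}_ks_sd"] = sd
                entry[f"{tag}_ks_cv"] = sd / mean if mean else float("nan")
        report["parameters"][p] = entry
    try:
        z = zprime_ks(features, layout)
        report["z_prime"] = z.z_prime
        report["z_prime_detail"] = {
            "mu_p": z.mu_p,
            "mu_n": z.mu_n,
            "sigma_p": z.sigma_p,
            "sigma_n": z.sigma_n,
        }
    except QCError as exc:
        report["z_prime"] = None
        report["warnings"].append(f"Z' not computed: {exc}")
    return report
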