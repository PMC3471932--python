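"""Generative stand-in for the wet-lab screen.

Simulates per-cell feature tables for plates of compounds drawn from five
mechanistic response archetypes, so that every downstream stage (well
statistics, SCRIT assembly, clustering) is testable without instrument data:

* ``I``  -- direct mitochondrial toxins: TMRM / viability / nuclear-morphology
  response present in glucose medium and strongly amplified after galactose
  substitution (glu-).
* ``II`` -- glucose-independent toxins: equal response in both media.
* ``III``-- glucose-dependent toxins: response only in glu-.
* ``IV`` -- inactive compounds: flat in both media.
* ``V``  -- uncouplers (FCCP-like): TMRM collapse with partial viability loss
  in glu+, near-total viability loss in glu- with little additional TMRM
  change.  About half of the cells stay viable at a saturating dose in glu+.
* ``inverse_tmrm`` -- nicardipine-like: TMRM *increase* with viability loss.

Model structure
---------------
Fluorescence intensities are log-normal (positive, right-skewed).  A compound
multiplies the median of each channel by ``1 - effect(dose)`` where
``effect`` follows a Hill curve (negative maximal effects therefore encode
intensity increases).  Nuclear circularity lives on a logit scale; toxicants
shift the logit location upward (condensation makes nuclei rounder and
smaller, with brighter Hoechst).  TO-PRO-3 is a two-component log-normal
live/dead mixture whose dead fraction follows its own Hill curve; the live
and dead medians (10**2.5 and 10**4 a.u.) bracket the default intensity gate
of 10**3.25 a.u.

Each well additionally receives a small log-normal well-to-well staining
factor per channel (``well_sigma``, the source of the untreated-well KS
spread) and one shared response-strength factor (``effect_sigma``) that
scales all of the well's dose effects, emulating the variability of treated
wells.  The two are calibrated together so that the simulated 48/48 control
plate yields a Z' in the 0.6-0.7 band while untreated wells stay well below
the 20%-change activity cutoff.

Everything is deterministic for a fixed master seed: per-well streams are
derived from a stable hash of (master seed, plate id, well id).
"""

from __future__ import annotations

import copy
import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, DomainError
from .plate_core import (
    CONDITIONS,
    FEATURE_COLUMNS,
    POSITIVE_CONTROL_DOSE,
    CellFeatureTable,
    PlateLayout,
)

__all__ = [
    "ARCHETYPES",
    "LOG_CHANNELS",
    "HillResponse",
    "DeathResponse",
    "ConditionResponse",
    "PhenotypeModel",
    "SimulationConfig",
    "make_phenotype_model",
    "simulate_well",
    "simulate_plate",
    "expected_well_response",
    "archetype_references",
    "benchmark_models",
    "render_well_image",
    "RenderResult",
]

#: Channels sampled log-normally (all features except circularity and TO-PRO-3).
LOG_CHANNELS = (
    "tmrm_peripheral_integral",
    "tmrm_max_pixel",
    "hoechst_integral",
    "hoechst_mean",
    "nuclear_area",
)

#: Untreated medians (a.u.; nuclear_area in um^2).
DEFAULT_BASELINES = {
    "tmrm_peripheral_integral": 5.0e4,
    "tmrm_max_pixel": 8.0e3,
    "hoechst_integral": 4.0e6,
    "hoechst_mean": 6.0e3,
    "nuclear_area": 110.0,
}

#: Cell-to-cell log-normal sigma (natural log) per channel.
DEFAULT_SIGMAS = {
    "tmrm_peripheral_integral": 0.50,
    "tmrm_max_pixel": 0.45,
    "hoechst_integral": 0.35,
    "hoechst_mean": 0.30,
    "nuclear_area": 0.18,
}

#: Area filter bounds (um^2) the generator respects.
AREA_BOUNDS = (20.0, 250.0)


@dataclass(frozen=True)
class HillResponse:
    """Dose-dependent fractional change of a channel median.

    ``effect(dose) = max_effect * dose^h / (ec50^h + dose^h)``; the median
    multiplier is ``1 - effect``, so ``max_effect = 0.9`` shrinks the median
    to 0.1x at saturation while ``max_effect = -1`` doubles it.
    """

    max_effect: float
    ec50: float = 1.0  # uM
    hill: float = 1.5

    def effect(self, dose: float) -> float:
        if dose <= 0 or self.max_effect == 0:
            return 0.0
        dh = dose**self.hill
        return self.max_effect * dh / (self.ec50**self.hill + dh)


@dataclass(frozen=True)
class DeathResponse:
    """Hill curve for the dose-dependent dead (TO-PRO-3-positive) fraction."""

    max_fraction: float = 0.0
    ec50: float = 1.0
    hill: float = 1.5

    def dead_fraction(self, dose: float, baseline: float) -> float:
        if dose <= 0 or self.max_fraction <= baseline:
            return baseline
        dh = dose**self.hill
        return baseline + (self.max_fraction - baseline) * dh / (
            self.ec50**self.hill + dh
        )


@dataclass(frozen=True)
class ConditionResponse:
    """Per-medium-condition channel effects plus the death curve."""

    channels: Mapping[str, HillResponse]
    death: DeathResponse


@dataclass
class PhenotypeModel:
    """Generative archetype controlling simulated channel distributions."""

    archetype: str
    responses: Mapping[str, ConditionResponse]  # keyed by condition
    baselines: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    sigmas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMAS))
    live_topro_median: float = 10.0**2.5
    dead_topro_median: float = 10.0**4.0
    topro_sigma: float = 0.25 * math.log(10)  # natural-log sigma
    baseline_dead_fraction: float = 0.03
    well_sigma: float = 0.045
    morph_well_sigma: float = 0.015  # geometry is insensitive to staining/focus
    effect_sigma: float = 0.065
    circ_logit_center: float = 1.5
    circ_logit_sigma: float = 0.5
    circ_shift_scale: float = 3.0  # logit shift per unit (negative) effect

    def __post_init__(self) -> None:
        if not self.live_topro_median < 10.0**3.25 < self.dead_topro_median:
            raise ConfigurationError(
                "live/dead TO-PRO-3 medians must bracket the default gate"
            )
        for name, s in self.sigmas.items():
            if s <= 0:
                raise ConfigurationError(f"sigma for {name} must be positive")
        for cond in self.responses:
            if cond not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond!r}")

    def condition(self, condition: str) -> ConditionResponse:
        try:
            return self.responses[condition]
        except KeyError:
            raise ConfigurationError(
                f"model {self.archetype!r} has no response for condition {condition!r}"
            ) from None


@dataclass(frozen=True)
class SimulationConfig:
    """Plate-simulation settings; a fixed seed gives bit-reproducible output."""

    n_cells_per_well: int = 500
    seed: int = 0
    n_fields: int = 6
    pixel_um: float = 0.5
    field_um: tuple[float, float] = (500.0, 368.6)
    render_images: bool = False

    def __post_init__(self) -> None:
        if self.n_cells_per_well <= 0:
            raise ConfigurationError("n_cells_per_well must be positive")


# ---------------------------------------------------------------------------
# Archetype parameterisations
# ---------------------------------------------------------------------------


def _tox_channels(
    tmrm: float, ec50: float, strength: float = 1.0, hill: float = 1.5
) -> dict:
    """Coupled channel effects of a cytotoxic response.

    TMRM (both readouts) drops by *tmrm*; nuclear condensation brightens the
    Hoechst signal, shrinks the nucleus and rounds it up, all scaled by
    *strength* and sharing the dose placement.
    """
    return {
        "tmrm_peripheral_integral": {"max_effect": tmrm, "ec50": ec50, "hill": hill},
        "tmrm_max_pixel": {"max_effect": tmrm, "ec50": ec50, "hill": hill},
        "hoechst_mean": {"max_effect": -0.40 * strength, "ec50": ec50, "hill": hill},
        "hoechst_integral": {"max_effect": -0.15 * strength, "ec50": ec50, "hill": hill},
        "nuclear_area": {"max_effect": 0.35 * strength, "ec50": ec50, "hill": hill},
        "nuclear_circularity": {"max_effect": -0.50 * strength, "ec50": ec50, "hill": hill},
    }


#: Default archetype parameter sets (see module docstring for the phenotypes).
ARCHETYPES: dict[str, dict] = {
    "I": {
        "glu_plus": {
            "channels": _tox_channels(0.50, ec50=3.0, strength=0.5),
            "death": {"max_fraction": 0.40, "ec50": 4.0},
        },
        "glu_minus": {
            "channels": _tox_channels(0.90, ec50=0.15, strength=1.0),
            "death": {"max_fraction": 0.90, "ec50": 0.2},
        },
    },
    "II": {
        "glu_plus": {
            "channels": _tox_channels(0.75, ec50=1.5, strength=0.9),
            "death": {"max_fraction": 0.85, "ec50": 2.0},
        },
        "glu_minus": {
            "channels": _tox_channels(0.75, ec50=1.5, strength=0.9),
            "death": {"max_fraction": 0.85, "ec50": 2.0},
        },
    },
    "III": {
        "glu_plus": {"channels": {}, "death": {"max_fraction": 0.0}},
        "glu_minus": {
            "channels": _tox_channels(0.80, ec50=3.0, strength=0.5, hill=2.0),
            "death": {"max_fraction": 0.85, "ec50": 3.5, "hill": 2.0},
        },
    },
    "IV": {
        "glu_plus": {"channels": {}, "death": {"max_fraction": 0.0}},
        "glu_minus": {"channels": {}, "death": {"max_fraction": 0.0}},
    },
    # Uncoupling dissipates MMP without the apoptotic nuclear-condensation
    # programme, so the Hoechst / morphology channels stay nearly flat; in
    # glucose about half of the cells survive at saturation, while galactose
    # substitution collapses viability with little further TMRM change.
    "V": {
        "glu_plus": {
            "channels": {
                "tmrm_peripheral_integral": {"max_effect": 0.70, "ec50": 0.5},
                "tmrm_max_pixel": {"max_effect": 0.70, "ec50": 0.5},
                "hoechst_mean": {"max_effect": -0.05, "ec50": 0.5},
                "nuclear_area": {"max_effect": 0.10, "ec50": 0.5},
                "nuclear_circularity": {"max_effect": -0.10, "ec50": 0.5},
            },
            "death": {"max_fraction": 0.50, "ec50": 0.8},
        },
        "glu_minus": {
            "channels": {
                "tmrm_peripheral_integral": {"max_effect": 0.72, "ec50": 0.5},
                "tmrm_max_pixel": {"max_effect": 0.72, "ec50": 0.5},
                "hoechst_mean": {"max_effect": -0.05, "ec50": 0.5},
                "nuclear_area": {"max_effect": 0.10, "ec50": 0.5},
                "nuclear_circularity": {"max_effect": -0.10, "ec50": 0.5},
            },
            "death": {"max_fraction": 0.95, "ec50": 0.5},
        },
    },
    "inverse_tmrm": {
        "glu_plus": {
            "channels": {
                "tmrm_peripheral_integral": {"max_effect": -1.0, "ec50": 3.0},
                "tmrm_max_pixel": {"max_effect": -1.0, "ec50": 3.0},
                "nuclear_circularity": {"max_effect": -0.30, "ec50": 3.0},
            },
            "death": {"max_fraction": 0.60, "ec50": 3.0},
        },
        "glu_minus": {
            "channels": {
                "tmrm_peripheral_integral": {"max_effect": -1.0, "ec50": 3.0},
                "tmrm_max_pixel": {"max_effect": -1.0, "ec50": 3.0},
                "nuclear_circularity": {"max_effect": -0.30, "ec50": 3.0},
            },
            "death": {"max_fraction": 0.60, "ec50": 3.0},
        },
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def make_phenotype_model(
    archetype: str,
    overrides: Mapping | None = None,
    ec50_scale: float = 1.0,
) -> PhenotypeModel:
    """Build the documented default parameterisation of an archetype.

    *overrides* is a nested mapping merged over the archetype defaults; keys
    ``glu_plus`` / ``glu_minus`` address the per-condition blocks, any other
    key addresses a :class:`PhenotypeModel` field.  *ec50_scale* multiplies
    every EC50 (channel and death), shifting the whole dose response along
    the concentration axis -- handy for emulating potency differences between
    compounds of one mechanistic class.
    """
    if archetype not in ARCHETYPES:
        raise DomainError(
            f"unknown archetype {archetype!r}; expected one of {sorted(ARCHETYPES)}"
        )
    spec = copy.deepcopy(ARCHETYPES[archetype])
    model_kwargs: dict = {}
    if overrides:
        cond_over = {k: v for k, v in overrides.items() if k in CONDITIONS}
        spec = _deep_merge(spec, cond_over)
        model_kwargs = {
            k: copy.deepcopy(v) for k, v in overrides.items() if k not in CONDITIONS
        }
    responses = {}
    for cond in CONDITIONS:
        block = spec.get(cond, {"channels": {}, "death": {}})
        channels = {
            name: HillResponse(**params)
            for name, params in block.get("channels", {}).items()
        }
        death = DeathResponse(**block.get("death", {}))
        if ec50_scale != 1.0:
            channels = {
                n: HillResponse(c.max_effect, c.ec50 * ec50_scale, c.hill)
                for n, c in channels.items()
            }
            death = DeathResponse(
                death.max_fraction, death.ec50 * ec50_scale, death.hill
            )
        responses[cond] = ConditionResponse(channels=channels, death=death)
    return PhenotypeModel(archetype=archetype, responses=responses, **model_kwargs)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

_SIGMOID = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_well(
    model: PhenotypeModel,
    dose: float,
    condition: str,
    n_cells: int,
    seed,
    well: str = "A01",
    n_fields: int = 6,
) -> CellFeatureTable:
    """Sample one well's per-cell feature table.

    The realised cell count is Poisson around *n_cells*; each channel is
    sampled log-normally around its Hill-modulated median, TO-PRO-3 from the
    live/dead mixture.  Identical seeds give identical tables.
    """
    if dose < 0:
        raise DomainError("dose must be non-negative")
    rng = _as_rng(seed)
    resp = model.condition(condition)
    n = int(rng.poisson(n_cells))
    # Per-well staining/focus factors, one per stochastic channel (drawn even
    # for n == 0 wells to keep the stream layout stable), plus one shared
    # response-strength factor: treated wells vary in how hard they respond
    # (cell state, incubation), untreated wells do not.
    wf = rng.normal(0.0, 1.0, size=len(LOG_CHANNELS) + 2)
    wf *= [
        model.morph_well_sigma if ch == "nuclear_area" else model.well_sigma
        for ch in LOG_CHANNELS
    ] + [model.morph_well_sigma, model.well_sigma]
    jitter = math.exp(rng.normal(0.0, model.effect_sigma))

    data: dict[str, np.ndarray] = {}
    for i, ch in enumerate(LOG_CHANNELS):
        eff = jitter * resp.channels.get(ch, HillResponse(0.0)).effect(dose)
        mult = max(1.0 - eff, 0.01)
        median = model.baselines[ch] * mult * math.exp(wf[i])
        data[ch] = median * np.exp(rng.normal(0.0, model.sigmas[ch], size=n))
    data["nuclear_area"] = np.clip(data["nuclear_area"], *AREA_BOUNDS)

    # circularity on the logit scale; negative effects push nuclei rounder
    circ_eff = jitter * resp.channels.get(
        "nuclear_circularity", HillResponse(0.0)
    ).effect(dose)
    loc = model.circ_logit_center - model.circ_shift_scale * circ_eff + wf[-2]
    data["nuclear_circularity"] = _SIGMOID(
        rng.normal(loc, model.circ_logit_sigma, size=n)
    )

    # TO-PRO-3 live/dead mixture; the excess over the baseline dead fraction
    # scales with the same per-well response factor
    base = model.baseline_dead_fraction
    dead_frac = resp.death.dead_fraction(dose, base)
    dead_frac = min(base + jitter * (dead_frac - base), 0.995)
    dead = rng.random(n) < dead_frac
    medians = np.where(dead, model.dead_topro_median, model.live_topro_median)
    data["topro_mean"] = medians * np.exp(
        wf[-1] + rng.normal(0.0, model.topro_sigma, size=n)
    )

    frame = pd.DataFrame(
        {
            "well": well,
            "field": (np.arange(n) % n_fields) + 1,
            "cell": np.arange(1, n + 1),
            **{c: data[c] for c in FEATURE_COLUMNS},
        }
    )
    return CellFeatureTable(frame)


def _well_seed(master_seed: int, plate_id: str, well: str) -> np.random.SeedSequence:
    """Stable per-well stream: a layout edit elsewhere never changes this well."""
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(plate_id.encode()), zlib.crc32(well.encode())]
    )


def simulate_plate(
    layout: PlateLayout,
    models: Mapping[str, PhenotypeModel],
    config: SimulationConfig,
) -> CellFeatureTable:
    """Simulate every well of a plate; deterministic for a fixed master seed.

    Negative-control wells use the inactive archetype at dose 0; positive
    controls use the FCCP model (archetype V at 75 uM) unless *models*
    provides an explicit ``"FCCP"`` entry.
    """
    control = models.get("__control__") or make_phenotype_model("IV")
    fccp = models.get("FCCP") or make_phenotype_model("V")
    missing = [c for c in layout.compounds() if c not in models]
    if missing:
        raise ConfigurationError(f"no phenotype model for compound(s): {missing}")

    tables = []
    for w in sorted(layout.wells, key=lambda a: a.well):
        if w.role == "negative_control":
            model, dose = control, 0.0
        elif w.role == "positive_control":
            model, dose = fccp, w.dose or POSITIVE_CONTROL_DOSE
        else:
            model, dose = models[w.compound], w.dose
        rng = np.random.default_rng(_well_seed(config.seed, layout.plate_id, w.well))
        tables.append(
            simulate_well(
                model,
                dose,
                w.condition,
                config.n_cells_per_well,
                rng,
                well=w.well,
                n_fields=config.n_fields,
            )
        )
    return CellFeatureTable.concat(tables)


# ---------------------------------------------------------------------------
# Closed-form expected responses (noise-free oracle / reference vectors)
# ---------------------------------------------------------------------------


def expected_well_response(
    model: PhenotypeModel, dose: float, condition: str
) -> dict[str, float]:
    """Noise-free expected per-well statistics under the generative model.

    For a log-normal channel whose median is multiplied by ``m`` at constant
    sigma, the signed KS distance against the untreated distribution is the
    exact closed form ``sign(ln m) * (2 Phi(|ln m| / (2 sigma)) - 1)`` (the
    CDF gap peaks halfway between the two medians).  The same expression
    applies to circularity on the logit scale, KS being invariant under
    strictly increasing transforms.  Area clipping at the filter bounds is
    ignored here (its distortion is negligible at the default spread).

    Returns signed KS per channel plus ``viability`` (expected live fraction)
    and ``viability_rescaled``.
    """
    resp = model.condition(condition)

    def loc_shift_ks(delta: float, sigma: float) -> float:
        if delta == 0:
            return 0.0
        return math.copysign(2.0 * norm.cdf(abs(delta) / (2.0 * sigma)) - 1.0, delta)

    out: dict[str, float] = {}
    for ch in LOG_CHANNELS:
        eff = resp.channels.get(ch, HillResponse(0.0)).effect(dose)
        out[ch] = loc_shift_ks(math.log(max(1.0 - eff, 0.01)), model.sigmas[ch])
    circ_eff = resp.channels.get("nuclear_circularity", HillResponse(0.0)).effect(dose)
    out["nuclear_circularity"] = loc_shift_ks(
        -model.circ_shift_scale * circ_eff, model.circ_logit_sigma
    )
    v = 1.0 - resp.death.dead_fraction(dose, model.baseline_dead_fraction)
    out["viability"] = v
    out["viability_rescaled"] = 2.0 * v - 1.0
    return out


def archetype_references(
    parameters: Sequence[str],
    doses: Sequence[float],
    conditions: Sequence[str] = CONDITIONS,
    archetypes: Sequence[str] = ("I", "II", "III", "IV", "V"),
):
    """Noise-free reference SCRIT vector per archetype (component order as built).

    These serve as the default anchors for group assignment: a cluster is
    labelled with the archetype whose expected fingerprint its medoid most
    resembles.
    """
    from .scrit import SCRITVector, component_index

    index = component_index(parameters, conditions, doses)
    refs = {}
    for arch in archetypes:
        model = make_phenotype_model(arch)
        values = []
        for p, c, d in index:
            exp = expected_well_response(model, d, c)
            values.append(exp["viability_rescaled"] if p == "viability" else exp[p])
        refs[arch] = SCRITVector(
            compound=f"ref_{arch}",
            replicate="ref",
            values=np.asarray(values, dtype=float),
            index=index,
        )
    return refs


def benchmark_models(
    archetypes: Sequence[str] = ("I", "II", "III", "IV", "V"),
    n_compounds: int = 3,
) -> dict[str, PhenotypeModel]:
    """Deterministic benchmark compound set: *n_compounds* per archetype.

    Compounds of one archetype differ in potency (EC50 scaled by about one
    dilution step either way); group-I compounds additionally differ in the
    strength and placement of their glucose-medium response, as real
    respiratory-chain inhibitors do -- some are nearly silent in glucose and
    only reveal themselves after galactose substitution.
    """
    ec50_mults = [0.4, 1.0, 2.5]
    # Group-I compounds: the glucose-medium response varies strongly between
    # real respiratory-chain inhibitors, both in strength and in placement
    # along the dose axis, while the sensitised galactose response is shared.
    # (tmrm max effect, death max, glu+ ec50, glu- ec50 mult)
    # the third compound is rotenone-like: nearly silent in glucose medium
    group1 = [(0.35, 0.28, 0.6, 0.5), (0.55, 0.45, 3.0, 1.0), (0.12, 0.10, 5.0, 1.0)]
    models: dict[str, PhenotypeModel] = {}
    for arch in archetypes:
        for j in range(n_compounds):
            name = f"{arch}{j + 1}"
            if arch == "I":
                tm, dm, ecp, mm = group1[j % len(group1)]
                base = ARCHETYPES["I"]["glu_minus"]
                ecm = base["channels"]["tmrm_peripheral_integral"]["ec50"] * mm
                overrides = {
                    "glu_plus": {
                        "channels": _tox_channels(tm, ec50=ecp, strength=tm),
                        "death": {"max_fraction": dm, "ec50": ecp * 1.3},
                    },
                    "glu_minus": {
                        "channels": _tox_channels(0.90, ec50=ecm, strength=1.0),
                        "death": {"max_fraction": 0.90, "ec50": ecm * 1.3},
                    },
                }
                models[name] = make_phenotype_model(arch, overrides)
            else:
                scale = ec50_mults[j % len(ec50_mults)]
                models[name] = make_phenotype_model(arch, ec50_scale=scale)
    return models


# ---------------------------------------------------------------------------
# Field-image rendering (round-trip oracle for the segmentation stage)
# ---------------------------------------------------------------------------


@dataclass
class RenderResult:
    """Rendered field plus bookkeeping of which table rows were placed."""

    image: "FieldImage"  # noqa: F821 - forward ref, see segmentation module
    placed: pd.DataFrame  # placed rows with centre coordinates (row/col px)
    n_dropped: int


def render_well_image(
    table: CellFeatureTable,
    config: SimulationConfig = SimulationConfig(),
    seed=0,
    threshold: float = 2500.0,
    expand_px: int = 4,
    ring_width_px: int = 14,
    max_attempts: int = 200,
) -> RenderResult:
    """Render the rows of *table* into one synthetic multi-channel field.

    The Hoechst channel carries one disk per cell whose segmented area and
    integrated intensity (over the 4-px-expanded measurement region)
    reproduce the row's ``nuclear_area`` and ``hoechst_integral``; TMRM is
    painted into the perinuclear annulus so the ring-integrated signal
    matches ``tmrm_peripheral_integral``; TO-PRO-3 co-locates with the
    nucleus at the row's mean intensity.  Additive Gaussian background noise
    stays far below the segmentation threshold.  Painted disk radii are
    pre-compensated for the outward bias introduced by the 5x5 smoothing +
    threshold step, so the segmentation round trip recovers each area.

    Per-cell means and max-pixel values are *derived* quantities in rendered
    mode (they follow from area, integral and geometry) and are not matched
    to the table columns independently.

    Cells are placed by rejection sampling with non-overlapping measurement
    rings; rows that cannot be placed within *max_attempts* draws are dropped
    with a warning.
    """
    from skimage.draw import disk as draw_disk

    from .segmentation import FieldImage

    rng = _as_rng(seed)
    h = int(round(config.field_um[1] / config.pixel_um))
    w = int(round(config.field_um[0] / config.pixel_um))
    pixel_area = config.pixel_um**2

    hoechst = np.zeros((h, w), dtype=float)
    tmrm = np.zeros((h, w), dtype=float)
    topro = np.zeros((h, w), dtype=float)

    placed_rows = []
    centers: list[tuple[float, float, float]] = []  # (row, col, core radius)
    n_dropped = 0
    reach = expand_px + ring_width_px

    for _, row in table.frame.iterrows():
        r_core = math.sqrt(row["nuclear_area"] / pixel_area / math.pi)
        margin = r_core + reach + 2
        if 2 * margin >= min(h, w):
            n_dropped += 1
            continue
        pos = None
        for _ in range(max_attempts):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(
                math.hypot(cy - oy, cx - ox) > r_core + orad + 2 * reach + 4
                for oy, ox, orad in centers
            ):
                pos = (cy, cx)
                break
        if pos is None:
            n_dropped += 1
            continue
        cy, cx = pos
        centers.append((cy, cx, r_core))

        # Radius compensation: the 5x5 low-pass pushes the threshold crossing
        # outward by ~(2.5 - 5 t / v) px for a straight edge at paint value v.
        r_draw = r_core
        v_core = threshold * 2.5
        for _ in range(3):
            v_core = row["hoechst_integral"] / (math.pi * r_draw**2)
            if v_core < threshold * 1.6:
                v_core = threshold * 1.6
            shift = max(0.0, 2.5 - 5.0 * threshold / v_core)
            r_draw = max(2.0, r_core - shift)

        rr, cc = draw_disk((cy, cx), r_draw, shape=(h, w))
        hoechst[rr, cc] = v_core
        # TO-PRO-3 over the whole expanded measurement region (+1 px slack)
        rr, cc = draw_disk((cy, cx), r_core + expand_px + 1, shape=(h, w))
        topro[rr, cc] = row["topro_mean"]
        # TMRM annulus covering the measurement ring with 1 px slack each way
        ring_area = math.pi * ((r_core + reach) ** 2 - (r_core + expand_px) ** 2)
        t_val = row["tmrm_peripheral_integral"] / ring_area
        rr, cc = draw_disk((cy, cx), r_core + reach + 1, shape=(h, w))
        outer = np.zeros((h, w), dtype=bool)
        outer[rr, cc] = True
        rr, cc = draw_disk((cy, cx), max(r_draw + expand_px - 1, 0), shape=(h, w))
        outer[rr, cc] = False
        tmrm[outer] = t_val

        rec = row.to_dict()
        rec["center_row"], rec["center_col"] = cy, cx
        placed_rows.append(rec)

    if n_dropped:
        warnings.warn(
            f"render_well_image: dropped {n_dropped} cell(s) that could not be "
            "placed without ring overlap",
            stacklevel=2,
        )

    hoechst += np.clip(rng.normal(150.0, 40.0, size=(h, w)), 0, None)
    tmrm += np.clip(rng.normal(0.5, 0.3, size=(h, w)), 0, None)
    topro += np.clip(rng.normal(1.0, 0.5, size=(h, w)), 0, None)

    image = FieldImage(
        channels={"hoechst": hoechst, "tmrm": tmrm, "topro": topro},
        pixel_um=config.pixel_um,
    )
    placed = pd.DataFrame(placed_rows) if placed_rows else pd.DataFrame()
    return RenderResult(image=image, placed=placed, n_dropped=n_dropped)
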