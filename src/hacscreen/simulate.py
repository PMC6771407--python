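"""Synthetic data for the HAC/dGFP chromosome-instability screen.

Everything the analysis pipeline consumes can be generated here with known
ground truth: cell populations carrying a human artificial chromosome (HAC)
that is lost at a per-division rate, two-channel (DAPI/GFP) microscopy
fields, 384-well siRNA plates, flow-cytometry event tables, micronucleus
count tables and growth curves.

The generative model is deliberately simple and fully documented in
``docs/methods.md``:

* HAC loss is an independent Bernoulli event per cell per division with
  probability ``loss_rate_per_division`` (R); HAC+ and HAC− cells
  proliferate at the same rate, so after N divisions the expected HAC+
  fraction is ``initial_hac_fraction * (1 - R) ** N``.
* The destabilised GFP reporter decays quickly but not instantly: a cell
  that lost the HAC within the last ``reporter_lag_hours`` (default 9 h)
  still scores GFP+.  The lag is converted to fractional generations via
  the doubling time.
* Loss is irreversible — a GFP− cell never re-gains the HAC.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimCellPopulation",
    "IntensityModel",
    "PlateMap",
    "PlacementError",
    "ConfigurationError",
    "simulate_population",
    "render_field",
    "make_plate_map",
    "simulate_plate",
    "simulate_facs_events",
    "simulate_mn_counts",
    "simulate_growth_curve",
    "sirna_final_concentration_nm",
    "cells_seeded_per_well",
]

PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well plate: rows A-P, columns 1-24
PLATE_COLUMNS = 24
WELL_ROLES = ("sample", "negative_control", "positive_control", "empty")


class ConfigurationError(ValueError):
    """A plate map / gene-effect / generator configuration is inconsistent."""


class PlacementError(RuntimeError):
    """Requested nucleus density is incompatible with non-overlap placement."""


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the HAC segregation model for one condition.

    Parameters
    ----------
    loss_rate_per_division
        Probability R in [0, 1] that a cell loses the HAC in one division.
    n_divisions
        Number of generations elapsed; fractional values are allowed
        (e.g. 96 h at a 24 h doubling time gives N = 4).
    initial_cells
        Number of founder lineages tracked.
    initial_hac_fraction
        Fraction of founder cells carrying the HAC at time zero.
    reporter_lag_hours
        Time after HAC loss during which the destabilised GFP reporter is
        still detectable (default 9 h).
    doubling_time_hours
        Population doubling time, used to convert the reporter lag into
        fractional generations.
    rng_seed
        Seed for the stochastic mode.
    """

    loss_rate_per_division: float = 0.0
    n_divisions: float = 4.0
    initial_cells: int = 2000
    initial_hac_fraction: float = 1.0
    reporter_lag_hours: float = 9.0
    doubling_time_hours: float = 24.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_rate_per_division <= 1.0:
            raise ValueError("loss_rate_per_division must lie in [0, 1]")
        if self.n_divisions < 0:
            raise ValueError("n_divisions must be non-negative")
        if self.initial_cells < 1:
            raise ValueError("initial_cells must be >= 1")
        if not 0.0 <= self.initial_hac_fraction <= 1.0:
            raise ValueError("initial_hac_fraction must lie in [0, 1]")
        if self.reporter_lag_hours < 0:
            raise ValueError("reporter_lag_hours must be non-negative")
        if self.doubling_time_hours <= 0:
            raise ValueError("doubling_time_hours must be positive")

    @property
    def reporter_lag_generations(self) -> float:
        return self.reporter_lag_hours / self.doubling_time_hours


@dataclass
class SimCellPopulation:
    """A cell population after N divisions under a HAC-loss process.

    ``n_gfp_positive`` counts HAC+ cells plus cells that lost the HAC
    within the reporter lag and therefore still fluoresce.  In
    expectation mode the counts are expected values (floats).
    """

    n_total: float
    n_hac_positive: float
    n_gfp_positive: float
    generation_log: pd.DataFrame
    config: SimulationConfig

    def __post_init__(self) -> None:
        if not (0 <= self.n_hac_positive <= self.n_gfp_positive <= self.n_total):
            raise ValueError(
                "population counts must satisfy 0 <= HAC+ <= GFP+ <= total"
            )

    @property
    def hac_fraction(self) -> float:
        return self.n_hac_positive / self.n_total

    @property
    def gfp_fraction(self) -> float:
        return self.n_gfp_positive / self.n_total

    @property
    def gfp_negative_fraction(self) -> float:
        return 1.0 - self.gfp_fraction


def expected_hac_fraction(config: SimulationConfig) -> float:
    """Closed-form expected HAC+ fraction: f0 * (1 - R)^N."""
    return config.initial_hac_fraction * (
        (1.0 - config.loss_rate_per_division) ** config.n_divisions
    )


def expected_gfp_fraction(config: SimulationConfig) -> float:
    """Expected GFP+ fraction, accounting for the reporter lag.

    Cells that lost the HAC during the last ``reporter_lag_generations``
    still fluoresce, so the GFP+ fraction equals the HAC+ fraction at
    ``max(0, N - lag)`` generations.
    """
    n_eff = max(0.0, config.n_divisions - config.reporter_lag_generations)
    return config.initial_hac_fraction * (
        (1.0 - config.loss_rate_per_division) ** n_eff
    )


def simulate_population(
    config: SimulationConfig, mode: str = "stochastic"
) -> SimCellPopulation:
    """Evolve a population of cells through ``config.n_divisions`` divisions.

    Parameters
    ----------
    config
        Model parameters; see :class:`SimulationConfig`.
    mode
        ``"expectation"`` returns the deterministic expected counts
        (exactly ``f0 * (1-R)**N`` of the total);  ``"stochastic"`` draws
        an independent Bernoulli loss per cell per division, seeded by
        ``config.rng_seed`` and reproducible for a fixed seed.
    """
    if mode not in ("stochastic", "expectation"):
        raise ValueError(f"unknown mode {mode!r}")

    n = config.initial_cells
    r = config.loss_rate_per_division
    n_div = config.n_divisions
    lag = config.reporter_lag_generations
    n_full = int(math.floor(n_div))
    frac = n_div - n_full
    gens = np.arange(n_full + 1, dtype=float)

    if mode == "expectation":
        hac = expected_hac_fraction(config) * n
        gfp = expected_gfp_fraction(config) * n
        log = pd.DataFrame(
            {
                "generation": gens,
                "n_hac_positive": n * config.initial_hac_fraction * (1 - r) ** gens,
            }
        )
        return SimCellPopulation(float(n), hac, gfp, log, config)

    rng = np.random.default_rng(config.rng_seed)
    has_hac = rng.random(n) < config.initial_hac_fraction
    # loss_gen[i] = generation (possibly fractional for the trailing partial
    # division) at which cell i lost the HAC; +inf if never lost.
    loss_gen = np.full(n, np.inf)
    log_counts = [int(has_hac.sum())]
    alive = has_hac.copy()
    for g in range(1, n_full + 1):
        lost = alive & (rng.random(n) < r)
        loss_gen[lost] = g
        alive &= ~lost
        log_counts.append(int(alive.sum()))
    if frac > 0:
        p_frac = 1.0 - (1.0 - r) ** frac
        lost = alive & (rng.random(n) < p_frac)
        loss_gen[lost] = n_div
        alive &= ~lost

    gfp_pos = alive | (loss_gen > n_div - lag)
    # a cell never carrying the HAC is GFP- regardless of lag
    gfp_pos &= has_hac | alive
    log = pd.DataFrame({"generation": gens, "n_hac_positive": log_counts})
    return SimCellPopulation(
        float(n), float(alive.sum()), float(gfp_pos.sum()), log, config
    )


# ---------------------------------------------------------------------------
# field rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityModel:
    """Intensity parameters (16-bit camera AU) for rendered fields.

    Defaults put the GFP− and GFP+ nuclear means a factor of eight apart,
    far more than the pixel noise, mimicking the clean bimodality of the
    reporter; the DAPI nuclear signal sits well above background so the
    segmentation signal-to-background ratio exceeds five.
    """

    dapi_background: float = 100.0
    dapi_nucleus_mean: float = 3000.0
    gfp_background: float = 10.0
    gfp_neg_mean: float = 50.0
    gfp_pos_mean: float = 400.0
    noise_sd: float = 10.0


# Yokogawa CV7000S sCMOS sensor is 2550x2160; 2x2 binning gives 1275x1080.
DEFAULT_FIELD_SHAPE = (1080, 1275)


def _ellipse_mask(shape, row, col, r_row, r_col):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return ((rr - row) / r_row) ** 2 + ((cc - col) / r_col) ** 2 <= 1.0


def render_field(
    population: SimCellPopulation | float,
    n_nuclei: int,
    image_shape: tuple[int, int] = DEFAULT_FIELD_SHAPE,
    intensity: IntensityModel = IntensityModel(),
    seed: int = 0,
    radius_range: tuple[float, float] = (14.0, 22.0),
    axis_ratio_range: tuple[float, float] = (0.75, 1.0),
    n_border: int = 0,
    n_irregular: int = 0,
    irregular_axis_ratio: float = 0.15,
    max_tries_per_nucleus: int = 400,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one two-channel field and its ground truth.

    Nuclei are ellipses with jittered axis ratio placed by rejection
    sampling under a minimum centre distance, so the ground truth is
    unambiguous.  ``n_border`` nuclei are deliberately clipped by the
    field edge and ``n_irregular`` are drawn highly elongated
    (axis ratio ``irregular_axis_ratio``) so their isoperimetric
    roundness falls below typical QC cut-offs — both exist to exercise
    the QC filters downstream.

    Parameters
    ----------
    population
        Either a :class:`SimCellPopulation` (its GFP+ fraction sets the
        per-nucleus class probability) or that fraction directly.
    n_nuclei
        Interior, regular nuclei to place (on top of ``n_border`` and
        ``n_irregular``).

    Returns
    -------
    (dapi, gfp, truth)
        Two ``uint16`` images and a ground-truth table with one row per
        nucleus: centroid, equivalent radius, eccentricity, true GFP
        class, true mean GFP intensity, ``touches_border`` and
        ``planted_irregular`` flags.
    """
    gfp_fraction = (
        population.gfp_fraction
        if isinstance(population, SimCellPopulation)
        else float(population)
    )
    if not 0.0 <= gfp_fraction <= 1.0:
        raise ValueError("GFP+ fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = image_shape

    dapi = rng.normal(intensity.dapi_background, intensity.noise_sd, (h, w))
    gfp = rng.normal(intensity.gfp_background, intensity.noise_sd, (h, w))

    records = []
    # (row, col, major radius) of placed nuclei; non-overlap is enforced
    # pairwise: centre distance >= sum of the two major radii + 2 px
    centres: list[tuple[float, float, float]] = []

    def place(
        interior_margin: float, r_major: float, at_border: bool
    ) -> tuple[float, float]:
        for _ in range(max_tries_per_nucleus):
            if at_border:
                # centre in the border band so the nucleus is clipped
                edge = rng.integers(4)
                off = rng.uniform(0, radius_range[0] * 0.5)
                if edge == 0:
                    cand = (off, rng.uniform(0, w - 1))
                elif edge == 1:
                    cand = (h - 1 - off, rng.uniform(0, w - 1))
                elif edge == 2:
                    cand = (rng.uniform(0, h - 1), off)
                else:
                    cand = (rng.uniform(0, h - 1), w - 1 - off)
            else:
                cand = (
                    rng.uniform(interior_margin, h - 1 - interior_margin),
                    rng.uniform(interior_margin, w - 1 - interior_margin),
                )
            if all(
                (cand[0] - r0) ** 2 + (cand[1] - c0) ** 2
                >= (r_major + rm0 + 2.0) ** 2
                for r0, c0, rm0 in centres
            ):
                return cand
        raise PlacementError(
            f"could not place nucleus without overlap after "
            f"{max_tries_per_nucleus} tries (n={len(centres)} placed)"
        )

    # largest-footprint objects first so the rejection sampler can still
    # find room for them at realistic densities
    kinds = ["irregular"] * n_irregular + ["border"] * n_border + ["regular"] * n_nuclei
    for kind in kinds:
        r_eq = rng.uniform(*radius_range)
        if kind == "irregular":
            ratio = irregular_axis_ratio
        else:
            ratio = rng.uniform(*axis_ratio_range)
        # equivalent radius r_eq: area = pi*r_eq^2 = pi*a*b with b = ratio*a
        r_major = r_eq / math.sqrt(ratio)
        r_minor = r_eq * math.sqrt(ratio)
        margin = r_major + 2.0
        row, col = place(margin, r_major, at_border=(kind == "border"))
        centres.append((row, col, r_major))

        mask = _ellipse_mask((h, w), row, col, r_major, r_minor)
        is_gfp_pos = bool(rng.random() < gfp_fraction)
        gfp_mean = intensity.gfp_pos_mean if is_gfp_pos else intensity.gfp_neg_mean
        npix = int(mask.sum())
        dapi[mask] = rng.normal(intensity.dapi_nucleus_mean, intensity.noise_sd, npix)
        gfp[mask] = rng.normal(gfp_mean, intensity.noise_sd, npix)

        ecc = math.sqrt(1.0 - ratio**2)
        records.append(
            {
                "row": row,
                "col": col,
                "equivalent_radius": r_eq,
                "eccentricity": ecc,
                "gfp_class": "GFP+" if is_gfp_pos else "GFP-",
                "true_mean_gfp": gfp_mean,
                "touches_border": kind == "border",
                "planted_irregular": kind == "irregular",
            }
        )

    truth = pd.DataFrame(
        records,
        columns=[
            "row",
            "col",
            "equivalent_radius",
            "eccentricity",
            "gfp_class",
            "true_mean_gfp",
            "touches_border",
            "planted_irregular",
        ],
    )
    dapi_u16 = np.clip(dapi, 0, 65535).astype(np.uint16)
    gfp_u16 = np.clip(gfp, 0, 65535).astype(np.uint16)
    return dapi_u16, gfp_u16, truth


# ---------------------------------------------------------------------------
# plate layout and plate-level simulation
# ---------------------------------------------------------------------------

@dataclass
class PlateMap:
    """Layout of a 384-well screening plate.

    ``entries`` has one row per used well with columns ``well`` (e.g.
    ``"A1"``), ``role`` (sample / negative_control / positive_control /
    empty), ``gene`` and ``replicate``.
    """

    entries: pd.DataFrame
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        df = self.entries
        required = {"well", "role", "gene", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"plate map missing columns: {sorted(missing)}")
        if df["well"].duplicated().any():
            dupes = df.loc[df["well"].duplicated(), "well"].tolist()
            raise ConfigurationError(f"duplicate wells in plate map: {dupes}")
        for well in df["well"]:
            validate_well_id(well)
        bad_roles = set(df["role"]) - set(WELL_ROLES)
        if bad_roles:
            raise ConfigurationError(f"unknown well roles: {sorted(bad_roles)}")
        if len(df) > len(PLATE_ROWS) * PLATE_COLUMNS:
            raise ConfigurationError("plate map exceeds 384 wells")

    @property
    def n_wells(self) -> int:
        return len(self.entries)

    def wells_with_role(self, role: str) -> pd.DataFrame:
        return self.entries[self.entries["role"] == role]

    @property
    def sample_genes(self) -> list[str]:
        return sorted(self.wells_with_role("sample")["gene"].unique())


def validate_well_id(well: str) -> tuple[int, int]:
    """Parse a well id like ``"B7"`` into 0-based (row, column); raise on ids
    outside A1–P24."""
    if not isinstance(well, str) or len(well) < 2:
        raise ConfigurationError(f"malformed well id: {well!r}")
    row_letter, col_str = well[0], well[1:]
    if row_letter not in PLATE_ROWS or not col_str.isdigit():
        raise ConfigurationError(f"malformed well id: {well!r}")
    col = int(col_str)
    if not 1 <= col <= PLATE_COLUMNS:
        raise ConfigurationError(f"well column out of range (1-24): {well!r}")
    return PLATE_ROWS.index(row_letter), col - 1


def _well_name(index: int) -> str:
    return f"{PLATE_ROWS[index // PLATE_COLUMNS]}{index % PLATE_COLUMNS + 1}"


def make_plate_map(
    genes: Iterable[str],
    replicates_per_gene: int = 1,
    n_negative_controls: int = 8,
    n_positive_controls: int = 8,
    plate_id: str = "plate1",
    negative_control_gene: str = "scrambled",
    positive_control_gene: str = "SKA3",
) -> PlateMap:
    """Build a plate layout with the screen's control convention.

    Controls occupy the first wells; each control is laid out in eight
    replicates per plate by default, matching screening practice.
    """
    rows = []
    idx = 0
    for rep in range(n_negative_controls):
        rows.append((_well_name(idx), "negative_control", negative_control_gene, rep))
        idx += 1
    for rep in range(n_positive_controls):
        rows.append((_well_name(idx), "positive_control", positive_control_gene, rep))
        idx += 1
    for gene in genes:
        for rep in range(replicates_per_gene):
            rows.append((_well_name(idx), "sample", gene, rep))
            idx += 1
    if idx > len(PLATE_ROWS) * PLATE_COLUMNS:
        raise ConfigurationError("layout exceeds 384 wells")
    entries = pd.DataFrame(rows, columns=["well", "role", "gene", "replicate"])
    return PlateMap(entries, plate_id=plate_id)


def simulate_plate(
    plate_map: PlateMap,
    gene_effects: Mapping[str, float],
    config: SimulationConfig,
    seed: int = 0,
    positive_control_rate: float = 0.2,
    cytotoxicity: Mapping[str, float] | None = None,
    count_noise: bool = True,
) -> pd.DataFrame:
    """Simulate per-well cell counts and GFP− counts for a whole plate.

    Negative-control wells evolve at the baseline
    ``config.loss_rate_per_division``; each sample gene must appear in
    ``gene_effects`` (its per-division loss rate), and positive controls
    use ``positive_control_rate``.  ``cytotoxicity`` maps gene → survival
    factor in (0, 1] scaling that gene's well cell counts.

    Per-well GFP− counts are drawn binomially with the per-cell GFP−
    probability implied by the loss model — the exact marginal
    distribution of the per-cell, per-division Bernoulli process — which
    keeps whole-plate simulations cheap.  Deterministic for a fixed seed.
    """
    cytotoxicity = dict(cytotoxicity or {})
    missing = [
        g for g in plate_map.sample_genes if g not in gene_effects
    ]
    if missing:
        raise ConfigurationError(f"genes in plate map without effect entry: {missing}")
    unknown = set(gene_effects) - set(plate_map.sample_genes)
    if unknown:
        raise ConfigurationError(
            f"gene_effects entries absent from plate map: {sorted(unknown)}"
        )

    rng = np.random.default_rng(seed)
    rows = []
    for entry in plate_map.entries.itertuples(index=False):
        if entry.role == "empty":
            continue
        if entry.role == "negative_control":
            rate = config.loss_rate_per_division
        elif entry.role == "positive_control":
            rate = positive_control_rate
        else:
            rate = float(gene_effects[entry.gene])
        well_cfg = dataclasses.replace(config, loss_rate_per_division=rate)
        p_gfp = expected_gfp_fraction(well_cfg)

        mean_cells = config.initial_cells * cytotoxicity.get(entry.gene, 1.0)
        n_cells = int(rng.poisson(mean_cells)) if count_noise else int(round(mean_cells))
        n_cells = max(n_cells, 0)
        n_gfp_neg = int(rng.binomial(n_cells, 1.0 - p_gfp)) if n_cells else 0
        rows.append(
            {
                "plate": plate_map.plate_id,
                "well": entry.well,
                "role": entry.role,
                "gene": entry.gene,
                "replicate": entry.replicate,
                "loss_rate_true": rate,
                "n_cells": n_cells,
                "n_gfp_negative": n_gfp_neg,
                "pct_gfp_negative": 100.0 * n_gfp_neg / n_cells if n_cells else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flow cytometry, micronucleus counts, growth curves
# ---------------------------------------------------------------------------

def simulate_facs_events(
    population: SimCellPopulation | float,
    n_events: int,
    dead_fraction: float = 0.05,
    seed: int = 0,
    gfp_neg_mean: float = 50.0,
    gfp_pos_mean: float = 400.0,
    gfp_sd: float = 20.0,
    dye_live_mean: float = 100.0,
    dye_dead_mean: float = 1500.0,
    dye_sd: float = 50.0,
) -> pd.DataFrame:
    """Draw a flow-cytometry event table (GFP and viability-dye intensity).

    Dead cells carry an elevated far-red viability-dye signal (DRAQ7-like);
    live events are GFP-bimodal with GFP+ probability equal to the
    population's GFP+ fraction.  Dead events draw their GFP intensity from
    the same mixture — dye gating, not GFP, is what identifies them.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0.0 <= dead_fraction <= 1.0:
        raise ValueError("dead_fraction must lie in [0, 1]")
    gfp_fraction = (
        population.gfp_fraction
        if isinstance(population, SimCellPopulation)
        else float(population)
    )
    rng = np.random.default_rng(seed)
    dead = rng.random(n_events) < dead_fraction
    gfp_pos = rng.random(n_events) < gfp_fraction
    gfp_int = np.where(
        gfp_pos,
        rng.normal(gfp_pos_mean, gfp_sd, n_events),
        rng.normal(gfp_neg_mean, gfp_sd, n_events),
    )
    dye_int = np.where(
        dead,
        rng.normal(dye_dead_mean, dye_sd, n_events),
        rng.normal(dye_live_mean, dye_sd, n_events),
    )
    return pd.DataFrame(
        {
            "gfp_intensity": np.clip(gfp_int, 0, None),
            "viability_dye_intensity": np.clip(dye_int, 0, None),
            "is_dead_true": dead,
            "is_gfp_positive_true": gfp_pos,
        }
    )


def simulate_mn_counts(
    n_scored: int,
    baseline_rate: float,
    fold_effect: float = 1.0,
    seed: int = 0,
) -> tuple[int, int]:
    """Draw (cells with event, cells without event) for a micronucleus or
    nucleoplasmic-bridge scoring experiment.

    The per-cell event probability is ``baseline_rate * fold_effect``;
    multi-event cells collapse to a binary per-cell call, matching
    percent-of-cells reporting.
    """
    if n_scored < 1:
        raise ValueError("n_scored must be >= 1")
    if not 0.0 <= baseline_rate <= 1.0:
        raise ValueError("baseline_rate must lie in [0, 1]")
    if fold_effect < 0:
        raise ValueError("fold_effect must be non-negative")
    rate = baseline_rate * fold_effect
    if rate > 1.0:
        raise ValueError(
            f"effective event rate {rate:.3g} exceeds 1 "
            f"(baseline {baseline_rate} x fold {fold_effect})"
        )
    rng = np.random.default_rng(seed)
    with_event = int(rng.binomial(n_scored, rate))
    return with_event, n_scored - with_event


def simulate_growth_curve(
    doubling_time_hours: float,
    n0: float = 100.0,
    duration_hours: float = 210.0,
    interval_hours: float = 6.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential growth counts ``n0 * 2^(t/Td)`` with multiplicative
    log-normal noise of coefficient of variation ``noise_cv``.

    Defaults mirror a 210 h time-lapse proliferation measurement.
    """
    if doubling_time_hours <= 0:
        raise ValueError("doubling_time_hours must be positive")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    t = np.arange(0.0, duration_hours + 1e-9, interval_hours)
    if len(t) < 3:
        raise ConfigurationError("growth curve needs at least 3 time points")
    counts = n0 * np.exp2(t / doubling_time_hours)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        counts = counts * rng.lognormal(-0.5 * sigma**2, sigma, len(t))
    return pd.DataFrame({"time_hours": t, "count": counts})


# ---------------------------------------------------------------------------
# protocol arithmetic
# ---------------------------------------------------------------------------

def sirna_final_concentration_nm(
    spot_volume_ul: float = 2.0,
    spot_concentration_um: float = 1.25,
    final_volume_ul: float = 50.0,
) -> float:
    """Final siRNA concentration (nM) after diluting the spotted oligo pool
    into the transfection-mix + cell volume.

    With the screen's reverse-transfection layout — 2 µL of 1.25 µM pool,
    25 µL transfection mix and 25 µL cell suspension, volume rounded to
    50 µL — this is 50 nM.
    """
    if spot_volume_ul <= 0 or final_volume_ul <= 0 or spot_concentration_um < 0:
        raise ValueError("volumes must be positive and concentration non-negative")
    if spot_volume_ul > final_volume_ul:
        raise ValueError("spot volume cannot exceed final volume")
    return 1000.0 * spot_concentration_um * spot_volume_ul / final_volume_ul


def cells_seeded_per_well(
    volume_ul: float = 25.0, density_cells_per_ul: float = 18.0
) -> float:
    """Cells dispensed per well: 25 µL at 18 cells/µL = 450 cells."""
    if volume_ul <= 0 or density_cells_per_ul < 0:
        raise ValueError("volume must be positive and density non-negative")
    return volume_ul * density_cells_per_ul
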