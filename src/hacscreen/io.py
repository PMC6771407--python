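"""File formats, run configuration and end-to-end orchestration.

Conventions:

* Field images are single-plane 16-bit grayscale TIFFs named
  ``<plate>_<well>_f<field>_<channel>.tif`` (channels ``DAPI``/``GFP``),
  mirroring plate/well/field/channel acquisition naming.
* Plate maps are CSV with header ``well,role,gene,replicate``.
* Per-field nucleus tables and well-level exports are tab-separated
  text; the screen's well export carries plate, well, role, gene,
  n_nuclei_qc, pct_gfp_negative, Z and the cytotoxicity flag.
* Run configuration is YAML; every stage takes an explicit seed.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import ClassifierParams, SegmentationParams, analyze_field
from .screen import (
    WellSummary,
    call_hits,
    compute_zscores,
    flag_cytotoxic,
    summarize_well,
    wells_to_frame,
)
from .simulate import (
    ConfigurationError,
    IntensityModel,
    PlateMap,
    SimulationConfig,
    expected_gfp_fraction,
    render_field,
    validate_well_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_plate_map",
    "write_plate_map",
    "field_image_name",
    "write_field_tiffs",
    "read_field_tiffs",
    "write_nucleus_table",
    "simulate_plate_images",
    "score_plate",
    "run_screen",
]

_FIELD_NAME = "{plate}_{well}_f{field:02d}_{channel}.tif"


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------

def read_plate_map(path: str | Path, plate_id: str | None = None) -> PlateMap:
    """Read and validate a plate-map CSV (header well,role,gene,replicate).

    Malformed well ids (outside A1-P24) and duplicate wells are rejected
    with the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"well": str, "role": str, "gene": str})
    required = {"well", "role", "gene", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"{path}: plate map missing columns {sorted(missing)}"
        )
    for i, well in enumerate(df["well"]):
        try:
            validate_well_id(well)
        except ConfigurationError as exc:
            # +2: header line plus 1-based numbering
            raise ConfigurationError(f"{path}, line {i + 2}: {exc}") from exc
    df["gene"] = df["gene"].fillna("")
    return PlateMap(df, plate_id=plate_id or path.stem)


def write_plate_map(plate_map: PlateMap, path: str | Path) -> None:
    plate_map.entries.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images and tables
# ---------------------------------------------------------------------------

def field_image_name(plate: str, well: str, field_index: int, channel: str) -> str:
    return _FIELD_NAME.format(
        plate=plate, well=well, field=field_index, channel=channel
    )


def write_field_tiffs(
    dapi: np.ndarray,
    gfp: np.ndarray,
    outdir: str | Path,
    plate: str,
    well: str,
    field_index: int,
) -> tuple[Path, Path]:
    """Write one field's channels as 16-bit TIFFs with the acquisition
    naming convention; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, img in (("DAPI", dapi), ("GFP", gfp)):
        p = outdir / field_image_name(plate, well, field_index, channel)
        tifffile.imwrite(p, np.asarray(img, dtype=np.uint16))
        paths.append(p)
    return paths[0], paths[1]


def read_field_tiffs(
    images_dir: str | Path, plate: str, well: str, field_index: int
) -> tuple[np.ndarray, np.ndarray]:
    images_dir = Path(images_dir)
    dapi = tifffile.imread(
        images_dir / field_image_name(plate, well, field_index, "DAPI")
    )
    gfp = tifffile.imread(
        images_dir / field_image_name(plate, well, field_index, "GFP")
    )
    return dapi, gfp


def list_well_fields(images_dir: str | Path, plate: str, well: str) -> list[int]:
    """Field indices present on disk for one well, sorted."""
    pattern = re.compile(
        re.escape(plate) + "_" + re.escape(well) + r"_f(\d+)_DAPI\.tif$"
    )
    out = []
    for p in Path(images_dir).iterdir():
        m = pattern.match(p.name)
        if m:
            out.append(int(m.group(1)))
    return sorted(out)


def write_nucleus_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# simulated plates on disk
# ---------------------------------------------------------------------------

def simulate_plate_images(
    plate_map: PlateMap,
    gene_effects: dict[str, float],
    config: SimulationConfig,
    images_dir: str | Path,
    n_fields: int = 9,
    nuclei_per_field: int = 40,
    field_shape: tuple[int, int] = (512, 512),
    intensity: IntensityModel = IntensityModel(),
    positive_control_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Render and write TIFF field images for every used well of a plate.

    Per-well GFP+ fractions follow the loss model (negative controls at
    the baseline rate, sample genes at their ``gene_effects`` rate) and
    each field is rendered with its own derived seed.  Returns the
    per-nucleus ground truth across all wells and fields.
    """
    missing = [g for g in plate_map.sample_genes if g not in gene_effects]
    if missing:
        raise ConfigurationError(
            f"genes in plate map without effect entry: {missing}"
        )
    rng = np.random.default_rng(seed)
    truths = []
    for entry in plate_map.entries.itertuples(index=False):
        if entry.role == "empty":
            continue
        if entry.role == "negative_control":
            rate = config.loss_rate_per_division
        elif entry.role == "positive_control":
            rate = positive_control_rate
        else:
            rate = float(gene_effects[entry.gene])
        cfg = dataclasses.replace(config, loss_rate_per_division=rate)
        p_gfp = expected_gfp_fraction(cfg)
        for f_idx in range(n_fields):
            dapi, gfp, truth = render_field(
                p_gfp,
                n_nuclei=nuclei_per_field,
                image_shape=field_shape,
                intensity=intensity,
                seed=int(rng.integers(2**31)),
            )
            write_field_tiffs(
                dapi, gfp, images_dir, plate_map.plate_id, entry.well, f_idx
            )
            truth["well"] = entry.well
            truth["field"] = f_idx
            truths.append(truth)
    return pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end screen configuration.

    Defaults match the screen's constants: GFP threshold 100 AU,
    roundness cut-off 0.7, nine fields per well, 96 h treatment.
    """

    images_dir: str = "images"
    plate_map: str = "plate_map.csv"
    plate_id: str | None = None  # default: plate-map file stem
    output_dir: str = "screen_out"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    alpha: float = 0.05
    reference: str = "plate_population"
    min_count_fraction: float = 0.5
    n_fields: int = 9
    duration_hours: float = 96.0
    doubling_time_hours: float = 24.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        cls_params = ClassifierParams(**raw.pop("classifier", {}))
        return cls(segmentation=seg, classifier=cls_params, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def score_plate(
    plate_map: PlateMap,
    nuclei_dir: str | Path,
    alpha: float = 0.05,
    reference: str = "plate_population",
    min_count_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a plate from per-field nucleus TSVs already on disk.

    Expects tables named ``<plate>_<well>_f<NN>_nuclei.tsv`` as written
    by :func:`run_screen`.  Returns the well-level table and the
    gene-level hit table.
    """
    nuclei_dir = Path(nuclei_dir)
    wells: list[WellSummary] = []
    for entry in plate_map.entries.itertuples(index=False):
        if entry.role == "empty":
            continue
        paths = sorted(
            nuclei_dir.glob(f"{plate_map.plate_id}_{entry.well}_f*_nuclei.tsv")
        )
        if not paths:
            logger.warning("well %s: no nucleus tables found; skipped", entry.well)
            continue
        tables = [pd.read_csv(p, sep="\t") for p in paths]
        wells.append(
            summarize_well(
                tables,
                plate=plate_map.plate_id,
                well=entry.well,
                role=entry.role,
                gene=entry.gene,
                replicate=int(entry.replicate),
            )
        )
    compute_zscores(wells, reference=reference)
    flag_cytotoxic(wells, min_count_fraction=min_count_fraction)
    result = call_hits(wells, alpha=alpha)
    return wells_to_frame(wells), result.genes


def run_screen(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis on a directory of field images.

    Stages: read the plate map; per well, segment every field, measure
    and QC nuclei, classify GFP, write the per-field nucleus TSV; pool
    fields into well summaries; Z-score; flag cytotoxic wells; call
    hits.  Writes ``wells.tsv``, ``hits.tsv``, per-field nucleus tables
    and a log recording every exclusion; idempotent for fixed inputs.

    Returns the paths of the main artifacts.
    """
    images_dir = Path(config.images_dir)
    if not images_dir.is_dir():
        raise FileNotFoundError(f"image directory not found: {images_dir}")
    plate_map = read_plate_map(config.plate_map, plate_id=config.plate_id)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    nuclei_dir = outdir / "nuclei"

    log_path = outdir / "screen.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hacscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        wells: list[WellSummary] = []
        for entry in plate_map.entries.itertuples(index=False):
            if entry.role == "empty":
                continue
            field_ids = list_well_fields(images_dir, plate_map.plate_id, entry.well)
            if not field_ids:
                logger.warning("well %s: no images found; skipped", entry.well)
                continue
            tables = []
            for f_idx in field_ids:
                dapi, gfp = read_field_tiffs(
                    images_dir, plate_map.plate_id, entry.well, f_idx
                )
                table, removed = analyze_field(
                    dapi, gfp, config.segmentation, config.classifier
                )
                logger.info(
                    "well %s field %d: %d nuclei, removed %d border / %d low-roundness",
                    entry.well, f_idx, len(table),
                    removed["touches_border"], removed["low_roundness"],
                )
                write_nucleus_table(
                    table,
                    nuclei_dir
                    / f"{plate_map.plate_id}_{entry.well}_f{f_idx:02d}_nuclei.tsv",
                )
                tables.append(table)
            wells.append(
                summarize_well(
                    tables,
                    plate=plate_map.plate_id,
                    well=entry.well,
                    role=entry.role,
                    gene=entry.gene,
                    replicate=int(entry.replicate),
                )
            )
        compute_zscores(wells, reference=config.reference)
        flag_cytotoxic(wells, min_count_fraction=config.min_count_fraction)
        result = call_hits(wells, alpha=config.alpha)

        wells_path = outdir / "wells.tsv"
        wells_to_frame(wells).to_csv(
            wells_path, sep="\t", index=False, float_format="%.6g"
        )
        hits_path = outdir / "hits.tsv"
        result.genes.to_csv(hits_path, sep="\t", index=False, float_format="%.6g")
        logger.info("hits: %s", ", ".join(result.hits) or "(none)")
    finally:
        root.removeHandler(handler)
        handler.close()
    return {"wells": wells_path, "hits": hits_path, "log": log_path}
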