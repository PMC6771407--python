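"""Well-level aggregation, Z-scores, cytotoxicity gating and hit calling.

The percentage of GFP− cells per well is the proxy for HAC loss.  Nuclei
are pooled across a well's fields of view before the percentage is
computed; wells with no QC-passing nuclei are flagged undefined and
excluded from references and tests.  Each sample well gets a Z-score
relative to a reference population (all sample wells of the plate by
default, or the negative controls), wells with depressed cell counts are
flagged cytotoxic, and genes are called hits by a two-sample Welch
t-test of their replicate wells against the negative-control wells —
a hit requires p < alpha and no cytotoxicity flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imaging import GFP_NEGATIVE

logger = logging.getLogger(__name__)

__all__ = [
    "WellSummary",
    "ScreenResult",
    "DegeneratePlateError",
    "summarize_well",
    "compute_zscores",
    "flag_cytotoxic",
    "call_hits",
    "wells_to_frame",
]


class DegeneratePlateError(ValueError):
    """The Z-score reference population has zero spread."""


@dataclass
class WellSummary:
    """Per-well aggregate over all fields of view."""

    plate: str
    well: str
    role: str
    gene: str
    n_fields: int
    n_nuclei_total: int
    n_nuclei_qc: int
    n_gfp_negative: int
    replicate: int = 0
    cytotoxic: bool = False
    z_score: float = np.nan

    def __post_init__(self) -> None:
        if not 0 <= self.n_gfp_negative <= self.n_nuclei_qc <= self.n_nuclei_total:
            raise ValueError(
                "well counts must satisfy GFP- <= QC-passing <= total nuclei"
            )

    @property
    def defined(self) -> bool:
        return self.n_nuclei_qc > 0

    @property
    def pct_gfp_negative(self) -> float:
        if not self.defined:
            return float("nan")
        return 100.0 * self.n_gfp_negative / self.n_nuclei_qc


def summarize_well(
    field_tables: list[pd.DataFrame],
    plate: str = "plate1",
    well: str = "A1",
    role: str = "sample",
    gene: str = "",
    replicate: int = 0,
) -> WellSummary:
    """Pool nucleus tables from all fields of one well.

    Each field table holds one row per segmented nucleus with at least
    ``qc_pass`` and ``gfp_class`` columns (as written by
    :func:`hacscreen.imaging.analyze_field`).  Pooling precedes the
    percentage computation, so field order is irrelevant.  A well whose
    fields contain no QC-passing nucleus is returned flagged undefined
    (``pct_gfp_negative`` is NaN) and must be excluded downstream.
    """
    if not field_tables:
        raise ValueError("at least one field table is required")
    pooled = pd.concat(field_tables, ignore_index=True)
    n_total = len(pooled)
    qc = pooled[pooled["qc_pass"].astype(bool)] if n_total else pooled
    n_qc = len(qc)
    n_neg = int((qc["gfp_class"] == GFP_NEGATIVE).sum()) if n_qc else 0
    summary = WellSummary(
        plate=plate,
        well=well,
        role=role,
        gene=gene,
        replicate=replicate,
        n_fields=len(field_tables),
        n_nuclei_total=n_total,
        n_nuclei_qc=n_qc,
        n_gfp_negative=n_neg,
    )
    if not summary.defined:
        logger.warning("well %s/%s has no QC-passing nuclei; flagged undefined",
                       plate, well)
    return summary


def compute_zscores(
    wells: list[WellSummary], reference: str = "plate_population"
) -> dict[str, float]:
    """Z-score each sample well's %GFP− against a reference population.

    ``reference="plate_population"`` uses all defined sample wells (the
    population-mean convention); ``"negative_controls"`` uses the
    negative-control wells.  The sample standard deviation (ddof=1) is
    used.  Z-scores are written back onto the ``WellSummary`` objects and
    returned as a mapping well id → Z.  Control wells are annotated with
    a Z against the same reference but never included in the
    plate-population reference itself.
    """
    if reference == "plate_population":
        ref = [w for w in wells if w.role == "sample" and w.defined]
    elif reference == "negative_controls":
        ref = [w for w in wells if w.role == "negative_control" and w.defined]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if len(ref) < 2:
        raise DegeneratePlateError("Z-score reference needs >= 2 usable wells")
    values = np.array([w.pct_gfp_negative for w in ref])
    mean, sd = values.mean(), values.std(ddof=1)
    if sd == 0:
        raise DegeneratePlateError("constant reference population: sd = 0")
    out: dict[str, float] = {}
    for w in wells:
        if not w.defined:
            continue
        w.z_score = (w.pct_gfp_negative - mean) / sd
        out[w.well] = w.z_score
    return out


def flag_cytotoxic(
    wells: list[WellSummary], min_count_fraction: float = 0.5
) -> list[WellSummary]:
    """Flag wells whose QC-passing nucleus count falls below
    ``min_count_fraction`` of the negative-control median count.

    siRNAs that kill most cells cannot report on HAC loss, so flagged
    wells are barred from the hit list.
    """
    controls = [w for w in wells if w.role == "negative_control" and w.defined]
    if not controls:
        raise ValueError("cytotoxicity gating requires negative-control wells")
    median_count = float(np.median([w.n_nuclei_qc for w in controls]))
    threshold = min_count_fraction * median_count
    for w in wells:
        w.cytotoxic = w.n_nuclei_qc < threshold
    return wells


@dataclass
class ScreenResult:
    """Gene-level outcome of one plate: a table with per-gene mean %GFP−,
    Z-score, t-test p-value vs the negative controls, cytotoxicity and hit
    flags, sorted by descending Z."""

    genes: pd.DataFrame
    alpha: float
    n_negative_control_wells: int

    @property
    def hits(self) -> list[str]:
        return self.genes.loc[self.genes["hit"], "gene"].tolist()


def call_hits(
    wells: list[WellSummary],
    alpha: float = 0.05,
    correction: str | None = None,
) -> ScreenResult:
    """Call hit genes from replicate wells.

    Per gene, a two-sided Welch t-test compares the gene's
    ``pct_gfp_negative`` replicates against the negative-control wells;
    a gene is a hit iff p < alpha and it is not cytotoxic (majority of
    its wells flagged).  Genes with fewer than two usable replicate
    wells are excluded with a warning.  ``correction="bh"`` applies
    Benjamini–Hochberg to the gene p-values (off by default; primary
    screens typically defer correction to independent reconfirmation).
    """
    controls = [
        w.pct_gfp_negative
        for w in wells
        if w.role == "negative_control" and w.defined
    ]
    if len(controls) < 2:
        raise ValueError("hit calling requires >= 2 defined negative-control wells")

    rows = []
    sample_wells = [w for w in wells if w.role == "sample" and w.defined]
    by_gene: dict[str, list[WellSummary]] = {}
    for w in sample_wells:
        by_gene.setdefault(w.gene, []).append(w)
    for gene in sorted(by_gene):
        replicates = by_gene[gene]
        if len(replicates) < 2:
            warnings.warn(
                f"gene {gene!r} has a single usable replicate; excluded from testing",
                stacklevel=2,
            )
            continue
        values = [w.pct_gfp_negative for w in replicates]
        t_stat, p = stats.ttest_ind(values, controls, equal_var=False)
        cytotoxic = sum(w.cytotoxic for w in replicates) * 2 > len(replicates)
        zs = [w.z_score for w in replicates if np.isfinite(w.z_score)]
        rows.append(
            {
                "gene": gene,
                "n_wells": len(replicates),
                "mean_pct_gfp_negative": float(np.mean(values)),
                "z_score": float(np.mean(zs)) if zs else np.nan,
                "t_statistic": float(t_stat),
                "p_value": float(p),
                "cytotoxic": bool(cytotoxic),
            }
        )
    genes = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_wells",
            "mean_pct_gfp_negative",
            "z_score",
            "t_statistic",
            "p_value",
            "cytotoxic",
        ],
    )
    if len(genes):
        if correction == "bh":
            reject, p_adj, _, _ = multipletests(
                genes["p_value"], alpha=alpha, method="fdr_bh"
            )
            genes["p_adjusted"] = p_adj
            genes["hit"] = reject & ~genes["cytotoxic"]
        elif correction is None:
            genes["hit"] = (genes["p_value"] < alpha) & ~genes["cytotoxic"]
        else:
            raise ValueError(f"unknown correction {correction!r}")
        genes = genes.sort_values(
            "z_score", ascending=False, ignore_index=True
        )
    else:
        genes["hit"] = pd.Series(dtype=bool)
    return ScreenResult(genes=genes, alpha=alpha,
                        n_negative_control_wells=len(controls))


def wells_to_frame(wells: list[WellSummary]) -> pd.DataFrame:
    """Tabulate well summaries for TSV export."""
    rows = [
        {
            "plate": w.plate,
            "well": w.well,
            "role": w.role,
            "gene": w.gene,
            "replicate": w.replicate,
            "n_fields": w.n_fields,
            "n_nuclei_total": w.n_nuclei_total,
            "n_nuclei_qc": w.n_nuclei_qc,
            "n_gfp_negative": w.n_gfp_negative,
            "pct_gfp_negative": w.pct_gfp_negative,
            "z_score": w.z_score,
            "cytotoxic": w.cytotoxic,
        }
        for w in wells
    ]
    return pd.DataFrame(rows)
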