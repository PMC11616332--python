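"""qPCR calculators: end-resection level, percent input, fold enrichment.

Resection is quantified by restriction protection: genomic DNA is split
into a mock and a restriction-digested fraction, and a site that has been
resected to ssDNA resists digestion, so it still amplifies.  With
``dCq = Cq_digested - Cq_mock`` the single-stranded fraction is

    ssDNA% = 100 / (2**(dCq - 1) + 0.5)

which is 100% at dCq = 0 (full protection) and decays toward zero as the
digested fraction drops out.  The same Cq arithmetic underlies the
ChIP/DRIP calculators: percent input recovery corrects the input Cq for
its dilution and exponentiates the Cq difference, and fold enrichment is
the recovery ratio between a target and a reference region, called
significant at a twofold increase.

Technical replicates are averaged on the Cq scale before any
exponentiation; biological replicates are summarized (mean +/- SD) after
transformation to percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CqMeasurement",
    "resection_percent",
    "resection_table",
    "percent_input_recovery",
    "fold_enrichment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CqMeasurement:
    """One well group: technical-replicate Cq values for a site/condition."""

    site: str
    condition: str  # digested | mock | input | IP
    cq: tuple[float, ...]
    distance_bp: float = math.nan
    timepoint_h: float = math.nan
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if not self.cq:
            raise ValueError("at least one Cq replicate required")
        if any(not math.isfinite(c) or c <= 0 for c in self.cq):
            raise ValueError("Cq values must be finite and > 0")

    @property
    def mean_cq(self) -> float:
        return float(np.mean(self.cq))


def resection_percent(cq_digested: float, cq_mock: float) -> float:
    """ssDNA percentage from digested/mock mean Cq values.

    Negative dCq (digested amplifying *earlier* than mock) is physically
    impossible up to noise and is clamped to 100% with a warning.
    """
    if not (math.isfinite(cq_digested) and math.isfinite(cq_mock)):
        raise ValueError("Cq values must be finite")
    dcq = cq_digested - cq_mock
    if dcq < 0:
        log.warning("negative dCq (%.3f) clamped to 100%% ssDNA", dcq)
        return 100.0
    return 100.0 / (2.0 ** (dcq - 1.0) + 0.5)


def resection_table(
    measurements: pd.DataFrame,
    unedited: pd.DataFrame | None = None,
    default_cutoff: float = 10.0,
) -> pd.DataFrame:
    """Per site x timepoint resection summary.

    ``measurements`` is a tidy table with columns site, timepoint_h,
    condition (digested/mock), replicate (biological), cq — one row per
    technical replicate.  Technical replicates are averaged on the Cq
    scale; each biological replicate yields one ssDNA percentage; the
    output carries mean, SD and n per (site, timepoint), plus an
    ``above_baseline`` flag.  The baseline is the site's unedited-sample
    level when ``unedited`` is given (same schema), else
    ``default_cutoff`` percent — the resection level of unedited samples
    is the detection cutoff.
    """
    df = measurements.copy()
    required = {"site", "timepoint_h", "condition", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError("missing columns: %s" % sorted(missing))

    mean_cq = (
        df.groupby(["site", "timepoint_h", "replicate", "condition"])["cq"]
        .mean()
        .unstack("condition")
    )
    if "digested" not in mean_cq or "mock" not in mean_cq:
        raise ValueError("unpaired measurement: need digested and mock conditions")
    if mean_cq[["digested", "mock"]].isna().any().any():
        bad = mean_cq[mean_cq[["digested", "mock"]].isna().any(axis=1)].index.tolist()
        raise ValueError("unpaired measurement at %s" % bad[:5])

    pct = mean_cq.apply(
        lambda r: resection_percent(r["digested"], r["mock"]), axis=1
    ).rename("ssdna_pct")
    per_cell = (
        pct.reset_index()
        .groupby(["site", "timepoint_h"])["ssdna_pct"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "ssdna_mean", "std": "ssdna_sd", "count": "n"})
        .reset_index()
    )

    if unedited is not None:
        base = resection_table(unedited, unedited=None, default_cutoff=default_cutoff)
        baseline = base.groupby("site")["ssdna_mean"].max()
        per_cell["baseline"] = per_cell["site"].map(baseline).fillna(default_cutoff)
    else:
        per_cell["baseline"] = default_cutoff
    per_cell["above_baseline"] = per_cell["ssdna_mean"] > per_cell["baseline"]
    return per_cell


def percent_input_recovery(
    cq_input: float, cq_ip: float, dilution: float = 1.0
) -> float:
    """Percent of input chromatin recovered in the immunoprecipitate.

    The input Cq is first corrected for its dilution factor
    (``cq_input - log2(dilution)`` is the undiluted-equivalent Cq), then
    ``recovery% = 100 * 2**(adjusted_input_cq - cq_ip)``.
    """
    if dilution < 1:
        raise ValueError("dilution must be >= 1")
    adj = cq_input - math.log2(dilution)
    return 100.0 * 2.0 ** (adj - cq_ip)


def fold_enrichment(
    recovery_target: float, recovery_reference: float
) -> tuple[float, bool]:
    """Enrichment of a target region over the reference region.

    Returns ``(fold, significant)``; a twofold (or greater, inclusive)
    increase over the reference is called significant.
    """
    if recovery_reference <= 0:
        raise ValueError("reference recovery must be > 0")
    fold = recovery_target / recovery_reference
    return fold, fold >= 2.0
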