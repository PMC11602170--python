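"""Quantitative utilities for characterizing coupling-element constructs.

Fluorescence reporter distributions from flow cytometry are approximately
log-normal, so averages use the geometric mean; the dynamic range of a
construct is the fold change, the ratio of geometric-mean ON-state to
OFF-state fluorescence, with the two states' relative errors combined in
quadrature.  Design features (stem dG, RBS strength, intergenic distance,
local structure) are regressed against measured outputs by ordinary least
squares, and colony counts convert to viable-cell density via the plating
formula CFU/ml = colonies x dilution / 0.005 ml (5 ul spotted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import OperonDesign, scan_internal_rbs, validate_operon
from .config import DesignConfig, default_config
from .design import Candidate, DesignError
from .seqcore import SeqValidationError
from .thermo import EnergyModel, default_energy_model

__all__ = [
    "MeasurementSample",
    "RegressionFit",
    "fold_change",
    "fit_linear",
    "cfu_per_ml",
    "feature_table",
    "read_measurements",
]

#: Plated volume (ml) in the viability assay.
PLATED_VOLUME_ML = 0.005


@dataclass(frozen=True)
class MeasurementSample:
    """Replicate fluorescence measurements of one construct in one state.

    ``relative_error`` follows the sample-s.d.-over-geometric-mean
    convention (s.d. of the raw replicate values divided by their
    geometric mean).
    """

    construct_id: str
    state: str  # "ON" | "OFF"
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.state not in ("ON", "OFF"):
            raise SeqValidationError(
                f"state must be 'ON' or 'OFF', got {self.state!r}"
            )
        if len(self.values) < 1:
            raise SeqValidationError("at least one replicate is required")
        if any(v <= 0 for v in self.values):
            raise SeqValidationError(
                "all replicate values must be > 0 (geometric mean)"
            )
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def geometric_mean(self) -> float:
        return float(stats.gmean(self.values))

    @property
    def relative_error(self) -> float:
        if len(self.values) < 2:
            return 0.0
        return float(np.std(self.values, ddof=1)) / self.geometric_mean


def fold_change(
    on: MeasurementSample, off: MeasurementSample
) -> Tuple[float, float]:
    """Fold change and its quadrature relative error.

    fold = geomean(ON) / geomean(OFF);
    relative_error = sqrt(rel_ON^2 + rel_OFF^2).
    """
    fold = on.geometric_mean / off.geometric_mean
    rel = math.sqrt(on.relative_error ** 2 + off.relative_error ** 2)
    return fold, rel


@dataclass(frozen=True)
class RegressionFit:
    """Simple-linear-regression result."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


def fit_linear(
    x: Sequence[float], y: Sequence[float], log_response: bool = False
) -> RegressionFit:
    """Ordinary-least-squares simple linear regression of y on x.

    ``log_response`` regresses log10(y) instead (all y must be positive),
    matching the log-normal character of fluorescence data when desired.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SeqValidationError(
            f"length mismatch: {x.shape[0]} x values vs {y.shape[0]} y values"
        )
    if x.size < 3:
        raise SeqValidationError("at least 3 points are required")
    if np.ptp(x) == 0:
        raise SeqValidationError("degenerate predictor: x is constant")
    if log_response:
        if np.any(y <= 0):
            raise SeqValidationError("log response requires positive y")
        y = np.log10(y)
    if np.ptp(y) == 0:
        return RegressionFit(0.0, float(y[0]), 0.0, x.size)
    res = stats.linregress(x, y)
    return RegressionFit(
        float(res.slope), float(res.intercept),
        float(res.rvalue ** 2), x.size,
    )


def cfu_per_ml(colonies: int, dilution_factor: float) -> float:
    """Viable-cell density from a spot-plating count.

    CFU/ml = colonies x dilution_factor / 0.005 ml.
    """
    if colonies < 0 or int(colonies) != colonies:
        raise SeqValidationError("colony count must be a non-negative integer")
    if dilution_factor < 1:
        raise SeqValidationError("dilution factor must be >= 1")
    return colonies * dilution_factor / PLATED_VOLUME_ML


FEATURE_COLUMNS = [
    "design_id",
    "stem_dG",
    "rbs_total",
    "rbs_dG_rRNA_mRNA",
    "rbs_dG_spacing",
    "intergenic_distance",
    "loop_len",
    "local_structure",
    "internal_rbs_count",
]


def feature_table(
    designs: Iterable[Union[Candidate, OperonDesign]],
    model: EnergyModel | None = None,
    config: DesignConfig | None = None,
) -> pd.DataFrame:
    """One row of thermodynamic/geometric features per candidate (or per
    operon junction), ready to join against a measurement table for
    feature-vs-output regression."""
    model = model or default_energy_model()
    config = config or default_config()
    rows: List[dict] = []
    for k, design in enumerate(designs):
        if isinstance(design, Candidate):
            if not design.scored:
                raise DesignError(
                    f"candidate {k} is unscored; run filter_candidate first"
                )
            cassette = str(design.cassette)
            rows.append({
                "design_id": f"candidate_{design.draw_index}",
                "stem_dG": design.stem_dG,
                "rbs_total": design.rbs_score.total,
                "rbs_dG_rRNA_mRNA": design.rbs_score.dG_rRNA_mRNA,
                "rbs_dG_spacing": design.rbs_score.dG_spacing,
                "intergenic_distance": -1,
                "loop_len": len(design.spec.loop_seq),
                "local_structure": design.local_structure,
                # exclude the cassette's own coupled AUG: only unintended
                # initiation sites count
                "internal_rbs_count": len(
                    scan_internal_rbs(cassette[:-3], None, model, None, config)
                ),
            })
        elif isinstance(design, OperonDesign):
            reports = validate_operon(design, model, config)
            s = str(design.transcript)
            for j, (junction, report) in enumerate(zip(design.junctions, reports)):
                from .thermo import local_structure_score, stem_dG as _stem_dG

                stem5 = s[junction.cassette_region.start:
                          junction.cassette_region.start + junction.stem_len]
                rows.append({
                    "design_id": f"operon_{k}_junction_{j}",
                    "stem_dG": _stem_dG(stem5, model) if stem5 else 0.0,
                    "rbs_total": report.rbs_score.total,
                    "rbs_dG_rRNA_mRNA": report.rbs_score.dG_rRNA_mRNA,
                    "rbs_dG_spacing": report.rbs_score.dG_spacing,
                    "intergenic_distance": report.intergenic_distance,
                    "loop_len": junction.loop_len,
                    "local_structure": local_structure_score(
                        s, junction.start_region.start, model
                    ),
                    "internal_rbs_count": len(
                        scan_internal_rbs(
                            s[junction.cassette_region.start:
                              junction.cassette_region.end - 3],
                            None, model, None, config,
                        )
                    ),
                })
        else:
            raise DesignError(
                f"feature_table accepts Candidate or OperonDesign, got "
                f"{type(design).__name__}"
            )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def read_measurements(path) -> List[MeasurementSample]:
    """Read a measurement CSV (columns construct_id, state, replicate,
    value) into per-construct, per-state samples."""
    df = pd.read_csv(path)
    required = {"construct_id", "state", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SeqValidationError(
            f"measurement CSV missing column(s): {sorted(missing)}"
        )
    samples = []
    for (cid, state), group in df.groupby(["construct_id", "state"], sort=True):
        samples.append(
            MeasurementSample(str(cid), str(state), tuple(group["value"]))
        )
    return samples
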