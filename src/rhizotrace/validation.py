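"""Built-in validation experiments for the extraction pipeline.

Two self-contained studies mirror how plate-based phenotyping software is
conventionally validated:

* :func:`rod_length_accuracy` — straight reference rods of known length are
  rendered, traced, and regressed against truth (reported as R^2 of the
  measured-vs-true lengths).
* :func:`recovery_study` — whole synthetic root systems are rendered and
  re-extracted; per plant the study reports the relative primary-length
  error, lateral-count match, branch-position error and the branching-angle
  error, plus whether the plant falls in the "well-separated" regime (every
  lateral at least 1 mm long, adjacent branch points at least 1 mm apart)
  in which lateral counting is expected to be exact.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .extraction import ExtractionParams, extract_root_systems
from .root_traits import TraitConfig, branching_angle
from .synthetic import (
    GrowthParams,
    RenderParams,
    make_calibration_rods,
    prune_immature,
    render_root_image,
    sample_root_system,
)

__all__ = ["rod_length_accuracy", "recovery_study", "well_separated"]


def rod_length_accuracy(
    lengths_mm: Sequence[float],
    seed: int = 0,
    render: Optional[RenderParams] = None,
    params: Optional[ExtractionParams] = None,
) -> tuple[pd.DataFrame, float]:
    """Trace rendered calibration rods and regress measured on true length.

    Returns the per-rod table (true and measured mm) and the R^2 of the
    linear regression.
    """
    render = render or RenderParams()
    params = params or ExtractionParams()
    rng = np.random.default_rng(seed)
    plates, _systems, truth = make_calibration_rods(lengths_mm, render, rng)
    measured = []
    for plate in plates:
        systems = extract_root_systems(plate.image, params)
        measured.append(max((s.primary().length_mm() for s in systems if not s.empty), default=np.nan))
    table = truth.assign(measured_mm=measured)
    x = table["length_mm"].to_numpy()
    y = table["measured_mm"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float((resid**2).sum()) / float(((y - y.mean()) ** 2).sum())
    return table, r2


def well_separated(system, min_lateral_mm: float = 1.0, min_spacing_mm: float = 1.0) -> bool:
    """True when every first-order lateral is at least ``min_lateral_mm`` long
    and consecutive branch points are at least ``min_spacing_mm`` apart."""
    lats = system.laterals(order=1)
    if any(ax.length_mm() < min_lateral_mm for ax in lats):
        return False
    pos = sorted(ax.branch_pos_mm for ax in lats)
    return all(b - a >= min_spacing_mm for a, b in zip(pos, pos[1:]))


def recovery_study(
    n_plants: int = 20,
    seed: int = 0,
    growth: Optional[GrowthParams] = None,
    render: Optional[RenderParams] = None,
    params: Optional[ExtractionParams] = None,
    age_days: Optional[float] = None,
    separation_regime: bool = False,
) -> pd.DataFrame:
    """Render -> extract -> compare, one synthetic plant per plate.

    Returns a DataFrame with one row per plant: true and estimated primary
    length, first-order lateral counts, per-plant mean branching angles
    (true and estimated, degrees), and the well-separated flag.

    With ``separation_regime`` the ground truth is put into the
    well-separated regime before rendering: immature laterals (< 1 mm) are
    pruned and plants whose branch points sit closer than 1 mm are skipped,
    so exact lateral counting is a meaningful expectation.
    """
    growth = growth or GrowthParams()
    render = render or RenderParams(plate_mm=growth.plate_mm)
    params = params or ExtractionParams()
    cfg = TraitConfig()
    rng = np.random.default_rng(seed)
    rows = []
    attempts = 0
    while len(rows) < n_plants and attempts < 20 * n_plants:
        attempts += 1
        i = len(rows)
        truth = sample_root_system(growth, age_days if age_days is not None else growth.duration_days, rng, plant_id=f"p{i + 1:02d}")
        if separation_regime:
            truth = prune_immature(truth, 1.0)
            if not well_separated(truth):
                continue
        plate = render_root_image([truth], render, rng, plate_id=f"P{i + 1:02d}")
        extracted = extract_root_systems(plate.image, params)
        est = min(
            (s for s in extracted if not s.empty),
            key=lambda s: abs(s.seed_point[0] - truth.seed_point[0]),
            default=None,
        )
        def _mean_angle(system) -> float:
            angles = [
                a
                for a in (branching_angle(system, ax, cfg) for ax in system.laterals(order=1))
                if a is not None
            ]
            return float(np.mean(angles)) if angles else np.nan

        rows.append(
            {
                "plant": truth.plant_id,
                "true_primary_mm": truth.primary().length_mm(),
                "est_primary_mm": est.primary().length_mm() if est else np.nan,
                "true_n_lateral": len(truth.laterals(order=1)),
                "est_n_lateral": len(est.laterals(order=1)) if est else 0,
                "true_angle_deg": _mean_angle(truth),
                "est_angle_deg": _mean_angle(est) if est else np.nan,
                "well_separated": well_separated(truth),
            }
        )
    return pd.DataFrame(rows)
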