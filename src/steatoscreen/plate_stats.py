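"""Plate-level statistics: normalization, QC metrics, hit/cytotoxicity calls.

Quality control follows standard HTS practice on the per-plate control
columns: the stimulator control (maximal lipid accumulation) and the neutral
control (no induction). The Z'-factor,

    Z' = 1 - 3 * (SD_sample + SD_negative) / |mean_sample - mean_negative|,

summarizes control separation versus spread (0.5-1.0: excellent assay;
0-0.5: suboptimal; < 0: unsuccessful). The robust variant substitutes the
median and the scaled MAD (1.4826 * MAD). Percent inhibition normalizes a
compound-well value between the stimulator control mean (0%) and the neutral
control mean (100%):

    % inhibition = 100 * (value - AVE_stim) / (AVE_neut - AVE_stim).

Hit calling is threshold-based, exactly as screens report it: a compound
well is a hit when it inhibits the integrated spot signal (and, optionally,
the spot count) by at least 50% while retaining more than 60% of the control
cell count; wells at or below 40% of the control cell count are cytotoxic,
and cytotoxicity takes precedence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateLayout",
    "PlateQC",
    "HitThresholds",
    "WellCall",
    "z_prime",
    "robust_z_prime",
    "z_prime_band",
    "percent_inhibition",
    "qc_plate",
    "call_wells",
    "median_polish_correct",
]


@dataclass
class PlateLayout:
    """Control placement; layout is config-driven, never hard-coded."""

    stim_col: int = 11  # 1-based column of the stimulator (max lipid) control
    neut_col: int = 12  # 1-based column of the neutral (no induction) control


@dataclass
class PlateQC:
    z_prime: float
    robust_z_prime: float
    signal_to_background: float
    cv_stimulator: float  # %CV
    cv_neutral: float  # %CV
    n_stimulator: int
    n_neutral: int
    band: str = ""


def _check_groups(sample_values, negative_values):
    s = np.asarray(sample_values, dtype=float)
    n = np.asarray(negative_values, dtype=float)
    if s.size < 2 or n.size < 2:
        raise ValueError("need at least 2 values per control group")
    return s, n


def z_prime(sample_values, negative_values) -> float:
    """Z'-factor between a sample (stimulator) group and a negative control.

    Uses the absolute mean difference in the denominator so the statistic
    does not depend on which group is passed first.
    """
    s, n = _check_groups(sample_values, negative_values)
    denom = abs(s.mean() - n.mean())
    if denom == 0:
        raise ValueError("Z' undefined: control group means are equal (division by zero)")
    return float(1.0 - 3.0 * (s.std(ddof=1) + n.std(ddof=1)) / denom)


def robust_z_prime(sample_values, negative_values) -> float:
    """Z'-factor with medians and scaled MADs (1.4826 * MAD) for outlier resistance."""
    s, n = _check_groups(sample_values, negative_values)
    med_s, med_n = np.median(s), np.median(n)
    denom = abs(med_s - med_n)
    if denom == 0:
        raise ValueError("robust Z' undefined: control medians are equal")
    mad_s = 1.4826 * np.median(np.abs(s - med_s))
    mad_n = 1.4826 * np.median(np.abs(n - med_n))
    return float(1.0 - 3.0 * (mad_s + mad_n) / denom)


def z_prime_band(z: float) -> str:
    """Conventional assay-quality band for a Z' value."""
    if z >= 0.5:
        return "excellent"
    if z >= 0.0:
        return "suboptimal"
    return "unsuccessful"


def percent_inhibition(value, ave_pos, ave_neg) -> float:
    """Normalize a well value to percent inhibition.

    ``ave_pos`` is the fully-inhibited (neutral control) mean and ``ave_neg``
    the uninhibited (stimulator control) mean: a value at ``ave_neg`` is 0%
    and at ``ave_pos`` is 100%.
    """
    if ave_pos == ave_neg:
        raise ValueError("percent inhibition undefined: control means are equal")
    return float(100.0 * (np.asarray(value, dtype=float) - ave_neg) / (ave_pos - ave_neg))


def _control_values(plate: pd.DataFrame, layout: PlateLayout, column: str):
    stim = plate.loc[plate["col"] + 1 == layout.stim_col, column].to_numpy(dtype=float)
    neut = plate.loc[plate["col"] + 1 == layout.neut_col, column].to_numpy(dtype=float)
    if stim.size < 2:
        raise ValueError(f"missing stimulator control column {layout.stim_col}")
    if neut.size < 2:
        raise ValueError(f"missing neutral control column {layout.neut_col}")
    return stim, neut


def qc_plate(plate: pd.DataFrame, layout: PlateLayout | None = None) -> PlateQC:
    """Compute plate QC from the control wells of a well-summary table.

    ``plate`` is a well-summary DataFrame with at least columns
    (col, iss_mean); QC uses only the two control columns.
    """
    layout = layout or PlateLayout()
    stim, neut = _control_values(plate, layout, "iss_mean")
    z = z_prime(stim, neut)
    rz = robust_z_prime(stim, neut)
    sb = float(stim.mean() / neut.mean()) if neut.mean() != 0 else float("inf")
    cv_s = float(100.0 * stim.std(ddof=1) / stim.mean()) if stim.mean() else float("nan")
    cv_n = float(100.0 * neut.std(ddof=1) / neut.mean()) if neut.mean() else float("nan")
    return PlateQC(
        z_prime=z,
        robust_z_prime=rz,
        signal_to_background=sb,
        cv_stimulator=cv_s,
        cv_neutral=cv_n,
        n_stimulator=int(stim.size),
        n_neutral=int(neut.size),
        band=z_prime_band(z),
    )


@dataclass
class HitThresholds:
    """Hit/cytotoxicity cutoffs (percent scales).

    A hit requires ISS inhibition >= ``hit_iss`` and, when
    ``require_spot_inhibition`` is on, spot-count inhibition >=
    ``hit_spots``, with relative cell count > ``min_cells``. Wells at or
    below ``tox_cells`` relative cell count are cytotoxic regardless of
    inhibition.
    """

    hit_iss: float = 50.0
    hit_spots: float = 50.0
    require_spot_inhibition: bool = True
    min_cells: float = 60.0
    tox_cells: float = 40.0


@dataclass
class WellCall:
    well: str
    iss_inhibition: float
    spot_inhibition: float
    relative_cell_count: float
    call: str  # hit | cytotoxic | no-effect | control


def classify_well(
    iss_inhibition: float,
    spot_inhibition: float,
    relative_cell_count: float,
    thresholds: HitThresholds,
) -> str:
    """Pure threshold rule for one compound well; cytotoxic beats hit."""
    if relative_cell_count <= thresholds.tox_cells:
        return "cytotoxic"
    spot_ok = (
        spot_inhibition >= thresholds.hit_spots
        if thresholds.require_spot_inhibition
        else True
    )
    if (
        iss_inhibition >= thresholds.hit_iss
        and spot_ok
        and relative_cell_count > thresholds.min_cells
    ):
        return "hit"
    return "no-effect"


def call_wells(
    plate: pd.DataFrame,
    layout: PlateLayout | None = None,
    thresholds: HitThresholds | None = None,
) -> pd.DataFrame:
    """Call every well of a plate summary table.

    Returns a DataFrame with per-well percent inhibition of ISS and spot
    count, the relative valid cell count (% of the average over both control
    columns), and the call. Control wells are labeled ``control``.
    """
    layout = layout or PlateLayout()
    thresholds = thresholds or HitThresholds()
    stim_iss, neut_iss = _control_values(plate, layout, "iss_mean")
    stim_spots, neut_spots = _control_values(plate, layout, "spot_count_mean")
    stim_cells, neut_cells = _control_values(plate, layout, "valid_cell_count")
    ave_neg_iss, ave_pos_iss = stim_iss.mean(), neut_iss.mean()
    ave_neg_sp, ave_pos_sp = stim_spots.mean(), neut_spots.mean()
    control_cells = float(np.concatenate([stim_cells, neut_cells]).mean())

    rows = []
    for _, well in plate.iterrows():
        is_control = well["col"] + 1 in (layout.stim_col, layout.neut_col)
        iss_inh = percent_inhibition(well["iss_mean"], ave_pos_iss, ave_neg_iss)
        spot_inh = percent_inhibition(well["spot_count_mean"], ave_pos_sp, ave_neg_sp)
        rel_cells = 100.0 * well["valid_cell_count"] / control_cells
        call = (
            "control"
            if is_control
            else classify_well(iss_inh, spot_inh, rel_cells, thresholds)
        )
        rows.append(
            {
                "plate": well.get("plate", ""),
                "well": well["well"],
                "iss_inhibition": iss_inh,
                "spot_inhibition": spot_inh,
                "relative_cell_count": rel_cells,
                "call": call,
            }
        )
    return pd.DataFrame(rows)


def median_polish_correct(
    plate: pd.DataFrame, column: str = "iss_mean", n_iter: int = 2
) -> pd.DataFrame:
    """Optional per-row/per-column median-polish bias correction (off by default).

    A minimal hook for spatial plate artifacts: alternately removes row and
    column medians of the residual surface and returns a corrected copy.
    Control columns are included in the fit, which is only appropriate for
    roughly centered biases; full spatial-bias modeling is out of scope.
    """
    out = plate.copy()
    pivot = out.pivot_table(index="row", columns="col", values=column)
    resid = pivot - pivot.stack().median()
    for _ in range(n_iter):
        resid = resid.sub(resid.median(axis=1), axis=0)
        resid = resid.sub(resid.median(axis=0), axis=1)
    bias = pivot - resid - pivot.stack().median()
    correction = out.apply(lambda r: bias.loc[r["row"], r["col"]], axis=1)
    out[column] = out[column] - correction
    return out
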