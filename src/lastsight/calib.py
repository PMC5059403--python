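"""Single-date radiocarbon calibration against a gridded calibration curve.

A radiocarbon determination ``age ± err`` (conventional ¹⁴C years BP) is
converted to a posterior density over calendar age τ (cal BP) by evaluating

    p(τ) ∝ N(age; μ(τ), err² + σ(τ)²)

on a uniform 1-year calendar grid, where μ(τ) and σ(τ) are the calibration
curve's ¹⁴C age and its 1σ uncertainty, linearly interpolated between the
curve's knots.  This is the standard intercept-free probabilistic
calibration used by OxCal and friends, restricted to single dates (no
reservoir corrections, no phase models).

Summary conventions: the reported 95% interval is the *central* interval
(2.5th and 97.5th percentiles of cumulative mass), which is unique and easy
to verify, unlike the highest-posterior-density ranges printed by OxCal;
on wiggly curve segments the two can differ by more than the grid step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import CalibrationError, CurveFormatError, RecordValidationError
from .records import RecordSet, SightingRecord, _replace

__all__ = ["CalCurve", "CalPosterior", "read_curve", "calibrate", "calibrate_batch"]


@dataclass(frozen=True)
class CalCurve:
    """Gridded calibration curve: calendar age → ¹⁴C age ± curve error."""

    cal_bp: np.ndarray
    c14_age: np.ndarray
    c14_err: np.ndarray
    name: str = "synthetic"

    def __post_init__(self) -> None:
        for arr in (self.cal_bp, self.c14_age, self.c14_err):
            if len(arr) != len(self.cal_bp) or len(arr) < 2:
                raise CurveFormatError("curve arrays must have equal length >= 2")
        if not np.all(np.diff(self.cal_bp) > 0):
            raise CurveFormatError("cal_bp grid must be strictly monotone")
        if np.any(self.c14_err < 0):
            raise CurveFormatError("curve errors must be >= 0")


@dataclass(frozen=True)
class CalPosterior:
    """Calibration posterior on a uniform calendar grid, with summaries.

    ``lo95`` is the older bound of the central 95% interval and ``hi95``
    the younger one, so ``hi95 <= median <= lo95`` on the cal BP axis.
    """

    grid: np.ndarray
    density: np.ndarray
    mean: float
    sd: float
    median: float
    lo95: float
    hi95: float


def read_curve(path) -> CalCurve:
    """Read an IntCal-dialect ``.14c`` text file.

    Lines starting with ``#`` are comments; data rows are comma-separated
    ``cal BP, 14C age, error`` with any trailing columns ignored.  Row
    order in the file is conventionally cal BP descending; the returned
    curve is normalized to ascending cal BP.
    """
    cal, age, err = [], [], []
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 3:
                raise CurveFormatError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                cal.append(float(parts[0]))
                age.append(float(parts[1]))
                err.append(float(parts[2]))
            except ValueError as exc:
                raise CurveFormatError(f"{path}: line {lineno}: non-numeric cell") from exc
    if len(cal) < 2:
        raise CurveFormatError(f"{path}: fewer than 2 data rows")
    order = np.argsort(cal)
    return CalCurve(
        np.asarray(cal)[order],
        np.asarray(age)[order],
        np.asarray(err)[order],
        name=str(getattr(path, "name", path)),
    )


def calibrate(age: float, err: float, curve: CalCurve, grid_step: float = 1.0) -> CalPosterior:
    """Calibrate one determination; see the module docstring for the model."""
    if err <= 0:
        raise CalibrationError(f"measurement error must be > 0, got {err}")
    if grid_step <= 0:
        raise CalibrationError(f"grid_step must be > 0, got {grid_step}")
    grid = np.arange(curve.cal_bp[0], curve.cal_bp[-1] + 0.5 * grid_step, grid_step)
    mu = np.interp(grid, curve.cal_bp, curve.c14_age)
    sig = np.interp(grid, curve.cal_bp, curve.c14_err)
    var = err * err + sig * sig
    logd = -0.5 * (age - mu) ** 2 / var - 0.5 * np.log(2.0 * np.pi * var)
    total = logsumexp(logd)
    if total < np.log(1e-300):
        raise CalibrationError(
            f"date {age} ± {err} carries no posterior mass on curve {curve.name!r}"
        )
    density = np.exp(logd - total)
    mean = float(np.sum(grid * density))
    sd = float(np.sqrt(np.sum((grid - mean) ** 2 * density)))
    cdf = np.cumsum(density)
    cdf /= cdf[-1]

    def q(p: float) -> float:
        return float(np.interp(p, cdf, grid))

    return CalPosterior(
        grid=grid,
        density=density,
        mean=mean,
        sd=sd,
        median=q(0.5),
        lo95=q(0.975),
        hi95=q(0.025),
    )


def calibrate_batch(rs: RecordSet, curve: CalCurve, grid_step: float = 1.0) -> RecordSet:
    """Calibrate every record of ``rs``, filling the calibrated summary fields.

    Pre-existing calibrated fields are overwritten; the filter log records
    the curve used.  Every record must carry ``c14_age`` and ``c14_err``.
    """
    out: list[SightingRecord] = []
    for r in rs:
        if r.c14_age is None or r.c14_err is None:
            raise RecordValidationError(f"{r.lab_code}: cannot calibrate without c14_age/c14_err")
        try:
            post = calibrate(r.c14_age, r.c14_err, curve, grid_step=grid_step)
        except CalibrationError as exc:
            raise CalibrationError(f"{r.lab_code}: {exc}") from exc
        out.append(
            _replace(
                r,
                cal_mean=post.mean,
                cal_sd=post.sd,
                cal_median=post.median,
                cal_lo95=post.lo95,
                cal_hi95=post.hi95,
            )
        )
    return rs._derive(out, f"CALIBRATE curve={curve.name} n={len(out)}")
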