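"""Image-quality and SUV-based evaluation.

Whole-image measures: NRMSE (percent), SSIM, PSNR (dB).  VOI measures:
SUV_mean and SUV_max within each lesion mask, and their signed relative
error (percent) against a reference reconstruction.  ``evaluate_run``
assembles these into the bias +/- s.d. report layout used to compare
recovery methods across lesion sizes, activities and dose levels.

SUV = r / (a'/w): activity concentration r (kBq/ml) normalized by
decay-corrected injected activity a' (kBq) per patient weight w (g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .core_io import PETVolume, ScanMeta, VOIMask

#: Finite stand-in reported when the mean squared error vanishes (identical
#: images have unbounded PSNR).
PSNR_SENTINEL_DB = 999.99


def nrmse(x: np.ndarray, y: np.ndarray) -> float:
    """100 * sqrt( sum((x-y)^2) / sum(y^2) ), y the reference."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("shapes must match")
    denom = float((y**2).sum())
    if denom == 0:
        raise ValueError("all-zero reference")
    return float(100.0 * np.sqrt(((x - y) ** 2).sum() / denom))


def psnr(x: np.ndarray, y: np.ndarray, paper_formula: bool = False) -> float:
    """Peak signal-to-noise ratio in dB with MAX = peak of the reference.

    The default is the standard 10*log10(MAX^2/MSE).  ``paper_formula``
    switches to the literal 20*log10(MAX/MSE) variant some reports print.
    """
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("shapes must match")
    mse = float(((x - y) ** 2).mean())
    if mse == 0:
        return PSNR_SENTINEL_DB
    peak = float(y.max())
    if paper_formula:
        return float(20.0 * np.log10(peak / mse))
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    data_range: float | None = None,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Mean structural similarity with an 11x11 Gaussian window (sigma 1.5).

    Constants C1=(0.01 L)^2, C2=(0.03 L)^2 with L the reference dynamic
    range unless ``data_range`` is given.  Symmetric in x and y up to the
    shared data range.
    """
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("shapes must match")
    if min(x.shape) < win_size:
        raise ValueError("window exceeds image")
    if data_range is None:
        rng = float(y.max() - y.min())
        data_range = rng if rng > 0 else 1.0
    return float(
        structural_similarity(
            x,
            y,
            win_size=win_size,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def suv(r, meta: ScanMeta):
    """Standardized uptake value r / (a'/w); elementwise on arrays."""
    return np.asarray(r, dtype=np.float64) / (
        meta.injected_activity_kbq / meta.patient_weight_g
    )


def suv_stats(vol: PETVolume, mask: VOIMask, meta: ScanMeta) -> tuple[float, float]:
    """(SUV_mean, SUV_max) of the voxelwise SUV map restricted to the VOI."""
    mask.check_against(vol)
    vals = suv(vol.values[mask.mask], meta)
    return float(vals.mean()), float(vals.max())


def relative_error(model_suv: float, ref_suv: float) -> float:
    """Signed percent error 100 * (model - ref) / ref."""
    if ref_suv == 0:
        raise ValueError("zero reference SUV")
    return float(100.0 * (model_suv - ref_suv) / ref_suv)


@dataclass
class EvalReport:
    """Per-VOI SUV errors plus whole-volume image-quality measures.

    ``voi_table`` has one row per (VOI, method) with SUV_mean/SUV_max and
    their relative errors against the full-dose reference (``re_mean``,
    ``re_max``) and against the noise-free truth when available
    (``re_mean_truth``, ``re_max_truth``).  ``volume_table`` holds
    NRMSE/SSIM/PSNR of each method against the full-dose reference.
    """

    voi_table: pd.DataFrame
    volume_table: pd.DataFrame

    def aggregate(self, by=("method",), value="re_mean") -> pd.DataFrame:
        """bias +/- sample s.d. of a relative-error column per group."""
        g = self.voi_table.groupby(list(by))[value]
        out = g.agg(bias="mean", sd=lambda s: s.std(ddof=1), n="count")
        return out.reset_index()


def evaluate_run(
    recovered: PETVolume,
    ld: PETVolume,
    fd: PETVolume,
    truth: PETVolume | None,
    masks: list[VOIMask],
    meta: ScanMeta,
    grouping: dict | None = None,
) -> EvalReport:
    """Score recovered and low-dose volumes against the full-dose reference.

    Relative errors use the full-dose reconstruction as reference (the
    clinically observable quantity); when a truth volume is supplied,
    truth-referenced errors are reported alongside — a simulator-only
    extra.  ``grouping`` values (e.g. dose level, activity) are copied into
    every row for downstream aggregation.
    """
    methods = {"recovered": recovered, "low_dose": ld}
    for name, v in methods.items():
        if v.shape != fd.shape:
            raise ValueError(f"{name} volume misaligned with reference")
    rows = []
    extra = grouping or {}
    for m in masks:
        ref_mean, ref_max = suv_stats(fd, m, meta)
        truth_stats = suv_stats(truth, m, meta) if truth is not None else None
        for name, v in methods.items():
            s_mean, s_max = suv_stats(v, m, meta)
            row = dict(
                voi=m.label,
                method=name,
                suv_mean=s_mean,
                suv_max=s_max,
                re_mean=relative_error(s_mean, ref_mean),
                re_max=relative_error(s_max, ref_max),
                **extra,
            )
            if truth_stats is not None:
                row["re_mean_truth"] = relative_error(s_mean, truth_stats[0])
                row["re_max_truth"] = relative_error(s_max, truth_stats[1])
            rows.append(row)
    vol_rows = []
    for name, v in methods.items():
        vol_rows.append(
            dict(
                method=name,
                nrmse=nrmse(v.values, fd.values),
                ssim=_ssim_volume(v.values, fd.values),
                psnr=psnr(v.values, fd.values),
                **extra,
            )
        )
    return EvalReport(pd.DataFrame(rows), pd.DataFrame(vol_rows))


def _ssim_volume(x: np.ndarray, y: np.ndarray) -> float:
    """Mean slice-wise SSIM over transverse slices (win shrunk if needed)."""
    win = min(11, x.shape[0] - (x.shape[0] + 1) % 2, y.shape[1])
    if win % 2 == 0:
        win -= 1
    rng = float(y.max() - y.min()) or 1.0
    vals = [
        structural_similarity(
            x[:, :, z],
            y[:, :, z],
            win_size=win,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=rng,
        )
        for z in range(x.shape[2])
    ]
    return float(np.mean(vals))
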