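"""Map-quality metrics: RMSE, MSE and PSNR over masked voxels.

RMSE = sqrt(sum_i (s_hat_i - s_i)^2 / N) over the N voxels inside the brain
mask; MSE is its square; PSNR = 10 log10(s_MAX^2 / MSE) in dB with s_MAX the
maximum of the ground-truth map inside the mask (using the truth map makes
PSNR directly comparable between estimation methods). A perfect estimate
has MSE = 0 and PSNR reported as +infinity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dki import ScalarMaps

__all__ = ["rmse", "mse", "psnr", "EvalReport", "evaluate_maps", "compare_methods"]

_SCALARS = ("FA", "MD", "MK", "KFA")


def _check(estimate, truth, mask):
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if estimate.shape != truth.shape or estimate.shape != mask.shape:
        raise ValueError("estimate, truth and mask shapes must match")
    if not np.any(mask):
        raise ValueError("mask is empty")
    return estimate[mask], truth[mask]


def mse(estimate, truth, mask) -> float:
    e, t = _check(estimate, truth, mask)
    return float(np.mean((e - t) ** 2))


def rmse(estimate, truth, mask) -> float:
    return float(np.sqrt(mse(estimate, truth, mask)))


def psnr(estimate, truth, mask) -> float:
    e, t = _check(estimate, truth, mask)
    if np.all(t == 0):
        raise ValueError("ground-truth map is all-zero inside the mask")
    m = float(np.mean((e - t) ** 2))
    s_max = float(np.max(np.abs(t)))
    if m == 0.0:
        return float("inf")
    return float(10.0 * np.log10(s_max ** 2 / m))


@dataclass
class EvalReport:
    """Per-scalar RMSE / MSE / PSNR for one estimation method."""

    method: str
    n_voxels: int
    metrics: dict = field(default_factory=dict)  # scalar -> {rmse, mse, psnr, s_max}

    def to_json(self) -> str:
        def _null_safe(v):
            return None if isinstance(v, float) and np.isinf(v) else v
        payload = {
            "method": self.method,
            "n_voxels": self.n_voxels,
            "metrics": {k: {kk: _null_safe(vv) for kk, vv in v.items()}
                        for k, v in self.metrics.items()},
        }
        return json.dumps(payload, indent=2)


def evaluate_maps(estimate: ScalarMaps, truth: ScalarMaps,
                  mask: np.ndarray | None = None) -> EvalReport:
    """Score one method's maps against the reference maps."""
    mask = truth.mask if mask is None else np.asarray(mask, dtype=bool)
    report = EvalReport(method=estimate.method, n_voxels=int(mask.sum()))
    for name in _SCALARS:
        e, t = estimate[name], truth[name]
        report.metrics[name] = {
            "rmse": rmse(e, t, mask),
            "mse": mse(e, t, mask),
            "psnr": psnr(e, t, mask),
            "s_max": float(np.max(np.abs(t[mask]))),
        }
    return report


def compare_methods(cnn_maps: ScalarMaps, modelfit_maps: ScalarMaps,
                    truth: ScalarMaps, mask: np.ndarray | None = None) -> dict:
    """Head-to-head comparison of the two estimation routes.

    Returns both EvalReports plus a per-scalar winner table (the method with
    the lower RMSE; exact ties are flagged as "tie").
    """
    mask = truth.mask if mask is None else np.asarray(mask, dtype=bool)
    rep_cnn = evaluate_maps(cnn_maps, truth, mask)
    rep_fit = evaluate_maps(modelfit_maps, truth, mask)
    winners = {}
    for name in _SCALARS:
        a = rep_cnn.metrics[name]["rmse"]
        b = rep_fit.metrics[name]["rmse"]
        winners[name] = "tie" if a == b else (
            rep_cnn.method if a < b else rep_fit.method)
    return {"cnn": rep_cnn, "model-fit": rep_fit, "lower_rmse": winners}


def report_to_tsv(report: dict, path) -> None:
    """Serialize a compare_methods result as a small TSV table."""
    lines = ["scalar\tmethod\trmse\tmse\tpsnr\tlower_rmse"]
    for name in _SCALARS:
        for key in ("cnn", "model-fit"):
            m = report[key].metrics[name]
            p = "inf" if np.isinf(m["psnr"]) else f"{m['psnr']:.4f}"
            lines.append(f"{name}\t{report[key].method}\t{m['rmse']:.6g}"
                         f"\t{m['mse']:.6g}\t{p}\t{report['lower_rmse'][name]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
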