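"""Pixel-level real-vs-synthetic agreement metrics: MAE, MSE, PSNR.

PSNR = 10*log10(MAX^2 / MSE) in dB, where MAX is the largest pixel value
over BOTH evaluated images, so all three metrics are symmetric in their
two arguments.  Metrics run on whole images by default; an optional binary
mask restricts them to the brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FidelityResult", "fidelity", "summarize_fidelity"]


@dataclass
class FidelityResult:
    mae: float
    mse: float
    psnr: float  # +inf iff mse == 0
    n: int
    max_value: float


def fidelity(
    real: np.ndarray, synthetic: np.ndarray, mask: np.ndarray | None = None
) -> FidelityResult:
    """MAE, MSE and PSNR between two aligned images."""
    real = np.asarray(real, dtype=float)
    synthetic = np.asarray(synthetic, dtype=float)
    if real.shape != synthetic.shape:
        raise ValueError(f"shape mismatch: {real.shape} vs {synthetic.shape}")
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        if m.shape != real.shape:
            raise ValueError("mask shape mismatch")
        if not m.any():
            raise ValueError("empty mask")
        a, b = real[m], synthetic[m]
    else:
        a, b = real.ravel(), synthetic.ravel()
    n = a.size
    diff = a - b
    mae = float(np.abs(diff).mean())
    mse = float((diff**2).mean())
    max_value = float(max(a.max(), b.max()))
    if max_value <= 0 and mse == 0:
        raise ValueError("both images identically zero: MAX undefined")
    psnr = float("inf") if mse == 0 else float(10.0 * np.log10(max_value**2 / mse))
    return FidelityResult(mae=mae, mse=mse, psnr=psnr, n=n, max_value=max_value)


def summarize_fidelity(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    masks: list[np.ndarray] | None = None,
) -> dict[str, float]:
    """Mean and population SD of each metric across pairs.

    Pairs with infinite PSNR are excluded from the PSNR moments and counted
    in ``n_psnr_inf``.
    """
    if not pairs:
        raise ValueError("empty pair list")
    results = [
        fidelity(r, s, None if masks is None else masks[k])
        for k, (r, s) in enumerate(pairs)
    ]
    mae = np.array([x.mae for x in results])
    mse = np.array([x.mse for x in results])
    psnr = np.array([x.psnr for x in results])
    finite = np.isfinite(psnr)
    out = {
        "mae_mean": float(mae.mean()), "mae_sd": float(mae.std()),
        "mse_mean": float(mse.mean()), "mse_sd": float(mse.std()),
        "n_pairs": len(results), "n_psnr_inf": int((~finite).sum()),
    }
    if finite.any():
        out["psnr_mean"] = float(psnr[finite].mean())
        out["psnr_sd"] = float(psnr[finite].std())
    else:
        out["psnr_mean"] = float("inf")
        out["psnr_sd"] = float("nan")
    return out
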