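"""Composite training objective: MSE + SSIM terms on the full volume and on
the target-region crop.

The structural similarity index is computed with a sliding 2D Gaussian
window (size 11, sigma 1.5) applied to every axial slice of the volume and
averaged over all window positions and slices (the mean SSIM).  The loss is
``1 - MSSIM``; the composite objective weights the two SSIM terms by 2:

    total = MSE(full) + MSE(roi) + 2 * (SSIMloss(full) + SSIMloss(roi))

Stability constants follow the standard convention C1 = (0.01 L)^2,
C2 = (0.03 L)^2 with dynamic range L = 1 on max-normalized volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor


@dataclass(frozen=True)
class SSIMParams:
    window_size: int = 11
    sigma: float = 1.5
    c1: float = 0.01**2
    c2: float = 0.03**2

    def window(self, dtype=np.float64) -> np.ndarray:
        """Normalized 2D Gaussian window as a (1,1,1,k,k) convolution kernel."""
        k = self.window_size
        g = self.window_1d(dtype)
        w2 = np.outer(g, g)
        return w2.reshape(1, 1, 1, k, k).astype(dtype)

    def window_1d(self, dtype=np.float64) -> np.ndarray:
        """Normalized 1D Gaussian factor (the 2D window is separable)."""
        ax = np.arange(self.window_size) - (self.window_size - 1) / 2.0
        g = np.exp(-(ax**2) / (2.0 * self.sigma**2))
        return (g / g.sum()).astype(dtype)


def _as5d(x: Tensor) -> Tensor:
    """Coerce (D,H,W) / (N,D,H,W) volumes to (N,1,D,H,W)."""
    if len(x.shape) == 3:
        return ag.reshape(x, (1, 1) + tuple(x.shape))
    if len(x.shape) == 4:
        return ag.reshape(x, (x.shape[0], 1) + tuple(x.shape[1:]))
    return x


def local_ssim(patch_r: np.ndarray, patch_t: np.ndarray,
               params: SSIMParams = SSIMParams()) -> float:
    """SSIM of two equally-shaped patches with uniform (unweighted) statistics.

    Uses biased (1/N) variances; the result lies in [-1, 1], reaching 1 only
    for identical patches.
    """
    a = np.asarray(patch_r, dtype=float)
    b = np.asarray(patch_t, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patches must share a shape")
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    c1, c2 = params.c1, params.c2
    return float((2 * mu_a * mu_b + c1) * (2 * cov + c2)
                 / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2)))


def _mssim_graph(xr: Tensor, xt: Tensor, params: SSIMParams) -> Tensor:
    xr, xt = _as5d(xr), _as5d(xt)
    if xr.shape != xt.shape:
        raise ValueError(f"shape mismatch {xr.shape} vs {xt.shape}")
    if xr.shape[3] < params.window_size or xr.shape[4] < params.window_size:
        raise ValueError(
            f"slices {xr.shape[3:]} smaller than the {params.window_size}-pixel window")
    # the Gaussian window is separable: two 1D passes cost 2k taps, not k^2
    k = params.window_size
    g1 = params.window_1d(xr.data.dtype)
    wv = Tensor(g1.reshape(1, 1, 1, k, 1))
    wh = Tensor(g1.reshape(1, 1, 1, 1, k))

    def wconv(t: Tensor) -> Tensor:
        # valid windows only: every patch lies fully inside a slice
        return ag.conv3d(ag.conv3d(t, wv, None, pad=(0, 0, 0)), wh, None,
                         pad=(0, 0, 0))

    mu_r = wconv(xr)
    mu_t = wconv(xt)
    mu_r2 = mu_r * mu_r
    mu_t2 = mu_t * mu_t
    mu_rt = mu_r * mu_t
    var_r = wconv(xr * xr) - mu_r2
    var_t = wconv(xt * xt) - mu_t2
    cov = wconv(xr * xt) - mu_rt
    c1, c2 = params.c1, params.c2
    ssim_map = ((2.0 * mu_rt + c1) * (2.0 * cov + c2)) \
        * ((mu_r2 + mu_t2 + c1) * (var_r + var_t + c2)) ** -1.0
    return ag.mean(ssim_map)


def mssim(xr, xt, params: SSIMParams = SSIMParams()):
    """Mean SSIM over all Gaussian-window positions on every axial slice.

    Accepts arrays or Tensors; returns a float for array inputs and a graph
    Tensor for Tensor inputs.
    """
    tensor_in = isinstance(xr, Tensor) or isinstance(xt, Tensor)
    out = _mssim_graph(as_tensor(xr), as_tensor(xt), params)
    return out if tensor_in else float(out.data)


def ssim_loss(xr, xt, params: SSIMParams = SSIMParams()):
    """1 - MSSIM; lies in [0, 2] and vanishes iff MSSIM = 1."""
    out = 1.0 - _mssim_graph(as_tensor(xr), as_tensor(xt), params)
    tensor_in = isinstance(xr, Tensor) or isinstance(xt, Tensor)
    return out if tensor_in else float(out.data)


def mse_loss(xr, xt):
    """Mean squared difference."""
    r = as_tensor(xr) - as_tensor(xt)
    out = ag.mean(r * r)
    tensor_in = isinstance(xr, Tensor) or isinstance(xt, Tensor)
    return out if tensor_in else float(out.data)


@dataclass
class LossComponents:
    """Decomposed composite objective; ``total`` recombines the parts as
    mse_full + mse_roi + 2 (ssim_loss_full + ssim_loss_roi)."""

    mse_full: float
    mse_roi: float
    ssim_loss_full: float
    ssim_loss_roi: float
    total: float


def roi_bounding_box(roi_mask: np.ndarray,
                     min_hw: int = 11) -> tuple[slice, slice, slice]:
    """Bounding-box slices of a nonempty mask, grown in-plane to at least
    ``min_hw`` pixels so the SSIM window fits."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    out = []
    for axis, min_size in zip(range(3), (1, min_hw, min_hw)):
        proj = roi_mask.any(axis=tuple(i for i in range(3) if i != axis))
        lo, hi = np.flatnonzero(proj)[[0, -1]]
        hi += 1
        n = roi_mask.shape[axis]
        while hi - lo < min(min_size, n):
            if lo > 0:
                lo -= 1
            if hi < n and hi - lo < min_size:
                hi += 1
        out.append(slice(int(lo), int(hi)))
    return tuple(out)


def composite_loss_graph(xr: Tensor, xt: Tensor, roi_mask: np.ndarray,
                         params: SSIMParams = SSIMParams()) -> dict[str, Tensor]:
    """Tensor-valued loss terms for one (D,H,W) sample (training path)."""
    bz, by, bx = roi_bounding_box(roi_mask, params.window_size)
    xr5, xt5 = _as5d(xr), _as5d(xt)
    xr_roi = xr5[:, :, bz, by, bx]
    xt_roi = xt5[:, :, bz, by, bx]
    terms = {
        "mse_full": mse_loss(xr5, xt5),
        "mse_roi": mse_loss(xr_roi, xt_roi),
        "ssim_loss_full": ssim_loss(xr5, xt5, params),
        "ssim_loss_roi": ssim_loss(xr_roi, xt_roi, params),
    }
    terms["total"] = (terms["mse_full"] + terms["mse_roi"]
                      + 2.0 * (terms["ssim_loss_full"] + terms["ssim_loss_roi"]))
    return terms


def composite_loss(xr: np.ndarray, xt: np.ndarray, roi_mask: np.ndarray,
                   params: SSIMParams = SSIMParams()) -> LossComponents:
    """Composite objective of a reconstruction against its ground truth."""
    terms = composite_loss_graph(as_tensor(np.asarray(xr, dtype=float)),
                                 as_tensor(np.asarray(xt, dtype=float)),
                                 roi_mask, params)
    return LossComponents(**{k: float(v.data) for k, v in terms.items()})


def composite_gradient(xr: np.ndarray, xt: np.ndarray, roi_mask: np.ndarray,
                       params: SSIMParams = SSIMParams()) -> np.ndarray:
    """Analytic gradient of the composite total w.r.t. the reconstruction."""
    xr_t = Tensor(np.asarray(xr, dtype=float), requires_grad=True)
    terms = composite_loss_graph(xr_t, as_tensor(np.asarray(xt, dtype=float)),
                                 roi_mask, params)
    terms["total"].backward()
    return xr_t.grad.reshape(np.asarray(xr).shape)
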