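"""Masked RMSE: the training loss of both surrogates.

Only entries inside the aorta (the validity mask) contribute; values at
padded positions are ignored entirely, so the loss is invariant to whatever
the network emits there.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError


def _expand_mask(mask: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape == shape:
        return mask
    if mask.shape == shape[:-1]:
        return np.broadcast_to(mask[..., None], shape)
    raise ParameterError(
        f"mask shape {mask.shape} incompatible with predictions {shape}"
    )


def masked_rmse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """RMSE over valid entries only.

    ``mask`` may either match ``pred`` exactly or omit the trailing channel
    axis (one flag per point, applied to every channel).
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ParameterError("pred and target shapes must agree")
    m = _expand_mask(mask, pred.shape)
    n = int(m.sum())
    if n == 0:
        raise ParameterError("mask selects no valid entries; loss undefined")
    diff = (pred - target)[m]
    return float(np.sqrt(np.mean(diff**2)))


def masked_rmse_grad(
    pred: np.ndarray, target: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to ``pred``."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    m = _expand_mask(mask, pred.shape)
    n = int(m.sum())
    if n == 0:
        raise ParameterError("mask selects no valid entries; loss undefined")
    diff = np.where(m, pred - target, 0.0)
    loss = float(np.sqrt(np.sum(diff**2) / n))
    if loss == 0.0:
        return 0.0, np.zeros_like(diff)
    grad = diff / (n * loss)
    return loss, grad.astype(pred.dtype)
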