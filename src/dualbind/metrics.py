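"""Regression metrics and pK_D / binding free-energy conversions.

pK_D = -log10(K_D) with K_D in molar units; the Gibbs free energy of binding
follows ΔG = 2.303·R·T·log10(K_D) = -2.303·R·T·pK_D with
R = 1.987e-3 kcal/(mol·K), so tighter binding (higher pK_D) is more negative
ΔG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GAS_CONSTANT_KCAL = 1.987e-3   # kcal / (mol K)
LN10_FACTOR = 2.303


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs (zero variance)."""


@dataclass(frozen=True)
class EvalReport:
    """Evaluation summary: MAE, RMSE, coefficient of determination, Pearson r."""

    mae: float
    rmse: float
    r2: float
    pcc: float
    n: int

    def __post_init__(self) -> None:
        if self.mae > self.rmse + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2,
                "pcc": self.pcc, "n": self.n}


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error (1/N) * sum (pred - target)^2."""
    pred = np.asarray(pred, dtype=np.float64).reshape(-1)
    target = np.asarray(target, dtype=np.float64).reshape(-1)
    if pred.size == 0 or target.size == 0:
        raise ValueError("mse_loss requires non-empty inputs")
    if pred.shape != target.shape:
        raise ValueError(f"length mismatch: {pred.size} vs {target.size}")
    return float(np.mean((pred - target) ** 2))


def mae(pred: np.ndarray, target: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=np.float64).reshape(-1)
    target = np.asarray(target, dtype=np.float64).reshape(-1)
    return float(np.mean(np.abs(pred - target)))


def r2(pred: np.ndarray, target: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    pred = np.asarray(pred, dtype=np.float64).reshape(-1)
    target = np.asarray(target, dtype=np.float64).reshape(-1)
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("r2 undefined: targets have zero variance")
    ss_res = float(np.sum((target - pred) ** 2))
    return 1.0 - ss_res / ss_tot

def pcc(pred: np.ndarray, target: np.ndarray) -> float:
    """Pearson correlation coefficient."""
    pred = np.asarray(pred, dtype=np.float64).reshape(-1)
    target = np.asarray(target, dtype=np.float64).reshape(-1)
    if np.var(pred) == 0.0:
        raise UndefinedMetricError("pcc undefined: predictions have zero variance")
    if np.var(target) == 0.0:
        raise UndefinedMetricError("pcc undefined: targets have zero variance")
    dp, dt = pred - pred.mean(), target - target.mean()
    return float(np.sum(dp * dt) / np.sqrt(np.sum(dp**2) * np.sum(dt**2)))


def evaluate(preds: np.ndarray, targets: np.ndarray) -> EvalReport:
    """Full evaluation report; requires N >= 2 and nondegenerate variances."""
    preds = np.asarray(preds, dtype=np.float64).reshape(-1)
    targets = np.asarray(targets, dtype=np.float64).reshape(-1)
    if preds.shape != targets.shape:
        raise ValueError(f"length mismatch: {preds.size} vs {targets.size}")
    if preds.size < 2:
        raise ValueError("evaluate requires at least 2 pairs")
    return EvalReport(
        mae=mae(preds, targets),
        rmse=float(np.sqrt(mse_loss(preds, targets))),
        r2=r2(preds, targets),
        pcc=pcc(preds, targets),
        n=int(preds.size),
    )


def pkd_to_dg(pkd: float, temperature_k: float = 298.0) -> float:
    """Binding free energy (kcal/mol) from pK_D at a given temperature."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return -LN10_FACTOR * GAS_CONSTANT_KCAL * temperature_k * pkd


def dg_to_pkd(dg_kcal_mol: float, temperature_k: float = 298.0) -> float:
    """Inverse conversion; round-trips with :func:`pkd_to_dg` to 1e-9."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return -dg_kcal_mol / (LN10_FACTOR * GAS_CONSTANT_KCAL * temperature_k)
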