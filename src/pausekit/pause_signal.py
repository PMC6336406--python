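"""Multipartite pause-signal analysis.

The elemental pause signal has four elements — the upstream fork junction
(usFJ), the RNA–DNA hybrid (Hyb), the downstream fork junction (dsFJ) and
the downstream duplex DNA (dsDNA).  Substituting an element reduces pause
strength (PS = efficiency × lifetime of the major pause species) by some
factor; if the elements independently contribute to a single free-energy
barrier to pause escape, their effects on ΔG‡ are additive and therefore
multiplicative in PS.  This module computes per-element reduction factors,
the multiplicative prediction for combinations with a 95% confidence
bracket, and the additivity verdict, plus correlation summaries across a
panel of signal variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import prod

import numpy as np
import pandas as pd

from .fitting import PauseMetrics

__all__ = [
    "ELEMENTS",
    "ElementEffect",
    "CombinedPrediction",
    "AdditivityVerdict",
    "reduction_factor",
    "predict_combined",
    "additivity_test",
    "metric_correlations",
    "round_sig",
]

ELEMENTS = ("usFJ", "Hyb", "dsFJ", "dsDNA")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, sig - 1 - int(np.floor(np.log10(abs(x))))))


def _check_label(label: str) -> None:
    for part in label.split("+"):
        if part not in ELEMENTS:
            raise ValueError(
                f"unknown pause-signal element {part!r}; expected one of "
                f"{ELEMENTS} (combinations joined with '+')"
            )


@dataclass
class ElementEffect:
    """PS reduction factor of one signal element (or a '+'-combination).

    ``factor = PS(reference) / PS(variant)`` is > 0 and dimensionless;
    ``se`` is its standard error (``log_se`` the SE of its logarithm,
    which is what error propagation uses).
    """

    label: str
    factor: float
    se: float = 0.0

    def __post_init__(self) -> None:
        _check_label(self.label)
        if self.factor <= 0:
            raise ValueError("reduction factor must be positive")
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")

    @property
    def log_se(self) -> float:
        return self.se / self.factor


@dataclass
class CombinedPrediction:
    """Multiplicative prediction for a combination of elements."""

    label: str
    factor: float
    ci95: tuple[float, float]
    se_log: float
    method: str

    @property
    def factor_2sig(self) -> float:
        return round_sig(self.factor, 2)


@dataclass
class AdditivityVerdict:
    label: str
    predicted: float
    observed: float
    ci95: tuple[float, float]
    additive: bool
    log_ratio: float


def reduction_factor(
    reference: PauseMetrics,
    variant: PauseMetrics,
    label: str,
) -> ElementEffect:
    """PS reduction of a signal variant relative to the consensus.

    The factor's standard error is propagated from the two fits' PS
    uncertainties on the log scale (independent fits assumed).
    """
    if variant.PS <= 0:
        raise ValueError("variant pause strength must be positive")
    if reference.PS <= 0:
        raise ValueError("reference pause strength must be positive")
    factor = reference.PS / variant.PS
    rel_var = (reference.PS_se / reference.PS) ** 2 + (variant.PS_se / variant.PS) ** 2
    return ElementEffect(label=label, factor=factor, se=factor * np.sqrt(rel_var))


def predict_combined(
    effects: list[ElementEffect],
    method: str = "delta",
    n_boot: int = 10_000,
    seed: int = 0,
) -> CombinedPrediction:
    """Multiplicative (energy-additive) prediction for combined elements.

    The point prediction is the product of the single-element factors.
    The 95% CI comes from first-order propagation on log-factors
    (``method="delta"``) or from a parametric lognormal bootstrap
    (``method="bootstrap"``); the method used is named in the output.
    """
    if len(effects) < 2:
        raise ValueError("need at least two single-element effects")
    labels = [e.label for e in effects]
    if len(set(labels)) != len(labels):
        raise ValueError(f"combination label collision in {labels}")
    label = "+".join(labels)
    factor = prod(e.factor for e in effects)
    var_log = sum(e.log_se**2 for e in effects)
    se_log = float(np.sqrt(var_log))
    if method == "delta":
        ci = (factor * np.exp(-1.96 * se_log), factor * np.exp(1.96 * se_log))
    elif method == "bootstrap":
        rng = np.random.Generator(np.random.Philox(seed))
        draws = np.ones(n_boot)
        for e in effects:
            draws = draws * np.exp(rng.normal(np.log(e.factor), e.log_se, n_boot))
        ci = tuple(np.quantile(draws, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return CombinedPrediction(
        label=label, factor=float(factor),
        ci95=(float(ci[0]), float(ci[1])), se_log=se_log, method=method,
    )


def additivity_test(
    predicted: CombinedPrediction,
    observed: ElementEffect,
) -> AdditivityVerdict:
    """Is the observed combined reduction consistent with additivity?

    Additive (multiplicative-in-PS) means the observed factor falls within
    the predicted 95% bracket; the log-ratio quantifies the discrepancy.
    """
    if set(predicted.label.split("+")) != set(observed.label.split("+")):
        raise ValueError(
            f"label mismatch: predicted {predicted.label!r} vs "
            f"observed {observed.label!r}"
        )
    lo, hi = predicted.ci95
    return AdditivityVerdict(
        label=predicted.label,
        predicted=predicted.factor,
        observed=observed.factor,
        ci95=predicted.ci95,
        additive=bool(lo <= observed.factor <= hi),
        log_ratio=float(np.log(observed.factor / predicted.factor)),
    )


def metric_correlations(
    metrics: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise Pearson correlations across a panel of signal variants.

    ``metrics`` has one row per variant and numeric columns such as
    ``tau_major``, ``tau_minor``, ``E_a``, ``E_b``, ``E``, ``k_sp_app``.
    P-values come from a seeded permutation null.  Raises on constant
    columns (correlation undefined).
    """
    cols = [c for c in metrics.columns if np.issubdtype(metrics[c].dtype, np.number)]
    if len(metrics) < 4:
        raise ValueError("need at least 4 variants for correlation analysis")
    for c in cols:
        if np.ptp(metrics[c].to_numpy()) == 0:
            raise ValueError(f"column {c!r} is constant; correlation undefined")
    rng = np.random.Generator(np.random.Philox(seed))
    rows = []
    for x, y in combinations(cols, 2):
        xv = metrics[x].to_numpy(dtype=float)
        yv = metrics[y].to_numpy(dtype=float)
        r = float(np.corrcoef(xv, yv)[0, 1])
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = np.corrcoef(xv, rng.permutation(yv))[0, 1]
        p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_permutations + 1))
        rows.append({"x": x, "y": y, "r": r, "p_perm": p})
    return pd.DataFrame(rows)
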