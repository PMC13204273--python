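"""Analytic utilities for the drug-screen layer.

Converts docking affinities to dissociation constants via
``delta G = R T ln Kd``, applies the -7.0 kcal/mol retention filter,
derives consensus blood-brain-barrier classes from per-tool permeability
predictions, and maps conformational population densities to a free-energy
landscape via ``delta G = -k_B T ln(P / Pmax)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL",
    "KB_KJ",
    "delta_g_to_kd",
    "kd_to_delta_g",
    "affinity_filter",
    "bbb_classify",
    "bbb_classify_table",
    "fel_transform",
]

#: gas constant, kcal mol^-1 K^-1 (conventional thermochemical value)
R_KCAL = 1.987e-3
#: gas constant on the molar energy scale, kJ mol^-1 K^-1
KB_KJ = 8.314e-3

AFFINITY_CUTOFF = -7.0


def delta_g_to_kd(delta_g: float, temperature: float = 298.0) -> float:
    """Dissociation constant (molar) from a binding free energy in kcal/mol.

    ``Kd = exp(delta_g / (R T))``; -7.0 kcal/mol at 298 K gives ~7.3 uM.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return float(np.exp(delta_g / (R_KCAL * temperature)))


def kd_to_delta_g(kd: float, temperature: float = 298.0) -> float:
    """Inverse of :func:`delta_g_to_kd` (kcal/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return float(R_KCAL * temperature * np.log(kd))


def affinity_filter(
    records: pd.DataFrame,
    cutoff: float = AFFINITY_CUTOFF,
    column: str = "affinity_kcal_mol",
) -> pd.DataFrame:
    """Retain rows with predicted affinity <= cutoff (inclusive)."""
    return records[records[column] <= cutoff]


def _tool_class(permeant: bool, logbb: float) -> str:
    # precedence: High, then Medium, then Low (the Medium disjunction
    # overlaps High's conjunction, so High is evaluated first)
    if permeant and logbb > 0.3:
        return "High"
    if permeant or logbb > 0.3 or (-1.0 <= logbb <= 0.3):
        return "Medium"
    return "Low"


def bbb_classify(permeant_flags, logbb_values) -> str:
    """Consensus blood-brain-barrier class across three predictor tools.

    Each tool votes High (permeant and logBB > 0.3), Medium (either
    criterion met, or -1 <= logBB <= 0.3) or Low (non-permeant and
    logBB < -1); a unanimous vote gives that class, any disagreement gives
    ``"uncertain"``. Order of tools does not matter.
    """
    flags = list(permeant_flags)
    logbb = list(logbb_values)
    if len(flags) != 3 or len(logbb) != 3:
        raise ValueError("exactly 3 per-tool predictions required")
    if any(f is None for f in flags) or any(v is None or np.isnan(v) for v in logbb):
        raise ValueError("missing prediction")
    votes = {_tool_class(bool(f), float(v)) for f, v in zip(flags, logbb)}
    return votes.pop() if len(votes) == 1 else "uncertain"


def bbb_classify_table(records: pd.DataFrame) -> pd.Series:
    """Vectorized consensus class over a drug table with per-tool columns."""
    out = []
    for _, row in records.iterrows():
        flags = [row[f"permeant_tool{t}"] for t in (1, 2, 3)]
        logbb = [row[f"logbb_tool{t}"] for t in (1, 2, 3)]
        out.append(bbb_classify(flags, logbb))
    return pd.Series(out, index=records.index, name="bbb_class")


def fel_transform(density: np.ndarray, temperature: float = 310.0) -> np.ndarray:
    """Free-energy landscape (kJ/mol) from a population density matrix.

    ``delta G = -k_B T ln(P / Pmax)``: the modal cell maps to exactly 0 and
    zero-density cells to +inf.
    """
    p = np.asarray(density, dtype=float)
    if np.any(p < 0):
        raise ValueError("densities must be non-negative")
    pmax = p.max()
    if pmax <= 0:
        raise ValueError("all-zero density has no defined landscape")
    with np.errstate(divide="ignore"):
        return -KB_KJ * temperature * np.log(p / pmax)
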