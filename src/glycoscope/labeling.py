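"""Isotopologue arithmetic for 13C metabolic-labeling experiments.

After feeding cells uniformly labeled 13C6-glucose, LC-MS reports each
metabolite as a ladder of isotopologues M0..Mn (n = number of carbons), where
Mi is the signal of the species carrying i heavy carbons. Two summaries drive
the analysis:

* relative amount — the sum of all isotopologue signals of a metabolite;
* fractional contribution (FC) — the fraction of the metabolite's carbon
  atoms that are 13C, ``FC = sum_i i*Mi / (n * sum_i Mi)``.

FC is a ratio, so it is invariant under per-sample normalization (cell number,
protein concentration) and under any rescaling of the abundance vector.
Natural-abundance 13C correction is intentionally not applied (see the
methods note); missing isotopologue columns are treated as zero with a
warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "relative_amount",
    "fractional_contribution",
    "normalize_sample",
    "summarize_labeling",
    "read_isotopologue_csv",
]


def _check_abundances(abundances) -> np.ndarray:
    vec = np.asarray(abundances, dtype=float)
    if vec.ndim != 1 or len(vec) < 2:
        raise InvalidInputError("abundances must be a 1-D vector M0..Mn, n >= 1")
    if np.any(vec < 0) or not np.all(np.isfinite(vec)):
        raise InvalidInputError("abundances must be finite and >= 0")
    return vec


def relative_amount(abundances) -> float:
    """Total metabolite signal: the sum over all isotopologues."""
    return float(_check_abundances(abundances).sum())


def fractional_contribution(abundances) -> float:
    """Fraction of the metabolite's carbons carrying 13C.

    ``FC = sum_i i*Mi / (n * sum_i Mi)`` for a vector (M0, ..., Mn); always
    in [0, 1]. Raises on an all-zero vector, where FC is undefined.
    """
    vec = _check_abundances(abundances)
    total = vec.sum()
    if total == 0:
        raise InvalidInputError("fractional contribution undefined for zero total signal")
    n_carbons = len(vec) - 1
    weights = np.arange(len(vec))
    return float((weights * vec).sum() / (n_carbons * total))


def normalize_sample(values, protein_conc: float = 1.0, cell_number: float = 1.0):
    """Divide signals by protein concentration and cell number.

    Leaves any ratio of signals — in particular FC — unchanged.
    """
    if protein_conc <= 0 or cell_number <= 0:
        raise InvalidInputError("normalizers must be positive")
    return np.asarray(values, dtype=float) / (protein_conc * cell_number)


def read_isotopologue_csv(path) -> pd.DataFrame:
    """Read a long-format isotopologue table.

    Expected columns: sample, metabolite, n_carbons, isotopologue_index, area.
    """
    df = pd.read_csv(path)
    required = {"sample", "metabolite", "n_carbons", "isotopologue_index", "area"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"isotopologue CSV missing columns: {sorted(missing)}")
    return df


def summarize_labeling(
    df: pd.DataFrame,
    protein_conc: dict | None = None,
    cell_number: dict | None = None,
) -> pd.DataFrame:
    """Per (sample, metabolite) relative amount and fractional contribution.

    ``df`` is long-format (sample, metabolite, n_carbons, isotopologue_index,
    area). Isotopologue indices absent from a metabolite's ladder count as
    zero signal (with a warning). Optional per-sample normalizer dicts rescale
    the relative amounts; FC is unaffected. Metabolites with zero total signal
    get FC = NaN and ``fc_defined = False`` rather than silent NaN arithmetic.
    """
    if np.any(df["area"] < 0):
        raise InvalidInputError("negative isotopologue area")
    rows = []
    for (sample, metabolite), grp in df.groupby(["sample", "metabolite"], sort=True):
        n_carbons = int(grp["n_carbons"].iloc[0])
        vec = np.zeros(n_carbons + 1)
        idx = grp["isotopologue_index"].to_numpy(dtype=int)
        if np.any(idx < 0) or np.any(idx > n_carbons):
            raise InvalidInputError(
                f"isotopologue index out of range for {metabolite} (n_carbons={n_carbons})"
            )
        np.add.at(vec, idx, grp["area"].to_numpy(dtype=float))
        if len(np.unique(idx)) < n_carbons + 1:
            warnings.warn(
                f"{sample}/{metabolite}: missing isotopologue columns treated as 0",
                stacklevel=2,
            )
        amount = vec.sum()
        if amount > 0:
            fc = fractional_contribution(vec)
            defined = True
        else:
            fc, defined = np.nan, False
        norm = 1.0
        if protein_conc is not None:
            norm *= protein_conc[sample]
        if cell_number is not None:
            norm *= cell_number[sample]
        if norm <= 0:
            raise InvalidInputError("normalizers must be positive")
        rows.append({
            "sample": sample,
            "metabolite": metabolite,
            "n_carbons": n_carbons,
            "relative_amount": amount / norm,
            "fractional_contribution": fc,
            "fc_defined": defined,
        })
    return pd.DataFrame(rows)
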