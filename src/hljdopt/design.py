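"""Orthogonal experimental design and small outcome formulas.

The study varies the weight proportions of the four HLJDD component herbs
(*Rhizoma coptidis* Rc, *Radix scutellariae* Rs, *Cortex phellodendri* Cp,
*Fructus gardeniae* Fg) over nine treatment formulae arranged by a Taguchi
L9 orthogonal array: four factors, three levels each, nine runs instead of
the 3^4 = 81 runs a full factorial would need.

Two published dose tables coexist here on purpose:

* :func:`build_l9_design` produces the *canonical* L9(3^4) array, which is
  balanced (each level three times per column) and pairwise orthogonal.
* :func:`load_table1_doses` returns the verbatim printed dose matrix of the
  nine formulae (F1..F9).  That matrix is **not** a balanced L9 (e.g. the
  Rc column holds dose 3 five times), so no orthogonality is asserted on it.

The module also carries the outcome arithmetic of the animal study: the
edema-corrected infarct percentage I% = (Vc - Vi)/Vc x 100 and the Longa
five-point neurobehavioral score.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FACTORS = ("Rc", "Rs", "Cp", "Fg")

# Canonical Taguchi L9(3^4) orthogonal array (standard tabulation, level
# indices 1..3).  Every column is balanced and every column pair covers the
# nine level combinations exactly once.
_L9 = (
    (1, 1, 1, 1),
    (1, 2, 2, 2),
    (1, 3, 3, 3),
    (2, 1, 2, 3),
    (2, 2, 3, 1),
    (2, 3, 1, 2),
    (3, 1, 3, 2),
    (3, 2, 1, 3),
    (3, 3, 2, 1),
)

# Verbatim printed dose matrix (mass parts) of formulae F1..F9, columns
# Rc, Rs, Cp, Fg.  Kept as an immutable constant; never edited.
_TABLE1 = (
    ("F1", 3, 2, 2, 3),
    ("F2", 6, 2, 2, 3),
    ("F3", 3, 4, 4, 6),
    ("F4", 3, 4, 2, 12),
    ("F5", 3, 2, 8, 6),
    ("F6", 3, 8, 4, 3),
    ("F7", 12, 4, 8, 3),
    ("F8", 6, 1, 2, 6),
    ("F9", 6, 4, 1, 3),
)

LONGA_LABELS = {
    0: "no neurological deficit",
    1: "failure to extend right forelimb",
    2: "circling to the contralateral side",
    3: "falling to the contralateral side at rest",
    4: "no spontaneous motor activity",
}


class DesignError(ValueError):
    """Invalid factor/level structure for an orthogonal design."""


@dataclass(frozen=True)
class DesignTable:
    """An orthogonal design: runs as level indices plus a dose mapping."""

    factors: tuple[str, ...]
    runs: tuple[dict, ...]  # each: {"run": str, factor: level_index}
    dose_map: dict  # factor -> {level_index: dose}

    def levels_frame(self) -> pd.DataFrame:
        """Run-by-factor table of level indices (1..3)."""
        idx = [r["run"] for r in self.runs]
        data = {f: [r[f] for r in self.runs] for f in self.factors}
        return pd.DataFrame(data, index=idx)

    def dose_frame(self) -> pd.DataFrame:
        """Run-by-factor table of dose weights."""
        lv = self.levels_frame()
        out = lv.copy().astype(float)
        for f in self.factors:
            out[f] = [self.dose_map[f][int(i)] for i in lv[f]]
        return out

    def is_balanced(self) -> bool:
        lv = self.levels_frame()
        return all(
            sorted(lv[f].value_counts().items()) == [(1, 3), (2, 3), (3, 3)]
            for f in self.factors
        )

    def is_orthogonal(self) -> bool:
        lv = self.levels_frame()
        for a, b in itertools.combinations(self.factors, 2):
            pairs = set(zip(lv[a], lv[b]))
            if len(pairs) != 9:
                return False
        return True


@dataclass(frozen=True)
class LongaScore:
    value: int
    label: str


def build_l9_design(factors=FACTORS, dose_map=None) -> DesignTable:
    """Build the canonical L9(3^4) array over *factors*.

    Parameters
    ----------
    factors : sequence of 4 names
    dose_map : {factor: {1: dose, 2: dose, 3: dose}}, optional
        Defaults to the identity mapping (dose = level index).
    """
    factors = tuple(factors)
    if len(factors) != 4 or len(set(factors)) != 4:
        raise DesignError("exactly 4 distinct factors are required")
    if dose_map is None:
        dose_map = {f: {1: 1.0, 2: 2.0, 3: 3.0} for f in factors}
    for f in factors:
        if f not in dose_map or sorted(dose_map[f]) != [1, 2, 3]:
            raise DesignError(f"factor {f!r} needs exactly levels 1, 2, 3 in dose_map")
    runs = tuple(
        {"run": f"F{i + 1}", **dict(zip(factors, row))} for i, row in enumerate(_L9)
    )
    table = DesignTable(factors=factors, runs=runs, dose_map=dict(dose_map))
    assert table.is_balanced() and table.is_orthogonal()
    return table


def full_factorial(factors=FACTORS, levels=(1, 2, 3)) -> pd.DataFrame:
    """Enumerate the full factorial over *factors* (3^4 = 81 runs by default)."""
    rows = list(itertools.product(levels, repeat=len(factors)))
    return pd.DataFrame(rows, columns=list(factors))


def load_table1_doses() -> pd.DataFrame:
    """The printed 9x4 dose matrix of formulae F1..F9 (mass parts).

    Returned fresh on every call from an immutable constant, so the fixture
    cannot drift.  This matrix is not a balanced canonical L9; do not run
    orthogonality checks against it.
    """
    rows = [r[1:] for r in _TABLE1]
    idx = [r[0] for r in _TABLE1]
    return pd.DataFrame(rows, index=idx, columns=list(FACTORS))


def infarct_percent(vc: float, vi: float) -> float:
    """Edema-corrected infarct percentage I% = (Vc - Vi)/Vc x 100.

    Vc is the intact contralateral hemisphere volume, Vi the intact portion
    of the ipsilateral hemisphere.  Vi > Vc yields a negative percentage
    (edema overshoot); it is returned as-is with a warning, never clamped.
    """
    if not np.isfinite(vc) or vc <= 0:
        raise ValueError("Vc must be a positive finite volume")
    if not np.isfinite(vi) or vi < 0:
        raise ValueError("Vi must be a nonnegative finite volume")
    pct = (vc - vi) / vc * 100.0
    if pct < 0:
        warnings.warn(
            f"negative infarct percent ({pct:.3g}%): Vi exceeds Vc", stacklevel=2
        )
    return pct


def validate_longa(score) -> LongaScore:
    """Validate a Longa five-point neurobehavioral score (0..4)."""
    if isinstance(score, bool) or not isinstance(score, (int, np.integer)):
        raise ValueError(f"Longa score must be an integer, got {score!r}")
    score = int(score)
    if score not in LONGA_LABELS:
        raise ValueError(f"Longa score must be in 0..4, got {score}")
    return LongaScore(value=score, label=LONGA_LABELS[score])


def summarize_outcomes(records: pd.DataFrame, groups=None) -> pd.DataFrame:
    """Per-group outcome summary: n, mean +/- SD, mortality fraction.

    Parameters
    ----------
    records : DataFrame with columns ``group``, ``score``, ``infarct_pct``,
        ``died`` (bool).  Missing outcome columns are simply skipped.
    groups : optional explicit group list; records outside it raise.

    SD of a single record is reported as NaN (missing), never as 0.
    """
    required = {"group"}
    if not required.issubset(records.columns):
        raise ValueError("records need a 'group' column")
    if groups is not None:
        unknown = set(records["group"]) - set(groups)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        order = [g for g in groups if g in set(records["group"])]
    else:
        order = list(dict.fromkeys(records["group"]))

    rows = []
    for g in order:
        sub = records[records["group"] == g]
        row = {"group": g, "n": len(sub)}
        for col in ("score", "infarct_pct"):
            if col in records.columns:
                v = sub[col].astype(float)
                row[f"{col}_mean"] = v.mean()
                row[f"{col}_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
        if "died" in records.columns:
            row["mortality"] = float(sub["died"].astype(bool).mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
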