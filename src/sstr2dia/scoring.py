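"""Manual immunohistochemistry scoring systems and counting rules.

Implements the eyeball-based scores used for SSTR2 membrane staining —
the Volante score (0–3) and the immunoreactive score (IRS, 0–12) — plus
the Ki-67 labeling index, WHO 2019 NET grading from Ki-67, and the
chromogranin-A double-stain positive rate used for normal neuroendocrine
cells.

Truncation conventions follow the source tables these scores feed: the
Ki-67 labeling index is rounded *down* to two decimals and the double-stain
positive rate down to four decimals, so both are computed with integer
arithmetic rather than floating-point rounding.
"""

from __future__ import annotations

import warnings
from typing import Optional

__all__ = [
    "volante_score",
    "irs",
    "ki67_li",
    "who_grade",
    "double_stain_rate",
    "IRS_VALUES",
]

#: Attainable IRS values: products of positivity bin (0-4) and intensity (0-3).
IRS_VALUES = frozenset({0, 1, 2, 3, 4, 6, 8, 9, 12})

_LOCALIZATIONS = ("none", "cytoplasmic", "membranous")
_EXTENTS = ("circumferential", "incomplete")


def volante_score(
    localization: str,
    extent: Optional[str] = None,
    positive_fraction: float = 0.0,
) -> int:
    """Volante score (0–3) from staining localization, membranous extent
    and the fraction of positive tumor cells.

    Mapping: 0 — no staining; 1 — purely cytoplasmic; 2 — membranous but
    either incomplete or in ≤50% of cells; 3 — circumferential membranous
    staining in >50% of cells.

    Parameters
    ----------
    localization : {"none", "cytoplasmic", "membranous"}
    extent : {"circumferential", "incomplete"}, optional
        Only meaningful (and required) for membranous staining.
    positive_fraction : float
        Percentage of positively stained tumor cells, in [0, 100].
    """
    if localization not in _LOCALIZATIONS:
        raise ValueError(f"unknown localization {localization!r}")
    if not 0.0 <= positive_fraction <= 100.0:
        raise ValueError("positive_fraction must be in [0, 100]")
    if localization != "membranous":
        if extent is not None:
            raise ValueError("extent is defined only for membranous staining")
        return 0 if localization == "none" else 1
    if extent not in _EXTENTS:
        raise ValueError("membranous staining requires extent "
                         "'circumferential' or 'incomplete'")
    if extent == "circumferential" and positive_fraction > 50.0:
        return 3
    return 2


def _irs_positivity_bin(positive_fraction: float) -> int:
    # bins: 0: 0%; 1: <10%; 2: 10-50%; 3: 51-80% (values in (50,51) -> 3); 4: >80%
    if positive_fraction == 0.0:
        return 0
    if positive_fraction < 10.0:
        return 1
    if positive_fraction <= 50.0:
        return 2
    if positive_fraction <= 80.0:
        return 3
    return 4


def irs(positive_fraction: float, intensity: int) -> int:
    """Immunoreactive score: positivity bin (0–4) × staining intensity (0–3).

    The positivity bins are 0: 0%, 1: <10%, 2: 10–50%, 3: 51–80%, 4: >80%;
    intensity 0 none, 1 weak, 2 moderate, 3 strong. The attainable values
    are exactly ``IRS_VALUES`` = {0, 1, 2, 3, 4, 6, 8, 9, 12}.
    """
    if not 0.0 <= positive_fraction <= 100.0:
        raise ValueError("positive_fraction must be in [0, 100]")
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be an integer in {0, 1, 2, 3}")
    return _irs_positivity_bin(positive_fraction) * intensity


def ki67_li(positive_nuclei: int, total_nuclei: int) -> float:
    """Ki-67 labeling index in percent, truncated (not rounded) to 2 decimals.

    Counting follows the WHO 2019 convention of at least 500 tumor nuclei;
    smaller denominators are accepted with a warning. Truncation is done in
    integer arithmetic so e.g. (1, 3) → 33.33, never 33.34.
    """
    if total_nuclei < 1:
        raise ValueError("total_nuclei must be >= 1")
    if positive_nuclei < 0 or positive_nuclei > total_nuclei:
        raise ValueError("positive_nuclei must be in [0, total_nuclei]")
    if total_nuclei < 500:
        warnings.warn(
            f"Ki-67 denominator {total_nuclei} < 500 nuclei; index is unstable",
            stacklevel=2,
        )
    # floor(100 * p/t to 2 decimals) == (10000*p // t) / 100 exactly
    return (10_000 * positive_nuclei // total_nuclei) / 100


def who_grade(ki67: float) -> str:
    """WHO 2019 NET grade from the Ki-67 labeling index alone.

    G1 for Ki-67 < 3%, G2 for 3–20% (both boundaries inclusive), G3 for >20%.
    Mitotic counts are not considered.
    """
    if ki67 < 0:
        raise ValueError("Ki-67 labeling index must be >= 0")
    if ki67 < 3.0:
        return "G1"
    if ki67 <= 20.0:
        return "G2"
    return "G3"


def double_stain_rate(n_double: int, n_cga: int) -> float:
    """SSTR2 positive rate of neuroendocrine cells from double staining.

    Rate = (SSTR2/chromogranin-A double-positive cells) / (chromogranin-A
    positive cells), truncated to four decimal places. Evaluation requires
    at least 10 chromogranin-positive cells in the hot spot; fewer is
    accepted with a warning.
    """
    if n_cga < 1:
        raise ValueError("n_cga must be >= 1")
    if n_double < 0 or n_double > n_cga:
        raise ValueError("n_double must be in [0, n_cga]")
    if n_cga < 10:
        warnings.warn(
            f"only {n_cga} chromogranin-positive cells (< 10); rate is unstable",
            stacklevel=2,
        )
    return (10_000 * n_double // n_cga) / 10_000
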