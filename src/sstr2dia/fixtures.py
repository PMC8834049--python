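"""Embedded clinicopathological case tables.

Two small cohorts ship with the package as plain CSV so that every
downstream analysis is reproducible without external data access:

* the SSA-treated cohort: 14 gastrointestinal neuroendocrine tumor (GI-NET)
  patients treated with somatostatin analogues, with SSTR2 immunoreactivity
  scored three ways (Volante score, immunoreactive score, digital-image-analysis
  composite) and RECIST response dichotomized as positive (CR or SD) versus
  negative (PD);
* the normal-mucosa cohort: 37 non-neoplastic mucosal specimens (stomach,
  duodenum, rectum) with the SSTR2/chromogranin-A double-stain positive rate
  of neuroendocrine cells.

Loaders validate a schema and a SHA-256 checksum so a corrupted install
fails loudly rather than silently shifting a statistic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "CaseRecord",
    "MucosaRecord",
    "load_ssa_cohort",
    "load_mucosa_cohort",
    "ssa_cohort_frame",
    "mucosa_cohort_frame",
    "FixtureIntegrityError",
]

_CHECKSUMS = {
    "group3_ssa_cases.csv": "77d60ae6b017491ee9c858a1f1a4bc49fd9e0eac32325f54940b8644c73480de",
    "group4_mucosa.csv": "06711397b502992d5873f53c3110f21a16eb4272a0197f468986df2bb3fe5025",
}

_IRS_VALUES = {0, 1, 2, 3, 4, 6, 8, 9, 12}
_SITES = {"foregut", "midgut", "hindgut"}
_MUCOSA_SITES = {"stomach", "duodenum", "rectum"}


class FixtureIntegrityError(RuntimeError):
    """Raised when an embedded table fails checksum or schema validation."""


@dataclass(frozen=True)
class CaseRecord:
    """One SSA-treated GI-NET case: scores, site, grade and response."""

    case_id: int
    sex: str
    age: int
    site_class: str
    tissue_origin: str
    grade: str
    preop_therapy: str
    volante: int
    irs: int
    dia_score: float
    treatment: str
    response: str
    response_binary: str


@dataclass(frozen=True)
class MucosaRecord:
    """One non-neoplastic mucosa specimen with its SSTR2 positive rate."""

    case_id: int
    site: str
    subsite: str
    age: int
    sex: str
    positive_rate: float


def _read_csv(name: str) -> pd.DataFrame:
    ref = resources.files("sstr2dia.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"embedded table {name!r} failed its checksum "
            f"(got {digest}, expected {_CHECKSUMS[name]})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), keep_default_na=False, na_values=[])


def ssa_cohort_frame() -> pd.DataFrame:
    """SSA-treated cohort as a DataFrame (14 rows), schema-validated."""
    df = _read_csv("group3_ssa_cases.csv")
    if len(df) != 14:
        raise FixtureIntegrityError(f"expected 14 SSA-treated cases, found {len(df)}")
    bad_volante = ~df["volante"].isin([0, 1, 2, 3])
    bad_irs = ~df["irs"].isin(sorted(_IRS_VALUES))
    bad_site = ~df["site_class"].isin(_SITES)
    if bad_volante.any() or bad_irs.any() or bad_site.any():
        raise FixtureIntegrityError("SSA cohort table violates its schema")
    if (df["dia_score"] < 0).any():
        raise FixtureIntegrityError("negative DIA score in SSA cohort table")
    expected = df["response"].isin(["CR", "SD"]).map({True: "positive", False: "negative"})
    if not (df["response_binary"] == expected).all():
        raise FixtureIntegrityError("response_binary inconsistent with RECIST response")
    return df


def mucosa_cohort_frame() -> pd.DataFrame:
    """Normal-mucosa cohort as a DataFrame (37 rows), schema-validated."""
    df = _read_csv("group4_mucosa.csv")
    if len(df) != 37:
        raise FixtureIntegrityError(f"expected 37 mucosa specimens, found {len(df)}")
    if not df["site"].isin(_MUCOSA_SITES).all():
        raise FixtureIntegrityError("unknown mucosal site in table")
    rate = df["positive_rate"].astype(float)
    if ((rate < 0) | (rate > 1)).any():
        raise FixtureIntegrityError("positive_rate outside [0, 1]")
    return df


def load_ssa_cohort() -> list[CaseRecord]:
    """Load the 14 SSA-treated cases as typed records."""
    df = ssa_cohort_frame()
    return [
        CaseRecord(
            case_id=int(r.case_id),
            sex=str(r.sex),
            age=int(r.age),
            site_class=str(r.site_class),
            tissue_origin=str(r.tissue_origin),
            grade=str(r.grade),
            preop_therapy=str(r.preop_therapy),
            volante=int(r.volante),
            irs=int(r.irs),
            dia_score=float(r.dia_score),
            treatment=str(r.treatment),
            response=str(r.response),
            response_binary=str(r.response_binary),
        )
        for r in df.itertuples(index=False)
    ]


def load_mucosa_cohort() -> list[MucosaRecord]:
    """Load the 37 mucosal specimens as typed records."""
    df = mucosa_cohort_frame()
    return [
        MucosaRecord(
            case_id=int(r.case_id),
            site=str(r.site),
            subsite=str(r.subsite),
            age=int(r.age),
            sex=str(r.sex),
            positive_rate=float(r.positive_rate),
        )
        for r in df.itertuples(index=False)
    ]
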