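"""Phasing-method survey over a PDB-metadata extract.

Historically the PDB 'structure determination method' field was free text.
Each record is normalized to a phasing category; when several methods are
named the most senior wins, with the precedence

    MIRAS > MIR > MAD > SIRAS > SIR > SAD > MR > FOURIER_SYNTHESIS.

Records are then binned into five-year windows such that BOTH the
deposition and the release date fall inside the window (straddling entries
are dropped), restricted to entity ID '1', and reported as per-window
percentage shares, either over all methods (experimental grouped together)
or within experimental phasing only.

Ab-initio/direct-methods strings are excluded from the analysis; unknown
non-empty strings map to NULL, and both are dropped from shares.  The alias
dictionary is best-effort and extensible via a YAML mapping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhasingCategory",
    "SurveyRecord",
    "BinnedCounts",
    "normalize_method",
    "bin_records",
    "report_shares",
    "generate_survey_fixture",
    "load_records",
    "EXPERIMENTAL_CATEGORIES",
]


class PhasingCategory(Enum):
    MIRAS = 8
    MIR = 7
    MAD = 6
    SIRAS = 5
    SIR = 4
    SAD = 3
    MR = 2
    FOURIER_SYNTHESIS = 1
    EXCLUDED = 0
    NULL = -1

    @property
    def seniority(self) -> int:
        return self.value


EXPERIMENTAL_CATEGORIES = (
    PhasingCategory.SAD, PhasingCategory.MAD, PhasingCategory.SIR,
    PhasingCategory.SIRAS, PhasingCategory.MIR, PhasingCategory.MIRAS,
)


@dataclass(frozen=True)
class SurveyRecord:
    entry_id: str
    deposition_date: date
    release_date: date
    entity_id: str
    method_text: str | None

    def __post_init__(self) -> None:
        if self.deposition_date > self.release_date:
            raise ValueError(f"{self.entry_id}: deposition after release")


# -- free-text normalization ------------------------------------------------

#: token (after lower-casing and punctuation stripping) -> categories named.
#: Multi-word phrases are matched against the normalized whole string.
_TOKEN_ALIASES: dict[str, tuple[PhasingCategory, ...]] = {
    "miras": (PhasingCategory.MIRAS,),
    "mir": (PhasingCategory.MIR,),
    "mirsad": (PhasingCategory.MIR, PhasingCategory.SAD),
    "mad": (PhasingCategory.MAD,),
    "siras": (PhasingCategory.SIRAS,),
    "sir": (PhasingCategory.SIR,),
    "sad": (PhasingCategory.SAD,),
    "sas": (PhasingCategory.SAD,),
    "mr": (PhasingCategory.MR,),
    "mrsad": (PhasingCategory.MR, PhasingCategory.SAD),
    "sadmr": (PhasingCategory.MR, PhasingCategory.SAD),
    "remr": (PhasingCategory.MR,),
    "epmr": (PhasingCategory.MR,),
}

_PHRASE_ALIASES: dict[str, tuple[PhasingCategory, ...]] = {
    "molecular replacement": (PhasingCategory.MR,),
    "fourier synthesis": (PhasingCategory.FOURIER_SYNTHESIS,),
    "difference fourier": (PhasingCategory.FOURIER_SYNTHESIS,),
    "isomorphous with": (PhasingCategory.FOURIER_SYNTHESIS,),
    "rigid body": (PhasingCategory.FOURIER_SYNTHESIS,),
    "multiwavelength anomalous": (PhasingCategory.MAD,),
    "multiple wavelength anomalous": (PhasingCategory.MAD,),
    "single wavelength anomalous": (PhasingCategory.SAD,),
    "multiple isomorphous replacement with anomalous": (PhasingCategory.MIRAS,),
    "multiple isomorphous replacement": (PhasingCategory.MIR,),
    "single isomorphous replacement with anomalous": (PhasingCategory.SIRAS,),
    "single isomorphous replacement": (PhasingCategory.SIR,),
}

_EXCLUDE_PHRASES = ("ab initio", "abinitio", "direct methods", "direct method")

_unknown_logged = 0


def _canonical(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", " ", text.lower()).strip()


def normalize_method(text: str | None) -> PhasingCategory:
    """Map a free-text method string to its most senior phasing category.

    Total and deterministic: null/empty -> NULL, ab-initio-style strings ->
    EXCLUDED, unknown non-empty strings -> NULL (a sample is logged).
    """
    global _unknown_logged
    if text is None or not str(text).strip() or (isinstance(text, float) and np.isnan(text)):
        return PhasingCategory.NULL
    canon = _canonical(str(text))
    if not canon:
        return PhasingCategory.NULL
    for phrase in _EXCLUDE_PHRASES:
        if phrase in canon:
            return PhasingCategory.EXCLUDED
    found: set[PhasingCategory] = set()
    for phrase, cats in _PHRASE_ALIASES.items():
        if phrase in canon:
            found.update(cats)
    for token in canon.split():
        found.update(_TOKEN_ALIASES.get(token, ()))
    # dotted abbreviations ("S.A.D.") survive only as a collapsed form
    collapsed = canon.replace(" ", "")
    if not found and collapsed in _TOKEN_ALIASES:
        found.update(_TOKEN_ALIASES[collapsed])
    if not found:
        if _unknown_logged < 20:
            logger.info("unrecognized method text %r -> NULL", text)
            _unknown_logged += 1
        return PhasingCategory.NULL
    return max(found, key=lambda c: c.seniority)


def add_aliases(mapping: dict[str, str]) -> None:
    """Extend the alias dictionary: normalized token/phrase -> category name."""
    for key, cat_name in mapping.items():
        cats = (PhasingCategory[cat_name.upper()],)
        key_norm = _canonical(key)
        if " " in key_norm:
            _PHRASE_ALIASES[key_norm] = cats
        else:
            _TOKEN_ALIASES[key_norm] = cats


# -- binning and shares -----------------------------------------------------


@dataclass
class BinnedCounts:
    """Per-window category counts plus a tally of dropped records."""

    counts: pd.DataFrame        # index: window start year; columns: category names
    window_years: int
    n_dropped_dates: int = 0
    n_dropped_entity: int = 0
    n_dropped_straddle: int = 0
    n_dropped_category: int = 0


def _window_start(year: int, start_year: int, window_years: int) -> int:
    return start_year + ((year - start_year) // window_years) * window_years


def bin_records(records, start_year: int = 2000, window_years: int = 5) -> BinnedCounts:
    """Assign records to calendar windows [start, start + window_years).

    A record enters a window only when both its deposition and release years
    fall inside that same window; entity IDs other than '1', dates before
    the start year, and NULL/EXCLUDED categories are dropped.
    """
    if window_years < 1:
        raise ValueError("window must be at least one year")
    rows: dict[int, dict[str, int]] = {}
    dropped_dates = dropped_entity = dropped_straddle = dropped_cat = 0
    for rec in records:
        if not isinstance(rec, SurveyRecord):
            try:
                rec = SurveyRecord(
                    str(rec.entry_id), rec.deposition_date, rec.release_date,
                    str(rec.entity_id), rec.method_text)
            except (AttributeError, TypeError, ValueError) as exc:
                logger.warning("dropping unusable record: %s", exc)
                dropped_dates += 1
                continue
        if str(rec.entity_id) != "1":
            dropped_entity += 1
            continue
        dep, rel = rec.deposition_date.year, rec.release_date.year
        if dep < start_year or rel < start_year:
            dropped_straddle += 1
            continue
        w_dep = _window_start(dep, start_year, window_years)
        w_rel = _window_start(rel, start_year, window_years)
        if w_dep != w_rel:
            dropped_straddle += 1
            continue
        cat = normalize_method(rec.method_text)
        if cat in (PhasingCategory.NULL, PhasingCategory.EXCLUDED):
            dropped_cat += 1
            continue
        rows.setdefault(w_dep, {})
        rows[w_dep][cat.name] = rows[w_dep].get(cat.name, 0) + 1
    all_cats = [c.name for c in PhasingCategory
                if c not in (PhasingCategory.NULL, PhasingCategory.EXCLUDED)]
    counts = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=all_cats, fill_value=0).fillna(0).astype(int).sort_index()
    return BinnedCounts(counts, window_years, dropped_dates, dropped_entity,
                        dropped_straddle, dropped_cat)


def report_shares(binned: BinnedCounts, scope: str = "all-methods") -> pd.DataFrame:
    """Per-window percentage shares.

    scope 'all-methods': shares over {EXPERIMENTAL (grouped), MR,
    FOURIER_SYNTHESIS}; scope 'experimental-only': shares over the six
    experimental methods.  Windows with no records in scope are absent from
    the output rather than reported as zeros.
    """
    counts = binned.counts
    if scope == "all-methods":
        exp = counts[[c.name for c in EXPERIMENTAL_CATEGORIES]].sum(axis=1)
        table = pd.DataFrame({
            "EXPERIMENTAL": exp,
            "MR": counts["MR"],
            "FOURIER_SYNTHESIS": counts["FOURIER_SYNTHESIS"],
        })
    elif scope == "experimental-only":
        table = counts[[c.name for c in EXPERIMENTAL_CATEGORIES]].copy()
    else:
        raise ValueError("scope must be 'all-methods' or 'experimental-only'")
    totals = table.sum(axis=1)
    table = table.loc[totals > 0]
    return table.div(totals[totals > 0], axis=0) * 100.0


# -- synthetic fixture ------------------------------------------------------

#: spelling pools emulating the free-format field, per category.
_SPELLING_POOL: dict[PhasingCategory, tuple[str, ...]] = {
    PhasingCategory.MIRAS: ("MIRAS", "miras"),
    PhasingCategory.MIR: ("MIR", "multiple isomorphous replacement"),
    PhasingCategory.MAD: ("MAD", "SIRAS/MAD", "Multiwavelength anomalous dispersion"),
    PhasingCategory.SIRAS: ("SIRAS", "siras"),
    PhasingCategory.SIR: ("SIR", "single isomorphous replacement"),
    PhasingCategory.SAD: ("SAD", "S.A.D.", "MRSAD", "SAD with molecular replacement"),
    PhasingCategory.MR: ("MR", "molecular replacement", "MOLECULAR REPLACEMENT"),
    PhasingCategory.FOURIER_SYNTHESIS: ("Fourier synthesis", "difference Fourier"),
}


def generate_survey_fixture(seed: int, n_records: int, composition,
                            start_year: int = 2000, window_years: int = 5,
                            straddle_fraction: float = 0.0,
                            null_fraction: float = 0.0):
    """Seeded synthetic survey records.

    ``composition`` maps window start year -> {PhasingCategory: fraction};
    fractions must sum to 1 per window.  A ``straddle_fraction`` of records
    get a release date pushed into the next window (so they bin nowhere),
    and a ``null_fraction`` get a null method text.
    """
    rng = np.random.default_rng(seed)
    windows = sorted(composition)
    for w, comp in composition.items():
        if abs(sum(comp.values()) - 1.0) > 1e-9:
            raise ValueError(f"composition fractions for window {w} must sum to 1")
    records: list[SurveyRecord] = []
    for i in range(n_records):
        w = windows[int(rng.integers(len(windows)))]
        comp = composition[w]
        cats = list(comp)
        cat = cats[int(rng.choice(len(cats), p=np.array([comp[c] for c in cats])))]
        dep_year = w + int(rng.integers(window_years))
        dep = date(dep_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        straddle = rng.random() < straddle_fraction
        if straddle:
            rel_year = w + window_years + int(rng.integers(2))
        else:
            rel_year = int(rng.integers(dep_year, w + window_years))
        rel = date(rel_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        if rel < dep:
            rel = dep
        text: str | None
        if rng.random() < null_fraction:
            text = None
        else:
            pool = _SPELLING_POOL[cat]
            text = pool[int(rng.integers(len(pool)))]
        records.append(SurveyRecord(f"SYN{i:05d}", dep, rel, "1", text))
    return records


def load_records(path) -> list[SurveyRecord]:
    """Read a CSV/TSV extract: id, deposition_date, release_date, entity_id,
    method_text (ISO-8601 dates).  Unparseable rows are dropped with a warning."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"id", "deposition_date", "release_date", "entity_id", "method_text"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(SurveyRecord(
                row["id"],
                date.fromisoformat(row["deposition_date"]),
                date.fromisoformat(row["release_date"]),
                str(row["entity_id"]),
                None if pd.isna(row["method_text"]) else row["method_text"],
            ))
        except (ValueError, TypeError) as exc:
            logger.warning("dropping row %s: %s", row.get("id"), exc)
    return records
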