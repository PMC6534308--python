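"""Survey table I/O, century-month-code arithmetic, and birth-history reshaping.

Demographic surveys in the WFS/DHS tradition code every event date as a
Century Month Code (CMC): the number of months elapsed since January 1900,
with January 1900 = 1.  All estimation in this package runs on CMC integers;
this module owns the conversions, the readers for the standard recode file
formats (Stata ``.dta``, SPSS ``.sav``, CSV), the wide (IR-style
``b3_01..b3_20``) <-> long (BR-style one row per birth) birth-history
reshapes, and the binding of the sampling-design columns (cluster, stratum,
weight).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("demorates")

#: number of wide birth-history slots in a DHS IR recode
N_BIRTH_SLOTS = 20

#: conventional divisor turning the DHS v005 integer weight into a
#: normalized weight averaging ~1
DEFAULT_WEIGHT_DIVISOR = 1_000_000.0


# ---------------------------------------------------------------------------
# Century Month Code arithmetic
# ---------------------------------------------------------------------------

def cmc_from_year_month(year: int, month: int) -> int:
    """Return the CMC for a Gregorian (year, month).

    CMC = (year - 1900) * 12 + month, so January 1900 -> 1.
    """
    year = int(year)
    month = int(month)
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    if year < 1900:
        raise ValueError(f"year must be >= 1900, got {year}")
    return (year - 1900) * 12 + month


def cmc_to_year_month(cmc: int) -> tuple[int, int]:
    """Invert :func:`cmc_from_year_month`."""
    cmc = int(cmc)
    if cmc < 1:
        raise ValueError(f"CMC must be >= 1, got {cmc}")
    year = 1900 + (cmc - 1) // 12
    month = (cmc - 1) % 12 + 1
    return year, month


def cmc_to_decimal_year(cmc: float) -> float:
    """Decimal calendar year of a CMC month, e.g. Sep 2010 (1329) -> 2010.75.

    Accepts fractional CMCs (e.g. a mean interview date).
    """
    if cmc < 1:
        raise ValueError(f"CMC must be >= 1, got {cmc}")
    return 1900.0 + cmc / 12.0


_MONTH_ABBR = ["", "Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


def cmc_to_label(cmc: int) -> str:
    """Human-readable 'Mon YYYY' label for a CMC month."""
    year, month = cmc_to_year_month(int(cmc))
    return f"{_MONTH_ABBR[month]} {year}"


def parse_period_end(text: str) -> int:
    """Parse a 'YYYY-MM' reference-period end into the CMC of that month.

    En-dashes and slashes are tolerated as separators.
    """
    cleaned = str(text).strip()
    for sep in ("–", "—", "/"):
        cleaned = cleaned.replace(sep, "-")
    parts = cleaned.split("-")
    if len(parts) != 2:
        raise ValueError(f"period end must look like 'YYYY-MM', got {text!r}")
    try:
        year, month = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(f"period end must look like 'YYYY-MM', got {text!r}") from exc
    return cmc_from_year_month(year, month)


# ---------------------------------------------------------------------------
# Table loading
# ---------------------------------------------------------------------------

def load_survey_table(path: str | Path, format: str = "auto") -> pd.DataFrame:
    """Read a survey table from ``.dta``, ``.sav`` or ``.csv``.

    Column names are lowercased so that the DHS variable contract
    (v005, v008, v011, v021, v022, b3_*, b7_*, awfact*) can be matched
    case-insensitively across releases.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        table = pd.read_csv(path)
    elif fmt == "dta":
        table = pd.read_stata(path)
    elif fmt == "sav":
        try:
            import pyreadstat  # optional: SPSS support only when installed
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError(
                "reading .sav files requires the optional 'pyreadstat' "
                "package; install it or convert the file to .csv/.dta"
            ) from exc
        table, _ = pyreadstat.read_sav(str(path))  # pragma: no cover
    else:
        raise ValueError(f"unknown survey table format {format!r} for {path.name}")
    table.columns = [str(c).lower() for c in table.columns]
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result or fixture table as CSV or JSON based on the extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        table.to_json(path, orient="records", indent=2)
    else:
        table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Birth-history reshaping
# ---------------------------------------------------------------------------

def _slot_columns(prefix: str) -> list[str]:
    return [f"{prefix}{i:02d}" for i in range(1, N_BIRTH_SLOTS + 1)]


def present_birth_columns(
    women: pd.DataFrame, dob_prefix: str = "b3_"
) -> list[str]:
    """Return the wide birth-history columns present, warning about gaps.

    At least one of the 20 standard slots must exist; absent slots are
    reported once and treated as all-missing.
    """
    dob_cols = _slot_columns(dob_prefix)
    present = [c for c in dob_cols if c in women.columns]
    if not present:
        raise ValueError(
            f"no birth-history columns {dob_prefix}01..{dob_prefix}{N_BIRTH_SLOTS} found"
        )
    missing = [c for c in dob_cols if c not in women.columns]
    if missing:
        msg = (
            f"Birth history variables {dob_prefix}01:{dob_prefix}{N_BIRTH_SLOTS} "
            f"are not complete; the missing variables were created "
            f"(absent: {', '.join(missing)})"
        )
        warnings.warn(msg, stacklevel=3)
        logger.warning(msg)
    return present


def births_from_wide(
    women: pd.DataFrame,
    dob_prefix: str = "b3_",
    death_prefix: str = "b7_",
    mother_id: str | None = None,
) -> pd.DataFrame:
    """Explode IR-style wide birth-history columns into one row per birth.

    Each non-missing ``b3_NN`` cell becomes a row carrying the mother's other
    columns (design variables, interview date, ...), the birth line number,
    the child date of birth ``b3`` and, when a matching ``b7_NN`` column
    exists, the age at death ``b7``.  Absent slots among the 20 standard
    columns are warned about once and treated as all-missing, mirroring how
    survey-processing tools pad an incomplete birth history.
    """
    present = present_birth_columns(women, dob_prefix)
    death_cols = {c: death_prefix + c[len(dob_prefix):] for c in present}
    carry = [
        c
        for c in women.columns
        if not (c.startswith(dob_prefix) or c.startswith(death_prefix))
    ]
    if mother_id is None:
        mother_key = women.index.to_numpy()
    else:
        mother_key = women[mother_id].to_numpy()

    pieces = []
    for dob_col in present:
        line = int(dob_col[len(dob_prefix):])
        mask = women[dob_col].notna().to_numpy()
        if not mask.any():
            continue
        piece = women.loc[mask, carry].copy()
        piece["mother_id"] = mother_key[mask]
        piece["birth_line"] = line
        piece["b3"] = women.loc[mask, dob_col].to_numpy()
        death_col = death_cols[dob_col]
        piece["b7"] = (
            women.loc[mask, death_col].to_numpy()
            if death_col in women.columns
            else np.nan
        )
        pieces.append(piece)
    if not pieces:
        out = women.loc[[], carry].copy()
        out["mother_id"] = pd.Series(dtype=object)
        out["birth_line"] = pd.Series(dtype=int)
        out["b3"] = pd.Series(dtype=float)
        out["b7"] = pd.Series(dtype=float)
        return out
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["mother_id", "birth_line"], kind="stable").reset_index(
        drop=True
    )


def birth_history_to_wide(
    long_births: pd.DataFrame,
    mother_id: str,
    line: str,
    dob: str,
    women: pd.DataFrame | None = None,
    dob_prefix: str = "b3_",
) -> pd.DataFrame:
    """Pivot a long birth table to wide ``b3_01..b3_20`` columns.

    This is how a MICS-style separate birth-history file is attached to its
    women file: one column per birth line number, missing where a woman has
    fewer births.  If ``women`` is given the wide columns are merged onto it
    (left join on ``mother_id``); otherwise a table keyed by mother is
    returned.  Inverse of :func:`births_from_wide` up to line ordering.
    """
    lines = long_births[line].to_numpy()
    if not np.all((lines == lines.astype(int)) & (lines >= 1) & (lines <= N_BIRTH_SLOTS)):
        bad = sorted(set(lines[(lines < 1) | (lines > N_BIRTH_SLOTS)]))
        raise ValueError(
            f"birth line numbers must be integers in 1..{N_BIRTH_SLOTS}; got {bad}"
        )
    dup = long_births.duplicated(subset=[mother_id, line])
    if dup.any():
        pairs = long_births.loc[dup, [mother_id, line]].to_records(index=False)
        raise ValueError(f"duplicate (mother, line) pairs: {list(pairs)[:5]}")

    wide = long_births.pivot(index=mother_id, columns=line, values=dob)
    wide.columns = [f"{dob_prefix}{int(c):02d}" for c in wide.columns]
    wide = wide.reindex(columns=_slot_columns(dob_prefix))
    wide = wide.reset_index()
    if women is not None:
        return women.merge(wide, on=mother_id, how="left")
    return wide


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyDesign:
    """Resolved sampling-design columns of a survey table."""

    cluster_var: str
    stratum_var: str
    weight_var: str
    weight_divisor: float = DEFAULT_WEIGHT_DIVISOR


def _resolve_column(table: pd.DataFrame, name: str) -> str:
    lower = {str(c).lower(): c for c in table.columns}
    key = str(name).lower()
    if key not in lower:
        raise KeyError(
            f"column {name!r} not found; available columns: "
            f"{sorted(map(str, table.columns))}"
        )
    return lower[key]


def resolve_design(
    table: pd.DataFrame,
    cluster: str = "v021",
    strata: str = "v022",
    weight: str = "v005",
    weight_divisor: float = DEFAULT_WEIGHT_DIVISOR,
) -> tuple[SurveyDesign, np.ndarray]:
    """Bind the design columns and return normalized weights.

    Defaults follow the DHS recode contract (v021 cluster, v022 stratum,
    v005 weight scaled by 10^6).  Column matching is case-insensitive; for
    non-DHS weights already on a natural scale pass ``weight_divisor=1``.
    """
    if weight_divisor <= 0:
        raise ValueError("weight_divisor must be positive")
    design = SurveyDesign(
        cluster_var=_resolve_column(table, cluster),
        stratum_var=_resolve_column(table, strata),
        weight_var=_resolve_column(table, weight),
        weight_divisor=float(weight_divisor),
    )
    raw = pd.to_numeric(table[design.weight_var], errors="coerce").to_numpy(float)
    weights = raw / design.weight_divisor
    if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
        n_bad = int(np.sum(~np.isfinite(weights) | (weights <= 0)))
        raise ValueError(
            f"{n_bad} rows have missing or non-positive weights in "
            f"{design.weight_var!r}"
        )
    return design, weights
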