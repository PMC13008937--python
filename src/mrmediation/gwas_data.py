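"""Data model and readers/writers for GWAS summary statistics.

A :class:`SummaryStats` holds one trait's per-variant association estimates
(effect/other allele, effect-allele frequency, beta, SE, p-value, sample
sizes).  Two column dialects are built in:

* ``generic`` — tab-separated with columns ``rsid chrom pos effect_allele
  other_allele eaf beta se pval n [n_cases n_controls]``;
* ``finngen`` — the FinnGen release layout ``#chrom pos ref alt rsids af_alt
  beta sebeta pval``, with the ALT allele taken as the effect allele.

Files may be gzip-compressed; compression is inferred from the ``.gz``
suffix.  Rows violating the record invariants (non-positive SE, p outside
(0, 1], identical alleles, out-of-range frequency) are dropped and counted
in a :class:`LoadReport`; duplicate rsids keep the record with the smallest
p-value.  Positions are 1-based; alleles are uppercased at load.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError

__all__ = [
    "Variant",
    "AssocRecord",
    "SummaryStats",
    "LoadReport",
    "DIALECTS",
    "read_summary_stats",
    "write_summary_stats",
]

#: canonical column order of the generic dialect
CANONICAL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_cases",
    "n_controls",
]

REQUIRED_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
]

#: dialect name -> {canonical column: source column}
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {c: c for c in CANONICAL_COLUMNS},
    "finngen": {
        "rsid": "rsids",
        "chrom": "#chrom",
        "pos": "pos",
        "effect_allele": "alt",
        "other_allele": "ref",
        "eaf": "af_alt",
        "beta": "beta",
        "se": "sebeta",
        "pval": "pval",
    },
}


@dataclass(frozen=True)
class Variant:
    """A single bi-allelic variant with its effect-allele frequency."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float] = None


@dataclass(frozen=True)
class AssocRecord:
    """One variant's association estimate for one trait."""

    variant: Variant
    beta: float
    se: float
    pval: float
    n: Optional[float] = None
    n_cases: Optional[float] = None
    n_controls: Optional[float] = None


@dataclass
class LoadReport:
    """Bookkeeping of rows dropped while building a :class:`SummaryStats`."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    reasons: Counter = field(default_factory=Counter)

    def add(self, reason: str, count: int) -> None:
        if count:
            self.reasons[reason] += int(count)
            self.n_dropped += int(count)


def _nan_to_none(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)


class SummaryStats:
    """One trait's GWAS summary statistics, keyed by rsid.

    Parameters
    ----------
    trait_id : str
        Identifier of the trait (protein, immune phenotype, disease endpoint).
    trait_type : {"continuous", "binary"}
        Binary traits carry case/control counts and betas on the log-odds
        scale; continuous traits report effects in (standardized) trait units.
    table : pandas.DataFrame
        Per-variant rows; validated and cleaned on construction.
    provenance : str
        Free-text source tag (file path, simulation seed, ...).
    """

    def __init__(
        self,
        trait_id: str,
        trait_type: str,
        table: pd.DataFrame,
        provenance: str = "",
        validate: bool = True,
    ):
        if trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        self.trait_id = str(trait_id)
        self.trait_type = trait_type
        self.provenance = provenance
        if validate:
            table, report = _validate_table(table, trait_type)
        else:
            report = LoadReport(n_input=len(table), n_kept=len(table))
        if len(table) == 0:
            raise EmptyInputError(
                f"summary statistics for {trait_id!r} contain no valid rows"
            )
        self.table = table.reset_index(drop=True)
        self.load_report = report
        self._index = pd.Index(self.table["rsid"])

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, rsid: str) -> bool:
        return rsid in set(self._index)

    def __repr__(self) -> str:
        return (
            f"SummaryStats({self.trait_id!r}, {self.trait_type}, "
            f"{len(self)} records)"
        )

    @property
    def rsids(self) -> list[str]:
        return list(self._index)

    def record(self, rsid: str) -> AssocRecord:
        """Return one row as an :class:`AssocRecord`."""
        pos = self._index.get_loc(rsid)
        row = self.table.iloc[pos]
        variant = Variant(
            rsid=row["rsid"],
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=_nan_to_none(row["eaf"]),
        )
        return AssocRecord(
            variant=variant,
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=_nan_to_none(row.get("n", np.nan)),
            n_cases=_nan_to_none(row.get("n_cases", np.nan)),
            n_controls=_nan_to_none(row.get("n_controls", np.nan)),
        )

    @property
    def records(self) -> dict[str, AssocRecord]:
        return {r: self.record(r) for r in self.rsids}

    def subset(self, rsids) -> pd.DataFrame:
        """Rows for the given rsids (those present), in stored order."""
        keep = self.table["rsid"].isin(set(rsids))
        return self.table.loc[keep].reset_index(drop=True)


def _validate_table(table: pd.DataFrame, trait_type: str):
    """Coerce dtypes, drop invariant-violating rows, dedup rsids."""
    report = LoadReport(n_input=len(table))
    df = table.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]

    df["rsid"] = df["rsid"].astype(str).str.strip()
    df["chrom"] = df["chrom"].astype(str).str.strip()
    for col in ("pos", "eaf", "beta", "se", "pval", "n", "n_cases", "n_controls"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.strip().str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.strip().str.upper()

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            report.add(reason, n)
            df = df.loc[~mask]

    drop(df["rsid"].isin(("", "nan", "None", ".")), "missing_rsid")
    drop(df["beta"].isna() | df["se"].isna() | df["pval"].isna(), "missing_value")
    drop(df["pos"].isna(), "missing_position")
    drop(~(df["se"] > 0), "nonpositive_se")
    drop(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval_out_of_range")
    drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    bad_eaf = df["eaf"].notna() & ~((df["eaf"] >= 0) & (df["eaf"] <= 1))
    drop(bad_eaf, "eaf_out_of_range")
    if trait_type == "binary":
        both = df["n_cases"].notna() & df["n_controls"].notna()
        # fill n from the counts where absent, then require consistency
        df.loc[both & df["n"].isna(), "n"] = (
            df.loc[both, "n_cases"] + df.loc[both, "n_controls"]
        )
        mismatch = both & df["n"].notna() & (
            (df["n_cases"] + df["n_controls"] - df["n"]).abs() > 0.5
        )
        drop(mismatch, "case_control_mismatch")

    # duplicate rsids: keep the smallest p-value (ties by row order)
    if df["rsid"].duplicated().any():
        n_dup = int(df["rsid"].duplicated().sum())
        df = df.sort_values("pval", kind="stable").drop_duplicates("rsid")
        df = df.sort_index()
        report.add("duplicate_rsid", n_dup)

    df["pos"] = df["pos"].astype(np.int64)
    report.n_kept = len(df)
    return df, report


def _resolve_dialect(dialect) -> dict[str, str]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise FormatError(f"unknown dialect {dialect!r}") from None
    return dict(dialect)


def read_summary_stats(
    path,
    dialect: str | Mapping[str, str] = "generic",
    trait_id: Optional[str] = None,
    trait_type: Optional[str] = None,
    provenance: Optional[str] = None,
) -> SummaryStats:
    """Load a summary-statistics file.

    Parameters
    ----------
    path : path-like
        Tab-separated file, optionally gzip-compressed (``.gz``).
    dialect : str or mapping
        Dialect name (``"generic"``, ``"finngen"``) or an explicit
        ``{canonical: source}`` column mapping.
    trait_id : str, optional
        Defaults to the file stem.
    trait_type : {"continuous", "binary"}, optional
        Inferred as binary when case/control counts are present.

    Raises
    ------
    FormatError
        A required column is missing; the message names it.
    EmptyInputError
        No row survives validation.
    """
    path = Path(path)
    mapping = _resolve_dialect(dialect)
    raw = pd.read_csv(path, sep="\t", compression="infer", dtype={})
    missing = [
        src for canon, src in mapping.items()
        if canon in REQUIRED_COLUMNS and src not in raw.columns
    ]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(sorted(missing))}"
        )
    data = {}
    for canon, src in mapping.items():
        if src in raw.columns:
            data[canon] = raw[src]
    df = pd.DataFrame(data)

    if trait_type is None:
        has_counts = "n_cases" in df.columns and df["n_cases"].notna().any()
        trait_type = "binary" if has_counts else "continuous"
    if trait_id is None:
        trait_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    return SummaryStats(
        trait_id,
        trait_type,
        df,
        provenance=provenance if provenance is not None else str(path),
    )


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write ``stats`` as a generic-dialect TSV (gzip if the path ends .gz).

    Floats are printed with 17 significant digits so that a read-back
    round-trips every value exactly.
    """
    if len(stats) == 0:  # defensive; construction already forbids this
        raise EmptyInputError("refusing to write an empty summary-statistics set")
    cols = CANONICAL_COLUMNS[:10]
    if stats.trait_type == "binary":
        cols = CANONICAL_COLUMNS
    out = stats.table[cols]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
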