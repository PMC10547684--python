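"""Species trait tables: loading, validation, research-intensity subsets.

The table holds one row per species with binary behavioural traits
(male/female same-sex sexual behaviour, sociality, sex-specific adulticide),
the context in which SSB was observed (wild / captivity / both / unknown),
display types, age class, a per-species citation count (research-effort
proxy) and a multi-year/multi-site study flag.

Four nested research-intensity subsets address false negatives from
under-studied species:

I   every species in the table;
II  species whose SSB was observed only in captivity are removed
    (their record is dropped, not recoded to absent);
III only species studied in the wild across multiple years or sites;
IV  only heavily cited species (citations >= threshold by default; the
    published criterion is self-contradictory, so the direction is
    configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "load_trait_table",
    "apply_subset",
    "summarize_prevalence",
    "PrevalenceSummary",
    "normalize_species_name",
    "DEFAULT_DIALECT",
]

REQUIRED_COLUMNS = (
    "species", "male_ssb", "female_ssb", "observed_context", "sociality",
    "adulticide_male", "adulticide_female", "citations",
)
OPTIONAL_COLUMNS = (
    "display_types", "age_class", "studied_multi_year_site",
)
BINARY_COLUMNS = (
    "male_ssb", "female_ssb", "sociality", "adulticide_male",
    "adulticide_female", "studied_multi_year_site",
)
CONTEXTS = ("wild", "captivity", "both", "unknown")
AGE_CLASSES = ("adult", "young", "both", "unknown")
DISPLAY_TYPES = ("courtship", "mounting_genital", "copulation", "pair_bonding")

DEFAULT_DIALECT: dict[str, str] = {c: c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}

SUBSETS = ("I", "II", "III", "IV")


class TraitTableError(ValueError):
    pass


def normalize_species_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Case-insensitive, underscore/space-insensitive species key."""
    key = str(name).strip().replace(" ", "_").lower()
    if synonyms:
        norm_syn = {normalize_species_name(k): v for k, v in synonyms.items()}
        if key in norm_syn:
            key = normalize_species_name(norm_syn[key])
    return key


@dataclass
class TraitTable:
    """A validated species trait table.

    ``data`` is a DataFrame with the canonical columns; ``provenance`` labels
    where it came from (file path, subset id, generator seed ...).
    """

    data: pd.DataFrame
    provenance: str = ""
    rejected: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        missing_req = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing_req:
            raise TraitTableError(f"missing required column(s) {missing_req}")
        for c in OPTIONAL_COLUMNS:
            if c not in self.data.columns:
                self.data[c] = np.nan
        keys = self.data["species"].map(normalize_species_name)
        dup = keys[keys.duplicated()]
        if not dup.empty:
            raise TraitTableError(
                f"duplicate species after normalization: {sorted(set(dup))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    def ssb_any(self) -> pd.Series:
        return (self.data["male_ssb"].fillna(0).astype(int)
                | self.data["female_ssb"].fillna(0).astype(int)).astype(bool)

    def n_ssb_positive(self) -> int:
        return int(self.ssb_any().sum())

    def binary_map(self, column: str, *, dropna: bool = True) -> dict[str, int]:
        """species -> 0/1 map for one binary column (missing rows dropped)."""
        s = self.data.set_index("species")[column]
        if dropna:
            s = s.dropna()
        return {k: int(v) for k, v in s.items()}

    def completeness_report(self) -> pd.Series:
        """Fraction of non-missing values per column (never silently imputed)."""
        return self.data.notna().mean()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _coerce_binary(series: pd.Series, column: str) -> tuple[pd.Series, pd.Series]:
    """Returns coerced values and a boolean mask of invalid rows."""
    raw = series.replace({"": np.nan, "NA": np.nan, "na": np.nan, None: np.nan})
    num = pd.to_numeric(raw, errors="coerce")
    bad = raw.notna() & (num.isna() | ~num.isin((0, 1)))
    return num.where(num.isin((0, 1))), bad


def load_trait_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    provenance: str | None = None,
) -> TraitTable:
    """Load and validate a trait table from CSV.

    ``dialect`` maps canonical column names to the CSV's column names.  Rows
    failing validation are rejected and reported on ``TraitTable.rejected``
    with a per-row reason; a missing required column is a configuration error.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, dtype={dialect["species"]: str})
    missing = [c for c in REQUIRED_COLUMNS if dialect[c] not in df.columns]
    if missing:
        raise TraitTableError(
            f"missing required column(s) {missing} in {path} (dialect: "
            f"{ {c: dialect[c] for c in missing} })"
        )
    out = pd.DataFrame()
    for canonical in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        src = dialect.get(canonical)
        out[canonical] = df[src] if src in df.columns else np.nan

    reasons = pd.Series("", index=out.index, dtype=object)
    for col in BINARY_COLUMNS:
        if out[col].notna().any():
            vals, bad = _coerce_binary(out[col], col)
            out[col] = vals
            reasons[bad] += f"{col} not in {{0,1}}; "
    cites = pd.to_numeric(out["citations"], errors="coerce")
    bad_c = out["citations"].notna() & (cites.isna() | (cites < 0))
    reasons[bad_c] += "citations must be a non-negative integer; "
    out["citations"] = cites.where(cites >= 0)
    ctx = out["observed_context"].fillna("unknown").astype(str).str.strip().str.lower()
    bad_ctx = ~ctx.isin(CONTEXTS)
    reasons[bad_ctx] += f"observed_context not in {CONTEXTS}; "
    out["observed_context"] = ctx
    out["age_class"] = (
        out["age_class"].fillna("unknown").astype(str).str.strip().str.lower()
    )
    out["display_types"] = out["display_types"].fillna("").astype(str)

    bad_rows = reasons.str.len() > 0
    rejected = None
    if bad_rows.any():
        rejected = out[bad_rows].assign(reason=reasons[bad_rows].str.rstrip("; "))
        out = out[~bad_rows]
    table = TraitTable(out, provenance=provenance or str(path))
    table.rejected = rejected
    return table


def apply_subset(
    table: TraitTable,
    subset: str,
    citation_threshold: int = 1000,
    *,
    invert_citation_filter: bool = False,
) -> TraitTable:
    """Restrict the table to one of the research-intensity subsets I-IV.

    Subset IV keeps species with ``citations >= citation_threshold`` (the
    well-studied set); ``invert_citation_filter`` keeps the complement.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; choose from {SUBSETS}")
    df = table.data
    if subset == "I":
        kept = df
    elif subset == "II":
        ssb = (df["male_ssb"].fillna(0).astype(int)
               | df["female_ssb"].fillna(0).astype(int)).astype(bool)
        captivity_only = ssb & (df["observed_context"] == "captivity")
        kept = df[~captivity_only]
    elif subset == "III":
        kept = df[df["studied_multi_year_site"].fillna(0).astype(int) == 1]
    else:  # IV
        cites = df["citations"]
        if cites.isna().any():
            raise TraitTableError(
                "subset IV requires a complete citations column; "
                f"{int(cites.isna().sum())} rows are missing it"
            )
        if invert_citation_filter:
            kept = df[cites < citation_threshold]
        else:
            kept = df[cites >= citation_threshold]
    prov = f"{table.provenance}|subset {subset}" if table.provenance else f"subset {subset}"
    if table.provenance.endswith(f"subset {subset}"):
        prov = table.provenance  # idempotent re-application
    return TraitTable(kept.copy(), provenance=prov)


@dataclass
class PrevalenceSummary:
    """Counts of SSB species overall and broken down by sex, display, context.

    Percentages are relative to the SSB-positive set and are NaN when that
    set is empty.
    """

    n_species: int
    n_ssb: int
    n_male: int
    n_female: int
    n_both_sexes: int
    by_display: dict[str, int]
    by_context: dict[str, int]

    def pct(self, count: int) -> float:
        return float("nan") if self.n_ssb == 0 else 100.0 * count / self.n_ssb

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("all_species", self.n_species, np.nan),
            ("ssb_any", self.n_ssb, self.pct(self.n_ssb)),
            ("ssb_male", self.n_male, self.pct(self.n_male)),
            ("ssb_female", self.n_female, self.pct(self.n_female)),
            ("ssb_both_sexes", self.n_both_sexes, self.pct(self.n_both_sexes)),
        ]
        rows += [(f"display_{k}", v, self.pct(v)) for k, v in self.by_display.items()]
        rows += [(f"context_{k}", v, self.pct(v)) for k, v in self.by_context.items()]
        return pd.DataFrame(rows, columns=["quantity", "count", "pct_of_ssb"])


def summarize_prevalence(table: TraitTable) -> PrevalenceSummary:
    df = table.data
    male = df["male_ssb"].fillna(0).astype(int).astype(bool)
    female = df["female_ssb"].fillna(0).astype(int).astype(bool)
    ssb = male | female
    by_display = {}
    displays = df.loc[ssb, "display_types"].fillna("").astype(str)
    for d in DISPLAY_TYPES:
        by_display[d] = int(displays.str.contains(d).sum())
    by_context = {}
    for c in CONTEXTS:
        by_context[c] = int((df.loc[ssb, "observed_context"] == c).sum())
    return PrevalenceSummary(
        n_species=len(df),
        n_ssb=int(ssb.sum()),
        n_male=int(male.sum()),
        n_female=int(female.sum()),
        n_both_sexes=int((male & female).sum()),
        by_display=by_display,
        by_context=by_context,
    )
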