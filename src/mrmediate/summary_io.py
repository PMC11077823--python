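"""Data model and delimited-text IO for GWAS summary statistics.

A summary-statistics panel is one trait's per-SNP association table: identifier,
genomic location, effect/other allele, effect-allele frequency, additive effect
(beta; log-odds for binary traits), its standard error, p-value, and sample size.
Readers validate hard invariants row by row (positive SE, biallelic single-base
alleles, frequencies in [0, 1]) and drop offending rows with a logged reason
rather than failing, mirroring how heterogeneous public GWAS downloads are
cleaned in practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order for every panel written by this package.
PANEL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")

#: Default header dialect: GWAS-SSF-style names plus common community variants,
#: mapped to the internal schema. User-supplied dialects override these.
DEFAULT_DIALECT: Mapping[str, str] = {
    "snp_id": "snp_id",
    "rsid": "snp_id",
    "variant_id": "snp_id",
    "snp": "snp_id",
    "markername": "snp_id",
    "chrom": "chrom",
    "chromosome": "chrom",
    "chr": "chrom",
    "pos": "pos",
    "position": "pos",
    "base_pair_location": "pos",
    "bp": "pos",
    "effect_allele": "effect_allele",
    "ea": "effect_allele",
    "a1": "effect_allele",
    "other_allele": "other_allele",
    "oa": "other_allele",
    "a2": "other_allele",
    "non_effect_allele": "other_allele",
    "eaf": "eaf",
    "effect_allele_frequency": "eaf",
    "freq": "eaf",
    "beta": "beta",
    "se": "se",
    "standard_error": "se",
    "pvalue": "pvalue",
    "p_value": "pvalue",
    "p": "pvalue",
    "pval": "pvalue",
    "n": "n",
    "sample_size": "n",
}

LOG10_2 = math.log10(2.0)


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP's association with one trait (1-based position)."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str = ""
    pos: Optional[int] = None
    eaf: Optional[float] = None
    pvalue: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class ParseReport:
    """Accounting of what a reader kept, dropped, and flagged."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class SummaryPanel:
    """A named trait's summary statistics, one row per SNP, snp_id unique.

    Backed by a :class:`pandas.DataFrame` with the :data:`PANEL_COLUMNS` schema;
    row order is preserved from the source.
    """

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.df["snp_id"].duplicated().any():
            dup = self.df["snp_id"][self.df["snp_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id in panel {self.trait_name!r}: {dup}")
        self._index = {s: i for i, s in enumerate(self.df["snp_id"])}

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> SummaryAssociation:
        row = self.df.iloc[self._index[snp_id]]
        return _row_to_record(row)

    @property
    def records(self) -> Iterator[SummaryAssociation]:
        for _, row in self.df.iterrows():
            yield _row_to_record(row)

    def subset(self, snp_ids: Sequence[str]) -> "SummaryPanel":
        keep = [s for s in snp_ids if s in self._index]
        sub = self.df.iloc[[self._index[s] for s in keep]].reset_index(drop=True)
        return SummaryPanel(self.trait_name, self.trait_type, sub)

    @classmethod
    def from_records(
        cls,
        trait_name: str,
        records: Sequence[SummaryAssociation],
        trait_type: str = "quantitative",
    ) -> "SummaryPanel":
        df = pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in records],
                "chrom": [r.chrom for r in records],
                "pos": pd.array([r.pos for r in records], dtype="Int64"),
                "effect_allele": [r.effect_allele for r in records],
                "other_allele": [r.other_allele for r in records],
                "eaf": [np.nan if r.eaf is None else r.eaf for r in records],
                "beta": [r.beta for r in records],
                "se": [r.se for r in records],
                "pvalue": [
                    _two_sided_p(r.beta / r.se) if r.pvalue is None else r.pvalue
                    for r in records
                ],
                "n": [np.nan if r.n is None else r.n for r in records],
            }
        )
        return cls(trait_name, trait_type, df)


def _row_to_record(row: pd.Series) -> SummaryAssociation:
    return SummaryAssociation(
        snp_id=row["snp_id"],
        chrom="" if pd.isna(row["chrom"]) else str(row["chrom"]),
        pos=None if pd.isna(row["pos"]) else int(row["pos"]),
        effect_allele=row["effect_allele"],
        other_allele=row["other_allele"],
        eaf=None if pd.isna(row["eaf"]) else float(row["eaf"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pvalue=None if pd.isna(row["pvalue"]) else float(row["pvalue"]),
        n=None if pd.isna(row["n"]) else float(row["n"]),
    )


def _two_sided_p(z: float) -> float:
    # Clamp away from exact 0 so the (0, 1] domain invariant survives underflow.
    return max(2.0 * stats.norm.sf(abs(z)), 5e-324)


def _log10_two_sided_p(z: float) -> float:
    return LOG10_2 + stats.norm.logsf(abs(z)) / math.log(10.0)


def read_panel(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    trait_name: Optional[str] = None,
    trait_type: str = "quantitative",
) -> tuple[SummaryPanel, ParseReport]:
    """Read a TSV/CSV summary-statistics table into a validated panel.

    Rows violating hard invariants (non-biallelic or equal alleles, se <= 0,
    unparseable numerics, eaf outside [0, 1], p outside (0, 1], duplicate
    snp_id) are dropped and counted in the report. A reported p-value more than
    a factor of 10 discrepant from the two-sided normal p implied by |beta/se|
    triggers a validation warning, not a rejection. Missing p-values are filled
    from |beta/se|.

    Returns (panel, report). Missing mandatory columns are fatal.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update({k.lower(): v for k, v in dialect.items()})

    with open(path) as fh:
        first_line = fh.readline()
    sep = "\t" if "\t" in first_line else ","
    raw = pd.read_csv(
        path, sep=sep, na_values=["NA", "na", ""], float_precision="round_trip"
    )
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    raw = raw.rename(columns={c: mapping[c] for c in raw.columns if c in mapping})
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")

    report = ParseReport(n_rows=len(raw))
    df = pd.DataFrame(index=raw.index)
    df["snp_id"] = raw["snp_id"].astype(str)
    df["chrom"] = raw["chrom"].astype(str) if "chrom" in raw.columns else ""
    df["pos"] = (
        pd.to_numeric(raw["pos"], errors="coerce") if "pos" in raw.columns else np.nan
    )
    df["effect_allele"] = raw["effect_allele"].astype(str).str.upper()
    df["other_allele"] = raw["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(raw[col], errors="coerce") if col in raw.columns else np.nan

    drop_reason = pd.Series("", index=df.index, dtype=object)

    def _mark(mask: pd.Series, reason: str) -> None:
        mask = mask & (drop_reason == "")
        drop_reason[mask] = reason

    bad_allele = ~(
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
    )
    _mark(bad_allele, "allele not a single base in {A,C,G,T}")
    _mark(df["effect_allele"] == df["other_allele"], "effect allele equals other allele")
    _mark(df["beta"].isna(), "unparseable or missing beta")
    _mark(df["se"].isna() | (df["se"] <= 0), "se missing, unparseable, or <= 0")
    _mark(df["eaf"].notna() & ~df["eaf"].between(0.0, 1.0), "eaf outside [0, 1]")
    _mark(
        df["pvalue"].notna() & ~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        "pvalue outside (0, 1]",
    )
    _mark(df["snp_id"].duplicated(), "duplicate snp_id (first occurrence kept)")

    dropped_mask = drop_reason != ""
    for snp, reason in zip(df.loc[dropped_mask, "snp_id"], drop_reason[dropped_mask]):
        report.dropped.append((snp, reason))
    df = df[~dropped_mask].reset_index(drop=True)

    # p-vs-z consistency check (warning only), in log10 space to dodge underflow.
    has_p = df["pvalue"].notna()
    if has_p.any():
        z = (df.loc[has_p, "beta"] / df.loc[has_p, "se"]).abs().to_numpy()
        lp_implied = LOG10_2 + stats.norm.logsf(z) / math.log(10.0)
        lp_reported = np.log10(df.loc[has_p, "pvalue"].to_numpy())
        # below ~1e-300 the stored p saturates at the float minimum; skip
        inconsistent = (np.abs(lp_reported - lp_implied) > 1.0) & (lp_implied > -300)
        for snp, lr, li in zip(
            df.loc[has_p, "snp_id"].to_numpy()[inconsistent],
            lp_reported[inconsistent],
            lp_implied[inconsistent],
        ):
            report.warnings.append(
                f"{snp}: reported p (1e{lr:.2f}) inconsistent with |beta/se| "
                f"(implies 1e{li:.2f}) by more than a factor of 10"
            )
    fill = df["pvalue"].isna()
    if fill.any():
        z = (df.loc[fill, "beta"] / df.loc[fill, "se"]).abs().to_numpy()
        df.loc[fill, "pvalue"] = np.maximum(2.0 * stats.norm.sf(z), 5e-324)

    df["pos"] = df["pos"].round().astype("Int64")
    df = df[list(PANEL_COLUMNS)]
    report.n_kept = len(df)
    report.n_dropped = len(report.dropped)
    if report.warnings:
        warnings.warn(
            f"{path}: {len(report.warnings)} row(s) with p-values inconsistent "
            f"with |beta/se|; see parse report",
            stacklevel=2,
        )

    name = trait_name if trait_name is not None else str(path)
    return SummaryPanel(name, trait_type, df), report


def write_panel(panel: SummaryPanel, path) -> None:
    """Write a panel as TSV with the canonical column order; NA for missing.

    Floats are serialized at full repr precision so read_panel(write_panel(p))
    reproduces every numeric field bit-equal.
    """
    df = panel.df[list(PANEL_COLUMNS)]
    # default float formatting is the shortest round-trip repr; paired with
    # round_trip parsing in read_panel this makes read(write(p)) bit-equal
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
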