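"""Instrument selection, strength filtering, cis restriction, and harmonization.

Instruments are SNPs passing a significance threshold on the exposure, pruned
to near-independence by greedy LD clumping (strongest association kept within
each window), strength-filtered on the per-SNP F statistic, and finally aligned
allele-by-allele to the outcome panel. Palindromic (A/T, C/G) variants, whose
strand cannot be resolved from alleles alone, are removed outright during
harmonization, as are pairs whose alleles cannot be reconciled by swap and/or
strand complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .summary_io import SummaryPanel

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G allele pairs are strand-ambiguous."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered SNP list.

    Pairs absent from the matrix are treated as unlinked (r² = 0).
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.size and (self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12):
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2_between(self, a: str, b: str) -> float:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    @classmethod
    def read(cls, path) -> "LDMatrix":
        """Read square (header row+column of snp_ids) or long (snp_a, snp_b, r2) TSV."""
        df = pd.read_csv(path, sep=None, engine="python")
        cols = [c.lower() for c in df.columns]
        if cols[:3] == ["snp_a", "snp_b", "r2"] or set(cols) == {"snp_a", "snp_b", "r2"}:
            df.columns = cols
            ids = sorted(set(df["snp_a"]) | set(df["snp_b"]))
            idx = {s: i for i, s in enumerate(ids)}
            mat = np.eye(len(ids))
            for a, b, r in zip(df["snp_a"], df["snp_b"], df["r2"]):
                mat[idx[a], idx[b]] = r
                mat[idx[b], idx[a]] = r
            return cls(ids, mat)
        ids = [str(s) for s in df.iloc[:, 0]]
        mat = df.iloc[:, 1:].to_numpy(dtype=float)
        return cls(ids, mat)


@dataclass
class InstrumentSet:
    """Retained exposure-side instruments plus per-SNP F statistics and an audit log."""

    exposure_name: str
    df: pd.DataFrame  # PANEL_COLUMNS schema + "f_stat"
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def k(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    @property
    def f_stats(self) -> pd.Series:
        return self.df.set_index("snp_id")["f_stat"]

    @property
    def is_empty(self) -> bool:
        return len(self.df) == 0


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to shared effect alleles.

    Betas refer, SNP by SNP, to the same effect allele on both sides; flips
    records where the outcome beta was negated to achieve that. No palindromic
    SNP is retained.
    """

    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    flips: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    removed_palindromic: list[str] = field(default_factory=list)
    log: list[tuple[str, str]] = field(default_factory=list)
    exposure_name: str = ""
    outcome_name: str = ""
    outcome_type: str = "quantitative"

    def __post_init__(self) -> None:
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        k = len(self.beta_x)
        if not (len(self.se_x) == len(self.beta_y) == len(self.se_y) == k):
            raise ValueError("beta/se arrays must have equal length")
        if not self.snp_ids:
            self.snp_ids = [f"snp{i + 1}" for i in range(k)]
        if len(self.flips) != k:
            self.flips = np.zeros(k, dtype=bool)
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be > 0")

    @property
    def k(self) -> int:
        return len(self.beta_x)

    def subset(self, keep: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HarmonizedSet(
            beta_x=self.beta_x[keep],
            se_x=self.se_x[keep],
            beta_y=self.beta_y[keep],
            se_y=self.se_y[keep],
            snp_ids=[self.snp_ids[i] for i in keep],
            flips=self.flips[keep],
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            outcome_type=self.outcome_type,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
                "flipped": self.flips,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "HarmonizedSet":
        return cls(
            beta_x=df["beta_x"].to_numpy(float),
            se_x=df["se_x"].to_numpy(float),
            beta_y=df["beta_y"].to_numpy(float),
            se_y=df["se_y"].to_numpy(float),
            snp_ids=list(df["snp_id"].astype(str)),
            flips=df["flipped"].to_numpy(bool) if "flipped" in df else np.array([], bool),
            **kwargs,
        )


def f_statistic(rec) -> float:
    """Per-SNP instrument strength, F = (beta/se)² (summary-data approximation)."""
    return (rec.beta / rec.se) ** 2


def _f_column(df: pd.DataFrame) -> pd.Series:
    return (df["beta"] / df["se"]) ** 2


def select_instruments(
    panel: SummaryPanel,
    p_thresh: float = 1e-5,
    ld: Optional[LDMatrix] = None,
    window_kb: float = 10_000.0,
    r2_max: float = 0.001,
) -> InstrumentSet:
    """Greedy LD clumping of significance-passing SNPs.

    SNPs with p < p_thresh are ranked by ascending p (ties broken by larger
    |beta/se|, then lexicographic snp_id). The best is kept; any remaining
    candidate on the same chromosome within window_kb and with r² >= r2_max
    against a kept SNP is discarded; repeat. Without an LD matrix, clumping is
    distance-only: any same-chromosome candidate within the window of a kept
    SNP is discarded (one SNP per window).
    """
    df = panel.df
    log: list[tuple[str, str, str]] = []
    passing = df[df["pvalue"] < p_thresh].copy()
    for snp in df.loc[df["pvalue"] >= p_thresh, "snp_id"]:
        log.append((snp, "excluded", f"p >= {p_thresh:g}"))
    if len(passing) == 0:
        warnings.warn(
            f"no SNP in panel {panel.trait_name!r} passes p < {p_thresh:g}",
            stacklevel=2,
        )
        empty = df.iloc[0:0].copy()
        empty["f_stat"] = pd.Series(dtype=float)
        return InstrumentSet(panel.trait_name, empty.reset_index(drop=True), log)

    if passing["pos"].isna().any() or (passing["chrom"] == "").any():
        raise ValueError("clumping requires chrom and pos on all candidate SNPs")

    passing["_absz"] = (passing["beta"] / passing["se"]).abs()
    passing = passing.sort_values(
        ["pvalue", "_absz", "snp_id"], ascending=[True, False, True]
    )

    kept_rows = []
    window_bp = window_kb * 1000.0
    for row in passing.itertuples():
        conflict = None
        for krow in kept_rows:
            if row.chrom == krow.chrom and abs(row.pos - krow.pos) <= window_bp:
                if ld is None:
                    conflict = (krow.snp_id, "within clump window (no LD matrix)")
                    break
                r2 = ld.r2_between(row.snp_id, krow.snp_id)
                if r2 >= r2_max:
                    conflict = (krow.snp_id, f"r2={r2:g} >= {r2_max:g}")
                    break
        if conflict is None:
            kept_rows.append(row)
            log.append((row.snp_id, "kept", f"p={row.pvalue:g}"))
        else:
            log.append((row.snp_id, "removed", f"{conflict[1]} vs {conflict[0]}"))

    kept_ids = [r.snp_id for r in kept_rows]
    out = df[df["snp_id"].isin(kept_ids)].copy()
    # emit rows in selection-priority order so output is input-order invariant
    rank = {s: i for i, s in enumerate(kept_ids)}
    out = out.sort_values("snp_id", key=lambda s: s.map(rank)).reset_index(drop=True)
    out["f_stat"] = _f_column(out)
    return InstrumentSet(panel.trait_name, out, log)


def filter_weak(iset: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Remove weak instruments (F < f_min); removals are logged."""
    log = list(iset.selection_log)
    keep = iset.df["f_stat"] >= f_min
    for snp, f in zip(iset.df.loc[~keep, "snp_id"], iset.df.loc[~keep, "f_stat"]):
        log.append((snp, "removed", f"weak instrument F={f:.3g} < {f_min:g}"))
    out = iset.df[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn(
            f"all instruments for {iset.exposure_name!r} removed as weak", stacklevel=2
        )
    return InstrumentSet(iset.exposure_name, out, log)


def select_cis_instruments(
    biomarker: SummaryPanel,
    gene_region: tuple[str, int, int],
    flank_kb: float = 100.0,
    eqtl: Optional[SummaryPanel] = None,
    eqtl_p_thresh: float = 1e-4,
    p_thresh: float = 1e-5,
    ld: Optional[LDMatrix] = None,
    window_kb: float = 10_000.0,
    r2_max: float = 0.001,
) -> InstrumentSet:
    """Drug-target (cis) instruments oriented to the biomarker-lowering direction.

    Restricts the biomarker panel to the gene region ± flank_kb (1-based
    inclusive bounds), optionally requires eQTL support (eqtl p < eqtl_p_thresh
    for the gene's expression), clumps as usual, then recodes each SNP so its
    effect allele is the biomarker-LOWERING allele: a positive exposure beta
    always means a lowering (target-inhibiting) effect.
    """
    chrom, start, end = gene_region
    lo = start - flank_kb * 1000.0
    hi = end + flank_kb * 1000.0
    df = biomarker.df
    in_region = (df["chrom"].astype(str) == str(chrom)) & df["pos"].notna()
    pos = df["pos"].astype("float")
    in_region &= (pos >= lo) & (pos <= hi)
    sub = df[in_region].reset_index(drop=True)
    if len(sub) == 0:
        warnings.warn(f"no SNPs within {flank_kb} kb of region {gene_region}", stacklevel=2)
    if eqtl is not None and len(sub) > 0:
        supported = [
            s
            for s in sub["snp_id"]
            if s in eqtl and (eqtl.get(s).pvalue or 1.0) < eqtl_p_thresh
        ]
        sub = sub[sub["snp_id"].isin(supported)].reset_index(drop=True)
    region_panel = SummaryPanel(biomarker.trait_name, biomarker.trait_type, sub)
    iset = select_instruments(region_panel, p_thresh, ld, window_kb, r2_max)

    out = iset.df.copy()
    log = list(iset.selection_log)
    raising = out["beta"] > 0
    for snp in out.loc[raising, "snp_id"]:
        log.append((snp, "oriented", "effect allele recoded to the lowering allele"))
    ea = out["effect_allele"].where(~raising, out["other_allele"])
    oa = out["other_allele"].where(~raising, out["effect_allele"])
    out["effect_allele"], out["other_allele"] = ea, oa
    out.loc[raising, "eaf"] = 1.0 - out.loc[raising, "eaf"]
    # On the inhibition-exposure scale the per-allele effect is the magnitude
    # of biomarker lowering conferred by the (now) effect allele.
    out["beta"] = out["beta"].abs()
    return InstrumentSet(iset.exposure_name, out, log)


def harmonize(exposure: InstrumentSet, outcome: SummaryPanel) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles, SNP by SNP.

    Rules: identical allele pair — keep; swapped pair — negate the outcome beta;
    pairs matching only after strand complement (A<->T, C<->G) — complement then
    apply the same two cases. Palindromic SNPs and irreconcilable ("ambiguous")
    pairs are removed and recorded; SNPs absent from the outcome are dropped
    with a log entry.
    """
    if exposure.is_empty:
        raise ValueError("cannot harmonize an empty instrument set")
    bx, sx, by, sy = [], [], [], []
    ids: list[str] = []
    flips: list[bool] = []
    removed_palindromic: list[str] = []
    log: list[tuple[str, str]] = []

    for row in exposure.df.itertuples():
        ea, oa = row.effect_allele, row.other_allele
        if is_palindromic(ea, oa):
            removed_palindromic.append(row.snp_id)
            log.append((row.snp_id, "removed: palindromic"))
            continue
        if row.snp_id not in outcome:
            log.append((row.snp_id, "dropped: absent from outcome panel"))
            continue
        orec = outcome.get(row.snp_id)
        pair = (orec.effect_allele, orec.other_allele)
        cpair = (COMPLEMENT[orec.effect_allele], COMPLEMENT[orec.other_allele])
        if pair == (ea, oa):
            flip = False
        elif pair == (oa, ea):
            flip = True
        elif cpair == (ea, oa):
            flip = False
            log.append((row.snp_id, "strand complemented"))
        elif cpair == (oa, ea):
            flip = True
            log.append((row.snp_id, "strand complemented"))
        else:
            log.append((row.snp_id, "removed: ambiguous alleles"))
            continue
        ids.append(row.snp_id)
        bx.append(row.beta)
        sx.append(row.se)
        by.append(-orec.beta if flip else orec.beta)
        sy.append(orec.se)
        flips.append(flip)
        if flip:
            log.append((row.snp_id, "outcome beta negated (allele swap)"))

    if not ids:
        warnings.warn("harmonization left no usable SNPs", stacklevel=2)
    return HarmonizedSet(
        beta_x=np.array(bx),
        se_x=np.array(sx),
        beta_y=np.array(by),
        se_y=np.array(sy),
        snp_ids=ids,
        flips=np.array(flips, dtype=bool),
        removed_palindromic=removed_palindromic,
        log=log,
        exposure_name=exposure.exposure_name,
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
    )
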