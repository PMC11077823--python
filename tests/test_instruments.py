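import itertools

import numpy as np
import pandas as pd
import pytest

from mrmediate.estimators import wald_ratio
from mrmediate.instruments import (
    HarmonizedSet,
    InstrumentSet,
    LDMatrix,
    f_statistic,
    filter_weak,
    harmonize,
    select_cis_instruments,
    select_instruments,
)
from mrmediate.summary_io import SummaryAssociation, SummaryPanel


def make_panel(rows, name="exposure", trait_type="quantitative"):
    """rows: (snp_id, chrom, pos, ea, oa, beta, se, pvalue)."""
    recs = [
        SummaryAssociation(r[0], r[3], r[4], r[5], r[6], chrom=str(r[1]), pos=r[2], pvalue=r[7])
        for r in rows
    ]
    return SummaryPanel.from_records(name, recs, trait_type)


def to_instruments(panel):
    df = panel.df.copy()
    df["f_stat"] = (df["beta"] / df["se"]) ** 2
    return InstrumentSet(panel.trait_name, df)


# ---------------------------------------------------------------- F statistic


def test_f_statistic_arithmetic():
    assert f_statistic(SummaryAssociation("a", "A", "G", 2.0, 1.0)) == 4.0
    assert f_statistic(SummaryAssociation("a", "A", "G", 0.0, 0.1)) == 0.0
    # z = 7.681 squares to ~59, the magnitude of a strong single drug-target SNP
    f = f_statistic(SummaryAssociation("a", "A", "G", 7.681e-2, 1e-2))
    assert f == pytest.approx(59.0, abs=0.05)


def test_filter_weak():
    panel = make_panel(
        [
            ("rs1", 1, 100, "A", "G", 0.2, 0.1, 1e-6),  # F = 4
            ("rs2", 1, 200, "A", "G", 0.4, 0.1, 1e-6),  # F = 16
            ("rs3", 1, 300, "A", "G", 0.768, 0.1, 1e-6),  # F = 59
        ]
    )
    iset = to_instruments(panel)
    kept = filter_weak(iset, f_min=10)
    assert kept.snp_ids == ["rs2", "rs3"]
    assert any("weak" in msg for _, _, msg in kept.selection_log)
    # all instruments at F >= 16 pass untouched (the drug-target panel regime)
    again = filter_weak(kept, f_min=10)
    assert again.snp_ids == ["rs2", "rs3"]
    assert kept.f_stats.min() >= 16 - 1e-9


# ------------------------------------------------------------------- clumping


def test_single_candidate_retained():
    panel = make_panel([("rs1", 1, 1000, "A", "G", 0.5, 0.05, 1e-8)])
    iset = select_instruments(panel)
    assert iset.snp_ids == ["rs1"]


def test_ld_pair_keeps_best_p():
    panel = make_panel(
        [
            ("rs1", 1, 10_000, "A", "G", 0.57, 0.1, 1e-8),
            ("rs2", 1, 15_000, "C", "T", 0.49, 0.1, 1e-6),
        ]
    )
    ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
    iset = select_instruments(panel, ld=ld)
    assert iset.snp_ids == ["rs1"]


def test_no_ld_matrix_means_distance_only():
    panel = make_panel(
        [
            ("rs1", 1, 10_000, "A", "G", 0.57, 0.1, 1e-8),
            ("rs2", 1, 15_000, "C", "T", 0.49, 0.1, 1e-6),
            ("rs3", 2, 15_000, "C", "T", 0.49, 0.1, 1e-6),  # other chromosome
        ]
    )
    iset = select_instruments(panel)
    assert set(iset.snp_ids) == {"rs1", "rs3"}


def test_no_snp_passes_threshold_warns_empty():
    panel = make_panel([("rs1", 1, 1000, "A", "G", 0.1, 0.1, 0.5)])
    with pytest.warns(UserWarning, match="no SNP"):
        iset = select_instruments(panel)
    assert iset.is_empty


def brute_force_clump(snps, ld, window_bp, r2_max):
    """Independent reference clumper over explicit pairwise conflicts.

    snps: list of dicts with snp_id, chrom, pos, pvalue, absz. Conflicts are
    precomputed; candidates are consumed in (p, -|z|, id) order from a set.
    """
    conflict = {s["snp_id"]: set() for s in snps}
    for a, b in itertools.combinations(snps, 2):
        if a["chrom"] != b["chrom"] or abs(a["pos"] - b["pos"]) > window_bp:
            continue
        r2 = ld.r2_between(a["snp_id"], b["snp_id"]) if ld is not None else 1.0
        if ld is None or r2 >= r2_max:
            conflict[a["snp_id"]].add(b["snp_id"])
            conflict[b["snp_id"]].add(a["snp_id"])
    remaining = {s["snp_id"]: s for s in snps}
    kept = []
    while remaining:
        best = min(remaining.values(), key=lambda s: (s["pvalue"], -s["absz"], s["snp_id"]))
        kept.append(best["snp_id"])
        del remaining[best["snp_id"]]
        for other in conflict[best["snp_id"]]:
            remaining.pop(other, None)
    return sorted(kept)


def _oracle_check(panel, ld, p_thresh=1e-5, window_kb=10_000.0, r2_max=0.001):
    iset = select_instruments(panel, p_thresh, ld, window_kb, r2_max)
    snps = [
        dict(
            snp_id=r.snp_id,
            chrom=r.chrom,
            pos=r.pos,
            pvalue=r.pvalue,
            absz=abs(r.beta / r.se),
        )
        for r in panel.records
        if r.pvalue < p_thresh
    ]
    expected = brute_force_clump(snps, ld, window_kb * 1000, r2_max)
    assert sorted(iset.snp_ids) == expected
    return iset


def test_six_snp_fixture_matches_oracle(fixtures_dir):
    from mrmediate.summary_io import read_panel

    panel, _ = read_panel(fixtures_dir / "clump_panel.tsv", trait_name="clump")
    ld = LDMatrix.read(fixtures_dir / "clump_ld.tsv")
    iset = _oracle_check(panel, ld)
    assert set(iset.snp_ids) == {"rs6", "rs4", "rs1", "rs3"}


def test_clumper_matches_oracle_on_random_panels():
    rng = np.random.default_rng(20240507)
    for rep in range(40):
        k = int(rng.integers(2, 9))
        chrom = rng.choice(["1", "2"], k)
        pos = rng.integers(1, 30_000_000, k)
        z = rng.uniform(3, 9, k)
        se = np.full(k, 0.02)
        from scipy import stats

        pv = 2 * stats.norm.sf(z)
        rows = [
            (f"rs{i}", chrom[i], int(pos[i]), "A", "G", z[i] * se[i], se[i], pv[i])
            for i in range(k)
        ]
        panel = make_panel(rows, name=f"rand{rep}")
        # random sparse LD among same-chromosome pairs
        r2 = np.eye(k)
        for i, j in itertools.combinations(range(k), 2):
            if chrom[i] == chrom[j] and rng.random() < 0.5:
                r2[i, j] = r2[j, i] = rng.choice([0.0, 0.0005, 0.002, 0.3, 0.95])
        ld = LDMatrix([f"rs{i}" for i in range(k)], r2)
        _oracle_check(panel, ld, p_thresh=1e-2)


def test_clump_invariant_to_row_order():
    rng = np.random.default_rng(3)
    rows = [
        (f"rs{i}", "1", 1000 + 2000 * i, "A", "G", 0.3, 0.05, p)
        for i, p in enumerate([1e-8, 1e-8, 1e-7, 1e-9, 1e-6, 1e-8])
    ]
    ld = LDMatrix.identity([r[0] for r in rows])
    base = select_instruments(make_panel(rows), ld=ld).snp_ids
    for _ in range(5):
        shuffled = list(rows)
        rng.shuffle(shuffled)
        assert select_instruments(make_panel(shuffled), ld=ld).snp_ids == base


# ---------------------------------------------------------------- cis / LD IO


def test_cis_flank_and_orientation():
    panel = make_panel(
        [
            ("rs_in", 16, 1_000_000, "A", "G", 0.02, 0.002, 1e-7),  # raising allele
            ("rs_low", 16, 1_050_000, "C", "T", -0.015, 0.002, 1e-7),  # lowering allele
            ("rs_out", 16, 5_000_000, "A", "G", 0.02, 0.002, 1e-7),  # outside flank
            ("rs_chr", 2, 1_000_000, "A", "G", 0.02, 0.002, 1e-7),  # other chromosome
        ]
    )
    iset = select_cis_instruments(
        panel, ("16", 950_000, 1_100_000), flank_kb=100, ld=LDMatrix.identity([])
    )
    # identity LD keeps both in-region SNPs; orientation makes betas positive
    assert set(iset.snp_ids) == {"rs_in", "rs_low"}
    assert (iset.df["beta"] > 0).all()
    row_in = iset.df.set_index("snp_id").loc["rs_in"]
    assert (row_in["effect_allele"], row_in["other_allele"]) == ("G", "A")  # swapped
    row_low = iset.df.set_index("snp_id").loc["rs_low"]
    assert (row_low["effect_allele"], row_low["other_allele"]) == ("C", "T")  # unchanged


def test_cis_eqtl_filter():
    panel = make_panel(
        [
            ("rs1", 16, 1_000_000, "A", "G", -0.02, 0.002, 1e-7),
            ("rs2", 16, 1_200_000, "C", "T", -0.02, 0.002, 1e-8),
        ]
    )
    eqtl = make_panel(
        [
            ("rs1", 16, 1_000_000, "A", "G", 0.5, 0.05, 1e-9),
            ("rs2", 16, 1_200_000, "C", "T", 0.01, 0.05, 0.7),
        ],
        name="expression",
    )
    iset = select_cis_instruments(
        panel, ("16", 900_000, 1_300_000), eqtl=eqtl, ld=LDMatrix.identity([])
    )
    assert iset.snp_ids == ["rs1"]


def test_ld_matrix_validation_and_long_format(tmp_path):
    with pytest.raises(ValueError, match="symmetric"):
        LDMatrix(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        LDMatrix(["a", "b"], np.array([[0.9, 0.2], [0.2, 1.0]]))
    long = tmp_path / "ld_long.tsv"
    long.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.4\n")
    ld = LDMatrix.read(long)
    assert ld.r2_between("rs1", "rs2") == 0.4
    assert ld.r2_between("rs1", "rs_missing") == 0.0


# -------------------------------------------------------------- harmonization


def _exposure_set():
    return to_instruments(
        make_panel(
            [
                ("rs1", 1, 100, "A", "G", 0.1, 0.01, 1e-8),
                ("rs2", 1, 200, "C", "T", 0.2, 0.01, 1e-8),
                ("rs3", 1, 300, "G", "A", 0.3, 0.01, 1e-8),
                ("rs_pal", 1, 400, "A", "T", 0.1, 0.01, 1e-8),
                ("rs_amb", 1, 500, "A", "G", 0.1, 0.01, 1e-8),
                ("rs_missing", 1, 600, "A", "G", 0.1, 0.01, 1e-8),
            ]
        )
    )


def _outcome_panel():
    return make_panel(
        [
            ("rs1", 1, 100, "A", "G", 0.05, 0.02, 1e-2),  # identical alleles
            ("rs2", 1, 200, "T", "C", 0.04, 0.02, 1e-2),  # swapped
            ("rs3", 1, 300, "C", "T", 0.03, 0.02, 1e-2),  # strand complement of G/A
            ("rs_pal", 1, 400, "A", "T", 0.02, 0.02, 1e-2),
            ("rs_amb", 1, 500, "A", "C", 0.02, 0.02, 1e-2),  # irreconcilable
        ],
        name="outcome",
    )


def test_harmonize_cases():
    hset = harmonize(_exposure_set(), _outcome_panel())
    assert hset.snp_ids == ["rs1", "rs2", "rs3"]
    assert hset.beta_y[0] == pytest.approx(0.05) and not hset.flips[0]
    assert hset.beta_y[1] == pytest.approx(-0.04) and hset.flips[1]
    # C/T complements to G/A, matching the exposure pair directly -> no flip
    assert hset.beta_y[2] == pytest.approx(0.03) and not hset.flips[2]
    assert hset.removed_palindromic == ["rs_pal"]
    assert any("ambiguous" in msg for _, msg in hset.log)
    assert any("absent" in msg for _, msg in hset.log)


def test_harmonize_is_involution_safe():
    hset = harmonize(_exposure_set(), _outcome_panel())
    # re-expressing the harmonized outcome as a panel on the exposure's alleles
    # and harmonizing again must change nothing
    exp = _exposure_set()
    sub = exp.df[exp.df["snp_id"].isin(hset.snp_ids)].reset_index(drop=True)
    aligned = sub.copy()
    aligned["beta"] = hset.beta_y
    aligned["se"] = hset.se_y
    panel2 = SummaryPanel("outcome2", "quantitative", aligned)
    hset2 = harmonize(
        InstrumentSet(exp.exposure_name, sub.assign(f_stat=1.0)), panel2
    )
    np.testing.assert_allclose(hset2.beta_y, hset.beta_y)
    assert not hset2.flips.any()


def test_wald_ratio_invariant_to_allele_recoding():
    """Per-SNP causal ratios must not depend on which allele the files code as
    the effect allele, nor on strand."""
    rng = np.random.default_rng(11)
    exp = to_instruments(
        make_panel([("rs1", 1, 100, "A", "G", 0.25, 0.01, 1e-9)])
    )
    out_rows = [("rs1", 1, 100, "A", "G", 0.1, 0.02, 1e-3)]
    base = wald_ratio(harmonize(exp, make_panel(out_rows, name="o"))).beta
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for _ in range(10):
        ea, oa, beta = "A", "G", 0.1
        if rng.random() < 0.5:  # swap coded allele
            ea, oa, beta = oa, ea, -beta
        if rng.random() < 0.5:  # report the other strand
            ea, oa = comp[ea], comp[oa]
        recoded = make_panel([("rs1", 1, 100, ea, oa, beta, 0.02, 1e-3)], name="o")
        assert wald_ratio(harmonize(exp, recoded)).beta == pytest.approx(base, abs=1e-12)


def test_harmonize_empty_intersection_warns():
    exp = to_instruments(make_panel([("rsX", 1, 100, "A", "G", 0.1, 0.01, 1e-8)]))
    with pytest.warns(UserWarning, match="no usable"):
        hset = harmonize(exp, _outcome_panel())
    assert hset.k == 0
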