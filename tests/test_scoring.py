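"""PRS loading, harmonization and scoring arithmetic."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from famprs import scoring
from famprs.scoring import (
    GenotypePanel,
    compute_prs,
    harmonize,
    load_score_file,
    standardize,
)

from conftest import DOSAGES_TSV, VARIANTS_TSV, make_panel


def _score_from_rows(rows):
    header = "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
    return load_score_file(io.StringIO(header + "".join(rows)))


class TestLoadScoreFile:
    def test_or_column_becomes_log_weight(self):
        text = "rsID\teffect_allele\tother_allele\tOR\nrs1\tA\tG\t1.5\nrs2\tC\tT\t1.0\n"
        sf = load_score_file(io.StringIO(text))
        assert sf.weights["rs1"] == pytest.approx(math.log(1.5), abs=1e-6)
        assert sf.weights["rs2"] == 0.0

    def test_fixture_order_and_weights(self, score_file):
        assert score_file.variant_ids == ["rs1", "rs2", "rs3"]
        assert list(score_file.weights) == [0.1, -0.2, 0.3]

    def test_313_row_panel_dialect(self):
        rows = [f"rs{i}\t1\t{1000+i}\tA\tG\t0.01\n" for i in range(313)]
        sf = _score_from_rows(rows)
        assert len(sf) == 313
        assert sf.variant_ids[0] == "rs0" and sf.variant_ids[-1] == "rs312"

    @pytest.mark.parametrize(
        "text,match",
        [
            ("rsID\teffect_allele\tOR\nrs1\tA\t1.5\n", "other_allele"),
            ("rsID\teffect_allele\tother_allele\nrs1\tA\tG\n", "effect_weight or OR"),
            ("rsID\teffect_allele\tother_allele\tOR\nrs1\tA\tG\t0\n", "positive"),
            (
                "rsID\teffect_allele\tother_allele\tOR\nrs1\tA\tG\t1.5\nrs1\tC\tT\t1.2\n",
                "duplicate",
            ),
        ],
    )
    def test_malformed_tables_rejected(self, text, match):
        with pytest.raises(ValueError, match=match):
            load_score_file(io.StringIO(text))


class TestHarmonize:
    @pytest.mark.parametrize(
        "panel_alleles,status,complement",
        [
            (("A", "G"), "matched", False),
            (("G", "A"), "allele_swapped", True),
            (("T", "C"), "strand_flipped", False),  # reverse strand, same order
            (("C", "T"), "strand_flipped", True),  # reverse strand, swapped
        ],
    )
    def test_four_orientations(self, panel_alleles, status, complement):
        sf = _score_from_rows(["rs1\t1\t1000\tA\tG\t0.1\n"])
        panel = make_panel({"rs1": {"s1": 1}}, alleles={"rs1": panel_alleles})
        table = harmonize(sf, panel).table
        assert table.loc[0, "status"] == status
        assert bool(table.loc[0, "complement_dosage"]) is complement

    def test_palindromic_pairs_dropped(self):
        sf = _score_from_rows(["rs1\t1\t1\tA\tT\t0.1\n", "rs2\t1\t2\tC\tG\t0.1\n"])
        panel = make_panel(
            {"rs1": {"s1": 1}, "rs2": {"s1": 1}},
            alleles={"rs1": ("A", "T"), "rs2": ("C", "G")},
        )
        assert harmonize(sf, panel).counts["ambiguous_dropped"] == 2

    def test_allele_mismatch_dropped(self):
        sf = _score_from_rows(["rs1\t1\t1\tA\tG\t0.1\n"])
        panel = make_panel({"rs1": {"s1": 1}}, alleles={"rs1": ("A", "C")})
        assert harmonize(sf, panel).counts["ambiguous_dropped"] == 1

    def test_307_of_313_present(self):
        rows = [f"rs{i}\t1\t{1000+i}\tA\tG\t0.01\n" for i in range(313)]
        sf = _score_from_rows(rows)
        panel = make_panel({f"rs{i}": {"s1": 1, "s2": 0} for i in range(307)})
        report = harmonize(sf, panel)
        assert report.counts["absent_from_panel"] == 6
        assert report.n_contributing == 307


class TestComputePrs:
    def test_hand_computed_scores(self, score_file, panel):
        prs = compute_prs(score_file, panel, missing_policy="skip")
        # s1: 1*0.1 + 2*(-0.2) + 0*0.3 = -0.3  (spec-style brute force)
        assert prs.raw["s1"] == pytest.approx(-0.3)
        assert prs.raw["s2"] == 0.0
        # s3: rs3 missing under skip -> 2*0.1 + 1*(-0.2) = 0.0, 2 variants used
        assert prs.raw["s3"] == pytest.approx(0.0)
        assert prs.table.loc["s3", "n_variants_used"] == 2

    def test_single_variant_double_dose(self):
        sf = load_score_file(
            io.StringIO("rsID\teffect_allele\tother_allele\tOR\nrs1\tA\tG\t1.5\n")
        )
        panel = make_panel({"rs1": {"s1": 2}})
        prs = compute_prs(sf, panel)
        assert prs.raw["s1"] == pytest.approx(2 * math.log(1.5), abs=1e-6)

    def test_mean_dosage_fills_missing(self, score_file, panel):
        prs = compute_prs(score_file, panel, missing_policy="mean_dosage")
        # rs3 mean dosage over s1, s2 is 0 -> same raw score, full variant count
        assert prs.raw["s3"] == pytest.approx(0.0)
        assert prs.table.loc["s3", "n_variants_used"] == 3

    def test_policies_agree_without_missingness(self, score_file):
        panel = make_panel(
            {"rs1": {"a": 1, "b": 2}, "rs2": {"a": 0, "b": 1}, "rs3": {"a": 2, "b": 0}}
        )
        skip = compute_prs(score_file, panel, missing_policy="skip")
        mean = compute_prs(score_file, panel, missing_policy="mean_dosage")
        assert np.allclose(skip.raw, mean.raw)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        n_s, n_v = 9, 7
        ids = [f"v{j}" for j in range(n_v)]
        w = rng.normal(0, 0.2, n_v)
        D = rng.integers(0, 3, size=(n_s, n_v)).astype(float)
        D[rng.random((n_s, n_v)) < 0.15] = np.nan
        rows = [f"v{j}\t1\t{j}\tA\tG\t{w[j]}\n" for j in range(n_v)]
        sf = _score_from_rows(rows)
        panel = make_panel(
            {ids[j]: {f"s{i}": D[i, j] for i in range(n_s)} for j in range(n_v)}
        )
        prs = compute_prs(sf, panel, missing_policy="skip")
        for i in range(n_s):
            expect = sum(
                D[i, j] * w[j] for j in range(n_v) if not np.isnan(D[i, j])
            )
            assert prs.raw[f"s{i}"] == pytest.approx(expect)

    def test_weight_scaling_linearity(self, score_file, panel):
        base = compute_prs(score_file, panel).raw
        scaled_sf = scoring.ScoreFile(
            score_file.variants.assign(weight=score_file.variants["weight"] * 3.0)
        )
        assert np.allclose(compute_prs(scaled_sf, panel).raw, 3.0 * base)

    def test_orientation_correction_preserves_scores(self, score_file):
        d = {"rs1": {"a": 1, "b": 2}, "rs2": {"a": 0, "b": 1}, "rs3": {"a": 2, "b": 0}}
        straight = make_panel(d)
        # swap rs2's allele labels and complement its dosages
        swapped = make_panel(
            {k: ({s: 2 - v for s, v in vals.items()} if k == "rs2" else vals)
             for k, vals in d.items()},
            alleles={"rs1": ("A", "G"), "rs2": ("G", "A"), "rs3": ("A", "G")},
        )
        # fixture alleles must match the score file for rs1/rs3
        sf = _score_from_rows(
            ["rs1\t1\t1\tA\tG\t0.1\n", "rs2\t1\t2\tA\tG\t-0.2\n", "rs3\t1\t3\tA\tG\t0.3\n"]
        )
        r1, r2 = harmonize(sf, straight), harmonize(sf, swapped)
        assert r2.table.set_index("variant_id").loc["rs2", "status"] == "allele_swapped"
        assert np.allclose(
            compute_prs(sf, straight, r1).raw, compute_prs(sf, swapped, r2).raw
        )

    def test_no_contributing_variants_is_an_error(self, score_file):
        panel = make_panel({"other": {"s1": 1}})
        with pytest.raises(ValueError, match="contribute"):
            compute_prs(score_file, panel)


class TestStandardize:
    def test_unit_variance_reference(self, score_file):
        panel = make_panel(
            {"rs1": {"a": 0, "b": 1, "c": 2}, "rs2": {"a": 0, "b": 0, "c": 0},
             "rs3": {"a": 0, "b": 0, "c": 0}}
        )
        prs = standardize(compute_prs(score_file, panel))
        # raw scores 0, 0.1, 0.2 -> z = -1, 0, 1 with sd computed over n-1
        assert np.allclose(prs.z, [-1.0, 0.0, 1.0])
        assert prs.z.mean() == pytest.approx(0.0, abs=1e-12)
        assert prs.z.std(ddof=1) == pytest.approx(1.0)

    def test_reference_subset_transform_applies_to_all(self, score_file):
        panel = make_panel(
            {"rs1": {"a": 0, "b": 2, "c": 1}, "rs2": {"a": 0, "b": 0, "c": 0},
             "rs3": {"a": 0, "b": 0, "c": 0}}
        )
        prs = standardize(compute_prs(score_file, panel), reference=["a", "b"])
        mu, sd = 0.1, np.std([0.0, 0.2], ddof=1)
        assert prs.z["c"] == pytest.approx((0.1 - mu) / sd)

    def test_zero_variance_reference_rejected(self, score_file):
        panel = make_panel(
            {"rs1": {"a": 1, "b": 1}, "rs2": {"a": 0, "b": 0}, "rs3": {"a": 0, "b": 0}}
        )
        with pytest.raises(ValueError, match="variance"):
            standardize(compute_prs(score_file, panel))


class TestPanelIO:
    def test_dosage_tsv_roundtrip(self, panel, tmp_path):
        panel.to_dosage_tsv(tmp_path / "d.tsv", tmp_path / "v.tsv")
        back = GenotypePanel.from_dosage_tsv(tmp_path / "d.tsv", tmp_path / "v.tsv")
        pd.testing.assert_frame_equal(back.dosages, panel.dosages)

    def test_vcf_roundtrip(self, panel, tmp_path):
        from famprs.simdata import write_vcf

        path = tmp_path / "p.vcf"
        write_vcf(panel, path)
        back = GenotypePanel.from_vcf(path)
        assert back.sample_ids == panel.sample_ids
        assert np.isnan(back.dosages.loc["s3", "rs3"])
        got = back.dosages[panel.variant_ids]
        pd.testing.assert_frame_equal(got, panel.dosages, check_names=False)

    def test_bad_dosage_value_rejected(self):
        with pytest.raises(ValueError, match="dosage"):
            make_panel({"rs1": {"s1": 3}})
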