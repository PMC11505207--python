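import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import (
    DialectError,
    EmptyPanelError,
    HarmonizationError,
    SimulationParams,
    SummaryStats,
    beta_from_or,
    harmonize,
    is_palindromic,
    read_summary_stats,
    simulate_triple,
    write_summary_stats,
)
from tests.conftest import make_panel


def _write(tmp_path, name, header, rows):
    path = tmp_path / name
    lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


GENERIC_HEADER = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


class TestReadSummaryStats:
    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        path = _write(tmp_path, "x.tsv", GENERIC_HEADER, [
            ["rs1", "1", "100", "A", "G", "0.2", "0.1", "0.01", "1e-6", "5000"],
            ["rs2", "1", "200", "C", "T", "0.3", "0.2", "0", "1e-7", "5000"],
            ["rs3", "2", "300", "G", "A", "0.4", "-0.1", "0.02", "0.5", "5000"],
        ])
        stats = read_summary_stats(path, dialect="generic")
        assert stats.n_snps == 2
        assert list(stats.df["SNP"]) == ["rs1", "rs3"]
        assert stats.drops == {"nonpositive_se": 1}

    def test_finngen_dialect_uppercases_alleles(self, tmp_path):
        header = ["rsids", "#chrom", "pos", "alt", "ref", "af_alt", "beta", "sebeta", "pval"]
        path = _write(tmp_path, "fg.tsv", header, [
            ["rs1", "7", "100", "a", "t", "0.2", "0.1", "0.01", "1e-6"],
            ["rs2", "7", "500", "c", "g", "0.2", "0.1", "0.01", "1e-6"],
            ["rs3", "7", "900", "a", "c", "0.2", "0.1", "0.01", "1e-6"],
        ])
        stats = read_summary_stats(path, dialect="finngen", trait_type="binary")
        assert set(stats.df["EA"]) <= {"A", "C", "G", "T"}
        assert list(stats.df.loc[stats.df["SNP"] == "rs1", "EA"]) == ["A"]
        assert stats.df["N"].isna().all()  # dialect carries no sample size

    def test_gwascatalog_dialect(self, tmp_path):
        header = ["variant_id", "chromosome", "base_pair_location", "effect_allele",
                  "other_allele", "effect_allele_frequency", "beta", "standard_error",
                  "p_value"]
        path = _write(tmp_path, "gc.tsv", header, [
            ["rs9", "X", "100", "T", "C", "0.1", "0.05", "0.02", "0.01"],
        ])
        stats = read_summary_stats(path, dialect="gwascatalog")
        assert stats.df.loc[0, "CHR"] == "X"
        assert stats.df.loc[0, "BETA"] == pytest.approx(0.05)

    def test_missing_effect_column_raises_dialect_error(self, tmp_path):
        header = [c for c in GENERIC_HEADER if c != "BETA"]
        path = _write(tmp_path, "bad.tsv", header, [
            ["rs1", "1", "100", "A", "G", "0.2", "0.01", "1e-6", "5000"],
        ])
        with pytest.raises(DialectError, match="BETA"):
            read_summary_stats(path, dialect="generic")

    def test_indels_rejected(self, tmp_path):
        path = _write(tmp_path, "indel.tsv", GENERIC_HEADER, [
            ["rs1", "1", "100", "AT", "A", "0.2", "0.1", "0.01", "1e-6", "5000"],
            ["rs2", "1", "200", "A", "G", "0.2", "0.1", "0.01", "1e-6", "5000"],
        ])
        stats = read_summary_stats(path)
        assert stats.n_snps == 1
        assert stats.drops["non_biallelic_snp"] == 1

    def test_all_rows_invalid_raises_empty_panel(self, tmp_path):
        path = _write(tmp_path, "empty.tsv", GENERIC_HEADER, [
            ["rs1", "1", "100", "A", "G", "0.2", "NA", "0.01", "1e-6", "5000"],
        ])
        with pytest.raises(EmptyPanelError):
            read_summary_stats(path)

    def test_round_trip_preserves_fields(self, tmp_path):
        exposure, *_ = simulate_triple(SimulationParams(J=30, n_null_snps=70, seed=5))
        panel = SummaryStats("T1", "continuous", exposure.df.head(100).reset_index(drop=True))
        path = tmp_path / "rt.tsv"
        write_summary_stats(panel, path)
        back = read_summary_stats(path, dialect="generic", trait_id="T1")
        pd.testing.assert_frame_equal(back.df, panel.df, check_exact=True, check_dtype=False)


class TestBetaFromOr:
    @pytest.mark.parametrize(
        "or_v, l95, u95, beta, se",
        [
            (1.0, 1.0, 1.0, 0.0, 0.0),
            (1.060, 1.015, 1.108, 0.0583, 0.0224),
            (0.910, 0.844, 0.982, -0.0943, 0.0386),
        ],
    )
    def test_examples(self, or_v, l95, u95, beta, se):
        b, s = beta_from_or(or_v, l95, u95)
        assert b == pytest.approx(beta, abs=5e-5)
        assert s == pytest.approx(se, abs=5e-5)

    @pytest.mark.parametrize("args", [(0.0, 0.0, 0.0), (-1.0, 0.5, 2.0), (1.0, 1.2, 1.5)])
    def test_invalid_input_raises(self, args):
        with pytest.raises(ValueError):
            beta_from_or(*args)

    @given(
        beta=st.floats(-2, 2),
        se=st.floats(1e-6, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_recovers_or_scale(self, beta, se):
        from mrmediate import Z_95

        or_v = math.exp(beta)
        l95, u95 = math.exp(beta - Z_95 * se), math.exp(beta + Z_95 * se)
        b, s = beta_from_or(or_v, l95, u95)
        assert math.exp(b) == pytest.approx(or_v, rel=1e-6)
        assert math.exp(b - Z_95 * s) == pytest.approx(l95, rel=1e-6)
        assert math.exp(b + Z_95 * s) == pytest.approx(u95, rel=1e-6)


class TestIsPalindromic:
    @pytest.mark.parametrize("a1,a2,expected", [
        ("A", "T", True), ("T", "A", True), ("G", "C", True), ("C", "G", True),
        ("A", "G", False), ("C", "T", False), ("A", "C", False),
    ])
    def test_definition(self, a1, a2, expected):
        assert is_palindromic(a1, a2) is expected

    def test_invalid_allele_raises(self):
        with pytest.raises(ValueError):
            is_palindromic("A", "N")


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, beta_out=0.05):
        exp = make_panel([{"EA": exp_alleles[0], "OA": exp_alleles[1],
                           "BETA": 0.1, "P": 1e-8}], trait_id="E")
        out = make_panel([{"EA": out_alleles[0], "OA": out_alleles[1],
                           "BETA": beta_out, "P": 0.5}], trait_id="O")
        return exp, out

    def test_identity_orientation(self):
        exp, out = self._pair(("A", "G"), ("A", "G"))
        h = harmonize(exp, out)
        assert h.df.loc[0, "beta_out"] == pytest.approx(0.05)

    def test_swapped_alleles_flip_sign(self):
        exp, out = self._pair(("A", "G"), ("G", "A"))
        h = harmonize(exp, out)
        assert h.df.loc[0, "beta_out"] == pytest.approx(-0.05)

    def test_palindromic_removed_and_counted(self):
        exp, out = self._pair(("A", "T"), ("A", "T"))
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)  # the only SNP is palindromic -> empty
        exp2 = make_panel([
            {"EA": "A", "OA": "T", "BETA": 0.1, "P": 1e-8},
            {"EA": "A", "OA": "G", "BETA": 0.1, "P": 1e-8},
        ], trait_id="E")
        out2 = make_panel([
            {"EA": "A", "OA": "T", "BETA": 0.05, "P": 0.5},
            {"EA": "A", "OA": "G", "BETA": 0.05, "P": 0.5},
        ], trait_id="O")
        h = harmonize(exp2, out2)
        assert h.n_snp == 1
        assert h.n_dropped_palindromic == 1

    def test_incompatible_alleles_removed(self):
        exp, out = self._pair(("A", "G"), ("T", "C"))  # strand-flipped coding
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_missing_from_outcome_dropped(self):
        exp = make_panel([
            {"BETA": 0.1, "P": 1e-8},
            {"BETA": 0.1, "P": 1e-8},
        ], trait_id="E")
        out = make_panel([{"BETA": 0.05, "P": 0.5}], trait_id="O")
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert h.n_missing_outcome == 1

    def test_idempotent(self):
        exp, _, out, _, _ = simulate_triple(SimulationParams(seed=11, n_null_snps=20))
        h1 = harmonize(exp, out)
        # rebuild panels from the harmonized rows and harmonize again
        exp2 = make_panel([], trait_id="E")
        exp2.df = pd.DataFrame({
            "SNP": h1.df["SNP"], "CHR": h1.df["CHR"], "POS": h1.df["POS"],
            "EA": h1.df["EA"], "OA": h1.df["OA"], "EAF": 0.3,
            "BETA": h1.df["beta_exp"], "SE": h1.df["se_exp"],
            "P": 0.5, "N": 1000.0,
        })
        out2 = make_panel([], trait_id=out.trait_id)
        out2.df = exp2.df.assign(BETA=h1.df["beta_out"], SE=h1.df["se_out"])
        h2 = harmonize(exp2, out2)
        assert h2.n_snp == h1.n_snp
        assert h2.n_dropped_palindromic == 0
        np.testing.assert_allclose(h2.df["beta_out"], h1.df["beta_out"])
        np.testing.assert_allclose(h2.df["beta_exp"], h1.df["beta_exp"])

    @given(data=st.data())
    @settings(max_examples=100, derandomize=True)
    def test_never_emits_palindromic_rows(self, data):
        alleles = ["A", "C", "G", "T"]
        pairs = [(a, b) for a in alleles for b in alleles if a != b]
        n = data.draw(st.integers(2, 6))
        exp_pairs = [data.draw(st.sampled_from(pairs)) for _ in range(n)]
        out_pairs = [data.draw(st.sampled_from(pairs)) for _ in range(n)]
        exp = make_panel([{"EA": a, "OA": b, "BETA": 0.1, "P": 1e-8}
                          for a, b in exp_pairs], trait_id="E")
        out = make_panel([{"EA": a, "OA": b, "BETA": 0.05, "P": 0.5}
                          for a, b in out_pairs], trait_id="O")
        try:
            h = harmonize(exp, out)
        except HarmonizationError:
            return
        for _, row in h.df.iterrows():
            assert not is_palindromic(row["EA"], row["OA"])
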