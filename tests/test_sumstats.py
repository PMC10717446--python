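"""Reading, validation, harmonization and instrument selection."""

import pandas as pd
import pytest

from cannamr import (
    SimulationConfig,
    filter_palindromic,
    harmonize_pair,
    read_summary_stats,
    select_instruments,
    simulate_two_sample,
    write_summary_stats,
)
from cannamr.sumstats import ConfigurationError, InputError

from conftest import make_assoc, make_instrument


class TestReading:
    def test_clean_table_round_trip(self, tmp_path, sim_pair):
        path = tmp_path / "exposure.tsv"
        write_summary_stats(sim_pair.exposure_stats, path)
        result = read_summary_stats(path)
        assert len(result.records) == 64
        assert result.n_dropped == 0
        assert result.records[0] == sim_pair.exposure_stats[0]

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        df = pd.DataFrame(
            {
                "rsid": ["rs1", "rs2", "rs3"],
                "effect_allele": ["A", "A", "A"],
                "other_allele": ["G", "G", "G"],
                "eaf": [0.3, 0.3, 0.3],
                "beta": [0.1, 0.1, 0.1],
                "se": [0.02, 0.0, 0.02],  # rs2 violates se > 0
                "pvalue": [1e-6, 1e-6, 1e-6],
                "n": [1000, 1000, 1000],
            }
        )
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        result = read_summary_stats(path)
        assert [r.rsid for r in result.records] == ["rs1", "rs3"]
        assert result.n_dropped == 1

    def test_lowercase_alleles_normalized(self, tmp_path):
        df = pd.DataFrame(
            {
                "rsid": ["rs1"], "effect_allele": ["a"], "other_allele": ["g"],
                "eaf": [0.3], "beta": [0.1], "se": [0.02], "pvalue": [1e-6], "n": [1000],
            }
        )
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        (rec,), dropped = read_summary_stats(path)
        assert (rec.effect_allele, rec.other_allele) == ("A", "G")
        # survives a write/read round trip unchanged
        out = tmp_path / "u.tsv"
        write_summary_stats([rec], out)
        assert read_summary_stats(out).records == [rec]

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        pd.DataFrame({"rsid": ["rs1"], "beta": [0.1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ConfigurationError, match="effect_allele"):
            read_summary_stats(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("")
        with pytest.raises(InputError):
            read_summary_stats(path)

    def test_column_map_resolves_foreign_headers(self, tmp_path):
        df = pd.DataFrame(
            {
                "SNP": ["rs1"], "A1": ["A"], "A2": ["G"], "freq": [0.3],
                "b": [0.1], "stderr": [0.02], "p": [1e-6], "N": [1000],
            }
        )
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        result = read_summary_stats(
            path,
            column_map={
                "rsid": "SNP", "effect_allele": "A1", "other_allele": "A2",
                "eaf": "freq", "beta": "b", "se": "stderr", "pvalue": "p", "n": "N",
            },
        )
        assert result.records[0].rsid == "rs1"


class TestHarmonization:
    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = [make_assoc(ea="A", oa="G", beta=0.10, eaf=0.3)]
        out = [make_assoc(ea="G", oa="A", beta=0.05, eaf=0.7)]
        (ins,), excluded = harmonize_pair(exp, out)
        assert ins.beta_outcome == pytest.approx(-0.05)
        assert not excluded

    def test_strand_complement_resolves_orientation(self):
        exp = [make_assoc(ea="A", oa="G")]
        # outcome reported on the other strand: T/C is the complement of A/G
        same = harmonize_pair(exp, [make_assoc(ea="T", oa="C", beta=0.05)])
        assert same.instruments[0].beta_outcome == pytest.approx(0.05)
        flipped = harmonize_pair(exp, [make_assoc(ea="C", oa="T", beta=0.05)])
        assert flipped.instruments[0].beta_outcome == pytest.approx(-0.05)

    def test_missing_snp_reported_and_excluded(self):
        exp = [make_assoc(rsid=f"rs{i}") for i in range(5)] + [make_assoc(rsid="rs80144387")]
        out = [make_assoc(rsid=f"rs{i}") for i in range(5)]
        instruments, excluded = harmonize_pair(exp, out)
        assert len(instruments) == 5
        assert ("rs80144387", "missing from outcome") in excluded

    def test_irreconcilable_alleles_never_silently_kept(self):
        exp = [make_assoc(ea="A", oa="G")]
        out = [make_assoc(ea="A", oa="C")]
        instruments, excluded = harmonize_pair(exp, out)
        assert instruments == []
        assert excluded == [("rs1", "allele mismatch")]

    def test_palindromic_pair_flagged(self):
        exp = [make_assoc(ea="A", oa="T")]
        out = [make_assoc(ea="A", oa="T", beta=0.05)]
        assert harmonize_pair(exp, out).instruments[0].is_palindromic

    def test_involution_against_self(self, sim_pair):
        """Harmonizing a dataset against itself returns its own betas."""
        instruments, excluded = harmonize_pair(
            sim_pair.exposure_stats, sim_pair.exposure_stats
        )
        assert not excluded
        for ins in instruments:
            assert ins.beta_outcome == pytest.approx(ins.beta_exposure)

    def test_magnitude_conserved_under_flip(self, sim_pair):
        """Harmonization only changes sign/eaf orientation, never |beta|."""
        outcome_by_rsid = {r.rsid: r for r in sim_pair.outcome_stats}
        instruments, _ = harmonize_pair(sim_pair.exposure_stats, sim_pair.outcome_stats)
        for ins in instruments:
            assert abs(ins.beta_outcome) == pytest.approx(
                abs(outcome_by_rsid[ins.rsid].beta)
            )

    def test_covariate_attached_when_supplied(self, sim_pair):
        pair = simulate_two_sample(
            SimulationConfig(seed=3, theta=0.1, covariate_r2=0.02, covariate_theta=0.2)
        )
        instruments, _ = harmonize_pair(
            pair.exposure_stats, pair.outcome_stats, pair.covariate_stats
        )
        assert all(i.beta_covariate is not None for i in instruments)


class TestPalindromeFilter:
    @pytest.mark.parametrize(
        "ea,oa,eaf,kept",
        [
            ("A", "T", 0.50, False),  # ambiguous: palindromic at 50%
            ("A", "T", 0.10, True),   # palindromic but frequency informative
            ("C", "A", 0.50, True),   # not palindromic
            ("A", "T", None, False),  # palindromic, frequency unknown
            ("C", "G", 0.45, False),  # inside the default 0.08 window
        ],
    )
    def test_ambiguity_window(self, ea, oa, eaf, kept):
        ins = make_instrument(ea=ea, oa=oa, eaf=eaf)
        result = filter_palindromic([ins])
        assert (ins in result.kept) is kept
        assert len(result.kept) + len(result.removed) == 1

    def test_window_is_configurable(self):
        ins = make_instrument(ea="A", oa="T", eaf=0.40)
        assert filter_palindromic([ins], maf_window=0.08).kept == [ins]
        assert filter_palindromic([ins], maf_window=0.15).removed == [ins]


class TestInstrumentSelection:
    DISCORDANT = ["rs11749751", "rs2335349", "rs3740390", "rs61942416"]

    @pytest.fixture()
    def panel(self):
        """69 candidate SNPs: 5 genome-wide significant, 60 suggestive,
        4 discordant-direction SNPs to exclude by name."""
        snps = [make_instrument(rsid=f"rs{i}", p=1e-9) for i in range(5)]
        snps += [make_instrument(rsid=f"rs{i}", p=1e-6) for i in range(5, 65)]
        snps += [make_instrument(rsid=r, p=1e-6) for r in self.DISCORDANT]
        return snps

    def test_discordant_then_lenient_threshold(self, panel):
        selected = select_instruments(panel, 5e-5, self.DISCORDANT)
        assert len(selected) == 65
        assert sum(1 for s in selected if s.gw_significant) == 5

    def test_strict_threshold_keeps_genome_wide_set(self, panel):
        selected = select_instruments(panel, 5e-8, self.DISCORDANT)
        assert len(selected) == 5
        assert all(s.gw_significant for s in selected)

    def test_identity_when_unconstrained(self, panel):
        selected = select_instruments(panel, 1.0, [])
        assert [s.rsid for s in selected] == [p.rsid for p in panel]

    def test_threshold_validated(self, panel):
        with pytest.raises(ConfigurationError):
            select_instruments(panel, 0.0)
        with pytest.raises(ConfigurationError):
            select_instruments(panel, 1.5)
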