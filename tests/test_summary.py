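import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dietbarcode.summary import (
    DietRecord,
    PipelineCounts,
    method_overlap,
    read_records,
    seasonal_fruit_diversity,
    seed_intactness,
    success_rates,
    taxon_frequency,
    write_records,
)


def fruit(family, genus=None, species=None, source="D", pile=None, month=None, seed="n/a"):
    return DietRecord(
        family=family, genus=genus, species=species, source=source,
        item="fruit", sample_id=pile, month=month, seed_condition=seed,
    )


class TestSuccessRates:
    def test_study_scale_counts(self):
        """410 particles, 95 amplified, 57 sequenced -> 23%, 14%, 60%."""
        out = success_rates(PipelineCounts(410, 95, 57))
        assert out["rounded"]["amplification_pct"] == 23
        assert out["rounded"]["sequencing_overall_pct"] == 14
        assert out["rounded"]["sequencing_success_pct"] == 60

    def test_full_success(self):
        out = success_rates(PipelineCounts(100, 100, 100))["rounded"]
        assert set(out.values()) == {100}

    def test_direct_arithmetic(self):
        out = success_rates(PipelineCounts(1000, 250, 100))["rounded"]
        assert (out["amplification_pct"], out["sequencing_overall_pct"],
                out["sequencing_success_pct"]) == (25, 10, 40)

    def test_full_precision_retained(self):
        out = success_rates(PipelineCounts(410, 95, 57))
        assert out["amplification_pct"] == pytest.approx(100 * 95 / 410)

    def test_zero_denominator_marked_undefined(self):
        out = success_rates(PipelineCounts(0, 0, 0))
        assert out["amplification_pct"] is None

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            PipelineCounts(10, 20, 5)

    @given(st.integers(1, 1000), st.integers(0, 1000), st.integers(0, 1000))
    def test_percentages_bounded(self, n, a, s):
        a, s = min(a, n), min(s, min(a, n))
        out = success_rates(PipelineCounts(n, a, s))
        for key in ("amplification_pct", "sequencing_overall_pct", "sequencing_success_pct"):
            v = out[key]
            assert v is None or 0 <= v <= 100


class TestMethodOverlap:
    def test_single_source_no_overlap(self):
        records = [fruit("FamA", source="W"), fruit("FamB", source="W")]
        tab = method_overlap(records)
        row = tab[(tab["rank"] == "family") & (tab["item"] == "fruit")].iloc[0]
        assert row["n_W"] == 2
        assert row["n_shared_all"] == 0
        assert row["pct_W_found_elsewhere"] == 0.0

    def test_identical_lists_full_overlap(self):
        records = []
        for src in ("W", "D"):
            records += [fruit("FamA", "GenA", "SpA", source=src),
                        fruit("FamB", "GenB", "SpB", source=src)]
        tab = method_overlap(records)
        for rank in ("species", "genus", "family"):
            row = tab[(tab["rank"] == rank) & (tab["item"] == "fruit")].iloc[0]
            assert row["pct_W_found_elsewhere"] == 100.0
            assert row["n_shared_WD"] == 2

    def test_three_source_fixture_matches_set_algebra(self):
        """Overlap table equals brute-force set operations on a 3-source fixture."""
        sets = {
            "W": {"FamA", "FamB", "FamC"},
            "B": {"FamB", "FamC", "FamD"},
            "D": {"FamC", "FamE"},
        }
        records = [
            DietRecord(family=f, source=s, item="browse")
            for s, fams in sets.items()
            for f in fams
        ]
        tab = method_overlap(records)
        row = tab[(tab["rank"] == "family") & (tab["item"] == "browse")].iloc[0]
        assert row["n_shared_all"] == len(sets["W"] & sets["B"] & sets["D"])
        assert row["n_shared_WB"] == len(sets["W"] & sets["B"])
        assert row["n_shared_WD"] == len(sets["W"] & sets["D"])
        assert row["n_shared_BD"] == len(sets["B"] & sets["D"])
        expect_W = 100.0 * len(sets["W"] & (sets["B"] | sets["D"])) / len(sets["W"])
        assert row["pct_W_found_elsewhere"] == pytest.approx(expect_W)


class TestSeasonalDiversity:
    def test_single_pile_single_month(self):
        records = [fruit("F", species=f"Sp{i}", pile="p1", month=4) for i in range(4)]
        out = seasonal_fruit_diversity(records)
        assert len(out) == 1
        assert out.iloc[0]["mean_taxa"] == 4
        assert out.iloc[0]["sd_taxa"] == 0.0

    def test_two_piles_sample_sd(self):
        """Piles with 2 and 6 taxa: mean 4, sample SD = sqrt(8) ~ 2.828."""
        records = [fruit("F", species=f"A{i}", pile="p1", month=4) for i in range(2)]
        records += [fruit("F", species=f"B{i}", pile="p2", month=4) for i in range(6)]
        out = seasonal_fruit_diversity(records)
        assert out.iloc[0]["mean_taxa"] == pytest.approx(4.0)
        assert out.iloc[0]["sd_taxa"] == pytest.approx(np.sqrt(8), abs=1e-6)

    def test_population_sd_option(self):
        records = [fruit("F", species=f"A{i}", pile="p1", month=4) for i in range(2)]
        records += [fruit("F", species=f"B{i}", pile="p2", month=4) for i in range(6)]
        out = seasonal_fruit_diversity(records, sample_sd=False)
        assert out.iloc[0]["sd_taxa"] == pytest.approx(2.0)

    def test_months_without_piles_absent(self):
        records = [fruit("F", species="S", pile="p1", month=2)]
        out = seasonal_fruit_diversity(records)
        assert out["month"].tolist() == [2]

    def test_three_month_fixture_matches_groupby_oracle(self):
        rng = np.random.default_rng(17)
        records = []
        for month in (3, 4, 9):
            for pile in range(int(rng.integers(1, 4))):
                for sp in range(int(rng.integers(1, 6))):
                    records.append(
                        fruit("F", species=f"m{month}p{pile}s{sp}", pile=f"p{month}-{pile}", month=month)
                    )
        out = seasonal_fruit_diversity(records).set_index("month")
        by_month: dict[int, dict[str, set]] = {}
        for r in records:
            by_month.setdefault(r.month, {}).setdefault(r.sample_id, set()).add(r.species)
        for month, piles in by_month.items():
            counts = [len(s) for s in piles.values()]
            assert out.loc[month, "mean_taxa"] == pytest.approx(np.mean(counts))


class TestTaxonFrequency:
    def test_strict_genus_threshold(self):
        """A genus in exactly 3 piles is excluded; in 4 piles included."""
        records = [fruit("FamA", "Gen3", pile=f"p{i}") for i in range(3)]
        records += [fruit("FamA", "Gen4", pile=f"q{i}") for i in range(4)]
        out = taxon_frequency(records)
        genera = out[out["rank"] == "genus"]["taxon"].tolist()
        assert "Gen4" in genera and "Gen3" not in genera

    def test_strict_family_threshold(self):
        records = [fruit("Fam4", pile=f"p{i}") for i in range(4)]
        records += [fruit("Fam5", pile=f"q{i}") for i in range(5)]
        out = taxon_frequency(records)
        fams = out[out["rank"] == "family"]["taxon"].tolist()
        assert "Fam5" in fams and "Fam4" not in fams

    def test_no_records_empty_table(self):
        assert taxon_frequency([]).empty

    def test_pile_counts_match_recount(self):
        rng = np.random.default_rng(19)
        records = []
        for g in range(5):
            for p in rng.choice(12, size=int(rng.integers(1, 10)), replace=False):
                records.append(fruit("FamX", f"Gen{g}", pile=f"p{p}"))
        out = taxon_frequency(records, min_family_piles=1, min_genus_piles=1)
        truth = {}
        for r in records:
            truth.setdefault(r.genus, set()).add(r.sample_id)
        for _, row in out[out["rank"] == "genus"].iterrows():
            assert row["n_piles"] == len(truth[row["taxon"]])

    def test_lowering_threshold_never_removes_rows(self):
        records = [fruit("FamA", "GenA", pile=f"p{i}") for i in range(6)]
        records += [fruit("FamB", "GenB", pile=f"p{i}") for i in range(2)]
        strict = taxon_frequency(records)
        loose = taxon_frequency(records, min_family_piles=1, min_genus_piles=1)
        strict_keys = set(zip(strict["rank"], strict["taxon"]))
        loose_keys = set(zip(loose["rank"], loose["taxon"]))
        assert strict_keys <= loose_keys


class TestSeedIntactness:
    def test_all_always_intact(self):
        records = [fruit("F", species=f"S{i}", pile="p", seed="intact") for i in range(3)]
        out = seed_intactness(records)
        assert out["pct_sometimes_intact"] == 100.0
        assert out["pct_always_intact"] == 100.0

    def test_hand_tally(self):
        """A: intact,intact; B: intact,damaged; C: damaged -> 66.7% / 33.3%."""
        records = [
            fruit("F", species="A", pile="p1", seed="intact"),
            fruit("F", species="A", pile="p2", seed="intact"),
            fruit("F", species="B", pile="p1", seed="intact"),
            fruit("F", species="B", pile="p2", seed="damaged"),
            fruit("F", species="C", pile="p1", seed="damaged"),
        ]
        out = seed_intactness(records)
        assert out["pct_sometimes_intact"] == pytest.approx(200 / 3)
        assert out["pct_always_intact"] == pytest.approx(100 / 3)

    def test_always_subset_of_sometimes(self):
        rng = np.random.default_rng(23)
        conds = ["intact", "damaged", "mixed"]
        records = [
            fruit("F", species=f"S{rng.integers(0, 6)}", pile="p",
                  seed=conds[rng.integers(0, 3)])
            for _ in range(30)
        ]
        out = seed_intactness(records)
        assert out["pct_always_intact"] <= out["pct_sometimes_intact"]

    def test_no_fruit_records(self):
        assert seed_intactness([])["pct_sometimes_intact"] is None


class TestRecordValidation:
    def test_seed_condition_requires_fruit(self):
        with pytest.raises(ValueError):
            DietRecord(family="F", item="browse", seed_condition="intact")

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            DietRecord(family="F", source="X")

    def test_tsv_roundtrip(self, tmp_path):
        records = [
            fruit("FamA", "GenA", "SpA", pile="p1", month=4, seed="intact"),
            DietRecord(family="FamB", source="B", item="browse"),
        ]
        write_records(records, tmp_path / "r.tsv")
        back = read_records(tmp_path / "r.tsv")
        assert back == records
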