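import numpy as np
import pytest

import avitrend as av
from avitrend.datamodel import root_to_tip_depths, tip_labels, tips_missing_from


def _species_rows():
    return [
        av.SpeciesRecord("sp1", 20.0, "grassland", "resident", "granivore"),
        av.SpeciesRecord("sp2", 350.0, "forest", "long-distance", "invertivore"),
        av.SpeciesRecord("sp3", 15.5, "wetland", "partial", "omnivore"),
    ]


class TestSpeciesTable:
    def test_round_trip_preserves_fields(self, tmp_path):
        path = tmp_path / "species.csv"
        rows = _species_rows()
        av.write_species_table(rows, path)
        back = av.read_species_table(path)
        assert back == rows

    def test_random_tables_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        from avitrend.datamodel import HABITATS, MIGRATIONS

        rows = [
            av.SpeciesRecord(
                f"s{i}",
                float(rng.lognormal(3, 1)),
                str(rng.choice(HABITATS)),
                str(rng.choice(MIGRATIONS)),
                "omnivore",
            )
            for i in range(30)
        ]
        path = tmp_path / "r.csv"
        av.write_species_table(rows, path)
        back = av.read_species_table(path)
        for a, b in zip(rows, back):
            assert a.species_id == b.species_id
            assert a.body_mass == pytest.approx(b.body_mass, rel=1e-12)

    def test_negative_mass_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "species_id,body_mass,habitat,migration,trophic_niche\n"
            "sp1,-1,grassland,resident,granivore\n"
        )
        with pytest.raises(av.ValidationError, match="row 0"):
            av.read_species_table(path)

    def test_unknown_habitat_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "species_id,body_mass,habitat,migration,trophic_niche\n"
            "sp1,10,volcano,resident,granivore\n"
        )
        with pytest.raises(av.ValidationError, match="volcano"):
            av.read_species_table(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species_id,body_mass\nsp1,10\n")
        with pytest.raises(av.SchemaError):
            av.read_species_table(path)

    def test_duplicate_species_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "species_id,body_mass,habitat,migration,trophic_niche\n"
            "sp1,10,grassland,resident,granivore\n"
            "sp1,12,forest,resident,granivore\n"
        )
        with pytest.raises(av.ValidationError, match="duplicate"):
            av.read_species_table(path)


class TestSeriesAndEstimates:
    def test_index_series_round_trip(self, tmp_path):
        s = av.IndexSeries(
            "sp1", [2000, 2001, 2003], [1.0, 2.0, 3.0], [0.1, 0.2, 0.3], [0.5, 0.6, 0.7]
        )
        path = tmp_path / "idx.csv"
        av.write_index_series([s], path)
        back = av.read_index_series(path)["sp1"]
        np.testing.assert_array_equal(back.years, s.years)
        np.testing.assert_allclose(back.index, s.index)
        np.testing.assert_allclose(back.coverage, s.coverage)

    def test_years_must_increase(self):
        with pytest.raises(av.ValidationError):
            av.IndexSeries("x", [2001, 2000], [1, 2], [0.1, 0.1])

    def test_estimate_invariants(self):
        with pytest.raises(av.ValidationError):
            av.PopulationEstimate("x", 100, 50, 75, 1, 2016, 2016)
        e = av.PopulationEstimate("x", 50, 100, 70.7, 8.3, 2013, 2017)
        assert e.ref_year == 2015  # midpoint of the range

    def test_estimate_round_trip(self, tmp_path):
        e = av.PopulationEstimate("x", 50, 100, 70.7, 8.3, 2013, 2017)
        path = tmp_path / "est.csv"
        av.write_population_estimates([e], path)
        assert av.read_population_estimates(path)["x"] == e

    def test_national_trend_round_trip(self, tmp_path):
        r = av.NationalTrendRecord("x", "FR", 1.2, 12, 5000.0, 2008)
        path = tmp_path / "nt.csv"
        av.write_national_trends([r], path)
        assert av.read_national_trends(path) == [r]

    def test_nonpositive_trend_rejected(self):
        with pytest.raises(av.ValidationError):
            av.NationalTrendRecord("x", "FR", 0.0, 12, 5000.0, 2008)


class TestNewick:
    def test_small_tree_depths(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        tree = av.read_newick(path)
        assert sorted(tip_labels(tree)) == ["A", "B", "C"]
        depths = root_to_tip_depths(tree)
        assert all(abs(d - 2.0) < 1e-12 for d in depths.values())

    def test_tip_set_difference_reported(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        tree = av.read_newick(path)
        assert tips_missing_from(tree, ["A", "B", "D"]) == {"D"}

    def test_duplicate_tips_rejected(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,A:1):1,C:2);\n")
        with pytest.raises(av.ValidationError):
            av.read_newick(path)

    def test_unparseable_raises(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2\n")
        with pytest.raises(ValueError):
            av.read_newick(path)

    def test_yule_round_trip(self, tmp_path, yule_50):
        path = tmp_path / "yule.nwk"
        av.write_newick(yule_50, path)
        back = av.read_newick(path)
        d0 = root_to_tip_depths(yule_50)
        d1 = root_to_tip_depths(back)
        assert set(d0) == set(d1)
        for k in d0:
            assert d0[k] == pytest.approx(d1[k], abs=1e-9)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = av.AnalysisConfig(year_start=1980, year_end=2017, bootstrap_n=200)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert av.AnalysisConfig.from_yaml(path) == cfg

    def test_invalid_years_rejected(self):
        with pytest.raises(av.ValidationError):
            av.AnalysisConfig(year_start=2000, year_end=2000)
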