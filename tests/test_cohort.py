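"""Fate-table reading, validation, longevity derivation, stratification."""

import numpy as np
import pytest

from coralrec.cohort import (
    CohortTable,
    CohortValidationError,
    FateRecord,
    SchemaError,
    derive_longevities,
    fate_summary,
    read_cohort,
    stratify,
    write_cohort,
)


def make_record(colony_id, statuses, taxon="Pocillopora", habitat="consolidated"):
    return FateRecord(colony_id=colony_id, taxon=taxon, habitat=habitat, statuses=tuple(statuses))


STATUS_HEADER = "colony_id,taxon,habitat,status_y0,status_y1,status_y2,status_y3,status_y4\n"


class TestReadValidate:
    def test_status_long_round_trip(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(
            STATUS_HEADER
            + "c1,Pocillopora,consolidated,alive,alive,alive,alive,alive\n"
            + "c2,Pavona,unconsolidated,alive,dead,dead,dead,dead\n"
            + "c3,Porites,consolidated,Alive,ALIVE,lost, lost ,lost\n"  # mixed case/space
        )
        cohort = read_cohort(path)
        assert len(cohort) == 3
        assert cohort.window_years == 4
        assert cohort.records[2].statuses == ("alive", "alive", "lost", "lost", "lost")

        out = tmp_path / "copy.csv"
        write_cohort(cohort, out)
        again = read_cohort(out)
        assert again == cohort

    def test_longevity_wide_round_trip(self, tmp_path):
        cohort = CohortTable(
            (
                make_record("a", ["alive"] * 5),
                make_record("b", ["alive", "dead", "dead", "dead", "dead"]),
                make_record("c", ["alive", "alive", "alive", "lost", "lost"]),
            )
        )
        path = tmp_path / "wide.csv"
        write_cohort(cohort, path, format="longevity-wide")
        again = read_cohort(path, format="longevity-wide")
        assert again == cohort

    def test_resurrection_rejected(self):
        with pytest.raises(CohortValidationError, match="c9.*monotone|monotone.*c9"):
            make_record("c9", ["alive", "dead", "alive", "dead", "dead"])

    def test_first_status_must_be_alive(self):
        with pytest.raises(CohortValidationError, match="alive"):
            make_record("c1", ["dead", "dead", "dead", "dead", "dead"])

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("colony_id,taxon,status_y0,status_y1\nc1,Pavona,alive,dead\n")
        with pytest.raises(SchemaError, match="habitat"):
            read_cohort(path)

    def test_unknown_token_cites_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            STATUS_HEADER
            + "c1,Pavona,consolidated,alive,alive,alive,alive,alive\n"
            + "c2,Pavona,consolidated,alive,zombie,dead,dead,dead\n"
        )
        with pytest.raises(SchemaError, match="line 3.*zombie"):
            read_cohort(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(CohortValidationError, match="duplicate"):
            CohortTable((make_record("x", ["alive"] * 5), make_record("x", ["alive"] * 5)))


class TestDeriveLongevities:
    @pytest.mark.parametrize(
        "statuses, longevity, censored",
        [
            # every possible terminal position over a 4-year window
            (("alive", "dead", "dead", "dead", "dead"), 0, False),
            (("alive", "alive", "dead", "dead", "dead"), 1, False),
            (("alive", "alive", "lost", "lost", "lost"), 1, False),
            (("alive", "alive", "alive", "lost", "lost"), 2, False),
            (("alive", "alive", "alive", "alive", "dead"), 3, False),
            (("alive", "alive", "alive", "alive", "alive"), 4, True),
        ],
    )
    def test_terminal_positions(self, statuses, longevity, censored):
        (obs,) = derive_longevities(CohortTable((make_record("c", statuses),)))
        assert (obs.longevity, obs.censored) == (longevity, censored)

    def test_dead_and_lost_equivalent_for_longevity(self):
        dead = make_record("d", ["alive", "alive", "dead", "dead", "dead"])
        lost = make_record("l", ["alive", "alive", "lost", "lost", "lost"])
        obs = derive_longevities(CohortTable((dead, lost)))
        assert obs[0].longevity == obs[1].longevity == 1
        assert not obs[0].censored and not obs[1].censored

    def test_generator_writer_reader_round_trip(self, tmp_path, palmyra_cohort):
        """Composing generate -> write -> read -> derive reproduces the
        generator's longevity vector exactly."""
        direct = derive_longevities(palmyra_cohort)
        path = tmp_path / "cohort.csv"
        write_cohort(palmyra_cohort, path)
        reread = derive_longevities(read_cohort(path))
        assert reread == direct


class TestFateSummary:
    def test_counts_and_proportions(self):
        records = (
            [make_record(f"a{i}", ["alive"] * 5) for i in range(4)]
            + [make_record(f"d{i}", ["alive", "dead", "dead", "dead", "dead"]) for i in range(3)]
            + [make_record(f"l{i}", ["alive", "alive", "lost", "lost", "lost"]) for i in range(3)]
        )
        summary = fate_summary(CohortTable(tuple(records)))
        row = summary.loc["all"]
        assert row["n_initial"] == 10
        assert (row["alive"], row["dead"], row["lost"]) == (0.40, 0.30, 0.30)

    def test_single_survivor(self):
        summary = fate_summary(CohortTable((make_record("c", ["alive"] * 5),)))
        assert tuple(summary.loc["all", ["alive", "dead", "lost"]]) == (1.0, 0.0, 0.0)

    def test_proportions_sum_to_one_per_taxon(self, palmyra_cohort):
        summary = fate_summary(palmyra_cohort, by="taxon")
        assert len(summary) == 12
        total = summary[["alive", "dead", "lost"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_monte_carlo_matches_generator_settings(self, constant_cohort_factory):
        """A generator tuned to terminal-state frequencies (0.408, 0.303,
        0.289) reproduces them within sampling error at n=5000."""
        s_c = 0.408 ** 0.25           # whole-window survival 0.408
        dead_frac = 0.303 / (0.303 + 0.289)
        cohort = constant_cohort_factory(s_c=s_c, n=5000, seed=11, dead_fraction=dead_frac)
        row = fate_summary(cohort).loc["all"]
        assert row["alive"] == pytest.approx(0.408, abs=0.02)
        assert row["dead"] == pytest.approx(0.303, abs=0.02)
        assert row["lost"] == pytest.approx(0.289, abs=0.02)


class TestStratify:
    def _toy(self, n_cons, n_uncons):
        records = [
            make_record(f"c{i}", ["alive"] * 5, habitat="consolidated") for i in range(n_cons)
        ] + [
            make_record(f"u{i}", ["alive"] * 5, habitat="unconsolidated")
            for i in range(n_uncons)
        ]
        return CohortTable(tuple(records))

    def test_below_total_threshold(self):
        elig = stratify(self._toy(5, 4))  # n = 9
        row = elig.loc["Pocillopora"]
        assert not row["eligible_single"] and not row["eligible_split"]

    def test_single_models_only(self):
        elig = stratify(self._toy(8, 4))  # n = 12 split 8/4
        row = elig.loc["Pocillopora"]
        assert row["eligible_single"] and not row["eligible_split"]

    def test_default_fixture_exclusions(self, palmyra_cohort):
        """The taxa concentrated on consolidated substrate miss the
        5-per-habitat threshold and drop out of the two-habitat grid."""
        elig = stratify(palmyra_cohort)
        for taxon in ("Hydnophora", "Acropora", "Favites"):
            assert not elig.loc[taxon, "eligible_split"], taxon
        assert elig.loc["All corals", "eligible_split"]
        assert elig.loc["Pocillopora", "eligible_split"]

    def test_threshold_validation(self, palmyra_cohort):
        with pytest.raises(ValueError):
            stratify(palmyra_cohort, min_total=0)
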