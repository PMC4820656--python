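import pandas as pd
import pytest

from nkscreen import analysis


def make_tables(wells: dict[int, dict[str, tuple[int, int, int]]], labels, goodness=1.0):
    """Build per-screen well tables from {well_id: {label: (nk, live, dead)}}."""
    tables = {}
    for lab in labels:
        rows = []
        for wid, per in wells.items():
            if lab not in per:
                continue
            nk, live, dead = per[lab]
            rows.append(dict(well_id=wid, n_nk=nk, n_target_live=live,
                             n_target_dead=dead, goodness=goodness))
        tables[lab] = pd.DataFrame(rows).set_index("well_id")
    return tables


LABELS3 = ["T_0h", "T_6h", "T_12h"]
LABELS4 = ["T_minusNK", "T_0h", "T_6h", "T_12h"]


class TestAlign:
    def test_single_well_three_screens(self):
        tcs = analysis.align_screens(
            make_tables({0: {lab: (1, 2, 0) for lab in LABELS3}}, LABELS3))
        assert len(tcs) == 1
        assert list(tcs.attrs["timepoints"]) == LABELS3
        assert tcs.loc[0, "n_target_live_T_12h"] == 2

    def test_well_missing_from_one_screen_excluded(self):
        wells = {
            0: {lab: (1, 2, 0) for lab in LABELS3},
            1: {lab: (0, 3, 0) for lab in LABELS3 if lab != "T_12h"},
        }
        tcs = analysis.align_screens(make_tables(wells, LABELS3))
        assert list(tcs.index) == [0]

    def test_screens_ordered_by_time(self):
        tables = make_tables({0: {lab: (0, 1, 0) for lab in LABELS4}}, LABELS4)
        shuffled = {k: tables[k] for k in ["T_6h", "T_minusNK", "T_12h", "T_0h"]}
        tcs = analysis.align_screens(shuffled)
        assert list(tcs.attrs["timepoints"]) == LABELS4


class TestSelection:
    def _tcs(self):
        wells = {
            0: {lab: (1, 2, 0) for lab in LABELS3},   # single NK, 2 live
            1: {lab: (1, 4, 0) for lab in LABELS3},   # single NK, 4 live
            2: {lab: (0, 3, 0) for lab in LABELS3},   # NK-free
            3: {lab: (2, 5, 0) for lab in LABELS3},   # two NK
        }
        return analysis.align_screens(make_tables(wells, LABELS3))

    def test_fig2_vs_fig3(self):
        tcs = self._tcs()
        assert set(analysis.select_wells(tcs, "fig2").index) == {0, 1}
        assert set(analysis.select_wells(tcs, "fig3").index) == {1}

    def test_spontaneous_is_nk_free(self):
        assert set(analysis.select_wells(self._tcs(), "spontaneous").index) == {2}

    def test_unknown_criterion(self):
        with pytest.raises(ValueError, match="unknown criterion"):
            analysis.select_wells(self._tcs(), "fig9")

    def test_fig4_requires_prescreen_counts(self):
        with pytest.raises(ValueError, match="T_minusNK"):
            analysis.select_wells(self._tcs(), "fig4")

    def test_fig4_selection(self):
        wells = {
            0: {"T_minusNK": (0, 6, 0), "T_0h": (1, 6, 0), "T_6h": (1, 3, 3),
                "T_12h": (1, 2, 4)},
            1: {"T_minusNK": (0, 6, 0), "T_0h": (1, 6, 0), "T_6h": (2, 5, 1),
                "T_12h": (2, 5, 1)},  # extra NK appears later
            2: {"T_minusNK": (0, 4, 0), "T_0h": (1, 4, 0), "T_6h": (1, 4, 0),
                "T_12h": (1, 4, 0)},  # too few targets at prescreen
        }
        tcs = analysis.align_screens(make_tables(wells, LABELS4))
        assert set(analysis.select_wells(tcs, "fig4").index) == {0}

    def test_low_goodness_excluded_everywhere(self):
        wells = {0: {lab: (1, 3, 0) for lab in LABELS3}}
        tcs = analysis.align_screens(make_tables(wells, LABELS3, goodness=0.4))
        for crit in ("fig2", "fig3"):
            assert len(analysis.select_wells(tcs, crit)) == 0


class TestScoring:
    def test_live_decrease_counts_kills(self):
        wells = {0: {"T_0h": (1, 4, 0), "T_6h": (1, 1, 3), "T_12h": (1, 1, 3)}}
        tcs = analysis.align_screens(make_tables(wells, LABELS3))
        scores = analysis.score_all_kills(tcs)
        assert scores.loc[0, "total_kills"] == 3
        assert bool(scores.loc[0, "serial_killer"])

    def test_no_deaths_not_cytotoxic(self):
        wells = {0: {lab: (1, 5, 0) for lab in LABELS4}}
        tcs = analysis.align_screens(make_tables(wells, LABELS4))
        scores = analysis.score_all_kills(tcs, baseline="T_minusNK")
        assert scores.loc[0, "total_kills"] == 0
        assert not bool(scores.loc[0, "cytotoxic"])

    def test_interval_additivity(self):
        """Total kills are independent of how screens partition the assay
        when live counts are monotone."""
        fine = {0: {"T_0h": (1, 6, 0), "T_6h": (1, 4, 2), "T_12h": (1, 1, 5)}}
        coarse = {0: {"T_0h": (1, 6, 0), "T_12h": (1, 1, 5)}}
        t_fine = analysis.align_screens(make_tables(fine, LABELS3))
        t_coarse = analysis.align_screens(make_tables(coarse, ["T_0h", "T_12h"]))
        assert (analysis.score_all_kills(t_fine).loc[0, "total_kills"]
                == analysis.score_all_kills(t_coarse).loc[0, "total_kills"] == 5)

    def test_prescreen_baseline_captures_early_kills(self):
        wells = {0: {"T_minusNK": (0, 6, 0), "T_0h": (1, 4, 2), "T_6h": (1, 4, 2),
                     "T_12h": (1, 4, 2)}}
        tcs = analysis.align_screens(make_tables(wells, LABELS4))
        early = analysis.score_all_kills(tcs, baseline="T_minusNK").loc[0, "total_kills"]
        late = analysis.score_all_kills(tcs, baseline="T_0h").loc[0, "total_kills"]
        assert early == 2 and late == 0
        assert early >= late

    def test_inconsistent_dead_counts_dropped(self):
        wells = {0: {"T_0h": (1, 2, 3), "T_6h": (1, 2, 0), "T_12h": (1, 2, 0)}}
        tcs = analysis.align_screens(make_tables(wells, LABELS3))
        assert len(analysis.score_all_kills(tcs)) == 0

    def test_rebounding_live_counts_dropped(self):
        """Summed interval kills beyond the baseline live count indicate
        miscounting and disqualify the well."""
        wells = {0: {"T_minusNK": (0, 5, 0), "T_0h": (1, 0, 5),
                     "T_6h": (1, 4, 4), "T_12h": (1, 0, 5)}}
        tcs = analysis.align_screens(make_tables(wells, LABELS4))
        assert len(analysis.score_all_kills(tcs, baseline="T_minusNK")) == 0

    def test_killscore_invariants(self):
        ks = analysis.KillScore(well_id=0, kills_per_interval=(2, 1), total_kills=3)
        assert ks.serial_killer and ks.cytotoxic
        with pytest.raises(ValueError):
            analysis.KillScore(well_id=0, kills_per_interval=(1,), total_kills=3)


class TestSpontaneousRate:
    def test_no_deaths_rate_zero(self):
        wells = {i: {lab: (0, 3, 0) for lab in LABELS3} for i in range(5)}
        tcs = analysis.align_screens(make_tables(wells, LABELS3))
        out = analysis.spontaneous_rate(tcs)
        assert out["well_rate"] == 0.0
        assert out["cell_rate"] == 0.0
        assert out["well_denominator"] == 5

    def test_rates_match_bernoulli_model(self, rng):
        """3 targets/well over 2 intervals at 0.02/target/interval: the
        well-level rate approaches 1-(1-0.02)^6 ~ 11.4%, cell-level
        1-(1-0.02)^2 ~ 4%."""
        p_int = 0.02
        wells = {}
        for i in range(4000):
            alive = 3
            deaths = rng.binomial(alive, 1 - (1 - p_int) ** 2)
            wells[i] = {
                "T_0h": (0, 3, 0),
                "T_6h": (0, 3, 0),
                "T_12h": (0, 3 - deaths, deaths),
            }
        tcs = analysis.align_screens(make_tables(wells, LABELS3))
        out = analysis.spontaneous_rate(tcs)
        assert out["well_rate"] == pytest.approx(1 - 0.98 ** 6, abs=0.02)
        assert out["cell_rate"] == pytest.approx(1 - 0.98 ** 2, abs=0.01)

    def test_all_wells_with_nk_raises(self):
        wells = {0: {lab: (1, 3, 0) for lab in LABELS3}}
        tcs = analysis.align_screens(make_tables(wells, LABELS3))
        with pytest.raises(ValueError):
            analysis.spontaneous_rate(tcs)
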