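"""Min–max criterion scoring and the per-sample score table."""

import numpy as np
import pandas as pd
import pytest

from beescreen import (
    CRITERIA,
    RankingConfig,
    criterion_score,
    default_criteria,
    minmax_score,
    rank_table,
    standard_scores,
)
from beescreen.core import ELEMENTS
from beescreen.intake import WeeklyIntakeTable
from beescreen.ranking import CriterionLimit, DegenerateNormalizationError
from beescreen.synthdata import default_paper_like_config, generate_panel
from beescreen import build_intake_table


def _brute_criterion_score(code, criterion, table, limits, config):
    """Independent plain-float recomputation of a criterion score."""
    parts = []
    for lm in limits:
        if lm.criterion != criterion:
            continue
        xs = {}
        for c in table.mg_per_week.index:
            v = float(table.mg_per_week.at[c, lm.element]) * 1000.0  # µg
            if config.quantize_ug is not None:
                v = float(
                    __import__("decimal").Decimal(repr(round(v, 12))).quantize(
                        __import__("decimal").Decimal(1).scaleb(-config.quantize_ug),
                        rounding="ROUND_HALF_UP",
                    )
                )
            v = v / 1000.0 * config.bw_scale
            if config.se_faithful and criterion == "DNEL" and lm.element == "Se":
                v *= 1000.0
            xs[c] = v
        x, x_min = xs[code], min(xs.values())
        if lm.limit <= x_min:
            s = 0.0
        else:
            s = (lm.limit - x) / (lm.limit - x_min)
            s = min(1.0, max(0.0, s))
        parts.append(s)
    return sum(parts) / len(parts)


class TestMinmaxScore:
    def test_panel_minimum_scores_one(self):
        assert minmax_score(x=0.1, x_min=0.1, limit=2.0) == pytest.approx(1.0)

    def test_at_limit_scores_zero(self):
        assert minmax_score(x=2.0, x_min=0.1, limit=2.0) == pytest.approx(0.0)

    def test_beyond_limit_clamps_to_zero(self):
        assert minmax_score(x=5.0, x_min=0.1, limit=2.0, clamp=True) == 0.0
        assert minmax_score(x=5.0, x_min=0.1, limit=2.0, clamp=False) < 0.0

    def test_degenerate_normalization(self):
        # limit below the panel minimum: saturates at 0 when clamping,
        # raises otherwise
        assert minmax_score(x=5.0, x_min=3.0, limit=2.0, clamp=True) == 0.0
        with pytest.raises(DegenerateNormalizationError):
            minmax_score(x=1.0, x_min=3.0, limit=2.0, clamp=True)
        with pytest.raises(DegenerateNormalizationError):
            minmax_score(x=5.0, x_min=3.0, limit=2.0, clamp=False)

    def test_interior_value(self):
        # (limit - x) / (limit - x_min) with limit 0.3381, x 0.2205, min 0.0028
        assert minmax_score(0.2205, 0.0028, 0.3381) == pytest.approx(0.3507, abs=5e-4)


class TestCriterionScore:
    @pytest.mark.parametrize(
        ("code", "criterion", "expected"),
        [
            ("FS-30", "BMDL01", 0.994),
            ("FS-01", "BMDL01", 0.380),
            ("FS-10", "BMDL01", 0.175),
            ("FS-41", "BMDL10", 0.650),
            ("FS-41", "BMDL05", 0.807),
            ("FS-13", "LOAEL", 0.992),
            ("FS-02", "DNEL", 0.699),
            ("FS-24", "DNEL", 0.634),
        ],
    )
    def test_published_anchors(self, intake_table, code, criterion, expected):
        assert criterion_score(code, criterion, intake_table) == pytest.approx(
            expected, abs=5.1e-4
        )

    def test_se_faithful_off_raises_dnel_score(self, intake_table):
        on = criterion_score("FS-24", "DNEL", intake_table)
        off = criterion_score(
            "FS-24", "DNEL", intake_table, config=RankingConfig(se_faithful=False)
        )
        assert off > on  # the Se term stops saturating at 0

    def test_oracle_equivalence_on_random_panels(self):
        for seed in (3, 4):
            cfg = default_paper_like_config(seed=seed)
            cfg.n_per_group = {"RG": 5, "PR": 4, "HO": 3}
            table = build_intake_table(generate_panel(cfg))
            limits = default_criteria()
            for config in (RankingConfig(), RankingConfig(se_faithful=False, quantize_ug=None)):
                for crit in CRITERIA:
                    for code in table.mg_per_week.index:
                        assert criterion_score(code, crit, table, limits, config) == (
                            pytest.approx(
                                _brute_criterion_score(code, crit, table, limits, config),
                                rel=1e-12,
                            )
                        ), (crit, code)

    def test_monotone_in_intake(self, intake_table):
        # inflating one element's intake never raises any criterion score
        base = criterion_score("FS-20", "BMDL01", intake_table)
        bumped = intake_table.mg_per_week.copy()
        bumped.at["FS-20", "Pb"] *= 3.0
        t2 = WeeklyIntakeTable(bumped, intake_table.constants, intake_table.policy)
        assert criterion_score("FS-20", "BMDL01", t2) <= base

    def test_missing_criterion_raises(self, intake_table):
        with pytest.raises(ValueError, match="no element limits"):
            criterion_score("FS-01", "BMDL01", intake_table, limits=[])


class TestRankTable:
    def test_golden_survey_scores(self, intake_table, printed_scores):
        """All 51 samples × 6 criterion columns match the published table."""
        st = rank_table(intake_table)
        for crit in printed_scores.columns:
            diff = (st.scores[crit].loc[printed_scores.index] - printed_scores[crit]).abs()
            assert diff.max() <= 1e-3, f"{crit}: worst deviation {diff.max()}"

    def test_best_samples(self, intake_table):
        st = rank_table(intake_table)
        assert st.best["BMDL01"] == "FS-30"
        for crit in ("NOAEL", "BMDL10", "BMDL05"):
            assert st.best[crit] == "FS-06"

    def test_scores_bounded(self, intake_table):
        st = rank_table(intake_table)
        vals = st.scores[list(CRITERIA)].values
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_clamp_off_agrees_when_under_limits(self):
        # panel whose scaled intakes all stay below every limit
        codes = ["A", "B", "C"]
        grid = pd.DataFrame(
            {el: [1e-6, 2e-6, 3e-6] for el in ELEMENTS}, index=codes
        )
        table = WeeklyIntakeTable(mg_per_week=grid)
        limits = default_criteria()
        cfg_on = RankingConfig(se_faithful=False, quantize_ug=None)
        cfg_off = RankingConfig(se_faithful=False, clamp=False, quantize_ug=None)
        for crit in CRITERIA:
            for code in codes:
                assert criterion_score(code, crit, table, limits, cfg_on) == pytest.approx(
                    criterion_score(code, crit, table, limits, cfg_off)
                )

    def test_missing_criterion_limits_rejected(self, intake_table):
        limits = [lm for lm in default_criteria() if lm.criterion != "LOAEL"]
        with pytest.raises(ValueError, match="LOAEL"):
            rank_table(intake_table, limits)


class TestStandardScores:
    def test_elementwise_minimal_sample_scores_one(self):
        codes = ["low", "mid", "high"]
        grid = pd.DataFrame(
            {el: [1.0, 2.0, 4.0] for el in ELEMENTS}, index=codes
        )
        ss = standard_scores(WeeklyIntakeTable(mg_per_week=grid))
        assert ss["low"] == pytest.approx(1.0)
        assert ss["high"] == pytest.approx(0.0)

    def test_two_sample_ranks_are_binary(self):
        rng = np.random.default_rng(5)
        grid = pd.DataFrame(
            rng.uniform(0.1, 1.0, size=(2, 11)), index=["A", "B"], columns=list(ELEMENTS)
        )
        ss = standard_scores(WeeklyIntakeTable(mg_per_week=grid))
        wins_a = sum(grid.at["A", el] < grid.at["B", el] for el in ELEMENTS)
        assert ss["A"] == pytest.approx(wins_a / 11)
        assert ss["A"] + ss["B"] == pytest.approx(1.0)

    def test_survey_scores_bounded(self, intake_table):
        ss = standard_scores(intake_table)
        assert ((ss >= 0) & (ss <= 1)).all()

    def test_constant_column_convention(self):
        grid = pd.DataFrame(
            {el: [1.0, 2.0] for el in ELEMENTS}, index=["A", "B"]
        )
        grid["Hg"] = 5.0
        with pytest.warns(UserWarning, match="Hg"):
            ss = standard_scores(WeeklyIntakeTable(mg_per_week=grid))
        # constant element ranks 1 for everyone
        assert ss["A"] == pytest.approx((10 * 1.0 + 1.0) / 11)

    def test_polarity_flip(self):
        grid = pd.DataFrame({el: [1.0, 2.0] for el in ELEMENTS}, index=["A", "B"])
        cfg = RankingConfig(polarity=tuple((el, "higher") for el in ELEMENTS))
        ss = standard_scores(WeeklyIntakeTable(mg_per_week=grid), cfg)
        assert ss["A"] == pytest.approx(0.0)
        assert ss["B"] == pytest.approx(1.0)

    def test_single_sample_rejected(self):
        grid = pd.DataFrame({el: [1.0] for el in ELEMENTS}, index=["A"])
        with pytest.raises(ValueError, match="2 samples"):
            standard_scores(WeeklyIntakeTable(mg_per_week=grid))
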