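"""Weight sensitivity (crossover detection) and interval robustness."""

import itertools

import numpy as np
import pandas as pd
import pytest

import dietmcda as dm
from dietmcda.sensitivity import Relation, global_scores, partials_frame


def _renormalized_global(model, frame, criterion, w, scenario):
    """From-scratch global score with the varied weight set to w and the
    remaining weights rescaled proportionally (independent of the line
    representation)."""
    w0 = model.weights[criterion]
    factor = (1.0 - w) / (1.0 - w0)
    total = 0.0
    for c in model.criterion_ids:
        wc = w if c == criterion else model.weights[c] * factor
        total += wc * float(frame.at[scenario, c])
    return total


def _grid_top_changes(model, frame, criterion, step=1e-3):
    """Independent oracle: dense grid scan of the top-ranked scenario."""
    ws = np.arange(0.0, 1.0 + step / 2, step)
    tops = []
    current = None
    for w in ws:
        scores = {s: _renormalized_global(model, frame, criterion, w, s) for s in frame.index}
        best = max(scores, key=scores.get)
        # a tie with the incumbent is not a change of recommendation
        if current is None or scores[best] > scores[current] + 1e-9:
            current = best
        tops.append(current)
    changes = [
        (ws[i], tops[i - 1], tops[i]) for i in range(1, len(ws)) if tops[i] != tops[i - 1]
    ]
    return changes


class TestWeightSensitivity:
    def test_lines_match_from_scratch_evaluation(self, pt_case):
        frame = partials_frame(pt_case.printed_partials, pt_case.model)
        for criterion in ("diet_health", "local_communities", "profitability"):
            profile = dm.weight_sensitivity(pt_case.model, frame, criterion)
            for w in (0.0, 0.123, 0.5, 0.987):
                for s in frame.index:
                    assert profile.value(s, w) == pytest.approx(
                        _renormalized_global(pt_case.model, frame, criterion, w, s),
                        abs=1e-9,
                    )

    def test_current_weight_recovers_nominal_scores(self, dk_case):
        frame = partials_frame(dk_case.printed_partials, dk_case.model)
        nominal = global_scores(frame, dk_case.model)
        profile = dm.weight_sensitivity(dk_case.model, frame, "water_use")
        for s in frame.index:
            assert profile.value(s, profile.current_weight) == pytest.approx(
                nominal[s], abs=1e-9
            )

    def test_crossover_weights_are_roots(self, pt_case):
        frame = partials_frame(pt_case.printed_partials, pt_case.model)
        profile = dm.weight_sensitivity(pt_case.model, frame, "local_communities")
        assert profile.crossovers
        for x in profile.crossovers:
            gap = profile.value(x.outgoing, x.weight) - profile.value(x.incoming, x.weight)
            assert abs(gap) < 1e-9

    def test_crossovers_match_dense_grid_oracle(self, pt_case):
        frame = partials_frame(pt_case.printed_partials, pt_case.model)
        for criterion in pt_case.model.criterion_ids:
            profile = dm.weight_sensitivity(pt_case.model, frame, criterion)
            oracle = _grid_top_changes(pt_case.model, frame, criterion)
            assert len(profile.crossovers) == len(oracle), criterion
            for x, (w_grid, frm, to) in zip(profile.crossovers, oracle):
                assert abs(x.weight - w_grid) <= 1e-3
                assert (x.outgoing, x.incoming) == (frm, to)

    def test_local_communities_crossover_location(self, pt_case):
        """Varying the impact-on-local-communities weight flips the top
        alternative from 100% to 50% at w ~= 0.317."""
        profile = dm.weight_sensitivity(
            pt_case.model, pt_case.printed_partials, "local_communities"
        )
        assert profile.intersections("100%", "50%") == pytest.approx([0.3174], abs=5e-4)
        assert [(x.outgoing, x.incoming) for x in profile.crossovers] == [("100%", "50%")]

    def test_full_vs_threequarters_never_cross(self, pt_case):
        """The 100% scenario weakly dominates 75% criterion-by-criterion, so
        no single-weight variation can swap them."""
        frame = partials_frame(pt_case.printed_partials, pt_case.model)
        assert (frame.loc["100%"] >= frame.loc["75%"] - 1e-12).all()
        for criterion in pt_case.model.criterion_ids:
            profile = dm.weight_sensitivity(pt_case.model, frame, criterion)
            for w in np.linspace(0, 1, 101):
                assert profile.value("100%", w) >= profile.value("75%", w) - 1e-9
            assert not any(
                {"100%", "75%"} == {x.outgoing, x.incoming} for x in profile.crossovers
            )

    def test_unknown_criterion_errors(self, pt_case):
        with pytest.raises(dm.DataError):
            dm.weight_sensitivity(pt_case.model, pt_case.printed_partials, "nope")


class TestRecommendationStability:
    @pytest.mark.parametrize("country", ["PT", "DK"])
    @pytest.mark.parametrize("criterion", ["diet_health", "water_use"])
    def test_case_study_top_choice_weight_stable(self, both_cases, country, criterion):
        """No admissible change of the varied weight alters the recommended
        (100% substitution) alternative in either country."""
        study = both_cases[country]
        result = dm.recommendation_stability(
            study.model, study.printed_partials, criterion
        )
        assert result.stable
        assert result.min_change is None

    def test_constructed_flip_at_half(self):
        """Two criteria, two alternatives built to cross exactly at w = 0.5:
        the minimal weight change is 0.5 - w0."""
        levels = lambda: (
            dm.DescriptorLevel(1, 100.0, is_good=True),
            dm.DescriptorLevel(2, 0.0, is_neutral=True),
            dm.DescriptorLevel(3, -100.0),
        )
        anchors = lambda: (
            dm.ScaleAnchor(1, 100.0, 100.0),
            dm.ScaleAnchor(2, 0.0, 0.0),
            dm.ScaleAnchor(3, -100.0, -100.0),
        )
        model = dm.MCDAModel(
            [
                dm.Criterion("c1", "c1", "economic", "quantitative", "", levels()),
                dm.Criterion("c2", "c2", "economic", "quantitative", "", levels()),
            ],
            [dm.ValueScale("c1", anchors()), dm.ValueScale("c2", anchors())],
            dm.WeightVector({"c1": 0.2, "c2": 0.8}),
        )
        partials = pd.DataFrame(
            {"c1": [100.0, 0.0], "c2": [0.0, 100.0]}, index=["X", "Y"]
        )
        result = dm.recommendation_stability(model, partials, "c1")
        assert not result.stable
        assert result.flip_weight == pytest.approx(0.5, abs=1e-12)
        assert result.min_change == pytest.approx(0.3, abs=1e-12)
        assert result.new_top == "X"


def _random_instance(seed):
    rng = np.random.default_rng(seed)
    model = dm.synth_model(seed, n_criteria=3, n_levels=4)
    scenarios = ["A", "B", "C"]
    frame = pd.DataFrame(
        rng.uniform(-100, 100, size=(3, 3)), index=scenarios, columns=model.criterion_ids
    )
    widths = pd.DataFrame(
        rng.uniform(0, 30, size=(3, 3)), index=scenarios, columns=model.criterion_ids
    )
    intervals = {
        (s, c): (frame.at[s, c] - widths.at[s, c], frame.at[s, c] + widths.at[s, c])
        for s in scenarios
        for c in model.criterion_ids
    }
    return model, frame, dm.UncertaintyBox(intervals), widths


def _brute_force_min_gap(model, frame, box, a, b):
    """Minimum of V(a) - V(b) over every combination of interval endpoints."""
    crits = model.criterion_ids
    best = np.inf
    cells = [(a, c) for c in crits] + [(b, c) for c in crits]
    choices = [box.intervals.get(cell, (frame.at[cell[0], cell[1]],) * 2) for cell in cells]
    for combo in itertools.product(*([0, 1] for _ in cells)):
        va = sum(
            model.weights[c] * choices[i][combo[i]] for i, (s, c) in enumerate(cells) if s == a
        )
        vb = sum(
            model.weights[c] * choices[i][combo[i]] for i, (s, c) in enumerate(cells) if s == b
        )
        best = min(best, va - vb)
    return best


class TestRobustness:
    def test_zero_width_box_reduces_to_nominal_comparison(self, pt_case):
        frame = partials_frame(pt_case.printed_partials, pt_case.model)
        rel = dm.robustness(pt_case.model, frame)
        nominal = global_scores(frame, pt_case.model)
        for (a, b), r in rel.items():
            if nominal[a] > nominal[b]:
                assert r >= Relation.ROBUSTLY_PREFERRED
            elif nominal[a] < nominal[b]:
                assert r == Relation.INCOMPARABLE

    @pytest.mark.parametrize("country", ["PT", "DK"])
    def test_full_substitution_robust_under_interval_uncertainty(
        self, both_cases, country
    ):
        """+-25-point intervals on the three judgment-uncertain criteria
        (diet-related health, environment-related health, acceptance) leave
        100% substitution robustly preferred over every alternative."""
        study = both_cases[country]
        frame = partials_frame(study.printed_partials, study.model)
        box = dm.UncertaintyBox.symmetric(
            frame, ["diet_health", "env_health", "acceptance"], 25.0
        )
        rel = dm.robustness(study.model, frame, box)
        for other in ("75%", "50%", "25%", "0%"):
            assert rel[("100%", other)] >= Relation.ROBUSTLY_PREFERRED, (country, other)

    @pytest.mark.parametrize("seed", range(6))
    def test_vertex_formula_matches_exhaustive_enumeration(self, seed):
        model, frame, box, _ = _random_instance(seed)
        rel = dm.robustness(model, frame, box)
        lo, hi = box.bounds(frame)
        w = pd.Series(dict(model.weights.items()))
        for a in frame.index:
            for b in frame.index:
                if a == b:
                    continue
                vertex_min = float((w * (lo.loc[a] - hi.loc[b])).sum())
                brute = _brute_force_min_gap(model, frame, box, a, b)
                assert vertex_min == pytest.approx(brute, abs=1e-9)
                assert (rel[(a, b)] >= Relation.ROBUSTLY_PREFERRED) == (brute >= -1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_widening_never_upgrades_a_relation(self, seed):
        model, frame, box, widths = _random_instance(seed)
        wider = dm.UncertaintyBox(
            {
                (s, c): (lo - 5.0, hi + 5.0)
                for (s, c), (lo, hi) in box.intervals.items()
            }
        )
        rel = dm.robustness(model, frame, box)
        rel_wide = dm.robustness(model, frame, wider)
        for pair, r in rel.items():
            assert rel_wide[pair] <= r

    @pytest.mark.parametrize("seed", range(6))
    def test_relation_strength_implications(self, seed):
        """dominates => robustly_preferred => preferred on every instance."""
        model, frame, box, _ = _random_instance(seed)
        rel = dm.robustness(model, frame, box)
        lo, hi = box.bounds(frame)
        w = pd.Series(dict(model.weights.items()))
        nominal = global_scores(frame, model)
        for (a, b), r in rel.items():
            if r == Relation.DOMINATES:
                assert float((w * (lo.loc[a] - hi.loc[b])).sum()) >= -1e-9
            if r >= Relation.ROBUSTLY_PREFERRED:
                assert nominal[a] >= nominal[b] - 1e-9

    def test_box_must_contain_nominal_value(self, pt_case):
        frame = partials_frame(pt_case.printed_partials, pt_case.model)
        box = dm.UncertaintyBox({("100%", "diet_health"): (50.0, 60.0)})
        with pytest.raises(dm.DataError, match="excludes the nominal"):
            dm.robustness(pt_case.model, frame, box)

    def test_box_with_unknown_cell_errors(self, pt_case):
        frame = partials_frame(pt_case.printed_partials, pt_case.model)
        box = dm.UncertaintyBox({("200%", "diet_health"): (0.0, 1.0)})
        with pytest.raises(dm.DataError, match="unknown cell"):
            dm.robustness(pt_case.model, frame, box)

    def test_relation_matrix_export(self, pt_case):
        frame = partials_frame(pt_case.printed_partials, pt_case.model)
        rel = dm.robustness(pt_case.model, frame)
        mat = dm.relation_matrix(rel, list(frame.index))
        assert mat.shape == (5, 5)
        assert mat.at["100%", "0%"] in {"dominates", "robustly_preferred"}
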