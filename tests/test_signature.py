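"""Weight computation and the weighted n-gene combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcmap.grid import GridCell
from ihcmap.scoring import CellScore, IHCMap, PixelCounts
from ihcmap.signature import (
    GeneWeight,
    build_signature_map,
    compute_weights,
    region_summaries,
    signature_score,
)


def make_map(stain, values, region="3+3", mpp=2.5, offset=0):
    """IHCMap with the given per-cell scores laid out on one row."""
    cells, scores = {}, {}
    for i, v in enumerate(values):
        key = (0, i + offset)
        cells[key] = GridCell(0, i + offset, 100.0 * (i + offset), 0.0,
                              100.0 * (i + offset + 1), 100.0, region_label=region)
        empty = v is None
        scores[key] = CellScore(0, i + offset, PixelCounts(100, 0, 0, 0),
                                None if empty else float(v), empty=empty)
    return IHCMap(stain=stain, scores=scores, cells=cells, microns_per_pixel=mpp)


class TestComputeWeights:
    def test_single_stain_gets_magnitude_one(self):
        weights = compute_weights([make_map("ACPP", [0.37, 0.41])], {"ACPP": -1})
        assert weights[0].magnitude == 1.0
        assert weights[0].weight == -1.0

    def test_auto_reference_magnitudes(self):
        maps = [
            make_map("A", [0.40, 0.40]),
            make_map("B", [0.10, 0.10]),
            make_map("C", [0.02, 0.02]),
        ]
        weights = {w.stain: w for w in compute_weights(maps, {"A": 1, "B": 1, "C": 1})}
        assert weights["A"].magnitude == pytest.approx(1.0)
        assert weights["B"].magnitude == pytest.approx(4.0)
        assert weights["C"].magnitude == pytest.approx(20.0)

    def test_signs_applied(self):
        maps = [make_map("A", [0.4]), make_map("B", [0.1])]
        weights = {w.stain: w.weight for w in compute_weights(maps, {"A": -1, "B": +1})}
        assert weights == {"A": pytest.approx(-1.0), "B": pytest.approx(4.0)}

    def test_normalization_constant_across_stains(self, rng):
        """magnitude_i * m_i equals the reference mean for every stain (1e-12 rel)."""
        maps = [make_map(f"S{k}", rng.uniform(0.01, 0.9, 30)) for k in range(6)]
        means = {m.stain: np.mean([s.score for s in m.scores.values()]) for m in maps}
        weights = compute_weights(maps, {m.stain: 1 for m in maps})
        products = [w.magnitude * means[w.stain] for w in weights]
        assert np.allclose(products, products[0], rtol=1e-12)

    def test_zero_mean_stain_errors(self):
        maps = [make_map("A", [0.5]), make_map("B", [0.0])]
        with pytest.raises(ValueError, match="'B'"):
            compute_weights(maps, {"A": 1, "B": 1})

    def test_pooled_across_cases(self):
        # the same stain in two cases is pooled before the mean is taken
        maps = [make_map("A", [0.2]), make_map("A", [0.6]), make_map("B", [0.1])]
        weights = {w.stain: w for w in compute_weights(maps, {"A": 1, "B": 1})}
        assert weights["B"].magnitude == pytest.approx(0.4 / 0.1)


FOUR_GENE_WEIGHTS = [
    GeneWeight("ACPP", -1, 1.0),
    GeneWeight("CD34", +1, 19.0),
    GeneWeight("MKI67", +1, 4.0),
    GeneWeight("ENO2", +1, 4.0),
]


class TestSignatureScore:
    def test_cancellation(self):
        w = [GeneWeight("A", +1, 1.0), GeneWeight("B", -1, 1.0)]
        assert signature_score({"A": 0.3, "B": 0.3}, w) == pytest.approx(0.0)

    def test_four_gene_worked_value(self):
        """(-1.0, 19, 4, 4) . (0.50, 0.01, 0.02, 0.03) = -0.11"""
        scores = {"ACPP": 0.50, "CD34": 0.01, "MKI67": 0.02, "ENO2": 0.03}
        assert signature_score(scores, FOUR_GENE_WEIGHTS) == pytest.approx(-0.11, abs=1e-12)

    def test_missing_stain_raises(self):
        with pytest.raises(KeyError, match="ENO2"):
            signature_score({"ACPP": 0.5, "CD34": 0.1, "MKI67": 0.1}, FOUR_GENE_WEIGHTS)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4),
           st.floats(0.1, 5.0))
    def test_linearity_in_scores_and_weights(self, vals, c):
        scores = dict(zip(("ACPP", "CD34", "MKI67", "ENO2"), vals))
        s1 = signature_score(scores, FOUR_GENE_WEIGHTS)
        doubled = [GeneWeight(w.stain, w.sign, w.magnitude * c) for w in FOUR_GENE_WEIGHTS]
        assert signature_score(scores, doubled) == pytest.approx(c * s1, rel=1e-12, abs=1e-12)
        scaled = {k: v * c for k, v in scores.items()}
        assert signature_score(scaled, FOUR_GENE_WEIGHTS) == pytest.approx(c * s1, rel=1e-12, abs=1e-12)

    def test_permutation_invariance(self, rng):
        scores = {w.stain: float(rng.uniform()) for w in FOUR_GENE_WEIGHTS}
        shuffled = list(FOUR_GENE_WEIGHTS)
        rng.shuffle(shuffled)
        assert signature_score(scores, shuffled) == pytest.approx(
            signature_score(scores, FOUR_GENE_WEIGHTS)
        )


class TestBuildSignatureMap:
    def test_single_stain_weight_one_is_identity(self):
        m = make_map("A", [0.1, 0.2, 0.3])
        sig = build_signature_map([m], [GeneWeight("A", +1, 1.0)])
        assert {k: v for k, v in sig.scores.items()} == pytest.approx(
            {k: s.score for k, s in m.scores.items()}
        )

    def test_disjoint_nonempty_cells_warns_empty(self):
        a = make_map("A", [0.5, None])
        b = make_map("B", [None, 0.5])
        with pytest.warns(UserWarning, match="empty"):
            sig = build_signature_map([a, b], [GeneWeight("A", 1, 1.0), GeneWeight("B", 1, 1.0)])
        assert sig.scores == {}

    def test_stain_order_irrelevant(self, rng):
        a = make_map("A", rng.uniform(0, 1, 5))
        b = make_map("B", rng.uniform(0, 1, 5))
        w = [GeneWeight("A", 1, 2.0), GeneWeight("B", -1, 3.0)]
        s1 = build_signature_map([a, b], w).scores
        s2 = build_signature_map([b, a], w).scores
        assert s1 == pytest.approx(s2)

    def test_mismatched_grids_rejected(self):
        a = make_map("A", [0.5])
        b = make_map("B", [0.5], offset=3)
        with pytest.raises(ValueError, match="different grid"):
            build_signature_map([a, b], [GeneWeight("A", 1, 1.0), GeneWeight("B", 1, 1.0)])


class TestRegionSummaries:
    def test_single_cell_all_five_equal(self):
        sig = build_signature_map([make_map("A", [0.42])], [GeneWeight("A", 1, 1.0)])
        (summary,) = region_summaries(sig)
        assert summary.as_tuple() == (0.42, 0.42, 0.42, 0.42, 0.42)
        assert summary.n_cells == 1

    def test_values_one_to_five(self):
        sig = build_signature_map([make_map("A", [1, 2, 3, 4, 5])], [GeneWeight("A", 1, 1.0)])
        (summary,) = region_summaries(sig)
        assert summary.as_tuple() == (1, 2, 3, 4, 5)

    def test_order_invariant_and_sorted_stats(self, rng):
        vals = rng.uniform(-2, 2, 40)
        sig1 = build_signature_map([make_map("A", vals)], [GeneWeight("A", 1, 1.0)])
        sig2 = build_signature_map([make_map("A", vals[::-1])], [GeneWeight("A", 1, 1.0)])
        (s1,), (s2,) = region_summaries(sig1), region_summaries(sig2)
        assert s1.as_tuple() == pytest.approx(s2.as_tuple())
        assert s1.minimum <= s1.q1 <= s1.median <= s1.q3 <= s1.maximum
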